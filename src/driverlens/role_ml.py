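"""Random-forest role prediction and its evaluation statistics.

Genes are labeled OCG / TSG / neutral from a two-source gold standard
(a label requires agreement of both sources).  A random forest trained
on the gene x process Z-score matrix predicts class probabilities for
unlabeled genes.  Performance is measured by multi-class log loss,

    logloss = -(1/m) sum_i sum_j y_ij log p_ij,

and by one-vs-all AUC averaged over the OCG and TSG classes, under
leave-one-out cross-validation with the two majority classes
undersampled to the minority size, repeated with fresh undersampling
draws.  Significance comes from label randomization: the observed score
is compared against scores of models fit after randomly reassigning
gene identities to feature rows, counting (literally, so p may be 0)

    p_logloss = #{res_loo >= res_random_i} / n_random,
    p_auc     = #{res_loo <= res_random_i} / n_random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ConsistencyError, ParameterError
from .formats_io import GeneZMatrix, GoldStandardLists

log = logging.getLogger(__name__)

CLASSES = ("OCG", "TSG", "neutral")
P_CLIP = 1e-15


@dataclass
class RoleLabels:
    """gene -> class in {OCG, TSG, neutral}, with label provenance."""

    labels: pd.Series
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(CLASSES)
        if bad:
            raise ParameterError(f"unknown class label(s): {sorted(bad)}")

    def genes_of(self, cls: str) -> list[str]:
        return sorted(self.labels.index[self.labels == cls])

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in CLASSES}


@dataclass
class ClassProbabilities:
    """Per-gene class membership probabilities (rows sum to 1)."""

    probs: pd.DataFrame  # genes x CLASSES

    def __post_init__(self) -> None:
        self.probs = self.probs[list(CLASSES)]
        sums = self.probs.sum(axis=1).to_numpy()
        if len(sums) and np.any(np.abs(sums - 1.0) > 1e-9):
            raise ConsistencyError("class probabilities must sum to 1 per gene")


@dataclass
class EvaluationResult:
    """Cross-validated scores, averaged over undersampling repetitions."""

    logloss: float
    auc: float
    logloss_per_rep: list[float]
    auc_per_rep: list[float]
    params: dict = field(default_factory=dict)


def build_gold_standard(
    lists: GoldStandardLists, background: set[str]
) -> RoleLabels:
    """Two-source gold standard: OCG/TSG by intersection, dual excluded.

    OCG = source A OCG ∩ source B OCG; TSG likewise; genes on source A's
    dual list are excluded entirely; neutral = ``background`` minus all
    of the above.
    """
    ocg = (lists.source_a_ocg & lists.source_b_ocg) - lists.source_a_dual
    tsg = (lists.source_a_tsg & lists.source_b_tsg) - lists.source_a_dual
    conflict = ocg & tsg
    if conflict:
        raise ConsistencyError(
            f"gene(s) in both intersected OCG and TSG sets: {sorted(conflict)}"
        )
    neutral = set(background) - ocg - tsg - lists.source_a_dual
    labels = pd.Series(
        {**{g: "OCG" for g in ocg}, **{g: "TSG" for g in tsg}, **{g: "neutral" for g in neutral}}
    )
    provenance = {
        **{g: ["source_a_ocg", "source_b_ocg"] for g in ocg},
        **{g: ["source_a_tsg", "source_b_tsg"] for g in tsg},
        **{g: ["background"] for g in neutral},
    }
    return RoleLabels(labels.sort_index(), provenance)


def log_loss(probs: ClassProbabilities, truth: RoleLabels) -> float:
    """Multi-class log loss over the truth genes (natural log).

    Probabilities are clipped to [1e-15, 1] before the log.
    """
    missing = [g for g in truth.labels.index if g not in probs.probs.index]
    if missing:
        raise ConsistencyError(f"genes lacking a probability row: {missing[:5]}")
    p = probs.probs.loc[truth.labels.index]
    total = 0.0
    for cls in CLASSES:
        mask = (truth.labels == cls).to_numpy()
        if mask.any():
            total += np.sum(np.log(np.clip(p[cls].to_numpy()[mask], P_CLIP, 1.0)))
    return float(-total / len(truth.labels))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5."""
    n_pos = int(positive.sum())
    n_neg = int(len(positive) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs >= 1 positive and >= 1 negative")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_one_vs_all(probs: ClassProbabilities, truth: RoleLabels) -> float:
    """Mean of OCG-vs-rest and TSG-vs-rest AUC, scored by class probability."""
    missing = [g for g in truth.labels.index if g not in probs.probs.index]
    if missing:
        raise ConsistencyError(f"genes lacking a probability row: {missing[:5]}")
    p = probs.probs.loc[truth.labels.index]
    aucs = []
    for cls in ("OCG", "TSG"):
        positive = (truth.labels == cls).to_numpy()
        aucs.append(_binary_auc(p[cls].to_numpy(), positive))
    return float(np.mean(aucs))


def _features(zmat: GeneZMatrix, genes: list[str]) -> pd.DataFrame:
    """Z-score features for the given genes, missing entries imputed as 0."""
    return zmat.z.loc[genes].fillna(0.0)


def _undersample(labels: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Draw each class down (without replacement) to the minority size."""
    sizes = {c: int((labels == c).sum()) for c in CLASSES}
    if min(sizes.values()) == 0:
        raise ParameterError(f"every class must be nonempty; got {sizes}")
    m = min(sizes.values())
    keep: list[str] = []
    for c in CLASSES:
        genes = sorted(labels.index[labels == c])
        keep.extend(
            genes if len(genes) == m else list(rng.choice(genes, size=m, replace=False))
        )
    return labels.loc[sorted(keep)]


def _fit_forest(x: pd.DataFrame, y: pd.Series, seed: int, n_estimators: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(x.to_numpy(), y.to_numpy())
    return clf


def _proba_frame(clf: RandomForestClassifier, x: np.ndarray, index) -> pd.DataFrame:
    raw = clf.predict_proba(x)
    out = pd.DataFrame(0.0, index=index, columns=list(CLASSES))
    for j, cls in enumerate(clf.classes_):
        out[cls] = raw[:, j]
    return out


def _loo_once(
    feats: pd.DataFrame, labels: pd.Series, rng: np.random.Generator, n_estimators: int
) -> tuple[float, float]:
    """One undersampling draw + full leave-one-out pass; returns (logloss, auc)."""
    sub = _undersample(labels, rng)
    genes = list(sub.index)
    x = feats.loc[genes]
    rows = []
    for g in genes:
        train = [t for t in genes if t != g]
        clf = _fit_forest(
            x.loc[train], sub.loc[train], seed=int(rng.integers(2**31)), n_estimators=n_estimators
        )
        rows.append(_proba_frame(clf, x.loc[[g]].to_numpy(), [g]))
    probs = ClassProbabilities(pd.concat(rows))
    truth = RoleLabels(sub)
    return log_loss(probs, truth), auc_one_vs_all(probs, truth)


def loo_evaluate(
    zmat: GeneZMatrix,
    labels: RoleLabels,
    repetitions: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
) -> EvaluationResult:
    """Leave-one-out evaluation with repeated majority-class undersampling.

    Each repetition undersamples the majority classes to the minority
    size, predicts every retained gene from a forest trained on the
    others, and scores the held-out predictions; log loss and AUC are
    averaged over repetitions.
    """
    genes = [g for g in labels.labels.index if g in zmat.z.index]
    dropped = len(labels.labels) - len(genes)
    if dropped:
        log.info("%d labeled genes absent from the Z matrix; dropped", dropped)
    lab = labels.labels.loc[genes]
    sizes = {c: int((lab == c).sum()) for c in CLASSES}
    if min(sizes.values()) < 5:
        raise ParameterError(f"need >= 5 genes per class; got {sizes}")
    feats = _features(zmat, genes)
    rng = np.random.default_rng(seed)
    ll, auc = [], []
    for _ in range(repetitions):
        l_, a_ = _loo_once(feats, lab, rng, n_estimators)
        ll.append(l_)
        auc.append(a_)
    return EvaluationResult(
        logloss=float(np.mean(ll)),
        auc=float(np.mean(auc)),
        logloss_per_rep=ll,
        auc_per_rep=auc,
        params=dict(repetitions=repetitions, seed=seed, n_estimators=n_estimators),
    )


def randomization_p_from_scores(
    res_loo: float, res_random, metric: str = "logloss"
) -> float:
    """Literal randomization count: #{observed at least as bad as random}
    over the number of randomizations (>= for log loss, <= for AUC)."""
    if metric not in ("logloss", "auc"):
        raise ParameterError(f"unknown metric {metric!r}")
    res_random = np.asarray(res_random, dtype=float)
    if res_random.size == 0:
        raise ParameterError("need >= 1 randomized score")
    if metric == "logloss":
        return float(np.count_nonzero(res_loo >= res_random) / res_random.size)
    return float(np.count_nonzero(res_loo <= res_random) / res_random.size)


def randomization_p(
    res_loo: float,
    zmat: GeneZMatrix,
    labels: RoleLabels,
    metric: str = "logloss",
    n_random: int = 100,
    seed: int = 0,
    n_estimators: int = 500,
) -> float:
    """Label-randomization p-value for an observed cross-validated score.

    Gene identities are randomly reassigned to feature rows ``n_random``
    times; the metric is recomputed for each randomization, and the p is
    the literal fraction of randomizations at least as good as (log
    loss) or no worse than (AUC) the observed score, so p may be 0.
    """
    if metric not in ("logloss", "auc"):
        raise ParameterError(f"unknown metric {metric!r}")
    if n_random < 1:
        raise ParameterError("n_random must be >= 1")
    genes = [g for g in labels.labels.index if g in zmat.z.index]
    lab = labels.labels.loc[genes]
    feats = _features(zmat, genes)
    rng = np.random.default_rng(seed)
    res_random = []
    for _ in range(n_random):
        shuffled = pd.Series(
            rng.permutation(lab.to_numpy()), index=lab.index
        )
        ll, auc = _loo_once(feats, shuffled, rng, n_estimators)
        res_random.append(ll if metric == "logloss" else auc)
    return randomization_p_from_scores(res_loo, res_random, metric)


def predict_roles_ml(
    zmat: GeneZMatrix,
    labels: RoleLabels,
    unlabeled: set[str],
    seed: int = 0,
    n_estimators: int = 500,
    undersample: bool = True,
) -> tuple[ClassProbabilities, pd.Series, pd.Series]:
    """Train on all labeled genes and predict roles for unlabeled genes.

    Returns (probabilities, hard calls by argmax, per-process feature
    importances summing to 1).  Unlabeled genes absent from the Z matrix
    are skipped with a log entry.
    """
    genes = [g for g in labels.labels.index if g in zmat.z.index]
    lab = labels.labels.loc[genes]
    rng = np.random.default_rng(seed)
    if undersample:
        lab = _undersample(lab, rng)
    feats = _features(zmat, list(lab.index))
    clf = _fit_forest(feats, lab, seed=int(rng.integers(2**31)), n_estimators=n_estimators)
    importances = pd.Series(clf.feature_importances_, index=zmat.z.columns)
    present = [g for g in sorted(unlabeled) if g in zmat.z.index]
    for g in sorted(set(unlabeled) - set(present)):
        log.info("unlabeled gene %r absent from the Z matrix; skipped", g)
    if present:
        probs = ClassProbabilities(
            _proba_frame(clf, _features(zmat, present).to_numpy(), present)
        )
        calls = probs.probs.idxmax(axis=1)
    else:
        probs = ClassProbabilities(pd.DataFrame(columns=list(CLASSES), dtype=float))
        calls = pd.Series(dtype=object)
    return probs, calls, importances
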