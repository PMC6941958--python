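"""Gold-standard assembly, evaluation metrics, and forest prediction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from driverlens import role_ml
from driverlens.errors import ConsistencyError, ParameterError
from driverlens.formats_io import GoldStandardLists
from driverlens.simulate import simulate_zmatrix


def probs_of(rows: dict[str, tuple[float, float, float]]) -> role_ml.ClassProbabilities:
    return role_ml.ClassProbabilities(
        pd.DataFrame(rows, index=list(role_ml.CLASSES)).T
    )


def labels_of(mapping: dict[str, str]) -> role_ml.RoleLabels:
    return role_ml.RoleLabels(pd.Series(mapping))


class TestGoldStandard:
    def _lists(self, **overrides):
        base = dict(
            source_a_ocg={"MYC", "KRAS", "ONLYA"},
            source_a_tsg={"TP53", "RB1"},
            source_a_dual={"NOTCH1"},
            source_b_ocg={"MYC", "KRAS", "NOTCH1"},
            source_b_tsg={"TP53", "ONLYB"},
        )
        base.update(overrides)
        return GoldStandardLists(**base)

    def test_two_source_intersection(self):
        labels = role_ml.build_gold_standard(self._lists(), background={"BG1", "BG2"})
        assert set(labels.genes_of("OCG")) == {"MYC", "KRAS"}
        assert set(labels.genes_of("TSG")) == {"TP53"}

    def test_single_source_gene_not_driver_labeled(self):
        labels = role_ml.build_gold_standard(self._lists(), background={"ONLYA"})
        assert "ONLYA" not in labels.genes_of("OCG")

    def test_dual_genes_excluded_entirely(self):
        labels = role_ml.build_gold_standard(self._lists(), background={"NOTCH1", "BG"})
        assert "NOTCH1" not in labels.labels.index

    def test_overlapping_source_lists_rejected_at_construction(self):
        with pytest.raises(ConsistencyError, match="GX"):
            self._lists(source_a_ocg={"GX"}, source_a_tsg={"GX", "TP53"})

    def test_conflicting_gene_rejected(self):
        # bypass list validation to exercise the defensive conflict check
        lists = GoldStandardLists.__new__(GoldStandardLists)
        lists.source_a_ocg = {"GX"}
        lists.source_a_tsg = {"GX"}
        lists.source_a_dual = set()
        lists.source_b_ocg = {"GX"}
        lists.source_b_tsg = {"GX"}
        with pytest.raises(ConsistencyError, match="GX"):
            role_ml.build_gold_standard(lists, background=set())


class TestLogLoss:
    def test_uniform_is_ln3(self):
        p = probs_of({g: (1 / 3, 1 / 3, 1 / 3) for g in "abc"})
        truth = labels_of({"a": "OCG", "b": "TSG", "c": "neutral"})
        assert role_ml.log_loss(p, truth) == pytest.approx(math.log(3), abs=1e-12)

    def test_perfect_is_zero(self):
        p = probs_of({"a": (1.0, 0.0, 0.0), "b": (0.0, 1.0, 0.0)})
        truth = labels_of({"a": "OCG", "b": "TSG"})
        assert role_ml.log_loss(p, truth) == 0.0

    def test_half_probability_is_ln2(self):
        p = probs_of({"a": (0.5, 0.25, 0.25)})
        assert role_ml.log_loss(p, labels_of({"a": "OCG"})) == pytest.approx(math.log(2))

    def test_missing_row_rejected(self):
        p = probs_of({"a": (1.0, 0.0, 0.0)})
        with pytest.raises(ConsistencyError):
            role_ml.log_loss(p, labels_of({"a": "OCG", "zzz": "TSG"}))

    def test_matches_hand_expanded_sum_on_grid(self):
        grid = [0.05, 0.3, 0.65]
        classes = list(role_ml.CLASSES)
        for p_rows in itertools.product(itertools.permutations(grid), repeat=3):
            for truths in itertools.product(classes, repeat=3):
                p = probs_of({f"g{i}": tuple(p_rows[i]) for i in range(3)})
                truth = labels_of({f"g{i}": truths[i] for i in range(3)})
                expected = -np.mean(
                    [
                        math.log(p_rows[i][classes.index(truths[i])])
                        for i in range(3)
                    ]
                )
                assert role_ml.log_loss(p, truth) == pytest.approx(expected, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        p = probs_of(
            {"a": (0.8, 0.1, 0.1), "b": (0.1, 0.8, 0.1), "c": (0.1, 0.1, 0.8)}
        )
        truth = labels_of({"a": "OCG", "b": "TSG", "c": "neutral"})
        assert role_ml.auc_one_vs_all(p, truth) == 1.0

    def test_identical_scores_give_half(self):
        p = probs_of({g: (1 / 3, 1 / 3, 1 / 3) for g in "abcd"})
        truth = labels_of({"a": "OCG", "b": "TSG", "c": "neutral", "d": "neutral"})
        assert role_ml.auc_one_vs_all(p, truth) == 0.5

    def test_matches_pair_counting_oracle(self):
        p = probs_of(
            {
                "a": (0.7, 0.2, 0.1),
                "b": (0.4, 0.3, 0.3),
                "c": (0.5, 0.25, 0.25),
                "d": (0.2, 0.5, 0.3),
            }
        )
        truth = labels_of({"a": "OCG", "b": "neutral", "c": "OCG", "d": "TSG"})

        def pair_auc(scores, pos):
            wins = ties = 0
            for i in pos:
                for j in set(scores) - set(pos):
                    if scores[i] > scores[j]:
                        wins += 1
                    elif scores[i] == scores[j]:
                        ties += 1
            return (wins + 0.5 * ties) / (len(pos) * (len(scores) - len(pos)))

        ocg_scores = dict(zip("abcd", p.probs["OCG"]))
        tsg_scores = dict(zip("abcd", p.probs["TSG"]))
        expected = (pair_auc(ocg_scores, ["a", "c"]) + pair_auc(tsg_scores, ["d"])) / 2
        assert role_ml.auc_one_vs_all(p, truth) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        raw = rng.uniform(0.05, 0.9, size=(10, 3))
        raw /= raw.sum(axis=1, keepdims=True)
        genes = [f"g{i}" for i in range(10)]
        p1 = role_ml.ClassProbabilities(
            pd.DataFrame(raw, index=genes, columns=list(role_ml.CLASSES))
        )
        truth = labels_of(
            {g: ["OCG", "TSG", "neutral"][i % 3] for i, g in enumerate(genes)}
        )
        a1 = role_ml.auc_one_vs_all(p1, truth)
        # strictly monotone per-column transform of the scores
        p2 = role_ml.ClassProbabilities.__new__(role_ml.ClassProbabilities)
        p2.probs = np.exp(5 * p1.probs)
        assert role_ml.auc_one_vs_all(p2, truth) == pytest.approx(a1)

    def test_empty_class_rejected(self):
        p = probs_of({"a": (0.5, 0.3, 0.2), "b": (0.2, 0.5, 0.3)})
        with pytest.raises(ParameterError):
            role_ml.auc_one_vs_all(p, labels_of({"a": "OCG", "b": "OCG"}))


class TestRandomizationCounting:
    def test_observed_better_than_all(self):
        assert role_ml.randomization_p_from_scores(0.1, np.full(100, 0.9), "logloss") == 0.0

    def test_observed_worse_than_all(self):
        assert role_ml.randomization_p_from_scores(2.0, np.full(100, 0.9), "logloss") == 1.0

    def test_five_of_hundred(self):
        rand = np.concatenate([np.full(5, 0.1), np.full(95, 0.9)])
        assert role_ml.randomization_p_from_scores(0.5, rand, "logloss") == pytest.approx(0.05)

    def test_auc_direction(self):
        assert role_ml.randomization_p_from_scores(0.95, np.full(10, 0.5), "auc") == 0.0
        assert role_ml.randomization_p_from_scores(0.5, np.full(10, 0.5), "auc") == 1.0

    def test_unknown_metric(self):
        with pytest.raises(ParameterError):
            role_ml.randomization_p_from_scores(0.5, [0.1], "accuracy")


class TestLooEvaluate:
    def test_determinism(self):
        zmat, labels = simulate_zmatrix(n_per_class=6, seed=3)
        a = role_ml.loo_evaluate(zmat, labels, repetitions=2, seed=4, n_estimators=20)
        b = role_ml.loo_evaluate(zmat, labels, repetitions=2, seed=4, n_estimators=20)
        assert a == b

    def test_separable_classes_scored_highly(self):
        zmat, labels = simulate_zmatrix(n_per_class=8, class_separation=3.0, noise_sd=0.5, seed=5)
        res = role_ml.loo_evaluate(zmat, labels, repetitions=2, seed=6, n_estimators=50)
        assert res.auc >= 0.9
        assert res.logloss < math.log(3)

    def test_too_small_class_rejected(self):
        zmat, labels = simulate_zmatrix(n_per_class=4, seed=7)
        with pytest.raises(ParameterError):
            role_ml.loo_evaluate(zmat, labels, repetitions=1, seed=0, n_estimators=10)


class TestPredict:
    def test_centroid_gene_called_ocg(self):
        zmat, labels = simulate_zmatrix(n_per_class=10, class_separation=3.0, noise_sd=0.5, seed=8)
        # plant an unlabeled gene exactly at the OCG centroid
        centroid = zmat.z.loc[labels.genes_of("OCG")].mean()
        zmat.z.loc["novel"] = centroid
        zmat.n_support.loc["novel"] = 9
        probs, calls, importances = role_ml.predict_roles_ml(
            zmat, labels, {"novel"}, seed=9, n_estimators=100
        )
        assert calls["novel"] == "OCG"
        assert probs.probs.loc["novel", "OCG"] > 1 / 3
        assert importances.sum() == pytest.approx(1.0, abs=1e-9)
        # the two informative processes carry most of the signal
        assert importances[["proliferation", "apoptosis"]].sum() > 0.5

    def test_empty_unlabeled_still_reports_importances(self):
        zmat, labels = simulate_zmatrix(n_per_class=6, seed=10)
        probs, calls, importances = role_ml.predict_roles_ml(
            zmat, labels, set(), seed=11, n_estimators=20
        )
        assert len(probs.probs) == 0
        assert len(calls) == 0
        assert importances.sum() == pytest.approx(1.0, abs=1e-9)
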