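"""Seeded synthetic data with planted ground truth for every stage.

``simulate_dataset`` emulates a two-condition (normal vs tumor) RNA-seq
count experiment: counts are Poisson draws around lognormal rates
(log2-scale gene baselines plus Gaussian sample noise), planted driver
genes are shifted by ``effect_logfc`` in the tumor group (oncogenes up,
tumor suppressors down), and each driver's targets track its latent
log2 level linearly — in the tumor group only — so regulons are
recoverable by mutual information.  A minimal two-process knowledge
base (one cancer-promoting growth process, one cancer-reducing death
process) assigns each target the literature direction that makes the
planted role patterns hold at infinite sample size.

``simulate_zmatrix`` skips the pipeline and directly draws a gene x
process Z-score matrix with class-separated means, as a test harness
for the role classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .formats_io import ExpressionMatrix, GeneZMatrix, ProcessKnowledge
from .role_ml import RoleLabels

GROWTH_PROCESS = "proliferation"
DEATH_PROCESS = "apoptosis"


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter record of one simulated dataset."""

    planted_degs: dict[str, float]  # gene -> true tumor-vs-normal log2 FC
    planted_modules: dict[str, dict[str, float]]  # regulator -> target -> signed strength
    planted_roles: dict[str, str]  # gene -> OCG / TSG / neutral
    params: dict = field(default_factory=dict)

    def regenerate(self):
        """Re-run the generator from the recorded parameters (bit-for-bit)."""
        return simulate_dataset(**self.params)


def simulate_dataset(
    n_genes: int = 200,
    n_samples_per_group: int = 40,
    n_ocg: int = 10,
    n_tsg: int = 10,
    targets_per_regulator: int = 8,
    effect_logfc: float = 2.0,
    dependence_strength: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ProcessKnowledge, SyntheticTruth]:
    """Generate counts, knowledge base, and ground truth.

    Layout: the first ``n_ocg`` genes are planted oncogenes (shifted up
    by ``effect_logfc`` log2 units in the tumor group), the next
    ``n_tsg`` planted tumor suppressors (shifted down), each followed by
    ``targets_per_regulator`` dedicated targets whose tumor-group log2
    level is ``±dependence_strength`` times the regulator's latent
    level plus noise (half the targets with negative dependence).
    Remaining genes are neutral background.
    """
    params = dict(
        n_genes=n_genes,
        n_samples_per_group=n_samples_per_group,
        n_ocg=n_ocg,
        n_tsg=n_tsg,
        targets_per_regulator=targets_per_regulator,
        effect_logfc=effect_logfc,
        dependence_strength=dependence_strength,
        noise_sd=noise_sd,
        seed=seed,
    )
    n_reg = n_ocg + n_tsg
    needed = n_reg * (1 + targets_per_regulator)
    if needed > n_genes:
        raise ParameterError(
            f"layout needs {needed} genes (regulators + targets) but n_genes={n_genes}"
        )
    if n_samples_per_group < 2:
        raise ParameterError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    regulators = genes[:n_reg]
    reg_sign = {g: (1.0 if i < n_ocg else -1.0) for i, g in enumerate(regulators)}
    roles = {g: ("OCG" if reg_sign[g] > 0 else "TSG") for g in regulators}
    modules: dict[str, dict[str, float]] = {}
    pos = n_reg
    for r in regulators:
        targets = genes[pos : pos + targets_per_regulator]
        pos += targets_per_regulator
        signs = np.ones(targets_per_regulator)
        signs[targets_per_regulator // 2 :] = -1.0
        modules[r] = {t: float(s * dependence_strength) for t, s in zip(targets, signs)}
    background = genes[pos:]
    for g in genes:
        roles.setdefault(g, "neutral")

    # Baselines high enough that Poisson count noise (sd ~ 1/(ln2 sqrt(rate))
    # on the log2 scale) stays subordinate to the latent noise_sd even for
    # genes shifted down by effect_logfc (rate >= 2^6 -> sd <= 0.18), as for
    # expression-filtered genes in real data.
    baseline = rng.uniform(6.0 + abs(effect_logfc), 13.0, size=n_genes)
    base = {g: baseline[i] for i, g in enumerate(genes)}

    n = n_samples_per_group
    samples = [f"N{i:03d}" for i in range(n)] + [f"T{i:03d}" for i in range(n)]
    condition_map = {s: ("normal" if s.startswith("N") else "tumor") for s in samples}

    log2_rate = np.empty((n_genes, 2 * n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    # normal group: independent noise around baselines
    log2_rate[:, :n] = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n))
    # tumor group: planted shifts and regulator-driven targets
    dev = np.empty((n_genes, n))
    for g in genes:
        i = gene_pos[g]
        if g in reg_sign:
            dev[i] = rng.normal(reg_sign[g] * effect_logfc, noise_sd, size=n)
        else:
            dev[i] = rng.normal(0.0, noise_sd, size=n)
    for r, targets in modules.items():
        zr = dev[gene_pos[r]]
        for t, strength in targets.items():
            dev[gene_pos[t]] = strength * zr + rng.normal(0.0, noise_sd, size=n)
    log2_rate[:, n:] = baseline[:, None] + dev

    counts = rng.poisson(np.exp2(log2_rate)).astype(float)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), condition_map, counts=True
    )

    planted_degs: dict[str, float] = {}
    for r in regulators:
        planted_degs[r] = reg_sign[r] * effect_logfc
        for t, strength in modules[r].items():
            planted_degs[t] = strength * reg_sign[r] * effect_logfc

    # knowledge: targets get the direction that makes the planted pattern hold
    entries = []
    for r in regulators:
        for t, strength in modules[r].items():
            growth_dir = "Increased" if strength > 0 else "Decreased"
            death_dir = "Decreased" if strength > 0 else "Increased"
            entries.append((t, GROWTH_PROCESS, growth_dir, int(rng.integers(1, 50))))
            entries.append((t, DEATH_PROCESS, death_dir, int(rng.integers(1, 50))))
    n_affected = int(0.3 * len(background))
    if n_affected:
        for g in rng.choice(background, size=n_affected, replace=False):
            entries.append((str(g), GROWTH_PROCESS, "Affected", int(rng.integers(1, 10))))
            entries.append((str(g), DEATH_PROCESS, "Affected", int(rng.integers(1, 10))))
    knowledge = ProcessKnowledge(
        pd.DataFrame(entries, columns=["gene", "process", "direction", "publication_count"]),
        {GROWTH_PROCESS: "promotes_cancer", DEATH_PROCESS: "reduces_cancer"},
    )
    truth = SyntheticTruth(planted_degs, modules, roles, params)
    return expr, knowledge, truth


def simulate_zmatrix(
    n_per_class: int = 20,
    class_separation: float = 2.0,
    noise_sd: float = 0.5,
    n_processes: int = 10,
    seed: int = 0,
    require_separable: bool = False,
) -> tuple[GeneZMatrix, RoleLabels]:
    """Class-conditional Gaussian Z-score features with known roles.

    Oncogenes mean +``class_separation`` on the growth process and
    -``class_separation`` on the death process, tumor suppressors the
    mirror image, neutral genes zero everywhere; all other processes are
    pure noise.  Support counts are set per entry so |z| <= sqrt(n)
    always holds.
    """
    if n_processes < 2:
        raise ParameterError("need >= 2 processes")
    if require_separable and class_separation <= 0:
        raise ParameterError("separability requested but class_separation <= 0")
    rng = np.random.default_rng(seed)
    processes = [GROWTH_PROCESS, DEATH_PROCESS] + [
        f"bp_{i:02d}" for i in range(2, n_processes)
    ]
    genes, labels, means = [], [], []
    for cls, g_mean, d_mean in (
        ("OCG", class_separation, -class_separation),
        ("TSG", -class_separation, class_separation),
        ("neutral", 0.0, 0.0),
    ):
        for i in range(n_per_class):
            genes.append(f"{cls}{i:03d}")
            labels.append(cls)
            means.append([g_mean, d_mean] + [0.0] * (n_processes - 2))
    z = np.asarray(means) + rng.normal(0.0, noise_sd, size=(len(genes), n_processes))
    n_support = np.ceil(z**2).astype(int) + 1
    idx = pd.Index(genes, name="gene")
    zmat = GeneZMatrix(
        pd.DataFrame(z, index=idx, columns=processes),
        pd.DataFrame(n_support, index=idx, columns=processes),
    )
    return zmat, RoleLabels(pd.Series(labels, index=idx))
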