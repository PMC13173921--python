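"""Synthetic cohort-pair generator with injected platform shift.

Real multi-cohort whole-blood studies show samples clustering by cohort
and assay platform rather than by disease status. This generator
reproduces that structure on demand: a training cohort of RNA-seq-like
negative-binomial counts and a test cohort of microarray-like log2
intensities share the same underlying disease signal, but the test cohort
is distorted by a disease-independent platform shift — per-gene affine
jitter on the log2 scale plus an optional global monotone compression
(x → x^0.8 on the linear scale, i.e. a 0.8 slope on log2 values),
mimicking an RNA-seq → array transfer.

The shared signal model for gene g in group d is

    s_g(d) = log2(mu_g · 2^(±e_g · [d = disease] + λ_g c_j) + 1)

with baselines mu_g log-normal(ln 100, 1), log2 effect sizes e_g drawn
around ``effect_mean``, and a per-sample latent factor c_j ~ N(0, 1) with
per-gene loadings λ_g ~ N(0, loading_sd) emulating the cell-type
composition variability that dominates whole-blood covariance (and keeps
disease and control overlapping in the leading principal components, as
real cohorts do). DE genes load on this factor in their effect
direction — disease markers in blood are largely immune-cell-fraction
markers — making composition variation common-mode noise along the
signal axis and capping transfer performance realistically. Training
counts are NB with dispersion 0.3 — the heterogeneity of unrelated human
subjects, not technical replicates — times a per-sample depth factor;
test intensities are s_g plus Gaussian noise (SD 0.8). The additive +1
floor (array background when a platform shift is active) matches the
pseudocount of the
count transform, so with the platform shift switched off the two cohorts
land on the same feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import ExpressionMatrix, PhenotypeTable, ValidationError


@dataclass
class PlatformShift:
    """Disease-independent per-gene affine jitter + optional monotone warp.

    scale_sd / offset_sd are the SDs of the per-gene multiplicative slope
    (around 1, clipped to ≥ 0.2) and additive offset on the log2 scale;
    warp applies the global x → x^0.8 linear-scale compression. Per-gene
    offsets default to 3 log2 units: absolute per-gene levels are
    essentially incomparable between sequencing counts and array
    fluorescence, where probe affinities vary by orders of magnitude.
    background is the array detection floor on the linear scale:
    transcripts below it drown in hybridization background, so the array
    carries no usable signal for them even though the sequencing cohort
    quantifies them — at the default (the median baseline) roughly half
    the genes, matching typical array present-call rates.
    """

    scale_sd: float = 0.3
    offset_sd: float = 3.0
    warp: bool = True
    background: float = 100.0

    def __post_init__(self) -> None:
        if self.scale_sd < 0 or self.offset_sd < 0 or self.background < 0:
            raise ValidationError("shift SDs and background must be >= 0")


@dataclass
class SimTruth:
    """Everything the generator decided, for downstream verification."""

    de_genes_up: list[str]
    de_genes_down: list[str]
    effect_sizes: dict[str, float]  # per-DE-gene log2 shift (signed)
    baselines: dict[str, float]  # linear-scale mean per gene
    platform_shift: PlatformShift | None
    noise_sd: float
    nb_dispersion: float
    loading_sd: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.de_genes_up) & set(self.de_genes_down):
            raise ValidationError("up/down DE genes must be disjoint")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = m + dispersion·m²; Poisson limit at dispersion 0."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort_pair(
    n_genes: int = 2000,
    n_train: tuple[int, int] = (60, 60),
    n_test: tuple[int, int] = (40, 40),
    n_de: tuple[int, int] = (100, 100),
    effect_mean: float = 1.0,
    platform_shift: PlatformShift | None = PlatformShift(),
    noise_sd: float = 0.8,
    nb_dispersion: float = 0.3,
    loading_sd: float = 0.4,
    comp_coupling: float = 0.4,
    depth_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypeTable, ExpressionMatrix, PhenotypeTable, SimTruth]:
    """Paired train (counts) / test (log2 intensities) cohorts + ground truth.

    ``n_train``/``n_test`` are (disease, control) counts; ``n_de`` the
    number of (up, down) genes. Effect sizes are ``effect_mean`` times a
    Uniform(0.5, 1.5) draw (all exactly zero when ``effect_mean = 0``).
    DE genes are spread evenly across the baseline-expression range so a
    downstream IQR filter cannot silently remove the whole signal. The
    latent composition factor is drawn per subject independently in each
    cohort; its per-gene loadings are a gene property shared by both.
    Deterministic given ``seed``.
    """
    if min(n_train) <= 0 or min(n_test) <= 0 or n_genes <= 0:
        raise ValidationError("sample and gene counts must be positive")
    n_up, n_down = n_de
    if n_up + n_down > n_genes:
        raise ValidationError("more DE genes than genes")

    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    mu = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))

    # evenly spaced across the sorted baseline range, then split up/down
    order = np.argsort(mu)
    slots = np.linspace(0, n_genes - 1, n_up + n_down).round().astype(int)
    de_idx = order[np.unique(slots)]
    while de_idx.size < n_up + n_down:  # collisions at tiny n_genes
        extra = np.setdiff1d(order, de_idx)[:1]
        de_idx = np.append(de_idx, extra)
    de_idx = rng.permutation(de_idx)
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up : n_up + n_down]

    effect = np.zeros(n_genes)
    magnitudes = effect_mean * rng.uniform(0.5, 1.5, size=n_up + n_down)
    effect[up_idx] = magnitudes[:n_up]
    effect[down_idx] = -magnitudes[n_up:]

    # guard: DE genes must span the expression range, not hide in one tail
    if n_up + n_down >= 10:
        ranks = np.argsort(np.argsort(mu))[np.concatenate([up_idx, down_idx])]
        assert ranks.min() < n_genes * 0.2 and ranks.max() > n_genes * 0.8

    # per-gene loadings of the latent composition factor (gene property).
    # DE genes load in their effect direction: whole-blood disease markers
    # are largely immune-cell-fraction markers, so healthy between-subject
    # composition variation is common-mode noise along the signal axis —
    # the realistic ceiling on cohort-transfer performance.
    loadings = rng.normal(0.0, loading_sd, size=n_genes)
    sign = np.sign(effect)
    de_mask = sign != 0
    loadings[de_mask] = (
        comp_coupling * sign[de_mask]
        * np.abs(rng.normal(1.0, 0.3, size=int(de_mask.sum())))
    )

    # ---- training cohort: NB counts ---------------------------------
    n_dz, n_ct = n_train
    train_labels = ["disease"] * n_dz + ["control"] * n_ct
    train_ids = [f"tr{j + 1:03d}" for j in range(n_dz + n_ct)]
    depth = np.exp(rng.normal(0.0, depth_sd, size=n_dz + n_ct))
    is_dz = np.array([lab == "disease" for lab in train_labels])
    comp_train = rng.normal(0.0, 1.0, size=n_dz + n_ct)  # latent factor per subject
    log2_mean = (
        effect[:, None] * is_dz[None, :] + loadings[:, None] * comp_train[None, :]
    )
    mean_mat = mu[:, None] * 2.0**log2_mean * depth[None, :]
    counts = _nb_draw(rng, mean_mat, nb_dispersion).astype(float)
    train_m = ExpressionMatrix(genes, train_ids, counts, "counts", "rnaseq_synthetic")
    train_p = PhenotypeTable(train_ids, train_labels)

    # ---- test cohort: log2 intensities from the same signal model ----
    n_dz_t, n_ct_t = n_test
    test_labels = ["disease"] * n_dz_t + ["control"] * n_ct_t
    test_ids = [f"te{j + 1:03d}" for j in range(n_dz_t + n_ct_t)]
    is_dz_t = np.array([lab == "disease" for lab in test_labels])
    comp_test = rng.normal(0.0, 1.0, size=n_dz_t + n_ct_t)
    log2_mean_t = (
        effect[:, None] * is_dz_t[None, :] + loadings[:, None] * comp_test[None, :]
    )
    floor = 1.0 if platform_shift is None else max(platform_shift.background, 1.0)
    signal = np.log2(mu[:, None] * 2.0**log2_mean_t + floor)
    y = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if platform_shift is not None:
        if platform_shift.warp:
            y = 0.8 * y  # x -> x^0.8 on the linear scale
        a = np.clip(rng.normal(1.0, platform_shift.scale_sd, size=n_genes), 0.2, None)
        b = rng.normal(0.0, platform_shift.offset_sd, size=n_genes)
        y = a[:, None] * y + b[:, None]
    test_m = ExpressionMatrix(genes, test_ids, y, "log2_intensity", "array_synthetic")
    test_p = PhenotypeTable(test_ids, test_labels)

    truth = SimTruth(
        de_genes_up=[genes[i] for i in up_idx],
        de_genes_down=[genes[i] for i in down_idx],
        effect_sizes={genes[i]: float(effect[i]) for i in np.concatenate([up_idx, down_idx])},
        baselines={g: float(v) for g, v in zip(genes, mu)},
        platform_shift=platform_shift,
        noise_sd=noise_sd,
        nb_dispersion=nb_dispersion,
        loading_sd=loading_sd,
        seed=seed,
    )
    return train_m, train_p, test_m, test_p, truth


def inject_imbalance(
    pheno: PhenotypeTable, ratio: float, seed: int = 0, minority: str = "disease"
) -> PhenotypeTable:
    """Subsample one class so minority/majority = ``ratio`` (0 < ratio < 1)."""
    if not 0 < ratio < 1:
        raise ValidationError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(pheno.labels)
    ids = np.asarray(pheno.sample_ids, dtype=object)
    keep_other = ids[labels != minority]
    pool = ids[labels == minority]
    target = int(round(ratio * keep_other.size))
    if target < 4:
        raise ValidationError(f"resulting minority class would have {target} < 4 samples")
    if target > pool.size:
        raise ValidationError("ratio would require more minority samples than exist")
    chosen = rng.choice(pool, size=target, replace=False)
    keep = set(chosen.tolist()) | set(keep_other.tolist())
    order = [s for s in pheno.sample_ids if s in keep]
    return pheno.subset(order)
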