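"""MA-plot statistics for tag-count comparisons under the random sampling model.

For two libraries with per-gene mapped-read counts ``c1``, ``c2`` and library
totals ``n1``, ``n2``, each gene is summarised by

* ``M = log2(c1) - log2(c2)`` — the log2 expression difference, and
* ``A = (log2(c1) + log2(c2)) / 2`` — the average log2 expression,

with a pseudocount added to both counts before any logarithm so that zero
counts stay finite.  Under the random sampling null the gene's combined count
``K = c1 + c2`` is partitioned binomially between the libraries with success
probability ``p0 = n1 / (n1 + n2)``; the delta method then gives

* ``E[M]   = log2(p0 / (1 - p0))``
* ``Var[M] = 1 / (ln(2)^2 * K * p0 * (1 - p0))``

and the theoretical z-score ``z = (M - E[M]) / sqrt(Var[M])``.

Because duplicate embryo samples scatter more than binomial sampling alone
predicts, the screening statistic is instead calibrated against an empirical
noise model fitted from a technical-replicate pair: the local mean and
standard deviation of M in sliding windows along A (the MATR/CTR approach).
:func:`fit_noise_model` builds that model and :func:`matr_zscore` evaluates
the replicate-calibrated z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LN2",
    "DEFAULT_PSEUDOCOUNT",
    "LOW_COUNT_MIN_K",
    "NullMoments",
    "NoiseModel",
    "compute_ma",
    "rsm_null_moments",
    "rsm_null_moments_exact",
    "rsm_zscore",
    "fit_noise_model",
    "average_noise_models",
    "matr_zscore",
    "two_sided_p",
    "qq_normality",
]

LN2 = float(np.log(2.0))

#: Pseudocount added to both counts before any log2 (keeps zeros finite).
DEFAULT_PSEUDOCOUNT = 0.5

#: Genes with combined count K below this are flagged ``low_count`` and
#: excluded from noise-model fitting (discreteness dominates their M).
LOW_COUNT_MIN_K = 10


@dataclass(frozen=True)
class NullMoments:
    """Moments of M under the binomial random-sampling null."""

    muM: float
    varM: float
    K: float
    p0: float

    @property
    def sdM(self) -> float:
        return float(np.sqrt(self.varM))


def compute_ma(c1, c2, n1=1.0, n2=1.0, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Return ``(M, A)`` for counts ``c1`` vs ``c2``.

    Accepts scalars or arrays.  Library totals are accepted for interface
    symmetry with :func:`rsm_zscore` but do not enter M or A: library-size
    differences are handled through the null proportion ``p0``, not by
    rescaling counts.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    l1 = np.log2(c1 + pseudocount)
    l2 = np.log2(c2 + pseudocount)
    M = l1 - l2
    A = 0.5 * (l1 + l2)
    if M.ndim == 0:
        return float(M), float(A)
    return M, A


def rsm_null_moments(K, p0) -> NullMoments:
    """Delta-method mean and variance of M under the binomial null.

    ``K`` is the combined count ``c1 + c2`` and ``p0 = n1/(n1+n2)`` the null
    proportion set by the library totals.
    """
    K = float(K)
    p0 = float(p0)
    if K < 1:
        raise ValueError("combined count K must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion p0 must lie strictly in (0, 1)")
    muM = float(np.log2(p0 / (1.0 - p0)))
    varM = 1.0 / (LN2**2 * K * p0 * (1.0 - p0))
    return NullMoments(muM=muM, varM=varM, K=K, p0=p0)


def rsm_null_moments_exact(
    K: int, p0: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> NullMoments:
    """Exact null moments of M by enumeration over all binomial outcomes.

    Sums ``M(k) = log2(k+pc) - log2(K-k+pc)`` over ``k ~ Binomial(K, p0)``.
    Serves as the validation oracle for the delta-method approximation in
    :func:`rsm_null_moments`; exact for any K at O(K) cost.
    """
    K = int(K)
    if K < 1:
        raise ValueError("combined count K must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion p0 must lie strictly in (0, 1)")
    k = np.arange(K + 1)
    w = stats.binom.pmf(k, K, p0)
    M = np.log2(k + pseudocount) - np.log2(K - k + pseudocount)
    muM = float(np.sum(w * M))
    varM = float(np.sum(w * (M - muM) ** 2))
    return NullMoments(muM=muM, varM=varM, K=float(K), p0=float(p0))


def rsm_zscore(c1, c2, n1, n2, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Theoretical (random-sampling) z-score for counts ``c1`` vs ``c2``.

    ``z = (M - E[M]) / sd[M]`` with ``K = c1 + c2`` and ``p0 = n1/(n1+n2)``.
    Genes with ``K = 0`` get ``z = nan`` (no information).  Accepts scalars
    or arrays.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    M, _ = compute_ma(c1, c2, n1, n2, pseudocount)
    K = c1 + c2
    p0 = float(n1) / (float(n1) + float(n2))
    muM = np.log2(p0 / (1.0 - p0))
    with np.errstate(divide="ignore", invalid="ignore"):
        varM = 1.0 / (LN2**2 * K * p0 * (1.0 - p0))
        z = (np.asarray(M) - muM) / np.sqrt(varM)
    z = np.where(K > 0, z, np.nan)
    if z.ndim == 0:
        return float(z)
    return z


@dataclass
class NoiseModel:
    """Empirical mean and SD of M as a function of A, from a replicate pair.

    Grid values come from sliding windows of genes ordered by A; between grid
    points the model interpolates linearly, and outside the observed A range
    it clamps to the nearest grid value.
    """

    a_grid: np.ndarray
    mean_m: np.ndarray
    sd_m: np.ndarray
    n_genes: np.ndarray = field(default=None)
    sd_floor: float = 1e-3

    def __post_init__(self):
        self.a_grid = np.asarray(self.a_grid, dtype=float)
        self.mean_m = np.asarray(self.mean_m, dtype=float)
        self.sd_m = np.asarray(self.sd_m, dtype=float)
        if self.a_grid.size < 1:
            raise ValueError("noise model needs at least one grid point")
        if np.any(np.diff(self.a_grid) <= 0):
            raise ValueError("A grid must be strictly increasing")
        if np.any(self.sd_m < self.sd_floor):
            raise ValueError("SD values below the configured floor")

    def mean_at(self, a):
        return np.interp(a, self.a_grid, self.mean_m)

    def sd_at(self, a):
        return np.interp(a, self.a_grid, self.sd_m)


def fit_noise_model(
    rep_a,
    rep_b,
    window_size: int = 500,
    *,
    window_step: int | None = None,
    trim: float = 0.1,
    sd_floor: float = 1e-3,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_k: int = LOW_COUNT_MIN_K,
) -> NoiseModel:
    """Fit the replicate noise model: local mean/SD of M along A.

    ``rep_a`` and ``rep_b`` are count vectors from two libraries of the same
    condition.  Genes with combined count below ``min_k`` are excluded (their
    M is dominated by discreteness).  Remaining genes are sorted by A and
    scanned in windows of ``window_size`` genes advancing by ``window_step``
    (default: half a window, i.e. 50% overlap); each window contributes one
    grid point at its median A with a ``trim``-trimmed mean of M and the
    standard deviation of M, floored at ``sd_floor``.
    """
    rep_a = np.asarray(rep_a, dtype=float)
    rep_b = np.asarray(rep_b, dtype=float)
    if rep_a.shape != rep_b.shape:
        raise ValueError("replicate columns must have equal length")
    if window_size < 20:
        raise ValueError("window_size must be >= 20")
    if window_step is None:
        window_step = max(1, window_size // 2)

    M, A = compute_ma(rep_a, rep_b, pseudocount=pseudocount)
    keep = (rep_a + rep_b) >= min_k
    M, A = np.asarray(M)[keep], np.asarray(A)[keep]
    if M.size < window_size:
        raise ValueError(
            f"only {M.size} genes with combined count >= {min_k}; "
            f"need at least one window of {window_size}"
        )
    order = np.argsort(A, kind="stable")
    M, A = M[order], A[order]

    starts = list(range(0, M.size - window_size + 1, window_step))
    if starts[-1] != M.size - window_size:
        starts.append(M.size - window_size)
    a_pts, mean_pts, sd_pts, n_pts = [], [], [], []
    for s in starts:
        wM = M[s : s + window_size]
        wA = A[s : s + window_size]
        a_pts.append(np.median(wA))
        mean_pts.append(stats.trim_mean(wM, trim))
        sd_pts.append(max(float(np.std(wM, ddof=1)), sd_floor))
        n_pts.append(window_size)

    a_pts = np.asarray(a_pts)
    # identical median A in adjacent windows (heavy count ties): keep first
    uniq = np.concatenate([[True], np.diff(a_pts) > 0])
    return NoiseModel(
        a_grid=a_pts[uniq],
        mean_m=np.asarray(mean_pts)[uniq],
        sd_m=np.asarray(sd_pts)[uniq],
        n_genes=np.asarray(n_pts)[uniq],
        sd_floor=sd_floor,
    )


def average_noise_models(models: list[NoiseModel]) -> NoiseModel:
    """Average several replicate-pair noise models pointwise.

    Mean and SD curves are evaluated on the union of the models' A grids and
    averaged; used when more than one replicate pair is available.
    """
    if not models:
        raise ValueError("need at least one noise model")
    if len(models) == 1:
        return models[0]
    grid = np.unique(np.concatenate([m.a_grid for m in models]))
    mean = np.mean([m.mean_at(grid) for m in models], axis=0)
    sd = np.mean([m.sd_at(grid) for m in models], axis=0)
    floor = min(m.sd_floor for m in models)
    return NoiseModel(a_grid=grid, mean_m=mean, sd_m=np.maximum(sd, floor), sd_floor=floor)


def matr_zscore(M, A, model: NoiseModel):
    """Replicate-calibrated z-score: ``(M - mean(M|A)) / SD(M|A)``."""
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    z = (M - model.mean_at(A)) / model.sd_at(A)
    if z.ndim == 0:
        return float(z)
    return z


def two_sided_p(z):
    """Two-sided standard-normal tail probability ``2 * (1 - Phi(|z|))``."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if p.ndim == 0:
        return float(p)
    return p


def qq_normality(values):
    """Normal QQ pairs and their Pearson correlation as a normality index.

    Sample quantiles (sorted values) are paired with standard-normal
    quantiles at plotting positions ``(i - 0.5) / n``.  Returns
    ``(pairs, r)`` where ``pairs`` is an ``(n, 2)`` array of
    (theoretical, sample) quantiles.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 finite values for a QQ comparison")
    if np.ptp(v) == 0:
        raise ValueError("constant input: QQ correlation undefined")
    sample = np.sort(v)
    theo = stats.norm.ppf((np.arange(1, v.size + 1) - 0.5) / v.size)
    r = float(np.corrcoef(theo, sample)[0, 1])
    return np.column_stack([theo, sample]), r
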