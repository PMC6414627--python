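"""Shape-space statistics: PCA, broken-stick retention, permutation tests,
allometry, and the intra-observer error/reliability study.

Group inference follows the standard geometric-morphometric recipe: aligned
shape coordinates are decomposed by PCA, the number of statistically
meaningful shape variables is fixed by the broken-stick criterion, and
group pairs are compared on those retained PC scores with a permutation
variant of the two-sample Hotelling T-squared test (10,000 permutations by
default, significance threshold alpha = 0.05).  Because PCA and the
broken-stick choice use the pooled sample only, they are invariant under
label permutation and the permutation test remains exact.

Permutation p-values use the add-one convention p = (1 + #{T*_b >= T_obs})
/ (B + 1), which never returns zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import InsufficientSampleError, InvalidParameterError
from .resampling import SemilandmarkCurve
from .superimposition import AlignedSample, gpa_with_sliding

logger = logging.getLogger(__name__)

#: Default permutation count for the group tests.
DEFAULT_PERMUTATIONS = 10_000
#: Default significance threshold.
DEFAULT_ALPHA = 0.05
#: Default acceptability threshold for the reliability coefficient.
DEFAULT_RELIABILITY_THRESHOLD = 0.95


# --------------------------------------------------------------------------
# PCA of shape coordinates


@dataclass
class PCAModel:
    eigenvalues: np.ndarray  # (m,)
    variance_fractions: np.ndarray  # (m,)
    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (m, 3k), orthonormal rows
    mean_shape_flat: np.ndarray  # (3k,)
    n_retained_broken_stick: int

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def pca_shapes(sample: AlignedSample | np.ndarray) -> PCAModel:
    """PCA of flattened aligned shape coordinates.

    Eigendecomposition of the coordinate covariance via SVD of the centered
    data matrix; components ordered by decreasing eigenvalue, with a
    deterministic sign convention (the largest-magnitude loading element of
    each component is positive).  Components with numerically zero variance
    are dropped.
    """
    shapes = getattr(sample, "shapes", sample)
    shapes = np.asarray(shapes, float)
    n = shapes.shape[0]
    if n < 3:
        raise InsufficientSampleError(f"PCA needs n >= 3 specimens, got {n}")
    flat = shapes.reshape(n, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > max(eigenvalues[0], 1.0) * 1e-12 if len(eigenvalues) else []
    eigenvalues = eigenvalues[keep]
    vt = vt[keep]
    # deterministic sign: largest |loading| entry of each component positive
    flips = np.sign(vt[np.arange(len(vt)), np.abs(vt).argmax(axis=1)])
    vt = vt * flips[:, None]
    scores = centered @ vt.T
    fractions = eigenvalues / eigenvalues.sum()
    return PCAModel(
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        scores=scores,
        loadings=vt,
        mean_shape_flat=mean,
        n_retained_broken_stick=broken_stick_retain(fractions),
    )


def broken_stick_retain(variance_fractions: Sequence[float]) -> int:
    """Number of leading components whose variance fraction exceeds the
    broken-stick expectation.

    For p components the expected fraction of the j-th longest piece of a
    unit stick broken at p-1 uniform points is b_j = (1/p) * sum_{i=j}^{p} 1/i.
    Returns the largest r such that fraction_j > b_j for all j <= r (the
    leading run; possibly 0).
    """
    fr = np.asarray(variance_fractions, float)
    if fr.size == 0:
        raise InvalidParameterError("empty variance-fraction vector")
    if np.any(fr < -1e-12) or fr.sum() > 1.0 + 1e-9:
        raise InvalidParameterError("variance fractions must be >= 0 and sum to <= 1")
    p = fr.size
    inv = 1.0 / np.arange(1, p + 1)
    b = inv[::-1].cumsum()[::-1] / p  # b_j = (1/p) sum_{i=j..p} 1/i
    exceeds = fr > b
    r = 0
    while r < p and exceeds[r]:
        r += 1
    return r


# --------------------------------------------------------------------------
# Hotelling T-squared and permutation tests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    n_retained_vars: int
    group_sizes: tuple[int, int]
    seed: int | None = None


def _validated_groups(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise InvalidParameterError("score matrices must be 2D with equal columns")
    return x, y


def _t2_reduced(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """T-squared with automatic reduction to the largest leading invertible
    variable subset when the pooled covariance is singular."""
    n1, n2 = len(x), len(y)
    m = x.shape[1]
    while m >= 1:
        xs, ys = x[:, :m], y[:, :m]
        d = xs.mean(axis=0) - ys.mean(axis=0)
        s_pooled = (
            (n1 - 1) * np.cov(xs, rowvar=False).reshape(m, m)
            + (n2 - 1) * np.cov(ys, rowvar=False).reshape(m, m)
        ) / (n1 + n2 - 2)
        try:
            c = cho_factor(s_pooled)
        except LinAlgError:
            m -= 1
            continue
        t2 = (n1 * n2 / (n1 + n2)) * float(d @ cho_solve(c, d))
        return max(0.0, t2), m
    # all variables constant: identical groups have T2 = 0 by convention
    return 0.0, 0


def hotelling_t2(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Hotelling T-squared statistic.

    T2 = (n1 n2 / (n1 + n2)) d' S_pooled^{-1} d with d the mean difference
    and S_pooled the pooled sample covariance.  Invariant under any common
    invertible linear map of the variables.  When the pooled covariance is
    singular the statistic is computed on the largest leading variable
    subset that is invertible (with a warning).
    """
    x, y = _validated_groups(x, y)
    n1, n2 = len(x), len(y)
    if n1 + n2 - 2 <= x.shape[1]:
        raise InsufficientSampleError(
            f"need n1 + n2 - 2 > m; got n1={n1}, n2={n2}, m={x.shape[1]}"
        )
    t2, m_used = _t2_reduced(x, y)
    if m_used < x.shape[1]:
        logger.warning(
            "singular pooled covariance: reduced from %d to %d leading variables",
            x.shape[1], m_used,
        )
    return t2


def _t2_from_mean_diff(
    d: np.ndarray, t_inv_chol, c_factor: float, n_total: int
) -> np.ndarray:
    """T-squared from group-mean differences via the total-scatter identity.

    With T the (label-invariant) total scatter of the pooled sample and
    c = n1 n2 / n, the pooled within scatter is W = T - c d d', and by the
    Sherman-Morrison identity T2 = (n - 2) c q / (1 - c q), q = d' T^{-1} d.
    Perfect separation (1 - c q <= 0) maps to +inf.
    """
    q = np.einsum("bm,bm->b", d, cho_solve(t_inv_chol, d.T).T)
    denom = 1.0 - c_factor * q
    out = np.full_like(q, np.inf)
    ok = denom > 0
    out[ok] = (n_total - 2) * c_factor * q[ok] / denom[ok]
    return out


def permutation_hotelling(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Permutation two-sample Hotelling T-squared test.

    Group labels are permuted uniformly at random ``n_permutations`` times;
    p = (1 + #{T2* >= T2_obs}) / (B + 1).
    """
    if n_permutations < 1:
        raise InvalidParameterError("need at least 1 permutation")
    x, y = _validated_groups(x, y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n1 < 1 or n2 < 1 or n < 3:
        raise InsufficientSampleError("both groups must be non-empty, n >= 3")
    z = np.vstack([x, y])
    # drop variables until the total scatter is invertible (matches the
    # leading-subset reduction of hotelling_t2)
    m = z.shape[1]
    zc = z - z.mean(axis=0)
    chol = None
    while m >= 1:
        t_scatter = zc[:, :m].T @ zc[:, :m]
        try:
            chol = cho_factor(t_scatter)
            break
        except LinAlgError:
            m -= 1
    if chol is None:
        # all variables constant across the pooled sample
        return TestResult(0.0, 1.0, n_permutations, 0, (n1, n2),
                          seed if isinstance(seed, int) else None)
    zm = z[:, :m]
    c_factor = n1 * n2 / n

    total = zm.sum(axis=0)

    def t2_for(idx1: np.ndarray) -> np.ndarray:
        sum1 = zm[idx1].sum(axis=1)  # (B, m)
        d = sum1 / n1 - (total - sum1) / n2
        return _t2_from_mean_diff(d, chol, c_factor, n)

    observed = float(t2_for(np.arange(n1)[None, :])[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.random((n_permutations, n)).argsort(axis=1)[:, :n1]
    permuted = t2_for(order)
    n_ge = int(np.count_nonzero(permuted >= observed - 1e-12 * max(observed, 1.0)))
    p = (1 + n_ge) / (n_permutations + 1)
    return TestResult(
        statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        n_retained_vars=m,
        group_sizes=(n1, n2),
        seed=seed if isinstance(seed, int) else None,
    )


def permutation_mean_diff(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Two-sided permutation test on |mean(a) - mean(b)| for scalar measures
    (e.g. maximal tibial lengths)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise InsufficientSampleError("both samples must be non-empty")
    if n_permutations < 1:
        raise InvalidParameterError("need at least 1 permutation")
    n1, n = len(a), len(a) + len(b)
    z = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.random((n_permutations, n)).argsort(axis=1)[:, :n1]
    sum1 = z[order].sum(axis=1)
    permuted = np.abs(sum1 / n1 - (z.sum() - sum1) / (n - n1))
    n_ge = int(np.count_nonzero(permuted >= observed - 1e-12 * max(observed, 1.0)))
    p = (1 + n_ge) / (n_permutations + 1)
    return TestResult(
        statistic=float(observed),
        p_value=p,
        n_permutations=n_permutations,
        n_retained_vars=1,
        group_sizes=(n1, n - n1),
        seed=seed if isinstance(seed, int) else None,
    )


# --------------------------------------------------------------------------
# Pairwise group matrices


@dataclass
class PairwiseTestMatrix:
    """Lower-triangular p-value matrix over ordered group labels."""

    labels: list[str]
    p_values: np.ndarray  # (g, g), symmetric, nan diagonal
    results: dict[tuple[str, str], TestResult]
    alpha: float = DEFAULT_ALPHA

    def significant(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.p_values[i, j] < self.alpha)

    def to_dataframe(self) -> pd.DataFrame:
        """Lower-triangular layout matching the conventional p-value tables."""
        g = len(self.labels)
        out = pd.DataFrame("", index=self.labels[1:], columns=self.labels[:-1])
        for i in range(1, g):
            for j in range(i):
                p = self.p_values[i, j]
                cell = "<0.001" if p < 0.001 else f"{p:.3f}"
                if p < self.alpha:
                    cell += " *"
                out.iloc[i - 1, j] = cell
        return out


def derive_cell_seed(master_seed: int | None, label_a: str, label_b: str) -> int:
    """Deterministic per-cell seed, stable under adding/removing other groups."""
    crc = zlib.crc32(f"{label_a}|{label_b}".encode())
    base = 0 if master_seed is None else int(master_seed)
    return int((base * 2654435761 + crc) % (2**31))


def pairwise_group_tests(
    pca: PCAModel,
    groups: Sequence[str],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    n_pcs: int | None = None,
    group_order: Sequence[str] | None = None,
) -> PairwiseTestMatrix:
    """Permutation Hotelling tests over all unordered group pairs.

    Tests run on the broken-stick-retained PC scores (at least one PC is
    always used; ``n_pcs`` overrides the criterion for sensitivity
    analysis).  Groups with fewer than 3 specimens are excluded with a
    warning.  Each cell gets its own deterministic seed derived from the
    master seed and the pair of labels.
    """
    groups = np.asarray(list(groups))
    if len(groups) != pca.n:
        raise InvalidParameterError("group labels must match PCA specimen count")
    r = n_pcs if n_pcs is not None else max(1, pca.n_retained_broken_stick)
    r = min(r, pca.scores.shape[1])
    scores = pca.scores[:, :r]
    labels = list(group_order) if group_order is not None else list(dict.fromkeys(groups))
    usable = []
    for lab in labels:
        n_g = int(np.count_nonzero(groups == lab))
        if n_g < 3:
            logger.warning("group %r has n=%d < 3; excluded from pairwise tests", lab, n_g)
        else:
            usable.append(lab)
    g = len(usable)
    if g < 2:
        raise InsufficientSampleError("need at least 2 groups with n >= 3")
    p_mat = np.full((g, g), np.nan)
    results: dict[tuple[str, str], TestResult] = {}
    for i in range(g):
        for j in range(i):
            la, lb = usable[j], usable[i]
            cell_seed = derive_cell_seed(seed, la, lb)
            res = permutation_hotelling(
                scores[groups == la], scores[groups == lb],
                n_permutations=n_permutations, seed=cell_seed,
            )
            res.seed = cell_seed
            results[(la, lb)] = results[(lb, la)] = res
            p_mat[i, j] = p_mat[j, i] = res.p_value
    return PairwiseTestMatrix(labels=usable, p_values=p_mat, results=results, alpha=alpha)


def pairwise_scalar_tests(
    values: Sequence[float],
    groups: Sequence[str],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    group_order: Sequence[str] | None = None,
) -> PairwiseTestMatrix:
    """Pairwise permutation mean-difference tests on a scalar measure."""
    values = np.asarray(values, float)
    groups = np.asarray(list(groups))
    labels = list(group_order) if group_order is not None else list(dict.fromkeys(groups))
    g = len(labels)
    if g < 2:
        raise InsufficientSampleError("need at least 2 groups")
    p_mat = np.full((g, g), np.nan)
    results: dict[tuple[str, str], TestResult] = {}
    for i in range(g):
        for j in range(i):
            la, lb = labels[j], labels[i]
            cell_seed = derive_cell_seed(seed, f"len:{la}", f"len:{lb}")
            res = permutation_mean_diff(
                values[groups == la], values[groups == lb],
                n_permutations=n_permutations, seed=cell_seed,
            )
            res.seed = cell_seed
            results[(la, lb)] = results[(lb, la)] = res
            p_mat[i, j] = p_mat[j, i] = res.p_value
    return PairwiseTestMatrix(labels=labels, p_values=p_mat, results=results, alpha=alpha)


# --------------------------------------------------------------------------
# Allometry


@dataclass
class AllometryResult:
    stratum: str
    pc_index: int  # 0-based
    slope: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def allometry_anova(
    pca: PCAModel,
    curve_lengths: Sequence[float],
    strata: Sequence[str] | None = None,
    n_pcs: int | None = None,
) -> list[AllometryResult]:
    """Allometry check: per-stratum linear regression of each retained PC
    score on curve length, with ANOVA F test of the model.

    F = R^2 (n - 2) / (1 - R^2) on (1, n - 2) degrees of freedom.  Strata
    with constant lengths yield NaN results with a warning.
    """
    lengths = np.asarray(curve_lengths, float)
    if strata is None:
        strata = ["all"] * len(lengths)
    strata = np.asarray(list(strata))
    if len(lengths) != pca.n or len(strata) != pca.n:
        raise InvalidParameterError("lengths/strata must match PCA specimen count")
    r = n_pcs if n_pcs is not None else max(1, pca.n_retained_broken_stick)
    r = min(r, pca.scores.shape[1])
    out: list[AllometryResult] = []
    for lab in dict.fromkeys(strata):
        sel = strata == lab
        n = int(sel.sum())
        if n < 4:
            logger.warning("stratum %r has n=%d < 4; skipped", lab, n)
            continue
        x = lengths[sel]
        if np.ptp(x) == 0.0:
            logger.warning("stratum %r has zero length variance; slope undefined", lab)
            for pc in range(r):
                out.append(AllometryResult(str(lab), pc, np.nan, np.nan, np.nan, np.nan, n))
            continue
        for pc in range(r):
            y = pca.scores[sel, pc]
            fit = sps.linregress(x, y)
            r2 = fit.rvalue**2 if np.isfinite(fit.rvalue) else 0.0
            if r2 >= 1.0:
                f, p = np.inf, 0.0
            else:
                f = r2 * (n - 2) / (1.0 - r2)
                p = float(sps.f.sf(f, 1, n - 2))
            out.append(AllometryResult(str(lab), pc, float(fit.slope), float(r2),
                                       float(f), p, n))
    return out


# --------------------------------------------------------------------------
# Intra-observer error / reliability


@dataclass
class ErrorReport:
    per_landmark_sd: np.ndarray  # (k,), repeat SD per semilandmark (shape units)
    overall_me: float  # mean over semilandmarks
    total_sd: float  # between-specimen SD on the same scale
    reliability: float  # 1 - ME^2 / SD^2, clipped to [0, 1]
    threshold: float = DEFAULT_RELIABILITY_THRESHOLD

    @property
    def acceptable(self) -> bool:
        return bool(self.reliability >= self.threshold)


def measurement_error(
    repeat_sets: Sequence[Sequence[SemilandmarkCurve]],
    threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    slide: bool = True,
    align: bool = True,
) -> ErrorReport:
    """Intra-observer error from repeated digitizations.

    All repeats of all specimens are jointly superimposed (GPA + sliding).
    The error of one semilandmark for one specimen is the standard deviation
    of its position over that specimen's repeats, computed as the RMS 3D
    deviation from the repeat mean (with n-1 in the denominator).  Per-
    semilandmark errors are averaged over specimens; the overall measurement
    error (ME) is their mean over semilandmarks.  The between-specimen
    standard deviation (SD) is computed identically from the specimen repeat
    means around the grand mean.  The reliability coefficient is
    sigma_xx' = 1 - ME^2 / SD^2, clipped to [0, 1]; values at or above
    ``threshold`` (default 0.95) are considered acceptable.

    ``align=False`` treats the input coordinates as already superimposed
    (useful for validating the decomposition itself).
    """
    if len(repeat_sets) < 2:
        raise InsufficientSampleError("need at least 2 specimens with repeats")
    counts = [len(reps) for reps in repeat_sets]
    if min(counts) < 2:
        raise InsufficientSampleError("every specimen needs at least 2 repeats")
    flat = [rep for reps in repeat_sets for rep in reps]
    if align:
        aligned = gpa_with_sliding(flat, slide=slide)
    else:
        aligned = AlignedSample(
            shapes=np.stack([c.coords for c in flat]),
            consensus=np.mean([c.coords for c in flat], axis=0),
            centroid_sizes=np.ones(len(flat)),
            curve_lengths=np.array([c.length_mm for c in flat]),
        )
    k = aligned.k
    idx = np.cumsum([0] + counts)
    spec_means = np.empty((len(repeat_sets), k, 3))
    per_spec_sd = np.empty((len(repeat_sets), k))
    for s, (lo, hi) in enumerate(zip(idx[:-1], idx[1:])):
        block = aligned.shapes[lo:hi]  # (R, k, 3)
        mu = block.mean(axis=0)
        spec_means[s] = mu
        dev2 = np.sum((block - mu) ** 2, axis=2)  # (R, k)
        per_spec_sd[s] = np.sqrt(dev2.sum(axis=0) / (len(block) - 1))
    per_landmark_sd = per_spec_sd.mean(axis=0)
    overall_me = float(per_landmark_sd.mean())
    grand = spec_means.mean(axis=0)
    between = np.sqrt(
        np.sum((spec_means - grand) ** 2, axis=2).sum(axis=0) / (len(repeat_sets) - 1)
    )
    total_sd = float(between.mean())
    if total_sd == 0.0:
        logger.warning("zero between-specimen SD; reliability undefined")
        reliability = np.nan
    else:
        reliability = float(np.clip(1.0 - overall_me**2 / total_sd**2, 0.0, 1.0))
    return ErrorReport(
        per_landmark_sd=per_landmark_sd,
        overall_me=overall_me,
        total_sd=total_sd,
        reliability=reliability,
        threshold=threshold,
    )
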