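"""Pixel-wise randomization test with pseudo t statistics.

Two conditions with N_A and N_B animals are compared cell by cell on the
shared reference grid.  Under the null hypothesis the group labels are
arbitrary, so the observed statistic image is referred to the distribution of
statistic images over all C(N_A + N_B, N_A) relabelings.  The statistic is a
pseudo t,

    T(i) = (Abar(i) - Bbar(i)) / sqrt(S'_A^2(i)/N_A + S'_B^2(i)/N_B),

whose per-group sample variances are spatially smoothed with a Gaussian
kernel before forming the ratio: with only a handful of animals the raw
variance image is noisy, and borrowing strength from neighbouring cells
stabilises the denominator (the reason the statistic is "pseudo" t, and why
no parametric null distribution exists for it).

Family-wise error is controlled by the step-down maxT procedure: cells are
sorted by their observed statistic, each relabeling contributes a running
extremum along that order, and per-cell exceedance counts are converted to
adjusted p-values with monotonicity enforced along the sorted order.
Comparisons are non-strict, so the identity relabeling always counts and
every adjusted p lies in [1/N, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .maps import nan_gaussian

__all__ = [
    "PermutationScheme",
    "StatConfig",
    "SignificanceMaps",
    "enumerate_labelings",
    "variance_image",
    "smooth_variance",
    "pseudo_t",
    "step_down_adjusted_p",
    "threshold_and_contour",
    "fwer_estimate",
    "FwerResult",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

TAILS = ("one_activation", "one_deactivation", "two")


@dataclass(frozen=True)
class PermutationScheme:
    """All distinct assignments of N_A + N_B animals into the two groups."""

    n_a: int
    n_b: int
    labelings: np.ndarray  # (N, n_a) sorted index tuples of group A; row 0 observed

    @property
    def n(self) -> int:
        return self.labelings.shape[0]


def enumerate_labelings(n_a: int, n_b: int, cap: int = 200_000) -> PermutationScheme:
    """Enumerate every distinct group-A index set, observed labeling first.

    The number of relabelings is the binomial coefficient C(n_a + n_b, n_a);
    the smallest attainable adjusted p-value is its reciprocal.
    """
    if n_a < 1 or n_b < 1:
        raise ValidationError("group sizes must be >= 1")
    total = math.comb(n_a + n_b, n_a)
    if total > cap:
        raise ValidationError(
            f"{total} relabelings exceed the cap of {cap}; exhaustive "
            "enumeration only — reduce the group sizes"
        )
    combos = np.array(list(combinations(range(n_a + n_b), n_a)), dtype=np.intp)
    # lexicographic order puts the observed labeling (0..n_a-1) first
    assert tuple(combos[0]) == tuple(range(n_a))
    return PermutationScheme(n_a=n_a, n_b=n_b, labelings=combos)


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    tails: str = "two"
    variance_fwhm: float = 2.0  # grid cells; 0 disables variance smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tails not in TAILS:
            raise ValidationError(f"tails must be one of {TAILS}")
        if self.variance_fwhm < 0:
            raise ValidationError("variance_fwhm must be >= 0")

    @property
    def per_tail_threshold(self) -> float:
        return self.alpha / 2.0 if self.tails == "two" else self.alpha


@dataclass
class SignificanceMaps:
    """Adjusted p-value images of one comparison.

    ``p_activation`` / ``p_deactivation`` refer each signed tail to the
    successive extrema of the signed statistic (threshold at alpha for a
    one-tailed test, alpha/2 per tail for a conservative two-tailed one).
    ``p_two_sided`` refers |T| to the successive maxima of |T| — the exactly
    calibrated two-sided test, thresholded at alpha and attributed to a tail
    by the sign of T.  All maps take values in [1/N, 1].
    """

    t: np.ndarray  # observed pseudo-t raster
    p_activation: np.ndarray  # adjusted p, A > B tail
    p_deactivation: np.ndarray  # adjusted p, A < B tail
    p_two_sided: np.ndarray  # adjusted p of the |T| step-down test
    n_permutations: int
    config: StatConfig
    footprint: np.ndarray  # bool raster of tested cells
    zero_variance_cells: int = 0


def variance_image(stack: np.ndarray) -> np.ndarray:
    """Unbiased per-cell sample variance; NaN where < 2 values are defined."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValidationError("stack must be (n_animals, rows, cols)")
    finite = np.isfinite(stack)
    count = finite.sum(axis=0)
    filled = np.where(finite, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / count
        ss = ((np.where(finite, stack - mean, 0.0)) ** 2).sum(axis=0)
        var = ss / (count - 1)
    var[count < 2] = np.nan
    return var


def smooth_variance(var: np.ndarray, fwhm: float) -> np.ndarray:
    """NaN-aware Gaussian smoothing of a variance image (FWHM in grid cells)."""
    if fwhm <= 0:
        return var
    return nan_gaussian(var, fwhm / _FWHM_TO_SIGMA)


def pseudo_t(delta, var_a, var_b, n_a: int, n_b: int) -> np.ndarray:
    """Pseudo t image from a difference image and smoothed group variances.

    No equal-variance assumption: the denominator is the Welch-style
    sqrt(S'_A^2/N_A + S'_B^2/N_B).  Cells where both smoothed variances are
    zero are NaN (undefined).
    """
    delta = np.asarray(delta, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(var_a / n_a + var_b / n_b)
        t = delta / denom
    t[np.asarray(denom) == 0.0] = np.nan
    return t


# ---------------------------------------------------------------------------
# step-down adjusted p-values


def _group_stats(flat: np.ndarray, sel: np.ndarray) -> tuple:
    """Mean and ddof-1 variance over a batch of labelings.

    flat: (n_animals, m) cell values; sel: (batch, group_size) index matrix.
    Returns (batch, m) means and variances.
    """
    vals = flat[sel]  # (batch, size, m)
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    return mean, var


def _smooth_batch(var: np.ndarray, footprint: np.ndarray, fwhm: float) -> np.ndarray:
    """Smooth a batch of flattened variance images over the 2-D footprint."""
    if fwhm <= 0:
        return var
    from scipy import ndimage

    sigma = fwhm / _FWHM_TO_SIGMA
    batch = var.shape[0]
    grid = np.zeros((batch,) + footprint.shape)
    grid[:, footprint] = var
    num = ndimage.gaussian_filter(
        grid, sigma=(0.0, sigma, sigma), mode="constant", truncate=3.0
    )
    den = ndimage.gaussian_filter(
        footprint.astype(float), sigma=sigma, mode="constant", truncate=3.0
    )
    sm = num / den[None, :, :]
    return sm[:, footprint]


def _t_for_labelings(flat, sel_a, sel_b, n_a, n_b, footprint, fwhm):
    mean_a, var_a = _group_stats(flat, sel_a)
    mean_b, var_b = _group_stats(flat, sel_b)
    var_a = _smooth_batch(var_a, footprint, fwhm)
    var_b = _smooth_batch(var_b, footprint, fwhm)
    delta = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(var_a / n_a + var_b / n_b)
        t = delta / denom
    # all-equal cells under a labeling: 0/0 counts as a tie with the observed
    t[(denom == 0.0) & (delta == 0.0)] = 0.0
    t[(denom == 0.0) & (delta > 0.0)] = np.inf
    t[(denom == 0.0) & (delta < 0.0)] = -np.inf
    return t


def step_down_adjusted_p(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    config: StatConfig = StatConfig(),
    scheme: PermutationScheme | None = None,
    chunk: int = 512,
) -> SignificanceMaps:
    """Step-down maxT adjusted p-value images for both tails.

    Cells defined in every animal form the tested footprint and are sorted by
    the observed pseudo t (ascending).  For each relabeling the running
    maximum along that order gives the successive-maxima image (activation
    tail) and the reversed running minimum the successive-minima image
    (deactivation tail).  Per-cell counts of relabelings whose extremum
    reaches the observed value (non-strict, so the identity labeling always
    counts) are divided by N and made monotone along the sorted order.
    """
    stack_a = np.asarray(stack_a, dtype=float)
    stack_b = np.asarray(stack_b, dtype=float)
    if stack_a.shape[1:] != stack_b.shape[1:]:
        raise ValidationError("condition stacks are on different grids")
    n_a, n_b = stack_a.shape[0], stack_b.shape[0]
    if n_a < 3 or n_b < 3:
        raise ValidationError(
            "need at least 3 animals per group: with fewer, the number of "
            "relabelings falls below 20 and no p-value can reach 0.05"
        )
    if scheme is None:
        scheme = enumerate_labelings(n_a, n_b)
    if scheme.n_a != n_a or scheme.n_b != n_b:
        raise ValidationError("permutation scheme does not match the group sizes")

    data = np.concatenate([stack_a, stack_b], axis=0)
    footprint = np.isfinite(data).all(axis=0)
    m = int(footprint.sum())
    if m == 0:
        raise ValidationError("no cell is defined in every animal")
    flat = data[:, footprint]  # (n_total, m)

    n_total = n_a + n_b
    all_idx = np.arange(n_total)
    n_perm = scheme.n

    t_obs = None
    order = None
    count_act = np.zeros(m, dtype=np.int64)
    count_deact = np.zeros(m, dtype=np.int64)

    # observed labeling first so the sort order exists before counting
    first = _t_for_labelings(
        flat,
        scheme.labelings[:1],
        np.array([np.setdiff1d(all_idx, scheme.labelings[0])]),
        n_a,
        n_b,
        footprint,
        config.variance_fwhm,
    )
    t_obs = first[0]
    zero_var = int((~np.isfinite(t_obs)).sum())
    order = np.argsort(np.nan_to_num(t_obs, nan=0.0), kind="stable")
    t_sorted = t_obs[order]
    abs_obs = np.abs(t_obs)
    order_abs = np.argsort(np.nan_to_num(abs_obs, nan=0.0), kind="stable")
    abs_sorted = abs_obs[order_abs]
    count_two = np.zeros(m, dtype=np.int64)

    for start in range(0, n_perm, chunk):
        sel_a = scheme.labelings[start : start + chunk]
        sel_b = np.array([np.setdiff1d(all_idx, row) for row in sel_a])
        t_perm = _t_for_labelings(
            flat, sel_a, sel_b, n_a, n_b, footprint, config.variance_fwhm
        )
        ts = t_perm[:, order]
        with np.errstate(invalid="ignore"):
            run_max = np.fmax.accumulate(ts, axis=1)
            run_min = np.fmin.accumulate(ts[:, ::-1], axis=1)[:, ::-1]
            count_act += (run_max >= t_sorted[None, :]).sum(axis=0)
            count_deact += (run_min <= t_sorted[None, :]).sum(axis=0)
            run_abs = np.fmax.accumulate(np.abs(t_perm)[:, order_abs], axis=1)
            count_two += (run_abs >= abs_sorted[None, :]).sum(axis=0)

    p_act_sorted = count_act / n_perm
    p_deact_sorted = count_deact / n_perm
    p_two_sorted = count_two / n_perm
    # monotone: p may never drop as the observed statistic becomes less extreme
    p_act_sorted = np.maximum.accumulate(p_act_sorted[::-1])[::-1]
    p_deact_sorted = np.maximum.accumulate(p_deact_sorted)
    p_two_sorted = np.maximum.accumulate(p_two_sorted[::-1])[::-1]

    def scatter(sorted_vals, by):
        out = np.full(footprint.shape, np.nan)
        buf = np.empty(m)
        buf[by] = sorted_vals
        out[footprint] = buf
        return out

    t_map = np.full(footprint.shape, np.nan)
    t_map[footprint] = t_obs
    return SignificanceMaps(
        t=t_map,
        p_activation=scatter(p_act_sorted, order),
        p_deactivation=scatter(p_deact_sorted, order),
        p_two_sided=scatter(p_two_sorted, order_abs),
        n_permutations=n_perm,
        config=config,
        footprint=footprint,
        zero_variance_cells=zero_var,
    )


def threshold_and_contour(
    maps: SignificanceMaps,
    alpha: float | None = None,
    tails: str | None = None,
    strict_alpha: float | None = None,
) -> dict:
    """Reject masks at the configured threshold plus boundary contours.

    For a two-tailed comparison each tail is thresholded at alpha/2; one-tailed
    comparisons use alpha directly.  Contours (marching squares on the mask)
    are returned at alpha and at a stricter second level (alpha/5 by default,
    e.g. 0.01 next to 0.05).
    """
    from skimage import measure

    alpha = maps.config.alpha if alpha is None else alpha
    tails = maps.config.tails if tails is None else tails
    if tails not in TAILS:
        raise ValidationError(f"tails must be one of {TAILS}")
    strict_alpha = alpha / 5.0 if strict_alpha is None else strict_alpha

    def masks_at(a):
        thr = a / 2.0 if tails == "two" else a
        act = np.isfinite(maps.p_activation) & (maps.p_activation <= thr)
        deact = np.isfinite(maps.p_deactivation) & (maps.p_deactivation <= thr)
        if tails == "one_activation":
            deact = np.zeros_like(deact)
        elif tails == "one_deactivation":
            act = np.zeros_like(act)
        return act, deact

    act, deact = masks_at(alpha)
    act_s, deact_s = masks_at(strict_alpha)

    def contours(mask):
        if not mask.any():
            return []
        return [c.tolist() for c in measure.find_contours(mask.astype(float), 0.5)]

    return {
        "alpha": alpha,
        "strict_alpha": strict_alpha,
        "tails": tails,
        "reject_activation": act,
        "reject_deactivation": deact,
        "reject_any": act | deact,
        "contours": {
            "alpha": contours(act | deact),
            "strict": contours(act_s | deact_s),
        },
    }


# ---------------------------------------------------------------------------
# FWER validation harness


@dataclass(frozen=True)
class FwerResult:
    reps: int
    rejections: int  # replicates with >= 1 cell at p <= alpha/2 in either tail
    rejections_activation: int
    rejections_deactivation: int
    one_tailed_activation: int  # replicates with >= 1 cell at p_act <= alpha
    one_tailed_deactivation: int
    alpha: float
    fwer: float
    binomial_ci95: tuple

    def summary(self) -> dict:
        return {
            "reps": self.reps,
            "rejections": self.rejections,
            "rejections_activation": self.rejections_activation,
            "rejections_deactivation": self.rejections_deactivation,
            "one_tailed_activation": self.one_tailed_activation,
            "one_tailed_deactivation": self.one_tailed_deactivation,
            "alpha": self.alpha,
            "fwer": self.fwer,
            "fwer_one_tailed_activation": self.one_tailed_activation / self.reps,
            "fwer_one_tailed_deactivation": self.one_tailed_deactivation / self.reps,
            "binomial_ci95": list(self.binomial_ci95),
        }


def fwer_estimate(
    reps: int,
    n_per_group: int = 3,
    grid: tuple = (30, 25),
    mean: float = 50.0,
    sd: float = 20.0,
    alpha: float = 0.05,
    seed: int = 0,
    variance_fwhm: float = 2.0,
) -> FwerResult:
    """Monte-Carlo estimate of the family-wise error rate under a pure null.

    Each replicate draws ``2 * n_per_group`` i.i.d. normal maps, splits them
    arbitrarily into two groups and runs the step-down test; a replicate
    counts as a family-wise error when any cell reaches p <= alpha/2 in
    either tail (the two-tailed rule).  Adjusted p-values are multiples of
    1/N with minimum 1/N, so whenever alpha/2 < 1/N — in particular the
    minimal 3-vs-3 design, where 1/N = 1/20 = 0.05 — the two-tailed rate is
    exactly 0: control is strong but maximally conservative at that
    permutation resolution.  The per-tail one-tailed rejection rates at
    p <= alpha, whose nominal level the enumeration can attain, are counted
    alongside.  Replicates use independent substreams derived from
    (seed, replicate index).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    config = StatConfig(alpha=alpha, tails="two", variance_fwhm=variance_fwhm)
    scheme = enumerate_labelings(n_per_group, n_per_group)
    thr = alpha / 2.0
    hits = hits_act = hits_deact = one_act = one_deact = 0
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        data = rng.normal(mean, sd, size=(2 * n_per_group,) + tuple(grid))
        maps = step_down_adjusted_p(
            data[:n_per_group], data[n_per_group:], config=config, scheme=scheme
        )
        min_act = np.nanmin(maps.p_activation)
        min_deact = np.nanmin(maps.p_deactivation)
        act = bool(min_act <= thr)
        deact = bool(min_deact <= thr)
        hits_act += act
        hits_deact += deact
        hits += act or deact
        one_act += bool(min_act <= alpha)
        one_deact += bool(min_deact <= alpha)
    fwer = hits / reps
    half = 1.96 * math.sqrt(alpha * (1.0 - alpha) / reps)
    return FwerResult(
        reps=reps,
        rejections=hits,
        rejections_activation=hits_act,
        rejections_deactivation=hits_deact,
        one_tailed_activation=one_act,
        one_tailed_deactivation=one_deact,
        alpha=alpha,
        fwer=fwer,
        binomial_ci95=(max(0.0, alpha - half), min(1.0, alpha + half)),
    )
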