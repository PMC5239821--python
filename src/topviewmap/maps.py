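"""Top-view map assembly: animal maps, the reference map and condition maps.

An animal's profiled slices form a scatter of (bregma, lateral, OD) samples.
The map pipeline

1. collects the scatter per animal,
2. smooths the medial and lateral edge curves with a weighted moving average
   whose weights penalise local curvature (the complement of the relative
   second derivative), refitting each slice's points to the new boundaries,
3. averages point and landmark positions across animals,
4. smooths the averaged positions along the cutting axis with the same
   weighted moving average, snaps them to a grid at the sectioning interval
   and fills gaps by linear interpolation (the *reference map*),
5. assigns each animal's OD values to the reference positions, and
6. averages animals within a condition into a condition map, with a
   10x-upsampled, Gaussian-smoothed display raster.

All lateral coordinates are distances (mm) from the per-slice reference line;
the cutting-axis coordinate is the stereotaxic (bregma) position in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .slices import SliceProfile

__all__ = [
    "AnimalMap",
    "ReferenceMap",
    "ConditionStack",
    "ConditionMap",
    "second_derivative_weights",
    "weighted_moving_average",
    "curvature_penalized_smooth",
    "smooth_map_edges",
    "refit_slice",
    "build_reference_map",
    "map_animal_to_reference",
    "condition_mean",
    "difference_map",
    "sampling_distribution",
    "threshold_map",
    "apply_mask",
    "nan_gaussian",
]

_INTERVAL_RTOL = 0.01


# ---------------------------------------------------------------------------
# curvature-penalised weighted moving average


def second_derivative_weights(x) -> np.ndarray:
    """Weights 1 - |D|/max|D| from mirror-padded second differences.

    The sequence is padded by mirroring its second and second-to-last values,
    so the discrete second difference D_n = 2*X_n - X_{n-1} - X_{n+1} is
    defined at every point.  A constant or locally linear stretch gets weight
    1; the sharpest bump gets weight 0.
    """
    seq = np.asarray(x, dtype=float)
    if seq.ndim != 1 or seq.size < 2:
        raise ValidationError("need a 1-D sequence of length >= 2")
    padded = np.concatenate([[seq[1]], seq, [seq[-2]]])
    d = 2.0 * padded[1:-1] - padded[:-2] - padded[2:]
    dmax = np.abs(d).max()
    if dmax < 1e-12:
        return np.ones_like(seq)
    return 1.0 - np.abs(d) / dmax


def weighted_moving_average(x, weights, w: int) -> np.ndarray:
    """Weight-normalised moving average over a window clipped to the sequence.

    Falls back to the unweighted window mean wherever all window weights
    vanish, so a maximally penalised point is replaced by its neighbourhood
    mean rather than left undefined.
    """
    seq = np.asarray(x, dtype=float)
    wt = np.asarray(weights, dtype=float)
    if seq.shape != wt.shape:
        raise ValidationError("x and weights must have the same length")
    if w < 1 or w % 2 == 0:
        raise ValidationError("window w must be an odd integer >= 1")
    half = w // 2
    out = np.empty_like(seq)
    n = seq.size
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        win_w = wt[lo:hi]
        wsum = win_w.sum()
        if wsum > 0.0:
            out[i] = float(np.dot(win_w, seq[lo:hi]) / wsum)
        else:
            out[i] = float(seq[lo:hi].mean())
    return out


def curvature_penalized_smooth(x, w: int = 3) -> np.ndarray:
    """Apply the curvature-penalised weighted moving average to a sequence.

    NaN entries are ignored: the smoother runs on the finite subsequence and
    NaNs are preserved in place.
    """
    seq = np.asarray(x, dtype=float)
    finite = np.isfinite(seq)
    if finite.sum() < 2:
        return seq.copy()
    vals = seq[finite]
    smoothed = weighted_moving_average(vals, second_derivative_weights(vals), w)
    out = seq.copy()
    out[finite] = smoothed
    return out


# ---------------------------------------------------------------------------
# containers


@dataclass
class AnimalMap:
    """All profiled slices of one animal as scattered points in the plane."""

    animal: str
    condition: str
    bregmas: np.ndarray  # (n_slices,)
    lateral: np.ndarray  # (n_slices, K-1) medial -> lateral
    od: np.ndarray  # (n_slices, K-1)
    landmarks: np.ndarray  # (n_slices, L)
    interval: float

    @classmethod
    def from_profiles(cls, profiles: list[SliceProfile]) -> "AnimalMap":
        if not profiles:
            raise ValidationError("no profiles given")
        animals = {p.metadata.animal for p in profiles}
        conditions = {p.metadata.condition for p in profiles}
        if len(animals) != 1 or len(conditions) != 1:
            raise ValidationError("profiles must belong to a single animal")
        profiles = sorted(profiles, key=lambda p: p.metadata.bregma)
        ks = {len(p.samples) for p in profiles}
        if len(ks) != 1:
            raise ValidationError("all slices of an animal must share the same K")
        ls = {p.landmark_distances.size for p in profiles}
        if len(ls) != 1:
            raise ValidationError("all slices must have the same landmark count")
        bregmas = np.array([p.metadata.bregma for p in profiles])
        if len(profiles) >= 2:
            steps = np.diff(bregmas)
            interval = float(np.median(steps))
            if np.any(np.abs(steps - interval) > _INTERVAL_RTOL * abs(interval)):
                raise ValidationError("slice interval not constant within 1%")
        else:
            interval = float("nan")
        return cls(
            animal=animals.pop(),
            condition=conditions.pop(),
            bregmas=bregmas,
            lateral=np.array([p.lateral for p in profiles]),
            od=np.array([p.od for p in profiles]),
            landmarks=np.array([p.landmark_distances for p in profiles]),
            interval=interval,
        )

    def copy(self) -> "AnimalMap":
        return AnimalMap(
            self.animal,
            self.condition,
            self.bregmas.copy(),
            self.lateral.copy(),
            self.od.copy(),
            self.landmarks.copy(),
            self.interval,
        )


@dataclass
class ReferenceMap:
    """Cross-animal average geometry on a grid along the cutting axis."""

    bregma_grid: np.ndarray  # (R,) equally spaced rows
    positions: np.ndarray  # (R, K-1) averaged lateral positions
    landmarks: np.ndarray  # (R, L)
    interval: float

    @property
    def medial_edge(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def lateral_edge(self) -> np.ndarray:
        return self.positions[:, -1]

    def grid_matches(self, other: "ReferenceMap") -> bool:
        return (
            self.positions.shape == other.positions.shape
            and np.allclose(self.bregma_grid, other.bregma_grid)
        )


@dataclass
class ConditionStack:
    """Per-animal OD rasters of one condition on the shared reference grid."""

    condition: str
    animals: list
    rasters: np.ndarray  # (n_animals, R, K-1); NaN = undefined
    reference: ReferenceMap

    def __post_init__(self) -> None:
        if self.rasters.ndim != 3 or self.rasters.shape[0] != len(self.animals):
            raise ValidationError("rasters must be (n_animals, R, K-1)")


@dataclass
class ConditionMap:
    condition: str
    mean: np.ndarray  # (R, K-1) arithmetic mean over defined animal values
    display: np.ndarray  # upsampled, Gaussian-smoothed raster
    reference: ReferenceMap
    n_animals: int
    upsample: int = 10


# ---------------------------------------------------------------------------
# NaN-aware raster helpers


def nan_gaussian(arr: np.ndarray, sigma, truncate: float = 3.0) -> np.ndarray:
    """Gaussian filter that renormalises over the defined footprint.

    Values and the finite-mask are convolved separately and divided, so
    signal never bleeds outside the footprint and edges are not darkened.
    """
    mask = np.isfinite(arr)
    filled = np.where(mask, arr, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="constant", truncate=truncate)
    den = ndimage.gaussian_filter(
        mask.astype(float), sigma, mode="constant", truncate=truncate
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask & (den < 1e-9)] = np.nan
    out[~mask] = np.nan  # keep the original footprint
    return out


def _nan_zoom(arr: np.ndarray, factor: int) -> np.ndarray:
    mask = np.isfinite(arr)
    filled = np.where(mask, arr, 0.0)
    num = ndimage.zoom(filled, factor, order=1, mode="nearest", grid_mode=True)
    den = ndimage.zoom(
        mask.astype(float), factor, order=1, mode="nearest", grid_mode=True
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 0.5] = np.nan
    return out


# ---------------------------------------------------------------------------
# map-level operations


def refit_slice(positions, landmarks, old_bounds, new_bounds):
    """Affine re-map of a slice's lateral coordinates to new edge positions.

    Sends the old (medial, lateral) boundary pair to the new pair — the
    offset-and-scale realisation of repositioning the reference line.
    """
    om, ol = old_bounds
    nm, nl = new_bounds
    if not (ol > om):
        raise ValidationError("degenerate slice extent (zero or negative width)")
    if not (nl > nm):
        raise ValidationError("new boundaries must satisfy medial < lateral")
    scale = (nl - nm) / (ol - om)

    def f(x):
        return nm + (np.asarray(x, dtype=float) - om) * scale

    return f(positions), f(landmarks)


def smooth_map_edges(amap: AnimalMap, w: int = 3) -> AnimalMap:
    """Smooth an animal map's medial/lateral edge curves and refit its slices.

    Slices whose original extent is degenerate are filled by linear
    interpolation across neighbouring slices instead.
    """
    out = amap.copy()
    n = amap.bregmas.size
    if n < 2:
        warnings.warn("single-slice map: edge smoothing skipped", stacklevel=2)
        return out
    medial = amap.lateral[:, 0]
    lateral = amap.lateral[:, -1]
    new_medial = curvature_penalized_smooth(medial, w)
    new_lateral = curvature_penalized_smooth(lateral, w)
    failed = []
    for i in range(n):
        try:
            pos, lms = refit_slice(
                amap.lateral[i],
                amap.landmarks[i],
                (medial[i], lateral[i]),
                (new_medial[i], new_lateral[i]),
            )
        except ValidationError:
            failed.append(i)
            continue
        out.lateral[i] = pos
        out.landmarks[i] = lms
    if failed:
        good = np.setdiff1d(np.arange(n), failed)
        if good.size < 2:
            raise ValidationError("too few valid slices to interpolate positions")
        for arr in (out.lateral, out.landmarks):
            for col in range(arr.shape[1]):
                arr[failed, col] = np.interp(
                    amap.bregmas[failed], amap.bregmas[good], arr[good, col]
                )
    return out


def _common_interval(maps) -> float:
    intervals = np.array([m.interval for m in maps])
    intervals = intervals[np.isfinite(intervals)]
    if intervals.size == 0:
        raise ValidationError("cannot determine sampling interval (single slices)")
    interval = float(np.median(intervals))
    if np.any(np.abs(intervals - interval) > _INTERVAL_RTOL * abs(interval)):
        raise ValidationError("animals do not share a common sampling interval")
    return interval


def _grid_rows(maps, interval: float) -> np.ndarray:
    lo = max(m.bregmas.min() for m in maps)
    hi = min(m.bregmas.max() for m in maps)
    if hi < lo - 0.5 * interval:
        raise ValidationError("animal bregma ranges do not overlap")
    n_rows = int(round((hi - lo) / interval)) + 1
    return lo + interval * np.arange(n_rows)


def _row_index(bregma, grid, interval):
    idx = np.round((bregma - grid[0]) / interval).astype(int)
    ok = (
        (idx >= 0)
        & (idx < grid.size)
        & (np.abs(bregma - grid[0] - idx * interval) <= 0.5 * interval)
    )
    return idx, ok


def _fill_nan_rows(col: np.ndarray) -> np.ndarray:
    finite = np.isfinite(col)
    if finite.all() or finite.sum() < 2:
        return col
    idx = np.arange(col.size)
    out = col.copy()
    out[~finite] = np.interp(idx[~finite], idx[finite], col[finite])
    return out


def build_reference_map(maps: list, w: int = 3) -> ReferenceMap:
    """Average point/landmark positions across animals onto a common grid.

    Positions are averaged across animals per (row, k) — a symmetric mean, so
    the result is invariant to animal order — then smoothed along the cutting
    axis with the curvature-penalised moving average, and missing grid rows
    are filled by linear interpolation.
    """
    if not maps:
        raise ValidationError("need at least one animal map")
    kk = {m.lateral.shape[1] for m in maps}
    ll = {m.landmarks.shape[1] for m in maps}
    if len(kk) != 1 or len(ll) != 1:
        raise ValidationError("animals must share the same K and landmark count")
    k1, nl = kk.pop(), ll.pop()
    interval = _common_interval(maps)
    grid = _grid_rows(maps, interval)
    n_rows = grid.size

    pos_sum = np.zeros((n_rows, k1))
    pos_cnt = np.zeros((n_rows, k1))
    lm_sum = np.zeros((n_rows, nl))
    lm_cnt = np.zeros((n_rows, nl))
    for m in maps:
        idx, ok = _row_index(m.bregmas, grid, interval)
        for i in np.nonzero(ok)[0]:
            r = idx[i]
            fin = np.isfinite(m.lateral[i])
            pos_sum[r, fin] += m.lateral[i, fin]
            pos_cnt[r, fin] += 1
            if nl:
                finl = np.isfinite(m.landmarks[i])
                lm_sum[r, finl] += m.landmarks[i, finl]
                lm_cnt[r, finl] += 1

    with np.errstate(invalid="ignore"):
        positions = np.where(pos_cnt > 0, pos_sum / np.maximum(pos_cnt, 1), np.nan)
        landmarks = np.where(lm_cnt > 0, lm_sum / np.maximum(lm_cnt, 1), np.nan)

    for col in range(k1):
        positions[:, col] = _fill_nan_rows(
            curvature_penalized_smooth(positions[:, col], w)
        )
    for col in range(nl):
        landmarks[:, col] = _fill_nan_rows(
            curvature_penalized_smooth(landmarks[:, col], w)
        )
    if np.isnan(positions).any():
        raise ValidationError("reference map has unfillable gaps")
    return ReferenceMap(
        bregma_grid=grid, positions=positions, landmarks=landmarks, interval=interval
    )


def map_animal_to_reference(amap: AnimalMap, ref: ReferenceMap) -> np.ndarray:
    """Raster of one animal's OD values on the reference grid (NaN outside)."""
    if amap.od.shape[1] != ref.positions.shape[1]:
        raise ValidationError("animal K does not match the reference map")
    raster = np.full(ref.positions.shape, np.nan)
    idx, ok = _row_index(amap.bregmas, ref.bregma_grid, ref.interval)
    if not ok.any():
        raise ValidationError("animal has no slices overlapping the reference grid")
    raster[idx[ok]] = amap.od[ok]
    return raster


def condition_mean(
    stack: ConditionStack,
    upsample: int = 10,
    display_fwhm_intervals: float = 2.0,
) -> ConditionMap:
    """Mean condition map plus its upsampled, Gaussian-smoothed display raster.

    The display raster is bilinearly upsampled by ``upsample`` in both axes
    and smoothed with a Gaussian of FWHM ``display_fwhm_intervals`` sampling
    intervals, NaN-aware so the footprint does not bleed.
    """
    if stack.rasters.shape[0] == 0:
        raise ValidationError("empty condition stack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack.rasters, axis=0)
    up = _nan_zoom(mean, upsample)
    sigma = display_fwhm_intervals * upsample / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    display = nan_gaussian(up, sigma)
    return ConditionMap(
        condition=stack.condition,
        mean=mean,
        display=display,
        reference=stack.reference,
        n_animals=stack.rasters.shape[0],
        upsample=upsample,
    )


def difference_map(a: ConditionMap, b: ConditionMap) -> np.ndarray:
    """Pixel-wise difference of two condition means on the common footprint."""
    if a.mean.shape != b.mean.shape or not a.reference.grid_matches(b.reference):
        raise ValidationError("condition maps are on different grids")
    return a.mean - b.mean


def sampling_distribution(ref: ReferenceMap) -> dict:
    """Tukey summary of the lateral spacing between adjacent reference points.

    Returns the median, upper quartile and upper fence (Q3 + 1.5 IQR, clipped
    to the observed maximum) of |C[k+1] - C[k]| pooled over all grid rows —
    the achieved perpendicular (lateral) grid resolution in mm.
    """
    if ref.positions.shape[1] < 3:
        raise ValidationError("need at least 3 points per row")
    spacing = np.abs(np.diff(ref.positions, axis=1)).ravel()
    spacing = spacing[np.isfinite(spacing)]
    q1, med, q3 = np.quantile(spacing, [0.25, 0.5, 0.75])
    fence = min(q3 + 1.5 * (q3 - q1), float(spacing.max()))
    return {
        "median_mm": float(med),
        "upper_quartile_mm": float(q3),
        "upper_fence_mm": float(fence),
    }


def threshold_map(cmap: ConditionMap, q: float) -> np.ndarray:
    """Keep cells at or above the q-quantile of the defined cell intensities."""
    if not 0.0 <= q < 1.0:
        raise ValidationError("quantile must be in [0, 1)")
    vals = cmap.mean[np.isfinite(cmap.mean)]
    if vals.size == 0:
        raise ValidationError("map has no defined cells")
    thr = np.quantile(vals, q)
    return np.isfinite(cmap.mean) & (cmap.mean >= thr)


def apply_mask(cmap: ConditionMap, polygons: dict) -> np.ndarray:
    """Label each defined cell with the mask polygon containing its centre.

    ``polygons`` maps integer labels (> 0) to shapely polygons in map mm
    coordinates (x = lateral position, y = bregma).  Cells outside every
    polygon get label 0.  Masks are placed without rescaling or translation,
    so a mask drawn on one map transfers verbatim to any map sharing the
    coordinate system.
    """
    from shapely import points as shp_points
    from shapely import contains

    ref = cmap.reference
    ys = np.repeat(ref.bregma_grid[:, None], ref.positions.shape[1], axis=1)
    xs = ref.positions
    pts = shp_points(np.column_stack([xs.ravel(), ys.ravel()]))
    labels = np.zeros(cmap.mean.shape, dtype=np.int32)
    hit_any = False
    for lab, poly in polygons.items():
        inside = contains(poly, pts).reshape(labels.shape)
        inside &= np.isfinite(cmap.mean)
        if inside.any():
            hit_any = True
        labels[inside] = int(lab)
    if polygons and not hit_any:
        warnings.warn("mask polygons do not overlap the map footprint", stacklevel=2)
    return labels
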