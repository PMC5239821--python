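"""Per-section geometry and optical-density profiling.

A registered section consists of a grayscale image plus hand-traced (or
synthetically generated) geometry: the top and bottom edge of the region of
interest, optional histological landmarks on the top edge, a rectangular
background reference zone ``B`` and a reference line ``R``.  The region is cut
into ``K - 1`` radial, quadrangular segments by placing ``K`` arc-length
equidistant points on each edge.  Each segment yields one sample: its mean
optical density normalised against the background zone,

    OD_norm = 1 - <I_segment> / <I_background>,

and its lateral position, the perpendicular distance from the segment's
top-edge centre to the reference line.  The ordered (lateral, OD) pairs of a
section form its :class:`SliceProfile` and are the raw material of the
top-view maps built in :mod:`topviewmap.maps`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import GeometryError, ValidationError

__all__ = [
    "Line",
    "SliceDelineation",
    "SliceMetadata",
    "SegmentSample",
    "SliceProfile",
    "smooth_contour",
    "resample_arc",
    "validate_monotonic_x",
    "segment_mean_od",
    "project_center",
    "profile_slice",
    "assign_segments",
]

DARK_SIGNAL = "dark_signal"
BRIGHT_SIGNAL = "bright_signal"


@dataclass(frozen=True)
class Line:
    """Implicit line ``a*x + b*y + c = 0`` in mm, normalised to a^2 + b^2 = 1."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        norm = float(np.hypot(self.a, self.b))
        if not np.isfinite(norm) or norm == 0.0:
            raise GeometryError("degenerate line: (a, b) must not be (0, 0)")
        object.__setattr__(self, "a", self.a / norm)
        object.__setattr__(self, "b", self.b / norm)
        object.__setattr__(self, "c", self.c / norm)

    @classmethod
    def from_points(cls, p1, p2) -> "Line":
        (x1, y1), (x2, y2) = map(np.asarray, (p1, p2))
        a = float(y2 - y1)
        b = float(x1 - x2)
        c = float(x2 * y1 - x1 * y2)
        return cls(a, b, c)

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.a * pts[:, 0] + self.b * pts[:, 1] + self.c

    def distance(self, points) -> np.ndarray:
        return np.abs(self.signed_distance(points))


def as_polyline(points, name: str = "polyline") -> np.ndarray:
    """Validate and return an (n, 2) float array of polyline vertices."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError(f"{name}: expected an (n, 2) array of points")
    if arr.shape[0] < 2:
        raise GeometryError(f"{name}: needs at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name}: coordinates must be finite")
    return arr


@dataclass
class SliceDelineation:
    """Registered geometry of one section, all coordinates in mm.

    The mm frame has its origin at the image corner, x along columns and y
    along rows, so a pixel at (row r, col c) has its centre at
    ``((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)``.
    """

    top_edge: np.ndarray
    bottom_edge: np.ndarray
    reference_line: Line
    background_box: tuple  # (x0, y0, x1, y1) mm
    pixel_size: float
    landmarks: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    signal_polarity: str = DARK_SIGNAL

    def __post_init__(self) -> None:
        self.top_edge = as_polyline(self.top_edge, "top_edge")
        self.bottom_edge = as_polyline(self.bottom_edge, "bottom_edge")
        self.landmarks = np.asarray(self.landmarks, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.background_box
        if not (x1 > x0 and y1 > y0):
            raise GeometryError("background_box must have positive extent")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.signal_polarity not in (DARK_SIGNAL, BRIGHT_SIGNAL):
            raise ValidationError(
                f"signal_polarity must be '{DARK_SIGNAL}' or '{BRIGHT_SIGNAL}'"
            )


@dataclass(frozen=True)
class SliceMetadata:
    condition: str
    animal: str
    filename: str
    bregma: float  # mm along the cutting axis

    def __post_init__(self) -> None:
        if not self.condition or not self.animal:
            raise ValidationError("condition and animal labels must be non-empty")
        if not np.isfinite(self.bregma):
            raise ValidationError("bregma must be finite")


@dataclass(frozen=True)
class SegmentSample:
    index: int
    corners: np.ndarray  # (4, 2): [P_top^k, P_top^{k+1}, P_bot^{k+1}, P_bot^k]
    center: np.ndarray  # midpoint of the two top-edge points
    od_normalized: float
    lateral_distance: float


@dataclass(frozen=True)
class SliceProfile:
    metadata: SliceMetadata
    samples: tuple  # (K-1) SegmentSamples ordered medial -> lateral
    landmark_distances: np.ndarray  # (L,) projected landmark positions, mm

    @property
    def lateral(self) -> np.ndarray:
        return np.array([s.lateral_distance for s in self.samples])

    @property
    def od(self) -> np.ndarray:
        return np.array([s.od_normalized for s in self.samples])


# ---------------------------------------------------------------------------
# contour smoothing


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def smooth_contour(edge, window: int = 7) -> np.ndarray:
    """Smooth a polyline by local weighted orthogonal regression.

    Each vertex is replaced by its orthogonal projection onto the total
    least-squares line fitted through its ``window`` nearest neighbours along
    the polyline, with tricube weights that decay with distance from the
    vertex.  Polylines shorter than the window are returned unchanged.
    """
    pts = as_polyline(edge, "edge")
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 3")
    n = pts.shape[0]
    if n < window:
        return pts.copy()
    half = window // 2
    out = pts.copy()
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        nbrs = pts[lo:hi]
        d = np.linalg.norm(nbrs - pts[i], axis=1)
        dmax = d.max()
        if dmax == 0.0:
            continue  # coincident points: nothing to fit
        w = _tricube(d / (dmax * 1.0001))
        wsum = w.sum()
        centre = (w[:, None] * nbrs).sum(0) / wsum
        centred = nbrs - centre
        cov = (w[:, None] * centred).T @ centred
        # principal axis of the weighted scatter = orthogonal regression line
        _, vecs = np.linalg.eigh(cov)
        direction = vecs[:, -1]
        out[i] = centre + np.dot(pts[i] - centre, direction) * direction
    return out


def resample_arc(edge, k: int) -> np.ndarray:
    """Place ``k`` points at equal cumulative arc length along a polyline."""
    pts = as_polyline(edge, "edge")
    if k < 2:
        raise ValidationError("K must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise GeometryError("polyline has zero arc length")
    targets = np.linspace(0.0, total, k)
    xs = np.interp(targets, s, pts[:, 0])
    ys = np.interp(targets, s, pts[:, 1])
    out = np.column_stack([xs, ys])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def validate_monotonic_x(points) -> np.ndarray:
    """Check that x strictly increases along the points; auto-flip if reversed.

    Returns the points oriented with increasing x, or raises
    :class:`ValidationError` naming the first offending index.
    """
    pts = as_polyline(points, "points")
    if pts[-1, 0] < pts[0, 0]:
        pts = pts[::-1].copy()
    dx = np.diff(pts[:, 0])
    bad = np.nonzero(dx <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"x positions not strictly monotonic at index {bad[0] + 1}"
        )
    return pts


# ---------------------------------------------------------------------------
# pixel membership and optical density


def _adjust_polarity(image: np.ndarray, polarity: str) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValidationError("expected a single-channel 2-D image")
    if polarity == DARK_SIGNAL:
        return img.astype(float)
    if polarity == BRIGHT_SIGNAL:
        if np.issubdtype(img.dtype, np.integer):
            imax = float(np.iinfo(img.dtype).max)
        else:
            imax = 1.0
        return imax - img.astype(float)
    raise ValidationError(f"unknown signal polarity: {polarity!r}")


def assign_segments(shape, top_pts, bottom_pts, pixel_size: float) -> np.ndarray:
    """Label every pixel of an image with its segment index (0 = outside).

    ``top_pts``/``bottom_pts`` are the K resampled edge points in mm.  A pixel
    belongs to segment k (1-based) when its centre lies inside the ribbon
    strip and between the radial boundaries k and k+1.  Membership on a shared
    boundary is resolved half-open so adjacent segments never share a pixel.
    """
    top = as_polyline(top_pts, "top_pts")
    bot = as_polyline(bottom_pts, "bottom_pts")
    if top.shape != bot.shape:
        raise GeometryError("top and bottom must have the same number of points")
    kpts = top.shape[0]
    nrow, ncol = shape

    xs = np.concatenate([top[:, 0], bot[:, 0]])
    ys = np.concatenate([top[:, 1], bot[:, 1]])
    c0 = max(0, int(np.floor(xs.min() / pixel_size - 0.5)))
    c1 = min(ncol, int(np.ceil(xs.max() / pixel_size + 0.5)))
    r0 = max(0, int(np.floor(ys.min() / pixel_size - 0.5)))
    r1 = min(nrow, int(np.ceil(ys.max() / pixel_size + 0.5)))
    labels = np.zeros(shape, dtype=np.int32)
    if c1 <= c0 or r1 <= r0:
        return labels

    cols = (np.arange(c0, c1) + 0.5) * pixel_size
    rows = (np.arange(r0, r1) + 0.5) * pixel_size
    px, py = np.meshgrid(cols, rows)
    pts = np.column_stack([px.ravel(), py.ravel()])

    ribbon = np.concatenate([top, bot[::-1]])
    inside = MplPath(ribbon).contains_points(pts)

    # signed side of each radial boundary (bottom_k -> top_k)
    dirs = top - bot  # (K, 2)
    rel_x = pts[:, 0][:, None] - bot[None, :, 0]
    rel_y = pts[:, 1][:, None] - bot[None, :, 1]
    cross = dirs[None, :, 0] * rel_y - dirs[None, :, 1] * rel_x  # (P, K)

    quad1_centroid = (top[0] + top[1] + bot[0] + bot[1]) / 4.0
    ref = (
        dirs[0, 0] * (quad1_centroid[1] - bot[0, 1])
        - dirs[0, 1] * (quad1_centroid[0] - bot[0, 0])
    )
    if ref == 0.0:
        raise GeometryError("degenerate first segment (zero area)")
    sign = 1.0 if ref > 0 else -1.0

    count = (sign * cross > 0.0).sum(axis=1)  # boundary ties fall leftward
    seg = np.where((count >= 1) & (count <= kpts - 1) & inside, count, 0)
    labels[r0:r1, c0:c1] = seg.reshape(r1 - r0, c1 - c0)
    return labels


def _background_mean(image: np.ndarray, box, pixel_size: float) -> float:
    x0, y0, x1, y1 = box
    nrow, ncol = image.shape
    cols = (np.arange(ncol) + 0.5) * pixel_size
    rows = (np.arange(nrow) + 0.5) * pixel_size
    csel = (cols >= x0) & (cols < x1)
    rsel = (rows >= y0) & (rows < y1)
    if not csel.any() or not rsel.any():
        raise GeometryError("background box encloses no pixel centre")
    return float(image[np.ix_(rsel, csel)].mean())


def segment_mean_od(
    image,
    corners,
    background_box,
    pixel_size: float,
    polarity: str = DARK_SIGNAL,
) -> float:
    """Normalised mean optical density of one quadrangular segment.

    ``corners`` is the (4, 2) mm quadrilateral
    [P_top^k, P_top^{k+1}, P_bot^{k+1}, P_bot^k].  Returns
    ``1 - mean(segment) / mean(background)`` on polarity-adjusted intensities.
    """
    img = _adjust_polarity(image, polarity)
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise GeometryError("corners must be a (4, 2) array")
    top = corners[:2]
    bot = corners[[3, 2]]
    labels = assign_segments(img.shape, top, bot, pixel_size)
    inside = labels == 1
    if not inside.any():
        raise GeometryError("segment encloses no pixel centre")
    bg = _background_mean(img, background_box, pixel_size)
    if bg <= 0.0:
        raise GeometryError("background mean must be positive")
    return float(1.0 - img[inside].mean() / bg)


def project_center(line: Line, p_k, p_k1) -> float:
    """Perpendicular distance from the midpoint of two edge points to a line."""
    centre = (np.asarray(p_k, dtype=float) + np.asarray(p_k1, dtype=float)) / 2.0
    return float(line.distance(centre[None, :])[0])


# ---------------------------------------------------------------------------
# full slice profile


def profile_slice(
    image,
    delineation: SliceDelineation,
    metadata: SliceMetadata,
    k: int,
    contour_window: int = 7,
) -> SliceProfile:
    """Segment a registered section and project its OD profile onto the plane.

    Both edges are contour-smoothed, resampled to ``k`` arc-length equidistant
    points (x validated to be strictly monotonic), and the resulting K-1
    quadrangular segments are averaged and projected with the reference line.
    The returned samples are ordered from medial (small lateral distance) to
    lateral.
    """
    if k < 2:
        raise ValidationError("K must be >= 2")
    img = _adjust_polarity(image, delineation.signal_polarity)
    ps = delineation.pixel_size

    top = smooth_contour(delineation.top_edge, contour_window)
    bot = smooth_contour(delineation.bottom_edge, contour_window)
    top_k = validate_monotonic_x(resample_arc(top, k))
    bot_k = validate_monotonic_x(resample_arc(bot, k))

    labels = assign_segments(img.shape, top_k, bot_k, ps)
    bg = _background_mean(img, delineation.background_box, ps)
    if bg <= 0.0:
        raise GeometryError("background mean must be positive")

    line = delineation.reference_line
    centres = (top_k[:-1] + top_k[1:]) / 2.0
    signed = line.signed_distance(centres)
    lm = delineation.landmarks
    if lm.size:
        signed = np.concatenate([signed, line.signed_distance(lm)])
    if signed.min() < 0 < signed.max():
        raise ValidationError(
            "slice straddles the reference line; all segment centres and "
            "landmarks must lie on one side"
        )

    samples = []
    for seg in range(1, k):
        inside = labels == seg
        if not inside.any():
            raise GeometryError(f"segment {seg} encloses no pixel centre")
        od = float(1.0 - img[inside].mean() / bg)
        corners = np.array(
            [top_k[seg - 1], top_k[seg], bot_k[seg], bot_k[seg - 1]]
        )
        centre = centres[seg - 1]
        dist = float(line.distance(centre[None, :])[0])
        samples.append(
            SegmentSample(
                index=seg,
                corners=corners,
                center=centre,
                od_normalized=od,
                lateral_distance=dist,
            )
        )

    lateral = np.array([s.lateral_distance for s in samples])
    if lateral[0] > lateral[-1]:
        samples = samples[::-1]
        lateral = lateral[::-1]
    if np.any(np.diff(lateral) <= 0):
        bad = int(np.nonzero(np.diff(lateral) <= 0)[0][0]) + 1
        raise ValidationError(
            f"projected lateral positions not strictly monotonic at sample {bad}"
        )

    lm_dist = (
        line.distance(lm) if lm.size else np.zeros(0)
    )
    return SliceProfile(
        metadata=metadata,
        samples=tuple(samples),
        landmark_distances=np.asarray(lm_dist, dtype=float),
    )
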