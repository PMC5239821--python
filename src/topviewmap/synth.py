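"""Synthetic inputs: null map stacks and curved-ribbon phantom studies.

Two kinds of synthetic data exercise the pipeline without any wet-lab input:

* **Null stacks** — per-animal rasters of i.i.d. normal OD values (defaults:
  mean 50%, SD 20%, 30x25 grid, 6 animals split 3 vs 3), the configuration
  used to validate family-wise error control of the randomization test.

* **Phantom studies** — rendered grayscale section images of a curved
  cortical ribbon (an annular sector, mimicking the coronal profile of
  cortex) spanning a fixed anterior-posterior interval, together with the
  delineation geometry and metadata the pipeline consumes.  The ribbon's
  intensity encodes a ground-truth OD field (a base level plus circular
  effect patches in map coordinates), a low-signal rectangular box provides
  the background reference, and a vertical line at the medial edge is the
  reference line.  Ground truth is saved alongside so recovery error is
  quantifiable.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .slices import (
    DARK_SIGNAL,
    Line,
    SliceDelineation,
    SliceMetadata,
)

__all__ = [
    "NullStackSpec",
    "RibbonGeometry",
    "EffectPatch",
    "PhantomStudySpec",
    "generate_null_stacks",
    "generate_phantom_slice",
    "generate_study",
]

U16_MAX = 65535


@dataclass(frozen=True)
class NullStackSpec:
    """Pure random-map stacks for the FWER experiment."""

    n_animals: int = 6
    grid: tuple = (30, 25)
    mean: float = 50.0  # OD %
    sd: float = 20.0  # OD %
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("sd must be > 0")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValidationError("grid dimensions must be >= 1")
        if self.n_animals < 2:
            raise ValidationError("need at least 2 animals")


def generate_null_stacks(spec: NullStackSpec) -> tuple:
    """Two condition stacks of i.i.d. normal maps, split n//2 vs the rest."""
    rng = np.random.default_rng(spec.seed)
    data = rng.normal(
        spec.mean, spec.sd, size=(spec.n_animals,) + tuple(spec.grid)
    )
    half = spec.n_animals // 2
    return data[:half], data[half:]


# ---------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class RibbonGeometry:
    """Annular-sector ribbon in image mm coordinates (y increases downward).

    The arc centre sits near the top-left corner; the ribbon spans polar
    angles theta (measured from straight down, opening laterally) between
    ``theta_min_deg`` and ``theta_max_deg`` and radii between
    ``outer_radius - thickness`` and ``outer_radius``.  The reference line is
    the vertical through the arc centre, so the lateral coordinate of a
    ribbon point at angle theta on the pial (outer) surface is
    ``outer_radius * sin(theta)``.  Set ``shape='rect'`` for an axis-aligned
    rectangular ribbon with the same lateral extent (exact analytic checks).
    """

    outer_radius: float = 3.0  # mm, pial surface
    thickness: float = 0.8  # mm
    theta_min_deg: float = 10.0
    theta_max_deg: float = 75.0
    pixel_size: float = 0.02  # mm per pixel
    margin: float = 0.15  # mm from the arc centre to the image corner
    shape: str = "annular"  # 'annular' | 'rect'
    n_edge_points: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.theta_min_deg < self.theta_max_deg < 90:
            raise ValidationError("need 0 < theta_min < theta_max < 90 degrees")
        if self.thickness <= 0 or self.thickness >= self.outer_radius:
            raise ValidationError("thickness must be in (0, outer_radius)")
        if self.shape not in ("annular", "rect"):
            raise ValidationError("shape must be 'annular' or 'rect'")

    @property
    def center(self) -> tuple:
        return (self.margin, self.margin)

    @property
    def lateral_range(self) -> tuple:
        t0, t1 = np.radians([self.theta_min_deg, self.theta_max_deg])
        return (
            self.outer_radius * float(np.sin(t0)),
            self.outer_radius * float(np.sin(t1)),
        )

    @property
    def image_shape(self) -> tuple:
        extent = self.margin + self.outer_radius + self.margin
        n = int(np.ceil(extent / self.pixel_size))
        return (n, n)

    def background_box(self) -> tuple:
        """Rectangle in the sub-ribbon ('white matter') zone, mm."""
        cx, cy = self.center
        r_in = self.outer_radius - self.thickness
        if self.shape == "rect":
            y0 = cy + self.outer_radius + 2 * self.pixel_size
            y1 = min(y0 + 0.3, self.image_shape[0] * self.pixel_size - self.pixel_size)
            return (cx + 0.2, y0, cx + 0.6, y1)
        mid = np.radians(45.0)
        r = 0.45 * r_in
        bx, by = cx + r * np.sin(mid), cy + r * np.cos(mid)
        h = min(0.15, 0.25 * r_in)
        return (bx - h, by - h, bx + h, by + h)


@dataclass(frozen=True)
class EffectPatch:
    """Circular OD offset in map coordinates (bregma, lateral), mm."""

    condition: str
    bregma_mm: float
    lateral_mm: float
    radius_mm: float
    delta_od: float

    def contains(self, bregma, lateral):
        return (np.asarray(bregma) - self.bregma_mm) ** 2 + (
            np.asarray(lateral) - self.lateral_mm
        ) ** 2 <= self.radius_mm**2


@dataclass(frozen=True)
class PhantomStudySpec:
    """A complete two-condition phantom study design."""

    conditions: tuple = (("control", 3), ("treated", 3))
    slices_per_animal: int = 8
    interval_mm: float = 0.1  # serial sectioning interval
    bregma_start: float = 0.0
    geometry: RibbonGeometry = field(default_factory=RibbonGeometry)
    base_od: float = 0.4
    patches: tuple = ()
    noise_sd: float = 0.05  # OD units, i.i.d. per pixel
    animal_jitter_sd: float = 0.015  # mm, per-animal radial offset of the ribbon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slices_per_animal < 2:
            raise ValidationError("need at least 2 slices per animal")
        if self.interval_mm <= 0:
            raise ValidationError("interval must be positive")
        known = {c for c, _ in self.conditions}
        lat_lo, lat_hi = self.geometry.lateral_range
        b_lo = self.bregma_start
        b_hi = self.bregma_start + (self.slices_per_animal - 1) * self.interval_mm
        for p in self.patches:
            if p.condition not in known:
                raise ValidationError(f"patch condition {p.condition!r} unknown")
            if not (lat_lo <= p.lateral_mm <= lat_hi and b_lo <= p.bregma_mm <= b_hi):
                raise ValidationError("patch centre outside the ribbon footprint")

    def bregmas(self) -> np.ndarray:
        return self.bregma_start + self.interval_mm * np.arange(
            self.slices_per_animal
        )


def _od_field(spec: PhantomStudySpec, condition: str, bregma, lateral):
    od = np.full(np.broadcast(np.asarray(bregma), np.asarray(lateral)).shape,
                 spec.base_od, dtype=float)
    for p in spec.patches:
        if p.condition == condition:
            od = od + p.delta_od * p.contains(bregma, lateral)
    return od


def generate_phantom_slice(
    geometry: RibbonGeometry,
    od_of_lateral,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    radial_offset: float = 0.0,
    reference_level: float = 0.55,
) -> tuple:
    """Render one phantom section image plus its delineation.

    ``od_of_lateral`` maps an array of lateral positions (mm) to target OD
    values in [0, 1).  With dark-signal polarity the ribbon intensity is
    ``reference_level * U16_MAX * (1 - OD)`` so that profiling against the
    background box (held exactly at the reference level) recovers the OD
    field up to rasterisation error.  ``radial_offset`` shifts both edges
    radially (per-animal anatomical variability).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ps = geometry.pixel_size
    nrow, ncol = geometry.image_shape
    cx, cy = geometry.center
    r_out = geometry.outer_radius + radial_offset
    r_in = r_out - geometry.thickness
    i_ref = reference_level * U16_MAX

    xs = (np.arange(ncol) + 0.5) * ps
    ys = (np.arange(nrow) + 0.5) * ps
    px, py = np.meshgrid(xs, ys)

    if geometry.shape == "annular":
        dx, dy = px - cx, py - cy
        r = np.hypot(dx, dy)
        theta = np.degrees(np.arctan2(dx, dy))  # 0 = straight down, + lateral
        in_ribbon = (
            (r >= r_in)
            & (r <= r_out)
            & (theta >= geometry.theta_min_deg)
            & (theta <= geometry.theta_max_deg)
        )
        lateral = r_out * np.sin(np.radians(theta))
        t0, t1 = np.radians([geometry.theta_min_deg, geometry.theta_max_deg])
        thetas = np.linspace(t0, t1, geometry.n_edge_points)
        top = np.column_stack(
            [cx + r_out * np.sin(thetas), cy + r_out * np.cos(thetas)]
        )
        bottom = np.column_stack(
            [cx + r_in * np.sin(thetas), cy + r_in * np.cos(thetas)]
        )
        lm_th = np.linspace(t0, t1, 2 + 2)[1:-1]
        landmarks = np.column_stack(
            [cx + r_out * np.sin(lm_th), cy + r_out * np.cos(lm_th)]
        )
    else:  # axis-aligned rectangle, same lateral extent
        lat_lo, lat_hi = geometry.lateral_range
        y_top = cy + r_out - geometry.thickness
        y_bot = cy + r_out
        in_ribbon = (
            (px >= cx + lat_lo)
            & (px <= cx + lat_hi)
            & (py >= y_top)
            & (py <= y_bot)
        )
        lateral = px - cx
        xs_edge = cx + np.linspace(lat_lo, lat_hi, geometry.n_edge_points)
        top = np.column_stack([xs_edge, np.full_like(xs_edge, y_top)])
        bottom = np.column_stack([xs_edge, np.full_like(xs_edge, y_bot)])
        lm_x = cx + lat_lo + (lat_hi - lat_lo) * np.array([1 / 3, 2 / 3])
        landmarks = np.column_stack([lm_x, np.full(2, y_top)])

    od = np.asarray(od_of_lateral(lateral), dtype=float)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)

    image = np.full((nrow, ncol), 0.9 * U16_MAX)
    image[in_ribbon] = i_ref * (1.0 - od[in_ribbon])
    x0, y0, x1, y1 = geometry.background_box()
    bsel = (px >= x0) & (px < x1) & (py >= y0) & (py < y1)
    image[bsel] = i_ref
    image = np.clip(np.rint(image), 0, U16_MAX).astype(np.uint16)

    delineation = SliceDelineation(
        top_edge=top,
        bottom_edge=bottom,
        reference_line=Line(1.0, 0.0, -cx),  # vertical at the medial edge
        background_box=(x0, y0, x1, y1),
        pixel_size=ps,
        landmarks=landmarks,
        signal_polarity=DARK_SIGNAL,
    )
    return image, delineation


def generate_study(spec: PhantomStudySpec, outdir: str | Path) -> dict:
    """Write a complete, immediately runnable phantom study to ``outdir``.

    Produces per-slice TIFF images and delineation JSON files, a metadata
    TSV, and a ``truth.json`` with the ground-truth OD field parameters for
    recovery scoring.  Returns the manifest (paths plus slice records).
    """
    from . import fileio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    bregmas = spec.bregmas()
    animal_idx = 0
    for condition, n_animals in spec.conditions:
        for a in range(n_animals):
            animal = f"{condition}_{a + 1}"
            jitter_rng = np.random.default_rng([spec.seed, animal_idx])
            radial = float(jitter_rng.normal(0.0, spec.animal_jitter_sd))
            for s, bregma in enumerate(bregmas):
                rng = np.random.default_rng([spec.seed, animal_idx, s])
                image, delineation = generate_phantom_slice(
                    spec.geometry,
                    lambda lat: _od_field(spec, condition, bregma, lat),
                    noise_sd=spec.noise_sd,
                    rng=rng,
                    radial_offset=radial,
                )
                stem = f"{animal}_s{s:03d}"
                img_path = outdir / f"{stem}.tif"
                geo_path = outdir / f"{stem}.json"
                fileio.write_image(img_path, image)
                fileio.write_delineation(geo_path, delineation)
                records.append(
                    {
                        "condition": condition,
                        "animal": animal,
                        "filename": img_path.name,
                        "bregma_mm": float(bregma),
                    }
                )
            animal_idx += 1

    meta_path = outdir / "metadata.tsv"
    fileio.write_metadata(meta_path, records)
    truth = {
        "base_od": spec.base_od,
        "noise_sd": spec.noise_sd,
        "patches": [asdict(p) for p in spec.patches],
        "lateral_range_mm": list(spec.geometry.lateral_range),
        "bregma_range_mm": [float(bregmas[0]), float(bregmas[-1])],
        "interval_mm": spec.interval_mm,
        "seed": spec.seed,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {
        "outdir": str(outdir),
        "metadata": str(meta_path),
        "truth": str(truth_path),
        "n_slices": len(records),
        "records": records,
    }
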