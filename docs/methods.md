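# Methods

## Section profiling

A registered section consists of a grayscale image (8/16-bit TIFF or PNG), a
traced top and bottom edge of the region of interest, optional landmarks on
the top edge, a rectangular background zone and a reference line. All
geometry is stored on disk in continuous pixel coordinates and converted to
mm with the per-slice pixel size; the mm frame has x along columns, y along
rows, and pixel (r, c) centred at ((c + 0.5) ps, (r + 0.5) ps).

**Edge smoothing.** Raw traced edges are smoothed by local weighted
orthogonal regression: each vertex is projected onto the total-least-squares
line through its window of neighbours (default 7 points), with tricube
weights decaying with distance from the vertex. Orthogonal (rather than
ordinary) regression keeps the operation parameterisation-free for steep
edge orientations.

**Segmentation.** Each edge is resampled to K arc-length-equidistant points
(linear interpolation along the cumulative chord length of the densely
traced polyline; endpoints preserved exactly). The x-positions of the
resampled points must be strictly monotonic (orientation is auto-normalised;
violations are an error naming the offending index). The K-1 quadrangular
segments between corresponding point pairs partition the ribbon: a pixel
belongs to the segment whose radial boundaries bracket its centre, with a
half-open tie rule on shared boundaries so adjacent segments never share a
pixel and the union of segments equals the enclosed ribbon.

**Optical density.** `OD_norm = 1 - <I_seg>/<I_bg>` on polarity-adjusted
intensities. A `signal_polarity` flag inverts intensities (I' = I_max - I,
dtype maximum for integer images) for bright-signal material (fluorescence),
so the dark-signal convention of the formula always holds. Intensities are
used as raw polarity-adjusted grayscale; no log transform is applied — users
whose film response requires true optical density should linearise before
input. The background mean must be positive; empty segments are an error.

**Projection.** Segment centres are the midpoints of adjacent *top-edge*
points — a top view represents the surface, so the pial positions carry the
map coordinate. Lateral position is the unsigned perpendicular distance to
the reference line; all centres and landmarks of a slice must lie on one
side of the line (validated), and profiles are normalised to run
medial → lateral.

## Map construction

Per animal, profiled slices are stacked along the bregma axis (constant
interval within 1%, equal K). The medial and lateral edge curves are then
smoothed with the curvature-penalised weighted moving average: the sequence
is mirror-padded (second and second-to-last values), the second difference
D_n = 2X_n - X_{n-1} - X_{n+1} is computed at every point, normalised by its
maximum absolute value, and the complement 1 - |D|/max|D| weights a moving
average over a window w (default 3, the smallest symmetric window; single
pass, no iteration). Absolute values are taken before the complement so
weights stay in [0, 1]. If all window weights vanish (e.g. the two-point
case, where mirror padding zeroes both weights) the unweighted window mean
is used. The smoother fixes constants and contracts total variation; both
properties are tested.

Each slice's interior points and landmarks are refitted to the smoothed
boundaries by the affine map sending the old (medial, lateral) pair to the
new pair — the offset-and-scale realisation of "repositioning the reference
line"; a translation alone could not match both boundaries. Degenerate
slices (zero width) are filled by linear interpolation across neighbouring
slices.

The reference map averages positions per grid cell across animals with a
plain mean — deliberately symmetric, so the result is invariant to animal
order — followed by the same curvature-penalised smoothing along the cutting
axis per column, on a grid at the sampling interval covering the
intersection of the animals' bregma ranges; remaining gaps are filled by 1-D
linear interpolation along the cutting axis (a 2-D inpaint is out of scope).
Each animal's OD values are then assigned by (row, k) index to the reference
positions (nearest grid row within half an interval). Condition maps are
per-cell means over defined values; the display raster is 10x bilinearly
upsampled and Gaussian-smoothed with FWHM = 2 sampling intervals, NaN-aware
(values and footprint convolved separately and divided, truncation 3 sigma)
so signal never bleeds outside the footprint. Difference maps are defined on
the intersection of footprints.

The lateral sampling resolution of the reference map is summarised by the
median, upper quartile and Tukey upper fence (Q3 + 1.5 IQR, clipped to the
observed maximum) of adjacent-point spacings pooled over rows. Maps can be
thresholded at an intensity quantile (cells >= the q-quantile of defined
cells) and labelled with GeoJSON mask polygons placed in map mm coordinates
without rescaling or translation, so masks transfer verbatim between maps
sharing the coordinate frame. Layer-wise maps need no special code path:
run the identical pipeline on the alternative delineations.

## Randomization test

For groups of n_A and n_B animals all C(n_A + n_B, n_A) relabelings are
enumerated (deterministic order, observed labeling first; hard cap 200 000 —
exhaustive enumeration only). Per labeling: group means, unbiased per-cell
variances, Gaussian variance smoothing (FWHM in grid cells, default 2;
0 disables it — the raw-variance route is what the brute-force oracle tests
check), and the Welch-form pseudo-t. Cells undefined in any animal are
excluded; cells where both smoothed variances vanish get T = 0 when the
difference is also zero (an exact tie, counted with the observed), ±inf
otherwise, and are flagged.

Step-down adjusted p-values: cells are sorted by observed T ascending; for
each relabeling the running maximum along that order is the
successive-maxima image (activation tail) and the reversed running minimum
the successive-minima image (deactivation). Per-cell counts of relabelings
whose extremum reaches the observed value are non-strict (the identity
relabeling always counts), divided by N, and made monotone along the sorted
order. Both tails therefore take values in [1/N, 1]. A two-sided map
referring |T| to successive maxima of |T| is computed alongside
(`p_two_sided`).

**Attainable levels and the two-tailed test.** The p-value lattice is
{1/N, 2/N, ..., 1}. With 3 animals per group, N = 20: one-tailed tests at
alpha = 0.05 can just reject (minimum p = 0.05), and their family-wise error
under the null is exactly 1/20 — the probability that the observed labeling
attains the strict maximum of the 20 exchangeable image-maxima. The
two-tailed rule thresholds each tail at alpha/2 = 0.025, which lies below
the lattice minimum: at the minimal design the two-tailed test is therefore
maximally conservative (family-wise error exactly 0, verified by
simulation). The two-sided |T| map cannot help at this design either: the
complement of each labeling mirrors its statistic image, leaving only 10
distinct |T| images and a minimum two-sided p of 2/N = 0.1. From 4 vs 4
upward (N = 70) all three routes resolve below 0.05. The `fwer_estimate`
harness reports the two-tailed rate together with the per-tail one-tailed
rates at alpha, whose nominal calibration the enumeration can attain.

Thresholded rejection masks are contoured by marching squares at alpha and
at a stricter second level (alpha/5). Reports always include group sizes, N,
alpha, tails, the variance FWHM and seed.

## Synthetic phantoms

`generate_null_stacks` draws i.i.d. normal OD maps (defaults: 6 animals,
30x25 grid, mean 50%, SD 20%) — the null-calibration condition.

`generate_phantom_slice` renders a curved cortical ribbon as an annular
sector (arc centre near the image corner, polar angles 10-75 degrees, outer
radius 3 mm, thickness 0.8 mm, 0.02 mm pixels by default; a rectangular
variant exists for exact analytic checks). Ribbon intensity encodes a target
OD field — base level plus circular effect patches in (bregma, lateral) map
coordinates — as I = I_ref (1 - OD) with the background box held exactly at
I_ref, so profiling recovers the field up to rasterisation error (<= 0.02 on
noise-free input, tested). Per-pixel Gaussian OD noise and a per-animal
radial ribbon offset emulate staining noise and anatomical variability.
Images are quantised to 16 bit; the quantisation error is inside the stated
tolerances. Every generator is a pure function of its spec and seed
(independent substreams per animal and slice).

What the phantoms do *not* emulate: film response nonlinearity, microscope
point-spread, registration error beyond smooth radial offsets, within-slice
anatomical distortion, and gyrencephalic folding (edges whose x-positions
are non-monotonic are rejected, not handled). Passing phantom tests
therefore validates the geometry, bookkeeping and statistics of the
pipeline, not robustness to those acquisition effects.

## Problem sizes used by the test suite

The suite runs entirely on generated data: phantom studies of 2 x 3 animals
with 5-8 slices at 0.1 mm, 0.02-0.03 mm pixels and K = 14-20; oracle
comparisons on 4x4 grids with all 20 relabelings enumerated independently;
null calibration at 200 replicates in the suite and 1000 in
`scripts/acceptance.py`. These sizes were fixed once as realistic desk-scale
stand-ins for serial coronal section series.

## Known limitations

- Exhaustive enumeration only; no Monte-Carlo subsampling of relabelings.
- Pixel-level inference only; no cluster-level or threshold-free statistics,
  and no parametric fallback.
- Warping onto the reference map operates on extracted point sets, never on
  images; there is no nonrigid image registration.
- Whether the original variance smoothing width matters is exposed rather
  than resolved: FWHM is configurable and 0 disables smoothing.
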