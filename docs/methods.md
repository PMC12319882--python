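# Methods

This note records the models, conventions and numerical choices behind
`safsheet`, and what the synthetic phantoms do and do not establish.

## Coordinate and data conventions

All world coordinates are RAS millimetres (the TCK convention); +y is
anterior. Voxel labels carry a voxel→world affine and points are assigned
to voxels by round-to-nearest after the world→voxel transform. Polar angle
lives on [0, 360) degrees and is treated circularly everywhere (unit-vector
means, wrap-aware ranking); eccentricity is in degrees ≥ 0. Surface labels
are authoritative for endpoint projection; voxel labels are the ones
subject to overlap resolution, since overlap arises from volume resampling.

## Retinotopic map conditioning

The SNR of a vertex's phase-encoded response is the magnitude of the
one-sided DFT at the stimulus bin divided by the standard deviation of the
magnitudes of all non-DC bins. The stimulus bin is *included* in the
denominator (the literal "spectrum of the entire time series" reading);
with a pure integer-frequency sinusoid this makes the noise-free SNR
exactly `nb/sqrt(nb-1)` for `nb = T/2` non-DC bins (≈ 8.06 at T = 128), so
the default threshold of 5 separates responding from silent vertices with
margin. A vertex is reliable iff SNR ≥ threshold: the boundary value
counts as reliable ("below the threshold" is excluded). A vanishing
denominator yields SNR 0 by convention.

Smoothing is an iterative masked neighbourhood mean: per iteration each
reliable vertex becomes the mean of itself and its reliable 1-ring
neighbours; unreliable vertices contribute nothing and keep their entries.
The neighbourhood is the unweighted 1-ring — the simplest assertable
choice; the fixed iteration count (default 4) supplies the spatial extent.
This operator is a convex averaging, hence a contraction: the value range
can never grow, and constant maps are exact fixed points — both are tested.
A reliable vertex with no reliable neighbours averages only itself
(unchanged) and is counted in the log.

V1/V2 voxel overlap resolution assigns each overlap voxel to V1 iff
P(V1) ≥ 0.5, ties to V1 (deterministic, logged); outputs are asserted
disjoint and jointly conserve the input voxel union.

## Streamline geometry

The bending angle of a streamline is the angle at its apex between the two
vectors to the endpoints. The apex is the point of maximum discrete
curvature: the streamline is resampled to *exactly* uniform arc-length
spacing (the nominal 0.2 mm step is shrunk minimally so the spacing divides
the length — a short trailing segment would otherwise fake a curvature
spike at the end), coordinates are optionally 3-point smoothed (default
on), and curvature is the norm of the second central difference. Ties
within 0.1 % of the maximum break toward the arc-length midpoint (the apex
is expected near mid-course, under the sulcal fundus). The angle itself is
computed from the *unsmoothed* resampled apex position, which keeps
V-polyline apex angles exact. A maximum curvature below 1e-3 /mm (radius
beyond 1 m) counts as straight: apex at the midpoint, angle 180° —
near-straight streamlines therefore enter summaries at 180° rather than
being dropped (a flag records degenerate cases that cannot be resampled to
three points).

Selection filters: V1∧V2 traversal (≥ 1 point in each label; voxel
membership by rounding, surface membership by nearest labelled vertex
within 1 mm); length band 3–120 mm (in vivo) or 3–30 mm with a 0.1 mm
resample step (post mortem preset); deep-white-matter exclusion removes
streamlines with any point more than 2 mm below the white surface (signed
distance via the closest surface point and its barycentrically interpolated
vertex normal); the intracortical filter removes streamlines whose
resampled points lie more than 80 % between white and pial. The filters
commute and are idempotent (tested), so their order is cosmetic; the
pipeline fixes one order for reproducible stage counts.

Closest-point queries on meshes are exact: a KD-tree over triangle
centroids yields an upper bound (nearest-centroid distance), and only
triangles whose centroid lies within that bound plus the largest
centroid-to-vertex radius are examined with the standard region-based
point-triangle test. Agreement with an exhaustive search is tested.

## Sheet model

"Size" along an axis is the variance (mm²) of the *pooled* points of all
selected streamlines projected on that axis — pooled rather than
per-streamline summaries, matching the definition of size as variance of
streamline coordinates; a switch-free design keeps one definition, and the
trace identity (sizes sum to the total variance) pins it down in tests.
Axes default to the principal axes of the pooled cloud, ordered by
descending variance, signs fixed toward +anterior (fallback +x, +z); a
user-supplied anatomical frame is orthonormalised and used instead when
the anatomy is known. The 2D sheet surface is a least-squares polynomial
height function (default quadratic, configurable degree 1–3) of the two
largest axes; the thickness size is the raw third-axis variance,
independent of the fit.

Classification uses two ratio thresholds, both 3 by default and echoed in
every report: *sheet* iff size2/size3 ≥ 3 and size1/size2 < 3; *bundle*
iff size1/size2 ≥ 3 and size2/size3 < 3; otherwise *indeterminate*.
A zero smallest size is treated as an infinite ratio.

## Projection and topography

"The three vertices surrounding an endpoint" are the vertices of the
triangle containing the closest surface point (well-defined on any mesh),
found within a 2 mm off-surface tolerance; farther endpoints drop the
streamline from projection, counted and reported. Endpoint means over the
three vertices are unweighted by default (a barycentric-weighted variant
sits behind a flag); polar angle uses the circular mean. The V1 end is the
endpoint whose triangle lies (by 2-of-3 vertex majority) in the V1 surface
label and not ambiguously in both; ambiguous streamlines are flagged, or
raise in strict mode. Each projected streamline carries exactly four
retinotopy values (2 ends × 2 maps); its V1-end values are propagated
along its whole length.

Topographic bands partition a vertex region into n equal intervals of the
coordinate along a reference axis (6 for eccentricity along the gyrus, 15
for polar angle across it); each streamline joins the band of the vertex
nearest its V1 termination, and band colours are deterministic evenly
spaced hues. The topographic order index is the Spearman rank correlation
between carried V1-end values and per-streamline positions along a
reference axis; the pipeline uses the V2-end position projected on the
sheet axes, so the index measures whether fibres preserve the
correspondence from one area to the other rather than trivially comparing
a value with its own sampling location. Circular values are unwrapped by
centring on their circular mean before ranking. Constant inputs make the
index undefined; it is reported as 0 with a log flag.

## The phantom and what it shows

The phantom cortex is a single fold: a cross-section "tent" (two straight
banks of slope *a* joined tangentially by a circular crown of radius R,
default 2 mm) extruded along the A–P axis (default 18 mm, matching a
gyrus-scale region of interest), with the pial surface offset outward by
the cortical thickness (2 mm) along vertex normals. Fibres are the inward
offset of the white cross-section at a fixed depth (0.5 mm — superficial
white matter scale), one per A–P station, lengths drawn around 12 ± 2 mm.
Because fibre cross-sections are exact offset curves, each fibre's arc
length and apex-to-endpoint angle are analytic; the bank slope is solved
numerically (Brent) so the *measured* angle of the mean-length fibre
equals the configured target (default 140°), accounting for the rounded
crown. With the default proportions the pooled variances come out near
(16, 11, 0.4) mm² — a sheet by the classifier's ratios.

Retinotopy is linear: eccentricity 3°→6.9° along A–P (the experimentally
stimulated range), polar angle 180°→270° in cross-fold arc length. fMRI
responses are sinusoids at the stimulus frequency (8 cycles / 128 samples)
whose phase encodes eccentricity, plus Gaussian noise (sd 0.2 at amplitude
1) — the phase-calibration step of real phase-encoded mapping (hemodynamic
delay, opposed-direction runs) is deliberately bypassed by emitting the
coordinate-proportional phase directly.

Degradation knobs emulate tractography error, not rigid motion (which the
metrics are invariant to): `jitter_sd` displaces each fibre's V1 half
along A–P with a linear ramp (full at the V1 termination, zero at the V2
end), decoupling the carried V1-end value from the V2-end position;
`crowding_sd` (default 0.5 mm) perturbs the V1 arm's cross-fold extent
while the fibre keeps following the offset curve, so lengths and angles
stay analytic but polar-angle order degrades more than eccentricity order
— mirroring the expectation that cross-fold packing hurts polar topography
first. One seed fixes every artefact; scenes are byte-reproducible.

What passing phantom tests do **not** show: robustness to curving fibre
trajectories off the offset surface, partial-volume and noise properties
of real diffusion data, imperfect surface reconstruction, registration
error between diffusion and surface spaces (inputs are assumed
co-registered), or the behaviour of the SNR statistic under non-sinusoidal
hemodynamics. The phantom validates the *post-processing chain*, not
tractography itself.

## Problem sizes and tolerances

Default scenes use 200 fibres sampled at 0.2 mm on a 0.5 mm mesh grid
(~1.4 k vertices) — small enough that the full suite and the acceptance
script run in well under a minute each while keeping every estimator in
its asymptotic regime (variance recovery within ~3 %, angle recovery
within ~0.3°). Numerical tolerances: frame orthonormality 1e-8; curvature
straightness threshold 1e-3 /mm; curvature tie tolerance 0.1 % of the
maximum; off-surface endpoint tolerance 2 mm; surface-label membership
1 mm; probability ties at exactly 0.5 go to V1. I/O round-trips are exact
up to the TCK container's float32 (~1e-5 mm at these coordinates).
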