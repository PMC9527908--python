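# Methods

This note records the measurement conventions, generator assumptions and
numerical choices behind `ttmorph`, in the spirit of a model-description
document: what is computed, under which assumptions, and what the
synthetic validation does and does not establish.

## Coordinate and data model

Label volumes are integer grids in (Z, Y, X) order, Z being the serial-
sectioning axis; spacing is `(sx, sy, sz)` in nm, typically 8–11 nm
in-plane and 50 nm between sections. Voxel centres sit at `index ×
spacing` (0-based). One label marks the intracellular partition (cell
mask), one the extracellular space outside the sarcolemma, and remaining
positive labels mark segmented tubular objects; label roles must be
disjoint. TIFF stacks carry spacing and roles in a JSON sidecar; MRC2014
maps additionally encode spacing in the header cell (ångström). MRC data
are stored as float32 grids, which is exact for label values far below
2²⁴. Analysis portions of a fixed number of consecutive sections can be
cropped out (`crop_stack_portion`), with the window recorded in
provenance.

## Component identification and classification

Connected components are computed over the union of object labels,
default 26-connectivity: at 50 nm section steps, 6-connectivity severs
thin oblique tubes between sections. Components below `min_voxels`
(default 8) are discarded as segmentation specks and counted in the log.
The extracellular-contact test always uses face (6-)adjacency regardless
of the labelling connectivity, because diagonal "contact" across
anisotropic voxels is not physical continuity.

Classification is purely by connectivity: extracellular contact →
*tubule*; otherwise crop-face contact → *indeterminate* (connection
status is unknowable inside the portion); otherwise → *fragment*.
Indeterminate components are excluded from fragment statistics and
reported separately, making the treatment of portion-truncated
components explicit and reversible. On greyscale EM, fragments are
additionally recognized by a retained basement-membrane dark ring; with
label input that check is a labelling-time responsibility. Crop-
truncated tubules are measured and flagged, and they count in densities
(portions necessarily truncate tubules; excluding them would bias
density down).

## Per-component measurements

**Volume** is voxel count × voxel volume — exact conservation holds by
construction (the summed component volumes equal the object voxel count
times the voxel volume).

**Surface area** is the area of the 0.5 iso-surface mesh (marching
cubes, anisotropic spacing honoured). Raw marching cubes on binary masks
overestimates curved area substantially (up to ~20% on spheres at
10×10×50 nm, from in-plane pixelation plus terracing along Z), so the
mask is first smoothed with a Gaussian of 15 nm physical σ per axis;
residual bias on sphere/cylinder/ellipsoid oracles is ≲1%. The σ is
small against the ~200 nm tubule radius, so no feature is lost. Where a
component abuts the crop boundary, the artificial closing caps on those
faces are subtracted — reported areas are open at the crop faces.

**Equivalent diameter** implements the circular cross-section
approximation: the mean serial-section contour perimeter divided by π
(a circle's perimeter/π is its diameter). Contours are traced per slice
at the 0.5 level with sub-voxel linear interpolation (marching squares),
not voxel-boundary staircases, which would overestimate circumference by
~27%. On binary data the midpoint polygon still zig-zags and runs ~5%
high on discs, so a 5-vertex circular moving average is applied to each
contour before measuring; residual bias on 200 nm discs at 5–20 nm
spacing is ≲0.5%. An area-based alternative, d = 2·√(mean area/π), is
available behind a flag (`variant="area"`) for sensitivity analysis.
The "perimeter" reading is the default because it is the one under which
the formula Σ(contourᵢ)/(nπ) is dimensionally a diameter. Contour stacks
are built per *component*, after labelling, so one stack never mixes
objects. Slanted tubules make cross-sections elliptical and bias this
estimator upward; that is a property of the approximation itself.

**Longest-branch length** is the longest skeleton path from the
sarcolemmal attachment to any tip. The component is resampled to
isotropic voxels at the minimum in-plane spacing (exact integer
repetition when the anisotropy ratio is integral), thinned to a 3D
skeleton, and converted to a graph with physical edge lengths; Dijkstra
from the node nearest the attachment gives the farthest tip. Two
corrections matter numerically: (i) voxel-step paths zig-zag around the
true centreline, so path coordinates are smoothed over a ~150 nm window
(endpoints kept) before the polyline length is taken; (ii) thinning
retracts tips by roughly the local radius, so the Euclidean distance
transform value at each endpoint is added back. Together these bring the
bias on straight phantom tubules from ≈+4.5% to ≈+1.2%. Fragments (no
attachment) get the skeleton graph diameter; single-voxel components are
degenerate and report 0. Curvature is included (path length, not chord).

**Cell width and length fraction.** The published convention for "cell
width" is not specified, so the default measures, per tubule, the
cell-mask chord along the tubule's own penetration axis (first principal
axis of its voxels, oriented inward from the attachment point, marched
in half-voxel steps; tubule lumina count as cell interior). A per-cell
mean alternative (`cell_width_mode="cell_mean"`) is switchable. Length
fraction is longest-branch length / width; values above 1 are possible
for oblique tubules and flagged.

**Sub-sampling.** Diameter and length statistics use a per-cell uniform
random subsample of 15 tubules (deterministic given the seed); volume
and surface area use all tubules. This mirrors analysis practice in
which 15 tubules per cell were randomly chosen for the manual
length/diameter measurements while volumes were taken on every
reconstructed tubule, and it explains the differing n's between metrics.

## Hierarchical statistics

Per-tubule values are clustered (tubules in cells, cells in animals);
the regional contrast is

y = β₀ + β₁·region + a_animal + c_cell(animal) + ε,

random intercepts for animal and for cell nested in animal, fit by
maximum likelihood (not REML). The contrast p-value uses a *t* reference
with containment-style denominator degrees of freedom: region is a
between-animal effect, so df = n_animals − 2 (n_cells − 2 for the
cell-only fallback). With three animals per arm a normal (Wald z)
reference roughly triples the nominal 5% type-I error; with the *t*
reference the simulated type-I error under the clustered null
(3 animals × 3 cells × 15 observations per arm; animal sd 0.3, cell sd
0.2, residual sd 1.0; 1000 replicates) is ≈0.05, and a planted
one-residual-sd effect is recovered within 1% on average. A variance
component estimated at the numerical boundary (0) triggers a refit
without that term, cascading animal+cell → animal → cell → OLS; in the
fully collapsed limit the p-value coincides with a two-sample t-test.
One animal per region drops the animal intercept with a prominent
warning.

Before modelling, a Shapiro–Wilk screen (Lilliefors-corrected KS
available) selects the analysis scale: identity if normality is not
rejected at α = 0.05, else the first of log₁₀, √ that passes, else log₁₀
with a warning; non-positive data skip the inapplicable transforms. Per-
region mean ± s.e. are always reported on the original scale. Tests are
two-sided at α = 0.05 throughout; no multiplicity correction is applied
(actual p-values are reported). The before/after ejection-fraction
comparison is a paired t-test; a zero-variance difference vector is
handled explicitly (p = 1 for zero mean difference).

## The phantom generator

Scenes emulate the geometry the measurements are designed for: straight
tubules perpendicular to one sarcolemmal face, entering at z-lines
spaced 2 µm along X and at 0.9 µm lanes along Y, radius
r(s) = r₀(1 + a·sin(2πs/λ + φ)) with a = 0.15 and λ = 1.5 µm around
r₀ ≈ 200 nm (narrowings and dilations); penetration depth drawn from
N(0.41, 0.08)·cell width; twin tubules straddling a z-line at ±0.35 µm
with probability 0.1; longitudinal elements (radius 0.6·r₀, length
0.9 µm) bridging toward an adjacent z-line without joining it; ellipsoid
fragments placed in the interior clear of everything; optional tubule
dropout. The default cell is 8 µm wide and 1.8 µm deep with 3 z-lines —
at one tubule per (2 × 0.9) µm² of face per 8 µm width this yields the
healthy-morphology targets (density ≈0.07 µm⁻³, diameter ≈405 nm,
penetration ≈0.41). Region presets differ only in radius (202.5 /
224.5 / 266.5 nm for control / remote / border, i.e. 405 / 449 / 533 nm
diameters), dropout (0 / 0.1 / 0.3) and fragment load (0 / 1×0.01 µm³ /
4×0.06 µm³ per cell).

Voxelization uses the voxel-centre inclusion rule (unbiased volume in
expectation), one label per primitive, overlaps resolved by write order
and counted. Ground truth is closed-form where possible and 1D
quadrature elsewhere (modulated-radius volume/area; the junction
corrections where a longitudinal branch leaves its parent). For a tubule
carrying a longitudinal branch the merged cross-sections make the
circular-diameter approximation undefined, so its ground-truth diameter
is NaN and diameter-recovery statistics skip it; its volume and area
truths include the junction terms. Fragment surface areas use Thomsen's
ellipsoid approximation (max error ≈1%). Distributional choices
(Gaussian penetration, sinusoidal modulation, lognormal fragment sizes)
are conveniences, not claims about real data.

What phantom validation shows: the measurement operators recover known
geometry at EM-like anisotropy (mean relative errors ~1% for volume,
diameter, length; well under the 10% band for area) and classification
by connectivity is exact when connectivity is by construction. What it
does not show: robustness to segmentation errors, membrane-contrast
ambiguity, registration artefacts, or non-cylindrical (sheet-like)
tubule geometry — none of which the generator emulates. Real volumes
enter through the same `LabelVolume` interface, but those error sources
are upstream of this package.

## Problem sizes and determinism

The bundled study simulation uses 3 animals × 3 cells per region with
the 6-site default cell (≈50–60 tubules per region arm), which keeps a
full three-region study, the ≥50-tubule recovery panel and the
1000-replicate model calibration to a few minutes on one CPU; all
stochastic steps derive per-scene seeds from one master seed via
`numpy.random.SeedSequence`, and re-running a pipeline with the same
config and seed reproduces byte-identical CSV outputs.

## Known limitations

* The equivalent diameter inherits the circular approximation's upward
  bias for slanted tubules; the area-based variant bounds this from the
  other side.
* Skeleton-based lengths are biased by ~+1% even after path smoothing
  and tip correction; sub-voxel centreline fitting could do better.
* Cell width per tubule assumes the penetration axis chord is the
  intended normalizer; other conventions (minimal cell calliper, fixed
  per-cell width) would shift length fractions by a scale factor.
* Mean per-tubule volumes measured on cropped portions are truncation-
  dependent: a 100-section (5 µm) portion caps measurable tubule length,
  so whole-tubule phantom volumes exceed portion-based published means
  even when diameters match.
* The mixed model assumes Gaussian residuals on the analysis scale;
  the residual normality check is reported but not enforced.
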