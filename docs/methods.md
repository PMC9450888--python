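# Methods

This note documents the models, defaults and design choices behind
`exmfoci`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Units, frames and coordinates

All internal lengths and coordinates are nanometres; micrometres appear
only at I/O. Every `PhysicalLength` carries its reference frame
(`pre_expansion` or `post_expansion`), and frame mixing raises instead of
silently producing a wrong number. Voxel indices are 0-based,
`(z, y, x)`-ordered, and the physical position of a voxel is its **centre**
(`(index + 0.5) × voxel size`), with the origin at the image corner. Report
formatting uses half-up rounding at the printed precision; rounding is
never applied inside computations.

The default factor for post→pre conversion is **4.0** (the macroscale gel
expansion), configurable everywhere it is used. The volume route on real
nuclei gives ~3.7 (∛52); 4.0 is the default because reported pre-expansion
equivalents of post-expansion measurements are conventionally quoted at
the macroscale factor. No uncertainty is propagated on expansion factors
(they are point estimates).

## Registration and isotropy

Expansion isotropy is quantified by fitting the similarity transform
`y = s·R·x + t` to manually matched pre/post landmark pairs using Horn's
closed-form quaternion solution: the rotation is the principal eigenvector
of the 4×4 cross-covariance quaternion matrix, the scale is
`Σ y′·(R x′) / Σ‖x′‖²` on centred coordinates, and the translation follows
from the centroids. The fit is exact (≤1e-9 relative error) on noiseless
similarity-related point sets; collinear or coincident configurations
raise a rank-deficiency error.

The landmark set is split 80/20 train/validation by a seeded random draw
(`round(0.8·n)` training points, minimum 4) — the selection rule is not
otherwise constrained, so the seed is recorded in the registration report.
The reported "MSE" is the **mean Euclidean distance** between matched
points in nm, because the natural unit of a registration residual is a
length; the mean *squared* distance (nm²) is available behind
`squared=True`. Rotations are parameterised by unit quaternion internally
(no gimbal issues, a clean norm invariant); matrices and Euler angles
appear only at interfaces.

Isotropic resampling uses order-3 (tri-cubic) spline interpolation with
`grid_mode` extent preservation; upsampling factors above 50 per axis are
refused as a memory guard. The all-pairs control-point distance table
reports `post/factor − pre` deviations; a distortion-free expansion gives
zero deviation for every pair.

## Spot detection

Puncta are detected per channel as local maxima of a negated, scale-
normalised Laplacian-of-Gaussian filtered volume. The blob scale is
`σ = r/√3` per axis from the expected spot radius `r`, converted to voxels
per axis so anisotropic sampling is handled; radii below one voxel on any
axis are rejected. A candidate maximum's **quality** is its prominence —
the filter response minus the neighbourhood minimum over a radius-sized
window — and candidates below the quality threshold are dropped, which
makes the detected count monotonically non-increasing in the threshold.
Positions are refined per axis by a three-point quadratic fit (offsets
clamped to ±0.5 voxel); ties are broken by lexicographic voxel index so
detection is fully deterministic.

The default threshold of 25 (in scale-normalised response units) was
calibrated once against the simulator's default photon budget (2000
photons/spot over a 20-photon background), where true spots score ≳50 and
the brightest noise maxima ≲15. It scales with spot intensity and must be
re-calibrated for data on a different intensity scale.

## Clustering, assembly and classification

Site-channel spots (BRCA1 in the two-channel analysis, RAD51 in the
three-channel analysis) are grouped into the connected components of the
graph linking all spots within a fixed radius (default 1.5 µm
post-expansion); components are found by union-find over KD-tree
neighbour pairs, and each component's unweighted centre of mass is the
structure core. Partner spots within the search radius (default 2 µm
post-expansion) of a core are attached to that structure; a spot within
range of several cores joins all of them and is flagged as shared.

Classification is rule-based over per-channel spot counts plus one
geometric predicate, **encapsulation**: the core must lie inside the 3D
convex hull of at least 3 satellite spots, or — when the satellites are
coplanar within 200 nm (the typical axial localisation error; hull
degenerate, as for an in-plane ring) — the core must lie within that same
tolerance of the satellite plane and the satellites' angular coverage
around it must reach 180°. "Encapsulated" has no standard geometric
definition, so all parameters (minimum satellites, arc, hull on/off,
coplanarity tolerance) are exposed.

The five-class default taxonomy: class 1 = site spots only; 2 = one site +
one partner spot; 3 = multiple site + one partner; 4 = multiple site +
multiple partner, *or* one site with multiple non-encapsulating partners;
5 = one site spot encapsulated by multiple partner spots. Two choices here
were genuinely open and are isolated in the editable rules file: (a)
one-site/many-partner structures failing encapsulation fall to class 4,
the least-wrong bucket if the five classes are to be exhaustive; (b)
class 1 accepts any number of site spots with zero partner spots — a
site-only cluster must land somewhere, and "only the core spots" is the
natural reading. The rule engine validates at load time that every rule
set is exhaustive and mutually exclusive over the reachable count space
(encapsulation can only be true with enough satellites), so a custom rules
file cannot silently leave gaps.

The ten-class three-channel taxonomy (RAD51 as centre) is an exhaustive
enumeration over (single/multiple RAD51) × (absent/single/multiple 53BP1)
× (absent/present BRCA1). Three constraints are fixed: class 4 = multiple
RAD51 + multiple 53BP1 without BRCA1; classes 7–9 contain all three
proteins; class 9 = multiple RAD51 with BRCA1, encapsulated by multiple
53BP1. The remaining class boundaries are a reconstruction and are shipped
as an editable, re-validated YAML rules file
(`src/exmfoci/data/three_channel_default.yaml`).

Class-5 structures are subclassified by the **median** core-to-satellite
distance (mean/median/per-spot was an open choice; the median is robust to
a single stray satellite and is configurable) into bins: contracted
(<0.5 µm), intermediate (0.5–1.8 µm), control-like (1.8–2 µm) and extended
(2–2.5 µm), with distances beyond the last bin routed to an overflow label
with a warning rather than an error. Continuity of a multi-spot
accumulation is decided on the image crop: threshold at half the crop
maximum (configurable fraction), 26-connected components, "continuous" iff
at least two member-spot centres share one foreground component.

Structure crops default to a 5 µm-edge cube ("5 µm³" is read as edge
length, since class-5 structures span ~4–5 µm post-expansion; a volume
reading would give a 1.7 µm edge that truncates them — configurable).
Crops are zero-padded at image borders so all crops of one edge share a
voxel shape, and they carry their global physical origin.

## Averaging and radial profiles

Class-5 structures whose satellite ring lies roughly in a focal plane are
selected automatically: the best-fit (principal-axes) plane through the
partner spots must have its normal within 20° of the optical axis, and the
core must lie within half a band width of that plane. The 20° tolerance is
a surrogate for what was a by-eye selection in practice, and is exposed.
Alignment before averaging is by translation only (core at crop centre);
no per-structure rotation is applied, because radial profiles are
rotation-insensitive and a rotational alignment step would add an
unconstrained degree of freedom.

The radial profile bins central-slice pixels into fixed-width concentric
bands (default 100 nm post-expansion ≈ 25 nm pre-expansion at factor 4,
giving ≥12 bands across a class-5 structure) and takes the mean intensity
per band. **Peak-to-peak** is defined as twice the radius of the global
profile maximum (a symmetric averaged structure has its two satellite
peaks at ±r), refined by a three-point quadratic fit across neighbouring
bands; a profile whose maximum sits in the innermost band has no annular
peak — the collapsed-ring ("void lost") phenotype — and returns 0 with an
explicit flag rather than a fake radius. **Span** is twice the outermost
radius at which a channel's profile still reaches half (configurable
fraction) of its maximum, linearly interpolated at the crossing; the
**gap** is the satellite channel's inner half-max edge minus the core
channel's outer half-max edge, clamped at zero so overlapping
distributions report "no void" instead of a negative length.

## Synthetic specimens

The generator emulates the features of expanded-nucleus data that the
analysis depends on, with everything derived from one integer seed
(identical config + seed ⇒ bit-identical volumes and tables):

* **Structures** are planted by class: satellite rings are evenly spaced
  (bounded angular jitter) on a circle of default radius 650 nm
  post-expansion — consistent with a ~1.3 µm satellite peak-to-peak —
  tilted uniformly within a configurable range, or on a near-uniform
  sphere; multi-spot site clusters place 2–3 spots 0.8–1.2 µm apart
  (within the 1.5 µm link radius, above the axial resolution limit);
  "multiple" satellite counts default to 3–8, uniform. Every planted
  structure is re-classified from its coordinates at generation time and
  generation fails loudly on a mismatch, so planted labels are exact by
  construction.
* **Imaging** renders each spot as a separable anisotropic Gaussian PSF
  (defaults: post-expansion lateral σ 100 nm, axial σ 300 nm; the real
  widefield/SPIM PSFs are not parameterised, and a Gaussian is the
  standard surrogate) whose voxel sum equals the spot's photon count
  (default 2000 over a 20-photon background), then applies Poisson shot
  noise and Gaussian read noise (σ = 2). Default sampling is 100 nm
  lateral / 250 nm axial post-expansion and 120/250 nm pre-expansion.
* **Nuclei** are ellipsoids (default pre-expansion semi-axes
  1.5 × 3.2 × 4 µm — small, to keep scenes tractable) with cosmetic
  early/mid/late S-phase DNA textures (diffuse / patchy / peripheral).
  The textures keep the whole interior above background so
  intensity-based segmentation sees one body per nucleus; they are not
  biologically calibrated, and classification never reads the DNA channel.
* **Expansion** maps coordinates by a similarity transform (default scale
  4, identity rotation) plus an optional smooth random displacement field
  — a band-limited sum of 8 random harmonics with controllable RMS
  amplitude and correlation length — standing in for the qualitative
  concern of anisotropic gel distortion. Zero amplitude gives a pure
  similarity, and the true transform is always returned for recovery
  tests.

What passing the synthetic benchmarks does **not** show: the simulator has
no deconvolution residuals, no SIM reconstruction artefacts, no refractive
distortion, no antibody-labelling noise, and no quantitative model of real
focus intensity or size distributions (none are available to calibrate
against). Recovery rates on synthetic scenes therefore validate the
*algorithms* — detection, clustering, classification, profiling and their
geometry — not the biological accuracy of any particular parameter set on
real specimens.

## Benchmark problem sizes

The recovery benchmarks use: 500 planted structures (100 per class, 20
scenes of 25) for classification recovery; 100 seeded scenes of 10–500
spots for the clustering-vs-brute-force check; 100 noisy 21-landmark
replicates for the registration train/validation comparison; one ×4
nucleus scene per seed for expansion-factor recovery; and 10 seeds × 8
in-plane class-5 structures for each ring-geometry condition (control
650 nm, collapsed 80 nm, extended 1150 nm) in the profile benchmark.
These sizes give stable statistics (recovery rates vary by ~1% across
seeds) while keeping a full run around a minute on one CPU.

## Known limitations

* Detection merges spots closer than the (anisotropic) resolution limit,
  so multi-site structures oriented along the optical axis occasionally
  lose a site spot and slip one class down (~2% of structures at default
  geometry); this mirrors the physics of the imaging, not a bug in the
  rules.
* The 2D segmentation threshold is a required explicit parameter by
  design (it was a manual, histogram-based choice in the workflow this
  reproduces); an Otsu value can be supplied by the caller, as the
  pipeline does for synthetic scenes.
* Manual classification of exported crops is supported only in file form
  (crops out, hand-label CSV in); there is no GUI.
* No deformable registration, no automatic landmark detection, no
  time-lapse tracking, and no intensity-colocalisation coefficients.
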