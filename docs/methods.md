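# Methods

## Problem and pipeline

Weight-bearing cone-beam CT yields per-bone surface meshes of a standing
foot. The package turns one such set of meshes (tibia TI, calcaneus CA,
talus TA, navicular NA, cuboid CU, medial cuneiform CM, metatarsals M1,
M2 and optionally M5, plus a ground mesh) into 32 angular and linear
alignment measurements, and provides the statistical layer to compare two
measurement methods (for example two segmentation tools) across a cohort.
All coordinates are in millimetres; all angles are reported in degrees.

The stages are: STL ingestion with vertex welding → ground-plane fit →
foot anatomical frame (FootAF) → PCA bone frames → measurement catalog →
cohort statistics. Each stage is exposed as library API; the CLI is a thin
orchestration layer.

## Geometry

**Welding.** STL stores three vertices per facet; duplicates are merged on
a 1e-6 mm grid before any axis computation so that the point cloud feeding
PCA counts each surface point once, deterministically.

**Ground plane.** Total-least-squares plane of the ground-mesh vertices
(smallest singular direction), normal oriented toward the mean bone
centroid. The supporting surface is assumed rigid and planar.

**FootAF.** Origin = ground projection of the calcaneal plantar landmark;
anteroposterior axis toward the projected M2-head landmark; vertical =
ground normal; mediolateral = ap × up (lateral on a right-convention
foot). Left feet are mirrored to right convention before measurement —
signed angles pooled across sides require one convention, and mirroring
preserves every measurement of an exact mirror pair (verified by test).

**Plantar landmarks.** Heights (`Hg`) use the single most plantar vertex
(ties broken by lowest index, so results are reproducible). Landmarks
that define *directions* — the FootAF endpoints, the FAO tripod and the
arch apex — instead use the centroid of the plantar *contact patch*: all
candidate vertices within 0.5 mm of the minimal height. With realistic
sub-millimetre surface noise the identity of the single lowest vertex is
unstable and can wander ~1.5 mm tangentially, which rotates the whole AP
axis by several tenths of a degree; the ill-conditioned frontal and
azimuthal angles amplify that by factors of 5 or more. Averaging over the
patch removes this failure mode while changing noiseless landmarks by
well under a millimetre.

**Head regions.** The "head" of a metatarsal is the anterior 25% of its
extent along its own raw first principal axis (oriented by the bootstrap
anterior direction, calcaneus centroid → mean M1/M2 centroid); the talar
arch apex uses the anterior 30%. The landmark is the plantar contact
patch of that region. The extraction rule for these landmarks is a
package design choice; the classical definitions name the landmark but
not an algorithm.

**PCA bone frames.** Covariance of the welded vertices (unweighted, the
reference behaviour; an area-weighted variant is available to reduce
mesh-density sensitivity). Eigenvalues descending; longitudinal = first
axis, flipped anteriorly; dorsoplantar = remaining axis most aligned with
the vertical, flipped upward; mediolateral completes the right-handed
triad. Bones with first/second eigenvalue ratio below 1.2 carry an
"ambiguous axis" warning but are still measured. The near-vertical tibia
is handled at the measurement layer (its axis is re-oriented upward),
not by a special frame rule.

## Measurement conventions

Let (u_a, u_m, u_u) be the components of an anterior-oriented
longitudinal axis along (ap, ml, up).

* Lateral inclination `IL = atan2(−u_u, u_a)`: plantar declination of the
  anterior end positive. Tibia: `IL_TI = atan2(u_a, u_u)`, anterior lean
  from the vertical.
* Transverse inclination `IT = atan2(−u_m, u_a)`: internal (medial)
  rotation positive.
* 3D inclination `I3 = −asin(u_u)`; satisfies |IL| ≥ |I3| analytically.
* Relative planar angles are signed differences of inclinations, wrapped
  to (−180°, 180°]. Radiographic conventions are a historical patchwork,
  and the package adopts the set under which the standard identities hold
  exactly: sagittal hindfoot pairs first-named − second-named
  (`RL_TACA = IL_TA − IL_CA`), sagittal metatarsal angles
  distal − proximal (`RL_TAM1 = IL_M1 − IL_TA`, Meary;
  `RL_CAM1 = 180° − (IL_M1 − IL_CA)`, obtuse Hibb), transverse pairs
  second-named − first-named (`RT_TACA = IT_CA − IT_TA`). With these
  conventions the published reference table (below) is internally
  consistent to better than one degree.
* Frontal angles measure the projected axis from the vertical, medial
  lean positive, relative angles first − second. No published convention
  pins the frontal projections down, and projections of near-horizontal
  axes are intrinsically ill-conditioned; the RF codes are reported under
  this documented convention but deserve clinically informed definitions
  before interpretation.
* `R3` = arccos of the dot product of the two anterior-oriented axes,
  in [0°, 180°]; `R3_CAM1` is reported in its obtuse form (posterior
  calcaneal ray vs anterior metatarsal ray).
* Moreau–Costa–Bertani (`RL_TACAM1`, `R3_TACAM1`): angle at the talar
  apex landmark between rays to the calcaneal and M1 plantar landmarks;
  the lateral form projects the three points into the sagittal plane
  first.
* FAO: tripod = ground projections of the CA, M1-head and M5-head plantar
  landmarks; axis from the CA point to the M1/M5 midpoint; offset =
  signed perpendicular distance of the projected talus volume centroid,
  positive medial (hindfoot valgus positive); `FAO_% = 100·FAO_mm /
  foot length`.
* Degenerate projections (axis within 1e-6 of orthogonal to a plane)
  raise errors rather than returning silent zeros that would corrupt
  cohort statistics.

## Synthetic feet and ground truth

Bones are superellipsoids `Σ |x_i/a_i|^p = 1` (per-bone semi-axes and
exponent), triangulated by radially projecting a reflection-symmetric
UV sphere whose poles lie on the long axis. Two properties make them
ideal validation bodies: the PCA axes of the vertex set equal the design
axes exactly (by symmetry), and the extremal surface point in any
direction — including restricted to an anterior head region — has a
closed form via p-norm duality. The generator therefore evaluates every
catalog code analytically from the design poses (`GroundTruth`) without
touching a mesh, and the mesh pipeline must recover those values.

Pose controls map to deformity language: calcaneal pitch (= −IL_CA),
talar declination and internal rotation, M1 declination, arch heights
(exact plantar heights of NA/CU/CM), hindfoot valgus (medialises the
talar centre over the tripod: offset = tan(valgus)·talar height) and the
signed transverse intermetatarsal angle. The heel is placed at the
origin and the M2 head on the +x ground axis, so the design frame *is*
the FootAF and truth angles equal the pose angles by construction.
Physiologic bounds (e.g. talar declination 0–45°) are enforced.

**Templates.** The *flatfoot* template is calibrated to a published
cohort of 21 adult flexible flatfeet measured in single-leg standing
CBCT with two segmentation tools (`footmetry.reference`): the twelve free
pose angles are fitted by least squares to the 23 sagittal/transverse/3D
axis codes of the published semi-automatic means (maximum residual
0.9°); the talar height is solved so the lateral Moreau–Costa–Bertani
angle matches (139.7°), and the valgus control so FAO_mm matches
(19.45 mm). The frontal codes are excluded from the fit: the published
frontal means are not jointly realisable with the sagittal/transverse
means under any single projection convention — consistent with the
published caveat that those measures need further definition. The
*normal* template uses textbook mid-range values (pitch 18°, Meary 0°,
navicular height 34 mm, valgus 5°) as a documented choice; no control
cohort exists in the reference data.

**Mesh emulation.** `MIS-like` adds zero-mean Gaussian noise along vertex
normals (default SD 0.15 mm — the scale of segmentation surface error);
`DIS-like` first applies Laplacian smoothing, then decimates to ~1/8 of
the faces, then adds the same noise. Decimation keeps one actual vertex
per voxel cell (nearest the cell mean), with the grid aligned to the
bone's own principal frame, and re-triangulates by convex hull (the
generator's bodies are convex). This reproduces the near-uniform vertex
spread of real decimators; random subsampling or world-aligned clustering
would add 1–2° of covariance noise/bias that real tools do not exhibit.
Default density is 3200 vertices per bone (DIS-like ≈ 400) — far sparser
than real scans but in the same stable regime for PCA, keeping the
validation suite fast.

**Cohorts.** Feet are drawn around the flatfoot template with normal
dispersions mirroring the published SDs (e.g. talar declination 7.49°,
arch heights 5.2/3.6/3.4 mm), truncated to the physiologic bounds; the
tibial sagittal lean is bounded below at 3° because its transverse
azimuth is undefined at zero lean. Each foot is emitted as an
(MIS-like, DIS-like) pair sharing one generation frame, with one seeded
generator driving everything: equal seeds give bitwise-equal cohorts.

What the generator does *not* emulate: articular facets and joint
congruence, cortical texture, segmentation artefacts that merge adjacent
bones, and the registration step needed when two real segmentations live
in different scanner frames (synthetic pairs share a frame by
construction). Passing tests therefore validate the measurement and
statistics machinery, not any segmentation tool.

## Statistics

Descriptives are sample mean and SD (n−1). The normality gate is the
Kolmogorov–Smirnov test against a normal with estimated parameters,
which requires the Lilliefors correction (plain KS is available behind a
flag but is anti-conservative here). Paired comparisons use Student's
paired t when both samples pass the gate at 0.05, otherwise the Wilcoxon
signed-rank on the paired differences (the paired analogue of the
rank-sum family; an unpaired Mann–Whitney is available behind a flag).
Pearson r, r² and the t-transform p-value quantify between-method
correlation per code, and the full 32×32 r matrix between measurements
is reported with p < 0.05 marks; constant columns are flagged rather
than silently dropped. Significance is two-sided α = 0.05 throughout
with no multiple-testing correction, matching the raw per-code
convention of the clinical method-comparison literature.

Sample size defaults to the two-group normal approximation
`n = ⌈2 (z₁₋α⁄₂ + z₁₋β)² (σ/δ)²⌉` (16 at α 0.05, power 0.80,
δ = σ = 1); the paired-design formula with the Guenther `z²/2`
adjustment (10 at the same point) is available via `design="paired"`.
The two formulas answer slightly different questions and both are kept
because the literature quotes both.

Difference boxplots use the Tukey convention (1.5·IQR whiskers clipped to
the data, outliers beyond) — the convention that actually produces
outliers. The threshold count reports how many codes differ in mean by
more than a clinical threshold (default 3.5°).

## Numerical choices and limitations

* Validation tolerances: rigid-motion invariance to 1e-6; PCA axis
  recovery ≤ 0.5° on noiseless bodies; closed-form truth recovery ≤ 1.0°
  (axis codes) / 0.2 mm (heights) on noiseless meshes, and ≤ 2.5° mean
  per code / 0.5 mm under DIS-like perturbation over a 21-foot cohort.
  Monte-Carlo checks of the gated paired procedure use 10⁴ replicates
  (fixed seeds); its exact power at the design point (n = 16, two
  independent unit-variance arms, shift 1) is 0.751.
* Problem sizes in the shipped suite — 21-foot cohorts, 3200 vertices per
  bone, 10⁴ simulation replicates — are the package's validation scale,
  chosen so the full suite runs in about a minute.
* The elongation warning threshold (1.2) flags nearly isotropic bones
  where the longitudinal label is arbitrary; for real naviculars and
  cuboids PCA axes may not match traditional anatomical axes at all.
* UV-sphere vertex density is pole-heavy, so the *eigenvalue ratio* of an
  undecimated synthetic bone overstates its physical elongation; axis
  directions are unaffected (symmetry).
* Mesh repair beyond welding, DICOM ingestion and segmentation itself are
  out of scope; the pipeline starts at labelled STL files.
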