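# Methods

This note documents the models, algorithms, parameters and design choices
behind `hipmorph`, and what the synthetic validation does and does not
show about real CT-derived data.

## Geometry substrate

All geometry is an indexed triangle surface in millimetres
(`TriangleMesh`), with optional per-vertex region labels naming
anatomical patches (`head`, `head_base`, `neck`, `shaft`, `cup`). STL
(binary and ASCII) and ASCII PLY are read and written through `trimesh`.
STL duplicates vertices per facet, so loading merges vertices at 1e-6 mm
and drops zero-area faces; the merged order is the first-occurrence order
of the facet stream, a pure function of the file content, so label
sidecars (`<name>.labels.json`, vertex index → region) written next to a
mesh remain valid after a round trip, and meshes sharing a facet
structure keep identical topology through I/O. Binary STL stores float32
coordinates: round-trip identity at 1e-6 mm holds for coordinates below
about 32 mm; ASCII formats round-trip at full precision.

The canonical pose is a left hip in a right-handed frame with lateral =
+x, anterior = +y, superior = +z and the acetabular centre at the origin.
Right hips are mirrored across the sagittal plane into this pose before
any bilateral comparison; anatomical frames are therefore always
right-handed, and a `mirror` flag on rigid transforms carries chirality
where it is needed.

Surface area is the triangle-area sum. Volume is the signed-tetrahedron
(divergence-theorem) sum, taken as an absolute value; it is only defined
for watertight, consistently wound surfaces, and the error for an open
surface reports the boundary-edge count. Watertightness is *not* required
elsewhere — the acetabular inner surface is an open patch by nature.

Rigid alignment is point-to-point ICP: KD-tree nearest neighbours, Kabsch
update per iteration, at most 200 iterations, stopping when the RMS
nearest-neighbour distance improves by less than 1e-8 mm. ICP is a local
method, and rotations about an axis of near-symmetry (a femoral head is a
sphere about its own centre) are classic stall points; when no initial
transform is supplied, the start pose is therefore chosen among
centroid/principal-axes matches (all four proper sign combinations) and
the identity, by lowest initial RMS. A mirrored initialisation is refined
within the improper branch. Alignment to a mirror image without the
mirror flag either fails to converge or ends at a large RMS — that is the
documented detection behaviour, not an error.

## Synthetic bilateral hip generator

The generator stands in for the study's unavailable CT reconstructions
and defines the conditions under which the pipeline is validated.

**Healthy anatomy.** The femoral head is a spherical cap of height P5
closed by a planar disk (the cap more than covers a hemisphere for
anatomical P5 > r), fused — as separately closed, labelled components —
to a cylindrical neck and shaft realising the five shape parameters:
P1 = 2r head diameter, P2 neck diameter, P3 neck length from head centre
to the neck/shaft axis junction, P4 neck-shaft angle, P5 head height.
Defaults scale a 40 mm reference head: P2 = r, P3 = 2.25 r, P4 = 135°,
P5 = 1.1 r. The ground-truth head volume is the exact cap formula
π P5²(3r − P5)/3. The acetabulum is an open spherical patch concentric
with the head at radius r + 0.2 mm (a joint clearance), with a polar
extent per 45° azimuthal sector (90° everywhere for a hemispheric healthy
cup); its grid is aligned so sector boundaries fall exactly on cell
edges, making per-sector areas analytic
(R² · π/4 · (1 − cos θ_max)). Mesh topology depends only on the
resolution parameter, never on shape parameters, so all generated femurs
are in exact vertex correspondence — this is what makes template-based
shape averaging exact. At resolution 4 the discretisation error of head
volume and cup area against the analytic ground truth is below 0.1%.

**Disease model.** Clinically, the LCPD head collapses in its superior
and superolateral portion and extrudes laterally. The generator scales
head vertices radially toward the head centre by up to the collapse
fraction, with a raised-cosine falloff inside a 60° half-angle cap around
a direction tilted `sector_bias` degrees from superior toward lateral
(default 45°), then translates the head laterally by the shift. The
deformed head volume is recomputed from the mesh and recorded as ground
truth; the fitted sphere of a purely shifted head moves by exactly the
shift with unchanged radius.

**Simulated surgery.** The combined osteotomy is modelled as: superior
and superior-posterior cup sectors widened by the containment gain
(Salter-type redirection), the head recentred toward the cup centre by
the recenter fraction (default 1.0), and the collapse fraction reduced by
the volume-restore fraction (default 0.55, echoing the roughly halved
volume defect reported after implant removal). The post-operative model
is rebuilt from the stored generator state, so its ground truth is again
exact. Widening the cup while the healthy side keeps a 90° extent means
a well-recentred hip can end with *negative* D_AC (more covered area
than the healthy side) — containment beyond the healthy reference, not a
bug.

**Cohorts.** `make_cohort` draws per-patient head radii
N(19, 1.2²) mm (healthy head volume ≈ 16,000 mm³, hemispheric cup area
≈ 2,300–2,600 mm², the scale of published cohort means), sex 13:2
male:female, affected side 10:5 left:right, Herring class 10:5 C:B, and
diagnosis ages populating a 9:6 under/over-six split — the published
cohort's composition. Herring C hips draw more severe collapse
(0.20–0.40 vs 0.10–0.25) and extrusion (1.5–4.0 vs 0.5–2.0 mm); no
quantitative severity distribution is published, so these ranges are the
package's own choice, stated here and configurable. A single
`severity_scale` multiplies collapse, shift and surgical gain together;
zero gives a null cohort in which the affected and healthy sides are
identical by construction. Everything is a pure function of the
parameters and a seed.

## Measurement procedures

**Sphere fitting.** Algebraic linearised least squares (solving
|p − c|² = r² as a linear system) seeds a Gauss-Newton refinement of the
geometric residuals |p − c| − r. Inputs need at least four non-coplanar
points; the RMS radial residual is reported. Head fits use the labelled
`head` region (the paper's spheres were fitted interactively; labels are
the scripted equivalent), cup fits the labelled inner surface. With 500
points and 0.1 mm Gaussian noise the 95th-percentile centre error is
below 0.05 mm.

**Sector partition and coverage.** Sectors are eight equal 45° azimuthal
bins about the cup pole axis (the lateral direction through the fitted
cup centre), azimuth measured from anterior toward superior,
counter-clockwise viewed from lateral, with the superior sector centred
on the superior direction. A centroid exactly on a bin boundary joins the
counter-clockwise-lower bin. Coverage classifies whole triangles by
centroid distance against the fitted head radius plus a tolerance rather
than clipping triangles against the sphere: the overlap is not defined at
sub-triangle precision by the source procedure, and centroid
classification converges to the exact overlap with refinement. The bare
operation defaults to 0.5 mm tolerance; the pipeline default is 1.0 mm,
a joint-space allowance chosen so that a subluxated synthetic hip (up to
5 mm shift at ~19 mm head radius) retains a covered band throughout —
with 0.5 mm the covered band vanishes entirely beyond about 4.4 mm of
shift and coverage saturates at zero.

**Volume defect.** Head volumes come from the closed head submesh
(cap + base disk); D_FH = healthy − affected. Note the printed sign
conventions differ across metrics: D_SC subtracts healthy from affected,
D_AC and D_FH subtract affected from healthy; all are signed and never
clamped.

**Acetabular morphology.** The local cup radius at a sampled vertex is
the radius of a sphere fitted to the geodesic patch (graph shortest-path
distance, default 8 mm) around it; 20 vertices are sampled uniformly
without replacement under a recorded seed, degenerate patches are skipped
with a warning (error if more than half are). The mean is the cup radius.
On an ellipsoidal cup the mean lies strictly between the extreme
principal curvature radii.

**Shape difference.** P1–P5 are extracted per femur: head sphere fit
(P1), per-region principal axes for shaft and neck, junction as the
closest point between the two axis lines (P3 = head-centre distance, P4 =
angle between the junction→head direction and the distal shaft
direction), mid-neck cross-section mean diameter (P2), head extent along
the neck axis (P5). All five are pose- and chirality-invariant and are
recovered within 2%/2° from generated femurs (near-exactly at default
resolutions). Group averages are componentwise parameter means, and the
average model carries a vertex-wise mean surface over the corresponded
member meshes — a five-parameter template alone is rotationally smooth
and cannot preserve the localized collapse that the comparison is meant
to find. Superposition of two average models uses the closed-form
Procrustes fit over the known topological correspondences: it is the
exact minimiser of the corresponding-point distances being reported and
is exactly symmetric under argument swap, unlike nearest-neighbour ICP.
The maximum displacement is reported with a head-octant label by coronal
azimuth (superior, superior-lateral, lateral, ..., superior-medial — the
vocabulary in which head collapse is described); with superolateral
collapse injected, the maximum falls in the S or SL octant in ≥ 95% of
seeded cohorts. Age stratification uses age at diagnosis by default with
the ≥ 6-year boundary joining the older group.

## Statistics

Normality by Shapiro-Wilk (scipy), valid for 3 ≤ n ≤ 5000 and undefined
for constant samples. Comparisons by two-sided paired t-tests at
α = 0.05 with no multiple-testing correction, matching how such small
surgical cohorts are analysed; Holm-adjusted p values can be annotated as
an extra column (off by default). A metric whose paired differences have
zero variance is marked non-testable in the report rather than aborting
the batch. Display rounding follows the printed-table precision (ages
2 dp, follow-up and percentages 1 dp; p below 0.001 renders as
"< 0.001") while raw values are retained in machine output. The paired-t
implementation is calibrated: its type-I error over 1000 seeded null
cohorts of n = 15 lies within the 95% binomial interval of 0.05, and its
p values match an independent incomplete-beta evaluation of the t
distribution to 1e-4.

## Pipeline and reproducibility

The `simulate` / `measure` / `report` commands chain the stages over a
manifest. A single master seed fans out to per-stage seeds via a
stage-name-keyed SHA-256 hash, so stages are independently reproducible;
every output artifact embeds the software version, seed and a config
hash, and contains no timestamps — repeated runs are byte-identical.
Cohort meshes are written in the canonical left pose (the manifest
records the anatomical side; mirroring is lossless), which keeps the
facet stream, and hence the reloaded topology, identical across patients
and sides so template correspondence survives I/O. Per-patient failures
in `measure` (missing or unreadable files) are logged and recorded as
failed rows without aborting the batch.

Problem sizes: validation uses mesh resolution 4 (≈ 12k femur vertices)
for geometry-recovery and sweep checks, resolution 3 with 3-patient
cohorts for the 50-cohort localization experiment, and a 15-patient
resolution-4 cohort for the end-to-end metric summary.

## Limitations

The generator emulates idealized geometry: analytic head/cup surfaces,
no acetabular notch, no cartilage (measurements are bone-surface only,
as in the source procedure), no growth or fragmentation-stage texture,
no segmentation noise or smoothing artifacts, and a deformity field that
is smooth and radially structured. Passing recovery tests therefore
demonstrates the correctness of the measurement algorithms, not
robustness to real segmentation error; on real data, label quality and
mesh repair dominate. Published patient-level values cannot be
reproduced numerically without the unpublished CT reconstructions — only
the demographic table, the stratification counts and the direction of
every surgical effect are reproduced exactly; the mm-scale cohort tables
are emulated at realistic magnitudes. Real cohorts also show healthy-side
sphere-centre distances around 2 mm (cartilage offset between bony head
and socket centres); the synthetic healthy hip is exactly concentric, so
its SC is zero and bilateral differences isolate the injected deformity.
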