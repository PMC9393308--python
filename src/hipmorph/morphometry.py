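"""Hip morphometry: sphere fits, sector coverage, volume defect, cup shape.

Implements the four bilateral measurement procedures run on each hip side:

1. least-squares sphere fits of the femoral head and the acetabulum, and
   the distance SC between their centres; the bilateral difference
   ``D_SC = SC(affected) - SC(healthy)``;
2. acetabular coverage AC: the cup's inner surface is split into eight
   45-degree azimuthal sectors (anterior, superior-anterior, superior,
   superior-posterior, posterior, inferior-posterior, inferior,
   inferior-anterior) about the cup pole axis, and the covered area per
   sector is the summed area of triangles whose centroids lie within the
   best-fit head-sphere radius plus a tolerance;
   ``D_AC = AC(healthy) - AC(affected)``;
3. femoral-head volume FH from the closed head surface;
   ``D_FH = FH(healthy) - FH(affected)``;
4. acetabular morphology: inner-surface area, and the cup radius as the
   mean of local sphere fits over geodesic patches around randomly sampled
   surface points.

Note the printed sign conventions: D_SC subtracts healthy from affected,
while D_AC and D_FH subtract affected from healthy.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .meshkit import (
    AnatomicalFrame,
    DegenerateInputError,
    EmptyMeshError,
    TriangleMesh,
    mesh_volume,
    surface_area,
)

__all__ = [
    "SECTORS",
    "FittedSphere",
    "SectorCoverage",
    "BilateralMetrics",
    "fit_sphere",
    "sphere_center_distance",
    "compute_DSC",
    "compute_DAC",
    "compute_DFH",
    "partition_acetabulum",
    "sector_coverage",
    "acetabular_coverage",
    "total_AC",
    "head_volume",
    "inner_surface_area",
    "acetabular_radius",
    "measure_side",
    "measure_patient",
]

SECTORS = ("A", "SA", "S", "SP", "P", "IP", "I", "IA")

#: Default centroid-classification tolerance for coverage (mm).
DEFAULT_COVERAGE_TOLERANCE_MM = 0.5


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedSphere:
    """Least-squares sphere: centre (mm), radius (mm), RMS radial residual."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.radius <= 0:
            raise DegenerateInputError("fitted radius must be positive")
        if self.rms_residual < 0 or self.n_points < 4:
            raise DegenerateInputError("invalid sphere fit")


def fit_sphere(points) -> FittedSphere:
    """Fit a sphere to points: algebraic seed + geometric refinement.

    The linearised algebraic fit solves ``|p - c|^2 = r^2`` as a linear
    system in (c, r^2 - |c|^2); a Gauss-Newton pass on the geometric
    residuals ``|p - c| - r`` then refines it.  Requires at least four
    non-coplanar points.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateInputError(f"sphere fit needs >= 4 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateInputError("sphere fit is degenerate: points are coplanar")

    # algebraic: [2p, 1] @ [c, k] = |p|^2, with k = r^2 - |c|^2
    a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def residuals(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    def jac(x):
        diff = pts - x[:3]
        dist = np.linalg.norm(diff, axis=1)
        dist = np.where(dist > 0, dist, 1.0)
        j = np.empty((len(pts), 4))
        j[:, :3] = -diff / dist[:, None]
        j[:, 3] = -1.0
        return j

    fit = least_squares(residuals, np.append(c0, r0), jac=jac, method="lm")
    center, radius = fit.x[:3], float(fit.x[3])
    res = residuals(fit.x)
    return FittedSphere(center, abs(radius), float(np.sqrt(np.mean(res**2))), len(pts))


def sphere_center_distance(head: FittedSphere, cup: FittedSphere) -> float:
    """Euclidean distance SC between the two fitted centres (mm)."""
    return float(np.linalg.norm(head.center - cup.center))


def compute_DSC(sc_affected: float, sc_healthy: float) -> float:
    """D_SC = SC(affected) - SC(healthy); signed, not clamped."""
    if sc_affected < 0 or sc_healthy < 0:
        raise ValueError("centre distances must be non-negative")
    return float(sc_affected - sc_healthy)


def compute_DAC(ac_healthy: float, ac_affected: float) -> float:
    """D_AC = AC(healthy) - AC(affected); signed."""
    if ac_healthy < 0 or ac_affected < 0:
        raise ValueError("coverage areas must be non-negative")
    return float(ac_healthy - ac_affected)


def compute_DFH(v_healthy: float, v_affected: float) -> float:
    """D_FH = FH volume(healthy) - FH volume(affected); signed."""
    if v_healthy < 0 or v_affected < 0:
        raise ValueError("volumes must be non-negative")
    return float(v_healthy - v_affected)


# ---------------------------------------------------------------------------
# sector partition and coverage
# ---------------------------------------------------------------------------

def _sector_index(azimuth_deg: np.ndarray) -> np.ndarray:
    """Map azimuth (degrees from anterior toward superior, CCW viewed from
    lateral) to sector indices.  Bins are 45 degrees wide and centred on the
    eight directions; a value exactly on a bin boundary joins the
    counter-clockwise-lower bin."""
    az = np.mod(np.asarray(azimuth_deg, float), 360.0)
    return np.ceil((az - 22.5) / 45.0).astype(int) % 8


def sector_assignment(cup_mesh: TriangleMesh, frame: AnatomicalFrame) -> np.ndarray:
    """Per-face sector index for the cup mesh.

    The frame origin must lie on the cup pole axis (place it at the fitted
    cup centre); the pole axis is the frame's lateral direction and azimuth
    is taken in the (anterior, superior) plane from the face centroid.
    """
    if cup_mesh.n_faces == 0:
        raise EmptyMeshError("cannot partition an empty cup mesh")
    local = frame.to_local(cup_mesh.triangle_centroids())
    azimuth = np.rad2deg(np.arctan2(local[:, 2], local[:, 1]))
    return _sector_index(azimuth)


def partition_acetabulum(cup_mesh: TriangleMesh, frame: AnatomicalFrame) -> dict:
    """Split the cup into the eight labelled sector submeshes.

    The partition is exhaustive and disjoint: every face lands in exactly
    one sector, so sector areas sum to the whole-cup area.
    """
    idx = sector_assignment(cup_mesh, frame)
    out = {}
    for k, name in enumerate(SECTORS):
        mask = idx == k
        out[name] = (cup_mesh.submesh_from_faces(mask) if mask.any()
                     else TriangleMesh(np.empty((0, 3)), np.empty((0, 3), np.int64)))
    return out


def sector_coverage(sector_mesh: TriangleMesh, head_sphere: FittedSphere,
                    tolerance_mm: float = DEFAULT_COVERAGE_TOLERANCE_MM) -> float:
    """Covered area (mm^2) of one sector against the fitted head sphere.

    A triangle counts as covered when its centroid lies within
    ``head_sphere.radius + tolerance_mm`` of the head centre.  Monotone
    non-decreasing in both tolerance and radius; converges to the exact
    sphere-surface overlap with mesh refinement.
    """
    if tolerance_mm < 0:
        raise ValueError("tolerance must be >= 0")
    if sector_mesh.n_faces == 0:
        return 0.0
    dist = np.linalg.norm(sector_mesh.triangle_centroids() - head_sphere.center, axis=1)
    covered = dist <= head_sphere.radius + tolerance_mm
    return float(sector_mesh.triangle_areas()[covered].sum())


@dataclass
class SectorCoverage:
    """Covered area per named sector plus the partition metadata."""

    areas: dict
    frame: AnatomicalFrame
    tolerance_mm: float

    def __post_init__(self):
        if set(self.areas) != set(SECTORS):
            raise ValueError(f"sector areas must have exactly the keys {SECTORS}")
        if any(v < 0 for v in self.areas.values()):
            raise ValueError("sector areas must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))


def acetabular_coverage(cup_mesh: TriangleMesh, frame: AnatomicalFrame,
                        head_sphere: FittedSphere,
                        tolerance_mm: float = DEFAULT_COVERAGE_TOLERANCE_MM) -> SectorCoverage:
    """Coverage of all eight sectors in one pass."""
    idx = sector_assignment(cup_mesh, frame)
    dist = np.linalg.norm(cup_mesh.triangle_centroids() - head_sphere.center, axis=1)
    covered = dist <= head_sphere.radius + tolerance_mm
    areas = cup_mesh.triangle_areas()
    out = {}
    for k, name in enumerate(SECTORS):
        out[name] = float(areas[(idx == k) & covered].sum())
    return SectorCoverage(out, frame, tolerance_mm)


def total_AC(coverage: SectorCoverage) -> float:
    """Total acetabular coverage: sum of the eight sector areas (mm^2)."""
    return coverage.total


# ---------------------------------------------------------------------------
# head volume and cup morphology
# ---------------------------------------------------------------------------

def head_volume(head_mesh: TriangleMesh) -> float:
    """Volume (mm^3) of the closed femoral-head surface."""
    return mesh_volume(head_mesh)


def inner_surface_area(cup_mesh: TriangleMesh) -> float:
    """Area (mm^2) of the labelled acetabular inner surface.

    Uses the ``cup`` region when labels are present, else the whole mesh.
    """
    if cup_mesh.labels is not None:
        if not np.any(cup_mesh.labels == "cup"):
            raise EmptyMeshError("no vertices labelled 'cup'")
        return surface_area(cup_mesh.region_submesh("cup"))
    return surface_area(cup_mesh)


def _vertex_graph(mesh: TriangleMesh):
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    return coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                      shape=(n, n)).tocsr()


def acetabular_radius(cup_mesh: TriangleMesh, n_points: int = 20,
                      patch_radius_mm: float = 8.0, seed: int = 0):
    """Mean local cup radius from sphere fits over geodesic patches.

    ``n_points`` vertices are sampled uniformly without replacement under
    ``seed``; at each, a sphere is fitted to the vertices within geodesic
    distance ``patch_radius_mm`` and its radius taken as the local radius.
    Points whose patch is too small or degenerate are skipped with a
    warning; more than half skipped is an error.  Returns
    ``(mean_radius, per_point_radii)``.
    """
    mesh = cup_mesh
    if mesh.labels is not None and np.any(mesh.labels == "cup"):
        mesh = mesh.region_submesh("cup")
    if mesh.n_vertices < n_points:
        raise DegenerateInputError(
            f"cup has {mesh.n_vertices} vertices, fewer than n_points={n_points}")
    rng = np.random.default_rng(seed)
    samples = rng.choice(mesh.n_vertices, size=n_points, replace=False)
    graph = _vertex_graph(mesh)
    dists = dijkstra(graph, indices=samples, limit=patch_radius_mm)

    radii = []
    skipped = 0
    for row, vidx in zip(dists, samples):
        patch = mesh.vertices[np.isfinite(row)]
        try:
            radii.append(fit_sphere(patch).radius)
        except DegenerateInputError as exc:
            skipped += 1
            warnings.warn(
                f"local radius at vertex {vidx} skipped: {exc}", stacklevel=2)
    if skipped > n_points / 2:
        raise DegenerateInputError(
            f"{skipped}/{n_points} local patches unusable for sphere fitting")
    return float(np.mean(radii)), radii


# ---------------------------------------------------------------------------
# per-side and bilateral measurement
# ---------------------------------------------------------------------------

@dataclass
class SideMeasurements:
    """All per-side quantities from one hip model."""

    head_sphere: FittedSphere
    cup_sphere: FittedSphere
    sc_mm: float
    coverage: SectorCoverage
    ac_mm2: float
    fh_mm3: float
    acetab_area_mm2: float
    acetab_radius_mm: float


def measure_side(model, coverage_tolerance_mm: float = DEFAULT_COVERAGE_TOLERANCE_MM,
                 n_radius_points: int = 20, patch_radius_mm: float = 8.0,
                 seed: int = 0) -> SideMeasurements:
    """Run all four measurement procedures on one hip side.

    Right hips are mirrored to the canonical left pose first; the sector
    frame is re-anchored at the fitted cup centre.
    """
    canonical = model.to_canonical()
    head_fit = fit_sphere(canonical.femur.region_points("head"))
    cup_fit = fit_sphere(canonical.acetabulum.region_points("cup"))
    sc = sphere_center_distance(head_fit, cup_fit)
    frame = AnatomicalFrame(cup_fit.center, canonical.frame.lateral,
                            canonical.frame.anterior, canonical.frame.superior)
    coverage = acetabular_coverage(canonical.acetabulum, frame, head_fit,
                                   coverage_tolerance_mm)
    fh = head_volume(canonical.head_submesh())
    area = inner_surface_area(canonical.acetabulum)
    radius, _ = acetabular_radius(canonical.acetabulum, n_radius_points,
                                  patch_radius_mm, seed)
    return SideMeasurements(head_fit, cup_fit, sc, coverage, coverage.total,
                            fh, area, radius)


@dataclass
class BilateralMetrics:
    """Per-patient, per-stage bilateral metrics (the report row).

    Sign conventions as printed: ``d_sc = sc_affected - sc_healthy``,
    ``d_ac = ac_healthy - ac_affected``, ``d_fh = fh_healthy - fh_affected``.
    """

    patient: int
    stage: str
    sc_affected: float
    sc_healthy: float
    d_sc: float
    ac_affected: float
    ac_healthy: float
    d_ac: float
    fh_affected: float
    fh_healthy: float
    d_fh: float
    acetab_area_affected: float
    acetab_area_healthy: float
    acetab_radius_affected: float
    acetab_radius_healthy: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def measure_patient(patient_id: int, stage: str, affected_model, healthy_model,
                    coverage_tolerance_mm: float = DEFAULT_COVERAGE_TOLERANCE_MM,
                    n_radius_points: int = 20, patch_radius_mm: float = 8.0,
                    seed: int = 0) -> BilateralMetrics:
    """Measure both sides of one patient at one stage and take differences."""
    aff = measure_side(affected_model, coverage_tolerance_mm, n_radius_points,
                       patch_radius_mm, seed)
    heal = measure_side(healthy_model, coverage_tolerance_mm, n_radius_points,
                        patch_radius_mm, seed)
    return BilateralMetrics(
        patient=patient_id, stage=stage,
        sc_affected=aff.sc_mm, sc_healthy=heal.sc_mm,
        d_sc=compute_DSC(aff.sc_mm, heal.sc_mm),
        ac_affected=aff.ac_mm2, ac_healthy=heal.ac_mm2,
        d_ac=compute_DAC(heal.ac_mm2, aff.ac_mm2),
        fh_affected=aff.fh_mm3, fh_healthy=heal.fh_mm3,
        d_fh=compute_DFH(heal.fh_mm3, aff.fh_mm3),
        acetab_area_affected=aff.acetab_area_mm2,
        acetab_area_healthy=heal.acetab_area_mm2,
        acetab_radius_affected=aff.acetab_radius_mm,
        acetab_radius_healthy=heal.acetab_radius_mm,
    )
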