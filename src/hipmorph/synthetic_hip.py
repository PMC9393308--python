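"""Parametric generator of bilateral pre/post-operative hip models.

No CT data ships with pediatric hip-deformity studies, so this module is a
first-class stand-in: it builds labelled triangle meshes of a proximal
femur (spherical-cap head closed by a planar disk, cylindrical neck and
shaft) and an acetabular cup (open spherical patch with per-sector angular
extent), together with exact ground truth for every quantity the
measurement pipeline recovers — sphere centres and radii, head volume,
cup inner area, per-sector extents, and the five proximal-femur shape
parameters.

The deformity model mimics Legg-Calvé-Perthes disease as described
clinically: radial collapse of the superior/superolateral cap of the
femoral head with a smooth cosine falloff, plus rigid lateral extrusion of
the head.  The simulated operation (combined pelvic + femoral osteotomy)
widens the superior and superior-posterior cup sectors, recentres the head
toward the cup centre, and partially restores the collapsed volume.

All geometry is generated in the canonical left-hip pose (lateral = +x,
anterior = +y, superior = +z, cup centre at the origin); right-side models
are produced by sagittal mirroring of the canonical build.  Topology is a
pure function of ``mesh_resolution``, never of the shape parameters, so
meshes from different parameter sets are in exact vertex correspondence.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .meshkit import (
    AnatomicalFrame,
    TriangleMesh,
    mesh_volume,
    mirror_sagittal,
    write_mesh,
)
from .cohort_stats import CohortRecord

__all__ = [
    "SECTORS",
    "ShapeParams",
    "NeckParams",
    "HipGroundTruth",
    "HipSideModel",
    "SyntheticPatient",
    "CohortDistributions",
    "build_femur",
    "build_cup",
    "make_healthy_hip",
    "apply_lcpd_deformity",
    "simulate_postop",
    "make_cohort",
    "write_cohort",
]

#: The eight acetabular sectors, counter-clockwise viewed from lateral,
#: by azimuth about the cup pole axis: anterior, superior-anterior,
#: superior, superior-posterior, posterior, inferior-posterior, inferior,
#: inferior-anterior.
SECTORS = ("A", "SA", "S", "SP", "P", "IP", "I", "IA")


# ---------------------------------------------------------------------------
# shape parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """The five proximal-femur shape parameters (P1-P5).

    P1 head diameter, P2 neck diameter, P3 neck length (head centre to the
    neck/shaft axis junction), P4 angle between neck and shaft axes
    (degrees; the obtuse anatomical neck-shaft angle), P5 head height
    (extent of the head region along the neck axis).
    """

    head_diameter_mm: float
    neck_diameter_mm: float
    neck_length_mm: float
    neck_shaft_angle_deg: float
    head_height_mm: float

    def __post_init__(self):
        for name in ("head_diameter_mm", "neck_diameter_mm", "neck_length_mm", "head_height_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 90.0 <= self.neck_shaft_angle_deg <= 180.0:
            warnings.warn(
                f"neck-shaft angle {self.neck_shaft_angle_deg:.1f} deg outside the "
                "anatomically plausible range [90, 180]", stacklevel=2)
        if self.head_height_mm >= self.head_diameter_mm:
            raise ValueError("head height (P5) must be below head diameter (P1)")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.head_diameter_mm, self.neck_diameter_mm, self.neck_length_mm,
            self.neck_shaft_angle_deg, self.head_height_mm])


@dataclass(frozen=True)
class NeckParams:
    """Neck/shaft geometry (P2-P5) used with an explicit head radius."""

    neck_diameter_mm: float
    neck_length_mm: float
    neck_shaft_angle_deg: float = 135.0
    head_height_mm: float | None = None

    @classmethod
    def default_for(cls, head_radius: float) -> "NeckParams":
        # ratios of the canonical example (P1 40, P2 20, P3 45, P4 135, P5 22)
        return cls(
            neck_diameter_mm=1.0 * head_radius,
            neck_length_mm=2.25 * head_radius,
            neck_shaft_angle_deg=135.0,
            head_height_mm=1.1 * head_radius,
        )

    def to_shape_params(self, head_radius: float) -> ShapeParams:
        h = self.head_height_mm if self.head_height_mm is not None else 1.1 * head_radius
        return ShapeParams(2.0 * head_radius, self.neck_diameter_mm,
                           self.neck_length_mm, self.neck_shaft_angle_deg, h)


def spherical_cap_volume(radius: float, height: float) -> float:
    """Exact volume of a spherical cap of the given height (mm^3)."""
    return np.pi * height**2 * (3.0 * radius - height) / 3.0


# ---------------------------------------------------------------------------
# ground truth and model containers
# ---------------------------------------------------------------------------

@dataclass
class HipGroundTruth:
    """Exact generator state, expressed in the canonical left-hip pose."""

    head_center: np.ndarray
    head_radius: float
    cup_center: np.ndarray
    cup_radius: float
    sector_extents_deg: dict
    head_volume_mm3: float
    cup_inner_area_mm2: float
    shape_params: ShapeParams
    collapse_fraction: float = 0.0
    lateral_shift_mm: float = 0.0
    sector_bias_deg: float = 45.0
    collapse_halfangle_deg: float = 60.0
    mesh_resolution: int = 4
    seed: int = 0
    side: str = "left"
    stage: str = "preop"

    def __post_init__(self):
        self.head_center = np.asarray(self.head_center, float).reshape(3)
        self.cup_center = np.asarray(self.cup_center, float).reshape(3)
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")
        if self.cup_radius < self.head_radius:
            raise ValueError("cup_radius must be >= head_radius")
        if not 0.0 <= self.collapse_fraction < 1.0:
            raise ValueError("collapse_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["head_center"] = [float(x) for x in self.head_center]
        out["cup_center"] = [float(x) for x in self.cup_center]
        out["shape_params"] = dataclasses.asdict(self.shape_params)
        return out


@dataclass
class HipSideModel:
    """One side's labelled meshes plus anatomical frame and metadata.

    Region labels: femur vertices are ``head`` (spherical cap, on the head
    sphere), ``head_base`` (closing-disk centre, interior), ``neck`` and
    ``shaft``; acetabulum vertices are ``cup`` (the inner articular patch).
    """

    femur: TriangleMesh
    acetabulum: TriangleMesh
    frame: AnatomicalFrame
    side: str = "left"
    stage: str = "preop"
    affected: bool = False

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.stage not in ("preop", "postop"):
            raise ValueError("stage must be 'preop' or 'postop'")

    def to_canonical(self) -> "HipSideModel":
        """Return the model in the canonical left pose (mirror right hips)."""
        if self.side == "left":
            return self
        return replace(
            self,
            femur=mirror_sagittal(self.femur, self.frame),
            acetabulum=mirror_sagittal(self.acetabulum, self.frame),
            side="left",
        )

    def head_submesh(self) -> TriangleMesh:
        """Closed femoral-head surface (cap + base disk), watertight."""
        return self.femur.region_submesh(("head", "head_base"))


# ---------------------------------------------------------------------------
# mesh builders (fixed topology per resolution)
# ---------------------------------------------------------------------------

def _grid_counts(resolution: int):
    if resolution < 3:
        raise ValueError("mesh_resolution must be >= 3")
    scale = 2 ** (resolution - 1)
    return {
        "head_az": 16 * scale,   # azimuthal segments of the head cap
        "head_rings": 8 * scale,  # polar rings of the head cap
        "cup_az": 16 * scale,     # multiple of 8: sector boundaries on cell edges
        "cup_rings": 4 * scale,
        "cyl_az": 8 * scale,
        "cyl_len": 4 * scale,
    }


def _orthobasis(u: np.ndarray):
    u = u / np.linalg.norm(u)
    helper = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


def _capped_sphere(center, radius, axis, cap_height, n_az, n_rings):
    """Spherical cap of given height about ``axis`` closed by a planar disk.

    Returns (vertices, faces, labels) with the cap labelled ``head`` and the
    disk-centre vertex ``head_base``.  Watertight and outward-wound.
    """
    u, e1, e2 = _orthobasis(np.asarray(axis, float))
    center = np.asarray(center, float)
    cos_max = np.clip((radius - cap_height) / radius, -1.0, 1.0)
    theta_max = float(np.arccos(cos_max))

    phi = np.arange(n_az) * (2.0 * np.pi / n_az)
    ring_dirs = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2

    verts = [center + radius * u]  # apex
    for i in range(1, n_rings + 1):
        th = theta_max * i / n_rings
        verts.append(center + radius * (np.cos(th) * u + np.sin(th) * ring_dirs))
    base_center = center + (radius - cap_height) * u
    vertices = np.vstack([verts[0][None, :]] + verts[1:] + [base_center[None, :]])

    def ring(i, j):  # ring index 1..n_rings
        return 1 + (i - 1) * n_az + (j % n_az)

    faces = []
    for j in range(n_az):
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_rings):
        for j in range(n_az):
            a, b = ring(i, j), ring(i, j + 1)
            d, c = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, d, c])
            faces.append([a, c, b])
    bc = len(vertices) - 1
    for j in range(n_az):
        faces.append([bc, ring(n_rings, j + 1), ring(n_rings, j)])

    labels = np.full(len(vertices), "head", dtype="U32")
    labels[bc] = "head_base"
    return vertices, np.asarray(faces, np.int64), labels


def _closed_cylinder(p0, p1, radius, n_az, n_len, label):
    """Closed right cylinder from p0 to p1, outward-wound."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    w, e1, e2 = _orthobasis(p1 - p0)
    phi = np.arange(n_az) * (2.0 * np.pi / n_az)
    ring_dirs = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2

    rings = []
    for i in range(n_len + 1):
        c = p0 + (p1 - p0) * (i / n_len)
        rings.append(c + radius * ring_dirs)
    vertices = np.vstack(rings + [p0[None, :], p1[None, :]])
    c0, c1 = len(vertices) - 2, len(vertices) - 1

    def ring(i, j):
        return i * n_az + (j % n_az)

    faces = []
    for i in range(n_len):
        for j in range(n_az):
            a, b = ring(i, j), ring(i, j + 1)
            d, c = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    for j in range(n_az):
        faces.append([c0, ring(0, j + 1), ring(0, j)])
        faces.append([c1, ring(n_len, j), ring(n_len, j + 1)])

    labels = np.full(len(vertices), label, dtype="U32")
    return vertices, np.asarray(faces, np.int64), labels


def build_femur(params: ShapeParams, resolution: int = 4) -> TriangleMesh:
    """Parametric proximal femur in canonical pose, head centre at origin.

    Topology depends only on ``resolution``; meshes built from different
    parameter sets are in exact vertex correspondence.
    """
    g = _grid_counts(resolution)
    r = params.head_diameter_mm / 2.0
    alpha = np.deg2rad(180.0 - params.neck_shaft_angle_deg)
    # neck axis: junction -> head centre, superomedial in the x-z plane
    n_hat = np.array([-np.sin(alpha), 0.0, np.cos(alpha)])
    head_center = np.zeros(3)
    junction = head_center - params.neck_length_mm * n_hat
    shaft_dir = np.array([0.0, 0.0, -1.0])  # distal

    parts = []
    parts.append(_capped_sphere(head_center, r, n_hat, params.head_height_mm,
                                g["head_az"], g["head_rings"]))
    base_center = head_center + (r - params.head_height_mm) * n_hat
    # neck ends 0.5 mm inside the head so no vertex ever coincides with the
    # head-base centre (mesh parts stay index-stable through I/O merging)
    neck_end = base_center + 0.5 * n_hat
    parts.append(_closed_cylinder(junction, neck_end, params.neck_diameter_mm / 2.0,
                                  g["cyl_az"], g["cyl_len"], "neck"))
    shaft_top = junction - 0.5 * r * shaft_dir
    shaft_bottom = junction + 3.0 * r * shaft_dir
    parts.append(_closed_cylinder(shaft_top, shaft_bottom, 0.45 * params.neck_diameter_mm,
                                  g["cyl_az"], g["cyl_len"], "shaft"))

    offset = 0
    verts, faces, labels = [], [], []
    for v, f, l in parts:
        verts.append(v)
        faces.append(f + offset)
        labels.append(l)
        offset += len(v)
    return TriangleMesh(np.vstack(verts), np.vstack(faces), np.concatenate(labels))


def _normalize_extents(sector_extents_deg) -> dict:
    if sector_extents_deg is None:
        return {s: 90.0 for s in SECTORS}
    if set(sector_extents_deg) != set(SECTORS):
        raise ValueError(f"sector extents must have exactly the keys {SECTORS}")
    out = {s: float(sector_extents_deg[s]) for s in SECTORS}
    for s, e in out.items():
        if not 0.0 < e <= 150.0:
            raise ValueError(f"sector extent {s}={e} out of range (0, 150] deg")
    return out


def cup_sector_area(radius: float, extent_deg: float) -> float:
    """Exact area of one 45-degree azimuthal sector of a spherical cup."""
    return radius**2 * (np.pi / 4.0) * (1.0 - np.cos(np.deg2rad(extent_deg)))


def build_cup(cup_center, cup_radius: float, sector_extents_deg=None,
              resolution: int = 4) -> TriangleMesh:
    """Open spherical cup patch, pole medial, opening facing lateral.

    The polar extent may differ per 45-degree azimuthal sector; azimuth is
    measured from anterior toward superior (counter-clockwise viewed from
    lateral), so the grid's sector boundaries land exactly on the
    A/SA/S/... bin edges at 22.5 + k*45 degrees.
    """
    extents = _normalize_extents(sector_extents_deg)
    g = _grid_counts(resolution)
    n_az, n_rings = g["cup_az"], g["cup_rings"]
    center = np.asarray(cup_center, float)

    phi = np.deg2rad(-22.5) + np.arange(n_az) * (2.0 * np.pi / n_az)
    phi_deg = np.rad2deg(phi)
    # per-vertex-column polar extent: the sector whose bin the column is in
    # (boundary columns take the counter-clockwise-lower sector)
    col_sector = np.ceil((phi_deg - 22.5) / 45.0).astype(int) % 8
    theta_max = np.deg2rad(np.array([extents[SECTORS[k]] for k in col_sector]))

    pole = center - cup_radius * np.array([1.0, 0.0, 0.0])
    dirs_plane = np.cos(phi)[:, None] * np.array([0.0, 1.0, 0.0]) \
        + np.sin(phi)[:, None] * np.array([0.0, 0.0, 1.0])

    verts = [pole[None, :]]
    for i in range(1, n_rings + 1):
        th = theta_max * i / n_rings
        ring = center + cup_radius * (
            -np.cos(th)[:, None] * np.array([1.0, 0.0, 0.0]) + np.sin(th)[:, None] * dirs_plane)
        verts.append(ring)
    vertices = np.vstack(verts)

    def ring(i, j):
        return 1 + (i - 1) * n_az + (j % n_az)

    faces = []
    for j in range(n_az):
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_rings):
        for j in range(n_az):
            a, b = ring(i, j), ring(i, j + 1)
            d, c = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, d, c])
            faces.append([a, c, b])

    labels = np.full(len(vertices), "cup", dtype="U32")
    return TriangleMesh(vertices, np.asarray(faces, np.int64), labels)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def make_healthy_hip(
    head_radius: float = 19.0,
    cup_radius: float | None = None,
    neck_params: NeckParams | None = None,
    side: str = "left",
    mesh_resolution: int = 4,
    seed: int = 0,
    sector_extents_deg=None,
    stage: str = "preop",
):
    """Healthy reference hip: concentric head and cup, exact ground truth.

    The cup is concentric with the head (sphere-centre distance 0) at
    ``cup_radius`` (default head_radius + 0.2 mm joint clearance) with a
    hemispheric 90-degree extent in every sector unless overridden.
    """
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    if cup_radius is None:
        cup_radius = head_radius + 0.2
    if cup_radius < head_radius:
        raise ValueError("cup_radius must be >= head_radius")
    if neck_params is None:
        neck_params = NeckParams.default_for(head_radius)
    params = neck_params.to_shape_params(head_radius)
    extents = _normalize_extents(sector_extents_deg)

    femur = build_femur(params, mesh_resolution)
    cup = build_cup(np.zeros(3), cup_radius, extents, mesh_resolution)
    frame = AnatomicalFrame.canonical()
    model = HipSideModel(femur, cup, frame, side="left", stage=stage, affected=False)
    truth = HipGroundTruth(
        head_center=np.zeros(3),
        head_radius=float(head_radius),
        cup_center=np.zeros(3),
        cup_radius=float(cup_radius),
        sector_extents_deg=extents,
        head_volume_mm3=spherical_cap_volume(head_radius, params.head_height_mm),
        cup_inner_area_mm2=float(sum(cup_sector_area(cup_radius, extents[s]) for s in SECTORS)),
        shape_params=params,
        mesh_resolution=mesh_resolution,
        seed=int(seed),
        side=side,
        stage=stage,
    )
    if side == "right":
        model = replace(
            model,
            femur=mirror_sagittal(model.femur, frame),
            acetabulum=mirror_sagittal(model.acetabulum, frame),
            side="right",
        )
    return model, truth


def apply_lcpd_deformity(
    model: HipSideModel,
    truth: HipGroundTruth,
    collapse_fraction: float,
    lateral_shift_mm: float,
    sector_bias_deg: float = 45.0,
    collapse_halfangle_deg: float = 60.0,
):
    """Inject the disease deformity into a healthy model.

    Head vertices within ``collapse_halfangle_deg`` of the collapse
    direction (coronal azimuth ``sector_bias_deg`` from superior toward
    lateral) are scaled radially toward the head centre by up to
    ``collapse_fraction`` with a raised-cosine falloff; the whole head is
    then translated laterally by ``lateral_shift_mm``.  Ground truth is
    updated, with the deformed head volume recomputed from the mesh.
    """
    if not 0.0 <= collapse_fraction < 1.0:
        raise ValueError("collapse_fraction must be in [0, 1)")
    canonical = model.to_canonical()
    femur = canonical.femur.copy()

    center = truth.head_center
    bias = np.deg2rad(sector_bias_deg)
    w = np.array([np.sin(bias), 0.0, np.cos(bias)])  # superior -> lateral tilt
    psi0 = np.deg2rad(collapse_halfangle_deg)

    head_mask = femur.region_vertex_mask(("head", "head_base"))
    v = femur.vertices[head_mask]
    rv = v - center
    norms = np.linalg.norm(rv, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_psi = np.clip((rv @ w) / np.where(norms > 0, norms, 1.0), -1.0, 1.0)
    psi = np.arccos(cos_psi)
    fall = np.where(psi < psi0, 0.5 * (1.0 + np.cos(np.pi * psi / psi0)), 0.0)
    scale = 1.0 - collapse_fraction * fall
    v = center + rv * scale[:, None]
    v = v + lateral_shift_mm * np.array([1.0, 0.0, 0.0])
    femur.vertices[head_mask] = v

    out = replace(canonical, femur=femur, affected=True)
    new_truth = replace(
        truth,
        head_center=truth.head_center + np.array([lateral_shift_mm, 0.0, 0.0]),
        collapse_fraction=float(collapse_fraction),
        lateral_shift_mm=float(lateral_shift_mm),
        sector_bias_deg=float(sector_bias_deg),
        collapse_halfangle_deg=float(collapse_halfangle_deg),
    )
    new_truth.head_volume_mm3 = mesh_volume(out.head_submesh())
    if model.side == "right":
        out = replace(
            out,
            femur=mirror_sagittal(out.femur, out.frame),
            acetabulum=mirror_sagittal(out.acetabulum, out.frame),
            side="right",
        )
    return out, new_truth


def simulate_postop(
    model: HipSideModel,
    truth: HipGroundTruth,
    containment_gain_deg: float = 15.0,
    recenter_fraction: float = 1.0,
    volume_restore_fraction: float = 0.55,
):
    """Emulate the combined osteotomy on an affected hip.

    The superior (S) and superior-posterior (SP) cup sectors are widened by
    ``containment_gain_deg``; the head is recentred toward the cup centre
    by ``recenter_fraction`` of its lateral extrusion; the collapse
    fraction is reduced by ``volume_restore_fraction`` (remodelling under a
    restored mechanical environment).  The postoperative model is rebuilt
    from the stored generator state, so its ground truth is again exact.
    """
    if not model.affected:
        raise ValueError("simulate_postop requires an affected model")
    extents = dict(truth.sector_extents_deg)
    for s in ("S", "SP"):
        extents[s] = min(extents[s] + containment_gain_deg, 150.0)

    new_collapse = truth.collapse_fraction * (1.0 - volume_restore_fraction)
    new_shift = truth.lateral_shift_mm * (1.0 - recenter_fraction)

    neck = NeckParams(
        truth.shape_params.neck_diameter_mm,
        truth.shape_params.neck_length_mm,
        truth.shape_params.neck_shaft_angle_deg,
        truth.shape_params.head_height_mm,
    )
    base, base_truth = make_healthy_hip(
        head_radius=truth.head_radius,
        cup_radius=truth.cup_radius,
        neck_params=neck,
        side=model.side,
        mesh_resolution=truth.mesh_resolution,
        seed=truth.seed,
        sector_extents_deg=extents,
        stage="postop",
    )
    post, post_truth = apply_lcpd_deformity(
        base, base_truth, new_collapse, new_shift,
        truth.sector_bias_deg, truth.collapse_halfangle_deg)
    post = replace(post, stage="postop")
    post_truth.stage = "postop"
    return post, post_truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDistributions:
    """Sampling distributions for synthetic cohorts.

    Defaults emulate the published 15-patient cohort: 13/15 male, 10/15
    left, 10/15 Herring C, 9/15 diagnosed under six years; head radii around
    19 mm (healthy head volume ~ 16,400 mm^3, hemispheric cup inner area
    ~ 2,300-2,500 mm^2); Herring C hips draw more severe collapse and
    extrusion than Herring B.  ``severity_scale`` scales collapse, lateral
    shift and surgical containment gain together (0 gives a null cohort).
    """

    severity_scale: float = 1.0
    head_radius_mean_mm: float = 19.0
    head_radius_sd_mm: float = 1.2
    cup_clearance_mm: float = 0.2
    collapse_range_b: tuple = (0.10, 0.25)
    collapse_range_c: tuple = (0.20, 0.40)
    shift_range_b_mm: tuple = (0.5, 2.0)
    shift_range_c_mm: tuple = (1.5, 4.0)
    sector_bias_range_deg: tuple = (30.0, 60.0)
    containment_gain_range_deg: tuple = (10.0, 20.0)
    recenter_range: tuple = (0.7, 0.95)
    restore_range: tuple = (0.45, 0.65)
    p_male: float = 13.0 / 15.0
    p_left: float = 10.0 / 15.0
    p_under6: float = 9.0 / 15.0
    p_herring_c: float = 10.0 / 15.0
    mesh_resolution: int = 4


@dataclass
class SyntheticPatient:
    """Bilateral pre/post models for one synthetic patient.

    ``models`` and ``truths`` are keyed by ``(role, stage)`` with role in
    {"affected", "healthy"} and stage in {"preop", "postop"}.
    """

    patient_id: int
    record: CohortRecord
    models: dict
    truths: dict


def make_cohort(
    n_patients: int = 15,
    distributions: CohortDistributions | None = None,
    seed: int = 0,
) -> list:
    """Generate a reproducible synthetic cohort with ground truth.

    Each patient gets four models (healthy/affected x preop/postop); the
    healthy side is identical at both stages (no growth model).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    dist = distributions or CohortDistributions()
    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)))
        sex = "male" if rng.random() < dist.p_male else "female"
        affected_side = "left" if rng.random() < dist.p_left else "right"
        herring = "C" if rng.random() < dist.p_herring_c else "B"
        if rng.random() < dist.p_under6:
            age_dx = round(float(rng.uniform(3.5, 5.9)), 1)
        else:
            age_dx = round(float(rng.uniform(6.0, 8.5)), 1)
        age_op = round(age_dx + float(rng.uniform(0.3, 1.5)), 1)
        followup = int(rng.integers(6, 18))
        record = CohortRecord(
            patient_id=i + 1, sex=sex, side=affected_side,
            age_at_diagnosis=age_dx, age_at_intervention=age_op,
            herring=herring, followup_months=followup)

        head_r = float(np.clip(rng.normal(dist.head_radius_mean_mm, dist.head_radius_sd_mm),
                               15.0, 23.0))
        cup_r = head_r + dist.cup_clearance_mm
        c_lo, c_hi = dist.collapse_range_c if herring == "C" else dist.collapse_range_b
        s_lo, s_hi = dist.shift_range_c_mm if herring == "C" else dist.shift_range_b_mm
        collapse = dist.severity_scale * float(rng.uniform(c_lo, c_hi))
        shift = dist.severity_scale * float(rng.uniform(s_lo, s_hi))
        bias = float(rng.uniform(*dist.sector_bias_range_deg))
        gain = dist.severity_scale * float(rng.uniform(*dist.containment_gain_range_deg))
        recenter = float(rng.uniform(*dist.recenter_range))
        restore = float(rng.uniform(*dist.restore_range))

        healthy_side = "right" if affected_side == "left" else "left"
        healthy_pre, healthy_pre_truth = make_healthy_hip(
            head_r, cup_r, side=healthy_side,
            mesh_resolution=dist.mesh_resolution, seed=seed)
        healthy_post, healthy_post_truth = make_healthy_hip(
            head_r, cup_r, side=healthy_side,
            mesh_resolution=dist.mesh_resolution, seed=seed, stage="postop")
        base, base_truth = make_healthy_hip(
            head_r, cup_r, side=affected_side,
            mesh_resolution=dist.mesh_resolution, seed=seed)
        aff_pre, aff_pre_truth = apply_lcpd_deformity(
            base, base_truth, collapse, shift, sector_bias_deg=bias)
        aff_post, aff_post_truth = simulate_postop(
            aff_pre, aff_pre_truth, containment_gain_deg=gain,
            recenter_fraction=recenter, volume_restore_fraction=restore)

        patients.append(SyntheticPatient(
            patient_id=i + 1,
            record=record,
            models={
                ("healthy", "preop"): healthy_pre,
                ("healthy", "postop"): healthy_post,
                ("affected", "preop"): aff_pre,
                ("affected", "postop"): aff_post,
            },
            truths={
                ("healthy", "preop"): healthy_pre_truth,
                ("healthy", "postop"): healthy_post_truth,
                ("affected", "preop"): aff_pre_truth,
                ("affected", "postop"): aff_post_truth,
            },
        ))
    return patients


def write_cohort(patients, outdir, mesh_format: str = "stl-binary") -> Path:
    """Write cohort meshes, label sidecars, ground truth and manifest.

    Returns the manifest CSV path.  Layout:
    ``patient_NN/{role}_{stage}_{femur,acetabulum}.stl`` plus
    ``.labels.json`` sidecars and a ``ground_truth.json`` per model.

    All meshes are stored in the canonical left pose (the ``side`` column
    records the anatomical side; mirroring is lossless), which keeps every
    femur's facet stream — hence its reloaded topology — identical across
    patients and sides, preserving template correspondence through I/O.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["patient_id,role,stage,side,pose,affected,femur,acetabulum,ground_truth"]
    cohort_rows = ["patient_id,sex,side,age_at_diagnosis,age_at_intervention,herring,followup_months"]
    for pat in patients:
        pdir = outdir / f"patient_{pat.patient_id:02d}"
        pdir.mkdir(exist_ok=True)
        r = pat.record
        cohort_rows.append(
            f"{r.patient_id},{r.sex},{r.side},{r.age_at_diagnosis},"
            f"{r.age_at_intervention},{r.herring},{r.followup_months}")
        for (role, stage), model in sorted(pat.models.items()):
            base = f"{role}_{stage}"
            femur_path = pdir / f"{base}_femur.stl"
            cup_path = pdir / f"{base}_acetabulum.stl"
            truth_path = pdir / f"{base}_ground_truth.json"
            canonical = model.to_canonical()
            write_mesh(canonical.femur, femur_path, mesh_format)
            write_mesh(canonical.acetabulum, cup_path, mesh_format)
            truth_path.write_text(
                json.dumps(pat.truths[(role, stage)].to_dict(), sort_keys=True, indent=1) + "\n")
            rows.append(
                f"{pat.patient_id},{role},{stage},{model.side},canonical,{model.affected},"
                f"{femur_path.relative_to(outdir)},{cup_path.relative_to(outdir)},"
                f"{truth_path.relative_to(outdir)}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    (outdir / "cohort.csv").write_text("\n".join(cohort_rows) + "\n")
    return manifest
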