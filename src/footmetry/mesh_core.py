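"""Mesh ingestion, ground-plane fitting, plantar landmarks and mirroring.

This module is the geometric substrate of the pipeline: labelled bone
surfaces (triangulated, millimetre coordinates), the weight-bearing ground
plane, and the extremal-vertex landmarks every downstream measurement is
built from.  STL parsing and serialisation are delegated to :mod:`trimesh`;
welding of the per-facet duplicated STL vertices is done here so that the
vertex set feeding the PCA axis computation is deterministic and does not
triple-count surface points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: Recognised bone labels.  GROUND labels the supporting-surface mesh.
BONE_CODES = ("TI", "CA", "TA", "NA", "CU", "CM", "M1", "M2", "M5", "GROUND")

#: Bones that must be present for the 30 non-tripod measurements.
REQUIRED_BONES = ("TI", "CA", "TA", "NA", "CU", "CM", "M1", "M2")

SIDES = ("LEFT", "RIGHT", "NA")

#: Vertices closer than this (mm) are welded into one.
WELD_TOL = 1e-6


class MeshError(ValueError):
    """Malformed, empty or otherwise unusable mesh."""


class DegeneratePlaneError(ValueError):
    """Ground vertices do not span a plane."""


def _as_points(a, name: str, width: int = 3) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise MeshError(f"{name} must be an (n, {width}) array, got {arr.shape}")
    return arr


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` and drop degenerate faces.

    Merging is done on a grid of pitch ``tol`` which is exact for the usual
    case of bitwise-duplicated STL facet corners.  The first occurrence of
    each welded vertex keeps its index order, so the result is independent
    of how many facets referenced it.
    """
    vertices = _as_points(vertices, "vertices")
    faces = np.asarray(faces, dtype=np.int64)
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_vertices = vertices[np.sort(first)]
    new_faces = rank[inverse][faces]
    # drop faces that collapsed onto fewer than 3 distinct vertices
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[ok]


@dataclass(frozen=True)
class BoneMesh:
    """Labelled triangulated surface of one bone (coordinates in mm)."""

    label: str
    vertices: np.ndarray
    faces: np.ndarray
    side: str = "NA"

    def __post_init__(self):
        if self.label not in BONE_CODES:
            raise MeshError(f"unknown bone label {self.label!r}")
        if self.side not in SIDES:
            raise MeshError(f"unknown side {self.side!r}")
        v = _as_points(self.vertices, "vertices")
        f = np.asarray(self.faces, dtype=np.int64)
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (n, 3), got {f.shape}")
        if v.shape[0] == 0:
            raise MeshError(f"{self.label}: empty mesh")
        if not np.isfinite(v).all():
            raise MeshError(f"{self.label}: non-finite vertex coordinates")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise MeshError(f"{self.label}: face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the welded surface vertices."""
        return self.vertices.mean(axis=0)

    @property
    def volume_centroid(self) -> np.ndarray:
        """Centre of mass of the enclosed volume (falls back to the vertex
        mean when the surface is not watertight)."""
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        if tm.is_watertight and tm.volume > 0:
            return np.asarray(tm.center_mass, dtype=float)
        return self.centroid

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "BoneMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return replace(self, vertices=v)

    def reflected(self, point: np.ndarray, normal: np.ndarray) -> "BoneMesh":
        """Mirror across the plane through ``point`` with unit ``normal``,
        flipping face winding so outward normals are preserved."""
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        d = (self.vertices - np.asarray(point, dtype=float)) @ n
        v = self.vertices - 2.0 * d[:, None] * n
        f = self.faces[:, ::-1].copy()
        return replace(self, vertices=v, faces=f)

    def require_noncoplanar(self) -> None:
        """Raise unless the mesh has >= 4 vertices spanning 3 dimensions."""
        if self.n_vertices < 4:
            raise MeshError(f"{self.label}: fewer than 4 vertices")
        c = self.vertices - self.vertices.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[2] < 1e-9 * max(s[0], 1.0):
            raise MeshError(f"{self.label}: vertices are coplanar")


@dataclass(frozen=True)
class GroundPlane:
    """The weight-bearing support plane: a point on it and the unit normal
    pointing toward the foot."""

    point: np.ndarray
    up: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        u = np.asarray(self.up, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if abs(n - 1.0) > 1e-9:
            u = u / n
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "up", u)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Height above the plane along ``up`` (negative below)."""
        return (np.atleast_2d(points) - self.point) @ self.up

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(pts)
        out = pts - d[:, None] * self.up
        return out[0] if np.asarray(points).ndim == 1 else out


@dataclass
class FootModel:
    """One foot: bone meshes, ground plane, side and an identifier."""

    foot_id: str
    side: str
    bones: dict[str, BoneMesh]
    ground: GroundPlane
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("LEFT", "RIGHT"):
            raise MeshError(f"foot side must be LEFT or RIGHT, got {self.side!r}")
        missing = [b for b in REQUIRED_BONES if b not in self.bones]
        if missing:
            raise MeshError(f"foot {self.foot_id}: missing required bones {missing}")

    def __getitem__(self, code: str) -> BoneMesh:
        return self.bones[code]

    def __contains__(self, code: str) -> bool:
        return code in self.bones

    @property
    def measure_bones(self) -> dict[str, BoneMesh]:
        return {k: v for k, v in self.bones.items() if k != "GROUND"}


# ---------------------------------------------------------------------------
# STL I/O

def read_stl(path, label: str, side: str = "NA") -> BoneMesh:
    """Read an ASCII or binary STL file into a welded :class:`BoneMesh`."""
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        raise MeshError(f"{path}: cannot parse STL ({exc})") from exc
    v = np.asarray(tm.vertices, dtype=float)
    f = np.asarray(tm.faces, dtype=np.int64)
    if v.size == 0 or f.size == 0:
        raise MeshError(f"{path}: empty STL")
    v, f = weld_vertices(v, f)
    log.debug("read %s: %d vertices, %d faces after welding", path, len(v), len(f))
    return BoneMesh(label=label, vertices=v, faces=f, side=side)


def write_stl(mesh: BoneMesh, path, mode: str = "binary") -> None:
    """Write a mesh as STL; ``mode`` is ``ascii`` or ``binary``.

    Round-trip through :func:`read_stl` preserves the welded vertex set to
    well under 1e-6 mm (binary STL stores float32; coordinates here are a
    few hundred mm at most, so float32 quantisation is ~1e-5 mm — welding
    keys survive it for the meshes this package produces and consumes).
    """
    if mode not in ("ascii", "binary"):
        raise ValueError(f"mode must be 'ascii' or 'binary', got {mode!r}")
    if mesh.n_faces == 0:
        raise MeshError("refusing to write a mesh with no faces")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    raw = data if isinstance(data, (bytes, bytearray)) else data.encode()
    with open(path, "wb") as fh:
        fh.write(raw)


# ---------------------------------------------------------------------------
# Ground plane and plantar landmarks

def fit_ground_plane(ground_mesh: BoneMesh, foot_hint: np.ndarray) -> GroundPlane:
    """Least-squares plane through the ground-mesh vertices, normal oriented
    toward ``foot_hint`` (e.g. the mean bone centroid)."""
    v = ground_mesh.vertices
    if v.shape[0] < 3:
        raise DegeneratePlaneError("ground mesh needs at least 3 vertices")
    c = v.mean(axis=0)
    u, s, vt = np.linalg.svd(v - c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegeneratePlaneError("ground vertices are collinear")
    normal = vt[2]
    hint = np.asarray(foot_hint, dtype=float)
    if (hint - c) @ normal < 0:
        normal = -normal
    if abs((hint - c) @ normal) < 1e-9:
        raise DegeneratePlaneError("foot hint lies on the ground plane")
    return GroundPlane(point=c, up=normal)


def most_plantar_point(mesh: BoneMesh, ground: GroundPlane) -> np.ndarray:
    """Vertex with minimal height above the ground; ties broken by the
    smallest vertex index so the landmark is deterministic."""
    h = ground.signed_distance(mesh.vertices)
    return mesh.vertices[int(np.argmin(h))].copy()


def plantar_height(mesh: BoneMesh, ground: GroundPlane) -> float:
    """Signed height of the most plantar vertex (negative = penetration)."""
    return float(ground.signed_distance(mesh.vertices).min())


# ---------------------------------------------------------------------------
# Side harmonisation

def anterior_hint(foot: FootModel) -> np.ndarray:
    """Bootstrap anteroposterior direction: calcaneus centroid toward the
    mean of the metatarsal (M1, M2) centroids, projected into the ground."""
    start = foot["CA"].centroid
    end = 0.5 * (foot["M1"].centroid + foot["M2"].centroid)
    d = end - start
    d = d - (d @ foot.ground.up) * foot.ground.up
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise MeshError("degenerate anteroposterior bootstrap direction")
    return d / n


def reflect_foot(foot: FootModel) -> FootModel:
    """Mirror the whole foot across the vertical plane containing the
    bootstrap anteroposterior direction.  Pure involution: applying it twice
    returns the original geometry.  The side label is swapped."""
    ap = anterior_hint(foot)
    normal = np.cross(ap, foot.ground.up)
    normal /= np.linalg.norm(normal)
    anchor = foot["CA"].centroid
    bones = {k: m.reflected(anchor, normal) for k, m in foot.bones.items()}
    gp_point = foot.ground.point - 2.0 * ((foot.ground.point - anchor) @ normal) * normal
    ground = GroundPlane(point=gp_point, up=foot.ground.up)
    side = "RIGHT" if foot.side == "LEFT" else "LEFT"
    return FootModel(foot_id=foot.foot_id, side=side, bones=bones,
                     ground=ground, meta=dict(foot.meta))


def mirror_foot(foot: FootModel) -> FootModel:
    """Harmonise a LEFT foot to right-side convention (mirror across the
    sagittal-ish plane spanned by the bootstrap AP direction and the ground
    normal).  A RIGHT foot is returned unchanged with a warning."""
    if foot.side == "RIGHT":
        warnings.warn(f"foot {foot.foot_id} is already RIGHT; mirror is a no-op")
        return foot
    return reflect_foot(foot)


# ---------------------------------------------------------------------------
# foot directories: <footid>_<BONE>.stl plus <footid>_GROUND.stl

def save_foot_dir(foot: FootModel, directory, mode: str = "binary") -> list[str]:
    """Write every bone (and the ground mesh, if present) of a foot as
    ``<footid>_<BONE>.stl`` files into ``directory``; returns the names."""
    import os

    os.makedirs(directory, exist_ok=True)
    written = []
    for code, mesh in foot.bones.items():
        name = f"{foot.foot_id}_{code}.stl"
        write_stl(mesh, os.path.join(directory, name), mode=mode)
        written.append(name)
    return written


def load_foot_dir(directory, foot_id: str, side: str = "RIGHT") -> FootModel:
    """Load ``<footid>_<BONE>.stl`` files back into a :class:`FootModel`.

    The ground plane is fitted to the ``GROUND`` mesh with its normal
    oriented toward the mean bone centroid.
    """
    import os

    bones: dict[str, BoneMesh] = {}
    for code in BONE_CODES:
        path = os.path.join(directory, f"{foot_id}_{code}.stl")
        if os.path.exists(path):
            bones[code] = read_stl(path, code, side=side if code != "GROUND" else "NA")
    if "GROUND" not in bones:
        raise MeshError(f"{directory}: no {foot_id}_GROUND.stl ground mesh")
    body = [m for c, m in bones.items() if c != "GROUND"]
    if not body:
        raise MeshError(f"{directory}: no bone meshes for foot {foot_id}")
    hint = np.mean([m.centroid for m in body], axis=0)
    ground = fit_ground_plane(bones["GROUND"], hint)
    return FootModel(foot_id=foot_id, side=side, bones=bones, ground=ground)
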