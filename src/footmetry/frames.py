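"""Anatomical reference frames.

Two constructions live here:

* the foot anatomical frame (FootAF): vertical axis normal to the ground,
  anteroposterior axis along the ground-plane segment joining the
  projections of the most plantar points of the calcaneus and of the second
  metatarsal head;
* per-bone frames from principal component analysis of the welded surface
  vertices — the three orthogonal directions of maximal point variance,
  read as longitudinal / mediolateral / dorsoplantar anatomical axes, with
  deterministic eigenvalue ordering and sign fixing against the FootAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import (
    BoneMesh,
    FootModel,
    GroundPlane,
    MeshError,
    anterior_hint,
)

#: Warn (do not fail) below this first/second eigenvalue ratio: the axis
#: labelling is ambiguous for nearly isotropic bones.
ELONGATION_WARN = 1.2

#: Anterior fraction of a metatarsal's extent treated as its "head" region.
HEAD_FRACTION = 0.25


class DegenerateFrameError(ValueError):
    """FootAF landmarks too close together to define an axis."""


#: Height band (mm) of the plantar "contact patch" whose centroid is used
#: as a landmark.  Averaging over the near-lowest vertices instead of
#: taking the single lowest one makes frame and tripod landmarks robust to
#: sub-millimetre surface noise, which otherwise rotates the whole
#: anteroposterior axis by a fraction of a degree and is amplified in the
#: ill-conditioned frontal/azimuthal codes.
PATCH_TOL = 0.5


def plantar_patch_point(vertices: np.ndarray, ground: GroundPlane,
                        tol: float = PATCH_TOL) -> np.ndarray:
    """Centroid of the vertices within ``tol`` mm of the minimal height."""
    h = ground.signed_distance(vertices)
    sel = h <= h.min() + tol
    return vertices[sel].mean(axis=0)


@dataclass(frozen=True)
class FootFrame:
    """The FootAF: origin on the ground under the heel, orthonormal
    right-handed axes (ap anterior, up vertical, ml lateral on a
    right-convention foot) and the foot length in mm."""

    origin: np.ndarray
    ap: np.ndarray
    up: np.ndarray
    ml: np.ndarray
    foot_length: float

    def __post_init__(self):
        for name in ("origin", "ap", "up", "ml"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.foot_length <= 0:
            raise DegenerateFrameError("foot length must be positive")

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "ap": self.ap.tolist(),
            "up": self.up.tolist(),
            "ml": self.ml.tolist(),
            "foot_length_mm": self.foot_length,
        }


@dataclass(frozen=True)
class BoneFrame:
    """PCA-derived anatomical axes of one bone.

    ``longitudinal`` is the first principal axis (sign-fixed anteriorly),
    ``dorsoplantar`` the remaining axis most aligned with the foot vertical
    (sign-fixed upward), ``mediolateral`` completes the right-handed triad.
    ``eigenvalues`` are the three point variances in mm², descending.
    """

    label: str
    centroid: np.ndarray
    longitudinal: np.ndarray
    mediolateral: np.ndarray
    dorsoplantar: np.ndarray
    eigenvalues: np.ndarray
    elongation: float
    warnings: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "centroid": self.centroid.tolist(),
            "longitudinal": self.longitudinal.tolist(),
            "mediolateral": self.mediolateral.tolist(),
            "dorsoplantar": self.dorsoplantar.tolist(),
            "eigenvalues_mm2": self.eigenvalues.tolist(),
            "elongation": self.elongation,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# landmark helpers

def raw_principal_axis(mesh: BoneMesh) -> np.ndarray:
    """First principal axis of the welded vertices, unoriented."""
    c = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = c.T @ c / c.shape[0]
    w, v = np.linalg.eigh(cov)
    return v[:, 2]


def head_region_plantar_point(
    mesh: BoneMesh,
    ground: GroundPlane,
    anterior: np.ndarray,
    fraction: float = HEAD_FRACTION,
) -> np.ndarray:
    """Plantar contact-patch point of the anterior ``fraction`` of the
    bone's extent along its own (raw) first principal axis, oriented by
    ``anterior``.

    This is the rule used for the metatarsal "head" landmarks (and, with a
    larger fraction, for the talar arch apex): the anatomical head is the
    anterior end of a long bone, and its lowest surface region is the
    weight-bearing landmark of interest.
    """
    axis = raw_principal_axis(mesh)
    if axis @ np.asarray(anterior, dtype=float) < 0:
        axis = -axis
    t = mesh.vertices @ axis
    lo, hi = t.min(), t.max()
    cut = hi - fraction * (hi - lo)
    sel = np.flatnonzero(t >= cut)
    if sel.size == 0:  # cannot happen for finite meshes, guard anyway
        sel = np.array([int(np.argmax(t))])
    return plantar_patch_point(mesh.vertices[sel], ground)


def m2_head_point(foot: FootModel) -> np.ndarray:
    """Second-metatarsal head landmark used by the FootAF definition."""
    return head_region_plantar_point(foot["M2"], foot.ground, anterior_hint(foot))


# ---------------------------------------------------------------------------
# frame construction

def build_foot_frame(foot: FootModel) -> FootFrame:
    """Construct the FootAF from the calcaneus and M2-head plantar points.

    origin = ground projection of the calcaneal plantar contact patch;
    ap     = unit vector from the origin to the ground projection of the
             M2 head point (lies in the ground plane by construction);
    up     = ground normal;  ml = ap x up (lateral on a right foot).
    """
    ground = foot.ground
    heel = ground.project(plantar_patch_point(foot["CA"].vertices, ground))
    head = ground.project(m2_head_point(foot))
    d = head - heel
    length = float(np.linalg.norm(d))
    if length < 10.0:
        raise DegenerateFrameError(
            f"M2 head and calcaneus plantar points only {length:.1f} mm apart")
    ap = d / length
    up = ground.up
    ml = np.cross(ap, up)
    ml /= np.linalg.norm(ml)
    return FootFrame(origin=heel, ap=ap, up=up, ml=ml, foot_length=length)


def _vertex_weights(mesh: BoneMesh) -> np.ndarray:
    """Per-vertex weights: one third of the summed incident-face areas."""
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    w = np.zeros(v.shape[0])
    for k in range(3):
        np.add.at(w, f[:, k], area / 3.0)
    return w


def pca_bone_frame(
    mesh: BoneMesh,
    foot: FootFrame,
    area_weighted: bool = False,
) -> BoneFrame:
    """Anatomical axes of one bone from PCA of its surface points.

    The default uses the unweighted welded vertices.  ``area_weighted``
    weights each vertex by its incident surface area, which reduces the
    sensitivity of the axes to mesh density (useful when comparing a dense
    segmentation against a heavily decimated one); the unweighted variant
    is the reference behaviour.
    """
    mesh.require_noncoplanar()
    v = mesh.vertices
    if area_weighted:
        w = _vertex_weights(mesh)
        w = w / w.sum()
        mu = w @ v
        c = v - mu
        cov = (c * w[:, None]).T @ c
    else:
        mu = v.mean(axis=0)
        c = v - mu
        cov = c.T @ c / c.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    warn: list[str] = []
    elongation = float(evals[0] / max(evals[1], 1e-300))
    if elongation < ELONGATION_WARN:
        warn.append(
            f"{mesh.label}: ambiguous longitudinal axis "
            f"(eigenvalue ratio {elongation:.3f} < {ELONGATION_WARN})")

    longitudinal = evecs[:, 0]
    if longitudinal @ foot.ap < 0:
        longitudinal = -longitudinal

    # dorsoplantar = remaining axis most aligned with the vertical, upward
    cands = [evecs[:, 1], evecs[:, 2]]
    dots = [abs(c_ @ foot.up) for c_ in cands]
    dp = cands[int(np.argmax(dots))]
    if dp @ foot.up < 0:
        dp = -dp
    ml = np.cross(dp, longitudinal)
    ml /= np.linalg.norm(ml)

    return BoneFrame(
        label=mesh.label,
        centroid=mu,
        longitudinal=longitudinal,
        mediolateral=ml,
        dorsoplantar=dp,
        eigenvalues=evals,
        elongation=elongation,
        warnings=tuple(warn),
    )


def build_bone_frames(
    foot: FootModel,
    frame: FootFrame,
    codes=("TI", "CA", "TA", "NA", "CU", "CM", "M1", "M2"),
    area_weighted: bool = False,
) -> dict[str, BoneFrame]:
    out = {}
    for code in codes:
        if code not in foot:
            raise MeshError(f"foot {foot.foot_id}: missing bone {code}")
        out[code] = pca_bone_frame(foot[code], frame, area_weighted=area_weighted)
    return out
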