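"""The 32 foot-skeleton measurements.

Nomenclature: ``I`` = absolute inclination of one bone, ``R`` = relative
orientation of two bones, suffix plane ``L`` (lateral/sagittal), ``F``
(frontal), ``T`` (transverse) for planar projections, ``3`` for the single
3D angle; ``Hg`` = minimum height of a bone above the ground; ``FAO`` =
foot–ankle offset of the talus centre from the weight-bearing tripod axis.

Sign conventions (all angles in degrees):

* lateral plane (spanned by ap, up): plantar declination of the anterior
  end is positive, so a plantarflexed talus has a positive ``IL_TA`` and a
  normally pitched calcaneus a negative ``IL_CA``;
* transverse plane (ap, ml): internal (medial) rotation of the anterior
  end is positive;
* tibia: its long axis is near-vertical, so ``IL_TI`` is the anterior lean
  of the projected axis away from the vertical (dorsiflexion positive) and
  its transverse angle is the azimuth of that lean;
* relative planar angles are signed differences of the corresponding
  absolute inclinations, wrapped to (-180, 180].  Radiographic angle
  conventions are a historical patchwork and the package follows the one
  that makes the standard identities hold exactly: sagittal hindfoot pairs
  are first-named minus second-named (``RL_TACA = IL_TA - IL_CA``), the
  sagittal metatarsal angles follow the distal-minus-proximal radiographic
  convention (``RL_TAM1 = IL_M1 - IL_TA``, the Meary angle, negative in
  flatfoot; Hibb is its obtuse calcaneal analogue), and transverse pairs
  are second-named minus first-named (``RT_TACA = IT_CA - IT_TA``);
* frontal plane (ml, up): the absolute angle of a projected axis is taken
  from the vertical, medial lean positive; relative frontal angles are
  again first minus second.  Frontal projections of near-horizontal bone
  axes are intrinsically ill-conditioned and this convention is a
  documented package choice;
* 3D angles ``R3`` are the arccos of the dot product of the two
  anterior-oriented longitudinal axes, in [0, 180];
* the arch angles are reported in their obtuse radiographic form:
  ``RL_CAM1`` (Hibb) = 180 - (IL_M1 - IL_CA), and ``RL_TACAM1``
  (Moreau–Costa–Bertani) is the angle at the talar plantar apex between
  rays to the calcaneal and first-metatarsal plantar landmarks; both tend
  to 180 deg as the arch flattens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames import (
    BoneFrame,
    FootFrame,
    build_bone_frames,
    build_foot_frame,
    head_region_plantar_point,
    plantar_patch_point,
)
from .mesh_core import (
    BoneMesh,
    FootModel,
    GroundPlane,
    MeshError,
    anterior_hint,
    mirror_foot,
    most_plantar_point,
    plantar_height,
)

#: Anterior fraction of the talus used for the arch apex landmark.
TALUS_APEX_FRACTION = 0.30

PROJECTION_EPS = 1e-6


class ProjectionDegenerateError(ValueError):
    """A longitudinal axis is orthogonal to the requested projection plane."""


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    family: str  # I | R | 3 | H | FAO
    plane: str   # L | F | T | 3D | none
    bones: tuple[str, ...]
    units: str   # deg | mm | %


CATALOG: tuple[CatalogEntry, ...] = (
    # absolute planar inclinations
    CatalogEntry("IL_TI", "I", "L", ("TI",), "deg"),
    CatalogEntry("IL_TA", "I", "L", ("TA",), "deg"),
    CatalogEntry("IL_CA", "I", "L", ("CA",), "deg"),
    CatalogEntry("IT_TA", "I", "T", ("TA",), "deg"),
    CatalogEntry("IT_CA", "I", "T", ("CA",), "deg"),
    # relative planar angles
    CatalogEntry("RF_TICA", "R", "F", ("TI", "CA"), "deg"),
    CatalogEntry("RL_TICA", "R", "L", ("TI", "CA"), "deg"),
    CatalogEntry("RT_TICA", "R", "T", ("TI", "CA"), "deg"),
    CatalogEntry("RF_TACA", "R", "F", ("TA", "CA"), "deg"),
    CatalogEntry("RL_TACA", "R", "L", ("TA", "CA"), "deg"),
    CatalogEntry("RT_TACA", "R", "T", ("TA", "CA"), "deg"),
    CatalogEntry("RF_TANA", "R", "F", ("TA", "NA"), "deg"),
    CatalogEntry("RL_TANA", "R", "L", ("TA", "NA"), "deg"),
    CatalogEntry("RT_TANA", "R", "T", ("TA", "NA"), "deg"),
    CatalogEntry("RL_CAM1", "R", "L", ("CA", "M1"), "deg"),
    CatalogEntry("RL_TACAM1", "R", "L", ("TA", "CA", "M1"), "deg"),
    CatalogEntry("RL_TAM1", "R", "L", ("TA", "M1"), "deg"),
    CatalogEntry("RT_TAM1", "R", "T", ("TA", "M1"), "deg"),
    CatalogEntry("RT_M1M2", "R", "T", ("M1", "M2"), "deg"),
    # 3D measures
    CatalogEntry("I3_CA", "3", "3D", ("CA",), "deg"),
    CatalogEntry("I3_TA", "3", "3D", ("TA",), "deg"),
    CatalogEntry("R3_TICA", "3", "3D", ("TI", "CA"), "deg"),
    CatalogEntry("R3_TACA", "3", "3D", ("TA", "CA"), "deg"),
    CatalogEntry("R3_CAM1", "3", "3D", ("CA", "M1"), "deg"),
    CatalogEntry("R3_TAM1", "3", "3D", ("TA", "M1"), "deg"),
    CatalogEntry("R3_TANA", "3", "3D", ("TA", "NA"), "deg"),
    CatalogEntry("R3_TACAM1", "3", "3D", ("TA", "CA", "M1"), "deg"),
    # heights
    CatalogEntry("Hg_NA", "H", "none", ("NA",), "mm"),
    CatalogEntry("Hg_CU", "H", "none", ("CU",), "mm"),
    CatalogEntry("Hg_CM", "H", "none", ("CM",), "mm"),
    # foot-ankle offset
    CatalogEntry("FAO_%", "FAO", "none", ("TA", "CA", "M1", "M5"), "%"),
    CatalogEntry("FAO_mm", "FAO", "none", ("TA", "CA", "M1", "M5"), "mm"),
)

CODES: tuple[str, ...] = tuple(e.code for e in CATALOG)
assert len(CODES) == 32

#: Codes computed purely from longitudinal bone axes (no landmarks).
AXIS_CODES: tuple[str, ...] = tuple(
    e.code for e in CATALOG
    if e.family in ("I", "R", "3") and e.code not in ("RL_TACAM1", "R3_TACAM1")
)


@dataclass
class ArchLandmarks:
    """The three plantar landmarks of the medial longitudinal arch."""

    ca_plantar: np.ndarray
    talus_apex: np.ndarray
    m1_plantar: np.ndarray

    def __post_init__(self):
        pts = [np.asarray(p, dtype=float).reshape(3)
               for p in (self.ca_plantar, self.talus_apex, self.m1_plantar)]
        self.ca_plantar, self.talus_apex, self.m1_plantar = pts
        for a, b in ((pts[0], pts[1]), (pts[1], pts[2]), (pts[0], pts[2])):
            if np.linalg.norm(a - b) <= 1.0:
                raise ValueError("arch landmarks closer than 1 mm")


@dataclass
class MeasurementSet:
    """The 32 named values for one foot and one method."""

    foot_id: str
    method: str
    values: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def finite(self) -> bool:
        return all(np.isfinite(v) for v in self.values.values())


# ---------------------------------------------------------------------------
# pure angle helpers on unit axes expressed in a FootFrame

def wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    x = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if x == -180.0 else x


def _comps(u: np.ndarray, foot: FootFrame) -> tuple[float, float, float]:
    u = np.asarray(u, dtype=float)
    return float(u @ foot.ap), float(u @ foot.ml), float(u @ foot.up)


def _check_projection(x: float, y: float) -> None:
    if math.hypot(x, y) < PROJECTION_EPS:
        raise ProjectionDegenerateError(
            "longitudinal axis is orthogonal to the projection plane")


def lateral_inclination(u: np.ndarray, foot: FootFrame) -> float:
    """Sagittal inclination over the ground line, plantar-declination
    positive, for an anterior-oriented axis."""
    a, _, z = _comps(u, foot)
    _check_projection(a, z)
    return math.degrees(math.atan2(-z, a))


def tibial_lateral_inclination(u: np.ndarray, foot: FootFrame) -> float:
    """Sagittal lean of a near-vertical (up-oriented) axis away from the
    vertical, anterior lean positive."""
    a, _, z = _comps(u, foot)
    _check_projection(a, z)
    return math.degrees(math.atan2(a, z))


def transverse_inclination(u: np.ndarray, foot: FootFrame) -> float:
    """Transverse-plane angle from the AP axis, medial (internal) rotation
    positive, for an anterior-oriented axis."""
    a, m, _ = _comps(u, foot)
    _check_projection(a, m)
    return math.degrees(math.atan2(-m, a))


def tibial_transverse_inclination(u: np.ndarray, foot: FootFrame) -> float:
    """Azimuth of the tibial lean in the transverse plane, medial positive."""
    a, m, _ = _comps(u, foot)
    _check_projection(a, m)
    return math.degrees(math.atan2(-m, a))


def frontal_angle(u: np.ndarray, foot: FootFrame) -> float:
    """Frontal-plane angle of the projected axis from the vertical, medial
    lean positive.  Package convention (see module docstring)."""
    _, m, z = _comps(u, foot)
    _check_projection(m, z)
    return math.degrees(math.atan2(-m, z))


def spatial_inclination_axis(u: np.ndarray, foot: FootFrame) -> float:
    """3D inclination over the ground: elevation of the anterior-oriented
    axis, positive when the anterior end is more plantar."""
    _, _, z = _comps(u, foot)
    z = min(1.0, max(-1.0, z))
    return math.degrees(-math.asin(z))


def spatial_angle(u: np.ndarray, v: np.ndarray) -> float:
    """3D angle between two unit axes, in [0, 180]."""
    d = float(np.dot(u, v))
    return math.degrees(math.acos(min(1.0, max(-1.0, d))))


def _planar_value(code_plane: str, u, foot, tibial: bool = False) -> float:
    if code_plane == "L":
        return tibial_lateral_inclination(u, foot) if tibial \
            else lateral_inclination(u, foot)
    if code_plane == "T":
        return tibial_transverse_inclination(u, foot) if tibial \
            else transverse_inclination(u, foot)
    if code_plane == "F":
        return frontal_angle(u, foot)
    raise ValueError(f"unknown plane {code_plane!r}")


def axis_code_values(axes: dict[str, np.ndarray], foot: FootFrame) -> dict[str, float]:
    """Evaluate every axis-based catalog code from longitudinal unit axes.

    ``axes`` maps bone codes to unit vectors in world coordinates: the
    tibial axis oriented upward (proximal), all others anteriorly.  Shared
    by the mesh pipeline and by the synthetic generator's closed-form
    ground truth, so both speak exactly the same conventions.
    """
    def incl(bone, plane):
        return _planar_value(plane, axes[bone], foot, tibial=(bone == "TI"))

    def rel(a, b, plane):
        # L and F: first-named minus second-named; T: second minus first
        if plane == "T":
            a, b = b, a
        return wrap_angle(incl(a, plane) - incl(b, plane))

    out: dict[str, float] = {
        "IL_TI": incl("TI", "L"),
        "IL_TA": incl("TA", "L"),
        "IL_CA": incl("CA", "L"),
        "IT_TA": incl("TA", "T"),
        "IT_CA": incl("CA", "T"),
        "RF_TICA": rel("TI", "CA", "F"),
        "RL_TICA": rel("TI", "CA", "L"),
        "RT_TICA": rel("TI", "CA", "T"),
        "RF_TACA": rel("TA", "CA", "F"),
        "RL_TACA": rel("TA", "CA", "L"),
        "RT_TACA": rel("TA", "CA", "T"),
        "RF_TANA": rel("TA", "NA", "F"),
        "RL_TANA": rel("TA", "NA", "L"),
        "RT_TANA": rel("TA", "NA", "T"),
        "RL_CAM1": 180.0 - wrap_angle(incl("M1", "L") - incl("CA", "L")),
        "RL_TAM1": wrap_angle(incl("M1", "L") - incl("TA", "L")),
        "RT_TAM1": rel("TA", "M1", "T"),
        "RT_M1M2": rel("M1", "M2", "T"),
        "I3_CA": spatial_inclination_axis(axes["CA"], foot),
        "I3_TA": spatial_inclination_axis(axes["TA"], foot),
        "R3_TICA": spatial_angle(axes["TI"], axes["CA"]),
        "R3_TACA": spatial_angle(axes["TA"], axes["CA"]),
        "R3_CAM1": 180.0 - spatial_angle(axes["CA"], axes["M1"]),
        "R3_TAM1": spatial_angle(axes["TA"], axes["M1"]),
        "R3_TANA": spatial_angle(axes["TA"], axes["NA"]),
    }
    return out


# ---------------------------------------------------------------------------
# spec-level operations on frames

def oriented_axis(frame: BoneFrame, foot: FootFrame) -> np.ndarray:
    """Longitudinal axis re-oriented for measurement: upward for the tibia,
    anteriorly for every other bone."""
    u = frame.longitudinal
    if frame.label == "TI":
        return u if u @ foot.up >= 0 else -u
    return u if u @ foot.ap >= 0 else -u


def planar_inclination(frame: BoneFrame, plane: str, foot: FootFrame) -> float:
    """Absolute inclination of one bone in the lateral (L) or transverse (T)
    plane projection."""
    if plane not in ("L", "T"):
        raise ValueError("planar inclination is defined for planes L and T")
    u = oriented_axis(frame, foot)
    return _planar_value(plane, u, foot, tibial=(frame.label == "TI"))


def spatial_inclination(frame: BoneFrame, foot: FootFrame) -> float:
    """3D inclination of the bone's longitudinal axis over the ground."""
    return spatial_inclination_axis(oriented_axis(frame, foot), foot)


def planar_relative_angle(frame_a: BoneFrame, frame_b: BoneFrame,
                          plane: str, foot: FootFrame) -> float:
    """Relative orientation of two bones in one anatomical plane projection
    (lateral/frontal: first minus second inclination; transverse: second
    minus first — the catalog's sign conventions, wrapped)."""
    va = _planar_value(plane, oriented_axis(frame_a, foot), foot,
                       tibial=(frame_a.label == "TI"))
    vb = _planar_value(plane, oriented_axis(frame_b, foot), foot,
                       tibial=(frame_b.label == "TI"))
    return wrap_angle(vb - va) if plane == "T" else wrap_angle(va - vb)


def spatial_relative_angle(frame_a: BoneFrame, frame_b: BoneFrame,
                           foot: FootFrame | None = None) -> float:
    """3D angle between two longitudinal axes, in [0, 180].

    When a FootFrame is given the axes are first re-oriented by the usual
    sign rules; without one the stored sign-fixed axes are used directly.
    """
    if foot is not None:
        ua, ub = oriented_axis(frame_a, foot), oriented_axis(frame_b, foot)
    else:
        ua, ub = frame_a.longitudinal, frame_b.longitudinal
    return spatial_angle(ua, ub)


def hibb_angle(ca: BoneFrame, m1: BoneFrame, mode: str, foot: FootFrame) -> float:
    """Calcaneus–first-metatarsal axis angle in its obtuse form (the Hibb
    angle): 180 deg minus the M1-vs-CA angle, lateral projection or 3D."""
    if mode == "L":
        raw = wrap_angle(lateral_inclination(oriented_axis(m1, foot), foot)
                         - lateral_inclination(oriented_axis(ca, foot), foot))
        val = 180.0 - raw
    elif mode == "3D":
        val = 180.0 - spatial_angle(oriented_axis(ca, foot), oriented_axis(m1, foot))
    else:
        raise ValueError("mode must be 'L' or '3D'")
    if val <= 0.0:
        val += 360.0
    return val


def mcb_angle(landmarks: ArchLandmarks, mode: str,
              foot: FootFrame | None = None) -> float:
    """Moreau–Costa–Bertani medial-arch angle at the talar plantar apex,
    between rays to the calcaneal and first-metatarsal plantar landmarks.

    ``mode='L'`` projects the three landmarks onto the sagittal plane of
    ``foot`` first; ``mode='3D'`` uses the raw 3D points.
    """
    a = landmarks.ca_plantar
    apex = landmarks.talus_apex
    b = landmarks.m1_plantar
    if mode == "L":
        if foot is None:
            raise ValueError("mode 'L' needs a FootFrame")
        def proj(p):
            q = p - foot.origin
            return np.array([q @ foot.ap, q @ foot.up])
        a, apex, b = proj(a), proj(apex), proj(b)
    elif mode != "3D":
        raise ValueError("mode must be 'L' or '3D'")
    r1 = a - apex
    r2 = b - apex
    n1, n2 = np.linalg.norm(r1), np.linalg.norm(r2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("arch apex coincides with a ray endpoint")
    c = float(np.dot(r1, r2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def height_above_ground(mesh: BoneMesh, ground: GroundPlane,
                        warn_sink: list[str] | None = None) -> float:
    """Minimum distance of the bone from the ground = signed height of its
    most plantar vertex.  Negative heights (ground penetration) are
    reported as-is with a warning."""
    h = plantar_height(mesh, ground)
    if h < 0 and warn_sink is not None:
        warn_sink.append(f"{mesh.label}: penetrates the ground by {-h:.3f} mm")
    return h


def fao_from_points(ca_pt, m1_pt, m5_pt, ankle_pt, foot: FootFrame) -> tuple[float, float]:
    """Foot–ankle offset from the four defining points (3D, mm).

    The weight-bearing tripod axis runs from the calcaneal plantar point to
    the midpoint of the M1 and M5 head points (all projected on the
    ground); the offset is the perpendicular distance of the
    ground-projected ankle point (talus volume centre) from that axis,
    signed positive toward medial so that hindfoot valgus is positive.
    Returns ``(FAO_%, FAO_mm)`` with the percentage normalised by foot
    length.
    """
    up = foot.up
    def flat(p):
        p = np.asarray(p, dtype=float)
        return p - ((p - foot.origin) @ up) * up
    heel = flat(ca_pt)
    fore = 0.5 * (flat(m1_pt) + flat(m5_pt))
    ankle = flat(ankle_pt)
    d = fore - heel
    nd = np.linalg.norm(d)
    if nd < 1e-6:
        raise ValueError("collinear/degenerate tripod")
    cross = np.cross(d / nd, ankle - heel)
    fao_mm = float(cross @ up)  # +up x-product => medial side positive
    fao_pct = 100.0 * fao_mm / foot.foot_length
    return fao_pct, fao_mm


def compute_fao(ta: BoneMesh, ca: BoneMesh, m1: BoneMesh, m5: BoneMesh,
                ground: GroundPlane, foot: FootFrame,
                anterior: np.ndarray | None = None) -> tuple[float, float]:
    """Foot–ankle offset from bone meshes (tripod = plantar points of the
    calcaneus and of the M1/M5 head regions; ankle = talus volume centre)."""
    ant = foot.ap if anterior is None else anterior
    ca_pt = plantar_patch_point(ca.vertices, ground)
    m1_pt = head_region_plantar_point(m1, ground, ant)
    m5_pt = head_region_plantar_point(m5, ground, ant)
    ankle = ta.volume_centroid
    return fao_from_points(ca_pt, m1_pt, m5_pt, ankle, foot)


def arch_landmarks(foot: FootModel, anterior: np.ndarray | None = None) -> ArchLandmarks:
    """Extract the medial-arch landmarks from the bone meshes."""
    ant = anterior if anterior is not None else anterior_hint(foot)
    return ArchLandmarks(
        ca_plantar=plantar_patch_point(foot["CA"].vertices, foot.ground),
        talus_apex=head_region_plantar_point(
            foot["TA"], foot.ground, ant, fraction=TALUS_APEX_FRACTION),
        m1_plantar=head_region_plantar_point(foot["M1"], foot.ground, ant),
    )


# ---------------------------------------------------------------------------
# full pipeline

def compute_all(foot: FootModel, method: str = "",
                area_weighted: bool = False) -> MeasurementSet:
    """Run the complete measurement pipeline on one foot.

    Left feet are first mirrored to right-side convention so that signed
    angles pool consistently across a cohort.  Returns exactly the 32
    catalog codes; the FAO pair is NaN (with a warning) when M5 is absent.
    """
    if foot.side == "LEFT":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            foot = mirror_foot(foot)

    warn: list[str] = []
    frame = build_foot_frame(foot)
    bone_frames = build_bone_frames(foot, frame, area_weighted=area_weighted)
    for bf in bone_frames.values():
        warn.extend(bf.warnings)

    axes = {code: oriented_axis(bf, frame) for code, bf in bone_frames.items()}
    values = axis_code_values(axes, frame)

    lm = arch_landmarks(foot, anterior=frame.ap)
    values["RL_TACAM1"] = mcb_angle(lm, "L", frame)
    values["R3_TACAM1"] = mcb_angle(lm, "3D")

    for code, bone in (("Hg_NA", "NA"), ("Hg_CU", "CU"), ("Hg_CM", "CM")):
        values[code] = height_above_ground(foot[bone], foot.ground, warn)

    if "M5" in foot:
        pct, mm = compute_fao(foot["TA"], foot["CA"], foot["M1"], foot["M5"],
                              foot.ground, frame)
        values["FAO_%"], values["FAO_mm"] = pct, mm
    else:
        values["FAO_%"] = values["FAO_mm"] = float("nan")
        warn.append("M5 missing: FAO not computed")

    ordered = {code: float(values[code]) for code in CODES}
    return MeasurementSet(foot_id=foot.foot_id, method=method,
                          values=ordered, warnings=warn)
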