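"""Parametric synthetic weight-bearing foot skeletons with exact ground truth.

Each bone is a triangulated superellipsoid (a p-norm ellipsoid: for
semi-axes ``a`` and exponent ``p`` the surface is ``sum |x_i/a_i|^p = 1``).
These bodies have two properties that make them ideal validation objects:
their principal component axes coincide with the design axes in closed
form, and the extremal surface point in any direction (optionally
restricted to the anterior "head" region) has an analytic expression via
p-norm duality.  The generator therefore knows, without ever looking at a
mesh, the exact value every catalog measurement should take — the
``GroundTruth`` — while the mesh pipeline must recover those values from
triangle soup.

The pose parameters mirror the clinically meaningful deformity controls of
adult flatfoot: calcaneal pitch, talar plantar declination and internal
rotation, first-metatarsal declination, arch heights of the midfoot bones,
hindfoot valgus (which medialises the talus over the weight-bearing
tripod) and the transverse intermetatarsal angle.  Two mesh perturbation
modes emulate the two segmentation families seen in practice: a dense,
noisy semi-automatic reconstruction ("MIS-like") and a smoothed, roughly
8x decimated automatic one ("DIS-like").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import trimesh
from scipy.optimize import least_squares, brentq

from .frames import FootFrame
from .mesh_core import BoneMesh, FootModel, GroundPlane
from .measurements import (
    ArchLandmarks,
    AXIS_CODES,
    CODES,
    TALUS_APEX_FRACTION,
    axis_code_values,
    fao_from_points,
    mcb_angle,
)
from .reference import reference_means

DEG = math.pi / 180.0

#: Physiologic bounds on the deformity controls (degrees / mm).
CONTROL_BOUNDS = {
    "calcaneal_pitch": (-5.0, 40.0),
    "talar_declination": (0.0, 45.0),
    "talar_internal_rotation": (-10.0, 50.0),
    "m1_declination": (-5.0, 35.0),
    "hindfoot_valgus": (-10.0, 35.0),
    "intermetatarsal_angle": (-25.0, 10.0),
    "arch_height": (5.0, 60.0),
}


class GenerationError(ValueError):
    """Invalid synthetic parameters or non-physical generated pose."""


# ---------------------------------------------------------------------------
# superellipsoid geometry

def superellipsoid_support(direction, semi_axes, exponent: float) -> np.ndarray:
    """Surface point maximising ``direction . x`` (local frame).

    Closed form via p-norm duality: substituting y = x/a, the problem is a
    linear functional over the unit p-ball, whose maximiser is the
    normalised (q-1)-power of the coefficients with q the Hoelder conjugate.
    """
    d = np.asarray(direction, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    p = float(exponent)
    q = p / (p - 1.0)
    b = d * a
    nb = np.abs(b)
    denom = (nb ** q).sum() ** (1.0 / q)
    if denom < 1e-300:
        raise ValueError("zero direction")
    y = np.sign(b) * (nb / denom) ** (q - 1.0)
    return a * y


def superellipsoid_region_support(direction, semi_axes, exponent: float,
                                  fraction: float) -> np.ndarray:
    """Like :func:`superellipsoid_support`, restricted to the anterior
    ``fraction`` of the body's extent along its local first (long) axis:
    ``x_0 >= a_0 * (1 - 2*fraction)``."""
    a = np.asarray(semi_axes, dtype=float)
    p = float(exponent)
    x_cut = a[0] * (1.0 - 2.0 * fraction)
    x = superellipsoid_support(direction, a, p)
    if x[0] >= x_cut:
        return x
    # optimum sits on the slice x0 = x_cut, a scaled 2D p-ball
    m = (1.0 - abs(x_cut / a[0]) ** p) ** (1.0 / p)
    d = np.asarray(direction, dtype=float)
    sub = superellipsoid_support(d[1:], a[1:] * m, p)
    return np.array([x_cut, sub[0], sub[1]])


def _uv_sphere(sectors: int, stacks: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit sphere with poles on the +-x axis, reflection-symmetric in all
    three coordinate planes (so the covariance of the mapped superellipsoid
    vertices is exactly diagonal in the local frame)."""
    theta = np.linspace(0.0, math.pi, stacks + 1)
    phi = np.arange(sectors) * (2.0 * math.pi / sectors)
    verts = [np.array([1.0, 0.0, 0.0])]
    for i in range(1, stacks):
        st, ct = math.sin(theta[i]), math.cos(theta[i])
        ring = np.column_stack([np.full(sectors, ct),
                                st * np.cos(phi), st * np.sin(phi)])
        verts.append(ring)
    verts.append(np.array([-1.0, 0.0, 0.0]))
    v = np.vstack([np.atleast_2d(x) for x in verts])

    faces = []
    def ring_index(i, j):  # ring i in 1..stacks-1
        return 1 + (i - 1) * sectors + (j % sectors)
    for j in range(sectors):  # top cap
        faces.append([0, ring_index(1, j), ring_index(1, j + 1)])
    for i in range(1, stacks - 1):
        for j in range(sectors):
            a00 = ring_index(i, j)
            a01 = ring_index(i, j + 1)
            a10 = ring_index(i + 1, j)
            a11 = ring_index(i + 1, j + 1)
            faces.append([a00, a10, a11])
            faces.append([a00, a11, a01])
    last = v.shape[0] - 1
    for j in range(sectors):  # bottom cap
        faces.append([last, ring_index(stacks - 1, j + 1), ring_index(stacks - 1, j)])
    return v, np.asarray(faces, dtype=np.int64)


def _grid_for_vertex_count(n: int) -> tuple[int, int]:
    """Pick (sectors, stacks) with sectors % 4 == 0, stacks even, vertex
    count sectors*(stacks-1)+2 close to ``n``."""
    sectors = max(8, 4 * round(math.sqrt(4.0 * n / 3.0) / 4.0))
    stacks = max(4, 2 * round((n - 2) / sectors / 2.0) + 2)
    if stacks % 2:
        stacks += 1
    return sectors, stacks


def superellipsoid_mesh(semi_axes, exponent: float, n_vertices: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated superellipsoid in the local frame (long axis = x)."""
    sectors, stacks = _grid_for_vertex_count(n_vertices)
    v, f = _uv_sphere(sectors, stacks)
    a = np.asarray(semi_axes, dtype=float)
    p = float(exponent)
    r = (np.abs(v / a) ** p).sum(axis=1) ** (-1.0 / p)
    return v * r[:, None], f


def superellipsoid_normals(local_points, semi_axes, exponent: float) -> np.ndarray:
    """Outward unit normals of surface points, from the implicit gradient."""
    x = np.asarray(local_points, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    p = float(exponent)
    g = p * np.sign(x) * np.abs(x) ** (p - 1.0) / a ** p
    n = np.linalg.norm(g, axis=1, keepdims=True)
    return g / np.maximum(n, 1e-300)


# ---------------------------------------------------------------------------
# axes and rotations from pose angles

def axis_from_angles(il: float, it: float) -> np.ndarray:
    """Anterior-oriented unit axis realising lateral inclination ``il``
    (plantar-declination positive) and transverse inclination ``it``
    (internal/medial positive) in the generation frame (x anterior, y
    medial, z up)."""
    u = np.array([1.0, math.tan(it * DEG), -math.tan(il * DEG)])
    return u / np.linalg.norm(u)


def tibial_axis_from_angles(il: float, it: float) -> np.ndarray:
    """Up-oriented tibial axis with sagittal anterior lean ``il`` and
    transverse lean azimuth ``it`` (medial positive)."""
    t = math.tan(il * DEG)
    w = np.array([t, t * math.tan(it * DEG), 1.0])
    return w / np.linalg.norm(w)


def rotation_for_axis(u: np.ndarray, roll: float = 0.0) -> np.ndarray:
    """Rotation whose local x maps to ``u``, local z as dorsal as the pose
    allows, spun by ``roll`` degrees about the long axis.  Columns are the
    local axes in world coordinates."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    zhat = np.array([0.0, 0.0, 1.0])
    dp = zhat - (zhat @ u) * u
    n = np.linalg.norm(dp)
    if n < 1e-9:  # axis vertical: dorsal direction conventionally anterior
        dp = np.array([1.0, 0.0, 0.0]) - (u[0]) * u
        n = np.linalg.norm(dp)
    dp = dp / n
    if roll:
        c, s = math.cos(roll * DEG), math.sin(roll * DEG)
        dp = c * dp + s * np.cross(u, dp)
    ml = np.cross(dp, u)
    return np.column_stack([u, ml, dp])


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class BoneShape:
    """Semi-axes (mm, descending) and superellipsoid exponent of one bone."""
    semi_axes: tuple[float, float, float]
    exponent: float = 2.0

    def __post_init__(self):
        a = self.semi_axes
        if not (a[0] >= a[1] >= a[2] > 0):
            raise GenerationError(f"semi-axes must be positive descending: {a}")
        if self.exponent <= 1.0:
            raise GenerationError("superellipsoid exponent must exceed 1")


DEFAULT_SHAPES: dict[str, BoneShape] = {
    "TI": BoneShape((55.0, 16.0, 13.0), 2.2),
    "CA": BoneShape((42.0, 18.0, 14.0), 2.4),
    "TA": BoneShape((28.0, 17.0, 13.0), 2.2),
    "NA": BoneShape((19.0, 11.0, 8.0), 2.0),
    "CU": BoneShape((17.0, 12.0, 9.0), 2.2),
    "CM": BoneShape((15.0, 9.0, 7.0), 2.0),
    "M1": BoneShape((31.0, 9.0, 7.5), 2.0),
    "M2": BoneShape((30.0, 7.0, 5.5), 2.0),
    "M5": BoneShape((28.0, 7.0, 5.5), 2.0),
}

#: Long bones must be clearly elongated; tarsals mildly so.
MIN_ELONGATION = {"TI": 2.0, "CA": 2.0, "M1": 2.0, "M2": 2.0, "M5": 2.0,
                  "TA": 1.3, "NA": 1.3, "CU": 1.3, "CM": 1.3}

#: Pose angles for bones not driven by a deformity control:
#: (il, it, roll) in degrees; for TI the pair is (sagittal lean, lean azimuth).
DEFAULT_ORIENTATION: dict[str, tuple[float, float, float]] = {
    "TI": (8.8, -53.6, 0.0),
    "NA": (11.2, -20.8, 0.0),
    "CU": (8.0, -15.0, 0.0),
    "CM": (10.0, 10.0, 0.0),
    "M2": (10.0, -6.1, 0.0),   # it overridden via the intermetatarsal control
    "M5": (5.0, -12.0, 0.0),
    "CA": (0.0, 5.9, 0.0),     # il overridden by pitch, roll by valgus
    "TA": (0.0, 0.0, 0.0),     # il/it overridden by the talar controls
    "M1": (0.0, 7.0, 0.0),     # il overridden by the M1 control
}

#: In-plane layout (mm): fixed x/y anchors of the design.
DEFAULT_LAYOUT = {
    "TA_x": 52.0,
    "NA_xy": (82.0, 12.0),
    "CU_xy": (80.0, -16.0),
    "CM_xy": (102.0, 14.0),
    "M1_head": (140.0, 22.0, 5.0),
    "M2_head_z": 4.0,
    "M5_head": (132.0, -36.0, 5.0),
    "TI_offset": 62.0,
    "foot_length": 146.0,
}


@dataclass(frozen=True)
class SyntheticParams:
    """Full description of one synthetic foot.

    The deformity controls are the scientific knobs; shapes, orientation
    table and layout define the rest of the skeleton.  All angles in
    degrees, lengths in mm.
    """

    calcaneal_pitch: float = 8.8
    talar_declination: float = 24.3
    talar_internal_rotation: float = 27.4
    m1_declination: float = 12.2
    arch_heights: tuple[float, float, float] = (24.2, 18.7, 18.6)  # NA, CU, CM
    hindfoot_valgus: float = 25.0
    intermetatarsal_angle: float = -13.1   # signed transverse M1-vs-M2 angle
    talus_height: float = 42.0             # talar centre height above ground
    orientation: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    shapes: dict = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    layout: dict = field(default_factory=lambda: dict(DEFAULT_LAYOUT))
    vertices_per_bone: int = 3200
    vertex_noise_sd: float = 0.0
    decimation_fraction: float = 0.0
    seed: int = 0
    foot_id: str = "synthetic"
    side: str = "RIGHT"

    def validate(self) -> None:
        for name in ("calcaneal_pitch", "talar_declination",
                     "talar_internal_rotation", "m1_declination",
                     "hindfoot_valgus", "intermetatarsal_angle"):
            lo, hi = CONTROL_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise GenerationError(f"{name}={v} outside physiologic [{lo}, {hi}]")
        lo, hi = CONTROL_BOUNDS["arch_height"]
        for h in self.arch_heights:
            if not lo <= h <= hi:
                raise GenerationError(f"arch height {h} outside [{lo}, {hi}] mm")
        if self.vertices_per_bone < 100:
            raise GenerationError("vertices_per_bone must be >= 100")
        if not 0.0 <= self.decimation_fraction < 1.0:
            raise GenerationError("decimation_fraction must be in [0, 1)")
        if self.vertex_noise_sd < 0:
            raise GenerationError("vertex_noise_sd must be >= 0")
        for code, shape in self.shapes.items():
            elong = shape.semi_axes[0] / shape.semi_axes[1]
            if elong < MIN_ELONGATION.get(code, 1.0) - 1e-9:
                raise GenerationError(
                    f"{code}: elongation {elong:.2f} below "
                    f"{MIN_ELONGATION.get(code)}")

    # effective pose angles after applying the deformity controls
    def pose_angles(self) -> dict[str, tuple[float, float, float]]:
        o = dict(self.orientation)
        ca = o["CA"]; ta = o["TA"]; m1 = o["M1"]; m2 = o["M2"]
        m1_it = m1[1]
        return {
            **o,
            "CA": (-self.calcaneal_pitch, ca[1], self.hindfoot_valgus),
            "TA": (self.talar_declination, self.talar_internal_rotation, ta[2]),
            "M1": (self.m1_declination, m1_it, m1[2]),
            "M2": (m2[0], m1_it + self.intermetatarsal_angle, m2[2]),
        }


@dataclass
class GroundTruth:
    """Closed-form expected values for one synthetic foot: true longitudinal
    axes per bone (generation frame) and the expected value of every
    catalog code, derived from the design poses without any mesh."""

    axes: dict[str, np.ndarray]
    expected: dict[str, float]
    foot_frame: FootFrame
    landmarks: ArchLandmarks
    params: SyntheticParams
    seed: int


# ---------------------------------------------------------------------------
# design construction (no meshes)

def _truth_foot_frame(foot_length: float) -> FootFrame:
    return FootFrame(origin=np.zeros(3), ap=np.array([1.0, 0.0, 0.0]),
                     up=np.array([0.0, 0.0, 1.0]), ml=np.array([0.0, -1.0, 0.0]),
                     foot_length=foot_length)


def build_design(params: SyntheticParams) -> dict:
    """Resolve poses into rotations, centres and analytic landmarks."""
    params.validate()
    poses = params.pose_angles()
    shapes = params.shapes
    lay = params.layout

    axes: dict[str, np.ndarray] = {}
    rots: dict[str, np.ndarray] = {}
    for code, (il, it, roll) in poses.items():
        if code == "TI":
            u = tibial_axis_from_angles(il, it)
        else:
            u = axis_from_angles(il, it)
        axes[code] = u
        rots[code] = rotation_for_axis(u, roll)

    down = np.array([0.0, 0.0, -1.0])

    def lowest_offset(code):
        """Offset (world) from centre to the globally most plantar point."""
        R = rots[code]
        x = superellipsoid_support(R.T @ down, shapes[code].semi_axes,
                                   shapes[code].exponent)
        return R @ x

    def head_offset(code, fraction=0.25):
        """Offset from centre to the plantar point of the anterior region."""
        R = rots[code]
        x = superellipsoid_region_support(R.T @ down, shapes[code].semi_axes,
                                          shapes[code].exponent, fraction)
        return R @ x

    centers: dict[str, np.ndarray] = {}
    # heel of the calcaneus sits exactly at the origin, on the ground
    centers["CA"] = -lowest_offset("CA")
    # talus: medialised by the valgus control, at the given height
    y_ta = math.tan(params.hindfoot_valgus * DEG) * params.talus_height
    centers["TA"] = np.array([lay["TA_x"], y_ta, params.talus_height])
    centers["TI"] = centers["TA"] + lay["TI_offset"] * axes["TI"]
    # midfoot bones: centre height chosen so the plantar point hits the
    # requested arch height exactly
    for code, xy, hg in (("NA", lay["NA_xy"], params.arch_heights[0]),
                         ("CU", lay["CU_xy"], params.arch_heights[1]),
                         ("CM", lay["CM_xy"], params.arch_heights[2])):
        off = lowest_offset(code)
        centers[code] = np.array([xy[0], xy[1], hg - off[2]])
    # metatarsals: placed so the analytic head landmark hits its target
    m1_head = np.asarray(lay["M1_head"], dtype=float)
    centers["M1"] = m1_head - head_offset("M1")
    m2_head = np.array([lay["foot_length"], 0.0, lay["M2_head_z"]])
    centers["M2"] = m2_head - head_offset("M2")
    m5_head = np.asarray(lay["M5_head"], dtype=float)
    centers["M5"] = m5_head - head_offset("M5")

    # analytic landmarks
    heel = centers["CA"] + lowest_offset("CA")          # = origin
    apex = centers["TA"] + head_offset("TA", TALUS_APEX_FRACTION)
    landmarks = ArchLandmarks(ca_plantar=heel, talus_apex=apex,
                              m1_plantar=m1_head)

    heights = {
        "Hg_NA": params.arch_heights[0],
        "Hg_CU": params.arch_heights[1],
        "Hg_CM": params.arch_heights[2],
    }
    lowest = {code: (centers[code] + lowest_offset(code))[2]
              for code in centers}

    return {
        "axes": axes, "rotations": rots, "centers": centers,
        "landmarks": landmarks, "heights": heights, "lowest": lowest,
        "m2_head": m2_head, "m5_head": m5_head,
        "foot_length": float(np.hypot(*(m2_head - heel)[:2])),
    }


def evaluate_truth(params: SyntheticParams) -> GroundTruth:
    """Expected catalog values from the design, mesh-free."""
    d = build_design(params)
    frame = _truth_foot_frame(d["foot_length"])
    expected = axis_code_values(d["axes"], frame)
    lm: ArchLandmarks = d["landmarks"]
    expected["RL_TACAM1"] = mcb_angle(lm, "L", frame)
    expected["R3_TACAM1"] = mcb_angle(lm, "3D")
    expected.update(d["heights"])
    pct, mm = fao_from_points(lm.ca_plantar, lm.m1_plantar, d["m5_head"],
                              d["centers"]["TA"], frame)
    expected["FAO_%"], expected["FAO_mm"] = pct, mm
    expected = {c: float(expected[c]) for c in CODES}
    return GroundTruth(axes=d["axes"], expected=expected, foot_frame=frame,
                       landmarks=lm, params=params, seed=params.seed)


# ---------------------------------------------------------------------------
# mesh generation

def _ground_mesh() -> BoneMesh:
    xs = np.linspace(-40.0, 190.0, 8)
    ys = np.linspace(-70.0, 70.0, 5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    v = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    ny = ys.size
    for i in range(xs.size - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append([a, a + ny, a + ny + 1])
            faces.append([a, a + ny + 1, a + 1])
    return BoneMesh("GROUND", v, np.asarray(faces), side="NA")


def generate_foot(params: SyntheticParams) -> tuple[FootModel, GroundTruth]:
    """Build the meshes and the matching closed-form ground truth.

    Deterministic given ``params.seed``: identical parameters produce
    bitwise-identical vertex arrays.
    """
    truth = evaluate_truth(params)
    d = build_design(params)

    offenders = [c for c, z in d["lowest"].items() if z < -0.5]
    if offenders:
        raise GenerationError(f"bones penetrate the ground: {offenders}")

    rng = np.random.default_rng(params.seed)
    bones: dict[str, BoneMesh] = {}
    for code in ("TI", "CA", "TA", "NA", "CU", "CM", "M1", "M2", "M5"):
        shape: BoneShape = params.shapes[code]
        v_local, f = superellipsoid_mesh(shape.semi_axes, shape.exponent,
                                         params.vertices_per_bone)
        if params.vertex_noise_sd > 0:
            n_local = superellipsoid_normals(v_local, shape.semi_axes,
                                             shape.exponent)
            v_local = v_local + params.vertex_noise_sd * \
                rng.standard_normal((v_local.shape[0], 1)) * n_local
        R, c = d["rotations"][code], d["centers"][code]
        v = v_local @ R.T + c
        if params.decimation_fraction > 0:
            target = int(v.shape[0] * (1 - params.decimation_fraction))
            v, f = decimate_convex(v, target)
        bones[code] = BoneMesh(code, v, f, side=params.side)

    bones["GROUND"] = _ground_mesh()
    ground = GroundPlane(point=np.zeros(3), up=np.array([0.0, 0.0, 1.0]))
    foot = FootModel(foot_id=params.foot_id, side="RIGHT", bones=bones,
                     ground=ground, meta={"seed": params.seed})
    if params.side == "LEFT":
        from .mesh_core import reflect_foot
        foot = reflect_foot(foot)  # swaps label to LEFT
    return foot, truth


# ---------------------------------------------------------------------------
# segmentation-tool emulation

def decimate_convex(vertices: np.ndarray,
                    target_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Decimate a convex body toward ``target_vertices``: keep one actual
    surface vertex per occupied voxel cell (the one nearest the cell mean),
    then re-triangulate by convex hull with outward-oriented faces.

    The surviving vertices are spread near-uniformly over the surface —
    the signature of real mesh-decimation output — so the sparse
    reconstruction estimates the dense mesh's principal axes without the
    1/sqrt(n) covariance noise a random subsample would add.  Intended for
    the generator's convex superellipsoid bodies.
    """
    from scipy.spatial import ConvexHull

    v = np.asarray(vertices, dtype=float)
    n = v.shape[0]
    if target_vertices < 100:
        raise GenerationError(
            f"decimation would leave {target_vertices} < 100 vertices")

    # voxelise in the body's own centred principal frame: the selection
    # pattern is then (statistically) mirror-symmetric with respect to the
    # body, so decimation does not tilt the principal axes
    mu = v.mean(axis=0)
    c = v - mu
    _, evecs = np.linalg.eigh(c.T @ c / n)
    w = c @ evecs
    extent = float(np.max(w.max(axis=0) - w.min(axis=0)))

    def representatives(h):
        keys = np.floor(w / h + 0.5).astype(np.int64)
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        k = uniq.shape[0]
        counts = np.bincount(inverse, minlength=k).astype(float)
        means = np.zeros((k, 3))
        for ax in range(3):
            means[:, ax] = np.bincount(inverse, weights=w[:, ax],
                                       minlength=k) / counts
        d2 = ((w - means[inverse]) ** 2).sum(axis=1)
        # nearest actual vertex to each cell mean
        order = np.lexsort((d2, inverse))
        first = np.searchsorted(inverse[order], np.arange(k))
        return np.sort(order[first])

    lo, hi = 1e-3, extent
    best = None
    for _ in range(40):
        h = 0.5 * (lo + hi)
        idx = representatives(h)
        m = idx.size
        if best is None or abs(m - target_vertices) < abs(best[1] - target_vertices):
            best = (idx, m)
        if abs(m - target_vertices) <= max(8, 0.02 * target_vertices):
            break
        if m > target_vertices:
            lo = h
        else:
            hi = h
        if hi - lo < 1e-9 * extent:
            break
    pts = v[best[0]]
    hull = ConvexHull(pts)
    keep = hull.vertices
    remap = np.full(pts.shape[0], -1, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    nv = pts[keep]
    nf = remap[hull.simplices]
    # orient faces outward (hull simplex winding is arbitrary)
    centroid = nv.mean(axis=0)
    normals = np.cross(nv[nf[:, 1]] - nv[nf[:, 0]], nv[nf[:, 2]] - nv[nf[:, 0]])
    centers = nv[nf].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centers - centroid) < 0
    nf[flip] = nf[flip][:, ::-1]
    return nv, nf


def perturb(foot: FootModel, mode: str, noise_sd: float = 0.15,
            seed: int = 0) -> FootModel:
    """Emulate a segmentation tool on an ideal foot.

    ``MIS-like``: zero-mean normal vertex noise along vertex normals (a
    dense, slightly rough semi-automatic reconstruction).  ``DIS-like``:
    Laplacian smoothing, decimation to roughly one eighth of the faces,
    then the same noise (a smooth automatic reconstruction).  The ground is
    left untouched.  Deterministic given ``seed``.
    """
    if mode not in ("MIS-like", "DIS-like"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    bones: dict[str, BoneMesh] = {}
    for code in sorted(foot.bones):
        mesh = foot.bones[code]
        if code == "GROUND":
            bones[code] = mesh
            continue
        v, f = mesh.vertices, mesh.faces
        if mode == "DIS-like":
            tm = trimesh.Trimesh(v, f, process=False)
            trimesh.smoothing.filter_laplacian(tm, lamb=0.5, iterations=4)
            v = np.asarray(tm.vertices, dtype=float)
            v, f = decimate_convex(v, v.shape[0] // 8)
        if noise_sd > 0:
            tm = trimesh.Trimesh(v, f, process=False)
            normals = np.asarray(tm.vertex_normals, dtype=float)
            v = v + noise_sd * rng.standard_normal((v.shape[0], 1)) * normals
        bones[code] = BoneMesh(code, v, f, side=mesh.side)
    out = FootModel(foot_id=foot.foot_id, side=foot.side, bones=bones,
                    ground=foot.ground,
                    meta={**foot.meta, "perturb": mode, "noise_sd": noise_sd,
                          "perturb_seed": seed})
    return out


# ---------------------------------------------------------------------------
# templates

_FIT_CODES = tuple(c for c in AXIS_CODES
                   if not c.startswith("RF_"))  # frontal codes not fitted


@lru_cache(maxsize=1)
def _fitted_flatfoot_angles() -> dict[str, tuple[float, float]]:
    """Least-squares pose angles reproducing the reference flatfoot cohort
    means over the sagittal/transverse/3D axis codes.

    The printed cohort means are averages of per-foot nonlinear angle
    functions and are not exactly jointly realisable by any single set of
    axes, so the template solves the small least-squares problem instead
    of chaining identities.  Frontal-plane codes are excluded: their
    projection convention is not pinned down by the reference values.
    """
    target = reference_means("semi_auto")
    frame = _truth_foot_frame(DEFAULT_LAYOUT["foot_length"])

    # x = [TI il, TI it, TA il, TA it, CA il, CA it, NA il, NA it,
    #      M1 il, M1 it, M2 it]; M2 il pinned (no code constrains it)
    m2_il = DEFAULT_ORIENTATION["M2"][0]

    def axes_from(x):
        return {
            "TI": tibial_axis_from_angles(x[0], x[1]),
            "TA": axis_from_angles(x[2], x[3]),
            "CA": axis_from_angles(x[4], x[5]),
            "NA": axis_from_angles(x[6], x[7]),
            "M1": axis_from_angles(x[8], x[9]),
            "M2": axis_from_angles(m2_il, x[10]),
        }

    def residuals(x):
        vals = axis_code_values(axes_from(x), frame)
        return np.array([vals[c] - target[c] for c in _FIT_CODES])

    x0 = np.array([
        target["IL_TI"], target["IT_CA"] - target["RT_TICA"],
        target["IL_TA"], target["IT_TA"],
        target["IL_CA"], target["IT_CA"],
        target["IL_TA"] - target["RL_TANA"], target["IT_TA"] + target["RT_TANA"],
        target["IL_TA"] + target["RL_TAM1"], target["IT_TA"] + target["RT_TAM1"],
        target["IT_TA"] + target["RT_TAM1"] + target["RT_M1M2"],
    ])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    x = sol.x
    return {"TI": (x[0], x[1]), "TA": (x[2], x[3]), "CA": (x[4], x[5]),
            "NA": (x[6], x[7]), "M1": (x[8], x[9]), "M2": (m2_il, x[10])}


def _params_from_fit(fit: dict[str, tuple[float, float]],
                     **overrides) -> SyntheticParams:
    orientation = dict(DEFAULT_ORIENTATION)
    orientation["TI"] = (fit["TI"][0], fit["TI"][1], 0.0)
    orientation["NA"] = (fit["NA"][0], fit["NA"][1], 0.0)
    orientation["CA"] = (0.0, fit["CA"][1], 0.0)
    orientation["M1"] = (0.0, fit["M1"][1], 0.0)
    orientation["M2"] = (fit["M2"][0], 0.0, 0.0)
    return SyntheticParams(
        calcaneal_pitch=-fit["CA"][0],
        talar_declination=fit["TA"][0],
        talar_internal_rotation=fit["TA"][1],
        m1_declination=fit["M1"][0],
        intermetatarsal_angle=fit["M2"][1] - fit["M1"][1],
        orientation=orientation,
        **overrides,
    )


@lru_cache(maxsize=1)
def _flatfoot_template() -> SyntheticParams:
    fit = _fitted_flatfoot_angles()
    target = reference_means("semi_auto")
    base = _params_from_fit(fit, hindfoot_valgus=20.0,
                            arch_heights=(target["Hg_NA"], target["Hg_CU"],
                                          target["Hg_CM"]),
                            foot_id="flatfoot-template")

    # talar centre height: solve so the lateral Moreau-Costa-Bertani arch
    # angle of the closed-form truth matches the reference mean
    def mcb_err(z):
        p = replace(base, talus_height=float(z))
        return evaluate_truth(p).expected["RL_TACAM1"] - target["RL_TACAM1"]
    z_ta = brentq(mcb_err, 28.0, 58.0, xtol=1e-6)
    base = replace(base, talus_height=float(z_ta))

    # hindfoot valgus: FAO_mm is linear in the talar medial offset, solve
    # for the reference offset through two evaluations
    def fao_of(valgus):
        return evaluate_truth(replace(base, hindfoot_valgus=valgus)).expected["FAO_mm"]
    v0, v1 = 10.0, 30.0
    f0, f1 = fao_of(v0), fao_of(v1)
    y0 = math.tan(v0 * DEG) * z_ta
    y1 = math.tan(v1 * DEG) * z_ta
    slope = (f1 - f0) / (y1 - y0)
    y_need = y0 + (target["FAO_mm"] - f0) / slope
    valgus = math.degrees(math.atan2(y_need, z_ta))
    return replace(base, hindfoot_valgus=float(valgus))


def default_templates() -> tuple[SyntheticParams, SyntheticParams]:
    """(normal, flatfoot) parameter templates.

    The flatfoot template is calibrated so its closed-form truth reproduces
    the reference cohort means (sagittal/transverse/3D axis codes to within
    the residual of the least-squares pose fit, arch and tripod codes via
    dedicated solves).  The normal template uses textbook mid-range values
    for an asymptomatic adult foot: calcaneal pitch ~18 deg, Meary angle
    ~0, higher arch, minimal hindfoot valgus.
    """
    normal = SyntheticParams(
        calcaneal_pitch=18.0,
        talar_declination=18.0,
        talar_internal_rotation=20.0,
        m1_declination=18.0,
        arch_heights=(34.0, 24.0, 27.0),
        hindfoot_valgus=5.0,
        intermetatarsal_angle=-8.0,
        talus_height=46.0,
        orientation={**DEFAULT_ORIENTATION,
                     "TI": (8.0, 30.0, 0.0),
                     "NA": (15.0, 60.0, 0.0)},
        foot_id="normal-template",
    )
    return normal, _flatfoot_template()


# ---------------------------------------------------------------------------
# cohorts

#: Default per-control normal dispersion (SDs) for cohort sampling, chosen
#: to mirror the spread of the reference flatfoot cohort.
DEFAULT_DISPERSION = {
    "calcaneal_pitch": 5.11,
    "talar_declination": 7.49,
    "talar_internal_rotation": 10.55,
    "m1_declination": 4.0,
    "hindfoot_valgus": 5.0,
    "intermetatarsal_angle": 3.66,
    "arch_NA": 5.24, "arch_CU": 3.57, "arch_CM": 3.39,
    "ti_il": 5.93, "ti_it": 10.0,
    "na_il": 6.0, "na_it": 8.0,
    "noise_sd": 0.15,
}


def sample_params(rng: np.random.Generator,
                  base: SyntheticParams | None = None,
                  dispersion: dict | None = None,
                  foot_id: str = "foot") -> SyntheticParams:
    """One random foot around the flatfoot template."""
    if base is None:
        base = default_templates()[1]
    disp = dict(DEFAULT_DISPERSION)
    if dispersion:
        disp.update(dispersion)

    def draw(value, sd, bounds):
        lo, hi = bounds
        return float(np.clip(value + sd * rng.standard_normal(), lo, hi))

    b = CONTROL_BOUNDS
    orientation = dict(base.orientation)
    ti = orientation["TI"]
    orientation["TI"] = (draw(ti[0], disp["ti_il"], (3.0, 25.0)),
                         draw(ti[1], disp["ti_it"], (-80.0, 85.0)), ti[2])
    na = orientation["NA"]
    orientation["NA"] = (draw(na[0], disp["na_il"], (-20.0, 40.0)),
                         draw(na[1], disp["na_it"], (30.0, 88.0)), na[2])
    return replace(
        base,
        calcaneal_pitch=draw(base.calcaneal_pitch,
                             disp["calcaneal_pitch"], b["calcaneal_pitch"]),
        talar_declination=draw(base.talar_declination,
                               disp["talar_declination"], b["talar_declination"]),
        talar_internal_rotation=draw(base.talar_internal_rotation,
                                     disp["talar_internal_rotation"],
                                     b["talar_internal_rotation"]),
        m1_declination=draw(base.m1_declination,
                            disp["m1_declination"], b["m1_declination"]),
        hindfoot_valgus=draw(base.hindfoot_valgus,
                             disp["hindfoot_valgus"], b["hindfoot_valgus"]),
        intermetatarsal_angle=draw(base.intermetatarsal_angle,
                                   disp["intermetatarsal_angle"],
                                   b["intermetatarsal_angle"]),
        arch_heights=(draw(base.arch_heights[0], disp["arch_NA"], b["arch_height"]),
                      draw(base.arch_heights[1], disp["arch_CU"], b["arch_height"]),
                      draw(base.arch_heights[2], disp["arch_CM"], b["arch_height"])),
        orientation=orientation,
        seed=int(rng.integers(0, 2**31 - 1)),
        foot_id=foot_id,
    )


def generate_cohort(n: int, dispersion: dict | None = None, seed: int = 0,
                    noise_sd: float | None = None,
                    base: SyntheticParams | None = None,
                    ) -> tuple[list[tuple[FootModel, FootModel]], list[GroundTruth]]:
    """n synthetic feet around the flatfoot template (or ``base``), each
    emitted as an (MIS-like, DIS-like) mesh pair sharing one generation
    frame."""
    if n < 1:
        raise GenerationError("cohort size must be >= 1")
    disp = dict(DEFAULT_DISPERSION)
    if dispersion:
        disp.update(dispersion)
    sd = disp["noise_sd"] if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    pairs: list[tuple[FootModel, FootModel]] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        params = sample_params(rng, base=base, dispersion=dispersion,
                               foot_id=f"synth{i:03d}")
        foot, truth = generate_foot(params)
        s1 = int(rng.integers(0, 2**31 - 1))
        s2 = int(rng.integers(0, 2**31 - 1))
        mis = perturb(foot, "MIS-like", noise_sd=sd, seed=s1)
        dis = perturb(foot, "DIS-like", noise_sd=sd, seed=s2)
        pairs.append((mis, dis))
        truths.append(truth)
    return pairs, truths
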