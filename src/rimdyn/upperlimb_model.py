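"""Reduced 15-marker upper-limb model.

Covers four stages:

* **Cluster calibration / reconstruction** — the epicondyle markers are
  referenced to the three-marker arm cluster and the metacarpal markers to
  the hand's own reference markers, so they can be rebuilt rigidly
  (orthogonal Procrustes) when occluded.
* **Segment frames** — trunk, arm (humerus), forearm and hand frames built
  from marker landmarks, each orthonormal right-handed with columns
  [x anterior, y longitudinal (pointing proximal/up), z lateral].
* **Joint kinematics** — Euler decomposition of the distal-in-proximal
  rotation: shoulder Y-X'-Y'' (plane of elevation, elevation, axial
  rotation), elbow and wrist Z-X'-Y'' (flexion, deviation/carrying angle,
  axial rotation), following the International Society of Biomechanics
  sequences, in degrees, continuity-unwrapped.
* **Inverse dynamics** — Newton-Euler recursion hand -> wrist -> elbow ->
  glenohumeral with the measured hand-rim load applied at the grip point,
  segments modelled as solids of revolution.

Joint loads are reported as the action the joint transmits to its distal
segment at the joint centre: forces in the lab frame (x anterior, z
superior) and, for convenience, moments both in the lab frame and projected
on the proximal segment's anatomical axes with + adduction / + flexion /
+ internal-rotation signs for the right side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .events_cycles import PropulsionCycle
from .io_core import (Anthropometry, HandrimKineticSeries, MarkerFrameSeries,
                      WheelchairGeometry)

__all__ = [
    "ClusterTemplate", "SegmentFrames", "SegmentInertia", "SegmentMotion",
    "JointKinematics", "JointKinetics",
    "ARM_CLUSTER", "HAND_CLUSTER",
    "calibrate_cluster", "reconstruct_markers", "build_frames",
    "joint_angles", "derive_motion", "estimate_axle", "rim_load_lab",
    "inverse_dynamics", "angle_summary",
]

GRAVITY = np.array([0.0, 0.0, -9.81])

#: (reference labels, dependent labels) of the two rigid clusters.
ARM_CLUSTER = (("rm1", "rm2", "rm3"), ("epc", "ipc"))
HAND_CLUSTER = (("ulr", "rdl", "3m"), ("2m", "5m"))

SEGMENTS = ("trunk", "arm", "forearm", "hand")
JOINTS = ("wrist", "elbow", "shoulder")

#: COM position as a fraction of segment length from the proximal joint.
COM_FRACTIONS = {"arm": 0.436, "forearm": 0.430, "hand": 0.506}


# ---------------------------------------------------------------------------
# rigid clusters
# ---------------------------------------------------------------------------

def _cluster_frame(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic frame from >=3 points: origin at centroid, x along the
    first edge, z along the triangle normal."""
    origin = p.mean(axis=0)
    e1 = p[1] - p[0]
    e2 = p[2] - p[0]
    nrm = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(nrm)
    if area <= 1e-6:
        raise ValueError(
            f"reference markers are collinear (triangle area {area:.2e} m^2)"
        )
    x = e1 / np.linalg.norm(e1)
    z = nrm / np.linalg.norm(nrm)
    y = np.cross(z, x)
    return origin, np.column_stack([x, y, z])


@dataclass
class ClusterTemplate:
    """Local coordinates of dependent markers in their reference-cluster frame."""

    reference_labels: tuple[str, ...]
    dependent_labels: tuple[str, ...]
    reference_local: np.ndarray   # (n_ref, 3) cluster-frame coords
    dependent_local: np.ndarray   # (n_dep, 3) cluster-frame coords


def calibrate_cluster(static: MarkerFrameSeries,
                      reference_labels=ARM_CLUSTER[0],
                      dependent_labels=ARM_CLUSTER[1]) -> ClusterTemplate:
    """Average dependent-marker local coordinates over static frames."""
    ref_idx = [static.index(l) for l in reference_labels]
    dep_idx = [static.index(l) for l in dependent_labels]
    ref_loc_acc = []
    dep_loc_acc = []
    for i in range(static.n_samples):
        if static.gaps[i, ref_idx].any() or static.gaps[i, dep_idx].any():
            continue
        refs = static.positions[i, ref_idx, :]
        deps = static.positions[i, dep_idx, :]
        origin, R = _cluster_frame(refs)
        ref_loc_acc.append((refs - origin) @ R)
        dep_loc_acc.append((deps - origin) @ R)
    if not ref_loc_acc:
        raise ValueError("no static frame with all cluster markers visible")
    return ClusterTemplate(
        tuple(reference_labels), tuple(dependent_labels),
        np.mean(ref_loc_acc, axis=0), np.mean(dep_loc_acc, axis=0),
    )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping src onto dst: dst ~ src @ R.T + t."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dc - R @ sc
    return R, t


def reconstruct_markers(template: ClusterTemplate,
                        dynamic: MarkerFrameSeries) -> MarkerFrameSeries:
    """Rebuild dependent markers rigidly from the tracked reference cluster.

    Frames where fewer than three reference markers are visible leave the
    reconstructed markers gap-flagged.
    """
    out = dynamic.copy()
    ref_idx = [dynamic.index(l) for l in template.reference_labels]
    dep_idx = [out.index(l) for l in template.dependent_labels]
    for i in range(dynamic.n_samples):
        visible = ~dynamic.gaps[i, ref_idx]
        if visible.sum() < 3:
            out.gaps[i, dep_idx] = True
            out.positions[i, dep_idx, :] = np.nan
            continue
        obs = dynamic.positions[i, ref_idx, :][visible]
        loc = template.reference_local[visible]
        R, t = _kabsch(loc, obs)
        out.positions[i, dep_idx, :] = template.dependent_local @ R.T + t
        out.gaps[i, dep_idx] = False
    return out


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------

@dataclass
class SegmentFrames:
    """Per-sample origin and rotation of each segment.

    ``origins[seg]`` is (n, 3); ``rotations[seg]`` is (n, 3, 3) with columns
    [x anterior, y longitudinal-proximal, z lateral].  Segment origins sit
    at the proximal joint centre (trunk: c7; arm: glenohumeral centre;
    forearm: elbow centre; hand: wrist centre).
    """

    origins: dict[str, np.ndarray]
    rotations: dict[str, np.ndarray]
    rate: float

    @property
    def n_samples(self) -> int:
        return next(iter(self.origins.values())).shape[0]

    def check_orthonormal(self, tol: float = 1e-9) -> None:
        for seg, R in self.rotations.items():
            err = np.abs(R @ np.swapaxes(R, 1, 2) - np.eye(3)).max()
            if err > tol:
                raise ValueError(f"{seg} rotations not orthonormal (max err {err:.2e})")
            det = np.linalg.det(R)
            if np.abs(det - 1).max() > tol:
                raise ValueError(f"{seg} rotations not proper (det off by "
                                 f"{np.abs(det - 1).max():.2e})")


def _frame_from_y(y0: np.ndarray, z0: np.ndarray, seg: str) -> np.ndarray:
    """Orthonormal frame with exact longitudinal axis y and approximate
    lateral axis z; vectorized over samples."""
    y = y0 / np.linalg.norm(y0, axis=-1, keepdims=True)
    z = z0 - np.sum(z0 * y, axis=-1, keepdims=True) * y
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(nz < 1e-9):
        raise ValueError(f"degenerate (collinear) defining points for segment {seg}")
    z = z / nz
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def _frame_from_z(z0: np.ndarray, x0: np.ndarray, seg: str) -> np.ndarray:
    """Orthonormal frame with exact lateral axis z and approximate anterior x."""
    z = z0 / np.linalg.norm(z0, axis=-1, keepdims=True)
    x = x0 - np.sum(x0 * z, axis=-1, keepdims=True) * z
    nx = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(nx < 1e-9):
        raise ValueError(f"degenerate (collinear) defining points for segment {seg}")
    x = x / nx
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def build_frames(markers: MarkerFrameSeries, side: str = "right") -> SegmentFrames:
    """Segment frames from the 15-marker set.

    Trunk from c7 and the acromion markers; arm from the glenohumeral
    centre (midpoint of the humeral-head markers) and the epicondyles;
    forearm from the elbow and wrist centres; hand from the styloids and
    the third metacarpal.
    """
    if markers.gaps.any():
        raise ValueError("fill or reconstruct gaps before building frames")
    get = markers.marker
    sgn = 1.0 if side == "right" else -1.0

    c7, acrr, acrl = get("c7"), get("acrr"), get("acrl")
    gh = 0.5 * (get("hha") + get("hhp"))
    elbow = 0.5 * (get("epc") + get("ipc"))
    wrist = 0.5 * (get("ulr") + get("rdl"))
    m3 = get("3m")

    origins = {"trunk": c7, "arm": gh, "forearm": elbow, "hand": wrist}
    rotations = {
        # trunk: lateral axis from the acromions, anterior from c7 forward
        "trunk": _frame_from_z(sgn * (acrr - acrl),
                               0.5 * (acrr + acrl) - c7, "trunk"),
        "arm": _frame_from_y(gh - elbow, sgn * (get("epc") - get("ipc")), "arm"),
        "forearm": _frame_from_y(elbow - wrist, sgn * (get("rdl") - get("ulr")),
                                 "forearm"),
        "hand": _frame_from_y(wrist - m3, sgn * (get("rdl") - get("ulr")), "hand"),
    }
    return SegmentFrames(origins, rotations, markers.rate)


# ---------------------------------------------------------------------------
# joint kinematics
# ---------------------------------------------------------------------------

#: Euler sequence and gimbal singularities of the middle angle, per joint.
_JOINT_SEQ = {
    "shoulder": ("YXY", (0.0, 180.0, -180.0)),
    "elbow": ("ZXY", (90.0, -90.0)),
    "wrist": ("ZXY", (90.0, -90.0)),
}
_JOINT_PAIR = {"shoulder": ("trunk", "arm"),
               "elbow": ("arm", "forearm"),
               "wrist": ("forearm", "hand")}


@dataclass
class JointKinematics:
    """Euler angle traces in degrees, one (n, 3) array per joint.

    Columns follow the rotation order of the joint's sequence:
    shoulder (plane of elevation ``beta``, elevation, axial rotation),
    elbow/wrist (flexion ``gamma``, deviation/carrying ``alpha``, axial
    rotation ``beta``).  ``named`` re-keys them under the conventional
    variable names; shoulder elevation is reported negative (``alpha_sh``).
    """

    angles: dict[str, np.ndarray]
    gimbal: dict[str, np.ndarray]
    rate: float

    @property
    def named(self) -> dict[str, np.ndarray]:
        sh, el, wr = (self.angles[j] for j in ("shoulder", "elbow", "wrist"))
        return {
            "beta_sh": sh[:, 0], "alpha_sh": -sh[:, 1], "gamma_sh": sh[:, 2],
            "gamma_e": el[:, 0], "beta_e": el[:, 2],
            "gamma_wr": wr[:, 0], "alpha_wr": wr[:, 1], "beta_wr": wr[:, 2],
        }


def _interp_flagged(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if not bad.any() or bad.all():
        return x
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def joint_angles(frames: SegmentFrames, gimbal_tol_deg: float = 1.0) -> JointKinematics:
    """Decompose distal-in-proximal rotations into Euler angle traces.

    Samples whose middle angle comes within ``gimbal_tol_deg`` of a gimbal
    singularity are flagged and linearly interpolated from their
    neighbours.  Angles are unwrapped over time.
    """
    angles: dict[str, np.ndarray] = {}
    gimbal: dict[str, np.ndarray] = {}
    for joint, (seq, sing) in _JOINT_SEQ.items():
        prox, dist = _JOINT_PAIR[joint]
        Rp = frames.rotations[prox]
        Rd = frames.rotations[dist]
        rel = np.swapaxes(Rp, 1, 2) @ Rd
        import warnings
        with warnings.catch_warnings():
            # singular samples are flagged and interpolated below
            warnings.filterwarnings("ignore", message="Gimbal lock")
            eul = Rotation.from_matrix(rel).as_euler(seq, degrees=True)
        mid = eul[:, 1]
        bad = np.zeros(len(mid), dtype=bool)
        for s in sing:
            bad |= np.abs(mid - s) < gimbal_tol_deg
        eul = np.unwrap(eul, axis=0, period=360.0)
        for k in range(3):
            eul[:, k] = _interp_flagged(eul[:, k], bad)
        angles[joint] = eul
        gimbal[joint] = bad
    return JointKinematics(angles, gimbal, frames.rate)


def angle_summary(trace: np.ndarray, cycle: PropulsionCycle) -> dict:
    """Max, min, ROM of an angle trace over one cycle, with push/recovery
    phase tags for where the extrema occur."""
    span = np.asarray(trace)[cycle.i_HO: cycle.i_end + 1]
    i_max = int(np.argmax(span))
    i_min = int(np.argmin(span))
    tag = lambda i: "p" if cycle.i_HO + i <= cycle.i_HR else "r"
    return {
        "max": float(span[i_max]), "min": float(span[i_min]),
        "rom": float(span[i_max] - span[i_min]),
        "phase_max": tag(i_max), "phase_min": tag(i_min),
    }


# ---------------------------------------------------------------------------
# inertial model and motion derivatives
# ---------------------------------------------------------------------------

@dataclass
class SegmentInertia:
    """Mass, COM fraction and local inertia tensor per dynamic segment.

    Segments are solids of revolution about their longitudinal (y) axis,
    taken as cylinders with the mean of the proximal and distal radii:
    I_long = m r^2 / 2, I_trans = m (3 r^2 + L^2) / 12 at the COM.
    """

    mass: dict[str, float]
    length: dict[str, float]
    com_fraction: dict[str, float]
    inertia_local: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for seg, m in self.mass.items():
            if m <= 0:
                raise ValueError(f"{seg} mass must be positive")
            w = np.linalg.eigvalsh(self.inertia_local[seg])
            if w.min() <= 0:
                raise ValueError(f"{seg} inertia tensor must be positive definite")

    @classmethod
    def from_anthropometry(cls, anthro: Anthropometry,
                           com_fractions: dict[str, float] | None = None
                           ) -> "SegmentInertia":
        cf = dict(COM_FRACTIONS)
        if com_fractions:
            cf.update(com_fractions)
        mass, length, inertia = {}, {}, {}
        for seg in ("arm", "forearm", "hand"):
            g = getattr(anthro, seg)
            r = 0.5 * (g.proximal_radius + g.distal_radius)
            mass[seg] = g.mass
            length[seg] = g.length
            i_long = 0.5 * g.mass * r ** 2
            i_trans = g.mass * (3 * r ** 2 + g.length ** 2) / 12.0
            inertia[seg] = np.diag([i_trans, i_long, i_trans])
        return cls(mass, length, cf, inertia)


@dataclass
class SegmentMotion:
    """COM kinematics and angular motion per dynamic segment (lab frame)."""

    com: dict[str, np.ndarray]     # (n, 3) m
    acc: dict[str, np.ndarray]     # (n, 3) m/s^2
    omega: dict[str, np.ndarray]   # (n, 3) rad/s
    alpha: dict[str, np.ndarray]   # (n, 3) rad/s^2
    rate: float


def derive_motion(frames: SegmentFrames, inertia: SegmentInertia,
                  rate: float | None = None) -> SegmentMotion:
    """COM accelerations and angular velocity/acceleration by central
    differences; angular velocity from the skew part of dR/dt R^T."""
    rate = rate or frames.rate
    if frames.n_samples < 5:
        raise ValueError("need at least 5 samples to differentiate")
    com, acc, omega, alpha = {}, {}, {}, {}
    for seg in ("arm", "forearm", "hand"):
        o = frames.origins[seg]
        R = frames.rotations[seg]
        # COM sits on the longitudinal axis, a fraction of the length
        # distal of the proximal origin; distal direction is -y.
        offset = np.array([0.0, -inertia.com_fraction[seg] * inertia.length[seg], 0.0])
        c = o + R @ offset
        v = np.gradient(c, axis=0) * rate
        a = np.gradient(v, axis=0) * rate
        dR = np.gradient(R, axis=0) * rate
        Om = dR @ np.swapaxes(R, 1, 2)
        w = np.stack([
            0.5 * (Om[:, 2, 1] - Om[:, 1, 2]),
            0.5 * (Om[:, 0, 2] - Om[:, 2, 0]),
            0.5 * (Om[:, 1, 0] - Om[:, 0, 1]),
        ], axis=1)
        com[seg], acc[seg] = c, a
        omega[seg] = w
        alpha[seg] = np.gradient(w, axis=0) * rate
    return SegmentMotion(com, acc, omega, alpha, rate)


# ---------------------------------------------------------------------------
# hand-rim load in the lab frame
# ---------------------------------------------------------------------------

def estimate_axle(grip_xyz: np.ndarray, active: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle fit (sagittal plane) of the grip trajectory
    during force application -> (axle centre, rim radius)."""
    p = np.asarray(grip_xyz, dtype=float)[np.asarray(active, dtype=bool)]
    if len(p) < 10:
        raise ValueError("too few push samples to fit the rim circle")
    x, z = p[:, 0], p[:, 2]
    A = np.column_stack([x, z, np.ones_like(x)])
    b = x ** 2 + z ** 2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    x0, z0 = coef[0] / 2, coef[1] / 2
    r = float(np.sqrt(coef[2] + x0 ** 2 + z0 ** 2))
    centre = np.array([x0, float(np.mean(p[:, 1])), z0])
    return centre, r


def rim_load_lab(rim: HandrimKineticSeries, grip_xyz: np.ndarray,
                 axle: np.ndarray, rim_radius: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reaction of the measured rim load on the hand, in the lab frame.

    The wheel sensor frame is fixed (x backward, y up, z left along the
    axle); the wheel angle theta carries the rotation, with theta = 90 deg
    at the rim top.  The sensor force is split into rotation-invariant
    tangential / radial-inward / axial components and re-attached at the
    hand's rim angle (from the grip marker).  Any measured axle moment in
    excess of r x F becomes a pure couple on the hand.

    Returns (force on hand, couple on hand, application point), each (n, 3).
    """
    grip = np.asarray(grip_xyz, dtype=float)
    th = rim.theta
    Fx, Fy, Fz = rim.F[:, 0], rim.F[:, 1], rim.F[:, 2]
    f_tang = -Fx * np.sin(th) + Fy * np.cos(th)
    f_rad_in = -(Fx * np.cos(th) + Fy * np.sin(th))

    # hand angle from the rim top, positive forward
    zeta = np.arctan2(grip[:, 0] - axle[0], grip[:, 2] - axle[2])
    t_hat = np.column_stack([np.cos(zeta), np.zeros_like(zeta), -np.sin(zeta)])
    p_hat = np.column_stack([np.sin(zeta), np.zeros_like(zeta), np.cos(zeta)])
    y_hat = np.array([0.0, 1.0, 0.0])

    F_on_rim = (f_tang[:, None] * t_hat - f_rad_in[:, None] * p_hat
                + Fz[:, None] * y_hat)
    app = axle + rim_radius * p_hat
    app[:, 1] = grip[:, 1]
    # sensor-frame moment mapped to lab: x_sw -> -x, y_sw -> +z, z_sw -> +y
    M_axle_lab = np.column_stack([-rim.M[:, 0], rim.M[:, 2], rim.M[:, 1]])
    couple_on_rim = M_axle_lab - np.cross(app - axle, F_on_rim)
    return -F_on_rim, -couple_on_rim, app


# ---------------------------------------------------------------------------
# Newton-Euler recursion
# ---------------------------------------------------------------------------

@dataclass
class JointKinetics:
    """Joint forces (N) and moments (Nm) over the trial.

    ``F`` / ``M`` are lab-frame actions on the distal segment at the joint
    centre.  ``F_conv`` reorders forces to (+anterior, +lateral, +superior)
    and ``M_conv`` projects moments on the proximal segment's axes as
    (+adduction, +flexion, +internal rotation) for the reported side.
    """

    F: dict[str, np.ndarray]
    M: dict[str, np.ndarray]
    F_conv: dict[str, np.ndarray]
    M_conv: dict[str, np.ndarray]
    rate: float
    side: str = "right"

    def summarize(self, cycle: PropulsionCycle) -> dict:
        out: dict[str, dict] = {}
        for joint in JOINTS:
            span = slice(cycle.i_HO, cycle.i_end + 1)
            fc = self.F_conv[joint][span]
            mc = self.M_conv[joint][span]
            d: dict[str, float | dict] = {}
            for k, ax in enumerate("xyz"):
                d[f"F{ax}max"] = float(fc[:, k].max())
                d[f"F{ax}min"] = float(fc[:, k].min())
                d[f"M{ax}max"] = float(mc[:, k].max())
                d[f"M{ax}min"] = float(mc[:, k].min())
            at: dict[str, dict[str, float]] = {}
            for name, idx in cycle.instants().items():
                if idx is None:
                    continue
                at[name] = {
                    **{f"F{ax}": float(self.F_conv[joint][idx, k])
                       for k, ax in enumerate("xyz")},
                    **{f"M{ax}": float(self.M_conv[joint][idx, k])
                       for k, ax in enumerate("xyz")},
                }
            d["at_instants"] = at
            out[joint] = d
        return out


def _tau_inertial(R: np.ndarray, I_loc: np.ndarray, omega: np.ndarray,
                  alpha: np.ndarray) -> np.ndarray:
    I_lab = R @ I_loc @ np.swapaxes(R, 1, 2)
    Iw = np.einsum("nij,nj->ni", I_lab, omega)
    Ia = np.einsum("nij,nj->ni", I_lab, alpha)
    return Ia + np.cross(omega, Iw)


def inverse_dynamics(frames: SegmentFrames, motion: SegmentMotion,
                     inertia: SegmentInertia, rim: HandrimKineticSeries,
                     geometry: WheelchairGeometry, grip_xyz: np.ndarray,
                     side: str = "right") -> JointKinetics:
    """Newton-Euler recursion from the measured rim load to the shoulder.

    ``grip_xyz`` is the lab trajectory of the hand's rim-contact landmark
    (the third metacarpal marker); the axle position is taken from the
    geometry when given, otherwise fitted from the grip path during force
    application.
    """
    n = frames.n_samples
    if rim.n_samples != n or len(grip_xyz) != n:
        raise ValueError(
            f"misaligned inputs: frames {n}, rim {rim.n_samples}, "
            f"grip {len(grip_xyz)} samples"
        )
    if geometry.axle_position is not None:
        axle = np.asarray(geometry.axle_position, dtype=float)
    else:
        active = total_norm(rim.F) > 1.0
        axle, _ = estimate_axle(grip_xyz, active)
    F_ext, M_ext, app = rim_load_lab(rim, grip_xyz, axle, geometry.rim_radius)

    joints_of = {"hand": "wrist", "forearm": "elbow", "arm": "shoulder"}
    F: dict[str, np.ndarray] = {}
    M: dict[str, np.ndarray] = {}
    F_dist, M_dist, P_dist = F_ext, M_ext, app
    for seg in ("hand", "forearm", "arm"):
        joint = joints_of[seg]
        m = inertia.mass[seg]
        c = motion.com[seg]
        a = motion.acc[seg]
        P_prox = frames.origins[seg]
        tau = _tau_inertial(frames.rotations[seg], inertia.inertia_local[seg],
                            motion.omega[seg], motion.alpha[seg])
        F_prox = m * a - m * GRAVITY - F_dist
        M_prox = (tau - np.cross(P_prox - c, F_prox)
                  - np.cross(P_dist - c, F_dist) - M_dist)
        F[joint], M[joint] = F_prox, M_prox
        F_dist, M_dist, P_dist = -F_prox, -M_prox, P_prox

    sgn = 1.0 if side == "right" else -1.0
    prox_of = {"wrist": "forearm", "elbow": "arm", "shoulder": "trunk"}
    F_conv: dict[str, np.ndarray] = {}
    M_conv: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        f = F[joint]
        F_conv[joint] = np.column_stack([f[:, 0], -sgn * f[:, 1], f[:, 2]])
        Rp = frames.rotations[prox_of[joint]]
        m_lab = M[joint] if side == "right" else \
            M[joint] * np.array([-1.0, 1.0, -1.0])
        m_loc = np.einsum("nji,nj->ni", Rp, m_lab)  # project on frame axes
        # (x, z, y) axes -> (adduction, flexion, internal rotation)
        M_conv[joint] = np.column_stack([m_loc[:, 0], m_loc[:, 2], m_loc[:, 1]])
    return JointKinetics(F, M, F_conv, M_conv, motion.rate, side)


def total_norm(v: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(v, dtype=float), axis=-1)
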