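"""Forward-model generator of semicircular propulsion trials.

The simulator builds a kinematically and kinetically consistent trial of
steady treadmill propulsion, right side:

* the wheel turns at ``treadmill_speed / wheel_radius`` rad/s;
* during each push the hand rides the hand-rim over ``push_arc`` radians
  centred on the rim top; during recovery it returns along a lower path
  (cubic Hermite blend with a downward bulge, velocity-continuous at both
  ends) — the semicircular pattern;
* shoulder position is fixed; elbow position follows from two-link inverse
  kinematics of the upper arm and forearm with the elbow held
  posterior of the shoulder-wrist line;
* all 15 model markers are placed rigidly on their segment frames;
* the push force has a half-sine total-force profile split into a
  tangential share and a radial remainder, written in the wheel sensor
  frame so the standard tangential-force formula recovers it, with the
  axle moment equal to rim radius times tangential force.

Ground truth (event indices, hand rim angle, segment frames, joint angles,
hand load) is recorded before noise.  :func:`forward_loads` computes
ground-truth joint kinetics with a self-contained Newton-Euler
implementation, deliberately sharing no code with the analysis modules so
it can serve as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import (Anthropometry, HandrimKineticSeries, MarkerFrameSeries,
                      StudyConfig, WheelchairGeometry)
from .upperlimb_model import SegmentFrames, SegmentInertia

__all__ = ["SimParams", "SyntheticTruth", "SyntheticTrial",
           "simulate_propulsion", "forward_loads", "group_params"]

_G = np.array([0.0, 0.0, -9.81])


@dataclass
class SimParams:
    """Study conditions of a simulated trial.

    Defaults reproduce the protocol: 0.833 m/s treadmill speed on a 600 mm
    wheel, cadence 1.25 strokes/s, a push arc of 0.97 rad centred on the
    rim top (push phase ~0.35 s), peak total rim force 47 N with 76 %
    tangential share.  Noise defaults: 1 mm marker, 0.5 N force.
    """

    treadmill_speed: float = 0.833
    wheel_diameter: float = 0.600
    rim_radius: float = 0.26
    cadence: float = 1.25
    push_arc: float = 0.97
    peak_total_force: float = 47.0
    tangential_share: float = 0.76
    anthropometry: Anthropometry = field(
        default_factory=lambda: Anthropometry.from_body(75.0, 1.75))
    noise_sd_marker: float = 0.001
    noise_sd_force: float = 0.5
    seed: int = 0
    rim_rate: float = 240.0
    marker_rate: float = 50.0
    # lab geometry: wheel axle at the origin, shoulder fixed relative to it
    axle: tuple[float, float, float] = (0.0, -0.28, 0.0)
    shoulder_offset: tuple[float, float, float] = (-0.05, 0.05, 0.55)
    recovery_dip: float = 0.10  # m the hand drops below the chord mid-recovery
    grip_length: float = 0.07   # m from wrist centre to the rim-contact landmark

    def __post_init__(self) -> None:
        if not 0 < self.tangential_share <= 1:
            raise ValueError("tangential_share must be in (0, 1]")
        if not 0 < self.push_arc < math.pi:
            raise ValueError("push_arc must be in (0, pi)")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.push_duration >= self.cycle_duration:
            raise ValueError(
                f"push arc {self.push_arc} rad at wheel speed "
                f"{self.wheel_omega:.3f} rad/s takes {self.push_duration:.3f} s, "
                f"longer than the cycle {self.cycle_duration:.3f} s"
            )

    @property
    def wheel_radius(self) -> float:
        return self.wheel_diameter / 2

    @property
    def wheel_omega(self) -> float:
        return self.treadmill_speed / self.wheel_radius

    @property
    def cycle_duration(self) -> float:
        return 1.0 / self.cadence

    @property
    def push_duration(self) -> float:
        return self.push_arc / self.wheel_omega

    def geometry(self) -> WheelchairGeometry:
        return WheelchairGeometry(self.wheel_diameter, self.rim_radius,
                                  axle_position=np.asarray(self.axle))


@dataclass
class SyntheticTruth:
    """Noise-free ground truth recorded by the generator (at the rim rate)."""

    rate: float
    push_on_idx: np.ndarray    # 1 Nm threshold crossings, rising
    push_off_idx: np.ndarray   # falling
    hand_on_idx: np.ndarray    # geometric rim contact (push phase start)
    apex_idx: np.ndarray       # hand at the rim top, one per push
    zeta: np.ndarray           # hand rim angle from top, rad, (n,)
    frames: SegmentFrames
    joint_angles: dict[str, np.ndarray]   # named traces, degrees
    F_on_hand: np.ndarray      # lab-frame external force on the hand (n, 3)
    app_point: np.ndarray      # its application point (n, 3)
    markers_clean: MarkerFrameSeries
    rim_clean: HandrimKineticSeries


@dataclass
class SyntheticTrial:
    markers: MarkerFrameSeries
    rim: HandrimKineticSeries
    truth: SyntheticTruth
    params: SimParams

    @property
    def geometry(self) -> WheelchairGeometry:
        return self.params.geometry()


# ---------------------------------------------------------------------------
# kinematic construction
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _septic_matrix() -> np.ndarray:
    """Constraint matrix for a degree-7 polynomial with value and first
    three derivatives prescribed at s = 0 and s = 1."""
    A = np.zeros((8, 8))
    for d in range(4):
        for kk in range(d, 8):
            coef = math.factorial(kk) / math.factorial(kk - d)
            A[4 + d, kk] = coef                # d-th derivative at s = 1
            if kk == d:
                A[d, kk] = coef                # d-th derivative at s = 0
    return A


def _hand_path(t: np.ndarray, p: SimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rim-contact point C(t), its rim angle from top, and the hand
    (grip) direction angle, all C3-continuous in time."""
    T = p.cycle_duration
    Tp = p.push_duration
    om = p.wheel_omega
    r = p.rim_radius
    axle = np.asarray(p.axle)
    z_on = -p.push_arc / 2
    z_off = p.push_arc / 2
    phase = np.mod(t, T)
    in_push = phase < Tp

    def on_rim(z):
        return np.stack([r * np.sin(z), np.zeros_like(z), r * np.cos(z)], axis=-1)

    C = np.empty((len(t), 3))
    zeta = np.empty(len(t))
    zeta[in_push] = z_on + om * phase[in_push]
    C[in_push] = on_rim(zeta[in_push])

    # recovery: C2-continuous quintic Hermite from release back to contact,
    # matching rim velocity and centripetal acceleration at both ends, with
    # a downward bulge whose window vanishes to second order at the ends
    s = (phase[~in_push] - Tp) / (T - Tp)
    Tr = T - Tp
    tan = lambda z: np.array([np.cos(z), 0.0, -np.sin(z)])
    rad = lambda z: np.array([np.sin(z), 0.0, np.cos(z)])
    # degree-7 polynomial in s matching position, velocity, centripetal
    # acceleration and jerk of the rim motion at both ends (C3 overall)
    bc = np.stack([
        on_rim(np.array([z_off]))[0],
        Tr * om * r * tan(z_off),
        Tr**2 * (-om**2 * r) * rad(z_off),
        Tr**3 * (-om**3 * r) * tan(z_off),
        on_rim(np.array([z_on]))[0],
        Tr * om * r * tan(z_on),
        Tr**2 * (-om**2 * r) * rad(z_on),
        Tr**3 * (-om**3 * r) * tan(z_on),
    ])
    A = _septic_matrix()
    coeffs = np.linalg.solve(A, bc)  # (8, 3)
    V = np.vander(s, 8, increasing=True)
    rec = V @ coeffs
    rec[:, 2] -= p.recovery_dip * 256 * s**4 * (1 - s)**4
    C[~in_push] = rec
    zeta[~in_push] = np.arctan2(rec[:, 0], rec[:, 2])
    C += axle

    # grip-direction angle: rides the rim tangent during the push, relaxes
    # back along its own C3 interpolant during recovery (the hand is free,
    # so its orientation need not track the rim geometry there)
    chi = np.empty(len(t))
    chi[in_push] = zeta[in_push]
    bc_chi = np.array([z_off, Tr * om, 0.0, 0.0, z_on, Tr * om, 0.0, 0.0])
    chi[~in_push] = V @ np.linalg.solve(A, bc_chi)
    return C, zeta, chi


def _frame_y(y0: np.ndarray, z0: np.ndarray) -> np.ndarray:
    y = _unit(y0)
    z = _unit(z0 - np.sum(z0 * y, axis=-1, keepdims=True) * y)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


#: marker local coordinates in their segment frame [x ant, y long-prox, z lat]
_ARM_LOCALS = {"rm1": (0.03, -0.10, 0.03), "rm2": (0.05, -0.14, 0.02),
               "rm3": (0.02, -0.18, 0.05)}
_HAND_LOCALS = {"ulr": (0.0, 0.0, -0.03), "rdl": (0.0, 0.0, 0.03),
                "2m": (0.01, -0.06, 0.02), "3m": (0.0, -0.07, 0.0),
                "5m": (0.0, -0.05, -0.02)}


def _pose_at(t: np.ndarray, p: SimParams) -> dict:
    """All segment frames and marker positions at the given times."""
    n = len(t)
    axle = np.asarray(p.axle)
    S = axle + np.asarray(p.shoulder_offset)
    L1 = p.anthropometry.arm.length
    L2 = p.anthropometry.forearm.length

    C, zeta, chi = _hand_path(t, p)
    h_hat = np.stack([np.cos(chi), np.zeros(n), -np.sin(chi)], axis=-1)
    W = C - p.grip_length * h_hat

    # two-link inverse kinematics, elbow posterior of the shoulder-wrist line
    SW = W - S
    d = np.linalg.norm(SW, axis=-1)
    if np.any(d > 0.98 * (L1 + L2)) or np.any(d < abs(L1 - L2) + 1e-3):
        raise ValueError(
            f"hand position unreachable: |S-W| in [{d.min():.3f}, {d.max():.3f}] m "
            f"for segment lengths {L1:.3f} + {L2:.3f} m"
        )
    u = SW / d[:, None]
    x_lab = np.array([1.0, 0.0, 0.0])
    w = x_lab - np.sum(u * x_lab, axis=-1, keepdims=True) * u
    w = _unit(w)
    a = (L1**2 - L2**2 + d**2) / (2 * d)
    h = np.sqrt(np.maximum(L1**2 - a**2, 0.0))
    E = S + a[:, None] * u - h[:, None] * w

    # lateral (rightward) normal of the arm plane
    m_hat = _unit(np.cross(u, w))

    # segment frames
    R_arm = _frame_y(S - E, m_hat)
    R_hand = _frame_y(-h_hat, m_hat)

    # markers
    pos = {}
    pos["hha"] = np.broadcast_to(S + np.array([0.035, 0.0, 0.0]), (n, 3))
    pos["hhp"] = np.broadcast_to(S + np.array([-0.035, 0.0, 0.0]), (n, 3))
    pos["c7"] = np.broadcast_to(S + np.array([-0.08, 0.20, 0.05]), (n, 3))
    pos["acrr"] = np.broadcast_to(S + np.array([0.0, 0.03, 0.04]), (n, 3))
    pos["acrl"] = np.broadcast_to(S + np.array([0.0, 0.39, 0.04]), (n, 3))
    for lab, loc in _ARM_LOCALS.items():
        pos[lab] = S + R_arm @ np.asarray(loc)
    pos["epc"] = E + 0.035 * m_hat
    pos["ipc"] = E - 0.035 * m_hat
    for lab, loc in _HAND_LOCALS.items():
        pos[lab] = W + R_hand @ np.asarray(loc)

    # trunk frame from its (static) markers
    z0 = pos["acrr"] - pos["acrl"]
    x0 = 0.5 * (pos["acrr"] + pos["acrl"]) - pos["c7"]
    zt = _unit(z0)
    xt = _unit(x0 - np.sum(x0 * zt, axis=-1, keepdims=True) * zt)
    R_trunk = np.stack([xt, np.cross(zt, xt), zt], axis=-1)

    # truth forearm frame follows the model definition: longitudinal from
    # wrist to elbow centre, lateral axis from the styloid line
    R_fa = _frame_y(E - W, pos["rdl"] - pos["ulr"])

    frames = SegmentFrames(
        origins={"trunk": pos["c7"].copy(), "arm": np.broadcast_to(S, (n, 3)).copy(),
                 "forearm": E, "hand": W},
        rotations={"trunk": R_trunk, "arm": R_arm, "forearm": R_fa,
                   "hand": R_hand},
        rate=0.0,  # set by caller
    )
    return {"C": C, "zeta": zeta, "W": W, "E": E, "S": S,
            "frames": frames, "markers": pos, "m_hat": m_hat}


# independent Euler extraction (used only for ground truth)

def _euler_yxy(R: np.ndarray) -> np.ndarray:
    b = np.arccos(np.clip(R[..., 1, 1], -1.0, 1.0))
    a = np.arctan2(R[..., 0, 1], R[..., 2, 1])
    c = np.arctan2(R[..., 1, 0], -R[..., 1, 2])
    return np.degrees(np.stack([a, b, c], axis=-1))


def _euler_zxy(R: np.ndarray) -> np.ndarray:
    b = np.arcsin(np.clip(R[..., 2, 1], -1.0, 1.0))
    a = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    c = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    return np.degrees(np.stack([a, b, c], axis=-1))


def _truth_angles(frames: SegmentFrames) -> dict[str, np.ndarray]:
    rel = lambda p, q: np.swapaxes(frames.rotations[p], 1, 2) @ frames.rotations[q]
    sh = _euler_yxy(rel("trunk", "arm"))
    el = _euler_zxy(rel("arm", "forearm"))
    wr = _euler_zxy(rel("forearm", "hand"))
    unw = lambda x: np.unwrap(x, axis=0, period=360.0)
    sh, el, wr = unw(sh), unw(el), unw(wr)
    return {
        "beta_sh": sh[:, 0], "alpha_sh": -sh[:, 1], "gamma_sh": sh[:, 2],
        "gamma_e": el[:, 0], "beta_e": el[:, 2],
        "gamma_wr": wr[:, 0], "alpha_wr": wr[:, 1], "beta_wr": wr[:, 2],
    }


# ---------------------------------------------------------------------------
# kinetics and assembly
# ---------------------------------------------------------------------------

def simulate_propulsion(params: SimParams, duration: float = 5.2) -> SyntheticTrial:
    """Generate one synchronized trial (markers + rim kinetics + truth)."""
    p = params
    if duration < 2 * p.cycle_duration:
        raise ValueError("duration must cover at least two cycles")
    rng = np.random.default_rng(p.seed)
    n = int(round(duration * p.rim_rate))
    t = np.arange(n) / p.rim_rate
    T, Tp, om, r = p.cycle_duration, p.push_duration, p.wheel_omega, p.rim_radius

    pose = _pose_at(t, p)
    pose["frames"].rate = p.rim_rate
    zeta = pose["zeta"]

    # force profile: half-sine in total force over each push
    phase = np.mod(t, T)
    in_push = phase < Tp
    ftot = np.where(in_push, p.peak_total_force * np.sin(np.pi * phase / Tp), 0.0)
    ftang = p.tangential_share * ftot
    frad_in = math.sqrt(1.0 - p.tangential_share**2) * ftot

    # wheel encoder angle; zero reference at the backward horizontal, rim
    # top at pi/2, aligned with the hand angle at the first contact
    theta = (math.pi / 2 - p.push_arc / 2) + om * t
    F_sw = np.stack([
        -ftang * np.sin(theta) - frad_in * np.cos(theta),
        ftang * np.cos(theta) - frad_in * np.sin(theta),
        np.zeros(n),
    ], axis=-1)
    M_sw = np.stack([np.zeros(n), np.zeros(n), r * ftang], axis=-1)

    # lab-frame load on the hand (reaction of the rim force), at the contact
    t_hat = np.stack([np.cos(zeta), np.zeros(n), -np.sin(zeta)], axis=-1)
    p_hat = np.stack([np.sin(zeta), np.zeros(n), np.cos(zeta)], axis=-1)
    F_on_hand = -(ftang[:, None] * t_hat - frad_in[:, None] * p_hat)

    # analytic 1 Nm crossings of the axle moment
    mz_peak = r * p.tangential_share * p.peak_total_force
    push_on, push_off, hand_on, apex = [], [], [], []
    k = 0
    while (k * T) < duration - 1e-9:
        t_on_k = k * T
        if t_on_k + Tp > duration:
            break
        if mz_peak > 1.0:
            dt_cross = (Tp / math.pi) * math.asin(1.0 / mz_peak)
            i_on = int(math.ceil((t_on_k + dt_cross) * p.rim_rate))
            i_off = int(math.ceil((t_on_k + Tp - dt_cross) * p.rim_rate))
            if i_off < n:
                push_on.append(i_on)
                push_off.append(i_off)
        hand_on.append(int(round(t_on_k * p.rim_rate)))
        t_apex = t_on_k + (p.push_arc / 2) / om
        apex.append(int(round(t_apex * p.rim_rate)))
        k += 1

    rim_clean = HandrimKineticSeries(F_sw, M_sw, theta, p.rim_rate, "right")

    # markers on their own clock
    n_m = int(round(duration * p.marker_rate))
    t_m = np.arange(n_m) / p.marker_rate
    pose_m = _pose_at(t_m, p)
    order = [lab for lab in
             ("c7", "acrr", "acrl", "hha", "hhp", "rm1", "rm2", "rm3",
              "epc", "ipc", "ulr", "rdl", "2m", "3m", "5m")]
    mk = np.stack([np.asarray(pose_m["markers"][lab]) for lab in order], axis=1)
    markers_clean = MarkerFrameSeries(tuple(order), mk.copy(), p.marker_rate)

    truth = SyntheticTruth(
        rate=p.rim_rate,
        push_on_idx=np.asarray(push_on), push_off_idx=np.asarray(push_off),
        hand_on_idx=np.asarray(hand_on), apex_idx=np.asarray(apex),
        zeta=zeta, frames=pose["frames"],
        joint_angles=_truth_angles(pose["frames"]),
        F_on_hand=F_on_hand, app_point=pose["C"],
        markers_clean=markers_clean, rim_clean=rim_clean,
    )

    mk_noisy = mk + rng.normal(0.0, p.noise_sd_marker, mk.shape) \
        if p.noise_sd_marker > 0 else mk.copy()
    F_noisy = F_sw + rng.normal(0.0, p.noise_sd_force, F_sw.shape) \
        if p.noise_sd_force > 0 else F_sw.copy()
    M_noisy = M_sw + rng.normal(0.0, p.noise_sd_force * r, M_sw.shape) \
        if p.noise_sd_force > 0 else M_sw.copy()

    return SyntheticTrial(
        markers=MarkerFrameSeries(tuple(order), mk_noisy, p.marker_rate),
        rim=HandrimKineticSeries(F_noisy, M_noisy, theta.copy(), p.rim_rate, "right"),
        truth=truth, params=p,
    )


# ---------------------------------------------------------------------------
# independent forward Newton-Euler oracle
# ---------------------------------------------------------------------------

def forward_loads(trial: SyntheticTrial, inertia: SegmentInertia) -> dict:
    """Ground-truth joint loads from the noise-free trial.

    Self-contained Newton-Euler pass (hand, then forearm, then upper arm)
    over the truth kinematics.  Angular velocity comes from incremental
    rotation vectors, a different algorithm than the analysis module uses.
    Returns ``{joint: {"F": (n,3), "M": (n,3)}}`` in the lab frame.
    """
    from scipy.spatial.transform import Rotation

    fr = trial.truth.frames
    rate = trial.truth.rate
    n = fr.n_samples
    dt = 1.0 / rate

    out: dict[str, dict[str, np.ndarray]] = {}
    F_dist = trial.truth.F_on_hand.copy()
    M_dist = np.zeros((n, 3))
    P_dist = trial.truth.app_point.copy()

    chain = (("hand", "wrist"), ("forearm", "elbow"), ("arm", "shoulder"))
    for seg, joint in chain:
        m = inertia.mass[seg]
        L = inertia.length[seg]
        cf = inertia.com_fraction[seg]
        R = fr.rotations[seg]
        org = fr.origins[seg]
        com = org + (R @ np.array([0.0, -cf * L, 0.0]))

        acc = np.empty_like(com)
        acc[1:-1] = (com[2:] - 2 * com[1:-1] + com[:-2]) / dt**2
        acc[0], acc[-1] = acc[1], acc[-2]

        # angular velocity from incremental rotation vectors over 2*dt
        w = np.empty((n, 3))
        dR = R[2:] @ np.swapaxes(R[:-2], 1, 2)
        w[1:-1] = Rotation.from_matrix(dR).as_rotvec() / (2 * dt)
        w[0], w[-1] = w[1], w[-2]
        dw = np.empty_like(w)
        dw[1:-1] = (w[2:] - w[:-2]) / (2 * dt)
        dw[0], dw[-1] = dw[1], dw[-2]

        I_loc = inertia.inertia_local[seg]
        I_lab = R @ I_loc @ np.swapaxes(R, 1, 2)
        tau = np.einsum("nij,nj->ni", I_lab, dw) \
            + np.cross(w, np.einsum("nij,nj->ni", I_lab, w))

        F_prox = m * acc - m * _G - F_dist
        M_prox = (tau - np.cross(org - com, F_prox)
                  - np.cross(P_dist - com, F_dist) - M_dist)
        out[joint] = {"F": F_prox, "M": M_prox}
        F_dist, M_dist, P_dist = -F_prox, -M_prox, org
    return out


# ---------------------------------------------------------------------------
# two-group fixture kit
# ---------------------------------------------------------------------------

def group_params(group: str, subject: int, base_seed: int = 0) -> SimParams:
    """Per-subject simulation parameters for the two study groups.

    Group "P" pushes with a lower force scale (~47 N peak, high tangential
    share), group "T" with a higher scale (~93 N peak, low share), echoing
    the contrast between paraplegic and tetraplegic propulsion.  Subject
    seeds add reproducible between-subject variation.
    """
    if group not in ("P", "T"):
        raise ValueError("group must be 'P' or 'T'")
    rng = np.random.default_rng([base_seed, {"P": 0, "T": 1}[group], subject])
    if group == "P":
        peak, share, cad = 47.0, 0.76, 1.25
    else:
        peak, share, cad = 93.0, 0.49, 1.05
    return SimParams(
        cadence=cad * float(rng.uniform(0.9, 1.1)),
        peak_total_force=peak * float(rng.uniform(0.85, 1.15)),
        tangential_share=min(0.95, share * float(rng.uniform(0.9, 1.1))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
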