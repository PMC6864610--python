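"""Push detection, cycle segmentation, propulsion instants and
temporal-spatial variables.

A push starts when the filtered rim moment about the axle rises above a
threshold (1 Nm by default) and ends when it falls back below it.  A
propulsion cycle runs from one hand-on (HO) to the next; within it five
instants are located:

HO  hand on          first rim contact (push onset)
TC  top centre       hand closest to the top of the rim during the push
HR  hand release     end of rim contact (push offset)
FT  follow-through   most anterior hand position in the cycle
AR  arm preparation  most posterior hand position in the cycle

Cycles are time-normalized to 0-100 % for averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import StudyConfig, WheelchairGeometry

__all__ = [
    "PropulsionCycle", "TemporalSpatial", "detect_pushes", "segment_cycles",
    "select_cycles", "locate_instants", "normalize_cycle", "temporal_spatial",
]

INSTANT_NAMES = ("HO", "TC", "HR", "FT", "AR")


@dataclass
class PropulsionCycle:
    """One HO -> HO propulsion cycle (all indices into the aligned series)."""

    i_HO: int
    i_HR: int
    i_end: int          # index of the next hand-on
    rate: float
    i_TC: int | None = None
    i_FT: int | None = None
    i_AR: int | None = None

    def __post_init__(self) -> None:
        if not (self.i_HO < self.i_HR <= self.i_end):
            raise ValueError(
                f"need i_HO < i_HR <= i_end, got {self.i_HO}, {self.i_HR}, {self.i_end}"
            )
        if self.i_TC is not None and not (self.i_HO <= self.i_TC <= self.i_HR):
            raise ValueError("i_TC must lie within the push phase")

    @property
    def Pphase(self) -> float:
        return (self.i_HR - self.i_HO) / self.rate

    @property
    def Rphase(self) -> float:
        return (self.i_end - self.i_HR) / self.rate

    @property
    def duration(self) -> float:
        return (self.i_end - self.i_HO) / self.rate

    def instants(self) -> dict[str, int | None]:
        return {"HO": self.i_HO, "TC": self.i_TC, "HR": self.i_HR,
                "FT": self.i_FT, "AR": self.i_AR}


@dataclass
class TemporalSpatial:
    """Per-condition temporal-spatial summary (means over selected cycles)."""

    PF: float              # cadence, strokes/s
    Pphase: float          # s
    Rphase: float          # s
    ratio: float           # mean Pphase / mean Rphase
    Dist: float            # m travelled per cycle
    CA: float              # contact angle, degrees
    RA: float              # release angle, degrees
    per_cycle_ratio: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.PF <= 0:
            raise ValueError("PF must be positive")
        if self.Dist < 0:
            raise ValueError("Dist must be non-negative")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"PF": self.PF, "Dist": self.Dist, "Pphase": self.Pphase,
                "Rphase": self.Rphase, "Pphase/Rphase": self.ratio,
                "CA": self.CA, "RA": self.RA}


def detect_pushes(rim_moment: np.ndarray, threshold: float, rate: float,
                  min_duration_s: float = 0.1) -> list[tuple[int, int]]:
    """Threshold-scan the axle moment for push on/off index pairs.

    ``i_on`` is the first sample strictly above the threshold, ``i_off`` the
    next sample strictly below it; samples exactly at the threshold keep the
    current state.  A trailing push with no off-crossing is discarded, as
    are pushes shorter than ``min_duration_s`` (debounce).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    m = np.asarray(rim_moment, dtype=float)
    pushes: list[tuple[int, int]] = []
    in_push = False
    i_on = 0
    for i, v in enumerate(m):
        if not in_push and v > threshold:
            in_push, i_on = True, i
        elif in_push and v < threshold:
            in_push = False
            pushes.append((i_on, i))
    # trailing incomplete push (in_push still True) is dropped
    min_len = min_duration_s * rate
    return [(a, b) for a, b in pushes if (b - a) >= min_len]


def segment_cycles(pushes: list[tuple[int, int]], series_length: int,
                   rate: float) -> list[PropulsionCycle]:
    """One cycle per consecutive push pair: HO_k -> HO_{k+1}."""
    cycles = []
    for (a, b), (a2, _b2) in zip(pushes, pushes[1:]):
        if a2 > series_length:
            break
        cycles.append(PropulsionCycle(i_HO=a, i_HR=b, i_end=a2, rate=rate))
    return cycles


def select_cycles(cycles: list[PropulsionCycle], window: tuple[float, float],
                  n: int) -> list[PropulsionCycle]:
    """First ``n`` consecutive cycles lying fully inside the time window."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t0, t1 = window
    inside = [c for c in cycles
              if c.i_HO / c.rate >= t0 and c.i_end / c.rate <= t1]
    if len(inside) < n:
        raise ValueError(
            f"need {n} cycles inside window [{t0}, {t1}] s, found {len(inside)}"
        )
    return inside[:n]


def locate_instants(cycle: PropulsionCycle, hand_xyz: np.ndarray) -> PropulsionCycle:
    """Fill in TC, FT and AR from the hand-marker trajectory.

    TC is the push-phase sample where the hand is highest (closest to the
    top of the rim); FT/AR are the most anterior / most posterior hand
    positions over the whole cycle.  Ties break to the earliest index.
    """
    hand_xyz = np.asarray(hand_xyz, dtype=float)
    if cycle.i_end >= len(hand_xyz):
        raise ValueError("cycle indices exceed hand trajectory length")
    push = hand_xyz[cycle.i_HO : cycle.i_HR + 1]
    i_TC = cycle.i_HO + int(np.argmax(push[:, 2]))
    cyc = hand_xyz[cycle.i_HO : cycle.i_end + 1]
    i_FT = cycle.i_HO + int(np.argmax(cyc[:, 0]))
    i_AR = cycle.i_HO + int(np.argmin(cyc[:, 0]))
    return PropulsionCycle(cycle.i_HO, cycle.i_HR, cycle.i_end, cycle.rate,
                           i_TC=i_TC, i_FT=i_FT, i_AR=i_AR)


def normalize_cycle(series: np.ndarray, cycle: PropulsionCycle,
                    n_points: int = 101) -> np.ndarray:
    """Resample the HO -> next-HO span onto equally spaced % -cycle stations.

    Linear interpolation; the first and last stations reproduce the raw
    values at HO and the next HO exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    y = np.asarray(series, dtype=float)[cycle.i_HO : cycle.i_end + 1]
    if len(y) < 2:
        raise ValueError("cycle span must cover at least 2 samples")
    src = np.arange(len(y))
    stations = np.linspace(0.0, len(y) - 1, n_points)
    if y.ndim == 1:
        return np.interp(stations, src, y)
    return np.column_stack([np.interp(stations, src, y[:, k])
                            for k in range(y.shape[1])])


def _rim_angle_deg(theta: float, reference: str) -> float:
    """Map an unwrapped wheel angle to the configured reporting convention.

    The dialect fixes the encoder zero at the backward horizontal, with the
    angle increasing in the direction of forward rotation (the rim top is
    at 90 degrees).  ``backward_horizontal`` reports that angle in
    [0, 360); ``top_dead_center`` reports the signed angle from the top in
    [-180, 180).
    """
    deg = np.degrees(theta) % 360.0
    if reference == "backward_horizontal":
        return float(deg)
    if reference == "top_dead_center":
        return float((deg - 90.0 + 180.0) % 360.0 - 180.0)
    raise ValueError(f"unknown angle reference {reference!r}")


def temporal_spatial(cycles: list[PropulsionCycle], theta: np.ndarray,
                     geometry: WheelchairGeometry, config: StudyConfig,
                     contact_angle: np.ndarray | None = None) -> TemporalSpatial:
    """Cadence, phase durations, distance per cycle and contact/release angles.

    ``Dist`` is the wheel-radius-scaled rotation over a cycle, averaged over
    the selected cycles; CA/RA are the rim angles at HO and HR in the
    configured reference, in degrees, averaged over cycles.  When
    ``contact_angle`` is given (the hand's rim angle from the markers, same
    zero reference as theta: backward horizontal, rim top at pi/2) it is
    used for CA/RA instead of the encoder angle, which only tracks the
    hand while it grips the rim.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    theta = np.asarray(theta, dtype=float)
    ca_src = theta if contact_angle is None else np.asarray(contact_angle, float)
    total = sum(c.duration for c in cycles)
    pf = len(cycles) / total
    p = float(np.mean([c.Pphase for c in cycles]))
    r = float(np.mean([c.Rphase for c in cycles]))
    dist = float(np.mean(
        [abs(theta[c.i_end] - theta[c.i_HO]) for c in cycles]
    )) * geometry.wheel_radius
    ca = float(np.mean([_rim_angle_deg(ca_src[c.i_HO], config.angle_reference)
                        for c in cycles]))
    ra = float(np.mean([_rim_angle_deg(ca_src[c.i_HR], config.angle_reference)
                        for c in cycles]))
    per_ratio = tuple(c.Pphase / c.Rphase for c in cycles if c.Rphase > 0)
    return TemporalSpatial(PF=pf, Pphase=p, Rphase=r, ratio=p / r,
                           Dist=dist, CA=ca, RA=ra, per_cycle_ratio=per_ratio)
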