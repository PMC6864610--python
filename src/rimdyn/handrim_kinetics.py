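"""Hand-rim kinetic variables over the push phase.

With F = (F_x, F_y, F_z) the force the hand applies to the rim in the wheel
sensor frame and theta the wheel angle:

    Ftot  = sqrt(Fx^2 + Fy^2 + Fz^2)          total force, N
    Ftang = -Fx sin(theta) + Fy cos(theta)     tangential (propulsive), N
    Feff  = Ftang / Ftot                       effective force fraction
    ERF   = max d(Ftot)/dt during force rise   elevation rate, N/s
    Mtot  = |M|, ERM = max d(Mtot)/dt          moment counterparts
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events_cycles import INSTANT_NAMES, PropulsionCycle
from .io_core import HandrimKineticSeries

__all__ = ["HandrimSummary", "total_force", "tangential_force",
           "effective_force", "elevation_rate", "summarize_handrim"]

#: samples with total force below this are excluded from the Feff ratio
LOW_FORCE_CUTOFF_N = 1.0


@dataclass
class HandrimSummary:
    """Push-phase kinetic summary for one propulsion cycle."""

    Ftot_max: float
    Ftang_max: float
    Feff: float
    ERF: float
    Mtot_max: float
    ERM: float
    at_instants: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Ftot_max < abs(self.Ftang_max) - 1e-9:
            raise ValueError("Ftot_max must dominate |Ftang_max|")
        if abs(self.Feff) > 1 + 1e-9:
            raise ValueError("|Feff| cannot exceed 1")
        if self.Mtot_max < 0:
            raise ValueError("Mtot_max must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"Ftotmax": self.Ftot_max, "Ftangmax": self.Ftang_max,
                "Feff": self.Feff, "ERF": self.ERF,
                "Mtotmax": self.Mtot_max, "ERM": self.ERM}


def total_force(F: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of the rim force."""
    F = np.asarray(F, dtype=float)
    return np.linalg.norm(F, axis=-1)


def tangential_force(F: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Tangential force -Fx sin(theta) + Fy cos(theta), pointwise."""
    F = np.asarray(F, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if F.shape[:-1] != theta.shape:
        raise ValueError(
            f"F and theta length mismatch: {F.shape[0]} vs {theta.shape[0]}"
        )
    return -F[..., 0] * np.sin(theta) + F[..., 1] * np.cos(theta)


def effective_force(F: np.ndarray, theta: np.ndarray,
                    push: slice | tuple[int, int]) -> float:
    """Mean push-phase fraction of the force that is tangential.

    Samples with total force below 1 N are excluded so the ratio does not
    blow up at the push edges.
    """
    if isinstance(push, tuple):
        push = slice(push[0], push[1])
    Fp = np.asarray(F, dtype=float)[push]
    tp = np.asarray(theta, dtype=float)[push]
    if Fp.shape[0] == 0:
        raise ValueError("push range is empty")
    tot = total_force(Fp)
    keep = tot >= LOW_FORCE_CUTOFF_N
    if not keep.any():
        raise ValueError(
            f"no push sample exceeds {LOW_FORCE_CUTOFF_N} N total force"
        )
    tang = tangential_force(Fp, tp)
    return float(np.mean(tang[keep] / tot[keep]))


def elevation_rate(x: np.ndarray, rate: float,
                   push: slice | tuple[int, int]) -> float:
    """Peak rate of rise during loading: max central-difference derivative
    between push onset and the in-push peak of the signal."""
    if isinstance(push, tuple):
        push = slice(push[0], push[1])
    xp = np.asarray(x, dtype=float)[push]
    if len(xp) < 3:
        raise ValueError(f"push range needs >= 3 samples, got {len(xp)}")
    i_peak = int(np.argmax(xp))
    rising = xp[: max(i_peak + 1, 3)]
    d = np.gradient(rising) * rate
    return float(np.max(d))


def summarize_handrim(rim: HandrimKineticSeries,
                      cycle: PropulsionCycle) -> HandrimSummary:
    """All push-phase kinetic variables of one cycle, plus the force and
    moment values at the five propulsion instants."""
    if cycle.i_end >= rim.n_samples:
        raise ValueError("cycle indices exceed rim series length")
    push = slice(cycle.i_HO, cycle.i_HR + 1)
    ftot = total_force(rim.F)
    ftang = tangential_force(rim.F, rim.theta)
    mtot = total_force(rim.M)
    if np.max(ftot[push]) < LOW_FORCE_CUTOFF_N:
        raise ValueError("no force applied during the nominal push phase")

    at: dict[str, dict[str, float]] = {}
    for name, idx in cycle.instants().items():
        if idx is None:
            continue
        at[name] = {
            "Ftot": float(ftot[idx]), "Ftang": float(ftang[idx]),
            "Mtot": float(mtot[idx]),
            "Fx": float(rim.F[idx, 0]), "Fy": float(rim.F[idx, 1]),
            "Fz": float(rim.F[idx, 2]),
            "Mx": float(rim.M[idx, 0]), "My": float(rim.M[idx, 1]),
            "Mz": float(rim.M[idx, 2]),
        }

    return HandrimSummary(
        Ftot_max=float(np.max(ftot[push])),
        Ftang_max=float(np.max(ftang[push])),
        Feff=effective_force(rim.F, rim.theta, push),
        ERF=elevation_rate(ftot, rim.rate, push),
        Mtot_max=float(np.max(mtot[push])),
        ERM=elevation_rate(mtot, rim.rate, push),
        at_instants=at,
    )
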