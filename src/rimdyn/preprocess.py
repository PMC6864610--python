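"""Filtering, gap interpolation and stream synchronization.

The wheel kinetics are recorded at 240 Hz and the optical markers at 50 Hz,
both started by a common trigger.  Kinetics are smoothed with a zero-phase
4th-order Butterworth low-pass at 20 Hz; marker trajectories receive the
same filter at a lower cutoff (6 Hz by default) before differentiation,
since inverse dynamics needs smooth accelerations.  The kinematic stream is
upsampled to the kinetic rate so that force rate-of-rise measures keep their
bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import interp1d

from .io_core import HandrimKineticSeries, MarkerFrameSeries

__all__ = ["AlignedTrial", "lowpass_zero_phase", "fill_gaps", "synchronize",
           "filter_handrim", "filter_markers"]


@dataclass
class AlignedTrial:
    """Marker and rim streams resampled onto one timebase."""

    markers: MarkerFrameSeries
    rim: HandrimKineticSeries
    common_rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.markers.n_samples != self.rim.n_samples:
            raise ValueError(
                "aligned streams must have equal length, got "
                f"{self.markers.n_samples} and {self.rim.n_samples}"
            )


def lowpass_zero_phase(x: np.ndarray, rate: float, cutoff: float,
                       order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    The forward-backward pass squares the filter magnitude, so a sinusoid at
    the cutoff frequency comes out with amplitude 0.5.  Edges are handled by
    reflect-padding of three times the filter order.  Works on 1-D series or
    (n, k) arrays filtered along axis 0.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= rate / 2:
        raise ValueError(
            f"cutoff ({cutoff} Hz) must be below the Nyquist frequency {rate / 2} Hz"
        )
    n = x.shape[0]
    padlen = 3 * order
    if n <= 3 * order + 1:
        raise ValueError(f"series too short to filter: {n} samples")
    b, a = signal.butter(order, cutoff, btype="low", fs=rate)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_handrim(rim: HandrimKineticSeries, cutoff: float = 20.0,
                   order: int = 4) -> HandrimKineticSeries:
    """Return a copy of the rim series with filtered forces and moments.

    The wheel angle is left untouched: it is an encoder signal and is used
    for event geometry, not differentiation.
    """
    return HandrimKineticSeries(
        lowpass_zero_phase(rim.F, rim.rate, cutoff, order),
        lowpass_zero_phase(rim.M, rim.rate, cutoff, order),
        rim.theta.copy(), rim.rate, rim.side,
    )


def filter_markers(series: MarkerFrameSeries, cutoff: float = 6.0,
                   order: int = 4) -> MarkerFrameSeries:
    """Low-pass marker trajectories (all gaps must be filled first)."""
    if series.gaps.any():
        raise ValueError("fill gaps before filtering marker trajectories")
    n, m, _ = series.positions.shape
    flat = series.positions.reshape(n, m * 3)
    out = lowpass_zero_phase(flat, series.rate, cutoff, order)
    return MarkerFrameSeries(series.labels, out.reshape(n, m, 3), series.rate)


def _interp_gap_run(t_valid: np.ndarray, y_valid: np.ndarray,
                    t_gap: np.ndarray) -> np.ndarray:
    """Interpolate one gap run from up to two valid samples on each side."""
    kind = "cubic" if len(t_valid) >= 4 else "linear"
    f = interp1d(t_valid, y_valid, kind=kind, axis=0, assume_sorted=True)
    return f(t_gap)


def fill_gaps(series: MarkerFrameSeries, max_gap_s: float = 0.1) -> MarkerFrameSeries:
    """Interpolate short gaps; long or boundary gaps stay flagged.

    Interior gap runs no longer than ``max_gap_s`` are filled with a cubic
    fit through the two nearest valid samples on each side (linear when
    fewer support points exist).  No extrapolation: runs touching either
    series boundary remain flagged.
    """
    out = series.copy()
    max_len = int(round(max_gap_s * series.rate))
    t = series.time
    for j in range(len(series.labels)):
        gap = out.gaps[:, j]
        if not gap.any():
            continue
        valid_idx = np.flatnonzero(~gap)
        if len(valid_idx) < 2:
            continue
        # contiguous gap runs
        starts = np.flatnonzero(gap & ~np.r_[False, gap[:-1]])
        for s in starts:
            e = s
            while e + 1 < len(gap) and gap[e + 1]:
                e += 1
            run = np.arange(s, e + 1)
            if len(run) > max_len:
                continue
            if s == 0 or e == len(gap) - 1:
                continue  # boundary gap: no extrapolation
            left = valid_idx[valid_idx < s][-2:]
            right = valid_idx[valid_idx > e][:2]
            support = np.r_[left, right]
            filled = _interp_gap_run(
                t[support], out.positions[support, j, :], t[run])
            out.positions[run, j, :] = filled
            out.gaps[run, j] = False
    return out


def synchronize(markers: MarkerFrameSeries, rim: HandrimKineticSeries,
                target_rate: float = 240.0) -> AlignedTrial:
    """Resample both trigger-started streams onto one timebase.

    Both streams are interpolated in time (cubic when enough samples,
    linear otherwise) onto a grid at ``target_rate`` and truncated to the
    shorter duration.  Marker gap flags propagate to any output sample
    whose interpolation bracket touches a flagged source sample.
    """
    import warnings

    if target_rate > 4 * min(markers.rate, rim.rate):
        warnings.warn(
            f"target rate {target_rate} Hz is more than 4x a source rate",
            stacklevel=2,
        )
    dur = min(markers.duration, rim.duration)
    n_out = int(np.floor((dur - 1e-12) * target_rate)) + 1
    if n_out < 2:
        raise ValueError("zero-length overlap between streams")
    t_out = np.arange(n_out) / target_rate

    def resample(t_src: np.ndarray, y: np.ndarray, kind: str = "cubic") -> np.ndarray:
        if len(t_src) < 4:
            kind = "linear"
        return interp1d(t_src, y, axis=0, kind=kind, bounds_error=False,
                        fill_value=(y[0], y[-1]), assume_sorted=True)(t_out)

    # a spline would smear NaNs from any remaining gap across the series
    pos_kind = "linear" if markers.gaps.any() else "cubic"
    pos = resample(markers.time, markers.positions.reshape(markers.n_samples, -1),
                   kind=pos_kind)
    pos = pos.reshape(n_out, len(markers.labels), 3)
    gapf = resample(markers.time, markers.gaps.astype(float), kind="linear")
    gaps = gapf > 1e-9
    pos[gaps] = np.nan
    m_out = MarkerFrameSeries(markers.labels, pos, target_rate, gaps)

    r_out = HandrimKineticSeries(
        resample(rim.time, rim.F),
        resample(rim.time, rim.M),
        resample(rim.time, rim.theta),
        target_rate, rim.side,
    )
    return AlignedTrial(m_out, r_out, target_rate)
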