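"""End-to-end analysis: streams in, study report out.

``analyze_trial`` chains the full method: filter the rim kinetics (20 Hz
zero-phase Butterworth), fill marker gaps and low-pass the trajectories
(6 Hz) for differentiation, synchronize both streams at 240 Hz, detect
pushes on the axle moment (1 Nm threshold), select five consecutive cycles,
then compute temporal-spatial variables, hand-rim kinetics, joint Euler
kinematics and Newton-Euler joint kinetics, each summarized per cycle and
averaged.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from . import events_cycles as ev
from . import handrim_kinetics as hk
from . import preprocess as pp
from .io_core import (Anthropometry, HandrimKineticSeries, MarkerFrameSeries,
                      StudyConfig, WheelchairGeometry, config_to_dict)
from .upperlimb_model import (SegmentInertia, angle_summary, build_frames,
                              derive_motion, estimate_axle, inverse_dynamics,
                              joint_angles, total_norm)

__all__ = ["analyze_trial", "flatten_report"]

#: marker used as the hand's rim-contact landmark
GRIP_MARKER = "3m"

ANGLE_VARS = ("alpha_sh", "beta_sh", "gamma_sh", "gamma_e", "beta_e",
              "alpha_wr", "beta_wr", "gamma_wr")


def _mean_dicts(dicts: list[dict]) -> dict:
    """Average numeric entries across per-cycle dicts; majority-vote tags."""
    out: dict = {}
    for key in dicts[0]:
        vals = [d[key] for d in dicts]
        if isinstance(vals[0], dict):
            out[key] = _mean_dicts(vals)
        elif isinstance(vals[0], str):
            out[key] = Counter(vals).most_common(1)[0][0]
        else:
            out[key] = float(np.mean(vals))
    return out


def analyze_trial(markers: MarkerFrameSeries, rim: HandrimKineticSeries,
                  config: StudyConfig | None = None,
                  geometry: WheelchairGeometry | None = None,
                  anthropometry: Anthropometry | None = None,
                  side: str | None = None) -> dict:
    """Run the complete analysis on one synchronized recording pair."""
    config = config or StudyConfig()
    geometry = geometry or WheelchairGeometry()
    anthropometry = anthropometry or Anthropometry.from_body(75.0, 1.75)
    side = side or rim.side
    config.validate_rates(markers.rate, rim.rate)

    rim_f = pp.filter_handrim(rim, config.filter.cutoff_hz, config.filter.order)
    mk = pp.fill_gaps(markers)
    if mk.gaps.any():
        raise ValueError(
            "marker gaps remain after interpolation; reconstruct clusters first"
        )
    mk = pp.filter_markers(mk, config.marker_filter.cutoff_hz,
                           config.marker_filter.order)
    aligned = pp.synchronize(mk, rim_f, config.sync_target_rate)
    rate = aligned.common_rate

    pushes = ev.detect_pushes(aligned.rim.M[:, 2], config.event_threshold_nm,
                              rate, config.min_push_duration_s)
    cycles = ev.segment_cycles(pushes, aligned.rim.n_samples, rate)
    cycles = ev.select_cycles(cycles, config.analysis_window, config.n_cycles)
    grip = aligned.markers.marker(GRIP_MARKER)
    cycles = [ev.locate_instants(c, grip) for c in cycles]

    # rim angle of the hand (same reference as the encoder: top at pi/2)
    if geometry.axle_position is not None:
        axle = np.asarray(geometry.axle_position, dtype=float)
    else:
        axle, _ = estimate_axle(grip, total_norm(aligned.rim.F) > 1.0)
    zeta = np.arctan2(grip[:, 0] - axle[0], grip[:, 2] - axle[2])
    ts = ev.temporal_spatial(cycles, aligned.rim.theta, geometry, config,
                             contact_angle=zeta + np.pi / 2)

    rim_summaries = [hk.summarize_handrim(aligned.rim, c) for c in cycles]

    frames = build_frames(aligned.markers, side)
    kin = joint_angles(frames)
    inertia = SegmentInertia.from_anthropometry(anthropometry)
    motion = derive_motion(frames, inertia, rate)
    kinetics = inverse_dynamics(frames, motion, inertia, aligned.rim,
                                geometry, grip, side)

    named = kin.named
    kinematics_report = {
        var: _mean_dicts([angle_summary(named[var], c) for c in cycles])
        for var in ANGLE_VARS
    }
    norm_traces = {
        var: np.mean([ev.normalize_cycle(named[var], c,
                                         config.normalization_points)
                      for c in cycles], axis=0).tolist()
        for var in ANGLE_VARS
    }
    kinetics_report = _mean_dicts([kinetics.summarize(c) for c in cycles])

    return {
        "config": config_to_dict(config),
        "side": side,
        "n_cycles": len(cycles),
        "temporal_spatial": ts.as_dict(),
        "handrim": _mean_dicts([s.as_dict() for s in rim_summaries]),
        "handrim_at_instants": _mean_dicts([s.at_instants for s in rim_summaries]),
        "kinematics": kinematics_report,
        "kinematics_normalized": norm_traces,
        "kinetics": kinetics_report,
    }


def flatten_report(report: dict) -> dict[str, float]:
    """Scalar view of a report for group statistics (dotted keys)."""
    flat: dict[str, float] = {}

    def walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
            flat[prefix] = float(obj)

    for section in ("temporal_spatial", "handrim", "kinematics", "kinetics"):
        walk(section, report.get(section, {}))
    return flat
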