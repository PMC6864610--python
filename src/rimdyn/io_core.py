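"""Data model, readers/writers and study configuration.

The pipeline touches three streams: optical marker trajectories for a reduced
15-marker upper-limb model (nominally 50 Hz), per-side instrumented-wheel
force/moment/angle recordings (nominally 240 Hz), and per-subject
anthropometry plus wheelchair geometry.  Everything is kept in SI units
(m, N, Nm, rad, s); degrees appear only at the reporting boundary.

Lab frame convention: x points in the direction of travel, y laterally
(positive to the subject's left), z up.

The on-disk marker/rim format is a deliberately simple CSV dialect:

    # rate=<Hz> [side=<left|right>] [key=value ...]
    t,<col>,<col>,...
    0.000,...

so fixtures are diff-able and bit-stable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MARKER_LABELS",
    "MARKER_SEGMENTS",
    "MarkerFrameSeries",
    "HandrimKineticSeries",
    "Anthropometry",
    "SegmentGeometry",
    "WheelchairGeometry",
    "StudyConfig",
    "read_marker_series",
    "write_marker_series",
    "read_handrim_series",
    "write_handrim_series",
    "load_study_config",
]

#: Canonical marker order for the reduced upper-limb model.
MARKER_LABELS: tuple[str, ...] = (
    "c7", "acrr", "acrl", "hha", "hhp",
    "rm1", "rm2", "rm3", "epc", "ipc",
    "ulr", "rdl", "2m", "3m", "5m",
)

#: Segment membership of each marker (trunk / arm / hand per the model table).
MARKER_SEGMENTS: dict[str, str] = {
    "c7": "trunk", "acrr": "trunk", "acrl": "trunk",
    "hha": "trunk", "hhp": "trunk",
    "rm1": "arm", "rm2": "arm", "rm3": "arm", "epc": "arm", "ipc": "arm",
    "ulr": "hand", "rdl": "hand", "2m": "hand", "3m": "hand", "5m": "hand",
}


def _canonical_order(labels: Sequence[str]) -> list[str]:
    return [lab for lab in MARKER_LABELS if lab in labels]


@dataclass
class MarkerFrameSeries:
    """Time-indexed 3-D marker positions with explicit gap flags.

    Parameters
    ----------
    labels : sequence of str
        Marker names, a subset of :data:`MARKER_LABELS`, stored in
        canonical order.
    positions : (n_samples, n_markers, 3) float array
        Positions in meters, lab frame.  Gap samples hold NaN.
    rate : float
        Sampling frequency in Hz.
    gaps : (n_samples, n_markers) bool array
        True where the marker is missing in that sample.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    rate: float
    gaps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        unknown = [lab for lab in self.labels if lab not in MARKER_LABELS]
        if unknown:
            raise ValueError(
                f"unknown marker label(s) {unknown}; allowed labels are "
                f"{list(MARKER_LABELS)}"
            )
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.labels), 3):
            raise ValueError(
                f"positions must have shape (n, {len(self.labels)}, 3), "
                f"got {self.positions.shape}"
            )
        if self.gaps is None:
            self.gaps = np.isnan(self.positions).any(axis=2)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)
            if self.gaps.shape != self.positions.shape[:2]:
                raise ValueError("gaps must have shape (n_samples, n_markers)")
        # canonicalize label order
        order = _canonical_order(self.labels)
        if list(self.labels) != order:
            idx = [list(self.labels).index(lab) for lab in order]
            self.positions = self.positions[:, idx, :]
            self.gaps = self.gaps[:, idx]
            self.labels = tuple(order)
        valid = ~self.gaps
        if not np.isfinite(self.positions[valid]).all():
            raise ValueError("non-gap coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in series") from None

    def marker(self, label: str) -> np.ndarray:
        """(n, 3) trajectory of one marker (NaN where gapped)."""
        return self.positions[:, self.index(label), :]

    def copy(self) -> "MarkerFrameSeries":
        return MarkerFrameSeries(
            self.labels, self.positions.copy(), self.rate, self.gaps.copy()
        )


@dataclass
class HandrimKineticSeries:
    """Instrumented-wheel recording for one side.

    ``F`` and ``M`` are the forces (N) and moments (Nm) the hand applies to
    the rim, expressed in the wheel sensor frame (x/y in the wheel plane,
    z along the axle); ``theta`` is the unwrapped wheel angle in radians.
    """

    F: np.ndarray
    M: np.ndarray
    theta: np.ndarray
    rate: float
    side: str = "right"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = len(self.theta)
        if self.F.shape != (n, 3) or self.M.shape != (n, 3):
            raise ValueError(
                f"F and M must have shape ({n}, 3); got {self.F.shape}, {self.M.shape}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.theta)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def copy(self) -> "HandrimKineticSeries":
        return HandrimKineticSeries(
            self.F.copy(), self.M.copy(), self.theta.copy(), self.rate, self.side
        )


@dataclass
class SegmentGeometry:
    """One limb segment modelled as a solid of revolution."""

    mass: float          # kg
    length: float        # m
    proximal_radius: float  # m
    distal_radius: float    # m

    def __post_init__(self) -> None:
        for name in ("mass", "length", "proximal_radius", "distal_radius"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"segment {name} must be positive, got {v}")


@dataclass
class Anthropometry:
    """Subject body measures and per-segment geometry (arm, forearm, hand)."""

    body_mass: float  # kg
    height: float     # m
    arm: SegmentGeometry
    forearm: SegmentGeometry
    hand: SegmentGeometry

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.height <= 0:
            raise ValueError("body_mass and height must be positive")
        seg_mass = self.arm.mass + self.forearm.mass + self.hand.mass
        if seg_mass >= self.body_mass:
            raise ValueError(
                f"segment masses ({seg_mass:.2f} kg) must be below body mass "
                f"({self.body_mass:.2f} kg)"
            )

    @classmethod
    def from_body(cls, body_mass: float, height: float) -> "Anthropometry":
        """Standard segment table scaled from body mass and stature.

        Mass fractions: upper arm 2.8 %, forearm 1.6 %, hand 0.6 % of body
        mass.  Segment lengths as stature fractions (upper arm 0.186,
        forearm 0.146, hand 0.108); radii are plausible revolution-solid
        values scaled with stature.
        """
        return cls(
            body_mass=body_mass,
            height=height,
            arm=SegmentGeometry(0.028 * body_mass, 0.186 * height,
                                0.045 * height / 1.75, 0.035 * height / 1.75),
            forearm=SegmentGeometry(0.016 * body_mass, 0.146 * height,
                                    0.040 * height / 1.75, 0.025 * height / 1.75),
            hand=SegmentGeometry(0.006 * body_mass, 0.108 * height,
                                 0.040 * height / 1.75, 0.020 * height / 1.75),
        )


@dataclass
class WheelchairGeometry:
    """Wheel and seat geometry relevant to the analysis."""

    wheel_diameter: float = 0.600  # m
    rim_radius: float = 0.26       # m, hand-rim circle radius
    camber: float = 0.0            # degrees
    seat_height: float = 0.43      # m, descriptive only
    axle_position: np.ndarray | None = None  # lab-frame axle centre, if known

    def __post_init__(self) -> None:
        if self.wheel_diameter <= 0:
            raise ValueError("wheel_diameter must be positive")
        if not 0 < self.rim_radius < self.wheel_diameter / 2 + 0.05:
            raise ValueError(
                f"rim_radius must be in (0, {self.wheel_diameter / 2 + 0.05:.3f}), "
                f"got {self.rim_radius}"
            )
        if self.axle_position is not None:
            self.axle_position = np.asarray(self.axle_position, dtype=float)

    @property
    def wheel_radius(self) -> float:
        return self.wheel_diameter / 2


@dataclass
class FilterSpec:
    order: int = 4
    cutoff_hz: float = 20.0


@dataclass
class StudyConfig:
    """Analysis parameters with protocol defaults.

    Defaults: treadmill speed 0.833 m/s (3 km/h), 4th-order 20 Hz zero-phase
    Butterworth on the wheel kinetics, 1 Nm rim-moment push threshold, five
    consecutive cycles normalized to 101 stations.
    """

    treadmill_speed: float = 0.833
    analysis_window: tuple[float, float] = (0.0, math.inf)
    n_cycles: int = 5
    filter: FilterSpec = field(default_factory=FilterSpec)
    marker_filter: FilterSpec = field(default_factory=lambda: FilterSpec(4, 6.0))
    event_threshold_nm: float = 1.0
    min_push_duration_s: float = 0.1
    normalization_points: int = 101
    angle_reference: str = "backward_horizontal"  # or "top_dead_center"
    sync_target_rate: float = 240.0

    def __post_init__(self) -> None:
        if self.analysis_window[0] >= self.analysis_window[1]:
            raise ValueError(
                f"analysis_window start must precede end, got {self.analysis_window}"
            )
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.treadmill_speed <= 0:
            raise ValueError("treadmill_speed must be positive")
        if self.event_threshold_nm <= 0:
            raise ValueError("event_threshold_nm must be positive")
        if self.normalization_points < 2:
            raise ValueError("normalization_points must be >= 2")
        if self.angle_reference not in ("backward_horizontal", "top_dead_center"):
            raise ValueError(
                "angle_reference must be 'backward_horizontal' or 'top_dead_center', "
                f"got {self.angle_reference!r}"
            )

    def validate_rates(self, *rates: float) -> None:
        """Check filter cutoffs against the Nyquist limit of every stream."""
        nyq = min(rates) / 2
        for spec, name in ((self.filter, "filter"), (self.marker_filter, "marker_filter")):
            if spec.cutoff_hz >= nyq:
                raise ValueError(
                    f"{name}.cutoff_hz ({spec.cutoff_hz} Hz) must be below the "
                    f"Nyquist frequency {nyq} Hz"
                )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _parse_header_line(line: str, path: Path) -> dict[str, str]:
    if not line.startswith("#"):
        raise ValueError(f"{path}: first line must be a '# key=value' header")
    meta: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    if "rate" not in meta:
        raise ValueError(f"{path}: header must declare rate, e.g. '# rate=50'")
    return meta


def read_marker_series(path: str | Path, dialect: str = "csv") -> MarkerFrameSeries:
    """Read a marker trajectory file.

    The CSV dialect is one metadata line ``# rate=<Hz>`` followed by a
    column header ``t,<label>_x,<label>_y,<label>_z,...``.  Blank cells are
    gap-flagged, never interpolated here.
    """
    path = Path(path)
    if dialect == "c3d":
        raise NotImplementedError(
            "C3D input is not supported in this build; convert to the CSV dialect"
        )
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no samples")
    meta = _parse_header_line(lines[0], path)
    rate = float(meta["rate"])
    cols = lines[1].split(",")
    if cols[0] != "t":
        raise ValueError(f"{path}: first column must be 't'")
    labels: list[str] = []
    for i in range(1, len(cols), 3):
        trip = cols[i : i + 3]
        if len(trip) != 3:
            raise ValueError(f"{path}: columns must come in _x/_y/_z triplets")
        base = trip[0].rsplit("_", 1)[0]
        if [f"{base}_x", f"{base}_y", f"{base}_z"] != trip:
            raise ValueError(f"{path}: malformed column triplet {trip}")
        if base not in MARKER_LABELS:
            raise ValueError(
                f"{path}: unknown marker label {base!r}; allowed labels are "
                f"{list(MARKER_LABELS)}"
            )
        labels.append(base)
    n_mark = len(labels)
    rows = []
    for ln in lines[2:]:
        cells = ln.split(",")
        if len(cells) != 1 + 3 * n_mark:
            raise ValueError(f"{path}: row has {len(cells)} cells, expected {1 + 3 * n_mark}")
        rows.append([float(c) if c.strip() != "" else np.nan for c in cells[1:]])
    if not rows:
        raise ValueError(f"{path}: no samples")
    pos = np.asarray(rows, dtype=float).reshape(len(rows), n_mark, 3)
    return MarkerFrameSeries(tuple(labels), pos, rate)


def write_marker_series(series: MarkerFrameSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={series.rate:g}\n")
        fh.write("t," + ",".join(
            f"{lab}_{ax}" for lab in series.labels for ax in "xyz") + "\n")
        for i in range(series.n_samples):
            cells = [f"{i / series.rate:.9g}"]
            for j in range(len(series.labels)):
                if series.gaps[i, j]:
                    cells.extend(["", "", ""])
                else:
                    cells.extend(f"{v:.12g}" for v in series.positions[i, j])
            fh.write(",".join(cells) + "\n")


_RIM_COLS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz", "theta")


def read_handrim_series(path: str | Path, side: str = "right") -> HandrimKineticSeries:
    """Read a wheel kinetics file; the wheel angle is unwrapped on read."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no samples")
    meta = _parse_header_line(lines[0], path)
    rate = float(meta["rate"])
    side = meta.get("side", side)
    cols = lines[1].split(",")
    if cols[0] != "t":
        raise ValueError(f"{path}: first column must be 't'")
    missing = [c for c in _RIM_COLS if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    idx = {c: cols.index(c) for c in _RIM_COLS}
    t_idx = 0
    data = []
    for ln in lines[2:]:
        cells = ln.split(",")
        if len(cells) != len(cols):
            raise ValueError(f"{path}: ragged row")
        data.append([float(c) for c in cells])
    if not data:
        raise ValueError(f"{path}: no samples")
    arr = np.asarray(data, dtype=float)
    t = arr[:, t_idx]
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    F = np.column_stack([arr[:, idx[c]] for c in ("Fx", "Fy", "Fz")])
    M = np.column_stack([arr[:, idx[c]] for c in ("Mx", "My", "Mz")])
    theta = np.unwrap(arr[:, idx["theta"]])
    return HandrimKineticSeries(F, M, theta, rate, side)


def write_handrim_series(series: HandrimKineticSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={series.rate:g} side={series.side}\n")
        fh.write("t," + ",".join(_RIM_COLS) + "\n")
        for i in range(series.n_samples):
            row = [f"{i / series.rate:.9g}"]
            row.extend(f"{v:.12g}" for v in series.F[i])
            row.extend(f"{v:.12g}" for v in series.M[i])
            row.append(f"{series.theta[i]:.12g}")
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "treadmill_speed", "analysis_window", "n_cycles", "filter", "marker_filter",
    "event_threshold_nm", "min_push_duration_s", "normalization_points",
    "angle_reference", "sync_target_rate",
}


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML study configuration; unspecified keys take protocol defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in raw.items():
        if key in ("filter", "marker_filter"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            spec = FilterSpec(**{k: v for k, v in val.items()})
            if spec.order < 1:
                raise ValueError(f"{key}.order must be >= 1, got {spec.order}")
            if spec.cutoff_hz <= 0:
                raise ValueError(f"{key}.cutoff_hz must be positive, got {spec.cutoff_hz}")
            kwargs[key] = spec
        elif key == "analysis_window":
            kwargs[key] = (float(val[0]), float(val[1]))
        else:
            kwargs[key] = val
    try:
        return StudyConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def config_to_dict(config: StudyConfig) -> dict:
    """JSON-serializable view of the configuration (for report provenance)."""
    d = dataclasses.asdict(config)
    d["analysis_window"] = [
        None if math.isinf(v) else v for v in config.analysis_window
    ]
    return d
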