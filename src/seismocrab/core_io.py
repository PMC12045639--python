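"""Domain types and file I/O for geophone sessions.

A recording session couples four geophone channels — a *close* pair at the
burrow entrance (10 cm) and a *far* pair (20–100 cm) — with a behaviour-event
table, a wind-speed series, and morphological measurements of the signalling
crab.  Each pair holds one low-frequency geophone (flat 4.5–160 Hz response)
and one high-frequency geophone (flat 100–400 Hz response), both sampled at
1612 Hz and expressed as ground velocity in m/s.

Traces are stored as single-channel WAV (float64, lossless) or single-column
CSV; behaviour events as a minimal fixed-column TSV; wind and morphology as
CSV.  Video–seismic synchronisation is recovered from a finger-tap impulse
planted near the geophones at the start of each session.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_FS = 1612.0

#: Flat-response range (Hz) of each geophone variant.
BAND_RANGES: dict[str, tuple[float, float]] = {
    "low": (4.5, 160.0),
    "high": (100.0, 400.0),
}

BANDS = ("low", "high")
POSITIONS = ("close", "far")

#: The nine-behaviour ethogram.  seqW and seqBD are the wave and body-drop
#: components of the sequential display, tagged as two separate point events.
POINT_LABELS = frozenset({"waving", "seqW", "seqBD", "simWBD"})
STATE_LABELS = frozenset({"UGD", "AD", "locomotion", "MB", "conflict"})
BEHAVIOUR_LABELS = POINT_LABELS | STATE_LABELS

CLOSE_DISTANCE_CM = 10.0
FAR_DISTANCES_CM = tuple(float(d) for d in range(20, 101, 10))


@dataclass
class TraceChannel:
    """One geophone's velocity time series plus sensor metadata."""

    samples: np.ndarray  # velocity, m/s
    fs: float = DEFAULT_FS
    band: str = "low"  # 'low' (4.5–160 Hz) or 'high' (100–400 Hz)
    position: str = "close"  # 'close' or 'far'
    distance_to_burrow_cm: float = CLOSE_DISTANCE_CM

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / fs)."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class BehaviourEvent:
    """A tagged behaviour: a point event (one timestamp) or a state event
    (start/stop pair).  Times are seconds from session start, before
    sync-offset correction."""

    label: str
    event_type: str  # 'point' or 'state'
    time: Optional[float] = None
    start: Optional[float] = None
    stop: Optional[float] = None
    crab_id: str = ""
    burrow_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in BEHAVIOUR_LABELS:
            raise ValueError(
                f"label {self.label!r} not in the nine-behaviour catalogue"
            )
        if self.event_type == "point":
            if self.time is None:
                raise ValueError("point event requires a single time")
        elif self.event_type == "state":
            if self.start is None or self.stop is None:
                raise ValueError("state event requires start and stop")
            if self.stop <= self.start:
                raise ValueError(
                    f"state event must have start < stop, got "
                    f"[{self.start}, {self.stop}]"
                )
        else:
            raise ValueError(f"unknown event_type {self.event_type!r}")

    @property
    def midpoint(self) -> float:
        if self.event_type == "point":
            return float(self.time)
        return 0.5 * (self.start + self.stop)

    @property
    def duration(self) -> float:
        return 0.0 if self.event_type == "point" else self.stop - self.start


@dataclass
class WindSeries:
    """Anemometer wind-speed samples (m/s) at strictly increasing times (s)."""

    times: np.ndarray
    speeds: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.times.shape != self.speeds.shape:
            raise ValueError("times and speeds must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("wind times must be strictly increasing")
        if np.any(self.speeds < 0):
            raise ValueError("wind speeds must be non-negative")


@dataclass
class MorphoRecord:
    """Morphology of one crab: claw width/length, carapace width/length (mm),
    mass (g)."""

    claw1: float
    claw2: float
    car1: float
    car2: float
    mass: float
    sex: str = "M"
    crab_id: str = ""

    def __post_init__(self) -> None:
        for name in ("claw1", "claw2", "car1", "car2", "mass"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class SessionRecording:
    """Four synchronous geophone channels (close/far × low/high) for one
    focal burrow.

    ``sync_offset`` maps annotated video time to trace time: a behaviour
    tagged at video time t occurred at trace time t + sync_offset.
    """

    channels: dict[str, TraceChannel]  # keys 'close_low', ..., 'far_high'
    burrow_id: str = ""
    sync_offset: float = 0.0
    wind: Optional[WindSeries] = None

    REQUIRED = ("close_low", "close_high", "far_low", "far_high")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self.channels]
        if missing:
            raise ValueError(f"session missing channels: {missing}")
        ref = self.channels["close_low"]
        for key in self.REQUIRED:
            ch = self.channels[key]
            if ch.fs != ref.fs:
                raise ValueError("all channels must share a sampling rate")
            if len(ch) != len(ref):
                raise ValueError("all channels must have equal length")

    @property
    def fs(self) -> float:
        return self.channels["close_low"].fs

    @property
    def n_samples(self) -> int:
        return len(self.channels["close_low"])

    def channel(self, position: str, band: str) -> TraceChannel:
        return self.channels[f"{position}_{band}"]


# ---------------------------------------------------------------------------
# Trace I/O


def write_trace(path: str | Path, trace: TraceChannel) -> None:
    """Write a trace as float64 WAV (``.wav``) or single-column CSV.

    The CSV header is ``fs=<rate>``; WAV carries the rate natively (rounded
    to an integer as the format requires).
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(trace.fs)), trace.samples.astype(np.float64))
    else:
        with open(path, "w") as fh:
            fh.write(f"fs={trace.fs!r}\n")
            np.savetxt(fh, trace.samples, fmt="%.17g")


def read_trace(path: str | Path, **meta) -> TraceChannel:
    """Read a WAV or CSV trace.

    ``meta`` supplies band/position/distance metadata and an optional
    ``scale`` (default 1.0) converting stored units to m/s — e.g. the
    reciprocal geophone sensitivity when the file stores volts.  For CSV the
    sampling rate comes from the ``fs=...`` header; a ``fs`` kwarg overrides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scale = float(meta.pop("scale", 1.0))
    if path.suffix.lower() == ".wav":
        fs_file, data = wavfile.read(path)
        fs = float(meta.pop("fs", fs_file))
        samples = np.asarray(data, dtype=float) * scale
    else:
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("fs="):
                raise ValueError(f"CSV trace header must be 'fs=<rate>', got {header!r}")
            fs = float(meta.pop("fs", float(header[3:])))
            try:
                samples = np.loadtxt(fh, dtype=float, ndmin=1) * scale
            except ValueError as exc:
                raise ValueError(f"non-numeric sample in {path}: {exc}") from exc
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    return TraceChannel(samples=samples, fs=fs, **meta)


# ---------------------------------------------------------------------------
# Behaviour-event I/O

EVENT_COLUMNS = ["label", "event_type", "time", "start", "stop", "crab_id", "burrow_id"]


def write_events(path_or_buf, events: list[BehaviourEvent]) -> None:
    """Write a behaviour-event table as fixed-column TSV."""
    rows = [
        {
            "label": e.label,
            "event_type": e.event_type,
            "time": e.time,
            "start": e.start,
            "stop": e.stop,
            "crab_id": e.crab_id,
            "burrow_id": e.burrow_id,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path_or_buf, sep="\t", index=False)


def parse_events(path_or_buf, column_map: Optional[dict[str, str]] = None) -> list[BehaviourEvent]:
    """Parse a TSV behaviour-event table into :class:`BehaviourEvent` objects.

    ``column_map`` renames source columns to the canonical names, so real
    observation-software exports with different headers can be ingested.
    """
    df = pd.read_csv(path_or_buf, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("label", "event_type") if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events = []
    for _, row in df.iterrows():
        kwargs = dict(
            label=str(row["label"]),
            event_type=str(row["event_type"]),
            crab_id="" if pd.isna(row.get("crab_id", "")) else str(row.get("crab_id", "")),
            burrow_id="" if pd.isna(row.get("burrow_id", "")) else str(row.get("burrow_id", "")),
        )
        if kwargs["event_type"] == "point":
            kwargs["time"] = float(row["time"])
        else:
            kwargs["start"] = float(row["start"])
            kwargs["stop"] = float(row["stop"])
        events.append(BehaviourEvent(**kwargs))
    return events


# ---------------------------------------------------------------------------
# Wind and morphology I/O


def write_wind(path_or_buf, wind: WindSeries) -> None:
    pd.DataFrame({"time_s": wind.times, "wind_mps": wind.speeds}).to_csv(
        path_or_buf, index=False
    )


def read_wind(path_or_buf) -> WindSeries:
    df = pd.read_csv(path_or_buf)
    return WindSeries(times=df["time_s"].to_numpy(), speeds=df["wind_mps"].to_numpy())


def read_morphology(path_or_buf) -> list[MorphoRecord]:
    """Read a morphology CSV: crab_id, claw1, claw2, car1, car2, mass, sex."""
    df = pd.read_csv(path_or_buf)
    return [
        MorphoRecord(
            claw1=row["claw1"], claw2=row["claw2"], car1=row["car1"],
            car2=row["car2"], mass=row["mass"],
            sex=str(row.get("sex", "M")), crab_id=str(row.get("crab_id", "")),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Video–seismic synchronisation


def detect_sync_offset(
    close_low: TraceChannel,
    annotated_tap_time: float,
    search_radius: float,
    threshold_factor: float = 5.0,
) -> float:
    """Locate the synchronisation finger-tap and return the trace−video offset.

    The tap produces a major spike near the annotated video time.  Within
    ``annotated_tap_time ± search_radius`` the sample of maximum absolute
    amplitude is taken as the tap, provided it exceeds ``threshold_factor``
    times the window's median absolute amplitude; otherwise synchronisation
    has failed and a ``ValueError`` is raised.
    """
    fs = close_low.fs
    i0 = int(round((annotated_tap_time - search_radius) * fs))
    i1 = int(round((annotated_tap_time + search_radius) * fs)) + 1
    if i0 < 0 or i1 > len(close_low):
        raise ValueError("sync search window extends beyond the trace")
    window = np.abs(close_low.samples[i0:i1])
    if window.size == 0:
        raise ValueError("empty sync search window")
    med = float(np.median(window))
    peak_idx = int(np.argmax(window))
    if window[peak_idx] <= threshold_factor * med or window[peak_idx] == 0:
        raise ValueError(
            "no qualifying synchronisation spike found "
            f"(peak {window[peak_idx]:.3g} vs {threshold_factor}x median {med:.3g})"
        )
    tap_time = (i0 + peak_idx) / fs
    return tap_time - annotated_tap_time
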