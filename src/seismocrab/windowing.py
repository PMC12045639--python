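"""Behaviour events → fixed-length analysis windows.

Feature extraction and spectrogram classification both run on a fixed 0.4 s
window per event (645 samples at 1612 Hz): point behaviours keep the tag
±0.2 s, state behaviours the middle 0.4 s of the event.  The 0.4 s length is
short enough that separate point events (e.g. a sequential wave and its body
drop) do not overlap.  Full-event parsing, used by the drumming-spike
analysis, spans the whole state event plus an onset/termination buffer —
0.6 s for underground drumming, whose onset is established aurally and is
less precise, and 0.2 s for everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import BehaviourEvent, SessionRecording

FEATURE_WINDOW_S = 0.4
POINT_HALF_WINDOW_S = 0.2
PARSE_BUFFER_S = 0.2
PARSE_BUFFER_UGD_S = 0.6


def samples_for_duration(duration: float, fs: float) -> int:
    """Number of samples spanning ``duration`` seconds at rate ``fs``,
    rounded half away from zero (0.4 s at 1612 Hz → 645)."""
    if duration < 0:
        raise ValueError(f"duration must be non-negative, got {duration}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    return int(math.floor(duration * fs + 0.5))


def duration_for_samples(n: int, fs: float) -> float:
    """Inverse conversion: n samples at fs → seconds."""
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    return n / fs


def event_window_bounds(event: BehaviourEvent) -> tuple[float, float]:
    """0.4 s feature-window bounds: point tag ±0.2 s, or the middle 0.4 s
    of a state event (midpoint ±0.2 s)."""
    mid = event.midpoint
    return (mid - POINT_HALF_WINDOW_S, mid + POINT_HALF_WINDOW_S)


def parse_bounds(event: BehaviourEvent) -> tuple[float, float]:
    """Full-event parse bounds: the event span plus the behaviour's
    onset/termination buffer (0.6 s for UGD, 0.2 s otherwise).  A point
    event's parse bounds coincide with its feature window."""
    if event.event_type == "point":
        return event_window_bounds(event)
    b = PARSE_BUFFER_UGD_S if event.label == "UGD" else PARSE_BUFFER_S
    return (event.start - b, event.stop + b)


@dataclass
class SignalWindow:
    """Per-channel velocity segments cut from a session for one event."""

    segments: dict[str, np.ndarray]  # keyed like SessionRecording.channels
    t0: float
    t1: float
    fs: float
    source_event: Optional[BehaviourEvent] = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.segments.values()}
        if len(lengths) != 1:
            raise ValueError("all segments must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.segments.values())))

    def segment(self, position: str, band: str) -> np.ndarray:
        return self.segments[f"{position}_{band}"]


def extract_window(
    session: SessionRecording,
    bounds: tuple[float, float],
    event: Optional[BehaviourEvent] = None,
    channels: Optional[list[str]] = None,
) -> SignalWindow:
    """Cut the per-channel segments for ``bounds`` (annotated video times;
    the session's sync offset is applied here).

    Windows crossing a trace boundary are rejected rather than zero-padded:
    padding would deflate the window's energy.
    """
    t0, t1 = bounds
    if t1 <= t0:
        raise ValueError(f"invalid bounds ({t0}, {t1})")
    fs = session.fs
    n = samples_for_duration(t1 - t0, fs)
    start = int(round((t0 + session.sync_offset) * fs))
    if start < 0 or start + n > session.n_samples:
        raise ValueError(
            f"window [{t0}, {t1}] s (sync offset {session.sync_offset} s) "
            "falls outside the recorded trace"
        )
    keys = channels if channels is not None else list(session.channels)
    segments = {k: session.channels[k].samples[start : start + n].copy() for k in keys}
    return SignalWindow(segments=segments, t0=t0, t1=t1, fs=fs, source_event=event)


def extract_feature_window(session: SessionRecording, event: BehaviourEvent) -> SignalWindow:
    """The event's fixed 0.4 s feature window."""
    return extract_window(session, event_window_bounds(event), event=event)


def extract_full_event(session: SessionRecording, event: BehaviourEvent) -> SignalWindow:
    """Variable-length window spanning a state event's parse bounds; used by
    the drumming-spike analysis on AD/UGD events."""
    if event.event_type != "state":
        raise ValueError("full-event extraction requires a state behaviour")
    return extract_window(session, parse_bounds(event), event=event)
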