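"""Differential Distance Classifier.

Turns the two-channel raw distance stream of a desk-mounted time-of-flight
sensor pair (one beam aimed at the seated torso, one just above seated head
height) into a per-sample posture state sequence — ``sit``, ``stand`` or
``away`` — and the transition events between states.

The pipeline is: trailing moving-average smoothing of each distance channel,
a presence gate (a target counts as "detected" when its smoothed distance
lies inside a fixed range), and a three-way decision:

* torso detected, head not detected  -> ``sit``
* torso and head both detected       -> ``stand``
* neither detected                   -> ``away``

A head-only detection is geometrically implausible (the head beam clears the
seated head, so a standing head implies a detectable torso); it is treated
as transient noise and the previous state is held.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("desksense")

STREAM_COLUMNS = ("timestamp_ms", "torso_mm", "head_mm")


class PostureState(str, enum.Enum):
    """The three admissible desk posture states."""

    SIT = "sit"
    STAND = "stand"
    AWAY = "away"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierConfig:
    """Operating parameters of the classifier.

    Parameters
    ----------
    window
        Moving-average window length in samples (omega). The trailing mean
        over the last ``window`` samples smooths transient spikes; it also
        sets the detection latency, roughly ``window * sample_period``.
    range_min_mm, range_max_mm
        Presence gate: a channel "detects" a target when its smoothed
        distance is within ``[range_min_mm, range_max_mm]`` (inclusive).
        The lower bound accommodates forward leans, the upper bound rejects
        background movement behind the desk.
    sensor_max_mm
        Saturation code the sensor reports when nothing reflects the beam.
    sample_period_s
        Sampling interval of the stream (0.3 s, i.e. 3.3 Hz).
    """

    window: int = 8
    range_min_mm: float = 300.0
    range_max_mm: float = 2000.0
    sensor_max_mm: float = 8191.0
    sample_period_s: float = 0.3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if not (0 <= self.range_min_mm < self.range_max_mm < self.sensor_max_mm):
            raise ValueError(
                "require 0 <= range_min_mm < range_max_mm < sensor_max_mm, got "
                f"{self.range_min_mm}, {self.range_max_mm}, {self.sensor_max_mm}"
            )
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")

    def in_range(self, distance_mm: float) -> bool:
        """Presence gate, inclusive at both ends."""
        return self.range_min_mm <= distance_mm <= self.range_max_mm


@dataclass(frozen=True)
class TransitionEvent:
    """One state-change record: timestamp plus the state entered."""

    timestamp_ms: int
    new_state: PostureState


class EmptyStreamError(ValueError):
    """Raised when an operation requires a non-empty stream."""


def _as_stream_frame(stream) -> pd.DataFrame:
    """Coerce a stream to a validated DataFrame with STREAM_COLUMNS."""
    if isinstance(stream, pd.DataFrame):
        df = stream
    else:
        df = pd.DataFrame(list(stream), columns=list(STREAM_COLUMNS))
    missing = set(STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stream is missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise EmptyStreamError("stream is empty")
    ts = df["timestamp_ms"].to_numpy()
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        bad = int(np.flatnonzero(np.diff(ts) <= 0)[0]) + 1
        raise ValueError(f"timestamps not strictly increasing at row {bad}")
    if (df[["torso_mm", "head_mm"]].to_numpy() < 0).any():
        raise ValueError("negative distances in stream")
    return df


def smooth(stream, config: ClassifierConfig) -> pd.DataFrame:
    """Trailing moving-average of both distance channels.

    Output sample ``i`` is the arithmetic mean of raw samples
    ``max(0, i - window + 1) .. i`` per channel, so the first ``window - 1``
    samples use a partial (growing) window and the output has the same
    length and timestamps as the input.
    """
    df = _as_stream_frame(stream)
    out = df.copy()
    roll = df[["torso_mm", "head_mm"]].rolling(config.window, min_periods=1).mean()
    out["torso_mm"] = roll["torso_mm"]
    out["head_mm"] = roll["head_mm"]
    return out


def classify_sample(
    torso_mm: float,
    head_mm: float,
    previous: PostureState | None,
    config: ClassifierConfig,
) -> PostureState:
    """Classify one smoothed sample pair.

    The fourth gate combination (head detected, torso not) cannot arise from
    the sensor geometry; it holds ``previous`` (or ``away`` when there is no
    previous state) and logs a warning.
    """
    if torso_mm < 0 or head_mm < 0:
        raise ValueError(f"negative distance: torso={torso_mm}, head={head_mm}")
    torso_in = config.in_range(torso_mm)
    head_in = config.in_range(head_mm)
    if torso_in and head_in:
        return PostureState.STAND
    if torso_in:
        return PostureState.SIT
    if head_in:
        logger.warning(
            "implausible head-only detection (torso=%.0f mm, head=%.0f mm); "
            "holding previous state",
            torso_mm,
            head_mm,
        )
        return previous if previous is not None else PostureState.AWAY
    return PostureState.AWAY


def classify_stream(
    stream, config: ClassifierConfig
) -> list[tuple[int, PostureState]]:
    """Smooth then classify every sample, carrying the running previous state.

    Returns one ``(timestamp_ms, state)`` per input sample.
    """
    smoothed = smooth(stream, config)
    timestamps = smoothed["timestamp_ms"].to_numpy()
    torso = smoothed["torso_mm"].to_numpy()
    head = smoothed["head_mm"].to_numpy()
    torso_in = (torso >= config.range_min_mm) & (torso <= config.range_max_mm)
    head_in = (head >= config.range_min_mm) & (head <= config.range_max_mm)

    states: list[tuple[int, PostureState]] = []
    previous: PostureState | None = None
    for ts, t_in, h_in in zip(timestamps, torso_in, head_in):
        if t_in and h_in:
            state = PostureState.STAND
        elif t_in:
            state = PostureState.SIT
        elif h_in:
            # implausible head-only detection: hold previous state
            state = previous if previous is not None else PostureState.AWAY
        else:
            state = PostureState.AWAY
        states.append((int(ts), state))
        previous = state
    return states


def stream_to_events(stream, config: ClassifierConfig) -> list["TransitionEvent"]:
    """Convenience: smooth, classify and extract transitions in one call."""
    return extract_transitions(classify_stream(stream, config))


def extract_transitions(
    states: Sequence[tuple[int, PostureState]]
) -> list[TransitionEvent]:
    """Compress a per-sample state sequence into its change points.

    The first sample always emits an initial event; thereafter an event is
    emitted exactly when the state differs from the previous sample, so the
    event count equals the number of state changes plus one.
    """
    if not states:
        raise EmptyStreamError("state sequence is empty")
    events = [TransitionEvent(int(states[0][0]), states[0][1])]
    for ts, state in states[1:]:
        if state != events[-1].new_state:
            events.append(TransitionEvent(int(ts), state))
    return events
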