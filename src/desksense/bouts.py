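"""Bout construction, the 60-s clinical filter, and desk-squat counting.

A *bout* is a maximal contiguous interval in one posture state. Its duration
is the difference between the timestamps of the event that opens it and the
next event (the final bout is closed at the end of the recording).

The clinical filter suppresses stand/away bouts shorter than a minimum
duration (default 60 s — the shortest activity bout considered
cardiometabolically meaningful) by *reassigning* their time to the
neighbouring retained bout, so total recorded time is conserved exactly.
The filter is an intervention trigger only: repetition counting and the
validation statistics consume the unfiltered transition log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classifier import PostureState, TransitionEvent


@dataclass(frozen=True)
class Bout:
    """One maximal single-state interval, ``[start_ms, end_ms)``."""

    state: PostureState
    start_ms: int
    end_ms: int

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


@dataclass(frozen=True)
class ClinicalFilterConfig:
    """Minimum-duration filter settings.

    ``filtered_states`` lists the states whose short bouts are suppressed;
    sitting is never filtered, since sedentary time is the quantity the
    monitor exists to measure.
    """

    min_bout_s: float = 60.0
    filtered_states: frozenset[PostureState] = frozenset(
        {PostureState.STAND, PostureState.AWAY}
    )

    def __post_init__(self) -> None:
        if self.min_bout_s <= 0:
            raise ValueError("min_bout_s must be positive")


@dataclass(frozen=True)
class RepetitionResult:
    """Desk-squat counting outcome.

    ``psi`` is the percentage of scripted cycles detected. A trailing
    sit->stand excursion with no return to sit is reported separately in
    ``unterminated_half_cycle`` and is not counted in ``detected_cycles``.
    """

    detected_cycles: int
    scripted_cycles: int
    psi: float
    unterminated_half_cycle: bool = False


def bouts_from_events(
    events: Sequence[TransitionEvent], stream_end_ms: int
) -> list[Bout]:
    """Durations from consecutive event timestamps.

    Bout ``i`` spans event ``i`` to event ``i + 1``; the final bout is
    closed at ``stream_end_ms``, so the durations sum to
    ``stream_end_ms - events[0].timestamp_ms`` exactly.
    """
    if not events:
        raise ValueError("event log is empty")
    ts = [e.timestamp_ms for e in events]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("event timestamps must be strictly increasing")
    if stream_end_ms < ts[-1]:
        raise ValueError(
            f"stream_end_ms ({stream_end_ms}) precedes last event ({ts[-1]})"
        )
    bounds = ts + [int(stream_end_ms)]
    return [
        Bout(e.new_state, bounds[i], bounds[i + 1]) for i, e in enumerate(events)
    ]


def _check_contiguous(bouts: Sequence[Bout]) -> None:
    for a, b in zip(bouts, bouts[1:]):
        if a.end_ms != b.start_ms:
            raise ValueError(
                f"bouts not contiguous: {a.end_ms} != {b.start_ms}"
            )


def apply_clinical_filter(
    bouts: Sequence[Bout], config: ClinicalFilterConfig | None = None
) -> list[Bout]:
    """Suppress short stand/away bouts, conserving total time.

    Each internal stand/away bout shorter than ``min_bout_s`` is merged into
    the immediately preceding retained bout (runs of consecutive
    sub-threshold bouts accumulate into the same predecessor). A leading
    sub-threshold bout, having no predecessor, merges forward into its
    successor. The final bout is always retained: the session may simply
    have been truncated there. Merges that leave two same-state bouts
    adjacent coalesce them into one.
    """
    config = config or ClinicalFilterConfig()
    bouts = list(bouts)
    if not bouts:
        return []
    _check_contiguous(bouts)

    out: list[Bout] = []
    for i, bout in enumerate(bouts):
        is_final = i == len(bouts) - 1
        suppress = (
            not is_final
            and bout.state in config.filtered_states
            and bout.duration_s < config.min_bout_s
        )
        if suppress:
            if out:
                prev = out[-1]
                out[-1] = Bout(prev.state, prev.start_ms, bout.end_ms)
            else:
                # leading sub-threshold bout: hand its time forward
                # by widening the next emitted bout's start
                continue
        else:
            start = out[-1].end_ms if out else bouts[0].start_ms
            if out and out[-1].state == bout.state:
                out[-1] = Bout(bout.state, out[-1].start_ms, bout.end_ms)
            else:
                out.append(Bout(bout.state, start, bout.end_ms))
    return out


def count_repetitions(
    events: Sequence[TransitionEvent], scripted_cycles: int
) -> RepetitionResult:
    """Count full sit -> stand -> sit excursions in an unfiltered event log.

    One cycle per consecutive sit->stand, stand->sit transition pair; the
    closing sit may open the next cycle. The percentage detected is
    ``psi = 100 * detected / scripted``.
    """
    if scripted_cycles <= 0:
        raise ValueError("scripted_cycles must be positive")
    states = [e.new_state for e in events]
    detected = 0
    i = 0
    while i + 2 < len(states):
        if (
            states[i] == PostureState.SIT
            and states[i + 1] == PostureState.STAND
            and states[i + 2] == PostureState.SIT
        ):
            detected += 1
            i += 2  # the closing sit can start the next cycle
        else:
            i += 1
    half_open = (
        len(states) >= 2
        and states[-1] == PostureState.STAND
        and states[-2] == PostureState.SIT
    )
    psi = 100.0 * detected / scripted_cycles
    return RepetitionResult(detected, scripted_cycles, psi, half_open)
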