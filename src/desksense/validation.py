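"""Event alignment and temporal-fidelity statistics.

Criterion validation of the classifier compares its transition log ``S``
against a ground-truth log ``G`` (scripted prompts, video, or a simulated
schedule):

* nearest-neighbour event alignment by absolute timestamp difference;
* sensitivity ``phi(delta)`` — the percentage of ground-truth events
  matched within a tolerance ``delta`` — swept over a tolerance grid to
  find ``delta_min``, the smallest tolerance at which sensitivity plateaus
  under a hard cap ``delta_T``;
* duration error statistics over the matched events (MAE, mean difference
  with a normal-approximation 95% CI, count bias), overall and per user.

Matching is purely temporal; whether the matched events carry the same
state label is assessed separately by the classification metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bouts import Bout
from .classifier import PostureState, TransitionEvent

logger = logging.getLogger("desksense")


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no ground truth / no matches)."""


@dataclass(frozen=True)
class MatchedPair:
    """One aligned (sensor, truth) event pair."""

    sensor_index: int
    truth_index: int
    sensor_event: TransitionEvent
    truth_event: TransitionEvent
    delta_s: float


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of greedy nearest-neighbour event matching."""

    sensor_events: tuple[TransitionEvent, ...]
    truth_events: tuple[TransitionEvent, ...]
    pairs: tuple[MatchedPair, ...]
    missed_truth: tuple[int, ...]  # truth indices with no sensor partner
    spurious_sensor: tuple[int, ...]  # sensor indices with no truth partner

    @property
    def n_truth(self) -> int:
        return len(self.truth_events)


def align_events(
    sensor: Sequence[TransitionEvent], truth: Sequence[TransitionEvent]
) -> AlignmentResult:
    """Globally greedy matching on absolute time difference.

    Repeatedly pairs the unmatched (sensor, truth) combination with the
    smallest ``|t_sensor - t_truth|``; ties break toward the earlier truth
    event, then the earlier sensor event. Unmatched truth events are
    *missed*, unmatched sensor events *spurious*. Empty logs are permitted.
    """
    sensor = list(sensor)
    truth = list(truth)
    candidates = sorted(
        (
            (abs(s.timestamp_ms - g.timestamp_ms) / 1000.0, gj, si)
            for si, s in enumerate(sensor)
            for gj, g in enumerate(truth)
        ),
        key=lambda c: (c[0], truth[c[1]].timestamp_ms, sensor[c[2]].timestamp_ms),
    )
    used_s: set[int] = set()
    used_g: set[int] = set()
    pairs: list[MatchedPair] = []
    for delta, gj, si in candidates:
        if si in used_s or gj in used_g:
            continue
        used_s.add(si)
        used_g.add(gj)
        pairs.append(MatchedPair(si, gj, sensor[si], truth[gj], delta))
    pairs.sort(key=lambda p: p.truth_index)
    return AlignmentResult(
        sensor_events=tuple(sensor),
        truth_events=tuple(truth),
        pairs=tuple(pairs),
        missed_truth=tuple(j for j in range(len(truth)) if j not in used_g),
        spurious_sensor=tuple(i for i in range(len(sensor)) if i not in used_s),
    )


def pooled_alignment(
    alignments: Sequence[AlignmentResult], gap_ms: int = 10_000_000
) -> AlignmentResult:
    """Concatenate per-participant alignments into one pooled result.

    Event timestamps are shifted block-by-block (separated by ``gap_ms``)
    so the pooled logs remain strictly increasing; pair deltas are
    untouched. Pooled sensitivity then has the cohort's total ground-truth
    count in its denominator, and per-event structures (bout lists)
    concatenated in the same order stay index-parallel.
    """
    sensor_events: list[TransitionEvent] = []
    truth_events: list[TransitionEvent] = []
    pairs: list[MatchedPair] = []
    missed: list[int] = []
    spurious: list[int] = []
    offset = 0
    for al in alignments:
        s_base, g_base = len(sensor_events), len(truth_events)
        all_ts = [e.timestamp_ms for e in al.sensor_events] + [
            e.timestamp_ms for e in al.truth_events
        ]
        lo = min(all_ts, default=0)
        shift = offset - lo
        sensor_events.extend(
            TransitionEvent(e.timestamp_ms + shift, e.new_state)
            for e in al.sensor_events
        )
        truth_events.extend(
            TransitionEvent(e.timestamp_ms + shift, e.new_state)
            for e in al.truth_events
        )
        pairs.extend(
            MatchedPair(
                p.sensor_index + s_base,
                p.truth_index + g_base,
                sensor_events[p.sensor_index + s_base],
                truth_events[p.truth_index + g_base],
                p.delta_s,
            )
            for p in al.pairs
        )
        missed.extend(j + g_base for j in al.missed_truth)
        spurious.extend(i + s_base for i in al.spurious_sensor)
        offset += (max(all_ts, default=0) - lo) + gap_ms
    return AlignmentResult(
        sensor_events=tuple(sensor_events),
        truth_events=tuple(truth_events),
        pairs=tuple(pairs),
        missed_truth=tuple(missed),
        spurious_sensor=tuple(spurious),
    )


@dataclass(frozen=True)
class ValidationConfig:
    """Tolerance sweep settings.

    ``max_tolerance_s`` is the hard cap delta_T on the acceptable detection
    delay (default 5 s, set by hardware hysteresis and human reaction
    speed); the sensitivity curve is evaluated on ``delta_grid_s``
    (default 1..10 s in 1-s steps). ``plateau_epsilon`` allows an
    approximate plateau: a grid point qualifies when no later grid point
    within the cap improves sensitivity by more than this many percentage
    points.
    """

    max_tolerance_s: float = 5.0
    delta_grid_s: tuple[float, ...] = tuple(float(d) for d in range(1, 11))
    plateau_epsilon: float = 0.0

    def __post_init__(self) -> None:
        grid = self.delta_grid_s
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("delta_grid_s must be non-empty and increasing")
        if not (grid[0] <= self.max_tolerance_s <= grid[-1]):
            raise ValueError("max_tolerance_s must lie within the grid span")
        if self.plateau_epsilon < 0:
            raise ValueError("plateau_epsilon must be >= 0")


@dataclass(frozen=True)
class SensitivityCurve:
    """phi(delta) over the tolerance grid and the selected delta_min."""

    deltas: tuple[float, ...]
    values: tuple[float, ...]
    delta_min: float
    plateau_found: bool = True


def sensitivity_at(
    alignment: AlignmentResult,
    delta_s: float,
    truth_state: PostureState | None = None,
) -> float:
    """Percentage of ground-truth events matched within ``delta_s``.

    With ``truth_state`` given, both the numerator and the denominator are
    restricted to ground-truth events of that state.
    """
    if delta_s < 0:
        raise ValueError("delta must be >= 0")
    if truth_state is None:
        total = alignment.n_truth
        hits = sum(1 for p in alignment.pairs if p.delta_s <= delta_s)
    else:
        total = sum(
            1 for g in alignment.truth_events if g.new_state == truth_state
        )
        hits = sum(
            1
            for p in alignment.pairs
            if p.truth_event.new_state == truth_state and p.delta_s <= delta_s
        )
    if total == 0:
        raise UndefinedMetricError("no ground-truth events in denominator")
    return 100.0 * hits / total


def find_delta_min(
    alignment: AlignmentResult,
    config: ValidationConfig | None = None,
    truth_state: PostureState | None = None,
) -> SensitivityCurve:
    """Sweep the tolerance grid and pick the plateau onset.

    ``delta_min`` is the smallest grid tolerance, not exceeding the cap,
    whose sensitivity is within ``plateau_epsilon`` of the best sensitivity
    achievable under the cap. When only the cap itself qualifies (the curve
    is still rising there), ``delta_min`` falls back to the cap and
    ``plateau_found`` is False.
    """
    config = config or ValidationConfig()
    values = tuple(
        sensitivity_at(alignment, d, truth_state) for d in config.delta_grid_s
    )
    capped = [
        (d, v)
        for d, v in zip(config.delta_grid_s, values)
        if d <= config.max_tolerance_s
    ]
    best = max(v for _, v in capped)
    qualifying = [d for d, v in capped if best - v <= config.plateau_epsilon]
    delta_min = min(qualifying)
    plateau_found = len(qualifying) > 1 or len(capped) == 1 or (
        delta_min < capped[-1][0]
    )
    if not plateau_found:
        logger.warning(
            "sensitivity still rising at the tolerance cap (%.1f s); "
            "using the cap as delta_min",
            config.max_tolerance_s,
        )
    return SensitivityCurve(
        deltas=tuple(config.delta_grid_s),
        values=values,
        delta_min=delta_min,
        plateau_found=plateau_found,
    )


@dataclass(frozen=True)
class ErrorSummary:
    """Duration-error statistics over matched events.

    MAE and its SD are in seconds; the mean sensor-minus-truth difference
    and its 95% confidence interval are in minutes (normal 1.96 quantile);
    ``count_bias`` is the raw sensor event count minus the ground-truth
    event count (negative = missed events).
    """

    mae_s: float
    mae_sd_s: float
    mean_diff_min: float
    ci95_half_width_min: float
    ci95_lower_min: float
    ci95_upper_min: float
    count_bias: int
    n: int


def duration_errors(
    sensor_bouts: Sequence[Bout],
    truth_bouts: Sequence[Bout],
    alignment: AlignmentResult,
    delta_min_s: float,
    truth_state: PostureState | None = None,
) -> ErrorSummary:
    """Compare the durations of the bouts opened by matched events.

    Only pairs aligned within ``delta_min_s`` contribute (true positives at
    the working tolerance). Bout ``i`` must be the bout opened by event
    ``i`` of the corresponding log. ``truth_state`` restricts the summary
    to ground-truth events of one state; the count bias is then the
    per-state event count difference.
    """
    if len(sensor_bouts) != len(alignment.sensor_events) or len(
        truth_bouts
    ) != len(alignment.truth_events):
        raise ValueError("bout sequences must parallel the aligned event logs")
    pairs = [p for p in alignment.pairs if p.delta_s <= delta_min_s]
    if truth_state is not None:
        pairs = [p for p in pairs if p.truth_event.new_state == truth_state]
    if not pairs:
        raise UndefinedMetricError("no matched events within delta_min")
    diffs_s = np.array(
        [
            sensor_bouts[p.sensor_index].duration_s
            - truth_bouts[p.truth_index].duration_s
            for p in pairs
        ]
    )
    abs_err = np.abs(diffs_s)
    n = len(diffs_s)
    mean_diff_min = float(np.mean(diffs_s)) / 60.0
    sd_min = float(np.std(diffs_s, ddof=1)) / 60.0 if n > 1 else 0.0
    half = 1.96 * sd_min / math.sqrt(n)
    if truth_state is None:
        count_bias = len(alignment.sensor_events) - len(alignment.truth_events)
    else:
        count_bias = sum(
            1 for e in alignment.sensor_events if e.new_state == truth_state
        ) - sum(1 for e in alignment.truth_events if e.new_state == truth_state)
    return ErrorSummary(
        mae_s=float(np.mean(abs_err)),
        mae_sd_s=float(np.std(abs_err, ddof=1)) if n > 1 else 0.0,
        mean_diff_min=mean_diff_min,
        ci95_half_width_min=half,
        ci95_lower_min=mean_diff_min - half,
        ci95_upper_min=mean_diff_min + half,
        count_bias=count_bias,
        n=n,
    )


@dataclass(frozen=True)
class PerUserError:
    """Per-participant mean absolute duration error."""

    user_id: str
    mae_s: float | None  # None when the user has no matched events
    n: int


def per_user_mae(
    per_user: Mapping[
        str, tuple[Sequence[Bout], Sequence[Bout], AlignmentResult]
    ],
    delta_min_s: float,
) -> list[PerUserError]:
    """Stratify the duration MAE by participant.

    The event-weighted mean of the per-user MAEs equals the pooled MAE.
    Users with no matched events within the tolerance are reported with an
    undefined (None) MAE and ``n = 0``.
    """
    if not per_user:
        raise ValueError("need at least one user")
    out: list[PerUserError] = []
    for user_id, (sensor_bouts, truth_bouts, alignment) in per_user.items():
        try:
            summary = duration_errors(
                sensor_bouts, truth_bouts, alignment, delta_min_s
            )
            out.append(PerUserError(user_id, summary.mae_s, summary.n))
        except UndefinedMetricError:
            logger.warning("user %s has no matched events; MAE undefined", user_id)
            out.append(PerUserError(user_id, None, 0))
    return out
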