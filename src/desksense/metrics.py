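"""One-vs-rest classification metrics over aligned events.

Every ground-truth event is attributed a predicted state: matched pairs
contribute the state label of the matched sensor event, and missed truth
events contribute the sensor's *prevailing* state at the truth timestamp
(the state the sensor log was in when the event should have occurred) —
a missed sit prompt, for example, shows up as that sit event being
"classified" as whatever the sensor still believed. Spurious sensor events
carry no ground truth and do not enter the table.

From the 3x3 table, each class is binarised one-vs-rest to obtain
precision, recall (sensitivity), specificity and F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import PostureState, TransitionEvent
from .validation import AlignmentResult

DEFAULT_LABELS: tuple[PostureState, ...] = (
    PostureState.SIT,
    PostureState.STAND,
    PostureState.AWAY,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Event-count table, rows = true state, columns = predicted state."""

    labels: tuple[PostureState, ...]
    counts: tuple[tuple[int, ...], ...]

    def _index(self, label: PostureState) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(f"label {label!r} not in {self.labels}") from None

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))

    def tp(self, label: PostureState) -> int:
        i = self._index(label)
        return self.counts[i][i]

    def fn(self, label: PostureState) -> int:
        i = self._index(label)
        return int(sum(self.counts[i])) - self.counts[i][i]

    def fp(self, label: PostureState) -> int:
        i = self._index(label)
        return int(sum(row[i] for row in self.counts)) - self.counts[i][i]

    def tn(self, label: PostureState) -> int:
        return self.total - self.tp(label) - self.fp(label) - self.fn(label)


def prevailing_state(
    sensor_events: Sequence[TransitionEvent], timestamp_ms: int
) -> PostureState:
    """State the sensor log asserts at ``timestamp_ms``.

    The state of the last sensor event at or before the timestamp; ``away``
    if the log is empty or starts later (the classifier's no-history prior).
    """
    state = PostureState.AWAY
    for e in sensor_events:
        if e.timestamp_ms <= timestamp_ms:
            state = e.new_state
        else:
            break
    return state


def build_confusion(
    alignment: AlignmentResult,
    labels: tuple[PostureState, ...] = DEFAULT_LABELS,
) -> ConfusionMatrix:
    """Tabulate (true state, predicted state) over all ground-truth events."""
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for pair in alignment.pairs:
        true_s = pair.truth_event.new_state
        pred_s = pair.sensor_event.new_state
        if true_s not in index or pred_s not in index:
            raise ValueError(f"state outside label set: {true_s}, {pred_s}")
        counts[index[true_s], index[pred_s]] += 1
    for j in alignment.missed_truth:
        truth_event = alignment.truth_events[j]
        pred_s = prevailing_state(alignment.sensor_events, truth_event.timestamp_ms)
        counts[index[truth_event.new_state], index[pred_s]] += 1
    return ConfusionMatrix(
        labels=labels, counts=tuple(tuple(int(c) for c in row) for row in counts)
    )


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest percentages for a single class.

    A metric whose denominator is zero (e.g. precision with no predicted
    positives) is None and named in ``undefined`` rather than reported as 0.
    """

    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    undefined: frozenset[str] = frozenset()


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def class_metrics(cm: ConfusionMatrix, label: PostureState) -> ClassMetrics:
    """Precision, recall, specificity and F1 for one class, in percent."""
    tp, fp, fn, tn = cm.tp(label), cm.fp(label), cm.fn(label), cm.tn(label)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    undefined = frozenset(
        name
        for name, value in (
            ("precision", precision),
            ("recall", recall),
            ("specificity", specificity),
            ("f1", f1),
        )
        if value is None
    )
    return ClassMetrics(precision, recall, specificity, f1, undefined)
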