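"""File formats, configuration, and the validation report.

Plain-text interchange formats:

* stream CSV — ``timestamp_ms,torso_mm,head_mm`` (integer ms and mm);
* event CSV — ``timestamp_ms,state`` with state in {sit,stand,away};
* bout CSV — ``state,start_ms,end_ms,duration_s``;
* YAML config overriding any pipeline default;
* JSON validation report shaped like the study's summary tables
  (per-state timing rows, per-class metrics, agreement).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import metrics as metrics_mod
from .agreement import bland_altman
from .bouts import Bout, ClinicalFilterConfig, bouts_from_events
from .classifier import (
    STREAM_COLUMNS,
    ClassifierConfig,
    PostureState,
    TransitionEvent,
)
from .simulator import NoiseModel
from .validation import (
    AlignmentResult,
    UndefinedMetricError,
    ValidationConfig,
    align_events,
    duration_errors,
    find_delta_min,
    pooled_alignment,
)

logger = logging.getLogger("desksense")


# ---------------------------------------------------------------- streams

def read_stream(path: str | Path) -> pd.DataFrame:
    """Read a stream CSV, validating columns and timestamp monotonicity."""
    df = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(STREAM_COLUMNS)]
    ts = df["timestamp_ms"]
    bad = ts.diff().le(0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-increasing timestamp at line {line}")
    return df


def write_stream(stream: pd.DataFrame, path: str | Path) -> None:
    stream.to_csv(path, index=False, columns=list(STREAM_COLUMNS))


# ----------------------------------------------------------------- events

def read_events(path: str | Path) -> list[TransitionEvent]:
    """Read an event CSV (``timestamp_ms,state``)."""
    df = pd.read_csv(path)
    for col in ("timestamp_ms", "state"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    events = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            state = PostureState(str(row.state))
        except ValueError:
            raise ValueError(
                f"{path}: invalid state {row.state!r} at line {line}"
            ) from None
        events.append(TransitionEvent(int(row.timestamp_ms), state))
    ts = [e.timestamp_ms for e in events]
    for i, (a, b) in enumerate(zip(ts, ts[1:])):
        if b <= a:
            raise ValueError(f"{path}: non-increasing timestamp at line {i + 3}")
    return events


def write_events(events: Sequence[TransitionEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp_ms": [e.timestamp_ms for e in events],
            "state": [e.new_state.value for e in events],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------------ bouts

def read_bouts(path: str | Path) -> list[Bout]:
    df = pd.read_csv(path)
    return [
        Bout(PostureState(str(r.state)), int(r.start_ms), int(r.end_ms))
        for r in df.itertuples(index=False)
    ]


def write_bouts(bouts: Sequence[Bout], path: str | Path) -> None:
    pd.DataFrame(
        {
            "state": [b.state.value for b in bouts],
            "start_ms": [b.start_ms for b in bouts],
            "end_ms": [b.end_ms for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------------ config

@dataclass(frozen=True)
class RunConfig:
    """Aggregate pipeline configuration with study defaults."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    filter: ClinicalFilterConfig = field(default_factory=ClinicalFilterConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)


_CLASSIFIER_KEYS = {
    "window": "window",
    "range_min_mm": "range_min_mm",
    "range_max_mm": "range_max_mm",
    "sensor_max_mm": "sensor_max_mm",
    "sample_period_s": "sample_period_s",
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; absent keys keep their defaults.

    Recognised sections: ``classifier``, ``filter`` (``min_bout_s``,
    ``filtered_states``), ``validation`` (``max_tolerance_s``,
    ``delta_grid_s``, ``plateau_epsilon``), ``noise``.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def build(cls, section: dict, transforms=None):
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in section.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
            if transforms and key in transforms:
                value = transforms[key](value)
            kwargs[key] = value
        return cls(**kwargs)

    return RunConfig(
        classifier=build(ClassifierConfig, raw.get("classifier", {})),
        filter=build(
            ClinicalFilterConfig,
            raw.get("filter", {}),
            {"filtered_states": lambda v: frozenset(PostureState(s) for s in v)},
        ),
        validation=build(
            ValidationConfig,
            raw.get("validation", {}),
            {"delta_grid_s": lambda v: tuple(float(x) for x in v)},
        ),
        noise=build(NoiseModel, raw.get("noise", {})),
    )


def config_to_dict(config: RunConfig) -> dict:
    """Serialisable view of a RunConfig (states as strings)."""
    d = dataclasses.asdict(config)
    d["filter"]["filtered_states"] = sorted(
        s.value for s in config.filter.filtered_states
    )
    return d


# ------------------------------------------------------------------ report

def run_validation(
    sensor_events: Sequence[TransitionEvent],
    truth_events: Sequence[TransitionEvent],
    config: RunConfig | None = None,
    stream_end_ms: int | None = None,
    allow_partial: bool = False,
) -> dict:
    """Full criterion-validation report for one sensor/truth log pair.

    Produces per-state timing rows (sensitivity, delta_min, MAE +- SD,
    mean difference with CI, count bias), per-class one-vs-rest metrics,
    and Bland-Altman agreement over all matched bout durations. With
    ``allow_partial`` undefined metrics become nulls instead of errors.
    """
    config = config or RunConfig()
    if stream_end_ms is None:
        stream_end_ms = max(
            sensor_events[-1].timestamp_ms if sensor_events else 0,
            truth_events[-1].timestamp_ms if truth_events else 0,
        )
    alignment = align_events(sensor_events, truth_events)
    sensor_bouts = bouts_from_events(sensor_events, stream_end_ms)
    truth_bouts = bouts_from_events(truth_events, stream_end_ms)
    return _report_from_alignment(
        alignment, sensor_bouts, truth_bouts, config, allow_partial
    )


def run_cohort_validation(
    logs: Sequence[
        tuple[Sequence[TransitionEvent], Sequence[TransitionEvent], int]
    ],
    config: RunConfig | None = None,
    allow_partial: bool = False,
) -> dict:
    """Pooled validation report over several participants.

    ``logs`` holds one ``(sensor_events, truth_events, stream_end_ms)``
    triple per participant. Events are aligned and bouts built per
    participant, then pooled, so cross-participant matches cannot occur
    and no artificial boundary bouts are introduced.
    """
    config = config or RunConfig()
    alignments, sensor_bouts, truth_bouts = [], [], []
    for sensor_events, truth_events, end_ms in logs:
        alignments.append(align_events(sensor_events, truth_events))
        sensor_bouts.extend(bouts_from_events(sensor_events, end_ms))
        truth_bouts.extend(bouts_from_events(truth_events, end_ms))
    alignment = pooled_alignment(alignments)
    return _report_from_alignment(
        alignment, sensor_bouts, truth_bouts, config, allow_partial
    )


def _report_from_alignment(
    alignment: AlignmentResult,
    sensor_bouts: Sequence[Bout],
    truth_bouts: Sequence[Bout],
    config: RunConfig,
    allow_partial: bool,
) -> dict:
    sensor_events = alignment.sensor_events
    truth_events = alignment.truth_events
    states_present = sorted(
        {e.new_state for e in truth_events}, key=lambda s: s.value
    )
    timing: dict[str, dict] = {}
    for state in states_present:
        row: dict = {}
        try:
            curve = find_delta_min(alignment, config.validation, state)
            row["sensitivity_pct"] = round(
                curve.values[curve.deltas.index(curve.delta_min)], 1
            )
            row["delta_min_s"] = curve.delta_min
            row["sensitivity_curve"] = {
                "delta_s": list(curve.deltas),
                "phi_pct": [round(v, 2) for v in curve.values],
            }
            errors = duration_errors(
                sensor_bouts, truth_bouts, alignment, curve.delta_min, state
            )
            row.update(
                mean_diff_min=round(errors.mean_diff_min, 4),
                ci95_min=[
                    round(errors.ci95_lower_min, 4),
                    round(errors.ci95_upper_min, 4),
                ],
                mae_s=round(errors.mae_s, 2),
                mae_sd_s=round(errors.mae_sd_s, 2),
                count_bias=errors.count_bias,
                n_matched=errors.n,
            )
        except UndefinedMetricError as exc:
            if not allow_partial:
                raise
            logger.warning("state %s: %s", state.value, exc)
            row["undefined"] = str(exc)
        timing[state.value] = row

    cm = metrics_mod.build_confusion(alignment)
    classes = {}
    for state in states_present:
        m = metrics_mod.class_metrics(cm, state)
        classes[state.value] = {
            "precision_pct": None if m.precision is None else round(m.precision, 2),
            "recall_pct": None if m.recall is None else round(m.recall, 2),
            "specificity_pct": None
            if m.specificity is None
            else round(m.specificity, 2),
            "f1_pct": None if m.f1 is None else round(m.f1, 2),
        }

    agreement: dict | None
    try:
        sensor_min = [
            sensor_bouts[p.sensor_index].duration_s / 60.0 for p in alignment.pairs
        ]
        truth_min = [
            truth_bouts[p.truth_index].duration_s / 60.0 for p in alignment.pairs
        ]
        ba = bland_altman(sensor_min, truth_min)
        agreement = {
            "mean_bias_min": round(ba.mean_bias_min, 4),
            "loa_half_width_min": round(ba.loa_half_width_min, 4),
            "loa_min": [round(ba.loa_lower_min, 4), round(ba.loa_upper_min, 4)],
            "slope": None if ba.slope is None else round(ba.slope, 4),
            "slope_p": None if ba.slope_p is None else round(ba.slope_p, 4),
            "n": ba.n,
        }
    except UndefinedMetricError as exc:
        if not allow_partial:
            raise
        agreement = {"undefined": str(exc)}

    return {
        "n_sensor_events": len(sensor_events),
        "n_truth_events": len(truth_events),
        "count_bias": len(sensor_events) - len(truth_events),
        "timing": timing,
        "confusion_matrix": {
            "labels": [label.value for label in cm.labels],
            "counts": [list(row) for row in cm.counts],
        },
        "classes": classes,
        "agreement": agreement,
    }
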