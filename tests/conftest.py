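import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from desksense import (
    ClassifierConfig,
    NOISE_FREE,
    PostureState,
    TransitionEvent,
    count_repetitions,
    simulate_protocol,
    stream_to_events,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> ClassifierConfig:
    return ClassifierConfig()


def make_stream(torso, head, period_ms: int = 300, start_ms: int = 0) -> pd.DataFrame:
    """Build a stream frame from parallel distance sequences."""
    torso = np.asarray(torso, dtype=float)
    head = np.asarray(head, dtype=float)
    assert torso.shape == head.shape
    ts = start_ms + period_ms * np.arange(len(torso))
    return pd.DataFrame(
        {"timestamp_ms": ts, "torso_mm": torso, "head_mm": head}
    )


def events(*pairs) -> list[TransitionEvent]:
    """events((t_ms, 'sit'), ...) -> TransitionEvent list."""
    return [TransitionEvent(int(t), PostureState(s)) for t, s in pairs]


@pytest.fixture(scope="session")
def noise_free_cohorts(config):
    """Noise-free simulated cohorts for all three protocols (7 users).

    Returns {protocol: [(sensor_events, truth_events, end_ms), ...]} plus
    pooled desk-squat counts for P3. Session-scoped: the simulation and
    classification run once for the whole suite.
    """
    out = {}
    squat = {"detected": 0, "scripted": 0}
    for proto in ("1", "2", "3"):
        logs = []
        for pid, (script, stream, truth) in simulate_protocol(
            proto, 7, 1, NOISE_FREE, config
        ).items():
            sensor = stream_to_events(stream, config)
            end_ms = max(int(stream["timestamp_ms"].iloc[-1]), truth[-1].timestamp_ms)
            logs.append((sensor, truth, end_ms))
            if proto == "3":
                r = count_repetitions(sensor, 10)
                squat["detected"] += r.detected_cycles
                squat["scripted"] += r.scripted_cycles
        out[f"P{proto}"] = logs
    out["squat"] = squat
    return out
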