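"""Scripted-protocol simulator: office-worker behaviour as sensor streams.

Renders the three laboratory protocols into two-channel distance streams
plus their ground-truth transition logs, so the whole pipeline can be
exercised without hardware:

* **P1** — static sit/stand bouts of 60–150 s (sedentary monitoring);
* **P2** — sit/stand bouts interleaved with desk departures of 60–150 s
  (presence vs absence);
* **P3** — 10 desk-squat cycles at 6 s per cycle (3 s standing + 3 s
  sitting), an active-break gesture.

A participant profile maps body height (160–190 cm) to per-state target
distances; only gate membership of those targets matters to the
classifier. The noise model injects Gaussian jitter, dropout spikes to the
sensor saturation code, postural-sway excursions while standing, and the
"chair effect" (a chair back reflecting like a seated torso during
absence). All randomness flows through a seed, so equal seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, PostureState, TransitionEvent

HEIGHT_RANGE_CM = (160.0, 190.0)

#: Per-participant bout counts that reproduce the study totals over
#: seven participants: P1 -> 56 sit + 63 stand events, P2 -> 14 sit +
#: 42 stand + 63 away events, P3 -> 140 squat transitions.
P1_DEFAULT_COUNTS = {PostureState.SIT: 8, PostureState.STAND: 9}
P2_DEFAULT_COUNTS = {
    PostureState.SIT: 2,
    PostureState.STAND: 6,
    PostureState.AWAY: 9,
}
P3_CYCLES = 10
P3_CYCLE_PERIOD_S = 6.0
P3_LEAD_IN_S = 6.0
DEFAULT_DURATION_RANGE_S = (60.0, 150.0)


@dataclass(frozen=True)
class ScriptedAction:
    """One prompt of the movement script: hold ``state`` for ``duration_s``."""

    state: PostureState
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("action duration must be positive")


@dataclass(frozen=True)
class ProtocolScript:
    """A participant's scripted schedule for one protocol."""

    protocol_id: str
    participant_id: str
    actions: tuple[ScriptedAction, ...]

    @property
    def total_duration_s(self) -> float:
        return sum(a.duration_s for a in self.actions)

    def truth_events(self, start_ms: int = 0) -> list[TransitionEvent]:
        """Ground-truth transition log: one event per action start."""
        events = []
        t = float(start_ms)
        for action in self.actions:
            events.append(TransitionEvent(int(round(t)), action.state))
            t += action.duration_s * 1000.0
        return events


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-state target distances for one participant.

    The torso beam sees the chest while seated (closer for shorter users)
    and the upper torso while standing; the head beam clears the seated
    head (saturating at ``seated_head_mm``) and sees the head while
    standing. Absence saturates both channels.
    """

    participant_id: str
    height_cm: float
    seated_torso_mm: float
    standing_torso_mm: float
    standing_head_mm: float
    seated_head_mm: float = 8191.0
    away_mm: float = 8191.0

    def targets(self, state: PostureState) -> tuple[float, float]:
        """(torso, head) target distances for a posture state."""
        if state is PostureState.SIT:
            return (self.seated_torso_mm, self.seated_head_mm)
        if state is PostureState.STAND:
            return (self.standing_torso_mm, self.standing_head_mm)
        return (self.away_mm, self.away_mm)


def profile_for_height(
    height_cm: float,
    participant_id: str = "U1",
    config: ClassifierConfig | None = None,
) -> ParticipantProfile:
    """Map body height to target distances.

    Seated torso distance interpolates linearly over 160–190 cm to
    600–900 mm; standing targets sit mid-gate with a mild height trend.
    """
    config = config or ClassifierConfig()
    lo, hi = HEIGHT_RANGE_CM
    if not (lo <= height_cm <= hi):
        raise ValueError(f"height {height_cm} cm outside [{lo}, {hi}]")
    frac = (height_cm - lo) / (hi - lo)
    profile = ParticipantProfile(
        participant_id=participant_id,
        height_cm=height_cm,
        seated_torso_mm=600.0 + 300.0 * frac,
        standing_torso_mm=1000.0 + 150.0 * frac,
        standing_head_mm=750.0 - 150.0 * frac,
        seated_head_mm=config.sensor_max_mm,
        away_mm=config.sensor_max_mm,
    )
    for mm in (
        profile.seated_torso_mm,
        profile.standing_torso_mm,
        profile.standing_head_mm,
    ):
        if not config.in_range(mm):
            raise ValueError(f"profile distance {mm} mm outside the gate")
    return profile


def default_heights(n_participants: int) -> np.ndarray:
    """Evenly spread heights across the recruited 160–190 cm range."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if n_participants == 1:
        return np.array([175.0])
    return np.linspace(*HEIGHT_RANGE_CM, n_participants)


@dataclass(frozen=True)
class NoiseModel:
    """Artifact injection parameters for stream synthesis.

    ``gaussian_sd_mm`` — per-sample ranging jitter; ``dropout_prob`` —
    per-sample, per-channel probability of a spike to the saturation code;
    ``sway_rate_per_min`` — Poisson rate of brief (<= 2 s) out-of-range
    excursions while standing; ``chair_effect`` — a chair back reflecting
    in-range on the torso channel during away bouts;
    ``transition_ramp_s`` — time the distances take to travel between
    posture targets at each scripted change; ``seed`` — RNG seed.
    """

    gaussian_sd_mm: float = 15.0
    dropout_prob: float = 0.005
    sway_rate_per_min: float = 0.0
    chair_effect: bool = False
    chair_torso_mm: float = 1200.0
    transition_ramp_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.gaussian_sd_mm < 0 or self.sway_rate_per_min < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.transition_ramp_s < 0:
            raise ValueError("transition_ramp_s must be >= 0")


#: Artifact-free rendering (posture ramps still apply — bodies take time
#: to move even in the idealised streams).
NOISE_FREE = NoiseModel(
    gaussian_sd_mm=0.0, dropout_prob=0.0, sway_rate_per_min=0.0,
    chair_effect=False,
)


def generate_script(
    protocol_id: str,
    participant_id: str,
    rng_seed: int,
    bout_counts: dict[PostureState, int] | None = None,
    duration_range_s: tuple[float, float] = DEFAULT_DURATION_RANGE_S,
) -> ProtocolScript:
    """Build one participant's scripted schedule.

    P1 alternates stand/sit (default 9 stand + 8 sit) with durations drawn
    uniformly from ``duration_range_s``; P2 interleaves desk departures
    with stand and sit bouts (default 9 away, 6 stand, 2 sit); P3 is a
    seated lead-in followed by 10 squat cycles of 3 s standing + 3 s
    sitting. The same seed always yields the same script.
    """
    protocol_id = str(protocol_id).upper().lstrip("P")
    rng = np.random.default_rng(rng_seed)
    lo, hi = duration_range_s
    if lo <= 0 or hi < lo:
        raise ValueError("invalid duration range")

    def draw() -> float:
        return float(rng.uniform(lo, hi))

    if protocol_id == "1":
        counts = dict(bout_counts or P1_DEFAULT_COUNTS)
        n_sit = counts.get(PostureState.SIT, 0)
        n_stand = counts.get(PostureState.STAND, 0)
        if abs(n_sit - n_stand) > 1 or n_sit + n_stand == 0:
            raise ValueError("P1 needs alternating sit/stand counts (|diff| <= 1)")
        first = PostureState.STAND if n_stand >= n_sit else PostureState.SIT
        other = PostureState.SIT if first is PostureState.STAND else PostureState.STAND
        sequence = []
        for i in range(n_sit + n_stand):
            sequence.append(first if i % 2 == 0 else other)
        actions = [ScriptedAction(s, draw()) for s in sequence]
    elif protocol_id == "2":
        counts = dict(bout_counts or P2_DEFAULT_COUNTS)
        n_sit = counts.get(PostureState.SIT, 0)
        n_stand = counts.get(PostureState.STAND, 0)
        n_away = counts.get(PostureState.AWAY, 0)
        if n_away != n_sit + n_stand + 1:
            raise ValueError(
                "P2 interleaves desk departures between presence bouts: "
                "need n_away == n_sit + n_stand + 1"
            )
        present = [PostureState.STAND] * n_stand + [PostureState.SIT] * n_sit
        sequence = [PostureState.AWAY]
        for state in present:
            sequence.extend([state, PostureState.AWAY])
        actions = [ScriptedAction(s, draw()) for s in sequence]
    elif protocol_id == "3":
        half = P3_CYCLE_PERIOD_S / 2.0
        actions = [ScriptedAction(PostureState.SIT, P3_LEAD_IN_S)]
        for _ in range(P3_CYCLES):
            actions.append(ScriptedAction(PostureState.STAND, half))
            actions.append(ScriptedAction(PostureState.SIT, half))
    else:
        raise ValueError(f"unknown protocol id: {protocol_id!r}")
    return ProtocolScript(
        protocol_id=f"P{protocol_id}",
        participant_id=participant_id,
        actions=tuple(actions),
    )


def synthesize_stream(
    script: ProtocolScript,
    profile: ParticipantProfile,
    noise: NoiseModel | None = None,
    config: ClassifierConfig | None = None,
    start_ms: int = 0,
) -> tuple[pd.DataFrame, list[TransitionEvent]]:
    """Render a script into a raw distance stream plus its ground truth.

    Samples are emitted every ``sample_period_s``; at each scripted change
    the channel targets travel linearly over ``transition_ramp_s``.
    Artifacts are injected per the noise model. Distances are rounded to
    integer millimetres and clipped to ``[0, sensor_max_mm]``.
    """
    noise = noise or NoiseModel()
    config = config or ClassifierConfig()
    if not script.actions:
        raise ValueError("script has no actions")
    rng = np.random.default_rng(noise.seed)

    period = config.sample_period_s
    total = script.total_duration_s
    n_samples = max(1, int(round(total / period)))
    t = np.arange(n_samples) * period  # seconds from stream start

    # per-sample piecewise-constant targets, then ramps at each boundary
    torso = np.empty(n_samples)
    head = np.empty(n_samples)
    boundaries = np.cumsum([0.0] + [a.duration_s for a in script.actions])
    for i, action in enumerate(script.actions):
        last = i == len(script.actions) - 1
        mask = (t >= boundaries[i]) if last else (
            (t >= boundaries[i]) & (t < boundaries[i + 1])
        )
        tgt_torso, tgt_head = profile.targets(action.state)
        if noise.chair_effect and action.state is PostureState.AWAY:
            tgt_torso = noise.chair_torso_mm
        torso[mask] = tgt_torso
        head[mask] = tgt_head

    if noise.transition_ramp_s > 0:
        for i in range(1, len(script.actions)):
            b = boundaries[i]
            mask = (t >= b) & (t < b + noise.transition_ramp_s)
            if not mask.any():
                continue
            frac = (t[mask] - b) / noise.transition_ramp_s
            prev_torso, prev_head = profile.targets(script.actions[i - 1].state)
            if noise.chair_effect and script.actions[i - 1].state is PostureState.AWAY:
                prev_torso = noise.chair_torso_mm
            new_torso, new_head = profile.targets(script.actions[i].state)
            if noise.chair_effect and script.actions[i].state is PostureState.AWAY:
                new_torso = noise.chair_torso_mm
            torso[mask] = prev_torso + (new_torso - prev_torso) * frac
            head[mask] = prev_head + (new_head - prev_head) * frac

    # postural sway: brief both-channel saturation excursions while standing
    if noise.sway_rate_per_min > 0:
        for i, action in enumerate(script.actions):
            if action.state is not PostureState.STAND:
                continue
            expected = noise.sway_rate_per_min * action.duration_s / 60.0
            for _ in range(rng.poisson(expected)):
                onset = boundaries[i] + rng.uniform(0.0, action.duration_s)
                length = rng.uniform(0.5, 2.0)
                mask = (t >= onset) & (t < onset + length)
                torso[mask] = config.sensor_max_mm
                head[mask] = config.sensor_max_mm

    if noise.gaussian_sd_mm > 0:
        torso = torso + rng.normal(0.0, noise.gaussian_sd_mm, n_samples)
        head = head + rng.normal(0.0, noise.gaussian_sd_mm, n_samples)

    if noise.dropout_prob > 0:
        torso = np.where(
            rng.random(n_samples) < noise.dropout_prob, config.sensor_max_mm, torso
        )
        head = np.where(
            rng.random(n_samples) < noise.dropout_prob, config.sensor_max_mm, head
        )

    stream = pd.DataFrame(
        {
            "timestamp_ms": start_ms + np.round(t * 1000.0).astype(np.int64),
            "torso_mm": np.clip(np.round(torso), 0, config.sensor_max_mm).astype(
                np.int64
            ),
            "head_mm": np.clip(np.round(head), 0, config.sensor_max_mm).astype(
                np.int64
            ),
        }
    )
    return stream, script.truth_events(start_ms)


def simulate_protocol(
    protocol_id: str,
    n_participants: int,
    seed: int,
    noise: NoiseModel | None = None,
    config: ClassifierConfig | None = None,
) -> dict[str, tuple[ProtocolScript, pd.DataFrame, list[TransitionEvent]]]:
    """Simulate a whole protocol cohort.

    Heights are spread evenly over 160–190 cm; each participant gets an
    independent script seed and noise seed derived from ``seed``.
    Returns ``{participant_id: (script, stream, truth_events)}``.
    """
    noise = noise or NoiseModel()
    config = config or ClassifierConfig()
    heights = default_heights(n_participants)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_participants)
    out = {}
    for k, height in enumerate(heights):
        pid = f"U{k + 1}"
        script = generate_script(protocol_id, pid, int(seeds[2 * k] % 2**31))
        profile = profile_for_height(float(height), pid, config)
        stream, truth = synthesize_stream(
            script,
            profile,
            replace(noise, seed=int(seeds[2 * k + 1] % 2**31)),
            config,
        )
        out[pid] = (script, stream, truth)
    return out
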