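# desksense

Tools for a privacy-preserving, desk-mounted dual **time-of-flight (ToF)
distance sensor** that monitors sedentary behaviour at a workstation. Two
infrared ranging beams — one aimed at the seated torso, one just above
seated head height — each report the distance (mm) to the nearest
reflecting surface at 3.3 Hz, saturating at 8191 mm when nothing is in the
beam. From that two-channel stream the package classifies the worker's
posture, logs bouts, counts desk-squat exercise repetitions, and computes
the full criterion-validation statistics used to assess such a device
against ground truth. A built-in simulator renders scripted office-worker
protocols into realistic streams, so the entire pipeline runs with no
hardware.

Intended users: researchers in occupational health / digital sensing who
want to reproduce, stress-test or extend this class of desk sensor, and
developers validating a classifier revision against scripted protocols.

## The method

**Differential Distance Classifier.** Each channel is smoothed with a
trailing moving average of ω = 8 samples, then gated: a target is
*detected* when its smoothed distance lies in [300, 2000] mm. The decision
tree is

| torso detected | head detected | state |
|---|---|---|
| yes | no | `sit` |
| yes | yes | `stand` |
| no | no | `away` |
| no | yes | hold previous (geometrically implausible) |

State changes are logged as transition events (t_i, new state); bout *i*
has duration D_i = t_{i+1} − t_i. A clinical filter suppresses `stand` /
`away` bouts shorter than 60 s (the minimum activity-bout duration
considered cardiometabolically meaningful) by merging their time into the
preceding retained bout — time is reassigned, never deleted.

**Desk squats.** The prescribed active break is 10 rapid sit→stand→sit
cycles at 6 s per cycle. Correctness is
ψ = 100 · (detected cycles) / (scripted cycles), counted on the
*unfiltered* transition log.

**Validation statistics.** Sensor events S = {t_i} are greedily matched to
ground-truth events G = {t_i′} by smallest |t_i − t_i′|. From the matching
the package computes:

* sensitivity ϕ_δ = 100 · (events matched within δ) / |G|, swept over
  δ = 1…10 s to find δ_min, the smallest tolerance (≤ δ_T = 5 s) at which
  ϕ plateaus;
* duration errors over matched events: MAE = (1/n) Σ |S_i − G_i| on paired
  bout durations, the mean difference d̄ with CI95 = d̄ ± 1.96·σ_d/√n, and
  the count bias N_sensor − N_truth (also stratified per user);
* one-vs-rest confusion matrices over all ground-truth events (missed
  events are attributed to the sensor's prevailing state), with per-class
  precision, recall, specificity and F1;
* Bland–Altman agreement: mean bias, 95 % limits of agreement
  d̄ ± 1.96·SD, and an OLS proportional-bias slope test.

## Worked example

Simulate the static sit/stand protocol (P1: 8 sit + 9 stand bouts of
60–150 s per participant, 7 participants), classify the noise-free
streams, and validate against the scripted ground truth:

```python
from desksense import (NOISE_FREE, RunConfig, simulate_protocol,
                       stream_to_events)
from desksense.io import run_cohort_validation

cfg = RunConfig()
logs = []
for pid, (script, stream, truth) in simulate_protocol("1", 7, 1,
                                                      NOISE_FREE).items():
    sensor = stream_to_events(stream, cfg.classifier)
    end = max(int(stream["timestamp_ms"].iloc[-1]), truth[-1].timestamp_ms)
    logs.append((sensor, truth, end))
report = run_cohort_validation(logs, cfg)
print(report["timing"]["sit"])
print(report["agreement"])
```

prints (abbreviated):

```
sit:   sensitivity 100.0 % at delta_min 2 s, MAE 1.53 ± 0.14 s,
       mean diff 0.0255 min, count bias 0, n = 56
stand: sensitivity 100.0 % at delta_min 3 s, MAE 1.57 ± 0.39 s,
       mean diff −0.0226 min, count bias 0, n = 63
agreement: bias 0.00 min, LoA ± 0.0517 min, slope −0.0018 (p = 0.75),
       n = 119
```

Every scripted transition is recovered (count bias 0) within the
smoothing latency ω·0.3 s = 2.4 s; the residual ~1.5-s MAE is exactly the
asymmetry of that latency between entering and leaving the detection
gate, and the Bland–Altman limits (± 3.1 s) show duration agreement at
the scale of single samples.

The same workflow is available from a shell:

```bash
desksense simulate --protocol 3 --participants 7 --seed 1 --out-dir runs/
desksense classify --stream runs/P3_U1_stream.csv --out runs/U1_events.csv
desksense reps --events runs/U1_events.csv --scripted 10
# {"detected_cycles": 10, "scripted_cycles": 10, "psi_pct": 100.0, ...}
desksense validate --sensor runs/U1_events.csv --truth runs/P3_U1_truth.csv \
    --allow-partial
desksense report --participants 7 --seed 1 --out report.json
```

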