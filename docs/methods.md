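# Methods

## Classifier model and assumptions

The Differential Distance Classifier assumes a fixed sensor geometry: the
torso beam intersects the user's chest whenever they are at the desk
(seated or standing), and the head beam clears the seated head, returning
the saturation code (8191 mm) unless the user stands into it. Posture is
then a pure function of which beams detect a target inside the presence
gate [300, 2000] mm — `sit` (torso only), `stand` (both), `away`
(neither). The gate bounds accommodate forward leans (300 mm floor) and
backward leans while rejecting passers-by (2000 mm ceiling).

Design choices where the behaviour was genuinely open:

* **Warm-up.** The trailing ω-sample moving average uses a partial
  (growing) window for the first ω − 1 samples instead of dropping them,
  keeping the state sequence index-aligned with the raw stream.
* **Gate closure.** The presence gate is inclusive at both ends.
* **Implausible input.** A head-only detection cannot arise from the
  geometry; it is treated as transient noise — the previous state is held
  (or `away` with no history) and a warning logged — rather than
  inventing a fourth state.
* **Order of operations.** Smoothing applies to raw distances before
  gating, not to gated booleans; detection latency (≈ ω·0.3 s = 2.4 s
  worst case) is an emergent property of the smoothing, not a separately
  modelled delay.

## Clinical filter

Stand/away bouts shorter than `min_bout_s` (default 60 s) are merged
*backward* into the immediately preceding retained bout; runs of
consecutive sub-threshold bouts accumulate into the same predecessor; a
leading sub-threshold bout (no predecessor) merges forward; the final
bout is always retained since the session may simply be truncated there.
Merges that leave equal-state neighbours adjacent coalesce them. Total
time is conserved to the millisecond, and the filter is idempotent.

The published worked example for this mechanism (a 90-s stand fragmented
at the 33-s mark by a 1-s sway artifact, yielding a 94-s sit and a
truncated stand) is internally inconsistent by about 1 s in its printed
arithmetic (33 + 56 = 89; 94 + 57 = 151 of a 150-s window); the
implementation and tests assert exact conservation — a 94-s sit and a
56-s stand — rather than the printed 57 s.

Repetition counting deliberately consumes the *unfiltered* transition log
(the 60-s threshold only triggers interventions); a desk-squat cycle is a
complete sit→stand→sit excursion whose closing sit may open the next
cycle, and a trailing unterminated sit→stand is reported separately, not
counted.

## Event alignment and tolerance analysis

Matching between sensor and ground-truth logs is globally greedy on
absolute time difference: repeatedly pair the unmatched combination with
the smallest |Δt|, ties broken toward the earlier truth event, then the
earlier sensor event. This rule is deterministic and is checked against
an independent exhaustive re-implementation in the tests. It is *not*
guaranteed to minimise total cost — a documented two-event counterexample
lives in the test suite — but it is the plainest reading of
nearest-neighbour pairing and behaves identically to optimal assignment
when inter-event spacing dominates detection latency, which holds for the
static protocols.

Matching is purely temporal. State-label agreement is assessed separately
via one-vs-rest confusion matrices in which every ground-truth event
appears: matched pairs contribute the sensor label, and missed truth
events contribute the sensor's prevailing state at the truth timestamp
(`away` when there is no earlier sensor event). Undefined ratios (0/0)
are flagged as such, never silently reported as 0.

δ_min selection: sensitivity ϕ_δ is evaluated on the grid 1…10 s; δ_min
is the smallest grid tolerance not exceeding the cap δ_T = 5 s whose
sensitivity is within `plateau_epsilon` (default 0, i.e. a strict
plateau) of the best achievable under the cap. If the curve is still
rising at the cap, δ_min falls back to the cap with a warning.

Numerical conventions: timestamps are integer milliseconds throughout;
durations are seconds except Bland–Altman quantities, which are minutes;
the CI95 of the mean difference uses the normal 1.96 quantile (not a t
quantile); SDs use the n − 1 denominator; the proportional-bias slope is
an OLS regression of differences on pair means with a two-sided t-test,
reported as undefined for n < 3 or degenerate variance.

## Simulator

The simulator renders three scripted protocols per participant:

* **P1** (static sit/stand): 9 stand + 8 sit alternating bouts, durations
  uniform on [60, 150] s.
* **P2** (presence/absence): 9 desk departures interleaving 6 stand and
  2 sit bouts (away–stand–…–away–sit–away), durations uniform on
  [60, 150] s.
* **P3** (desk squats): a 6-s seated lead-in followed by 10 cycles of 3-s
  stand + 3-s sit halves, so each cycle is a complete sit→stand→sit
  excursion and the script contains exactly 20 transitions.

With seven participants these per-participant counts give the cohort
census the validation framework expects: 119 P1 events (56 sit,
63 stand), 119 P2 events (14 sit, 42 stand, 63 away) and 140 P3
transitions — 378 events in all.

Participant profiles map height (160–190 cm, spread evenly across the
cohort) to target distances: seated torso 600–900 mm (linear in height),
standing torso 1000–1150 mm and standing head 750–600 mm (mid-gate with a
mild height trend), seated head and absence at the 8191-mm saturation
code. Only gate membership of these targets matters to the classifier;
the exact values are plumbing.

Streams are sampled every 0.3 s; at each scripted change the channel
distances travel linearly over a 1.0-s transition ramp (bodies take time
to move, and the ramp exercises the classifier's behaviour on
intermediate values, including the transient implausible head-only
combination during away→stand). The noise model adds, per configuration:
Gaussian ranging jitter (default SD 15 mm), per-sample dropout spikes to
the saturation code (default probability 0.005 per channel), Poisson
postural-sway excursions (≤ 2 s, both channels saturate) while standing,
and the "chair effect" — a chair back reflecting in-range on the torso
channel during absence, which the classifier necessarily misreads as
sitting. All randomness flows through explicit seeds; equal seeds give
bit-identical streams.

What the simulator does **not** emulate: biomechanically realistic
kinematics (ramps are linear, not sigmoid), sensor-specific noise spectra
or temperature drift, clock skew between sensor and reference, and
unscripted human variability (fidgeting, partial postures, chair
rotation). Passing round-trip tests therefore demonstrates the internal
consistency of the pipeline under the stated artifact models, not field
performance with real hardware and real workers.

## Known limitations and behaviour at protocol extremes

The trailing-mean gate has asymmetric latency: a channel crossing from
saturation (8191 mm) into the gate needs ~7 of 8 window samples in range
(≈ 1.8–2.4 s including the ramp), while leaving the gate needs only 2–3
(≈ 0.6–0.9 s). For the static protocols (bouts ≥ 60 s) this merely
shifts detections by ≤ 3 s and leaves a ~1.5-s duration MAE. At the
desk-squat cadence (3-s half-bouts) the slow crossing approaches the
inter-event spacing, so *temporal alignment* of individual squat
transitions becomes ill-posed: a label-agnostic nearest-neighbour matcher
can legitimately pair a late-detected event with the next scripted event.
The gesture protocol is therefore validated by repetition counting (ψ)
and event-count bias — both exact on noise-free streams — rather than by
tolerance sensitivity or duration errors, mirroring how gesture
correctness is defined in the validation framework. Cycle counting
remains exact down to cadences of ~4 samples per half-cycle; below that
the smoothed signal can no longer cross the gate within each half-bout.

## Problem sizes

The default study conditions — 7 participants, 17 bouts of 60–150 s per
static protocol (≈ 30 min of 3.3-Hz samples each) and 66-s squat
sessions — run the full simulate→classify→validate loop in a few seconds;
the property-based suites use up to 100 randomized examples per
invariant. These sizes were chosen to match the scripted laboratory
protocols exactly, so nothing is scaled down relative to the study
design.
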