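# Methods

This note records the models, parameter choices and numerical decisions
behind `glyforecast`, what the synthetic cohort does and does not emulate,
and the known limitations.

## Synthetic cohort

**Glucose dynamics.** Each subject's glucose follows a linear
three-compartment system integrated with RK4 at 1-minute steps: a gut
compartment Q (grams, first-order absorption, rate 1/40 min⁻¹, filled 10 min
after each logged meal), a two-stage insulin-action chain S→X (rate
1/55 min⁻¹, so action peaks near one hour and spans several hours), and
glucose G relaxing toward a basal level (rate 0.0035 min⁻¹) while being
driven up by carbohydrate absorption and down by insulin action. Gains are
set so that one unit of insulin ultimately offsets `carb_ratio` grams of
carbohydrate: cs = ISF/CR mg/dL per gram and si = ISF mg/dL per unit. The
system is linear, so excursions scale exactly with carbohydrate load — a
property the tests exploit — and an exactly matched bolus returns glucose to
basal. Readings are sampled on the 5-minute grid, perturbed by AR(1) noise
(ρ = 0.8, subject-specific SD 4–8 mg/dL) and clamped to the commercial
sensor reporting range [40, 400] mg/dL.

**Behavior model.** Three meals per day (≈45/55/62 g with jittered times,
≈160 g/day median, reflecting modest real-world carbohydrate intake) are
dosed from the subject's carb ratio with multiplicative lognormal error
(SD ≈ 0.2, slight under-dosing bias, clipped to [0.6, 1.45]) and an 8%
missed-bolus rate. Under the default population ranges (ISF 35–65 mg/dL/U,
CR 8–15 g/U, basal 128–172 mg/dL) this yields roughly 1–3% of time below
70 mg/dL, ~63–75% in [70, 180], and the rest above — a low-hypoglycemia,
appreciable-hyperglycemia mix typical of free-living adult cohorts. The
rates were fixed once against these population marginals and are not tuned
per experiment.

**Wristband waveforms.** BVP at 64 Hz is a sum of per-beat templates (a
dominant 40 ms Gaussian systolic peak plus a small dicrotic bump) at
ground-truth beat times drawn i.i.d. around the subject's mean IBI;
band-limited Gaussian noise is optional. EDA at 4 Hz is a slow tonic drift
(periods ≥ 28 min) plus unit-peak difference-of-exponentials SCR pulses
(rise 0.7 s, decay 4 s) at Poisson onsets with lognormal amplitudes. ACC
(32 Hz) is gravity plus noise with occasional motion bursts; TEMP (4 Hz) is
a noisy diurnal constant. The generator returns every latent quantity
(beat times, SCR onsets/amplitudes, tonic trace) as ground truth for the
recovery tests.

**Missingness.** Gaps are contiguous blocks, not pointwise dropout: CGM
targets 3.02% missing in ~30-minute blocks; wristband channels share a
common gap timeline targeting 23.05% including one 4–5 h block per day
(battery charging). Block placement repeats until the realized fraction is
within 0.5 percentage points of target.

**Scale limits.** Full-rate waveforms for a multi-week cohort would require
gigabytes, so `generate_cohort` renders a short waveform excerpt per subject
and produces the cohort-length wristband *grid features* (per-5-minute IBI
mean, SDNN, RMSSD, LF/HF, SCL, SCR level/count, activity, temperature)
directly from the same latent processes (circadian modulation +
Ornstein–Uhlenbeck variation). The waveform→features signal path is
validated separately on excerpt-scale data; the learning experiments consume
the grid features. Consequently the cohort's wristband features are only
weakly informative about glucose; passing the learning tests demonstrates
that the pipeline learns glucose/meal/insulin dynamics and that
meta-initialization transfers, not that HRV/EDA are predictive in real
patients.

## Signal processing

BVP is band-passed with a zero-phase order-3 Butterworth filter, 0.5–8 Hz
(cardiac fundamentals and harmonics). Beats come from a slope-sum transform
(trailing 128 ms window of positive slopes) whose local maxima are accepted
when they exceed 0.5× the running median of the last 8 accepted peak
amplitudes, with a 300 ms refractory period; detections are snapped to the
local maximum of the filtered waveform, removing the slope-sum lag. These
decision-rule constants are config-exposed since detector variants differ.
IBIs outside [0.3, 2.0] s are flagged invalid but retained.

EDA is split by a zero-phase order-2 high-pass at 0.01 Hz: phasic = filtered
signal, tonic = remainder, an exactly additive decomposition. The cutoff
sits an order of magnitude above the tonic drift band (< 0.001 Hz) yet low
enough to keep SCR pulse energy: SCR recovery half-times of seconds put
substantial pulse energy below 0.05 Hz, and a higher cutoff visibly distorts
the recovered phasic trace (recovery correlation ~0.68 at 0.05 Hz versus
~0.93 at 0.01 Hz on ground-truth pulses).

HRV uses the trailing 5-minute window only: mean IBI, SDNN, RMSSD in the
time domain; LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) power of the tachogram
linearly resampled at 4 Hz via Welch's method. Windows with fewer than 10
valid intervals are missing. All grid features average the half-open
trailing window (t−300 s, t], so nothing computed at t can see later data.

## Feature engineering

- **IOB**: each bolus decays by a piecewise-linear remaining-fraction curve —
  90% left at 1 h, zero at 4 h (insulin acts for about four hours with two
  slopes, the convention of commercial pumps); knots and duration are
  config-exposed because pump curves vary.
- **COB**: a meal's carbohydrate sits unabsorbed for 15 min, then absorbs at
  2.5 g/min until exhausted.
- **time_index**: minutes since midnight scaled to [0, 1); a sin/cos
  encoding is available for the midnight discontinuity.
- **Gap handling**: interior gaps are linearly interpolated; trailing gaps
  carry the last value forward (a last-slope extrapolation is available);
  leading gaps invalidate their windows. Carry-forward is the default
  because slope extrapolation can run away across long terminal gaps.
- **Normalization**: per-column min-max fitted on the chronological training
  rows only; test values may leave [0, 1]. Constant columns raise an error
  naming the column.
- **Selection**: features derived from the same sensor are strongly
  collinear, so candidate sets keep the core block (glucose, COB, IOB,
  time index) plus exactly one IBI-group and one EDA-group feature; the set
  minimizing validation RMSE summed over the four horizons wins, ties going
  to fewer features then lexicographic order. The shipped default input is
  (glucose, COB, IOB, time index, IBI mean, SCR level).
- **Windows**: length l = 12 (one hour of history), stride one grid step,
  one model per horizon w ∈ {3, 6, 9, 12} steps (15–60 min). A window needs
  l fully observed-or-interpolated rows and *observed* (not interpolated)
  glucose at both the anchor t and target t+w. Targets are glucose changes,
  normalized by their training-range min-max.

## Network and loss

Defaults: bidirectional GRU with 32 units per direction (16 in the compact
experiment configuration), a second 32-unit GRU, attention output of the
same width, and the four-neuron evidential head. Output activations enforce
the NIG domain: λ = softplus(r₂)+ε, α = softplus(r₃)+1+ε, β = softplus(r₄)+ε
with ε = 10⁻⁶. The loss is the Student-t NLL of the NIG marginal,
St(y; γ, β(1+λ)/(λα), 2α), plus 0.01·|y−γ|·(2λ+α) (evidence regularizer in
the range customary for evidential regression). The attention softmax is
max-subtracted; the logistic is computed via tanh for stability.

De-normalizing the uncertainty: an uncertainty is a scale, not a location,
so the default applies only the linear part of m⁻¹ (the training max−min of
the target) to u; the literal affine inverse (which can produce negative
widths) is available behind a flag for comparison. Bounds and forecast are
clamped to [40, 400] mg/dL.

Because no deep-learning framework is part of the dependency set, the model
runs on the package's own ~200-line reverse-mode autodiff engine
(numpy-array tensors, broadcast-aware backward). Its gradients are verified
against central finite differences at 10⁻⁴ relative tolerance in the suite.

## Training

Per subject, windows split chronologically: first 50% training pool (its
final 20% is validation), last 50% test. Random splitting is refused —
adjacent CGM windows are near-duplicates, and shuffling would leak them
across sets. A strict mode additionally drops the few windows whose input or
target spans a split boundary.

Population training is FOMAML: each outer step samples tasks (subjects),
adapts each with inner SGD steps (default inner_lr 0.01, 2 steps, batch 64)
on a support batch, and applies the query-batch gradient at the adapted
weights — no second derivatives — through an outer Adam (lr 0.002, 50 outer
steps in the compact configuration). `inner_steps=0` reduces to pooled
training, which is also the degenerate-case test. Personalization fine-tunes
with Adam at 10⁻³ and early stopping (patience 5) on the personal
validation split; the 1-day adaptation protocol restricts the personal
training windows to the first 288 grid rows. These optimizer constants are
package defaults (config-exposed), chosen for stable convergence of the
compact model, and are not claimed to replicate any particular deployment.

Bound thresholds k^l, k^u are grid-searched over {0, 0.25, …, 5}
independently for the hypo (B^l < 70) and hyper (B^u > 180) triggers,
maximizing point-level MCC on validation; ties break to the smallest k to
limit alarm fatigue, and a class with no validation events falls back to a
default k with a recorded warning.

## Evaluation

An adverse glycemic event is ≥ 3 consecutive CGM readings (≥ 15 min) below
70 or above 180 mg/dL; missing readings break runs; runs are maximal.
Confusion counts are tallied per grid point (positive truth = target time
inside an event), because percentage-style sensitivity/specificity over many
samples requires point-level accounting; an event-level summary (an event
counts as detected if ≥ 1 of its points is predicted positive) feeds the
missed-event list. MD is the MAE restricted to points inside events entirely
missed by the classifier, reported as absent — not zero — when nothing was
missed. MCC uses the 0-on-zero-denominator convention.

gRMSE multiplies each squared error by
P = 1 + 1.5·σ̄(G; 85, 30)·σ(Ĝ−G; 0, 10) + 1·σ(G; 155, 100)·σ̄(Ĝ−G; 0, 20),
where σ(x; T, s) = 1/(1+exp(−4(x−T)/s)) is a rising logistic of transition
width ≈ s and σ̄ its falling mirror. The low branch activates for
overestimated low glucose, the high branch for underestimated high glucose;
P ≥ 1 always, so gRMSE ≥ RMSE. The sigmoid shape is an internal convention
frozen in a brute-force oracle in the test suite; the eight constants are
hard defaults of `GrmseParams`. Time lag is the nonnegative shift of the
prediction series maximizing its Pearson correlation with the truth, in
minutes. Cohort numbers aggregate as mean ± SD across subjects.

## Experiment sizes

The learning experiments run on a 4-subject × 14-day cohort with the
16-unit model: meta-training on the three non-target subjects, full
personalization for the baseline comparison, and a matched-budget (4 epochs,
identical optimizer) meta-init vs random-init comparison on 1-day
adaptation. One replicate takes ~15 s on a single CPU; the acceptance
property uses 10 seeded replicates. These sizes were chosen so the full
suite runs comfortably on a laptop-class machine while preserving the
study structure (chronological splits, leave-subject-out population
training, per-subject personalization).

## Limitations

- The simulator is linear: no exercise, stress, circadian insulin
  sensitivity, protein/fat metabolism, or sensor drift/compression
  artifacts; its wristband features are largely independent of glucose, so
  cross-modal predictive value cannot be established on it.
- One model per horizon; no joint multi-horizon decoding.
- Motion-artifact detection for the wristband is out of scope; the beat
  detector is validated on template-based waveforms, not on real
  photoplethysmography with arrhythmias.
- Second-order MAML and automated hyperparameter search are intentionally
  excluded; all defaults are fixed and documented.
- The event-level "detected" rule (≥ 1 overlapping predicted-positive
  point) is an assumption; point-level metrics do not depend on it.
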