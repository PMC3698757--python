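# Methods

`telebp` re-implements, as a tested pipeline, the computational chain used to
characterise circadian blood-pressure rhythm and autonomic function in
radiotelemetered rats: arterial-waveform beat detection, telemetry-cadence
binning and 12-h dark/light summaries, LF/HF spectral power of systolic
pressure, spontaneous baroreflex gain by the sequence method, dipper/nondipper
classification, and the statistical decision tree those studies apply. No raw
animal data are available, so a calibrated synthetic waveform generator with
fully known ground truth is a first-class component: every estimator in the
package is validated by parameter recovery against what the generator
injected.

## The synthetic waveform model

Beats are generated sequentially; beat *i* starts at `t[i]` and lasts
`PI_i` ms, with `t[i+1] = t[i] + PI_i/1000`. Per beat:

- **Baseline MAP** `m(t)` interpolates between the preset's light and dark
  levels with a half-cosine ramp of 30 min around each transition (a hard step
  would be a spectral artifact). Optional per-day offsets (`day_sd`) add
  day-to-day wander of each 12-h period mean, and a dosing schedule subtracts
  a per-period reduction from each dose time (dark onset, 20:00) to the next.
- **Beat MAP** `MAP_i = m(t_i) + e_map,i`, with Gaussian noise of SD
  `noise_sd` plus a locomotor-activity-linked component: activity counts are
  drawn per 5-min epoch (gamma, period-specific mean) and scale an extra noise
  SD of `activity_coupling x activity/activity_dark`.
- **Systolic modulation** `s_i = lf_amp*sin(2*pi*lf_freq*t_i) +
  hf_amp*sin(2*pi*hf_freq*t_i)` is carried entirely by the pulse pressure:
  `SBP_i = MAP_i + PP/2 + s_i`, `DBP_i = 2*MAP_i - SBP_i`. The LF sinusoid
  (default 0.40 Hz, inside the 0.27-0.75 Hz band) emulates Mayer waves; the HF
  sinusoid (1.5 Hz, inside 0.75-3.3 Hz) emulates respiratory modulation. Its
  closed-form band power, `lf_amp^2/2`, is the spectral ground truth.
- **Baroreflex coupling**: `PI_i = 60000/hr(t_i) + G*(SBP_i - SBP_base(t_i)) +
  e_pi,i` with gain `G = brg_true` (ms/mmHg; higher pressure, longer interval)
  an optional beat delay, and residual pulse-interval noise `pi_noise_sd`
  (default 0.5 ms, well below the 1 ms/beat sequence threshold — the regime in
  which the sequence method is valid). In the noise-free limit the sequence
  method recovers `G` exactly.
- **Pulse shape**: an asymmetric raised cosine — a 50-ms half-cosine upstroke
  then a half-cosine decay filling the rest of the interval. Both halves
  average to `MAP_i` analytically, so the per-beat mean equals the injected
  baseline, and the peak sits at a fixed offset from beat onset, so
  peak-to-peak intervals equal the generated pulse intervals exactly. (A
  symmetric pulse would make detected intervals a two-beat moving average and
  corrupt the baroreflex ground truth.)

The recursion runs in a numba-compiled kernel with all noise drawn up front
from a `numpy` Generator, so equal seeds give bit-identical output; cohort
members get independent `SeedSequence`-spawned child seeds.

### Strain presets

The 12-h dark/light MAP levels of the three named presets are the published
group means: WKY 102.1/94.4, SHR 142.0/134.8, SHRcp 133.4/131.7 mmHg
(dark/light). **Everything else is a free parameter of the generator** — the
source study publishes no heart rates, pulse pressures, oscillation
amplitudes, gains or noise levels — chosen once at physiologically plausible
values: HR 340/310 (WKY), 330/300 (SHR), 320/295 (SHRcp) bpm (dark/light;
slightly lower in the hypertensive strains); pulse pressure 35 (WKY) or 45
mmHg; LF amplitude 3.0/3.5/5.0 mmHg and gain 1.6/1.2/0.8 ms/mmHg for
WKY/SHR/SHRcp, encoding the reported *directions* (elevated vasomotor LF
power and blunted baroreflex gain in SHRcp); beat-to-beat MAP noise 1.0 mmHg.

### Cohort variability: two named conditions

Between-animal jitter is configurable because two different study questions
need different conditions:

- **Calibration (default)**: level SD 0.5, period SD 0.3 mmHg, no day wander.
  A 5-animal cohort mean then recovers the preset period means to well within
  1 mmHg (SE ~0.26 mmHg), which is what the end-to-end calibration check
  measures.
- **SEM-matched (`sem_matched_jitter()`)**: level SD 1.0 + period SD 1.0 +
  day-to-day period wander SD 2.4 mmHg. The published group SEMs
  (0.7-1.3 mmHg at n=5) imply per-animal period-mean SDs of ~1.6-2.9 mmHg;
  over a 5-day recording this profile gives sqrt(1+1+2.4^2/5) ~ 1.8 mmHg,
  inside that range. This is the realistic-variability condition for the
  dipper-classification study.

## Beat detection

Systolic peaks: `scipy.signal.find_peaks` with a refractory distance of
`60/max_hr` s and a prominence threshold calibrated as 0.25x the median
prominence of an unconstrained first pass (roughly a quarter of the typical
pulse pressure, unit-free). Peak time and height are refined by a parabola
through the three apex samples; at the default 200 Hz this leaves a ~2 ms
systematic apex shift (which cancels in intervals) and a pulse-interval noise
floor of ~0.6 ms SD. Diastolic pressure is the minimum, and beat MAP the time
average, over each half-open peak-to-peak interval. Beats whose interval falls
outside `[60000/max_hr, 60000/min_hr]` ms are excluded as artifacts (counted,
never interpolated). The acquisition firmware of real telemetry systems is
proprietary, so this detector is a documented stand-in.

## Spectral analysis

Beat-to-beat SBP is linearly interpolated onto a 10 Hz grid (>2x the 3.3 Hz
band edge), then a Welch periodogram is taken: 60-s Hann-tapered segments,
50 % overlap, per-segment linear detrend, one-sided density normalised so its
integral equals the detrended-series variance. Band power integrates the
density by the trapezoid rule with linearly interpolated band edges, making
band power exactly additive over adjacent bands. The hourly index takes one
5-min window at the top of each hour (the telemetry cadence for LF/sBRG);
windows with under 8 beats or large gaps propagate as missing, never zero.

Linear interpolation attenuates the LF line by ~4 % in power at rat beat
rates (triangle-kernel roll-off) while broadband beat noise leaks ~2 % of
`noise_sd^2` into the band; at default settings recovery of `lf_amp^2/2` is
within ~5 % at 5-min windows and ~2 % at 30-min windows. HF power is
attenuated more strongly (~40 % at 1.5 Hz) — the HF band is reported but not
used as a calibration target.

## Spontaneous baroreflex gain

The sequence method scans for maximal runs of >= 3 beats in which SBP changes
monotonically by >= 0.5 mmHg/beat and pulse interval (at the configured
delay, default 0 beats) changes in the same direction by >= 1 ms/beat; each
run's gain is the OLS slope of PI on SBP, runs with |r| < 0.8 are discarded,
and the window estimate is the mean over positive slopes (falling-pressure
runs with shortening intervals also carry positive slopes and are kept). Zero
qualifying sequences yields an invalid estimate, never zero. These thresholds
are conventional sequence-method settings; the source study cites but does not
restate its parameters, so all are exposed in configuration and no fidelity to
the original ("modified") variant is claimed.

Known bias: with pulse-interval noise comparable to the per-beat threshold the
step selection favours noise-inflated excursions, overestimating low gains
(about +14 % at 0.5 ms/mmHg under default noise, <3 % at 1-4 ms/mmHg); the
noise-free limit recovers the injected gain to machine precision. The finder
is verified against brute-force enumeration of all candidate runs.

## Circadian summaries and dipper classification

Telemetry bins follow the vendor cadence: one bin every 5 min holding the
average over the first 30 s of the bin (the exact in-bin sampling convention
of the vendor is unknowable; this one is documented); bins with < 3 beats in
the sampling window are invalid. Period summaries average valid bins over
each 12-h dark (20:00-8:00) and light period, with analysis days anchored at
dark onset — the dosing time in the drug studies — so a day is one dark
period plus the following light period.

An animal is a **dipper** when its light-period MAP is significantly lower
than its dark-period MAP in a paired per-day comparison (paired t when the
day differences pass Shapiro-Wilk at alpha, Wilcoxon signed-rank otherwise;
>= 3 day pairs required). This is the statistical criterion used by the
telemetry literature this package follows, not the clinical 10 %-dip rule;
the descriptive dip percentage `100*(dark-light)/dark` is always reported. A
cohort is classified by majority vote over its animals' calls: with n = 5
animals, a cohort-level paired test cannot simultaneously detect a ~7-mmHg
dip reliably and ignore a ~1.7-mmHg dip (the noncentral-t power curve at 4 df
is too shallow for any realistic between-animal SD), whereas per-animal
classification over >= 5 recorded days followed by majority aggregation
separates the two phenotypes sharply.

Dose-response deltas compare the last day at each dose (day 7 of its week,
"after 7 days of dosing") against the animal's pre-treatment baseline mean,
per strain x period x dose. Dose effects in the generator are free
parameters; the defaults (-2/-6/-15 mmHg at 0.1/0.3/1.0 mg/kg, both periods)
encode a monotone ladder of plausible magnitude.

## Statistical decision tree

Per-group Shapiro-Wilk plus Bartlett across groups at alpha = 0.05 route every
comparison: all pass -> parametric (factorial ANOVA, repeated measures where
declared; Tukey HSD post hoc for <= 2-factor families, Bonferroni-corrected
unpaired t for 3-factor families), otherwise nonparametric (Kruskal-Wallis
with tie correction, Steel-Dwass all-pairs post hoc). Groups too small for
Shapiro-Wilk (n < 3) or with zero variance route nonparametric with the
reason logged.

Repeated measures use classical balanced split-plot strata (at most one
between-subject and two within-subject factors): each within effect is tested
against its subject-interaction stratum, with the Greenhouse-Geisser epsilon
estimated from the pooled within-group covariance and a corrected p reported
alongside the uncorrected one (the original analyses do not state a
sphericity correction; reporting both is this package's choice). No
mixed-model/REML machinery is used, matching the classical "ANOVA with
repeated measures" framing. The implementation is cross-checked in the test
suite against `pingouin.mixed_anova` and `statsmodels` `AnovaRM`.

Steel-Dwass: for each pair of groups the tie-corrected two-sample rank-sum
statistic is standardised and referred to the studentized-range distribution
with k = number of groups (df = infinity), giving single-step family-adjusted
p-values (the Steel-Dwass-Critchlow-Fligner construction). With k = 2 this
reduces to the two-sided normal rank-sum approximation. Note that with n = 5
per group and k = 6 the largest attainable standardised statistic (~2.61)
cannot reach the 5 % studentized-range critical value — an intrinsic
resolution limit of the procedure at telemetry-study sample sizes.

## Problem sizes and numerical choices

- Default waveform sampling 200 Hz (>= 4x the HF frequency with wide margin;
  ~17 beat samples at rat heart rates, enough for the parabolic peak
  refinement to resolve sub-ms timing).
- Calibration-recovery runs use 5-animal, 24-h cohorts per strain through the
  full waveform pipeline; the dipper study uses twenty replicated 5-animal,
  5-day cohorts per strain on the generator's beat-table path (the classifier
  consumes beat series; rendering and re-detecting 300 waveform-days would
  add hours of compute without touching the logic under test).
- Gain-ladder and spectral-recovery checks use 1-h stationary (mid-light)
  segments, 20 and 6 seeds respectively.
- Ties in rank tests use average ranks with tie correction; all adjusted
  p-values are clipped to [0, 1]; Bonferroni is exact `min(1, m*p)`.

## What passing tests do and do not show

The generator carries the statistical structure the analysis assumes:
stationary sinusoidal LF/HF oscillations, linear baroreflex coupling with
small residual PI noise, Gaussian beat noise, and clean pulse morphology.
Real telemetry departs from all of these — broadband 1/f pressure
variability, nonstationary bursts, waveform artifacts, non-sinusoidal Mayer
waves, state-dependent baroreflex gain — so recovery here demonstrates
correctness of the computational chain, not field performance on real
recordings. The HF band, heart rates, pulse pressures, oscillation
amplitudes, gains, noise levels and drug-effect magnitudes are generator
choices, not published values, and conclusions about them only test internal
consistency.
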