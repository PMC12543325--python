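# Methods

This note documents the models, conventions and numerical choices behind
`bpvkit`, in the order data flows through the package.

## Telemetry model

A recording is a uniform 30-s time series of SBP, DBP, MAP, PP, HR,
activity and pump state. The 30-s cadence stands for the telemeter's
burst-sampling scheme (a high-rate burst averaged to one value per 30 s);
no within-burst waveform is synthesized. Time 0 is clock midnight, so
hour-of-day is the hour index mod 24; `lights_on_clock_hour` (default 6)
makes hours 6–17 the inactive (light) phase and 18–5 the active (dark)
phase of the 12:12 cycle.

**MAP convention.** Telemetry vendors differ in how MAP is derived; the
package adopts the standard one-third rule, MAP = DBP + PP/3, applied
exactly at simulation time and verified (with PP = SBP − DBP) on read.
One consequence worth knowing: with pulse amplitudes ΔSBP = 70 and
ΔDBP = 29 mmHg the derived ΔMAP is 42.7 mmHg. Measured-channel datasets
whose MAP comes from the integrated waveform will not satisfy the
one-third identity, and their printed ΔMAP can differ from the derived
value by several mmHg; the validator therefore reports, rather than
silently repairs, inconsistent files.

## Pressor envelope

Each pump pulse drives a unitless effect `e(t) ∈ [0, 1]`: first-order rise
toward 1 with time constant `tau_rise` (default 5 min) while the pump is
on, exponential washout with half-life `t_half_decay` (default 10 min)
after it switches off — a deliberately minimal two-time-constant
pharmacodynamic model for a short-half-life agent such as angiotensin II.
Channel amplitudes scale the envelope: `delta_sbp` (70 mmHg) and
`delta_dbp` (29 mmHg) by default, giving ~150–185 mmHg SBP peaks on a
113-mmHg baseline. Heart rate couples to the SBP excursion through a
signed reflex gain `hr_gain` (default −4.2 bpm/mmHg, so a full pulse
evokes ≈ −294 bpm of bradycardia); a positive gain emulates a
norepinephrine-like tachycardic agent. Chronic blunting is linear:
the gain magnitude is multiplied by `max(0, 1 − gain_decline_per_day ·
days_since_treatment)`; no functional form being established for reflex
suppression, linearity in days is the simplest monotone choice and is off
(0/day) by default.

**Known limitation — 24-hr averages.** Because the envelope holds its
plateau for the whole 1-hr on-period, the pulses contribute their full
amplitude for roughly one hour in three, raising the treated arm's 24-hr
MAP average by ~16 mmHg over baseline. Real intermittent-pressor telemetry
shows spiky, partially escaping transients whose 24-hr averages stay near
baseline; reproducing that would require within-pulse escape dynamics that
are deliberately out of scope for this envelope. Analyses that compare
treated blocks to baseline on absolute level should therefore restrict to
pump-off epochs; variability indices, epoch deltas, slopes and NVC metrics
are unaffected.

Other generator elements: a square (or sinusoidal) circadian increment per
channel; Poisson-timed activity bursts (default 2/hr) with exponentially
decaying (τ = 120 s) excursions coupled into BP (10 mmHg/a.u.), DBP (60 %
of that) and HR (+30 bpm/a.u.), mimicking the large activity-linked BP
swings of raw traces; independent Gaussian noise per channel (defaults
6 mmHg, 20 bpm). Non-physiological samples are clamped (DBP ≥ 1 mmHg,
SBP > DBP) and counted in the log rather than rejected, so record counts
stay uniform. Note the hourly ARV this produces is cruder than real data
in both directions: baseline ARV (~4 mmHg) is below the ~11–14 mmHg of
real mice (whose non-pulse variability is dominated by behavior, not white
noise), and treated ARV (~32 mmHg) is above real values because simulated
pulses survive hourly averaging at nearly full amplitude. Passing tests
therefore demonstrate correct *analysis* behavior and correct effect
*directions*, not quantitative realism of variability magnitudes.

## Windowing and summaries

- Hourly values: the single record nearest each quarter-hour mark
  (:00/:15/:30/:45; ties broken toward the earlier record) is extracted, a
  mark counts only if a record lies within one cadence interval, and the
  ≤ 4 extracts are averaged. Hours with no extracts propagate as missing,
  never as zero.
- Phase splits: per-day active/inactive means over available hours
  (partial days keep `n_hours < 12`).
- Blocks: Baseline = mean of the last 5 pre-treatment days (day ≤ 0, day 1
  being the first full treatment day); treatment blocks are consecutive
  non-overlapping 2-day means; cohort SEM uses n−1.
- Epoch deltas: 5-min on-window at the end of the 1-hr pulse (pressor
  plateau) and 5-min off-window immediately before onset. Both placements
  are configurable (`EpochOffsetPolicy`) since acquisition pipelines
  differ; windows truncated by recording edges skip the pulse with a log
  entry. Pulses are labelled by the phase of their onset hour, so a pulse
  starting at a lights transition carries its off-window in the other
  phase — epoch tables keep per-pulse rows precisely so such cases remain
  visible.

## Variability indices

ARV uses hourly resolution (N = 24 per day, or 12 per phase) and computes
successive differences only within contiguous runs of same-phase hours:
pairs spanning the active/inactive boundary, a day boundary or a missing
hour are excluded, and the denominator is the pooled pair count. CV uses
the sample (n−1) SD; 24-hr CV divides by the day's 24-hr mean, and 12-hr
CV divides by the phase mean by default with a switch
(`cv_use_24h_denominator`) to use the 24-hr mean instead — the printed
formula fixes the denominator only for the 24-hr case, and the phase mean
keeps 12-hr CV a self-contained ratio.

## Slope analyses

All fits are ordinary least squares with a two-sided t-test on the slope;
fits require ≥ 3 points and non-degenerate x. Baroreflex windows are
100 min (20 pre + 60 pulse + 20 post), verified against the pump
annotation. Segmented autoregulation uses half-open bins
[min, 50], (50, 100], (100, max] mmHg — reported limits vary by ±1 mmHg
across sources, so the boundaries are parameters — on diameter changes
relative to the ~70-mmHg reference; bins with < 3 points are reported
missing rather than erroring. Transition analysis assigns rising samples
from pump-on onset until MAP first reaches 90 % of its plateau elevation
(plateau and pre-onset baselines are 60-s means) and falling samples
symmetrically from pump-off; the 90 % settle fraction is a free choice —
no published endpoint criterion exists — and is configurable. Spontaneous
transient dilations can be masked beforehand (rolling-median residual
> 2 robust SDs for ≥ 5 s, stimulus windows exempt); the z-threshold and
duration are heuristics for an exclusion practice that has no published
quantitative rule.

## NVC analysis

Events are cut as [onset − 30 frames, onset + 100 frames) at 3.75 fps
(8-s baseline; 100 frames = 20-s stimulus + ~6.7 s), normalized per event
to 100·(D − baseline mean)/baseline mean, and averaged with per-frame SEM.
The magnitude is the mean % change over the 75-frame stimulus window (the
peak is also reported, since "response size" summaries differ between
labs); pre/post diameters are 30-s raw-trace means flanking each
stimulus. The recovery fit is nonlinear least squares of
`plateau + span·e^{k t}` with t = 0 at stimulus offset over the first
30 s, k constrained to (−20, 0); non-convergence, < 10 frames or a
non-positive span yield a missing fit with a diagnostic instead of a
spurious rate. Because the 30-s recovery outlasts the event matrix, the
fit window is re-extracted from the raw trace per event using the same
baselines. An 8-s baseline (the shorter of the two windows in circulation;
20 s is the common alternative) is the default and configurable.

## Behavior

NOR inclusion applies the 4-s criterion to *each* object by default — the
strict reading of "explore an object for at least 4 s" — with
`per_object_rule="any"` for the permissive reading; when both criteria
fail the total-time reason is reported first. RI and DI are plain ratios
(DI ≡ 2·RI − 1). Y-maze alternation slides a width-3 window over the
entry sequence and counts pairwise-distinct triplets over (entries − 2);
immediate re-entries stay in the sequence (they consume triplet positions
and cannot score). The behavior generator draws exploration-time pairs
whose expected RI equals the requested value and arm sequences in which
each eligible triplet alternates with the requested probability, so the
expected alternation percentage equals the request.

## Scale, determinism, file formats

The packaged study conditions run at desk scale: 3 + 3 animals, 5 baseline
+ 10 treatment days at 30-s cadence, with Early = days 3–5 and Late =
days 8–10 (epoch ranges are parameters; chronic studies typically use
~days 21–25 for Late). Every stochastic element is seeded; cohort and
pipeline seeds are spawned from one root seed via `SeedSequence`, and
identical seeds give byte-identical CSV outputs. Interchange is plain CSV
(UTF-8, seconds from start, 9-decimal floats); telemetry files carry a
one-line `#` metadata header and are validated on read (schema, cadence
uniformity, PP identity, DBP ≤ MAP ≤ SBP) with offending row numbers in
the error.
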