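# Methods

This note documents the models, estimators and numerical choices behind
`cprstress`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Signals and study structure

The pipeline assumes the monitoring design of a two-person simulated
resuscitation: three phases per participant — baseline (`pre`, default
300 s), scenario (`Sim`, default 480 s; the scenario length is
configurable because protocols vary), recovery (`post`, 300 s) — with a
wrist-worn device exporting skin conductance (default 4 Hz) and
beat-to-beat intervals, and one team leader (TL) plus one team member (TM)
per dyad.

## Skin conductance

**Cleaning.** Samples outside mean ± 2 SD of the raw trace are replaced by
linear interpolation between the nearest retained neighbours. The band is
computed once on the raw trace and not iterated: iterating a 2 SD screen
progressively eats genuine signal variance (each pass re-tightens the band
on the trimmed data). Interpolation rather than deletion preserves uniform
sampling for windowed statistics; a deletion mode exists for amplitude-only
summaries.

**SCR detection.** A four-phase state machine over the cleaned trace:

1. *Listening.* The provisional baseline is the running value of the last
   local minimum since the previous event closed.
2. *Onset.* A candidate opens on any rise above the baseline and is
   confirmed when either (a) the rise is progressive — samples
   non-decreasing for at least 2 s with a cumulative rise of at least the
   0.005 μS significance floor — or (b) the signal sits ≥ 0.5 μS above the
   baseline. A drop > 0.1 μS from the candidate's running maximum before
   confirmation aborts it and returns the machine to listening.
3. *Measurement.* On confirmation, the earliest value of the rise (the
   tracked local minimum) becomes the base level; the amplitude is tracked
   to the running peak.
4. *Recovery.* The event closes at the first sample that has declined by
   at least 50 % of the peak amplitude below the peak. Events smaller
   than 0.005 μS are discarded post hoc. A trace that ends mid-event keeps
   the event with its recovery marked absent; the onset still counts
   toward SCR/min.

The two amplitude constants play different roles: 0.5 μS is an onset
*trigger*, 0.005 μS a post-hoc significance *floor*. The progressive
criterion has no slope floor, so on an unsmoothed trace white sensor noise
can occasionally assemble a qualifying non-decreasing run; with the
default noise level this contributes on the order of one spurious
low-amplitude event per minute. Real deployments smooth before detection;
the detector here is kept faithful to its stated rules instead.

**Rates and bands.** SCR/min is reported globally
(count / minutes) and over half-open 1-min sliding windows stepped by 1 s.
Half-open windows make the partition identity exact: when non-overlapping
windows tile the trace, their mean rate equals the global rate.
Arousal bands are made half-open and exhaustive — [0, 5) normal,
[5, 10) mild, [10, ∞) high — because the published bands leave 9–10 and
> 16 unassigned.

**Tonic level (SCL).** When SCRs are frequent, the mean or median of the
raw trace measures tonic *plus* phasic activity; with response amplitudes
of 0.5–1 μS at ~6 events/min the raw median sits ~0.4 μS above the true
level. `tonic_summary` therefore estimates SCL from the response-free
floor whenever detected events are supplied: detected response spans
(onset until the signal settles to within 5 % of the event amplitude above
its base) are masked; running medians over sliding 10-s windows locate the
floor (the minimum window median); and the summary is taken over samples
within 0.05 μS of that floor. This stays nearly unbiased (ground-truth
bias ≈ +0.01 μS at 6 SCR/min, ≈ +0.08 μS above 10 SCR/min) even when
responses overlap so densely that no fully response-free segment survives.
Without events the function returns the plain mean and median.

## Heart-rate variability

**Cleaning.** Zero intervals are discarded. A remaining interval is an
*isolated outlier* — a single-beat artifact such as a missed or doubled
pulse — when it falls outside the mean ± 2 SD band while both of its
neighbours fall inside; runs of extreme values are genuine physiology and
are kept, and edge beats (with only one neighbour) are never removed. The
band is evaluated leave-one-out: each interval is judged against the mean
and SD of the *other* intervals, so a gross artifact cannot widen the band
it is tested against (with a plain global band a 2000 ms artifact among
~800 ms beats escapes its own screen). Every removal breaks
successive-difference adjacency, so artifact gaps never inflate RMSSD.
The screen is a single pass; re-applying it to already-cleaned data can
trim a few band-marginal beats (no single-pass data-dependent screen is a
fixed point), which the tests document via containment rather than exact
idempotence. On artifact-free series the screen necessarily trims the
2 SD tails of genuine jitter, attenuating RMSSD by ≈ 11 %; this is the
price of the stated rule, stated here so downstream users know cleaned
RMSSD is conservative.

**Metrics.** Heart rate is 60000 / mean interval (ms). RMSSD is the root
mean square of successive differences between beats adjacent in the
recording. SD1 is the population standard deviation of those differences
divided by √2, reported in seconds — population divisor so that
SD1 = RMSSD/√2 holds exactly when the differences have zero mean and
SD1 ≤ RMSSD/√2 always. Windowed SD1 partitions the first 90 s into nine
consecutive non-overlapping 10-s windows, computes SD1 in every window
with at least three beats (sparser windows are skipped, not merged), and
averages; it is invariant to beats after the span. The windowed mean runs
slightly below the full-series value because short windows lose low-
frequency dispersion — that robustness under non-stationarity is the
reason for windowing. Seconds are used because the performance model's
optimum (0.0201) is physiologic only on that scale (~20 ms).

## Design computations

PSS-10 bands: ≤ 13 low, 14–25 moderate, ≥ 26 high. VAS stress bands keep
the instrument's published gap ([2.21, 3.62) is returned as an explicit
`unbanded` label); VAS anxiety flags values above 4.6.

Constrained randomization forbids pairing a PSS-10 ≥ 26 participant with a
PSS-10 ≤ 13 one. Feasibility has a closed form (forbidden edges connect
only the high and low groups, so only odd-sized high and low groups with
fewer than two moderate participants are unpairable). Sampling is by
rejection from uniform random perfect matchings — exactly uniform over
valid matchings, and effectively instant at study scale; for very large
cohorts, where a conflict-free shuffle has vanishing probability, a
randomized swap-repair produces a valid (no longer exactly uniform)
matching. Roles are a fair coin within each dyad; scenarios alternate
after a seeded shuffle of dyad order, giving balanced allocation.

Wilcoxon power: paired differences are modelled as Normal(δ, 1) — the
conventional standardized-shift reading of a signed-rank effect size. The
default evaluation scores the vectorized signed-rank statistic against its
exact null distribution (a dynamic-programming convolution over rank
sums); a per-replicate `scipy.stats.wilcoxon` path is retained and the
tests verify both paths produce identical decisions on shared draws.

## Statistical battery

Normality screening uses the Kolmogorov–Smirnov statistic with estimated
mean/SD and the Lilliefors correction (statsmodels); plain KS quantiles
would be anti-conservative with estimated parameters. Non-rejected
variables route to paired t tests and the mixed ANOVA, rejected ones to
Wilcoxon and Friedman; the pipeline computes both families and marks the
selected route. Friedman's χ² (df = phases − 1) gets Durbin–Conover rank
post hoc comparisons by default (pairwise Wilcoxon with Holm correction by
flag). The mixed ANOVA (phase within, role between) uses classical
sums-of-squares (pingouin) and is verified against an independent
brute-force sums-of-squares computation to 10⁻¹⁰; Bartlett's homogeneity
test is reported alongside. Bootstrap median CIs use the seeded percentile
method with 10,000 resamples by default. No multiple-testing correction is
applied across metrics by default (per-family Holm available), and the
dyadic correlation is a plain Pearson r across dyads.

## Synthetic cohort

The generator's defaults are the study conditions: per-phase HR
79.771 ± 13.924 / 95.522 ± 8.069 / 81.090 ± 18.648 bpm, RMSSD
45.507 ± 18.894 / 57.594 ± 31.750 / 45.611 ± 21.665 ms, EDA mean/median
pairs (3.2113, 1.48) / (3.7927, 1.985) / (6.0953, 2.57) μS, baseline SCR
rate 6.193 ± 3.23 events/min, PSS-10 16.67 ± 6.64, VAS stress/anxiety
3.89 ± 1.93 / 3.93 ± 1.98, dyadic coupling 0.62, performance coefficients
(−15748.2, 631.81, 2.88). Scenario- and recovery-phase SCR rates are not
reported anywhere; defaults of 10 and 8 events/min (same SD) encode
elevated sympathetic activity during and shortly after the scenario.
Performance noise defaults to 0.75 score units, a value that leaves the
dyad ranking largely intact while preventing a deterministic score.

**IBI traces** are white-jitter series: intervals 60000/HR ms plus iid
zero-mean Gaussian jitter with SD = RMSSD/√2, floored at 1 ms, filling the
phase duration. White jitter makes RMSSD and SD1 analytically controlled
(expected RMSSD equals the target; SD1 equals the per-beat SD);
autocorrelated noise is deliberately not the default.

**EDA traces** are a constant tonic level plus SCR shapes plus optional
white sensor noise (default 0.01 μS), floored at 0.001 μS. The tonic
level is drawn from the log-normal calibrated exactly to the phase's
(mean, median) pair — location ln(median), scale √(2 ln(mean/median)) —
and clipped to the physiological 0.05–30 μS range, the same clipping
policy applied to HR and RMSSD draws. The clip affects ~0.8 % of draws
and leaves the median calibration untouched; it lowers the achievable
population mean to ≈ 3.06 μS for the baseline phase (the unbounded tail
above 30 μS carried ~12 % of the reported 3.2113 mean — physiologically
impossible values the generator refuses to produce). SCRs arrive as a
homogeneous Poisson process; each is a linear ramp (1–3 s) to an amplitude
drawn uniformly in 0.5–1 μS, then exponential decay with a 4-s half-life
(so 50 % recovery terminates events in finite time). A `min_spacing`
option thins arrivals for detector-validation traces; it defaults to 0 so
event counts stay exactly Poisson.

**Dyadic coupling.** The TL's baseline tonic EDA and the TM's recovery
SCR rate are driven by a latent bivariate normal pair. Because the
bounded-log-normal transform attenuates correlation, the latent
correlation is calibrated in closed form (Stein's lemma on the clipped
margin) so the *measured* Pearson correlation of the pair equals the
configured 0.62 exactly; the calibration errors out if the requested
correlation is unattainable through the margin.

**Performance.** Each dyad's score is a·x² + b·x + c + Gaussian noise,
clipped to [0, 10] after the noise, where x is the dyad-mean *true* SD1 of
the scenario phase. Note an internal tension of the reported study
conditions: scenario RMSSD 57.6 ms implies true SD1 ≈ 0.0407 s, which
puts ~96 % of dyads on the falling limb right of the 0.0201 s optimum —
so a 15-dyad cohort shows a strong linear downslope rather than an
identifiable inverted U. The vertex analytics and parameter-recovery
tests therefore exercise the concave regime directly. The generator also
encodes no EDA → performance link, so logistic fits on sympathetic
predictors are correctly null on synthetic cohorts.

**What passing tests do and do not show.** The generator emulates
between-subject dispersion, right-skewed tonic EDA, Poisson phasic
activity, dyadic coupling and the SD1–performance law — not motion
artifacts beyond injected spikes/dropouts, not PPG-level noise,
autocorrelated HRV structure, circadian drift, or inter-phase carryover
(phases are independent draws; the reported post > Sim EDA elevation is
reproduced through the phase targets, not through a carryover mechanism).
Recovery of calibration targets on these cohorts validates the pipeline's
arithmetic and estimator design, not its robustness to real-world
artifact regimes.

## Numerical and reporting choices

- Phase labels are exactly `pre`, `Sim`, `post`; one value per
  participant × phase × metric in the cohort table, duplicates rejected,
  missing cells flagged and never imputed.
- Sliding/partition windows are half-open `[t0, t0 + w)` everywhere.
- Measured SCR/min undercounts the injected rate when responses overlap
  (two superposed responses merge into one detected event) — visible
  above ~6 events/min; rate-recovery claims are therefore made on ground
  truth, not on re-detected counts.
- Pipeline outputs are RFC-4180 CSVs; the configuration hash and seed are
  recorded in `run_manifest.json` rather than as in-file comments.
- Problem sizes in the routine runs: 30-participant cohorts for pipeline
  recovery, 2000 dyads for coupling calibration, 500 participants for the
  EDA-skew calibration, 10,000 replicates for power estimates — sizes at
  which the Monte-Carlo error is small against each check's tolerance.
- Logistic separation is detected (statsmodels perfect-separation
  warnings, non-convergence, exploding coefficients) and flagged; an
  L2-penalized refit is available by flag. Accuracy is in-sample at the
  0.5 cutoff — no holdout exists at 15 dyads.
- The quadratic fit reports OLS R²; a pseudo-R² label on a continuous
  outcome would be a category error, so none is emitted.
- All randomness descends from a single integer seed through
  `numpy.random.SeedSequence`; identical configurations reproduce outputs
  byte for byte.

## Known limitations

- The ± 2 SD screens are faithful to their stated rules but conservative:
  cleaned RMSSD on artifact-free data runs ≈ 11 % low, and the EDA screen
  flags ~4.6 % of samples on clean Gaussian noise.
- The sample median of 500 log-normal tonic draws has a standard error of
  ≈ 0.10 μS, so single-seed cohort medians scatter ~7 % around the
  calibration value even with an unbiased estimator.
- SCR detection has no smoothing stage and no deconvolution; dense
  overlapping responses merge, and tonic/phasic separation relies on the
  response-free floor rather than cvxEDA-style decomposition (out of
  scope by design).
- The rejection randomizer is exactly uniform only where a conflict-free
  shuffle is reachable; the large-cohort repair path is random but not
  proven uniform.
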