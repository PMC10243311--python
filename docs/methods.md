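# Methods

## Signal model and extrema detection

The surrogate signal is treated as a sequence of alternating breathing
extrema joined by monotone segments. Detection proceeds in three steps:

1. **Smoothing.** A centred moving average over the valid samples
   (default window 0.25 s, forced to an odd sample count so it is
   symmetric; edges use shrunken windows; invalid samples are excluded and
   all-invalid windows yield NaN). The window is deliberately short — at
   25 Hz it spans 7 samples and attenuates a 15 BPM (0.25 Hz) breathing
   fundamental by less than 1% (Dirichlet gain) while suppressing sensor
   noise. A window shorter than two sample intervals disables smoothing;
   detection then runs on the raw signal, which is also what makes
   detection idempotent on an already-smoothed trace.

2. **Candidate extrema.** Strict local extrema of the smoothed,
   polarity-corrected signal, scanned per contiguous valid run. Plateaus
   count once, at their first sample (determinism). Candidate *times* come
   from the smoothed signal; amplitudes are read from the recorded samples.

3. **Pruning.** Candidates are collapsed to alternate (the most extreme of
   a same-kind run survives; ties keep the earliest), then adjacent pairs
   violating either floor are removed iteratively, weakest first:
   - excursion ≥ `min_excursion_fraction` (default 0.2) × the typical
     peak-to-trough excursion,
   - time separation ≥ `min_half_period` (default 0.5 s, i.e. a 60 BPM
     physiological ceiling).

   The "typical excursion" is the larger of the median retained excursion
   and the p95−p5 span of the signal. The second term matters for slow
   breathers: residual noise wiggles along a long monotone descent can
   outnumber real breaths and would drag a pure median down until spurious
   extrema survive; the quantile span of the whole signal is immune to how
   many candidates there are and, for a breathing-like waveform, is close
   to the peak-to-trough distance.

Fewer than two surviving extrema means the trace is unanalyzable and is
reported as such rather than producing metrics.

Vendor marks are mapped P→peak, Z→trough at their samples' times and
amplitudes; non-alternating runs keep the more extreme mark. Polarity is
auto-detected per file (inhalation-down recordings are analysed
sign-flipped; the override is exposed).

## Per-scan metrics

A "phase" is a half-cycle: the interval between an adjacent peak and
trough. Per-interval rate is 30/Δt BPM (a full-cycle 60/Δt alternative is
available via the `seconds_per_breath` argument). Amplitude is half the
peak-to-trough distance per half-cycle. All SDs are sample SDs (n−1);
relative spreads are CVs reported in percent. The breathing-rate range uses
the detected (actual) series; the marked-interval range is available
programmatically. Percent differences divide by the second-named method
(marked vs GUI divides by GUI, actual vs marked divides by marked); the
spread difference is a difference of CVs in percentage points. At least
three extrema (two intervals) per series are required so sample SDs exist.

## Clinical error models

All closed-form, assuming a cosine trace with 0% phase at full inhalation:

- displacement Δy = A[cos(2πx) − cos(2π(x+φ))], maximal at 2A·|sin(πφ)|;
  φ > 0 means late arrival and the sign is retained so gating reports
  direction;
- gated miss on a circular PTV: lens area
  2r²·arccos(d/2r) − (d/2)·√(4r²−d²) for d < 2r, else 0; missed fraction
  clipped to [0, 1];
- voluming: ε = −5.13·v − 6.71 (percent; an empirical linear fit with
  r² = 0.76, so ε inherits that fit's scatter), v in mm; margin
  m = −ε·x_MIP/2 in mm, floored at 0 for ε > 0;
- misbinning: round(relative period error / bin width) bins.

Units are fixed per quantity (amplitudes and MIP lengths cm, v and m mm, ε
percent, phases as cycle fractions) and conversions are centralized in the
error-models module. Printed tables round half away from zero to one
decimal; a 1e−9 nudge absorbs binary-float representation error so decimal
halves (e.g. 2.85 mm) round up as a human would.

## Cohort statistics

Gaussian fits are maximum-likelihood on the raw per-scan values (sample
mean/SD) rather than histogram curve fits — better-posed at these sample
sizes — with normal-theory 95% CIs (t for μ, χ² for σ). A degenerate
(constant) sample is rejected. The 95% uncertainty summary doubles the
corresponding 1-SD cohort statistic; 2σ rather than 1.96σ for transparency,
and the two agree at the integer precision the figures are quoted at.
Percent figures double the SD of the marked-vs-actual rate differences, the
SD of the spread differences, and the mean within-scan amplitude CV; the mm
figures double the cohort mean of the per-scan peak and trough level SDs —
the same SDs that feed the voluming model. No outliers are removed by
default; 1.5×IQR trimming is a flag.

## QA tolerances

Defaults are statistical, set at the 1-SD cohort figures of the published
audit: 9.6% (marked-vs-actual rate), 18.4% (spread difference), 17%
(amplitude CV), 18% (rate CV), plus a 1 s ceiling on invalid-signal gaps.
Comparison is on absolute value; any exceedance fails the scan; an
undefined gated metric fails as "unanalyzable". The GUI-rate comparison is
advisory only (normal scans spread roughly ±20% around the GUI value).
Note that 1-SD tolerances intentionally flag a substantial fraction of
ordinarily-variable patients — the tool's purpose is to force a look at the
trace, not to pass most scans.

## Synthetic traces

The generator chains half-cosine segments between drawn extrema, so period
and level variability are independent knobs; this is the minimal model that
reproduces marked-vs-actual discrepancies and amplitude variability without
simulating physiology. Per interval the *rate* is drawn
(Normal(bpm_mean, bpm_cv·bpm_mean)), so the realized mean interval BPM is
unbiased at `bpm_mean` and `bpm_cv` is exactly the per-interval rate CV.
Floors keep every generated breath detectable by construction: half-cycles
are truncated at 0.6 s (the detector's 0.5 s floor plus headroom for sample
snapping) and each breath's excursion at 0.3× the nominal peak-to-trough
distance (above the detector's 0.2× floor). Levels are drawn per kind with
a random-walk drift; Gaussian sensor noise is added; marks are placed at
the true extrema, jittered in time (truncated to ±0.4 of the adjacent
half-cycles so marks cannot cross), and dropped with a miss probability.
All randomness flows from one seed through named streams (periods, levels,
noise, marks), so adding a component never perturbs the others; identical
specs give identical traces.

Ground-truth extremum indices are where the *sampled* noiseless waveform
attains each extremum (not the nearest sample to the continuous-time
extremum), so with zero noise and no smoothing the detector recovers the
truth sample-for-sample — the property the recovery tests assert exactly.

Cohort defaults emulate an uncoached lung population: per-patient rate
Normal(15, 4.6) BPM truncated below 4 and capped at 40; within-scan rate CV
~ Normal(0.18, 0.05) clipped to [0.05, 0.35]; amplitude ~ Normal(0.3, 0.1)
cm clipped to [0.15, 1.0]; level SDs a per-scan ratio ~ Normal(0.24, 0.10)
of the amplitude, clipped to [0.05, 0.45], which puts the within-scan
amplitude CV near 17% (ratio/√2); drift 0.01 cm per cycle and 0.01 cm
sensor noise; 2% mark-miss probability. The per-scan mark-jitter SD is
drawn Uniform(0, 0.42) × the patient's half-period: jitter expressed as a
period fraction keeps its effect comparable across slow and fast breathers,
the bounded distribution keeps the cohort spread statistic stable across
seeds, and 0.42 was calibrated once so the cohort marked-vs-actual rate
difference has an SD near the 9.6% the tolerances are built on.

What the generator does *not* emulate: cardiac components, coughs and
swallows, baseline shifts from couch motion, the vendor's real-time
predictive marking filter (jitter + misses is a statistical stand-in for
its errors), and any correlation between breathing rate and amplitude.
Passing tests therefore demonstrate correct metric arithmetic, detector
behaviour on breathing-like waveforms, and statistical calibration of the
pipeline — not performance on pathological real traces.

## Problem sizes and determinism

Statistical tests use 281-scan cohorts of 90 s traces at 25 Hz (the scale
at which the cohort SD of a per-scan statistic has a standard error well
below the asserted bands), 10⁶-point Monte Carlo for the lens-area oracle,
and a 10⁻³-cycle grid for the displacement maximum. All tests and the
acceptance script are seeded; audit-log rows carry no wall-clock timestamp,
so a fixed seed and config reproduce byte-identical logs and summaries.

## Known limitations

- The voluming fit is linear and empirical; outside roughly 0–3 mm of
  level variability it extrapolates.
- The gated-miss model is a 2D circle; real PTVs are 3D and non-spherical.
- The VXP dialect implemented is the publicly described key=value header +
  CSV rows form; vendor firmware variants with different layouts parse only
  if their `Data_layout` names the amplitude/timestamp/mark columns.
- Whether a mark was manually edited is not recorded in the file; marked
  extrema are treated as one population.
- Amplitude data are taken from the surrogate as recorded (marker-block
  motion, not tumor motion).
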