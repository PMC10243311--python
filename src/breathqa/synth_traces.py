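"""Synthetic breathing traces with controllable irregularity.

The waveform is a chain of half-cosine segments between drawn extrema, so
per-cycle period variability and peak/trough level variability are
independent knobs. On top sit a random-walk baseline drift, additive
Gaussian sensor noise, and a vendor-mark model that places P/Z marks at the
true extrema, perturbs them in time, and occasionally drops them — the
failure modes a QA tool has to catch.

Cohort defaults emulate an uncoached lung 4DCT population: per-patient
mean rate Normal(15, 4.6) BPM truncated at 4, within-scan rate CV around
18%, average amplitude around 0.3 cm with peak/trough level SDs that put
within-scan amplitude CV near 17%.

Every random component draws from its own named stream spawned from the
single spec seed, so changing one component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .breath_signal import PEAK, TROUGH, ExtremumSeries
from .errors import TraceSpecError
from .vxp_io import MARK_NONE, MARK_PEAK, MARK_TROUGH, BreathingTrace, VxpHeader, write_vxp

#: generator-side floor for drawn half-cycles: the detector's default
#: min_half_period (0.5 s, the 60 BPM ceiling) plus 20% headroom so that
#: sample-snapped extremum spacing still clears the detector's floor
MIN_HALF_PERIOD_S = 0.6

#: floor on each drawn breath's excursion, as a fraction of the nominal
#: peak-to-trough distance; sits above the detector's default excursion
#: floor (0.2 x the typical excursion) so every generated breath is
#: detectable by construction
MIN_EXCURSION_FRACTION = 0.3

#: upper end of the uniform distribution the per-scan mark-time jitter SD is
#: drawn from in cohort generation, expressed as a fraction of the patient's
#: mean half-period; calibrated once so the cohort marked-vs-actual BPM
#: difference has a spread near the published 9.6%
COHORT_MARK_JITTER_FRAC_MAX = 0.42


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic scan."""

    duration: float = 90.0  # s
    sample_rate: float = 25.0  # Hz
    bpm_mean: float = 15.0
    bpm_cv: float = 0.18  # per-interval period variability
    peak_level_mean: float = 0.3  # cm
    trough_level_mean: float = -0.3  # cm
    peak_level_sd: float = 0.072  # cm -> within-scan amplitude CV ~ 17%
    trough_level_sd: float = 0.072  # cm
    drift_sd_per_cycle: float = 0.0  # cm, baseline random walk
    noise_sd: float = 0.01  # cm
    mark_time_jitter_sd: float = 0.0  # s
    mark_miss_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0 or self.bpm_mean <= 0:
            raise TraceSpecError("duration, sample_rate and bpm_mean must be positive")
        for name in (
            "bpm_cv",
            "peak_level_sd",
            "trough_level_sd",
            "drift_sd_per_cycle",
            "noise_sd",
            "mark_time_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise TraceSpecError(f"{name} must be >= 0")
        if not 0 <= self.mark_miss_prob < 1:
            raise TraceSpecError("mark_miss_prob must be in [0, 1)")
        if self.peak_level_mean <= self.trough_level_mean:
            raise TraceSpecError("peak_level_mean must exceed trough_level_mean")
        if 30.0 / self.bpm_mean <= MIN_HALF_PERIOD_S:
            raise TraceSpecError(
                f"bpm_mean {self.bpm_mean} implies half-cycles at or below the "
                f"{MIN_HALF_PERIOD_S} s floor; every draw would truncate"
            )


def _draw_extrema(
    spec: TraceSpec, rng_periods: np.random.Generator, rng_levels: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw alternating extrema (times, levels, kinds) covering the scan
    window with one extremum beyond each edge."""
    half_mean = 30.0 / spec.bpm_mean
    min_exc = MIN_EXCURSION_FRACTION * (spec.peak_level_mean - spec.trough_level_mean)

    times = [-0.4 * half_mean]  # virtual extremum just before the trace
    kinds = [TROUGH]
    drift = 0.0
    levels = [spec.trough_level_mean]
    while times[-1] <= spec.duration:
        # draw the per-interval *rate*, so the realized mean interval BPM is
        # unbiased at bpm_mean and bpm_cv is exactly the per-interval rate CV
        bpm_i = max(rng_periods.normal(spec.bpm_mean, spec.bpm_cv * spec.bpm_mean), 2.0)
        h = max(MIN_HALF_PERIOD_S, 30.0 / bpm_i)
        times.append(times[-1] + h)
        kind = PEAK if kinds[-1] == TROUGH else TROUGH
        kinds.append(kind)
        drift += rng_levels.normal(0.0, spec.drift_sd_per_cycle / np.sqrt(2.0))
        if kind == PEAK:
            level = rng_levels.normal(spec.peak_level_mean, spec.peak_level_sd) + drift
            level = max(level, levels[-1] + min_exc)
        else:
            level = rng_levels.normal(spec.trough_level_mean, spec.trough_level_sd) + drift
            level = min(level, levels[-1] - min_exc)
        levels.append(level)
    return np.asarray(times), np.asarray(levels), np.asarray(kinds, dtype="<U6")


def generate_trace(spec: TraceSpec) -> tuple[BreathingTrace, ExtremumSeries]:
    """Synthesize one scan; returns the trace and its ground-truth extrema.

    Ground-truth times/indices are where the *sampled* noiseless waveform
    attains each extremum, so at zero noise the detector can recover them
    exactly. Identical specs (same seed) produce identical output.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_periods, rng_levels, rng_noise, rng_marks = (
        np.random.default_rng(s) for s in streams
    )

    e_time, e_level, e_kind = _draw_extrema(spec, rng_periods, rng_levels)

    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    seg = np.clip(np.searchsorted(e_time, t, side="right") - 1, 0, len(e_time) - 2)
    left_t, right_t = e_time[seg], e_time[seg + 1]
    left_a, right_a = e_level[seg], e_level[seg + 1]
    frac = (t - left_t) / (right_t - left_t)
    clean = left_a + (right_a - left_a) * (1.0 - np.cos(np.pi * frac)) / 2.0
    amplitude = clean + rng_noise.normal(0.0, spec.noise_sd, n)

    # phase in radians: 0 at a peak, pi at a trough
    base = np.where(e_kind[seg] == PEAK, 0.0, np.pi)
    phase = np.mod(base + np.pi * frac, 2.0 * np.pi)

    # interior extrema -> discrete ground truth (k: index into the drawn
    # extrema, idx: sample index of the discrete extremum)
    truth_items: list[tuple[int, int, str]] = []
    for k in range(1, len(e_time) - 1):
        if not t[1] <= e_time[k] <= t[-2]:
            continue
        h_left = e_time[k] - e_time[k - 1]
        h_right = e_time[k + 1] - e_time[k]
        lo = max(int(np.ceil((e_time[k] - 0.45 * h_left) * spec.sample_rate)), 0)
        hi = min(int(np.floor((e_time[k] + 0.45 * h_right) * spec.sample_rate)) + 1, n)
        window = clean[lo:hi]
        if window.size == 0:
            continue
        pick = np.argmax(window) if e_kind[k] == PEAK else np.argmin(window)
        truth_items.append((k, lo + int(pick), str(e_kind[k])))
    gt_idx = [idx for _, idx, _ in truth_items]
    gt_kind = [kind for _, _, kind in truth_items]

    # vendor marks: jittered, truncated to stay inside their half-cycles,
    # occasionally dropped
    marks = np.full(n, MARK_NONE, dtype="<U1")
    for k, idx0, kind in truth_items:
        if spec.mark_miss_prob > 0 and rng_marks.uniform() < spec.mark_miss_prob:
            continue
        delta = rng_marks.normal(0.0, spec.mark_time_jitter_sd) if spec.mark_time_jitter_sd else 0.0
        h_left = e_time[k] - e_time[k - 1]
        h_right = e_time[k + 1] - e_time[k]
        delta = float(np.clip(delta, -0.4 * h_left, 0.4 * h_right))
        idx = int(round((t[idx0] + delta) * spec.sample_rate))
        idx = min(max(idx, 0), n - 1)
        marks[idx] = MARK_PEAK if kind == PEAK else MARK_TROUGH

    header = VxpHeader(
        version="1.6",
        patient_id=f"SYN{spec.seed:010d}",
        date="2023-01-01",
        total_study_time=spec.duration,
        samples_per_second=spec.sample_rate,
        scale_factor=1000.0,
    )
    trace = BreathingTrace(
        header=header,
        time=t,
        amplitude=amplitude,
        phase=phase,
        valid=np.ones(n, dtype=bool),
        marks=marks,
    )
    truth = ExtremumSeries(
        index=np.asarray(gt_idx, dtype=np.int64),
        time=t[np.asarray(gt_idx, dtype=np.int64)],
        amplitude=amplitude[np.asarray(gt_idx, dtype=np.int64)],
        kind=np.asarray(gt_kind, dtype="<U6"),
        source="detected",
    )
    return trace, truth


@dataclass(frozen=True)
class CohortSpec:
    """Distributions the per-patient TraceSpec fields are drawn from."""

    bpm_mu: float = 15.0
    bpm_sigma: float = 4.6
    bpm_floor: float = 4.0
    bpm_ceiling: float = 40.0
    bpm_cv_mu: float = 0.18
    bpm_cv_sigma: float = 0.05
    amplitude_mu: float = 0.3  # cm
    amplitude_sigma: float = 0.1
    #: per-scan peak/trough level SD as a fraction of the scan amplitude;
    #: 0.24 puts the within-scan amplitude CV near the 17% cohort mode
    level_sd_ratio_mu: float = 0.24
    level_sd_ratio_sigma: float = 0.10
    #: per-scan mark jitter SD ~ Uniform(0, frac_max) x the scan's mean
    #: half-period
    mark_jitter_frac_max: float = COHORT_MARK_JITTER_FRAC_MAX
    mark_miss_prob: float = 0.02
    duration: float = 90.0
    sample_rate: float = 25.0
    drift_sd_per_cycle: float = 0.01
    noise_sd: float = 0.01


def generate_cohort_specs(
    n: int, seed: int = 0, cohort: CohortSpec | None = None
) -> list[TraceSpec]:
    """Draw ``n`` per-patient TraceSpecs from the cohort distributions."""
    if n < 1:
        raise TraceSpecError("cohort size must be >= 1")
    cohort = cohort or CohortSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    specs: list[TraceSpec] = []
    for _ in range(n):
        bpm = rng.normal(cohort.bpm_mu, cohort.bpm_sigma)
        while bpm < cohort.bpm_floor:  # truncated, not clipped: no atom at the floor
            bpm = rng.normal(cohort.bpm_mu, cohort.bpm_sigma)
        bpm = min(bpm, cohort.bpm_ceiling)
        amp = float(np.clip(rng.normal(cohort.amplitude_mu, cohort.amplitude_sigma), 0.15, 1.0))
        ratio = float(
            np.clip(rng.normal(cohort.level_sd_ratio_mu, cohort.level_sd_ratio_sigma), 0.05, 0.45)
        )
        level_sd = ratio * amp
        specs.append(
            TraceSpec(
                duration=cohort.duration,
                sample_rate=cohort.sample_rate,
                bpm_mean=float(bpm),
                bpm_cv=float(np.clip(rng.normal(cohort.bpm_cv_mu, cohort.bpm_cv_sigma), 0.05, 0.35)),
                peak_level_mean=amp,
                trough_level_mean=-amp,
                peak_level_sd=level_sd,
                trough_level_sd=level_sd,
                drift_sd_per_cycle=cohort.drift_sd_per_cycle,
                noise_sd=cohort.noise_sd,
                mark_time_jitter_sd=rng.uniform(0.0, cohort.mark_jitter_frac_max)
                * (30.0 / float(bpm)),
                mark_miss_prob=cohort.mark_miss_prob,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_cohort(
    n: int,
    outdir: str | Path,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> pd.DataFrame:
    """Write ``n`` VXP files plus a ``manifest.csv`` of true parameters.

    The manifest carries the generator ground truth per scan (rate, spread,
    amplitude, level SDs, mark corruption) for parameter-recovery tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = generate_cohort_specs(n, seed=seed, cohort=cohort)
    rows = []
    for i, spec in enumerate(specs):
        name = f"patient_{i + 1:04d}.vxp"
        trace, truth = generate_trace(replace(spec, seed=spec.seed))
        write_vxp(trace, outdir / name)
        rows.append(
            {
                "file": name,
                "patient_id": trace.header.patient_id,
                "true_bpm_mean": spec.bpm_mean,
                # realized mean of the per-interval rate over the drawn
                # ground-truth extrema (what a perfect detector would report)
                "true_realized_bpm": float(np.mean(30.0 / np.diff(truth.time)))
                if len(truth) >= 2
                else np.nan,
                "true_bpm_cv": spec.bpm_cv,
                "true_amplitude_cm": (spec.peak_level_mean - spec.trough_level_mean) / 2,
                "true_peak_level_sd_cm": spec.peak_level_sd,
                "true_trough_level_sd_cm": spec.trough_level_sd,
                "mark_time_jitter_sd_s": spec.mark_time_jitter_sd,
                "mark_miss_prob": spec.mark_miss_prob,
                "n_true_extrema": len(truth),
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
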