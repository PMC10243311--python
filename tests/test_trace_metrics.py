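"""Per-scan metric definitions, method differences and the audit log."""

import numpy as np
import pytest

from breathqa.breath_signal import (
    DetectionConfig,
    ExtremumSeries,
    detect_extrema,
    marked_extrema,
)
from breathqa.errors import (
    ConfigError,
    InsufficientBreathingError,
    UndefinedMetricError,
)
from breathqa.synth_traces import TraceSpec, generate_trace
from breathqa.trace_metrics import (
    AUDIT_COLUMNS,
    append_audit_record,
    audit_record,
    compute_diffs,
    compute_metrics,
    interval_bpm,
    read_audit_log,
)
from breathqa.vxp_io import BreathingTrace, VxpHeader

NO_SMOOTHING = DetectionConfig(smoothing_window=0.0)


def series(times, amps, kinds, source="detected"):
    return ExtremumSeries(
        index=np.arange(len(times)),
        time=np.asarray(times, dtype=float),
        amplitude=np.asarray(amps, dtype=float),
        kind=np.asarray(kinds),
        source=source,
    )


class TestIntervalBpm:
    def test_two_second_gap_is_15_bpm(self):
        s = series([0, 2], [0.5, -0.5], ["peak", "trough"])
        np.testing.assert_allclose(interval_bpm(s), [15.0])

    def test_constant_gaps_zero_spread(self):
        s = series([0, 2, 4, 6], [0.5, -0.5, 0.5, -0.5], ["peak", "trough"] * 2)
        bpm = interval_bpm(s)
        np.testing.assert_allclose(bpm, [15.0, 15.0, 15.0])
        assert np.std(bpm, ddof=1) == 0

    def test_single_extremum_rejected(self):
        with pytest.raises(InsufficientBreathingError):
            interval_bpm(series([0], [0.5], ["peak"]))

    def test_generator_mean_recovered(self):
        """Per-interval BPM over ~100 cycles recovers the generator rate
        within 2%. A modest rate CV keeps the renewal length-bias (faster
        breaths fit more intervals into a fixed window) below the band."""
        spec = TraceSpec(duration=420.0, bpm_mean=15.0, bpm_cv=0.10, seed=21)
        trace, truth = generate_trace(spec)
        assert len(truth) >= 200
        assert interval_bpm(truth).mean() == pytest.approx(15.0, rel=0.02)


def pipeline(trace):
    return marked_extrema(trace), detect_extrema(trace, NO_SMOOTHING)


class TestComputeMetrics:
    def test_perfect_cosine(self):
        """Regular 15 BPM breathing at +/-0.5 cm: exact metric values."""
        spec_amp = 0.5
        trace, _ = generate_trace(
            TraceSpec(
                duration=60,
                bpm_cv=0.0,
                peak_level_mean=spec_amp,
                trough_level_mean=-spec_amp,
                peak_level_sd=0.0,
                trough_level_sd=0.0,
                drift_sd_per_cycle=0.0,
                noise_sd=0.0,
                seed=8,
            )
        )
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        assert m.actual_bpm_mean == pytest.approx(15.0)
        assert m.amplitude_mean == pytest.approx(0.5)
        assert m.amplitude_sd == pytest.approx(0.0, abs=1e-12)
        assert m.peak_range == pytest.approx(0.0, abs=1e-12)
        assert m.trough_range == pytest.approx(0.0, abs=1e-12)
        assert m.bpm_min == pytest.approx(15.0)
        assert m.bpm_max == pytest.approx(15.0)

    def test_peak_range_by_definition(self):
        fs = 25.0
        n = 300
        t = np.arange(n) / fs
        trace = BreathingTrace(
            header=VxpHeader(samples_per_second=fs, scale_factor=1.0),
            time=t,
            amplitude=np.zeros(n),
            phase=np.full(n, np.nan),
            valid=np.ones(n, dtype=bool),
            marks=np.full(n, "", dtype="<U1"),
        )
        s = series([1, 3, 5, 7], [0.6, 0.0, 0.4, 0.0], ["peak", "trough"] * 2)
        m = compute_metrics(trace, s, s, gui_bpm=15.0)
        assert m.peak_range == pytest.approx(0.2)
        assert m.trough_range == pytest.approx(0.0)
        np.testing.assert_allclose(
            np.abs(np.diff(s.amplitude)) / 2, [0.3, 0.2, 0.2]
        )
        assert m.amplitude_mean == pytest.approx((0.3 + 0.2 + 0.2) / 3)

    def test_amplitude_cv_matches_generator(self):
        """Default level variability yields ~17% within-scan amplitude CV."""
        spec = TraceSpec(duration=210.0, seed=31)  # ~50 breathing cycles
        trace, _ = generate_trace(spec)
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        assert m.amplitude_sd / m.amplitude_mean == pytest.approx(0.17, abs=0.04)

    def test_too_short_series_rejected(self):
        trace, _ = generate_trace(TraceSpec(seed=1))
        s = series([0, 2], [0.5, -0.5], ["peak", "trough"])
        with pytest.raises(InsufficientBreathingError):
            compute_metrics(trace, s, s, gui_bpm=15)


class TestDiffs:
    def base_metrics(self, marked=15.0, gui=15.0, actual=15.0):
        trace, _ = generate_trace(TraceSpec(seed=2, noise_sd=0.0))
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=gui)
        m.marked_bpm_mean, m.actual_bpm_mean = marked, actual
        return m

    def test_equal_means_zero_diff(self):
        d = compute_diffs(self.base_metrics())
        assert d.marked_vs_gui_pct == pytest.approx(0.0)

    def test_minus_twenty_percent(self):
        d = compute_diffs(self.base_metrics(marked=12.0, gui=15.0))
        assert d.marked_vs_gui_pct == pytest.approx(-20.0)

    def test_gui_zero_rejected(self):
        with pytest.raises(UndefinedMetricError):
            compute_diffs(self.base_metrics(gui=0.0))

    def test_mark_jitter_inflates_marked_spread(self):
        """Jittered marks on an otherwise clean trace inflate the marked
        rate variance relative to the detected one."""
        spec = TraceSpec(duration=180.0, noise_sd=0.0, mark_time_jitter_sd=0.35, seed=17)
        trace, _ = generate_trace(spec)
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        d = compute_diffs(m)
        assert d.sd_marked_vs_actual_pct > 0

    def test_exact_marks_give_zero_diffs(self, clean_trace):
        trace, _ = clean_trace
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        d = compute_diffs(m)
        assert d.actual_vs_marked_pct == 0.0
        assert d.sd_marked_vs_actual_pct == 0.0


class TestEquivariance:
    def scaled(self, trace, k_amp=1.0, k_time=1.0):
        return BreathingTrace(
            header=VxpHeader(
                samples_per_second=trace.header.samples_per_second / k_time,
                scale_factor=trace.header.scale_factor,
                total_study_time=trace.header.total_study_time * k_time,
            ),
            time=trace.time * k_time,
            amplitude=trace.amplitude * k_amp,
            phase=trace.phase,
            valid=trace.valid,
            marks=trace.marks,
        )

    def test_amplitude_scale_equivariance(self):
        trace, _ = generate_trace(TraceSpec(seed=14, noise_sd=0.0))
        k = 2.5
        m1 = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        t2 = self.scaled(trace, k_amp=k)
        m2 = compute_metrics(t2, *pipeline(t2), gui_bpm=15.0)
        for name in ("amplitude_mean", "amplitude_sd", "peak_range", "trough_range"):
            assert getattr(m2, name) == pytest.approx(k * getattr(m1, name))
        for name in ("marked_bpm_mean", "actual_bpm_mean", "actual_bpm_sd"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name))

    def test_time_dilation_equivariance(self):
        trace, _ = generate_trace(TraceSpec(seed=14, noise_sd=0.0))
        k = 1.5
        m1 = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        t2 = self.scaled(trace, k_time=k)
        m2 = compute_metrics(t2, *pipeline(t2), gui_bpm=15.0)
        for name in ("marked_bpm_mean", "actual_bpm_mean", "bpm_min", "bpm_max"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name) / k)
        assert m2.amplitude_mean == pytest.approx(m1.amplitude_mean)


def test_parameter_recovery_unbiased():
    """Over many scans the detected rate and amplitude track the generator
    truth within 1% (paired)."""
    rel_bpm, rel_amp = [], []
    for seed in range(40):
        spec = TraceSpec(seed=seed, duration=120.0)
        trace, truth = generate_trace(spec)
        est = compute_metrics(
            trace, marked_extrema(trace), detect_extrema(trace), gui_bpm=spec.bpm_mean
        )
        true_bpm = interval_bpm(truth).mean()
        true_amp = np.abs(np.diff(truth.amplitude)).mean() / 2
        rel_bpm.append(est.actual_bpm_mean / true_bpm - 1)
        rel_amp.append(est.amplitude_mean / true_amp - 1)
    assert abs(np.mean(rel_bpm)) < 0.01
    assert abs(np.mean(rel_amp)) < 0.01


class TestAuditLog:
    def record(self, seed=1):
        trace, _ = generate_trace(TraceSpec(seed=seed))
        m = compute_metrics(trace, *pipeline(trace), gui_bpm=15.0)
        return audit_record(m, compute_diffs(m), source_file=f"s{seed}.vxp", qa_pass=True)

    def test_header_written_once_and_stable(self, tmp_path):
        log = tmp_path / "audit.csv"
        append_audit_record(log, self.record(1))
        append_audit_record(log, self.record(2))
        lines = log.read_text().splitlines()
        assert lines[0] == ",".join(AUDIT_COLUMNS)
        assert len(lines) == 3
        df = read_audit_log(log)
        assert list(df.columns) == list(AUDIT_COLUMNS)
        assert df["schema_version"].tolist() == [1, 1]

    def test_schema_mismatch_refused(self, tmp_path):
        log = tmp_path / "audit.csv"
        log.write_text("other,columns\n1,2\n")
        with pytest.raises(ConfigError):
            append_audit_record(log, self.record())
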