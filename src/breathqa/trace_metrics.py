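"""Per-scan breathing metrics and the central audit log.

Definitions follow the QA-application conventions:

* a "phase" is one half-cycle, the interval between an adjacent peak and
  trough, so the per-interval rate is 30/dt breaths per minute;
* amplitude is half the peak-to-trough distance of each half-cycle;
* peak (trough) range is the spread, max minus min, of the peak (trough)
  levels over the scan;
* marked statistics come from the vendor P/Z marks, actual statistics from
  the independently detected extrema;
* all standard deviations are sample SDs (n-1), and relative spreads are
  coefficients of variation, reported in percent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .breath_signal import PEAK, TROUGH, ExtremumSeries
from .errors import (
    ConfigError,
    InsufficientBreathingError,
    UndefinedMetricError,
)
from .vxp_io import BreathingTrace

AUDIT_SCHEMA_VERSION = 1

#: half-cycle (peak-to-trough) rate: BPM = 30 / dt. Switch to 60/dt when
#: rating from full peak-to-peak cycles.
HALF_CYCLE_SECONDS_PER_BREATH = 30.0


@dataclass
class TraceMetrics:
    """The per-scan metric set shown in the audit report."""

    gui_bpm: float  # operator-entered rate from the vendor GUI
    marked_bpm_mean: float
    marked_bpm_sd: float
    actual_bpm_mean: float
    actual_bpm_sd: float
    bpm_min: float  # over actual half-cycle intervals
    bpm_max: float
    amplitude_mean: float  # cm
    amplitude_sd: float  # cm
    peak_range: float  # cm
    trough_range: float  # cm
    n_cycles_marked: int  # half-cycle intervals in the marked series
    n_cycles_actual: int
    peak_level_sd: float = 0.0  # cm, feeds the voluming-error model
    trough_level_sd: float = 0.0  # cm
    invalid_gap_s: float = 0.0  # longest run of invalid samples

    @property
    def amplitude_cv_pct(self) -> float:
        return 100.0 * self.amplitude_sd / self.amplitude_mean

    @property
    def actual_bpm_cv_pct(self) -> float:
        return 100.0 * self.actual_bpm_sd / self.actual_bpm_mean

    @property
    def marked_bpm_cv_pct(self) -> float:
        return 100.0 * self.marked_bpm_sd / self.marked_bpm_mean


@dataclass
class MetricDiffs:
    """Percent differences between the GUI, marked and actual methods.

    The denominator is always the second-named method of the field name
    read right-to-left: ``marked_vs_gui_pct`` = (marked - gui)/gui x 100.
    ``sd_marked_vs_actual_pct`` compares relative spreads: (marked CV -
    actual CV) x 100.
    """

    marked_vs_gui_pct: float
    actual_vs_gui_pct: float
    actual_vs_marked_pct: float
    sd_marked_vs_actual_pct: float


def interval_bpm(
    extrema: ExtremumSeries,
    *,
    seconds_per_breath: float = HALF_CYCLE_SECONDS_PER_BREATH,
) -> np.ndarray:
    """Per-interval breathing rate from the gaps between adjacent extrema."""
    if len(extrema) < 2:
        raise InsufficientBreathingError("need at least 2 extrema for a rate")
    return seconds_per_breath / np.diff(extrema.time)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def compute_metrics(
    trace: BreathingTrace,
    marked: ExtremumSeries,
    detected: ExtremumSeries,
    gui_bpm: float,
) -> TraceMetrics:
    """Assemble the full per-scan metric set.

    Requires at least three extrema (two half-cycle intervals) in each
    series so sample SDs are defined.
    """
    if len(marked) < 3 or len(detected) < 3:
        raise InsufficientBreathingError(
            "need at least 3 extrema in each series to compute metrics"
        )
    sign = -1.0 if trace.inverted else 1.0

    m_bpm = interval_bpm(marked)
    a_bpm = interval_bpm(detected)
    marked_mean, marked_sd = _mean_sd(m_bpm)
    actual_mean, actual_sd = _mean_sd(a_bpm)

    amps = np.abs(np.diff(detected.amplitude)) / 2.0
    amp_mean, amp_sd = _mean_sd(amps)

    peaks = sign * detected.peaks
    troughs = sign * detected.troughs
    peak_range = float(peaks.max() - peaks.min())
    trough_range = float(troughs.max() - troughs.min())
    peak_sd = float(np.std(peaks, ddof=1)) if peaks.size >= 2 else 0.0
    trough_sd = float(np.std(troughs, ddof=1)) if troughs.size >= 2 else 0.0

    gaps = trace.invalid_gaps()
    dt = 1.0 / trace.sample_rate
    invalid_gap = max((b - a + dt for a, b in gaps), default=0.0)

    return TraceMetrics(
        gui_bpm=float(gui_bpm),
        marked_bpm_mean=marked_mean,
        marked_bpm_sd=marked_sd,
        actual_bpm_mean=actual_mean,
        actual_bpm_sd=actual_sd,
        bpm_min=float(a_bpm.min()),
        bpm_max=float(a_bpm.max()),
        amplitude_mean=amp_mean,
        amplitude_sd=amp_sd,
        peak_range=peak_range,
        trough_range=trough_range,
        n_cycles_marked=len(marked) - 1,
        n_cycles_actual=len(detected) - 1,
        peak_level_sd=peak_sd,
        trough_level_sd=trough_sd,
        invalid_gap_s=float(invalid_gap),
    )


def compute_diffs(metrics: TraceMetrics) -> MetricDiffs:
    """Percent differences between the three rate-estimation methods."""
    if metrics.gui_bpm <= 0:
        raise UndefinedMetricError("gui_bpm must be positive")
    for name in ("marked_bpm_mean", "actual_bpm_mean"):
        v = getattr(metrics, name)
        if not math.isfinite(v) or v <= 0:
            raise UndefinedMetricError(f"{name} undefined or non-positive")
    marked_cv = metrics.marked_bpm_sd / metrics.marked_bpm_mean
    actual_cv = metrics.actual_bpm_sd / metrics.actual_bpm_mean
    return MetricDiffs(
        marked_vs_gui_pct=100.0 * (metrics.marked_bpm_mean - metrics.gui_bpm) / metrics.gui_bpm,
        actual_vs_gui_pct=100.0 * (metrics.actual_bpm_mean - metrics.gui_bpm) / metrics.gui_bpm,
        actual_vs_marked_pct=100.0
        * (metrics.actual_bpm_mean - metrics.marked_bpm_mean)
        / metrics.marked_bpm_mean,
        sd_marked_vs_actual_pct=100.0 * (marked_cv - actual_cv),
    )


# --- central audit log -----------------------------------------------------

_PROVENANCE_COLUMNS = (
    "schema_version",
    "source_file",
    "tool_version",
    "config_hash",
    "file_sha256",
)
_METRIC_COLUMNS = tuple(f.name for f in fields(TraceMetrics))
_DIFF_COLUMNS = tuple(f.name for f in fields(MetricDiffs))
_DERIVED_COLUMNS = ("amplitude_cv_pct", "actual_bpm_cv_pct", "marked_bpm_cv_pct")

#: stable column order of the audit CSV; reordering requires a bump of
#: AUDIT_SCHEMA_VERSION
AUDIT_COLUMNS = (
    _PROVENANCE_COLUMNS + _METRIC_COLUMNS + _DERIVED_COLUMNS + _DIFF_COLUMNS + ("qa_pass",)
)


def audit_record(
    metrics: TraceMetrics,
    diffs: MetricDiffs,
    *,
    source_file: str = "",
    tool_version: str = "",
    config_hash: str = "",
    file_sha256: str = "",
    qa_pass: bool | None = None,
) -> dict[str, object]:
    """One audit-log row (stable key order) for a scan."""
    rec: dict[str, object] = {
        "schema_version": AUDIT_SCHEMA_VERSION,
        "source_file": source_file,
        "tool_version": tool_version,
        "config_hash": config_hash,
        "file_sha256": file_sha256,
    }
    for name in _METRIC_COLUMNS:
        rec[name] = getattr(metrics, name)
    for name in _DERIVED_COLUMNS:
        rec[name] = getattr(metrics, name)
    for name in _DIFF_COLUMNS:
        rec[name] = getattr(diffs, name)
    rec["qa_pass"] = "" if qa_pass is None else int(qa_pass)
    return rec


def append_audit_record(path: str | Path, record: dict[str, object]) -> Path:
    """Append one row to the central CSV log, writing the header once."""
    path = Path(path)
    new = not path.exists() or path.stat().st_size == 0
    if not new:
        with path.open(newline="") as fh:
            header = next(csv.reader(fh), None)
        if header != list(AUDIT_COLUMNS):
            raise ConfigError(
                f"{path}: existing audit log has a different schema; "
                "refusing to append"
            )
    with path.open("a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=AUDIT_COLUMNS)
        if new:
            writer.writeheader()
        writer.writerow({k: record.get(k, "") for k in AUDIT_COLUMNS})
    return path


def read_audit_log(path: str | Path) -> pd.DataFrame:
    """Load the central audit CSV."""
    return pd.read_csv(path)
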