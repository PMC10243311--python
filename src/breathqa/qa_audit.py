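"""Per-scan QA flagging against statistical tolerances.

Default tolerances are the 1-SD cohort statistics of the published
multi-centre audit: 9.6% for the marked-vs-actual rate difference, 18.4%
for the difference of relative rate spreads, 17% for within-scan amplitude
variability, 18% for within-scan rate variability. A scan failing any
gated metric fails overall and should prompt trace review and possible
re-simulation while the patient is still on the couch. The GUI-BPM
comparison is advisory only (normal scans spread about +/-20%).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .errors import ConfigError
from .trace_metrics import MetricDiffs, TraceMetrics


@dataclass(frozen=True)
class ToleranceConfig:
    """Absolute per-metric tolerances (percent except where noted)."""

    max_marked_vs_actual_bpm_pct: float = 9.6
    max_sd_diff_pct: float = 18.4
    max_amplitude_cv_pct: float = 17.0
    max_bpm_cv_pct: float = 18.0
    max_invalid_gap_s: float = 1.0
    gui_advisory_pct: float = 20.0  # note-only threshold

    def __post_init__(self) -> None:
        for name in (
            "max_marked_vs_actual_bpm_pct",
            "max_sd_diff_pct",
            "max_amplitude_cv_pct",
            "max_bpm_cv_pct",
            "max_invalid_gap_s",
            "gui_advisory_pct",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class MetricCheck:
    """One tolerance comparison: |value| against its limit."""

    name: str
    value: float
    tolerance: float
    passed: bool
    reason: str = ""


@dataclass
class QAResult:
    """Per-metric comparisons plus overall verdict (fail iff any metric
    fails)."""

    checks: list[MetricCheck]
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> list[MetricCheck]:
        return [c for c in self.checks if not c.passed]


def _check(name: str, value: float, tolerance: float) -> MetricCheck:
    if value is None or not math.isfinite(value):
        return MetricCheck(name, float("nan"), tolerance, False, "unanalyzable")
    ok = abs(value) <= tolerance
    return MetricCheck(name, float(value), tolerance, ok, "" if ok else "exceeds tolerance")


def evaluate(
    metrics: TraceMetrics,
    diffs: MetricDiffs,
    config: ToleranceConfig | None = None,
) -> QAResult:
    """Compare a scan's metrics against the tolerances.

    Every gated metric is compared on absolute value; an undefined metric is
    recorded as a failure with reason "unanalyzable".
    """
    config = config or ToleranceConfig()
    checks = [
        _check(
            "marked_vs_actual_bpm_pct",
            diffs.actual_vs_marked_pct,
            config.max_marked_vs_actual_bpm_pct,
        ),
        _check("bpm_sd_diff_pct", diffs.sd_marked_vs_actual_pct, config.max_sd_diff_pct),
        _check("amplitude_cv_pct", metrics.amplitude_cv_pct, config.max_amplitude_cv_pct),
        _check("bpm_cv_pct", metrics.actual_bpm_cv_pct, config.max_bpm_cv_pct),
        _check("invalid_gap_s", metrics.invalid_gap_s, config.max_invalid_gap_s),
    ]
    notes = []
    gui_diff = diffs.marked_vs_gui_pct
    if math.isfinite(gui_diff) and abs(gui_diff) > config.gui_advisory_pct:
        notes.append(
            f"advisory: marked BPM differs from the GUI value by {gui_diff:+.1f}% "
            f"(> {config.gui_advisory_pct:g}%); check the operator-entered rate"
        )
    return QAResult(checks=checks, notes=notes)


def result_to_dict(result: QAResult) -> dict:
    """Machine-readable twin of the report."""
    return {
        "overall": "pass" if result.passed else "fail",
        "checks": [
            {
                "name": c.name,
                "value": None if math.isnan(c.value) else c.value,
                "tolerance": c.tolerance,
                "result": "pass" if c.passed else "fail",
                "reason": c.reason,
            }
            for c in result.checks
        ],
        "notes": list(result.notes),
    }


def render_report(result: QAResult, metrics: TraceMetrics) -> str:
    """Deterministic human-readable report; failing metrics listed first."""
    lines = []
    verdict = "PASS" if result.passed else "FAIL"
    lines.append(f"QA result: {verdict}")
    lines.append("")
    lines.append("Tolerance checks (|value| vs limit):")
    ordered = result.failures + [c for c in result.checks if c.passed]
    for c in ordered:
        flag = "PASS" if c.passed else "FAIL"
        value = "undefined" if math.isnan(c.value) else f"{c.value:+.2f}"
        suffix = f"  [{c.reason}]" if c.reason else ""
        lines.append(f"  [{flag}] {c.name:<26s} {value:>10s}  limit {c.tolerance:g}{suffix}")
    lines.append("")
    lines.append("Scan metrics:")
    lines.append(f"  GUI BPM            {metrics.gui_bpm:8.2f}")
    lines.append(
        f"  Marked BPM         {metrics.marked_bpm_mean:8.2f} +/- {metrics.marked_bpm_sd:.2f}"
        f"  (n={metrics.n_cycles_marked} half-cycles)"
    )
    lines.append(
        f"  Actual BPM         {metrics.actual_bpm_mean:8.2f} +/- {metrics.actual_bpm_sd:.2f}"
        f"  (n={metrics.n_cycles_actual} half-cycles)"
    )
    lines.append(f"  BPM range          {metrics.bpm_min:8.2f} - {metrics.bpm_max:.2f}")
    lines.append(
        f"  Amplitude (cm)     {metrics.amplitude_mean:8.3f} +/- {metrics.amplitude_sd:.3f}"
    )
    lines.append(f"  Peak range (cm)    {metrics.peak_range:8.3f}")
    lines.append(f"  Trough range (cm)  {metrics.trough_range:8.3f}")
    for note in result.notes:
        lines.append("")
        lines.append(note)
    return "\n".join(lines) + "\n"


def write_report(result: QAResult, metrics: TraceMetrics, path) -> None:
    """Write the text report plus its machine-readable JSON twin."""
    from pathlib import Path

    path = Path(path)
    path.write_text(render_report(result, metrics))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(result_to_dict(result), indent=2) + "\n"
    )
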