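"""Cohort-level aggregation of per-scan audit records.

Turns the central audit CSV into the summaries a physics team reviews:
Gaussian fits of the breathing-rate distributions, mean +/- SD of the
per-scan method differences, and a 95% uncertainty summary for "any new
patient". The 95% figures follow the 2-sigma convention: twice the
corresponding 1-SD cohort statistic (2 x 9.6% -> 19%, etc.), which at the
printed integer precision coincides with the 1.96-sigma normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

#: audit-log columns holding per-scan percent differences between methods
DIFF_PAIRS = {
    "marked_vs_gui_pct": ("Marked", "GUI"),
    "actual_vs_gui_pct": ("Actual", "GUI"),
    "actual_vs_marked_pct": ("Actual", "Marked"),
    "sd_marked_vs_actual_pct": ("Marked SD", "Actual SD"),
}


@dataclass(frozen=True)
class GaussianFit:
    """Normal fit of a cohort distribution with 95% confidence intervals."""

    mu: float
    sigma: float
    mu_ci95: tuple[float, float]
    sigma_ci95: tuple[float, float]
    n: int

    def interval95(self) -> tuple[float, float]:
        """The 2-sigma population interval (where ~95% of patients fall)."""
        return (self.mu - 2 * self.sigma, self.mu + 2 * self.sigma)


@dataclass(frozen=True)
class UncertaintySummary:
    """95% breathing uncertainties to assume for a new patient without
    individualized QA."""

    marked_bpm_mean_unc_pct: float
    marked_bpm_sd_unc_pct: float
    amplitude_unc_pct: float
    inspiration_unc_mm: float
    exhalation_unc_mm: float


def _trim_iqr(x: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return x[(x >= q1 - k * iqr) & (x <= q3 + k * iqr)]


def fit_gaussian(values, *, trim_outliers: bool = False) -> GaussianFit:
    """Maximum-likelihood normal fit (sample mean / sample SD) with
    normal-theory 95% CIs (t for mu, chi-square for sigma).

    Raises
    ------
    InsufficientDataError
        For fewer than 2 finite values or a degenerate (constant) sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if trim_outliers and x.size >= 4:
        x = _trim_iqr(x)
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 finite values")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        raise InsufficientDataError("degenerate sample: sigma is 0")
    tcrit = stats.t.ppf(0.975, n - 1)
    half = tcrit * sigma / np.sqrt(n)
    chi_lo, chi_hi = stats.chi2.ppf([0.975, 0.025], n - 1)
    return GaussianFit(
        mu=mu,
        sigma=sigma,
        mu_ci95=(mu - half, mu + half),
        sigma_ci95=(
            float(np.sqrt((n - 1) * sigma**2 / chi_lo)),
            float(np.sqrt((n - 1) * sigma**2 / chi_hi)),
        ),
        n=n,
    )


def diff_summary(records: pd.DataFrame, *, trim_outliers: bool = False) -> pd.DataFrame:
    """Mean +/- sample SD of the per-scan percent differences, one row per
    method pair. Records with an undefined member are excluded and counted.
    """
    rows = []
    for column, (a, b) in DIFF_PAIRS.items():
        if column not in records.columns:
            continue
        x = pd.to_numeric(records[column], errors="coerce").to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        excluded = x.size - finite.size
        if trim_outliers and finite.size >= 4:
            trimmed = _trim_iqr(finite)
            excluded += finite.size - trimmed.size
            finite = trimmed
        if finite.size < 2:
            rows.append((column, a, b, np.nan, np.nan, finite.size, excluded))
            continue
        rows.append(
            (
                column,
                a,
                b,
                float(np.mean(finite)),
                float(np.std(finite, ddof=1)),
                finite.size,
                excluded,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["metric", "method_a", "method_b", "mean_pct", "sd_pct", "n", "n_excluded"],
    ).set_index("metric")
    if out.empty or out["n"].max() < 2:
        raise InsufficientDataError("no method pair has 2 or more defined records")
    return out


def _col(records: pd.DataFrame, name: str) -> np.ndarray:
    x = pd.to_numeric(records[name], errors="coerce").to_numpy(dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(f"column {name!r} has fewer than 2 defined records")
    return x


def summarize_uncertainty(
    records: pd.DataFrame, *, trim_outliers: bool = False
) -> UncertaintySummary:
    """95% (2 x 1-SD) uncertainty summary for any new patient.

    Percent figures double CV-type cohort statistics (the SD of the
    marked-vs-actual rate differences, the SD of the relative-spread
    differences, the mean per-scan amplitude CV); mm figures double the
    cohort mean of the per-scan peak/trough level SDs.
    """
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 audit records")

    def maybe_trim(x: np.ndarray) -> np.ndarray:
        return _trim_iqr(x) if trim_outliers and x.size >= 4 else x

    bpm_diff = maybe_trim(_col(records, "actual_vs_marked_pct"))
    sd_diff = maybe_trim(_col(records, "sd_marked_vs_actual_pct"))
    amp_cv = maybe_trim(_col(records, "amplitude_cv_pct"))
    peak_sd = maybe_trim(_col(records, "peak_level_sd"))
    trough_sd = maybe_trim(_col(records, "trough_level_sd"))

    return UncertaintySummary(
        marked_bpm_mean_unc_pct=2.0 * float(np.std(bpm_diff, ddof=1)),
        marked_bpm_sd_unc_pct=2.0 * float(np.std(sd_diff, ddof=1)),
        amplitude_unc_pct=2.0 * float(np.mean(amp_cv)),
        inspiration_unc_mm=2.0 * float(np.mean(peak_sd)) * 10.0,
        exhalation_unc_mm=2.0 * float(np.mean(trough_sd)) * 10.0,
    )


def cohort_plots(records: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Histogram and box-plot set for a cohort (headless, PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    hist_specs = [
        ("gui_bpm", "GUI BPM"),
        ("marked_bpm_mean", "Marked BPM"),
        ("actual_bpm_mean", "Actual BPM"),
        ("amplitude_mean", "Average amplitude (cm)"),
        ("peak_range", "Peak range (cm)"),
        ("trough_range", "Trough range (cm)"),
        ("amplitude_cv_pct", "Amplitude SD per scan (%)"),
    ]
    for column, label in hist_specs:
        if column not in records.columns:
            continue
        x = pd.to_numeric(records[column], errors="coerce").dropna()
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(x, bins=30, color="#4878a8", edgecolor="white")
        ax.set_xlabel(label)
        ax.set_ylabel("Scans")
        fig.tight_layout()
        p = outdir / f"hist_{column}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    diff_cols = [c for c in DIFF_PAIRS if c in records.columns]
    if diff_cols:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        data = [
            pd.to_numeric(records[c], errors="coerce").dropna() for c in diff_cols
        ]
        ax.boxplot(data, tick_labels=[c.replace("_pct", "") for c in diff_cols])
        ax.set_ylabel("Per-scan difference (%)")
        ax.tick_params(axis="x", labelrotation=20)
        fig.tight_layout()
        p = outdir / "box_method_differences.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
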