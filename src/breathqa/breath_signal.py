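"""Smoothing and independent peak/trough detection on the surrogate signal.

The vendor system places P (peak) / Z (trough) marks on the trace in real
time; those marks drive 4DCT phase binning but are not always where the
breathing extrema actually are. This module re-detects the "actual" extrema
offline: the signal is smoothed with a centred moving average, strict local
extrema are located, and candidates are pruned until every adjacent
peak-trough pair has (a) an excursion of at least ``min_excursion_fraction``
times the median excursion and (b) a time separation of at least
``min_half_period``. Small fluctuations that do not contribute to the
breathing cycle are thereby rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InsufficientBreathingError,
    InsufficientMarksError,
)
from .vxp_io import MARK_PEAK, MARK_TROUGH, BreathingTrace

PEAK = "peak"
TROUGH = "trough"


@dataclass
class ExtremumSeries:
    """Alternating peak/trough events, strictly increasing in time.

    ``source`` records whether the events come from the vendor marks
    (``"marked"``) or from this package's detector (``"detected"``).
    """

    index: np.ndarray  # sample indices
    time: np.ndarray  # seconds
    amplitude: np.ndarray  # cm, as recorded in the trace
    kind: np.ndarray  # 'peak' | 'trough'
    source: str

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.kind = np.asarray(self.kind, dtype="<U6")
        if len(self.time) >= 2:
            if np.any(np.diff(self.time) <= 0):
                raise ValueError("extremum times must strictly increase")
            if np.any(self.kind[1:] == self.kind[:-1]):
                raise ValueError("extremum kinds must alternate")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def peaks(self) -> np.ndarray:
        """Amplitudes of the peak events."""
        return self.amplitude[self.kind == PEAK]

    @property
    def troughs(self) -> np.ndarray:
        """Amplitudes of the trough events."""
        return self.amplitude[self.kind == TROUGH]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for extrema detection.

    smoothing_window:
        Moving-average width in seconds (0 disables smoothing; windows
        shorter than two sample intervals are treated the same way).
    min_half_period:
        Shortest admissible peak-to-trough separation in seconds. The
        default 0.5 s corresponds to 60 BPM, the physiological ceiling.
    min_excursion_fraction:
        Adjacent extrema whose excursion falls below this fraction of the
        median excursion are discarded as non-breathing fluctuations.
    """

    smoothing_window: float = 0.25
    min_half_period: float = 0.5
    min_excursion_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.smoothing_window < 0:
            raise ConfigError("smoothing_window must be >= 0")
        if self.min_half_period <= 0:
            raise ConfigError("min_half_period must be positive")
        if not 0 < self.min_excursion_fraction < 1:
            raise ConfigError("min_excursion_fraction must be in (0, 1)")


def window_samples(window: float, sample_rate: float) -> int:
    """Moving-average length in samples for a window in seconds.

    Rounded to the nearest odd number of samples so the window is centred
    symmetrically.
    """
    n = int(round(window * sample_rate))
    if n % 2 == 0:
        n += 1
    return n


def smooth(trace: BreathingTrace, window: float) -> np.ndarray:
    """Centred moving average of the recorded amplitude.

    Invalid samples are excluded from every window; output positions inside
    an all-invalid window are NaN. Edges use shrunken windows, so the output
    has the same length as the input.
    """
    n = window_samples(window, trace.sample_rate)
    if n < 2 or window * trace.sample_rate < 2:
        raise ConfigError(
            f"smoothing window {window} s spans fewer than 2 samples "
            f"at {trace.sample_rate} Hz"
        )
    values = np.where(trace.valid, trace.amplitude, np.nan)
    return (
        pd.Series(values)
        .rolling(n, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _local_extrema(z: np.ndarray, offset: int) -> tuple[list[int], list[str]]:
    """Strict interior local extrema of a finite-valued segment.

    Plateaus count once, at their first sample. Returns sample indices
    (shifted by ``offset``) and kinds.
    """
    m = len(z)
    if m < 3:
        return [], []
    s = np.sign(np.diff(z))
    # backward-fill zero slopes so a flat extremum is attributed to its
    # first sample; trailing zeros stay zero (no extremum in a final plateau)
    for i in range(len(s) - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    idx: list[int] = []
    kinds: list[str] = []
    for i in range(1, len(s)):
        if s[i - 1] > 0 and s[i] < 0:
            idx.append(i + offset)
            kinds.append(PEAK)
        elif s[i - 1] < 0 and s[i] > 0:
            idx.append(i + offset)
            kinds.append(TROUGH)
    return idx, kinds


def _enforce_alternation(
    idx: np.ndarray, kinds: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of same-kind candidates, keeping the most extreme.

    ``z`` is the orientation-corrected signal (peaks are maxima). Ties keep
    the earliest candidate.
    """
    keep_idx: list[int] = []
    keep_kind: list[str] = []
    for i, k in zip(idx, kinds):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = z[i] > z[prev] if k == PEAK else z[i] < z[prev]
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(str(k))
    return np.asarray(keep_idx, dtype=np.int64), np.asarray(keep_kind, dtype="<U6")


def _excursion_filter(
    idx: np.ndarray,
    kinds: np.ndarray,
    z: np.ndarray,
    time: np.ndarray,
    min_fraction: float,
    min_half_period: float,
    robust_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively drop the weakest adjacent pair violating the excursion or
    half-period floor, re-enforcing alternation after each removal.

    The excursion floor is ``min_fraction`` times the typical peak-to-trough
    excursion, taken as the larger of the median retained excursion and
    ``robust_scale`` (the p95-p5 span of the signal, which for a breathing
    waveform is close to the peak-to-trough distance). The second term keeps
    the floor honest when noise wiggles outnumber real breaths and would
    otherwise dilute the median.
    """
    while len(idx) >= 2:
        amp = z[idx]
        exc = np.abs(np.diff(amp))
        dt = np.diff(time[idx])
        med = max(np.median(exc), robust_scale)
        bad = (exc < min_fraction * med) | (dt < min_half_period)
        if not bad.any():
            break
        weakest = int(np.flatnonzero(bad)[np.argmin(exc[bad])])
        mask = np.ones(len(idx), dtype=bool)
        mask[weakest : weakest + 2] = False
        idx, kinds = _enforce_alternation(idx[mask], kinds[mask], z)
    return idx, kinds


def detect_extrema(
    trace: BreathingTrace, config: DetectionConfig | None = None
) -> ExtremumSeries:
    """Locate actual breathing peaks and troughs, ignoring fluctuations that
    do not contribute to the breathing cycle.

    Raises
    ------
    InsufficientBreathingError
        If fewer than two extrema survive filtering (unanalyzable trace).
    """
    config = config or DetectionConfig()
    use_smoothing = (
        config.smoothing_window * trace.sample_rate >= 2
        and window_samples(config.smoothing_window, trace.sample_rate) >= 2
    )
    if use_smoothing:
        y = smooth(trace, config.smoothing_window)
    else:
        y = np.where(trace.valid, trace.amplitude, np.nan)

    sign = -1.0 if trace.inverted else 1.0
    zs = sign * y  # smoothed, orientation-corrected: candidate location
    z = sign * trace.amplitude  # recorded values: readout and filtering

    # scan each contiguous finite run separately so invalid stretches never
    # produce spurious extrema
    idx_all: list[int] = []
    kind_all: list[str] = []
    finite = np.isfinite(zs)
    start = None
    for i in range(len(zs) + 1):
        inside = i < len(zs) and finite[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            ids, kinds = _local_extrema(zs[start:i], start)
            idx_all.extend(ids)
            kind_all.extend(kinds)
            start = None

    idx, kinds = _enforce_alternation(
        np.asarray(idx_all, dtype=np.int64), np.asarray(kind_all, dtype="<U6"), z
    )
    finite_z = zs[np.isfinite(zs)]
    robust_scale = (
        float(np.percentile(finite_z, 95) - np.percentile(finite_z, 5))
        if finite_z.size
        else 0.0
    )
    idx, kinds = _excursion_filter(
        idx,
        kinds,
        z,
        trace.time,
        config.min_excursion_fraction,
        config.min_half_period,
        robust_scale,
    )
    if len(idx) < 2:
        raise InsufficientBreathingError(
            "fewer than 2 breathing extrema detected; trace is unanalyzable"
        )
    return ExtremumSeries(
        index=idx,
        time=trace.time[idx],
        amplitude=trace.amplitude[idx],
        kind=kinds,
        source="detected",
    )


def marked_extrema(trace: BreathingTrace) -> ExtremumSeries:
    """Extrema as marked by the vendor system (P -> peak, Z -> trough).

    Runs of same-kind marks are resolved by keeping the more extreme sample.

    Raises
    ------
    InsufficientMarksError
        If the trace carries fewer than two P/Z marks.
    """
    mask = (trace.marks == MARK_PEAK) | (trace.marks == MARK_TROUGH)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise InsufficientMarksError("trace carries fewer than 2 P/Z marks")
    kinds = np.where(trace.marks[idx] == MARK_PEAK, PEAK, TROUGH).astype("<U6")
    sign = -1.0 if trace.inverted else 1.0
    idx, kinds = _enforce_alternation(idx, kinds, sign * trace.amplitude)
    if idx.size < 2:
        raise InsufficientMarksError("fewer than 2 alternating marks remain")
    return ExtremumSeries(
        index=idx,
        time=trace.time[idx],
        amplitude=trace.amplitude[idx],
        kind=kinds,
        source="marked",
    )
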