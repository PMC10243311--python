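"""Closed-form clinical impact models for breathing-trace variability.

Three families of estimate, all assuming a simple cosine breathing trace:

* **Phase-shift displacement** — if phase binning is wrong by a fraction
  ``phi`` of the cycle, a target breathing with amplitude ``A`` (half the
  peak-to-trough distance) sits at
  ``dy = A [cos(2 pi x) - cos(2 pi (x + phi))]`` away from its intended
  position at breathing phase ``x``; the worst case over the cycle is
  ``2 A |sin(pi phi)|``.

* **Gated-PTV geometric miss** — for a circular PTV of radius ``r``
  displaced by ``d``, the area still treated is the lens (intersection) of
  two circles and the missed fraction is ``1 - lens / (pi r^2)``.

* **Voluming error and margin** — amplitude variability
  ``v = (SD(peaks) + SD(troughs))/2`` in mm maps to a relative internal
  target area error ``epsilon = -5.13 v - 6.71`` percent (an empirical
  linear fit, r^2 = 0.76; negative = the simulated target is too small),
  and the margin to add at each end of travel of a MIP of length ``x_mip``
  is ``m = -epsilon * x_mip / 2``.

Units are centralized here: amplitudes and MIP lengths in cm, variability
``v`` and margins ``m`` in mm, ``epsilon`` in percent, phases and phase
shifts as fractions of a cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

#: slope/intercept of the empirical amplitude-variability -> ITA-error fit
#: (epsilon in percent, v in mm)
VOLUMING_SLOPE = -5.13
VOLUMING_INTERCEPT = -6.71


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables).

    A 1e-9 nudge absorbs binary-float representation error so that values
    that are exactly at .5 in decimal arithmetic round up.
    """
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


@dataclass(frozen=True)
class PhaseShiftScenario:
    """A target breathing with amplitude ``A`` cm observed at phase ``x``
    (fraction of cycle) under a phase-binning shift ``phi``."""

    A: float
    phi: float
    x: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ConfigError("amplitude A must be >= 0")
        if not 0 <= self.x < 1:
            raise ConfigError("breathing phase x must be in [0, 1)")
        if abs(self.phi) > 1:
            raise ConfigError("|phi| must be <= 1 cycle")


@dataclass(frozen=True)
class GatedMissScenario:
    """A circular PTV of radius ``ptv_radius`` cm displaced by
    ``displacement`` cm at beam-on."""

    ptv_radius: float
    displacement: float

    def __post_init__(self) -> None:
        if self.ptv_radius <= 0:
            raise ConfigError("ptv_radius must be positive")
        if self.displacement < 0:
            raise ConfigError("displacement must be >= 0")


@dataclass(frozen=True)
class VolumingEstimate:
    """Voluming error for one scan/scenario: variability ``v`` (mm),
    relative ITA error ``epsilon`` (percent), and, when a MIP length is
    given, the margin ``m`` (mm) to add at each end of travel."""

    v: float
    epsilon: float
    x_mip: float | None = None  # cm
    m: float | None = None  # mm


def phase_displacement(scenario: PhaseShiftScenario) -> float:
    """Signed target displacement (cm) at breathing phase ``x`` caused by a
    phase shift ``phi``."""
    two_pi = 2.0 * math.pi
    return scenario.A * (
        math.cos(scenario.x * two_pi) - math.cos((scenario.x + scenario.phi) * two_pi)
    )


def max_displacement(A: float, phi: float) -> float:
    """Worst-case |displacement| (cm) over all breathing phases:
    ``2 A |sin(pi phi)|``."""
    if A < 0:
        raise ConfigError("amplitude A must be >= 0")
    return 2.0 * A * abs(math.sin(math.pi * phi))


def displacement_table(
    amplitudes: list[float] | np.ndarray,
    phases: list[float] | np.ndarray,
    phi: float,
    *,
    decimals: int | None = 1,
) -> pd.DataFrame:
    """Displacement grid (cm): rows = amplitudes, columns = breathing
    phases. Rounded to ``decimals`` (None = raw values)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amplitudes.size == 0 or phases.size == 0:
        raise ConfigError("amplitudes and phases must be non-empty")
    grid = amplitudes[:, None] * (
        np.cos(2 * np.pi * phases)[None, :]
        - np.cos(2 * np.pi * (phases + phi))[None, :]
    )
    if decimals is not None:
        grid = np.vectorize(lambda v: round_half_away(v, decimals))(grid)
    return pd.DataFrame(grid, index=amplitudes, columns=phases)


def circle_overlap_area(r: float, d: float) -> float:
    """Lens area (cm^2) of two radius-``r`` circles with centres ``d``
    apart; zero once the circles are disjoint."""
    if r <= 0:
        raise ConfigError("radius must be positive")
    if d < 0:
        raise ConfigError("distance must be >= 0")
    if d >= 2 * r:
        return 0.0
    return 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)


def ptv_missed_fraction(scenario: GatedMissScenario) -> float:
    """Fraction of the PTV area not treated at the displaced position."""
    r, d = scenario.ptv_radius, scenario.displacement
    area = math.pi * r * r
    frac = (area - circle_overlap_area(r, d)) / area
    return min(max(frac, 0.0), 1.0)


def voluming_error(sd_peaks: float, sd_troughs: float) -> VolumingEstimate:
    """Voluming error from peak/trough level variability (both in mm)."""
    if sd_peaks < 0 or sd_troughs < 0:
        raise ConfigError("level SDs must be >= 0")
    v = (sd_peaks + sd_troughs) / 2.0
    epsilon = VOLUMING_SLOPE * v + VOLUMING_INTERCEPT
    return VolumingEstimate(v=v, epsilon=epsilon)


def required_margin(epsilon: float, x_mip: float) -> float:
    """Margin (mm) to add at each end of travel: ``-epsilon * x_mip / 2``,
    with ``epsilon`` in percent and ``x_mip`` in cm; floored at zero (a
    positive epsilon means the simulated target is already too large)."""
    if x_mip <= 0:
        raise ConfigError("x_mip must be positive")
    return max(0.0, -epsilon / 100.0 * (x_mip * 10.0) / 2.0)


def margin_table(
    mip_lengths: list[float] | np.ndarray,
    epsilon: float,
    *,
    decimals: int | None = 1,
) -> pd.DataFrame:
    """Required margin (mm) per MIP length (cm) for a fixed voluming
    error."""
    mip_lengths = np.asarray(mip_lengths, dtype=float)
    if mip_lengths.size == 0:
        raise ConfigError("mip_lengths must be non-empty")
    m = np.array([required_margin(epsilon, x) for x in mip_lengths])
    if decimals is not None:
        m = np.array([round_half_away(v, decimals) for v in m])
    return pd.DataFrame({"mip_length_cm": mip_lengths, "margin_mm": m})


def phase_uncertainty_to_bins(relative_period_error: float, bin_width: float) -> int:
    """Number of respiratory bins a period error shifts images by, e.g. a
    19% period error with 10% bins misbins by 2 (the 0-10% bin lands in
    20-30%)."""
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    return int(round_half_away(relative_period_error / bin_width, 0))
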