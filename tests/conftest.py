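"""Shared fixtures: small synthetic traces built in memory."""

import numpy as np
import pytest

from breathqa.synth_traces import TraceSpec, generate_trace
from breathqa.vxp_io import BreathingTrace, VxpHeader


def make_cosine_trace(
    duration=60.0,
    fs=25.0,
    bpm=15.0,
    amplitude=0.5,
    noise=0.0,
    seed=0,
    marks_at_extrema=False,
):
    """A plain sampled cosine: peaks at t = 0, T, 2T, ... (boundary peak at
    t=0 included), amplitude in cm."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / bpm  # one breath = one full cycle
    amp = amplitude * np.cos(2 * np.pi * t / period)
    if noise:
        amp = amp + np.random.default_rng(seed).normal(0, noise, n)
    marks = np.full(n, "", dtype="<U1")
    if marks_at_extrema:
        half = period / 2
        k = 0
        while k * half <= t[-1]:
            idx = int(round(k * half * fs))
            if 0 < idx < n - 1:
                marks[idx] = "P" if k % 2 == 0 else "Z"
            k += 1
    header = VxpHeader(samples_per_second=fs, scale_factor=1000.0, total_study_time=duration)
    return BreathingTrace(
        header=header,
        time=t,
        amplitude=amp,
        phase=np.full(n, np.nan),
        valid=np.ones(n, dtype=bool),
        marks=marks,
    )


@pytest.fixture
def cosine_trace():
    return make_cosine_trace()


@pytest.fixture
def clean_spec():
    """Zero-corruption spec: regular breathing, no noise, exact marks."""
    return TraceSpec(
        duration=60.0,
        bpm_mean=15.0,
        bpm_cv=0.0,
        peak_level_sd=0.0,
        trough_level_sd=0.0,
        drift_sd_per_cycle=0.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def clean_trace(clean_spec):
    return generate_trace(clean_spec)


@pytest.fixture
def noisy_trace():
    trace, truth = generate_trace(TraceSpec(seed=5))
    return trace, truth
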