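"""Shared fixtures: filter design, noise backgrounds, planted-event helpers,
and an independent brute-force Stage-1 oracle."""

from __future__ import annotations

import numpy as np
import pytest

from hfodetect.stage1 import (
    Stage1Params,
    design_bandpass,
    envelope_threshold,
    hilbert_envelope,
    zero_phase_filter,
)
from hfodetect.synth import hfo_burst, pink_noise

FS = 2000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def sos():
    return design_bandpass(FS, Stage1Params())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def background(duration_s: float, rng: np.random.Generator,
               rms_uv: float = 20.0) -> np.ndarray:
    return pink_noise(int(duration_s * FS), 1.0, rng) * rms_uv


def plant_burst(x: np.ndarray, sos, freq_hz: float, n_cycles: int,
                snr: float, center: int,
                rng: np.random.Generator | None = None) -> tuple[int, int]:
    """Add a Tukey burst at `snr` x band-limited RMS; returns its bounds."""
    band_rms = zero_phase_filter(x, sos).std()
    b = hfo_burst(freq_hz, n_cycles, FS) * snr * band_rms
    i0 = center - len(b) // 2
    x[i0 : i0 + len(b)] += b
    return i0, i0 + len(b)


def stage1_features(x: np.ndarray, sos):
    """(filtered, envelope, threshold) triple for a raw trace."""
    xf = zero_phase_filter(x, sos)
    env = hilbert_envelope(xf)
    thr = envelope_threshold(env, 3.0)
    return xf, env, thr


# ---------------------------------------------------------------------------
# Independent Stage-1 oracle: explicit sample-by-sample scan
# ---------------------------------------------------------------------------

def brute_force_eois(xf, env, fs, p: Stage1Params | None = None):
    """Reference Stage-1 detection as plain Python loops.

    Returns a list of (start, end, peak) tuples; intentionally implemented
    without reusing any package helper so it can serve as an oracle.
    """
    p = p or Stage1Params()
    env = list(map(float, env))
    xf = list(map(float, xf))
    n = len(env)
    mean = sum(env) / n
    sd = (sum((v - mean) ** 2 for v in env) / n) ** 0.5
    thr = mean + p.env_sd_mult * sd
    half = p.half_thresh_frac * thr

    # suprathreshold excursions -> half-threshold bounds
    raw = []
    i = 0
    while i < n:
        if env[i] > thr:
            j = i
            while j < n and env[j] > thr:
                j += 1
            lo = i
            while lo > 0 and env[lo - 1] >= half:
                lo -= 1
            hi = j
            while hi < n and env[hi] >= half:
                hi += 1
            if raw and lo < raw[-1][1]:
                pass  # same half-threshold region as previous event
            else:
                raw.append((lo, hi))
            i = hi if hi > j else j
        else:
            i += 1

    # duration rule (strict)
    min_len_ms = p.min_duration_ms
    kept = [(lo, hi) for lo, hi in raw if (hi - lo) / fs * 1000.0 > min_len_ms]

    # merge gaps < merge_gap_ms
    merged = []
    for lo, hi in kept:
        if merged and (lo - merged[-1][1]) / fs * 1000.0 < p.merge_gap_ms:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))

    # peak-count rule on rectified filtered signal
    rect = [max(v, 0.0) for v in xf]
    rmean = sum(rect) / n
    rsd = (sum((v - rmean) ** 2 for v in rect) / n) ** 0.5
    pthr = rmean + p.peak_sd_mult * rsd
    out = []
    for lo, hi in merged:
        count = 0
        for k in range(lo + 1, hi - 1):  # interior of the event slice
            if rect[k] > rect[k - 1] and rect[k] > rect[k + 1] and rect[k] > pthr:
                count += 1
        if count >= p.min_peaks:
            peak = lo + max(range(hi - lo), key=lambda q: env[lo + q])
            out.append((lo, hi, peak))
    return out
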