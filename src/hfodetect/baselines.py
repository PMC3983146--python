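"""Published baseline detectors: short-time RMS energy and line length.

Both detect suprathreshold excursions of a smoothed feature trace of the
band-passed signal; they share Stage 1's duration and merge post-processing
but do not use the time-frequency validation stage.

* RMS detector: 100-500 Hz band, 3 ms moving RMS, threshold mean + 5 SD,
  duration > 6 ms, merge < 10 ms, and rejection of events with fewer than
  6 rectified-signal peaks above mean + 3 SD.
* LineLength detector: 80-500 Hz band, short-time line length (moving sum
  of absolute first differences), threshold mean + 5 SD, duration > 6 ms,
  merge < 10 ms, no peak-count rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import Recording
from .stage1 import (
    EoI,
    Stage1Params,
    _supra_runs,
    count_suprathreshold_peaks,
    design_bandpass,
    merge_close_events,
    zero_phase_filter,
)

__all__ = [
    "RmsParams",
    "LineLengthParams",
    "rms_detect",
    "linelength_detect",
    "moving_rms",
    "moving_line_length",
]


@dataclass(frozen=True)
class RmsParams:
    band_low: float = 100.0
    band_high: float = 500.0
    window_ms: float = 3.0
    sd_mult: float = 5.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0
    min_peaks: int = 6
    peak_sd_mult: float = 3.0


@dataclass(frozen=True)
class LineLengthParams:
    band_low: float = 80.0
    band_high: float = 500.0
    window_ms: float = 3.0
    sd_mult: float = 5.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0


def moving_rms(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    """Centred moving RMS over a `window_ms` sliding window."""
    w = max(1, int(round(window_ms * fs / 1000.0)))
    return np.sqrt(uniform_filter1d(x**2, size=w, mode="reflect"))


def moving_line_length(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    """Short-time line length: moving sum of |x[i] - x[i-1]| over the window.

    Offset-invariant by construction (first differences kill constants).
    """
    w = max(1, int(round(window_ms * fs / 1000.0)))
    d = np.abs(np.diff(x, prepend=x[0]))
    return uniform_filter1d(d, size=w, mode="reflect") * w


def _feature_events(
    trace: np.ndarray,
    fs: float,
    sd_mult: float,
    min_duration_ms: float,
    merge_gap_ms: float,
    channel_index: int,
) -> list[EoI]:
    thr = trace.mean() + sd_mult * trace.std()
    events = []
    for start, end in _supra_runs(trace > thr):
        peak = start + int(np.argmax(trace[start:end]))
        dur = (end - start) / fs * 1000.0
        events.append(
            EoI(
                channel_index=channel_index,
                start_sample=int(start),
                end_sample=int(end),
                peak_sample=int(peak),
                peak_envelope_uv=float(trace[peak]),
                duration_ms=dur,
            )
        )
    events = [e for e in events if e.duration_ms > min_duration_ms]
    return merge_close_events(events, trace, fs, merge_gap_ms)


def rms_detect(rec: Recording, p: RmsParams | None = None) -> dict[str, list[EoI]]:
    """Staba-style RMS-energy detector; per-channel event lists."""
    p = p or RmsParams()
    s1 = Stage1Params(band_low=p.band_low, band_high=p.band_high)
    sos = design_bandpass(rec.fs, s1)
    out: dict[str, list[EoI]] = {}
    for ci, label in enumerate(rec.labels):
        x = rec.samples[ci]
        if np.all(x == 0):
            out[label] = []
            continue
        xf = zero_phase_filter(x, sos)
        trace = moving_rms(xf, rec.fs, p.window_ms)
        events = _feature_events(
            trace, rec.fs, p.sd_mult, p.min_duration_ms, p.merge_gap_ms, ci
        )
        rect = np.maximum(xf, 0.0)
        peak_thr = rect.mean() + p.peak_sd_mult * rect.std()
        out[label] = [
            e
            for e in events
            if count_suprathreshold_peaks(
                xf[e.start_sample : e.end_sample], peak_thr
            )
            >= p.min_peaks
        ]
    return out


def linelength_detect(
    rec: Recording, p: LineLengthParams | None = None
) -> dict[str, list[EoI]]:
    """Gardner-style line-length detector; per-channel event lists."""
    p = p or LineLengthParams()
    s1 = Stage1Params(band_low=p.band_low, band_high=p.band_high)
    sos = design_bandpass(rec.fs, s1)
    out: dict[str, list[EoI]] = {}
    for ci, label in enumerate(rec.labels):
        x = rec.samples[ci]
        if np.all(x == 0):
            out[label] = []
            continue
        xf = zero_phase_filter(x, sos)
        trace = moving_line_length(xf, rec.fs, p.window_ms)
        out[label] = _feature_events(
            trace, rec.fs, p.sd_mult, p.min_duration_ms, p.merge_gap_ms, ci
        )
    return out
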