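"""Stage 1: candidate-event (EoI) detection in the time domain.

The signal is band-pass filtered 80-500 Hz with a zero-phase elliptic
(Cauer) IIR filter, the Hilbert envelope is thresholded at the epoch mean
plus 3 SD, event bounds are taken at the surrounding half-threshold
crossings, short events are dropped, close events merged, and events
without enough suprathreshold oscillation peaks rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

__all__ = [
    "Stage1Params",
    "EoI",
    "FilterDesignError",
    "design_bandpass",
    "zero_phase_filter",
    "hilbert_envelope",
    "envelope_threshold",
    "detect_eois",
    "merge_close_events",
    "count_suprathreshold_peaks",
]


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class Stage1Params:
    """Detection parameters for the candidate (EoI) stage.

    Defaults give the published operating point: an 80-500 Hz elliptic
    band-pass (60 dB stopband, 0.5 dB ripple, 10 Hz transitions), an
    envelope threshold of mean + 3 SD, event bounds at half threshold,
    a strict >6 ms duration rule, 10 ms merging, and rejection of events
    with fewer than 6 rectified-signal peaks above mean + 2 SD.
    """

    band_low: float = 80.0
    band_high: float = 500.0
    stopband_atten_db: float = 60.0
    passband_ripple_db: float = 0.5
    transition_hz: float = 10.0
    env_sd_mult: float = 3.0
    half_thresh_frac: float = 0.5
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0
    min_peaks: int = 6
    peak_sd_mult: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        for name in ("env_sd_mult", "half_thresh_frac", "min_duration_ms",
                     "merge_gap_ms", "peak_sd_mult", "transition_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class EoI:
    """A Stage-1 candidate event on one channel.

    `start_sample`/`end_sample` are half-open bounds at the half-threshold
    crossings; `peak_sample` is the envelope argmax within the event.
    `truncated` flags events whose half-threshold bound hit the epoch edge.
    """

    channel_index: int
    start_sample: int
    end_sample: int
    peak_sample: int
    peak_envelope_uv: float
    duration_ms: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.start_sample <= self.peak_sample < self.end_sample):
            raise ValueError("peak must lie within [start, end)")


def design_bandpass(fs: float, p: Stage1Params | None = None) -> np.ndarray:
    """Design the zero-phase-ready elliptic band-pass as second-order sections.

    The minimum filter order meeting the attenuation/ripple/transition
    constraints at `fs` is computed with `scipy.signal.ellipord`; the
    design is verified stable (all poles strictly inside the unit circle).
    """
    p = p or Stage1Params()
    if fs < 2 * (p.band_high + p.transition_hz):
        raise FilterDesignError(
            f"sampling rate {fs} Hz too low for upper stopband edge "
            f"{p.band_high + p.transition_hz} Hz (need fs >= "
            f"{2 * (p.band_high + p.transition_hz)} Hz)"
        )
    wp = [p.band_low, p.band_high]
    ws = [p.band_low - p.transition_hz, p.band_high + p.transition_hz]
    if ws[0] <= 0:
        raise FilterDesignError("lower stopband edge must be positive")
    order, wn = sps.ellipord(
        wp, ws, gpass=p.passband_ripple_db, gstop=p.stopband_atten_db, fs=fs
    )
    sos = sps.ellip(
        order, p.passband_ripple_db, p.stopband_atten_db, wn,
        btype="bandpass", output="sos", fs=fs,
    )
    _, poles, _ = sps.sos2zpk(sos)
    if np.abs(poles).max() >= 1.0:
        raise FilterDesignError("designed filter is unstable")
    return sos


def _settle_samples(sos: np.ndarray) -> int:
    """Samples for the slowest pole's transient to decay by ~e^-7."""
    _, poles, _ = sps.sos2zpk(sos)
    rho = np.abs(poles).max()
    if rho >= 1.0:
        raise FilterDesignError("unstable filter")
    return int(np.ceil(-7.0 / np.log(rho)))


def zero_phase_filter(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Forward-backward (zero net phase) filtering with the given sections.

    Edge padding is sized from the slowest pole's settle time: sharp
    elliptic designs have poles very close to the unit circle, so scipy's
    default pad length would let edge transients bleed far into the epoch.
    """
    x = np.asarray(x, dtype=np.float64)
    order = 2 * sos.shape[0]
    if x.shape[-1] <= 3 * order:
        raise ValueError(
            f"signal too short for zero-phase filtering: {x.shape[-1]} "
            f"samples <= 3 x filter order {order}"
        )
    padlen = min(x.shape[-1] - 1, _settle_samples(sos))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def hilbert_envelope(xf: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal of the band-passed trace."""
    xf = np.asarray(xf, dtype=np.float64)
    if not np.all(np.isfinite(xf)):
        raise ValueError("non-finite values in filtered signal")
    n = xf.shape[-1]
    analytic = sps.hilbert(xf, N=next_fast_len(n), axis=-1)[..., :n]
    return np.abs(analytic)


def envelope_threshold(env: np.ndarray, sd_mult: float) -> float:
    """Epoch-level threshold: mean(env) + sd_mult * SD(env) (population SD)."""
    return float(env.mean() + sd_mult * env.std())


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    return list(zip(idx[0::2], idx[1::2]))


def _expand_to_half(env: np.ndarray, start: int, end: int,
                    half: float) -> tuple[int, int, bool]:
    """Grow [start, end) outward over samples with env >= half."""
    lo = start
    while lo > 0 and env[lo - 1] >= half:
        lo -= 1
    hi = end
    while hi < len(env) and env[hi] >= half:
        hi += 1
    truncated = (lo == 0 and env[0] >= half) or (hi == len(env) and env[-1] >= half)
    return lo, hi, truncated


def merge_close_events(events: list[EoI], env: np.ndarray, fs: float,
                       merge_gap_ms: float) -> list[EoI]:
    """Merge events separated by less than `merge_gap_ms`.

    Merged bounds are the union; the peak is the larger envelope peak.
    Idempotent: re-merging the output is a no-op.
    """
    if not events:
        return []
    gap_samples = merge_gap_ms * fs / 1000.0
    events = sorted(events, key=lambda e: e.start_sample)
    out = [events[0]]
    for ev in events[1:]:
        cur = out[-1]
        if ev.start_sample - cur.end_sample < gap_samples:
            if ev.peak_envelope_uv > cur.peak_envelope_uv:
                peak, peak_uv = ev.peak_sample, ev.peak_envelope_uv
            else:
                peak, peak_uv = cur.peak_sample, cur.peak_envelope_uv
            end = max(cur.end_sample, ev.end_sample)
            out[-1] = replace(
                cur,
                end_sample=end,
                peak_sample=peak,
                peak_envelope_uv=peak_uv,
                duration_ms=(end - cur.start_sample) / fs * 1000.0,
                truncated=cur.truncated or ev.truncated,
            )
        else:
            out.append(ev)
    return out


def count_suprathreshold_peaks(seg: np.ndarray, peak_thr: float) -> int:
    """Local maxima of the rectified trace strictly above `peak_thr`."""
    rect = np.maximum(seg, 0.0)
    peaks, _ = sps.find_peaks(rect)
    return int(np.sum(rect[peaks] > peak_thr))


def detect_eois(
    xf: np.ndarray,
    env: np.ndarray,
    fs: float,
    p: Stage1Params | None = None,
    channel_index: int = 0,
) -> list[EoI]:
    """Detect candidate events on one channel.

    Pipeline, in order: (1) threshold = mean + `env_sd_mult` SD of the
    envelope over the whole epoch; (2) each suprathreshold excursion is
    bounded by the surrounding crossings of `half_thresh_frac` x threshold;
    (3) events with duration <= `min_duration_ms` are dropped (strict rule);
    (4) events closer than `merge_gap_ms` are merged; (5) events with fewer
    than `min_peaks` rectified-signal peaks above mean + `peak_sd_mult` SD
    of the rectified trace are rejected.  Returned events are sorted and
    non-overlapping.
    """
    p = p or Stage1Params()
    xf = np.asarray(xf, dtype=np.float64)
    env = np.asarray(env, dtype=np.float64)
    if xf.shape != env.shape or xf.ndim != 1:
        raise ValueError("xf and env must be 1-D arrays of equal length")
    if len(xf) < fs:
        raise ValueError("epoch shorter than 1 s: threshold statistics unreliable")

    thr = envelope_threshold(env, p.env_sd_mult)
    half = p.half_thresh_frac * thr

    events: list[EoI] = []
    for start, end in _supra_runs(env > thr):
        lo, hi, truncated = _expand_to_half(env, start, end, half)
        if events and lo < events[-1].end_sample:
            continue  # same half-threshold region as the previous excursion
        peak = lo + int(np.argmax(env[lo:hi]))
        events.append(
            EoI(
                channel_index=channel_index,
                start_sample=int(lo),
                end_sample=int(hi),
                peak_sample=int(peak),
                peak_envelope_uv=float(env[peak]),
                duration_ms=(hi - lo) / fs * 1000.0,
                truncated=truncated,
            )
        )

    events = [e for e in events if e.duration_ms > p.min_duration_ms]
    events = merge_close_events(events, env, fs, p.merge_gap_ms)

    rect = np.maximum(xf, 0.0)
    peak_thr = rect.mean() + p.peak_sd_mult * rect.std()
    events = [
        e
        for e in events
        if count_suprathreshold_peaks(xf[e.start_sample:e.end_sample], peak_thr)
        >= p.min_peaks
    ]
    return events
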