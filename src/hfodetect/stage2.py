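"""Stage 2: recognize HFOs among candidate events in the time-frequency domain.

Each candidate is re-examined on the *raw* (unfiltered) signal in a 1 s
window centred on its envelope peak.  Every instantaneous spectrum within
the event's FWHM support must show a high-frequency peak (HiFP, searched
60-500 Hz) isolated from low-frequency activity by a spectral trough
(searched from 40 Hz up): the trough must be strictly below the HiFP in
frequency with Power(trough)/Power(HiFP) < 0.8, and the HiFP must stand
above the nearest low-frequency peak (LoFP) below the trough with
Power(HiFP)/Power(LoFP) > 0.5.  Windows whose global spectral maximum
above 60 Hz lies beyond 500 Hz are artifacts and rejected outright.
Accepted events are classed as ripples (HiFP < 200 Hz) or fast ripples.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import Montage, Recording
from .stage1 import (
    EoI,
    Stage1Params,
    design_bandpass,
    detect_eois,
    envelope_threshold,
    hilbert_envelope,
    zero_phase_filter,
)
from .stockwell import TFMap, fwhm_support, stockwell_transform

__all__ = [
    "Stage2Params",
    "SpectralTriplet",
    "RejectReason",
    "HfoClass",
    "HfoEvent",
    "parameterize_psd",
    "validate_eoi",
    "classify_event",
    "detect_hfos",
]


class RejectReason(str, Enum):
    NONE = "none"
    NO_TROUGH = "no_trough"
    RATIO_FAIL = "ratio_fail"
    PEAK_ABOVE_500 = "peak_above_500"
    NO_LOFP = "no_lofp"


class HfoClass(str, Enum):
    RIPPLE = "ripple"
    FAST_RIPPLE = "fast_ripple"


@dataclass(frozen=True)
class Stage2Params:
    """Spectral-parameterization thresholds for HFO recognition.

    `ratio_domain` selects whether the two power-ratio criteria are applied
    to linear power (default) or to dB values; linear ratios are scale-free
    and are the recommended reading.
    """

    f_min_hifp: float = 60.0
    f_max_hifp: float = 500.0
    f_min_trough: float = 40.0
    trough_ratio_max: float = 0.8
    r_thr: float = 0.5
    artifact_peak_hz: float = 500.0
    ripple_fr_split_hz: float = 200.0
    ratio_domain: str = "linear"

    def __post_init__(self) -> None:
        if not (self.f_min_trough < self.f_min_hifp < self.f_max_hifp):
            raise ValueError("require f_min_trough < f_min_hifp < f_max_hifp")
        if not (0 < self.trough_ratio_max < 1):
            raise ValueError("trough_ratio_max must be in (0, 1)")
        if self.r_thr <= 0:
            raise ValueError("r_thr must be > 0")
        if self.ratio_domain not in ("linear", "db"):
            raise ValueError("ratio_domain must be 'linear' or 'db'")


@dataclass(frozen=True)
class SpectralTriplet:
    """HiFP / trough / LoFP frequencies and linear powers of one spectrum.

    `lofp_hz` is NaN when no local maximum exists below the trough.
    """

    hifp_hz: float
    hifp_power: float
    trough_hz: float
    trough_power: float
    lofp_hz: float = float("nan")
    lofp_power: float = float("nan")


@dataclass
class HfoEvent:
    """A Stage-2 validated (accepted or rejected) event."""

    eoi: EoI
    accepted: bool
    reject_reason: RejectReason
    characteristic: SpectralTriplet | None
    hfo_class: HfoClass | None
    duration_ms: float
    amplitude_uv: float
    window_padded: bool = False


def _local_max_below(psd: np.ndarray, upper: int) -> int | None:
    """Nearest strict local maximum at a bin index < upper, scanning down.

    A bin qualifies when it exceeds its right neighbour and is not below its
    left neighbour (plateaus resolve to their highest-frequency bin).  Bin 0
    has no left neighbour and cannot qualify.
    """
    for j in range(upper - 1, 0, -1):
        if psd[j] > psd[j + 1] and psd[j] >= psd[j - 1]:
            return j
    return None


def parameterize_psd(
    psd: np.ndarray, p: Stage2Params | None = None
) -> tuple[SpectralTriplet, RejectReason]:
    """Parameterize one instantaneous spectrum by HiFP, trough and LoFP.

    The HiFP is the spectral argmax over [60, 500] Hz, the trough the argmin
    over [40 Hz, HiFP], and the LoFP the nearest local maximum below the
    trough.  Returns the triplet together with a status: NO_TROUGH when the
    trough coincides with the HiFP (no separating trough, the "false ripple"
    signature), NO_LOFP when no local maximum exists below the trough.

    The spectrum must be sampled on the 1 Hz grid starting at 0 Hz.
    """
    p = p or Stage2Params()
    psd = np.asarray(psd, dtype=np.float64)
    if not np.any(psd > 0):
        raise ValueError("all-zero spectrum cannot be parameterized")
    f_lo = int(round(p.f_min_hifp))
    f_hi = min(int(round(p.f_max_hifp)), len(psd) - 1)
    hifp = f_lo + int(np.argmax(psd[f_lo : f_hi + 1]))
    t_lo = int(round(p.f_min_trough))
    trough = t_lo + int(np.argmin(psd[t_lo : hifp + 1]))
    triplet = SpectralTriplet(
        hifp_hz=float(hifp),
        hifp_power=float(psd[hifp]),
        trough_hz=float(trough),
        trough_power=float(psd[trough]),
    )
    if trough == hifp:
        return triplet, RejectReason.NO_TROUGH
    lofp = _local_max_below(psd, trough)
    if lofp is None:
        return triplet, RejectReason.NO_LOFP
    triplet = SpectralTriplet(
        hifp_hz=float(hifp),
        hifp_power=float(psd[hifp]),
        trough_hz=float(trough),
        trough_power=float(psd[trough]),
        lofp_hz=float(lofp),
        lofp_power=float(psd[lofp]),
    )
    return triplet, RejectReason.NONE


def _ratios_ok(tr: SpectralTriplet, p: Stage2Params) -> tuple[bool, bool]:
    """(trough deep enough, HiFP high enough) under the configured domain."""
    if p.ratio_domain == "linear":
        hi, lo, th = tr.hifp_power, tr.lofp_power, tr.trough_power
    else:  # ratios of dB values (for comparison runs only)
        hi = 10 * np.log10(tr.hifp_power)
        lo = 10 * np.log10(tr.lofp_power)
        th = 10 * np.log10(tr.trough_power)
    trough_ok = th / hi < p.trough_ratio_max
    peak_ok = (hi / lo > p.r_thr) if np.isfinite(lo) else False
    return bool(trough_ok), bool(peak_ok)


def validate_eoi(
    raw: np.ndarray,
    env: np.ndarray,
    eoi: EoI,
    threshold: float,
    fs: float,
    p: Stage2Params | None = None,
    return_tfmap: bool = False,
) -> HfoEvent | tuple[HfoEvent, TFMap]:
    """Validate one candidate against the time-frequency criteria.

    `raw` and `env` are the full-epoch raw signal and Stage-1 envelope; the
    1 s analysis window is cut around the event's envelope peak (reflection
    padded and flagged if it overruns the epoch).  Every instantaneous
    spectrum within the FWHM support (clipped to the unmasked central half
    second) must pass, in order: the >500 Hz artifact check, the trough
    existence and depth checks, and the HiFP/LoFP height check.  The
    characteristic triplet is the one at the envelope peak.
    """
    p = p or Stage2Params()
    n = int(round(fs))
    center = eoi.peak_sample
    lo = center - n // 2
    hi = lo + n
    padded = lo < 0 or hi > len(raw)
    if padded:
        pad_before = max(0, -lo)
        pad_after = max(0, hi - len(raw))
        window = np.pad(
            raw[max(0, lo) : min(len(raw), hi)],
            (pad_before, pad_after),
            mode="reflect",
        )
    else:
        window = raw[lo:hi]
    tf = stockwell_transform(window, fs, start_sample=lo, center_sample=center)

    s_lo, s_hi = fwhm_support(env, eoi, threshold)
    v_lo, v_hi = tf.valid_time_range()
    w_lo = max(s_lo - lo, v_lo)
    w_hi = min(s_hi - lo, v_hi)
    center_w = center - lo
    w_lo = min(w_lo, center_w)
    w_hi = max(w_hi, center_w + 1)

    f_nyq = len(tf.freqs) - 1
    a_lo = int(round(p.f_min_hifp))
    accepted = True
    reason = RejectReason.NONE
    for t in range(w_lo, w_hi):
        psd = tf.power[:, t]
        if a_lo + int(np.argmax(psd[a_lo:])) > p.artifact_peak_hz:
            accepted, reason = False, RejectReason.PEAK_ABOVE_500
            break
        triplet, status = parameterize_psd(psd, p)
        if status is not RejectReason.NONE:
            accepted, reason = False, status
            break
        trough_ok, peak_ok = _ratios_ok(triplet, p)
        if not (trough_ok and peak_ok):
            accepted, reason = False, RejectReason.RATIO_FAIL
            break

    characteristic, _ = parameterize_psd(tf.power[:, center_w], p)
    ev = HfoEvent(
        eoi=eoi,
        accepted=accepted,
        reject_reason=reason,
        characteristic=characteristic,
        hfo_class=None,
        duration_ms=eoi.duration_ms,
        amplitude_uv=eoi.peak_envelope_uv,
        window_padded=padded,
    )
    if accepted:
        ev.hfo_class = classify_event(ev, p)
    if return_tfmap:
        return ev, tf
    return ev


def classify_event(ev: HfoEvent, p: Stage2Params | None = None) -> HfoClass:
    """Class an accepted event: ripple below the 200 Hz split, fast ripple at
    or above it.  Accepted events with HiFP below 80 Hz stay in the ripple
    bin so that ripples and fast ripples partition all accepted events."""
    p = p or Stage2Params()
    if not ev.accepted:
        raise ValueError("only accepted events are classified")
    if ev.characteristic.hifp_hz < p.ripple_fr_split_hz:
        return HfoClass.RIPPLE
    return HfoClass.FAST_RIPPLE


def detect_hfos(
    rec: Recording,
    s1: Stage1Params | None = None,
    s2: Stage2Params | None = None,
    min_duration_s: float = 60.0,
) -> dict[str, list[HfoEvent]]:
    """Run the full two-stage detector on every channel of a recording.

    Returns a mapping channel label -> validated events (accepted and
    rejected, with diagnostics).  Deterministic given the input.
    """
    s1 = s1 or Stage1Params()
    s2 = s2 or Stage2Params()
    if rec.duration_s < min_duration_s:
        raise ValueError(
            f"recording too short: {rec.duration_s:.1f} s < {min_duration_s} s"
        )
    if rec.montage is not Montage.BIPOLAR:
        import warnings

        warnings.warn(
            "detector is intended for bipolar montages; running on "
            "common-reference channels", stacklevel=2,
        )
    sos = design_bandpass(rec.fs, s1)
    out: dict[str, list[HfoEvent]] = {}
    for ci, label in enumerate(rec.labels):
        x = rec.samples[ci]
        if np.all(x == 0):
            out[label] = []
            continue
        xf = zero_phase_filter(x, sos)
        env = hilbert_envelope(xf)
        thr = envelope_threshold(env, s1.env_sd_mult)
        eois = detect_eois(xf, env, rec.fs, s1, channel_index=ci)
        out[label] = [validate_eoi(x, env, e, thr, rec.fs, s2) for e in eois]
    return out
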