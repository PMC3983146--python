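"""Synthetic iEEG generator with ground-truth event labels.

Emulates the study conditions the detector targets: multichannel 2000 Hz
recordings (5 min by default) of 1/f background activity into which three
kinds of transient are planted at per-channel Poisson rates with an
enforced dead time:

* **HFO bursts** — Tukey-windowed sinusoids of at least four cycles at a
  frequency drawn from 60-500 Hz, scaled to a target SNR relative to the
  band-limited (80-500 Hz) background RMS.  The tapered-cosine window
  keeps spectral splatter below the >500 Hz artifact-rejection region.
* **Interictal epileptiform spikes (IES)** — smoothed biphasic sharp
  transients (20-70 ms wide, cusp 5-20x the broadband background RMS).
  Their pointed main lobe rings an 80-500 Hz filter hard enough to pass
  Stage 1 as a "false ripple" while their spectrum decays smoothly with
  frequency, the signature Stage 2 rejects for lack of a spectral trough.
* **Artifacts** — 1-3-sample impulses or steps, far larger than the
  background, whose instantaneous spectra are flat or rising with
  frequency so the spectral peak falls above 500 Hz.

All randomness flows from a single seed; generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Montage, Recording
from .stage1 import Stage1Params, design_bandpass, zero_phase_filter

__all__ = [
    "BackgroundSpec",
    "HfoTemplate",
    "IesTemplate",
    "ArtifactTemplate",
    "EventRates",
    "SynthSpec",
    "GroundTruth",
    "pink_noise",
    "hfo_burst",
    "ies_transient",
    "synthesize_recording",
    "make_study",
]

#: Minimum spacing between planted events on one channel (seconds).
DEAD_TIME_S = 0.2
#: Keep events clear of the epoch edges so 1 s analysis windows fit.
EDGE_MARGIN_S = 0.6


@dataclass(frozen=True)
class BackgroundSpec:
    """1/f^alpha background: spectral exponent and target broadband RMS."""

    exponent: float = 1.0
    rms_uv: float = 20.0


@dataclass(frozen=True)
class HfoTemplate:
    """Planted oscillatory burst: >=4 cycles, 60-500 Hz, Tukey(0.25) taper.

    `snr` is the burst amplitude as a multiple of the 80-500 Hz band-limited
    background RMS; durations shorter than 6 ms are extended to 6 ms by
    adding cycles so planted events satisfy the Stage-1 duration rule by
    construction.
    """

    freq_range_hz: tuple[float, float] = (60.0, 500.0)
    n_cycles_range: tuple[int, int] = (6, 12)
    snr: float = 8.0
    tukey_alpha: float = 0.25
    min_duration_ms: float = 6.0

    def __post_init__(self) -> None:
        if self.n_cycles_range[0] < 4:
            raise ValueError("HFOs have at least four cycles")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


@dataclass(frozen=True)
class IesTemplate:
    """Interictal-spike template: sharp cusp riding a slow-wave body.

    The planted transient is the sum of a pointed cusp (decay constant
    `cusp_tau_ms`), a smooth sharp-wave body (Gaussian, width floored at
    `body_min_ms` and `body_amp` times the cusp amplitude) and a slower
    opposite-polarity after-wave; total support `width_ms_range`.  The
    amplitude multiplier scales the *cusp* in units of the broadband
    background RMS; the overall peak is about 3.4x that, putting spikes in
    the several-hundred-microvolt range typical of large interictal
    discharges.  The cusp's broadband tail is what rings an 80-500 Hz
    filter ("false ripples"), while body plus after-wave keep the
    instantaneous spectrum a smooth continuum falling from low to high
    frequency - the signature Stage 2 rejects for lack of a trough.
    """

    width_ms_range: tuple[float, float] = (20.0, 70.0)
    amplitude_mult_range: tuple[float, float] = (5.0, 20.0)
    cusp_tau_ms: float = 2.5
    body_amp: float = 2.5
    body_min_ms: float = 4.0


@dataclass(frozen=True)
class ArtifactTemplate:
    """1-3 sample impulse or step, 20-50x background RMS (sharp recording
    artifacts - electrode pops, connector glitches - are typically far
    larger than physiological activity)."""

    n_samples_range: tuple[int, int] = (1, 3)
    amplitude_mult_range: tuple[float, float] = (20.0, 50.0)
    kinds: tuple[str, ...] = ("impulse", "step")


@dataclass(frozen=True)
class EventRates:
    """Planted event rates per minute, per event type."""

    hfo: float = 0.0
    ies: float = 0.0
    ies_plus_hfo: float = 0.0
    artifact: float = 0.0

    def __post_init__(self) -> None:
        if min(self.hfo, self.ies, self.ies_plus_hfo, self.artifact) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic recording.

    `rates` may be one :class:`EventRates` applied to every channel or a
    list with one entry per channel.
    """

    fs: float = 2000.0
    duration_s: float = 300.0
    n_channels: int = 8
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    rates: EventRates | list[EventRates] = field(default_factory=EventRates)
    hfo: HfoTemplate = field(default_factory=HfoTemplate)
    ies: IesTemplate = field(default_factory=IesTemplate)
    artifact: ArtifactTemplate = field(default_factory=ArtifactTemplate)
    seed: int = 0

    def rates_for(self, channel: int) -> EventRates:
        if isinstance(self.rates, EventRates):
            return self.rates
        return self.rates[channel]


GroundTruth = pd.DataFrame  # columns: channel, type, start_s, end_s, true_freq_hz


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise of unit RMS via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= f ** (exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def hfo_burst(freq_hz: float, n_cycles: int, fs: float,
              tukey_alpha: float = 0.25,
              min_duration_ms: float = 6.0) -> np.ndarray:
    """Unit-amplitude Tukey-windowed sinusoidal burst."""
    duration = max(n_cycles / freq_hz, min_duration_ms / 1000.0)
    n = max(int(round(duration * fs)), 4)
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq_hz * t) * sps.windows.tukey(n, tukey_alpha)


def ies_transient(width_ms: float, fs: float,
                  cusp_tau_ms: float = 2.5,
                  body_amp: float = 2.5,
                  body_min_ms: float = 4.0) -> np.ndarray:
    """Smoothed biphasic interictal-spike waveform, unit cusp amplitude.

    A Laplacian cusp (decay `cusp_tau_ms`) on top of a Gaussian sharp-wave
    body (sigma = max(width/10, `body_min_ms`), amplitude `body_amp`),
    followed by an opposite-polarity half-sine after-wave; lightly smoothed
    so the cusp is a sharp transient rather than a digital edge.
    """
    n = max(int(round(width_ms / 1000.0 * fs)), 16)
    t = np.arange(n)
    c = n // 3
    sigma = max(n / 10.0, body_min_ms / 1000.0 * fs)
    body = body_amp * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    n_wave = n - c - int(2 * sigma)
    wave = np.zeros(n)
    if n_wave > 4:
        wave[n - n_wave:] = -0.5 * np.sin(
            np.pi * np.arange(n_wave) / max(n_wave - 1, 1)
        )
    tau = cusp_tau_ms / 1000.0 * fs
    cusp = np.exp(-np.abs(t - c) / tau)
    kernel = np.array([0.25, 0.5, 0.25])
    return np.convolve(body + wave + cusp, kernel, mode="same")


def _place_events(
    n_events: int, duration_s: float, existing: list[float],
    rng: np.random.Generator, max_tries: int = 10000,
) -> list[float]:
    """Draw event centre times uniformly with dead time against `existing`."""
    times = list(existing)
    placed = []
    lo, hi = EDGE_MARGIN_S, duration_s - EDGE_MARGIN_S
    if hi <= lo:
        raise ValueError("recording too short to place events")
    for _ in range(n_events):
        for attempt in range(max_tries):
            t = rng.uniform(lo, hi)
            if all(abs(t - u) >= DEAD_TIME_S for u in times):
                times.append(t)
                placed.append(t)
                break
        else:
            raise ValueError(
                "infeasible rate x dead-time combination: could not place event"
            )
    return placed


def synthesize_recording(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate a recording plus its ground-truth event table.

    Planted events are non-overlapping within a channel (dead time 0.2 s)
    and fully determined by `spec.seed`.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    sos = design_bandpass(fs, Stage1Params())

    samples = np.empty((spec.n_channels, n))
    rows = []
    for ci in range(spec.n_channels):
        bg = pink_noise(n, spec.background.exponent, rng) * spec.background.rms_uv
        band_rms = float(zero_phase_filter(bg, sos).std())
        x = bg
        rates = spec.rates_for(ci)
        occupied: list[float] = []
        for etype, rate in (
            ("hfo", rates.hfo),
            ("ies", rates.ies),
            ("ies_plus_hfo", rates.ies_plus_hfo),
            ("artifact", rates.artifact),
        ):
            n_ev = rng.poisson(rate * spec.duration_s / 60.0)
            centers = _place_events(n_ev, spec.duration_s, occupied, rng)
            occupied.extend(centers)
            for t0 in centers:
                freq = np.nan
                if etype in ("hfo", "ies_plus_hfo"):
                    freq = rng.uniform(*spec.hfo.freq_range_hz)
                    cyc = rng.integers(
                        spec.hfo.n_cycles_range[0],
                        spec.hfo.n_cycles_range[1] + 1,
                    )
                    burst = (
                        hfo_burst(freq, int(cyc), fs, spec.hfo.tukey_alpha,
                                  spec.hfo.min_duration_ms)
                        * spec.hfo.snr * band_rms
                    )
                    seg = burst
                    if etype == "ies_plus_hfo":
                        w = rng.uniform(*spec.ies.width_ms_range)
                        amp = rng.uniform(*spec.ies.amplitude_mult_range)
                        spike = (
                            ies_transient(w, fs, spec.ies.cusp_tau_ms,
                                      spec.ies.body_amp, spec.ies.body_min_ms)
                            * amp * spec.background.rms_uv
                        )
                        m = max(len(spike), len(burst))
                        seg = np.zeros(m)
                        o_s = (m - len(spike)) // 2
                        o_b = (m - len(burst)) // 2
                        seg[o_s : o_s + len(spike)] += spike
                        seg[o_b : o_b + len(burst)] += burst
                elif etype == "ies":
                    w = rng.uniform(*spec.ies.width_ms_range)
                    amp = rng.uniform(*spec.ies.amplitude_mult_range)
                    seg = (
                        ies_transient(w, fs, spec.ies.cusp_tau_ms,
                                      spec.ies.body_amp, spec.ies.body_min_ms)
                        * amp * spec.background.rms_uv
                    )
                else:  # artifact
                    kind = spec.artifact.kinds[
                        rng.integers(len(spec.artifact.kinds))
                    ]
                    k = int(
                        rng.integers(
                            spec.artifact.n_samples_range[0],
                            spec.artifact.n_samples_range[1] + 1,
                        )
                    )
                    amp = (
                        rng.uniform(*spec.artifact.amplitude_mult_range)
                        * spec.background.rms_uv
                    )
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    if kind == "impulse":
                        seg = np.full(k, sign * amp)
                    else:  # step: jump up, hold briefly, jump back
                        hold = int(0.05 * fs)
                        seg = np.full(hold, sign * amp)
                i0 = int(round(t0 * fs)) - len(seg) // 2
                x[i0 : i0 + len(seg)] += seg
                rows.append(
                    {
                        "channel": f"CH{ci + 1:02d}",
                        "type": etype,
                        "start_s": i0 / fs,
                        "end_s": (i0 + len(seg)) / fs,
                        "true_freq_hz": freq,
                    }
                )
        samples[ci] = x

    labels = [f"CH{ci + 1:02d}" for ci in range(spec.n_channels)]
    rec = Recording(samples, fs, labels, Montage.BIPOLAR)
    truth = pd.DataFrame(
        rows, columns=["channel", "type", "start_s", "end_s", "true_freq_hz"]
    ).sort_values(["channel", "start_s"]).reset_index(drop=True)
    return rec, truth


def make_study(
    n_soz_channels: int,
    n_other: int,
    rate_high: float,
    rate_low: float,
    seed: int,
    snr: float = 8.0,
    fs: float = 2000.0,
    duration_s: float = 300.0,
) -> tuple[Recording, set[str], GroundTruth]:
    """A labelled evaluation study: HFOs planted densely on "SOZ" channels.

    The first `n_soz_channels` channels carry `rate_high` HFOs/min, the
    remaining `n_other` carry `rate_low`; `rate_high > 2 * rate_low` is
    required so the half-maximum rule can separate them by construction.
    Returns the recording, the planted SOZ label set, and the ground truth.
    """
    if rate_high <= 2 * rate_low:
        raise ValueError("require rate_high > 2 * rate_low")
    n_ch = n_soz_channels + n_other
    rates = [
        EventRates(hfo=rate_high if ci < n_soz_channels else rate_low)
        for ci in range(n_ch)
    ]
    spec = SynthSpec(
        fs=fs,
        duration_s=duration_s,
        n_channels=n_ch,
        rates=rates,
        hfo=HfoTemplate(snr=snr),
        seed=seed,
    )
    rec, truth = synthesize_recording(spec)
    soz = {f"CH{ci + 1:02d}" for ci in range(n_soz_channels)}
    return rec, soz, truth
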