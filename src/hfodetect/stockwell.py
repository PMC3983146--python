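"""Stockwell (S-) transform and instantaneous power spectra.

The S-transform decomposes a signal with a Gaussian window whose width
scales inversely with frequency (sigma(f) = 1/f), giving a time-frequency
map that behaves like a short-time Fourier transform at low frequencies
and like a wavelet transform at high frequencies.  Validation of candidate
HFO events inspects 1 s windows of the raw signal; only the central 0.5 s
is trusted, the outer quarters absorb boundary effects.

Implementation follows the standard frequency-domain form: for the n-th
discrete frequency, S[n, :] = IFFT_m( X[n + m] * exp(-2 pi^2 m^2 / n^2) ),
where X is the DFT of the window and m runs over wrapped frequencies.  The
zero-frequency row is the window mean.  The time-marginal identity
mean_tau S(tau, f) = X(f) holds exactly and is used as a self-check in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stage1 import EoI

__all__ = [
    "TFMap",
    "stockwell_transform",
    "instantaneous_psd",
    "fwhm_support",
    "BoundaryRegionError",
]


class BoundaryRegionError(ValueError):
    """Requested time point falls in the masked boundary half-second."""


@dataclass
class TFMap:
    """Time-frequency power map of a 1 s window.

    `power` is linear mu-V^2/Hz on a [frequency x time] grid; for a 1 s
    window at integer sampling rate the frequency step is exactly 1 Hz
    (freqs = 0 .. fs/2).  `start_sample` locates the window within the
    epoch; `center_sample` is the event's envelope peak.
    """

    power: np.ndarray
    freqs: np.ndarray
    fs: float
    start_sample: int = 0
    center_sample: int | None = None

    @property
    def n_times(self) -> int:
        return self.power.shape[1]

    def valid_time_range(self) -> tuple[int, int]:
        """Half-open window-index range of the unmasked central 0.5 s."""
        n = self.n_times
        return n // 4, n - n // 4

    def to_frame(self):
        """Export the power grid as a DataFrame (rows = frequency bins)."""
        import pandas as pd

        times = (self.start_sample + np.arange(self.n_times)) / self.fs
        return pd.DataFrame(self.power, index=self.freqs, columns=times)


def _stockwell(x: np.ndarray) -> np.ndarray:
    """Complex S-transform, rows 0..N//2, columns = window samples."""
    n = len(x)
    X = np.fft.fft(x) / n
    n_freq = n // 2 + 1
    m = np.fft.fftfreq(n, 1.0 / n)  # wrapped integer frequency offsets
    k = np.arange(1, n_freq)
    # voice k: IFFT of shifted spectrum X[k+m] times Gaussian exp(-2pi^2 m^2/k^2)
    shifted = np.empty((n_freq - 1, n), dtype=complex)
    for i, kk in enumerate(k):
        shifted[i] = np.roll(X, -kk)
    gauss = np.exp(-2.0 * np.pi**2 * m[None, :] ** 2 / k[:, None] ** 2)
    S = np.empty((n_freq, n), dtype=complex)
    S[0] = x.mean()
    S[1:] = np.fft.ifft(shifted * gauss, axis=1) * n
    return S


def stockwell_transform(
    x: np.ndarray,
    fs: float,
    start_sample: int = 0,
    center_sample: int | None = None,
    pad: bool = False,
) -> TFMap:
    """S-transform power of a 1 s window.

    Parameters
    ----------
    x : ndarray
        Raw-signal window; its length must equal ``int(fs)`` samples
        (exactly 1 s) unless `pad` is set, in which case the window is
        symmetrically reflection-padded to 1 s.
    fs : float
        Sampling rate; must be an integer number of Hz for the 1 Hz grid.
    start_sample, center_sample : int
        Epoch coordinates of the window, carried through for bookkeeping.
    """
    x = np.asarray(x, dtype=np.float64)
    n = int(round(fs))
    if fs != n:
        raise ValueError("integer sampling rate required for the 1 Hz grid")
    if len(x) != n:
        if not pad:
            raise ValueError(
                f"window must be 1 s = {n} samples (got {len(x)}); "
                "pass pad=True to reflection-pad"
            )
        deficit = n - len(x)
        if deficit < 0:
            raise ValueError("window longer than 1 s")
        before = deficit // 2
        x = np.pad(x, (before, deficit - before), mode="reflect")
        start_sample -= before
    S = _stockwell(x)
    power = np.abs(S) ** 2
    freqs = np.arange(power.shape[0], dtype=float)
    return TFMap(power, freqs, float(fs), start_sample, center_sample)


def instantaneous_psd(tf: TFMap, t: int) -> np.ndarray:
    """One instantaneous spectrum (linear power vs frequency) at window index t.

    Only the central 0.5 s of the window is valid; requests in the masked
    boundary quarters raise :class:`BoundaryRegionError`.  For display the
    caller converts to dB as 10*log10(power).
    """
    lo, hi = tf.valid_time_range()
    if not lo <= t < hi:
        raise BoundaryRegionError(
            f"boundary region: t={t} outside central half-second [{lo}, {hi})"
        )
    return tf.power[:, t]


def fwhm_support(env: np.ndarray, eoi: EoI, threshold: float) -> tuple[int, int]:
    """Half-open interval of full-width-at-half-maximum support above threshold.

    The maximal contiguous run around the event's envelope peak where the
    envelope is both >= half the peak value and >= the Stage-1 threshold.
    Always contains the peak sample (degenerating to a single sample).
    """
    peak = eoi.peak_sample
    if not 0 <= peak < len(env):
        raise ValueError("event peak outside envelope")
    level = max(env[peak] / 2.0, threshold)
    lo = peak
    while lo > 0 and env[lo - 1] >= level:
        lo -= 1
    hi = peak + 1
    while hi < len(env) and env[hi] >= level:
        hi += 1
    return lo, hi
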