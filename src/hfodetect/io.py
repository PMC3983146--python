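"""Recording data model and readers/writers.

Two on-disk formats are supported: EDF (European Data Format, read via
:mod:`mne`, written by a minimal built-in writer) and a plain tab-separated
text format (one column per channel, header row of labels, sampling rate in
a JSON sidecar).  Samples are held in microvolts throughout.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "Recording",
    "BipolarPair",
    "InsufficientSamplingRateError",
    "MIN_SAMPLING_RATE_HZ",
    "load_recording",
    "write_delimited",
    "write_edf",
    "to_bipolar",
    "write_event_table",
    "read_event_table",
    "EVENT_TABLE_COLUMNS",
]

#: Detector contract: recordings sampled below this rate are rejected.
MIN_SAMPLING_RATE_HZ = 2000.0

EVENT_TABLE_COLUMNS = [
    "channel",
    "start_s",
    "end_s",
    "peak_s",
    "hifp_hz",
    "trough_hz",
    "lofp_hz",
    "class",
    "accepted",
    "reject_reason",
]


class InsufficientSamplingRateError(ValueError):
    """Raised when a recording's sampling rate is below the detector contract."""


class Montage(str, Enum):
    COMMON_REFERENCE = "common_reference"
    BIPOLAR = "bipolar"


@dataclass
class Recording:
    """Multichannel sampled iEEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz; must be >= 2000.
    labels : list of str
        Unique per-channel identifiers.
    montage : Montage
        Whether channels are referenced to a common reference or are
        bipolar derivations.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    montage: Montage = Montage.COMMON_REFERENCE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [channels x time] array")
        if self.fs < MIN_SAMPLING_RATE_HZ:
            raise InsufficientSamplingRateError(
                f"insufficient sampling rate: {self.fs} Hz < "
                f"{MIN_SAMPLING_RATE_HZ} Hz"
            )
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        self.montage = Montage(self.montage)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]


@dataclass(frozen=True)
class BipolarPair:
    """An (anode, cathode) channel pair for bipolar derivation."""

    anode_label: str
    cathode_label: str
    derived_label: str = field(default="")

    def __post_init__(self) -> None:
        if self.anode_label == self.cathode_label:
            raise ValueError("anode and cathode must differ")
        if not self.derived_label:
            object.__setattr__(
                self, "derived_label", f"{self.anode_label}-{self.cathode_label}"
            )


def to_bipolar(rec: Recording, pairs: list[BipolarPair | tuple]) -> Recording:
    """Derive a bipolar montage: each output channel is anode minus cathode.

    The order of `pairs` is preserved in the output.
    """
    if rec.montage is not Montage.COMMON_REFERENCE:
        raise ValueError("recording is already bipolar")
    pairs = [p if isinstance(p, BipolarPair) else BipolarPair(*p) for p in pairs]
    derived = [p.derived_label for p in pairs]
    if len(set(derived)) != len(derived):
        raise ValueError("duplicate derived labels in bipolar pairs")
    out = np.empty((len(pairs), rec.n_samples))
    for i, p in enumerate(pairs):
        for lbl in (p.anode_label, p.cathode_label):
            if lbl not in rec.labels:
                raise KeyError(f"unknown channel label {lbl!r}")
        out[i] = rec.channel(p.anode_label) - rec.channel(p.cathode_label)
    return Recording(out, rec.fs, derived, Montage.BIPOLAR)


# ---------------------------------------------------------------------------
# Delimited text format
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_delimited(rec: Recording, path: str | Path) -> None:
    """Write a recording as TSV (columns = channels) plus a JSON sidecar.

    The sidecar records the sampling rate and montage; samples are written
    with full float precision so the round trip is exact to well below
    1e-6 microvolt.
    """
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {"fs_hz": rec.fs, "montage": rec.montage.value, "unit": "uV"}
    _sidecar_path(path).write_text(json.dumps(meta))


def _load_delimited(path: Path, fs: float | None) -> Recording:
    montage = Montage.COMMON_REFERENCE
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs_hz", fs)
        montage = Montage(meta.get("montage", montage))
    if fs is None:
        raise ValueError(
            f"sampling rate not recoverable: no sidecar {sidecar.name} and no "
            "fs argument"
        )
    df = pd.read_csv(path, sep="\t")
    return Recording(df.to_numpy().T, float(fs), list(df.columns), montage)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _load_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if fs < MIN_SAMPLING_RATE_HZ:
        raise InsufficientSamplingRateError(
            f"insufficient sampling rate: {fs} Hz < {MIN_SAMPLING_RATE_HZ} Hz"
        )
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(data_uv, fs, list(raw.ch_names), Montage.COMMON_REFERENCE)


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numeric fields rather than corrupt the fixed layout
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit samples, physical unit uV).

    This is a minimal EDF writer for interchange and test fixtures.  The
    physical range per channel is set to the data range, so round-trip
    precision is limited to (range / 2^16) microvolts by the 16-bit sample
    format.  Record duration is 1 s when the recording spans a whole number
    of seconds, otherwise a single data record is used.
    """
    path = Path(path)
    n_ch, n_samp = rec.samples.shape
    fs = rec.fs
    if n_samp % int(fs) == 0 and fs == int(fs):
        spr = int(fs)  # samples per record
        n_rec = n_samp // spr
        rec_dur = 1
    else:
        spr = n_samp
        n_rec = 1
        rec_dur = n_samp / fs

    dig_min, dig_max = -32768, 32767
    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    digital = np.empty((n_ch, n_samp), dtype=np.int16)
    for i in range(n_ch):
        lo, hi = rec.samples[i].min(), rec.samples[i].max()
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min[i], phys_max[i] = lo, hi
        gain = (dig_max - dig_min) / (hi - lo)
        digital[i] = np.round((rec.samples[i] - lo) * gain + dig_min).astype(
            np.int16
        )

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X", 80)  # patient id
    header += _edf_field("X", 80)  # recording id
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(f"{rec_dur:.6g}" if rec_dur != int(rec_dur) else int(rec_dur), 8)
    header += _edf_field(n_ch, 4)
    for lbl in rec.labels:
        header += _edf_field(lbl, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))  # prefilter
    header += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for i in range(n_ch):
                chunk = digital[i, r * spr : (r + 1) * spr]
                fh.write(struct.pack(f"<{len(chunk)}h", *chunk))


def load_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> Recording:
    """Load a recording from EDF or delimited text.

    Parameters
    ----------
    path : path-like
    format : {"edf", "delimited"}, optional
        Inferred from the file extension when omitted.
    fs : float, optional
        Sampling rate override for delimited files without a sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _load_edf(path)
    if format == "delimited":
        return _load_delimited(path, fs)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_event_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-event table as TSV with the standard column set."""
    cols = [c for c in EVENT_TABLE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
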