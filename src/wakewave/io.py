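"""Containers and file I/O: the EEG recording type, EDF and TSV round-trips.

EEG is held in memory as a plain ``EEGRecording`` (channels x samples, µV).
On disk, recordings travel as EDF (16-bit, 1-second data records), the
standard interchange format for clinical/physiological time series; reading
is delegated to :func:`mne.io.read_raw_edf`. Event-like tables (stimuli,
probes, waves, trials) are tab-separated files with documented columns.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "write_edf",
    "read_edf",
    "write_table",
    "read_table",
]


@dataclass
class EEGRecording:
    """Multi-channel EEG time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels, same order as rows of ``data``.
    reference : str
        Free-text description of the current reference ("online", "mastoid").
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str] = field(default_factory=list)
    reference: str = "online"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match number of channels")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, rec: EEGRecording, *, patient: str = "X",
              recording_id: str = "synthetic SART session") -> None:
    """Write a recording as plain EDF (16-bit integers, 1-s data records).

    The sampling rate must be an integer: EDF stores a fixed number of
    samples per data record and we use one-second records. The last partial
    second is zero-padded. Physical scaling is chosen per channel from the
    data range so quantization error is below half a digital step.
    """
    path = Path(path)
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr)) if rec.n_samples else 0

    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    dig_min, dig_max = -32768, 32767
    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(patient, 80))
        fh.write(_pad(recording_id, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 + 256 * n_ch), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))          # record duration, seconds
        fh.write(_pad(str(n_ch), 4))
        for name in rec.ch_names:
            fh.write(_pad(name, 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        fh.write(_pad(str(dig_min), 8) * n_ch)
        fh.write(_pad(str(dig_max), 8) * n_ch)
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        fh.write(_pad(str(spr), 8) * n_ch)
        fh.write(_pad("", 32) * n_ch)
        # data records: channel-major within each record
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file back into an :class:`EEGRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return EEGRecording(data=data, sfreq=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names), reference="as stored")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a TSV with stable float formatting (deterministic bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
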