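"""Electrode montage utilities.

The default layout is a 63-channel subset of the extended 10-10 system as
used with active-electrode caps in high-density EEG studies of wakefulness,
including the left/right mastoid leads TP9 and TP10 used for off-line
re-referencing. 3-D positions come from the standard template head shipped
with MNE-Python.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Default 63-channel 10-10 montage (unique labels, includes TP9/TP10).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

#: Scalp regions used for spatial coupling and region-of-interest analyses.
#: Mastoids are reference leads and belong to no region.
FRONTAL_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in DEFAULT_MONTAGE if ch[:2] in ("Fp", "AF") or (ch[0] == "F" and ch[1] not in "CT")
)
POSTERIOR_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in DEFAULT_MONTAGE
    if ch[:2] in ("PO", "Oz", "O1", "O2", "Iz") or (ch[0] == "P" and ch[1] not in "O")
)


@lru_cache(maxsize=4)
def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mon = mne.channels.make_standard_montage("standard_1005")
    return mon.get_positions()["ch_pos"]


def channel_positions(labels: tuple[str, ...] | list[str]) -> np.ndarray:
    """Return (n, 3) head-frame positions in metres for the given labels.

    Raises
    ------
    KeyError
        If a label is not part of the standard 10-05 layout.
    """
    pos = _standard_positions()
    unknown = [lb for lb in labels if lb not in pos]
    if unknown:
        raise KeyError(f"unknown channel label(s): {unknown}")
    return np.asarray([pos[lb] for lb in labels], dtype=float)
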