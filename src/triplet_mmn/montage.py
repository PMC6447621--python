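"""Electrode montage: 59 scalp channels (10-10 subset), mastoids, and EOG.

Positions come from the standard 10-05 template shipped with MNE, projected
to the 2-D plane (x right, y anterior) and scaled so the outermost scalp
electrode sits at radius 1.  They are used only for topography weighting and
plotting — there is no volume conduction model.  Labels follow the
upper-case convention of the ROI definitions (FZ, FCZ, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["Montage", "MontageError", "ROI_MAP", "SCALP_CHANNELS", "standard_montage"]

#: nine regions of interest: 3 scalp areas x 3 lateralisations
ROI_MAP = {
    "frontal_left": ["F7", "F5", "F3", "FT7", "FC5", "FC3"],
    "frontal_middle": ["F1", "FZ", "F2", "FC1", "FCZ", "FC2"],
    "frontal_right": ["F8", "F6", "F4", "FT8", "FC6", "FC4"],
    "central_left": ["T7", "C5", "C3", "TP7", "CP5", "CP3"],
    "central_middle": ["C1", "CZ", "C2", "CPZ"],
    "central_right": ["T8", "C6", "C4", "TP8", "CP6", "CP4"],
    "parietal_left": ["P7", "P5", "P3", "PO7", "PO3", "O1"],
    "parietal_middle": ["P1", "PZ", "P2", "POZ", "OZ"],
    "parietal_right": ["P8", "P6", "P4", "PO8", "PO4", "O2"],
}

#: ROI grid coordinates: region -> (scalp area, lateralisation)
ROI_GRID = {
    name: (name.split("_")[0], name.split("_")[1]) for name in ROI_MAP
}

#: prefrontal row completing the 59-channel cap (51 electrodes sit in ROIs)
_EXTRA_SCALP = ["FP1", "FPZ", "FP2", "AF7", "AF3", "AFZ", "AF4", "AF8"]
SCALP_CHANNELS = tuple(
    _EXTRA_SCALP + [ch for chans in ROI_MAP.values() for ch in chans]
)
MASTOIDS = ("M1", "M2")
EOG_CHANNELS = ("HEOG", "VEOG")


class MontageError(KeyError):
    """Raised for unknown electrode labels."""


@dataclass
class Montage:
    """Channel labels with nominal 2-D positions."""

    channels: tuple                      # all labels, in recording order
    positions: dict                      # label -> (x, y), normalized
    scalp: tuple = SCALP_CHANNELS
    mastoids: tuple = MASTOIDS
    eog: tuple = EOG_CHANNELS

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise MontageError(f"unknown channel {label!r}") from None

    def distance(self, a: str, b: str) -> float:
        if a not in self.positions or b not in self.positions:
            raise MontageError(f"no position for {a!r} or {b!r}")
        return float(np.linalg.norm(np.subtract(self.positions[a], self.positions[b])))


@lru_cache(maxsize=1)
def standard_montage() -> Montage:
    """The study's 63-channel montage (59 scalp + M1/M2 + HEOG/VEOG)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    lower = {k.upper(): k for k in pos3d}
    positions = {}
    for ch in SCALP_CHANNELS + MASTOIDS:
        p = pos3d[lower[ch]]
        positions[ch] = (float(p[0]), float(p[1]))
    radius = max(np.hypot(x, y) for ch, (x, y) in positions.items() if ch in SCALP_CHANNELS)
    positions = {ch: (x / radius, y / radius) for ch, (x, y) in positions.items()}
    # nominal periocular spots for the EOG derivations (plot/bookkeeping only)
    positions["HEOG"] = (0.9, 1.0)
    positions["VEOG"] = (0.35, 1.1)
    channels = SCALP_CHANNELS + MASTOIDS + EOG_CHANNELS
    return Montage(channels=channels, positions=positions)
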