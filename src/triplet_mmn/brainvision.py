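"""BrainVision-style export/import of simulated recordings.

Writes the classic triplet: a text ``.vhdr`` header, a text ``.vmrk`` marker
file, and a multiplexed little-endian 32-bit float ``.eeg`` binary in µV.
Reading goes through MNE's BrainVision reader, which also serves as the
round-trip check in the tests.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .montage import standard_montage
from .simulate import Recording

__all__ = ["read_brainvision", "write_brainvision"]

_HEADER = """Brain Vision Data Exchange Header File Version 1.0
; Written by triplet-mmn

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<nr>=<name>,<ref>,<resolution in µV>,<unit>
{channels}
"""

_MARKER_HEADER = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Mk<nr>=<type>,<description>,<position>,<points>,<channel>
Mk1=New Segment,,1,1,0
{markers}
"""


def write_brainvision(recording: Recording, basepath: str) -> None:
    """Write ``basepath``.vhdr/.vmrk/.eeg for one recording."""
    stem = os.path.basename(basepath)
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV"
        for i, name in enumerate(recording.montage.channels)
    )
    sampling_interval = int(round(1e6 / recording.sample_rate))
    with open(basepath + ".vhdr", "w", encoding="utf-8") as fh:
        fh.write(
            _HEADER.format(
                stem=stem,
                n_ch=len(recording.montage.channels),
                sampling_interval=sampling_interval,
                channels=ch_lines,
            )
        )
    mk_lines = []
    for i, row in enumerate(recording.markers.itertuples(index=False)):
        # BrainVision positions are 1-based
        mk_lines.append(
            f"Mk{i + 2}=Stimulus,S{int(row.code):3d},{int(row.sample) + 1},1,0"
        )
    with open(basepath + ".vmrk", "w", encoding="utf-8") as fh:
        fh.write(_MARKER_HEADER.format(stem=stem, markers="\n".join(mk_lines)))
    recording.data.T.astype("<f4").tofile(basepath + ".eeg")


def read_brainvision(basepath: str) -> Recording:
    """Read a triplet written by :func:`write_brainvision` (via MNE)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(basepath + ".vhdr", preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; recordings are µV
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    rows = []
    code_of = {name: int(name.split("S")[-1]) for name in event_id if "S" in name}
    inv = {v: code_of[k] for k, v in event_id.items() if k in code_of}
    for sample, _, eid in events:
        if eid in inv:
            rows.append(dict(sample=int(sample), code=inv[eid]))
    return Recording(
        data=data,
        sample_rate=int(raw.info["sfreq"]),
        montage=standard_montage(),
        markers=pd.DataFrame(rows),
    )
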