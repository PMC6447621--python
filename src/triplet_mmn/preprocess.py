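"""ERP preprocessing chain: filtering, re-referencing, artifact rejection,
epoching with exclusion rules, and baseline handling.

The chain mirrors classical mastoid-referenced MMN processing:

1. re-reference scalp channels to the algebraic mean of the mastoids;
2. 30 Hz low-pass windowed-sinc FIR (Blackman, 2751 taps at 500 Hz), applied
   zero-phase by compensating the symmetric filter's group delay;
3. mark samples where any channel's standard deviation within a 200 ms or
   800 ms gliding window (stride 1) strictly exceeds 25 µV — this threshold
   mask is what catches the synthetic blinks;
4. cut epochs (−100..400 ms around triplet-ending onsets), dropping epochs
   that touch masked samples, fall within 3 s after a cover-task target, or
   overrun the recording edge — every marker is accounted for in a ledger;
5. baseline-correct ending epochs on the 100 ms pre-stimulus window.

Triplet-root epochs (−100..1000 ms, restricted to roots following standard
triplets) skip baseline correction; the recording is 0.5 Hz high-pass
filtered (551-tap Blackman FIR) instead to remove slow drifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Recording

__all__ = [
    "Epochs",
    "FilterSpec",
    "PreprocessError",
    "apply_filter",
    "baseline_correct",
    "design_fir",
    "epoch",
    "preprocess_recording",
    "reject_samples",
    "rereference",
    "select_ending_markers",
    "select_root_markers",
]

LOWPASS_SPEC_TAPS = 2750   # stated tap counts; made odd at design time
HIGHPASS_SPEC_TAPS = 550
REJECT_WINDOWS_MS = (200.0, 800.0)
REJECT_THRESHOLD_UV = 25.0
ENDING_WINDOW_MS = (-100.0, 400.0)
ROOT_WINDOW_MS = (-100.0, 1000.0)
POST_TARGET_EXCLUSION_S = 3.0


class PreprocessError(ValueError):
    """Raised for invalid preprocessing parameters."""


@dataclass(frozen=True)
class FilterSpec:
    """Windowed-sinc FIR specification (Blackman window)."""

    kind: str                  # "lowpass" or "highpass"
    cutoff_hz: float
    n_taps: int
    window: str = "blackman"

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass"):
            raise PreprocessError(f"unknown filter kind {self.kind!r}")


LOWPASS_30HZ = FilterSpec("lowpass", 30.0, LOWPASS_SPEC_TAPS)
HIGHPASS_05HZ = FilterSpec("highpass", 0.5, HIGHPASS_SPEC_TAPS)


def design_fir(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Design symmetric linear-phase FIR coefficients.

    An even tap count is incremented by one so the filter has integer group
    delay and exact (anti)symmetry; DC gain is 1 for low-pass, 0 for
    high-pass.
    """
    if spec.cutoff_hz >= sample_rate / 2:
        raise PreprocessError("cutoff must be below Nyquist")
    n_taps = spec.n_taps + (spec.n_taps % 2 == 0)
    lowpass = signal.firwin(
        n_taps, spec.cutoff_hz, window=spec.window, pass_zero=True, fs=sample_rate
    )
    if spec.kind == "lowpass":
        return lowpass
    # spectral inversion: exact zero at DC even when the window's transition
    # band is wider than the cutoff (as with 551 taps at 0.5 Hz)
    highpass = -lowpass
    highpass[n_taps // 2] += 1.0
    return highpass


def _filter_array(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric FIR along the last axis.

    Edges are reflection-padded by the filter length; the symmetric kernel
    applied with 'same' alignment compensates the group delay exactly, so
    component peak latencies are preserved.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n = data.shape[-1]
    if len(taps) >= n:
        raise PreprocessError("filter longer than the signal")
    pad = len(taps)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., pad:-pad]


def apply_filter(recording: Recording, taps: np.ndarray) -> Recording:
    """Return a copy of the recording with every channel filtered zero-phase."""
    filtered = _filter_array(recording.data, taps)
    return Recording(
        data=filtered,
        sample_rate=recording.sample_rate,
        montage=recording.montage,
        markers=recording.markers,
        ground_truth=recording.ground_truth,
        block_index=recording.block_index,
    )


def rereference(recording: Recording) -> Recording:
    """Re-reference scalp and mastoid channels to mean(M1, M2); EOG untouched."""
    m = recording.montage
    try:
        ref = (recording.channel("M1") + recording.channel("M2")) / 2.0
    except Exception as exc:
        raise PreprocessError("mastoid channels missing") from exc
    data = recording.data.copy()
    for i, ch in enumerate(m.channels):
        if ch in m.eog:
            continue
        data[i] = data[i] - ref
    return Recording(
        data=data,
        sample_rate=recording.sample_rate,
        montage=m,
        markers=recording.markers,
        ground_truth=recording.ground_truth,
        block_index=recording.block_index,
    )


def _moving_sd_exceeds(x: np.ndarray, w: int, threshold: float) -> np.ndarray:
    """Boolean per window start: does any channel's SD (ddof 0) exceed threshold?

    Cumulative-sum moving statistics over all channels at stride 1.
    """
    n = x.shape[-1]
    thr_var = threshold**2
    exceeded = np.zeros(n - w + 1, dtype=bool)
    c1 = np.empty(n + 1)
    c2 = np.empty(n + 1)
    for ch in x:  # channel loop keeps temporaries one-channel sized
        c1[0] = c2[0] = 0.0
        np.cumsum(ch, out=c1[1:])
        np.cumsum(ch * ch, out=c2[1:])
        m = (c1[w:] - c1[:-w]) / w
        var = (c2[w:] - c2[:-w]) / w - m * m
        exceeded |= var > thr_var
    return exceeded


def reject_samples(
    recording: Recording,
    windows_ms: tuple = REJECT_WINDOWS_MS,
    threshold_uv: float = REJECT_THRESHOLD_UV,
) -> np.ndarray:
    """Gliding-window artifact mask over all channels, EOG included.

    A sample is rejected iff, for either window length, any window containing
    it has any-channel SD strictly above the threshold; the returned boolean
    mask is the union over window lengths.
    """
    n = recording.n_samples
    mask = np.zeros(n, dtype=bool)
    for w_ms in windows_ms:
        w = int(round(w_ms * recording.sample_rate / 1000.0))
        if w > n:
            raise PreprocessError(f"window {w_ms} ms longer than recording")
        bad_start = _moving_sd_exceeds(recording.data, w, threshold_uv)
        # dilate window starts to the samples they cover
        delta = np.zeros(n + 1, dtype=int)
        starts = np.nonzero(bad_start)[0]
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + w, -1)
        mask |= np.cumsum(delta[:-1]) > 0
    return mask


@dataclass
class Epochs:
    """Trials x channels x time segments with labels and a kept/dropped ledger."""

    data: np.ndarray           # (n_trials, n_channels, n_times) µV
    times_ms: np.ndarray
    channels: tuple
    labels: pd.DataFrame       # one row per kept trial
    ledger: pd.DataFrame       # one row per input marker: kept, reason
    sample_rate: int

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def select(self, **criteria) -> "Epochs":
        """Subset trials by equality on label columns."""
        keep = np.ones(self.n_trials, dtype=bool)
        for col, val in criteria.items():
            keep &= (self.labels[col] == val).to_numpy()
        return Epochs(
            data=self.data[keep],
            times_ms=self.times_ms,
            channels=self.channels,
            labels=self.labels.loc[keep].reset_index(drop=True),
            ledger=self.ledger,
            sample_rate=self.sample_rate,
        )


def select_ending_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Triplet-ending events (position 3, never targets)."""
    sel = markers[(markers.position == 3) & (~markers.is_target)]
    return sel.assign(anchor_sample=sel["sample"].to_numpy())


def select_root_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """First-position root events of triplets preceded by a standard triplet.

    Epoch anchors are the PRECEDING triplet-ending onsets, so root epochs are
    time-locked to the end of the previous triplet; roots after low-TP or
    location-deviant endings are excluded to avoid deviant-response carryover.
    """
    endings = markers[(markers.position == 3) & (~markers.is_target)]
    good_prev = set(
        endings[
            (endings.ending_tp == 0.9) & (endings.ending_location == "standard")
        ].triplet_index
    )
    ending_sample = dict(zip(endings.triplet_index, endings["sample"]))
    roots = markers[(markers.position == 1) & (~markers.is_target)]
    roots = roots[roots.triplet_index.map(lambda i: (i - 1) in good_prev)]
    return roots.assign(
        anchor_sample=roots.triplet_index.map(lambda i: ending_sample[i - 1]).to_numpy()
    )


def epoch(
    recording: Recording,
    markers: pd.DataFrame,
    window_ms: tuple = ENDING_WINDOW_MS,
    mask: np.ndarray | None = None,
    post_target_exclusion_s: float = POST_TARGET_EXCLUSION_S,
) -> Epochs:
    """Cut epochs around marker anchors with drop bookkeeping.

    ``markers`` needs an ``anchor_sample`` column (see the selector helpers).
    Window boundaries are inclusive at sample resolution; 0 ms is the anchor
    sample.  Drop reasons: ``artifact`` (any masked sample inside the epoch),
    ``post-target`` (anchor within 3 s after a target marker), ``edge``.
    """
    fs = recording.sample_rate
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    times_ms = np.arange(lo, hi + 1) * 1000.0 / fs
    n = recording.n_samples
    target_samples = recording.markers.loc[
        recording.markers.is_target.astype(bool), "sample"
    ].to_numpy()
    horizon = int(round(post_target_exclusion_s * fs))

    rows, trials, ledger = [], [], []
    for row in markers.itertuples(index=False):
        anchor = int(row.anchor_sample)
        start, stop = anchor + lo, anchor + hi
        if start < 0 or stop >= n:
            ledger.append(dict(sample=anchor, kept=False, reason="edge"))
            continue
        if len(target_samples) and np.any(
            (anchor > target_samples) & (anchor - target_samples <= horizon)
        ):
            ledger.append(dict(sample=anchor, kept=False, reason="post-target"))
            continue
        if mask is not None and mask[start : stop + 1].any():
            ledger.append(dict(sample=anchor, kept=False, reason="artifact"))
            continue
        ledger.append(dict(sample=anchor, kept=True, reason=""))
        trials.append(recording.data[:, start : stop + 1])
        rows.append(row._asdict())
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, recording.data.shape[0], len(times_ms)))
    )
    return Epochs(
        data=data,
        times_ms=times_ms,
        channels=tuple(recording.montage.channels),
        labels=pd.DataFrame(rows),
        ledger=pd.DataFrame(ledger),
        sample_rate=fs,
    )


def baseline_correct(epochs: Epochs, window_ms: tuple = (-100.0, 0.0)) -> Epochs:
    """Subtract each trial/channel's mean over the pre-stimulus window."""
    sel = (epochs.times_ms >= window_ms[0]) & (epochs.times_ms <= window_ms[1])
    if not sel.any():
        raise PreprocessError("empty baseline window")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return Epochs(
        data=epochs.data - base,
        times_ms=epochs.times_ms,
        channels=epochs.channels,
        labels=epochs.labels,
        ledger=epochs.ledger,
        sample_rate=epochs.sample_rate,
    )


def preprocess_recording(
    recording: Recording,
    lowpass_taps: np.ndarray | None = None,
    reject_threshold_uv: float = REJECT_THRESHOLD_UV,
    reject_windows_ms: tuple = REJECT_WINDOWS_MS,
    window_ms: tuple = ENDING_WINDOW_MS,
) -> Epochs:
    """Full ending-ERP chain: reref -> 30 Hz low-pass -> reject -> epoch -> baseline."""
    if lowpass_taps is None:
        lowpass_taps = design_fir(LOWPASS_30HZ, recording.sample_rate)
    rec = rereference(recording)
    rec = apply_filter(rec, lowpass_taps)
    mask = reject_samples(rec, reject_windows_ms, reject_threshold_uv)
    eps = epoch(rec, select_ending_markers(rec.markers), window_ms, mask)
    return baseline_correct(eps)


def preprocess_roots(
    recording: Recording,
    lowpass_taps: np.ndarray | None = None,
    highpass_taps: np.ndarray | None = None,
) -> Epochs:
    """Root-ERP chain: reref -> low-pass -> 0.5 Hz high-pass -> reject -> epoch.

    No baseline correction; the high-pass replaces it for these long epochs.
    """
    if lowpass_taps is None:
        lowpass_taps = design_fir(LOWPASS_30HZ, recording.sample_rate)
    if highpass_taps is None:
        highpass_taps = design_fir(HIGHPASS_05HZ, recording.sample_rate)
    rec = rereference(recording)
    rec = apply_filter(rec, lowpass_taps)
    rec = apply_filter(rec, highpass_taps)
    mask = reject_samples(rec)
    return epoch(rec, select_root_markers(rec.markers), ROOT_WINDOW_MS, mask)
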