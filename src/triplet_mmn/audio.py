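"""Stimulus synthesis: Shepard tones, percussive transients, stereo rendering.

Each of the six stimulus sounds is a Shepard tone — nine sinusoidal partials
spaced one octave apart under a Gaussian spectral envelope over log-frequency,
which flattens the percept of pitch height — mixed with a short percussive
transient.  The original study used orchestral percussion samples; here the
percussive components are synthetic transients (exponentially decaying
band-passed noise) with per-instrument spectral centroids and decay times,
overridable by user-supplied waveforms.  All bank sounds are RMS-matched and
220 ms long with a 10 ms linear fade-in and 20 ms fade-out; the cover-task
target is a bare Shepard tone at C#5 (554.37 Hz).

Rendering places each sound at its onset sample on the left or right channel
(hard routing, emulating the two loudspeakers), sums overlapping tails, and
emits a marker per event.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .paradigm import (
    EVENT_CODES,
    ROLES,
    SOUND_DURATION_MS,
    TARGET_PITCH_HZ,
    ExperimentDesign,
    TripletSequence,
)

__all__ = [
    "AudioError",
    "MAIN_PITCHES_HZ",
    "PRACTICE_PITCHES_HZ",
    "PERCUSSION_PRESETS",
    "RenderedStream",
    "ShepardSpec",
    "SoundBank",
    "build_soundbank",
    "make_sound",
    "percussive_substitute",
    "read_wav",
    "render_stream",
    "shepard_tone",
    "write_wav",
]

#: main-experiment pitch classes (F3, G3, A3, B3, C#4, D#4)
MAIN_PITCHES_HZ = (174.61, 196.00, 220.00, 246.94, 277.18, 311.13)
#: practice-set pitch classes (E3, F#3, G#3, A#3, C4, D4)
PRACTICE_PITCHES_HZ = (164.81, 184.99, 207.65, 233.08, 261.62, 293.66)

#: synthetic percussive presets: (band center Hz, bandwidth octaves, decay tau s)
PERCUSSION_PRESETS = {
    "surdo": (90.0, 1.0, 0.150),
    "woodblock": (1200.0, 0.8, 0.040),
    "agogo": (1800.0, 0.6, 0.120),
    "castanet": (3500.0, 0.8, 0.030),
    "tambourine": (6000.0, 1.2, 0.080),
    "hihat": (8000.0, 1.5, 0.060),
    "bassdrum": (60.0, 1.0, 0.180),
}
#: instrument assigned to each concrete sound index of the main / practice sets
MAIN_PERCUSSION = ("surdo", "tambourine", "agogo", "hihat", "castanet", "woodblock")
PRACTICE_PERCUSSION = (
    "woodblock", "tambourine", "agogo", "castanet", "hihat", "bassdrum",
)

DEFAULT_SAMPLE_RATE = 44100
RMS_REFERENCE = 0.1


class AudioError(ValueError):
    """Raised for invalid synthesis or rendering parameters."""


@dataclass(frozen=True)
class ShepardSpec:
    """Parameters of one Shepard tone."""

    pitch_class_hz: float
    n_components: int = 9
    octave_offsets: tuple = tuple(range(-4, 5))
    envelope_sigma_octaves: float = 1.5   # Gaussian width over log2-frequency
    sample_rate: int = DEFAULT_SAMPLE_RATE
    duration_ms: float = SOUND_DURATION_MS
    fade_in_ms: float = 10.0
    fade_out_ms: float = 20.0


def _n_samples(duration_ms: float, sample_rate: int) -> int:
    return int(round(duration_ms * sample_rate / 1000.0))


def shepard_tone(spec: ShepardSpec) -> np.ndarray:
    """Synthesize one Shepard tone (peak-normalized, no fades).

    The nine partials sit at ``pitch_class_hz * 2**k`` with Gaussian weights
    ``exp(-k**2 / (2 sigma**2))`` over the octave offset k, so the nominal
    pitch class carries the maximum weight and dominates the spectrum.
    """
    if spec.pitch_class_hz <= 0:
        raise AudioError("pitch_class_hz must be positive")
    if len(spec.octave_offsets) != spec.n_components:
        raise AudioError("octave_offsets length must equal n_components")
    freqs = spec.pitch_class_hz * 2.0 ** np.asarray(spec.octave_offsets, float)
    if np.any(freqs >= spec.sample_rate / 2):
        raise AudioError(
            f"component at {freqs.max():.1f} Hz >= Nyquist ({spec.sample_rate / 2} Hz)"
        )
    if np.isinf(spec.envelope_sigma_octaves):
        weights = np.ones_like(freqs)
    else:
        k = np.asarray(spec.octave_offsets, float)
        weights = np.exp(-(k**2) / (2 * spec.envelope_sigma_octaves**2))
    n = _n_samples(spec.duration_ms, spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    wave = (weights[:, None] * np.sin(2 * np.pi * freqs[:, None] * t)).sum(axis=0)
    return wave / np.abs(wave).max()


def percussive_substitute(
    kind: str,
    duration_ms: float = SOUND_DURATION_MS,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic percussive transient: exponentially decaying band-passed noise.

    Deterministic in ``(kind, seed)``.  Each preset fixes the band center
    (hence the spectral centroid, distinct and ordered across instruments)
    and the energy decay constant.
    """
    if kind not in PERCUSSION_PRESETS:
        raise AudioError(f"unknown percussion kind {kind!r}")
    center, bw_oct, tau = PERCUSSION_PRESETS[kind]
    n = _n_samples(duration_ms, sample_rate)
    rng = np.random.default_rng(
        np.random.SeedSequence([zlib.crc32(kind.encode()), int(seed)])
    )
    noise = rng.standard_normal(n)
    lo = center * 2 ** (-bw_oct / 2)
    hi = min(center * 2 ** (bw_oct / 2), 0.45 * sample_rate)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    shaped = signal.sosfilt(sos, noise)
    env = np.exp(-np.arange(n) / (tau * sample_rate))
    wave = shaped * env
    return wave / np.abs(wave).max()


def _apply_fades(wave: np.ndarray, sample_rate: int, fade_in_ms: float, fade_out_ms: float) -> np.ndarray:
    out = wave.copy()
    n_in = _n_samples(fade_in_ms, sample_rate)
    n_out = _n_samples(fade_out_ms, sample_rate)
    if n_in:
        out[:n_in] *= np.linspace(0.0, 1.0, n_in, endpoint=False)
    if n_out:
        out[-n_out:] *= np.linspace(1.0, 0.0, n_out)
    return out


def _set_rms(wave: np.ndarray, rms: float) -> np.ndarray:
    cur = float(np.sqrt(np.mean(wave**2)))
    if cur == 0:
        raise AudioError("cannot RMS-normalize a silent waveform")
    return wave * (rms / cur)


def make_sound(
    shepard_spec: ShepardSpec,
    percussion_kind: str | None,
    mix_ratio: float = 0.5,
    percussion_wave: np.ndarray | None = None,
    percussion_seed: int = 0,
    rms_reference: float = RMS_REFERENCE,
) -> np.ndarray:
    """Mix a Shepard tone with a percussive component into one bank sound.

    Both components are brought to equal RMS, mixed as
    ``mix_ratio * shepard + (1 - mix_ratio) * percussion``, faded (10 ms
    linear in, 20 ms linear out), and finally RMS-normalized to the bank
    reference so every bank sound shares the same RMS exactly.
    """
    shep = _set_rms(shepard_tone(shepard_spec), 1.0)
    if mix_ratio >= 1.0 or (percussion_kind is None and percussion_wave is None):
        mixed = shep
    else:
        if percussion_wave is None:
            percussion_wave = percussive_substitute(
                percussion_kind,
                shepard_spec.duration_ms,
                shepard_spec.sample_rate,
                percussion_seed,
            )
        if len(percussion_wave) != len(shep):
            raise AudioError(
                f"component length mismatch: {len(shep)} vs {len(percussion_wave)}"
            )
        perc = _set_rms(np.asarray(percussion_wave, float), 1.0)
        mixed = mix_ratio * shep + (1.0 - mix_ratio) * perc
    faded = _apply_fades(
        mixed, shepard_spec.sample_rate, shepard_spec.fade_in_ms, shepard_spec.fade_out_ms
    )
    return _set_rms(faded, rms_reference)


@dataclass
class SoundBank:
    """Role -> waveform mapping plus the cover-task target sound."""

    sounds: dict                      # role "A".."F" -> np.ndarray
    target: np.ndarray
    sample_rate: int
    rms_reference: float = RMS_REFERENCE
    duration_ms: float = SOUND_DURATION_MS

    def waveform(self, role: str) -> np.ndarray:
        return self.target if role == "TARGET" else self.sounds[role]


def build_soundbank(
    design: ExperimentDesign,
    frequency_set: str = "main",
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    mix_ratio: float = 0.5,
    percussion_seed: int = 0,
    percussion_waves: dict | None = None,
) -> SoundBank:
    """Build the six role sounds (via the design's role permutation) + target.

    ``percussion_waves`` may map concrete sound index -> waveform to substitute
    user-supplied percussion samples for the synthetic transients.
    """
    if frequency_set == "main":
        pitches, kinds = MAIN_PITCHES_HZ, MAIN_PERCUSSION
    elif frequency_set == "practice":
        pitches, kinds = PRACTICE_PITCHES_HZ, PRACTICE_PERCUSSION
    else:
        raise AudioError(f"unknown frequency set {frequency_set!r}")
    sounds = {}
    for role in ROLES:
        idx = design.role_permutation[role]
        spec = ShepardSpec(pitch_class_hz=pitches[idx], sample_rate=sample_rate)
        wave = None if percussion_waves is None else percussion_waves.get(idx)
        sounds[role] = make_sound(
            spec,
            kinds[idx],
            mix_ratio=mix_ratio,
            percussion_wave=wave,
            percussion_seed=percussion_seed,
        )
    target = make_sound(
        ShepardSpec(pitch_class_hz=TARGET_PITCH_HZ, sample_rate=sample_rate),
        None,
        mix_ratio=1.0,
    )
    return SoundBank(sounds=sounds, target=target, sample_rate=sample_rate)


@dataclass
class RenderedStream:
    """Stereo waveform of one block plus sample-accurate event markers."""

    data: np.ndarray          # (2, n_samples): left, right
    sample_rate: int
    markers: pd.DataFrame     # events frame + sample_index, code

    @property
    def left(self) -> np.ndarray:
        return self.data[0]

    @property
    def right(self) -> np.ndarray:
        return self.data[1]


def _event_code(row) -> int:
    if row.is_target:
        return EVENT_CODES["TARGET"]
    if row.position == 3:
        return EVENT_CODES[row.category]
    return EVENT_CODES[f"ROOT_{row.position}"]


def render_stream(sequence: TripletSequence, bank: SoundBank) -> RenderedStream:
    """Render a triplet sequence to stereo audio with hard location routing."""
    fs = bank.sample_rate
    frame = sequence.to_frame()
    if (frame.onset_ms < 0).any():
        raise AudioError("negative event onset")
    n_sound = _n_samples(bank.duration_ms, fs)
    last_onset = int(frame.onset_ms.max())
    n_total = int(round(last_onset * fs / 1000.0)) + n_sound
    data = np.zeros((2, n_total))
    samples = []
    for row in frame.itertuples(index=False):
        start = int(round(row.onset_ms * fs / 1000.0))
        wave = bank.waveform(row.role)
        ch = 0 if row.location == "left" else 1
        data[ch, start : start + len(wave)] += wave
        samples.append(start)
    markers = frame.copy()
    markers["sample_index"] = samples
    markers["code"] = [_event_code(r) for r in frame.itertuples(index=False)]
    return RenderedStream(data=data, sample_rate=fs, markers=markers)


def write_wav(path, stream: RenderedStream) -> None:
    """Write a rendered stream as stereo 16-bit PCM."""
    clipped = np.clip(stream.data.T, -1.0, 1.0)
    wavfile.write(path, stream.sample_rate, (clipped * 32767).astype(np.int16))


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a WAV written by :func:`write_wav`; returns (rate, float array (2, n))."""
    rate, data = wavfile.read(path)
    return rate, (data.astype(float) / 32767.0).T
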