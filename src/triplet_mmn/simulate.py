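"""Forward simulation of continuous EEG with embedded event-related components.

Every sound event contributes a set of ERP components — Gaussian temporal
kernels scaled by a spatial topography — on top of white noise, 1/f noise,
slow drifts, and ocular blink artifacts.  The component defaults encode the
paradigm's expected effects:

* P1 / N1-like deflections on every sound;
* an sMMN (−1.50 µV peaking 210 ms post-onset, frontal-midline maximum) added
  to low-transition-probability triplet endings;
* a phMMN (−3.65 µV at 180 ms, fronto-central-midline) plus a posterior P3b
  on location-deviant endings;
* when an ending is BOTH a statistical and a physical deviant (double
  deviant), the sMMN contribution is multiplied by a suppression factor
  (default 0.2), modelling the observed interaction;
* block-group scalings modulate the sMMN (rise then fall) and phMMN
  (diminishing); they are mean-one across the three grouped blocks so
  across-block grand averages equal the nominal amplitudes.

The simulator is linear: with all noise terms at zero, the recording equals
the sum of the ground-truth kernels exactly, which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, standard_montage
from .paradigm import EVENT_CODES, ExperimentDesign, TripletSequence

__all__ = [
    "ERPComponentSpec",
    "ErpConfig",
    "NoiseSpec",
    "Recording",
    "default_erp_config",
    "ground_truth_erp",
    "simulate_block",
    "simulate_subject",
    "topography_weights",
]

SAMPLE_RATE = 500  # Hz, EEG sampling rate


@dataclass(frozen=True)
class ERPComponentSpec:
    """One ERP component: Gaussian kernel x spatial topography x condition rule.

    ``rule`` is one of ``"all_sounds"``, ``"low_tp_ending"``,
    ``"deviant_location_ending"``; ``block_scaling`` gives the multiplicative
    factor per grouped block (1..3).
    """

    name: str
    peak_latency_ms: float
    sigma_ms: float
    peak_amplitude_uv: float       # sign carries polarity
    topo_center: str
    topo_falloff: float            # 1 / normalized distance; larger = tighter
    rule: str
    block_scaling: tuple = (1.0, 1.0, 1.0)

    def fires(self, position: int, ending_tp, ending_location) -> bool:
        if self.rule == "all_sounds":
            return True
        if position != 3:
            return False
        if self.rule == "low_tp_ending":
            return ending_tp == 0.1
        if self.rule == "deviant_location_ending":
            return ending_location == "deviant"
        raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class ErpConfig:
    """Component list plus the statistical-by-physical interaction term."""

    components: tuple
    smmn_suppression: float = 0.2  # sMMN gain on double deviants

    def component(self, name: str) -> ERPComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


def default_erp_config() -> ErpConfig:
    """Default component configuration mirroring the reported effects."""
    return ErpConfig(
        components=(
            ERPComponentSpec("P1", 140.0, 25.0, 2.0, "CZ", 0.9, "all_sounds"),
            ERPComponentSpec("N1", 200.0, 30.0, -2.0, "CZ", 0.9, "all_sounds"),
            ERPComponentSpec(
                "sMMN", 210.0, 30.0, -1.50, "FZ", 1.2, "low_tp_ending",
                block_scaling=(0.85, 1.25, 0.90),
            ),
            ERPComponentSpec(
                "phMMN", 180.0, 28.0, -3.65, "FCZ", 1.2, "deviant_location_ending",
                block_scaling=(1.15, 1.00, 0.85),
            ),
            ERPComponentSpec(
                "P3b", 330.0, 45.0, 3.0, "PZ", 1.0, "deviant_location_ending",
                block_scaling=(1.0, 1.0, 1.0),
            ),
        )
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model (all amplitudes in µV; zero disables a term)."""

    white_sd: float = 8.0
    pink_sd: float = 6.0           # 1/f^alpha process SD
    pink_alpha: float = 1.0
    blink_rate_per_min: float = 12.0
    blink_amplitude_uv: float = 100.0
    drift_amplitude_uv: float = 10.0
    subject_gain_sd: float = 0.1   # per-subject multiplicative ERP gain spread

    def silent(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, self.pink_alpha, 0.0, 0.0, 0.0, 0.0)


@dataclass
class Recording:
    """Continuous multi-channel EEG in µV with event markers."""

    data: np.ndarray            # (n_channels, n_samples)
    sample_rate: int
    montage: Montage
    markers: pd.DataFrame       # per event: sample, code + stream metadata
    ground_truth: pd.DataFrame | None = None  # injected amplitudes per event
    block_index: int = 0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]


def topography_weights(
    center_label: str, falloff: float, montage: Montage | None = None
) -> np.ndarray:
    """Squared-exponential spatial gains: 1 at the center, 0 off-scalp.

    ``gain = exp(-(falloff * d)**2)`` with d the normalized 2-D distance;
    ``falloff -> inf`` concentrates all weight on the center electrode.
    Mastoids and EOG get zero gain: injected component amplitudes are defined
    as the values observed after mastoid re-referencing.
    """
    montage = montage or standard_montage()
    montage.index(center_label)  # raises MontageError for unknown labels
    weights = np.zeros(len(montage.channels))
    for i, ch in enumerate(montage.channels):
        if ch in montage.mastoids or ch in montage.eog:
            continue
        d = montage.distance(center_label, ch)
        weights[i] = np.exp(-((falloff * d) ** 2)) if np.isfinite(falloff) else float(ch == center_label)
    return weights


def _gauss_kernel(times_ms: np.ndarray, latency_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-((times_ms - latency_ms) ** 2) / (2 * sigma_ms**2))


def _block_group(block_index: int, n_blocks: int = 6) -> int:
    """Grouped block 1..3 (first / middle / last pair of the 6 blocks)."""
    return block_index * 3 // n_blocks + 1


def _event_amplitudes(
    config: ErpConfig, position: int, ending_tp, ending_location, group: int
) -> dict:
    """Effective amplitude of every firing component for one event."""
    amps = {}
    fired = {
        c.name: c
        for c in config.components
        if c.fires(position, ending_tp, ending_location)
    }
    for name, c in fired.items():
        a = c.peak_amplitude_uv * c.block_scaling[group - 1]
        if name == "sMMN" and "phMMN" in fired:
            a *= config.smmn_suppression  # double deviant: suppressed sMMN
        amps[name] = a
    return amps


def ground_truth_erp(
    erp_config: ErpConfig,
    condition: dict,
    channel: str,
    times_ms: np.ndarray | None = None,
    montage: Montage | None = None,
) -> np.ndarray:
    """Noiseless single-event waveform for a condition — the recovery oracle.

    ``condition`` has keys ``ending_tp``, ``ending_location`` and optionally
    ``block_group`` (default 2, the unit-scaling reference only when scalings
    are mean-one) and ``position`` (default 3).
    """
    montage = montage or standard_montage()
    if times_ms is None:
        times_ms = np.arange(-100, 401, 1000 / SAMPLE_RATE)
    times_ms = np.asarray(times_ms, float)
    amps = _event_amplitudes(
        erp_config,
        condition.get("position", 3),
        condition.get("ending_tp"),
        condition.get("ending_location"),
        condition.get("block_group", 2),
    )
    ch_i = montage.index(channel)
    wave = np.zeros_like(times_ms)
    for name, a in amps.items():
        c = erp_config.component(name)
        w = topography_weights(c.topo_center, c.topo_falloff, montage)[ch_i]
        wave += a * w * _gauss_kernel(times_ms, c.peak_latency_ms, c.sigma_ms)
    return wave


def _pink_noise(rng, n_ch: int, n: int, sd: float, alpha: float) -> np.ndarray:
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n)
    white = rng.standard_normal((n_ch, nfft))
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(nfft, 1 / SAMPLE_RATE)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2)
    out = sfft.irfft(spec * shaping, n=nfft, axis=1)[:, :n]
    cur = out.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return out * (sd / cur)


def _blink_waveform(fs: int) -> np.ndarray:
    """350 ms raised-cosine blink pulse (unit peak)."""
    n = int(round(0.35 * fs))
    return np.sin(np.pi * np.arange(n) / n) ** 2


def _blink_projection(montage: Montage) -> np.ndarray:
    """VEOG gets unit gain; scalp gain decays from the prefrontal midline."""
    proj = 0.5 * topography_weights("FPZ", 1.8, montage)
    proj[montage.index("VEOG")] = 1.0
    return proj


def simulate_block(
    design: ExperimentDesign,
    sequence: TripletSequence,
    erp_config: ErpConfig | None = None,
    noise_spec: NoiseSpec | None = None,
    seed=None,
    montage: Montage | None = None,
    subject_gain: float = 1.0,
    pad_ms: float = 1200.0,
) -> Recording:
    """Simulate one block's continuous EEG from its stimulus sequence."""
    erp_config = erp_config or default_erp_config()
    noise_spec = noise_spec or NoiseSpec()
    montage = montage or standard_montage()
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else design.rng(4, sequence.block_index)
    )
    fs = SAMPLE_RATE
    frame = sequence.to_frame()
    n = int(round((frame.onset_ms.max() + pad_ms) * fs / 1000.0))
    n_ch = len(montage.channels)
    group = _block_group(sequence.block_index, design.n_blocks)

    data = np.zeros((n_ch, n))
    topo = {
        c.name: topography_weights(c.topo_center, c.topo_falloff, montage)
        for c in erp_config.components
    }
    # per-component kernel sampled on the recording grid, offsets in samples
    kernels = {}
    for c in erp_config.components:
        lo = int(np.floor((c.peak_latency_ms - 4 * c.sigma_ms) * fs / 1000.0))
        hi = int(np.ceil((c.peak_latency_ms + 4 * c.sigma_ms) * fs / 1000.0))
        offsets = np.arange(lo, hi + 1)
        kernels[c.name] = (
            lo,
            _gauss_kernel(offsets * 1000.0 / fs, c.peak_latency_ms, c.sigma_ms),
        )

    truth_rows = []
    samples = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        onset_sample = int(round(row.onset_ms * fs / 1000.0))
        samples.append(onset_sample)
        tp = row.ending_tp if row.ending_tp != "" else None
        loc = None
        if row.position == 3:
            loc = (
                "deviant"
                if row.location != design.standard_side_per_block[row.block]
                else "standard"
            )
        amps = _event_amplitudes(erp_config, row.position, tp, loc, group)
        for name, a in amps.items():
            a = a * subject_gain
            lo, kern = kernels[name]
            start = onset_sample + lo
            k0 = max(0, -start)
            k1 = min(len(kern), n - start)
            if k1 > k0:
                data[:, start + k0 : start + k1] += (
                    a * topo[name][:, None] * kern[None, k0:k1]
                )
            truth_rows.append(
                dict(event=idx, component=name, amplitude_uv=a, onset_sample=onset_sample)
            )

    if noise_spec.white_sd > 0:
        data += rng.standard_normal((n_ch, n)) * noise_spec.white_sd
    if noise_spec.pink_sd > 0:
        data += _pink_noise(rng, n_ch, n, noise_spec.pink_sd, noise_spec.pink_alpha)
    if noise_spec.drift_amplitude_uv > 0:
        t = np.arange(n) / fs
        f = rng.uniform(0.01, 0.08, n_ch)
        phase = rng.uniform(0, 2 * np.pi, n_ch)
        data += noise_spec.drift_amplitude_uv * np.sin(
            2 * np.pi * f[:, None] * t[None, :] + phase[:, None]
        )
    if noise_spec.blink_rate_per_min > 0:
        pulse = _blink_waveform(fs)
        proj = _blink_projection(montage)
        n_blinks = rng.poisson(noise_spec.blink_rate_per_min * n / fs / 60.0)
        starts = rng.integers(0, max(1, n - len(pulse)), n_blinks)
        for s in starts:
            amp = noise_spec.blink_amplitude_uv * rng.uniform(0.8, 1.2)
            data[:, s : s + len(pulse)] += amp * proj[:, None] * pulse[None, :]

    markers = frame.copy()
    markers["sample"] = samples
    markers["code"] = [
        EVENT_CODES["TARGET"]
        if r.is_target
        else (EVENT_CODES[r.category] if r.position == 3 else EVENT_CODES[f"ROOT_{r.position}"])
        for r in frame.itertuples(index=False)
    ]
    markers["block_group"] = group
    markers["ending_location"] = [
        (
            "deviant"
            if (r.position == 3 and r.location != design.standard_side_per_block[r.block])
            else ("standard" if r.position == 3 else "")
        )
        for r in frame.itertuples(index=False)
    ]
    return Recording(
        data=data,
        sample_rate=fs,
        montage=montage,
        markers=markers,
        ground_truth=pd.DataFrame(truth_rows),
        block_index=sequence.block_index,
    )


def simulate_subject(
    design: ExperimentDesign,
    sequences: list,
    erp_config: ErpConfig | None = None,
    noise_spec: NoiseSpec | None = None,
    seed=None,
    montage: Montage | None = None,
) -> list:
    """Simulate all blocks of one subject; returns one Recording per block.

    A per-subject multiplicative ERP gain ~ N(1, subject_gain_sd) introduces
    mean-one between-subject amplitude variability.
    """
    noise_spec = noise_spec or NoiseSpec()
    rng = np.random.default_rng(seed) if seed is not None else design.rng(5)
    gain = (
        1.0 + noise_spec.subject_gain_sd * rng.standard_normal()
        if noise_spec.subject_gain_sd > 0
        else 1.0
    )
    recs = []
    for seq in sequences:
        block_seed = rng.integers(2**31)
        recs.append(
            simulate_block(
                design,
                seq,
                erp_config=erp_config,
                noise_spec=noise_spec,
                seed=block_seed,
                montage=montage,
                subject_gain=gain,
            )
        )
    return recs
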