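"""Filtering, re-referencing, gliding-window rejection, epoching, baseline."""

import numpy as np
import pandas as pd
import pytest

import triplet_mmn as tm
from triplet_mmn.montage import standard_montage
from triplet_mmn.preprocess import (
    HIGHPASS_05HZ,
    LOWPASS_30HZ,
    FilterSpec,
    PreprocessError,
    _filter_array,
    epoch,
    preprocess_recording,
    preprocess_roots,
    reject_samples,
    select_ending_markers,
    select_root_markers,
)
from triplet_mmn.simulate import NoiseSpec, Recording

FS = 500


def make_recording(data, markers=None):
    m = standard_montage()
    if data.ndim == 1:
        full = np.zeros((len(m.channels), len(data)))
        full[:] = data
        data = full
    if markers is None:
        markers = pd.DataFrame(
            dict(sample=[], code=[], position=[], is_target=[])
        )
    return Recording(data=data, sample_rate=FS, montage=m, markers=markers)


def freq_response(taps, f):
    w = 2 * np.pi * f / FS
    n = np.arange(len(taps))
    return np.abs(np.sum(taps * np.exp(-1j * w * n)))


class TestFilterDesign:
    def test_lowpass_dc_gain_one(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        assert len(taps) == 2751  # stated 2750 made odd for symmetry
        assert taps.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(taps, taps[::-1])

    def test_highpass_dc_gain_zero(self):
        taps = tm.design_fir(HIGHPASS_05HZ, FS)
        assert len(taps) == 551
        assert abs(taps.sum()) < 1e-6

    def test_passband_and_stopband(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        assert freq_response(taps, 10.0) == pytest.approx(1.0, abs=1e-3)
        assert freq_response(taps, 60.0) < 10 ** (-40 / 20)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(PreprocessError):
            tm.design_fir(FilterSpec("lowpass", 300.0, 101), FS)


class TestFilterApplication:
    def test_constant_through_lowpass_unchanged(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        x = np.full((1, 8000), 3.7)
        y = _filter_array(x, taps)
        assert np.allclose(y, 3.7, atol=1e-6)

    def test_zero_phase_delta_peak_unshifted(self):
        taps = tm.design_fir(FilterSpec("lowpass", 30.0, 501), FS)
        x = np.zeros((1, 4000))
        x[0, 2000] = 1.0
        y = _filter_array(x, taps)
        assert np.argmax(y[0]) == 2000

    def test_sine_peaks_unshifted(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = _filter_array(x, taps)
        mid = slice(4000, 6000)
        # passband: waveform preserved pointwise, so every extremum is in place
        assert np.allclose(y[0, mid], x[0, mid], atol=1e-3)
        period = FS // 10
        shift = (np.argmax(y[0, mid]) - np.argmax(x[0, mid])) % period
        assert min(shift, period - shift) <= 1

    def test_stopband_sine_attenuated(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 45 * t)[None, :]
        y = _filter_array(x, taps)
        # 45 Hz sits in the transition band of the 30 Hz design; well below pass level
        assert np.abs(y[0, 2000:-2000]).max() < 0.5
        x60 = np.sin(2 * np.pi * 60 * t)[None, :]
        y60 = _filter_array(x60, taps)
        assert np.abs(y60[0, 2000:-2000]).max() < 10 ** (-40 / 20)

    def test_filter_longer_than_signal_rejected(self):
        taps = tm.design_fir(LOWPASS_30HZ, FS)
        with pytest.raises(PreprocessError):
            _filter_array(np.zeros((1, 100)), taps)


class TestRereference:
    def test_zero_mastoids_identity(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(63, 1000)))
        m = rec.montage
        rec.data[m.index("M1")] = 0
        rec.data[m.index("M2")] = 0
        out = tm.rereference(rec)
        assert np.array_equal(out.data, rec.data)

    def test_mastoid_mean_zero_after(self):
        rec = make_recording(np.random.default_rng(1).normal(size=(63, 1000)))
        out = tm.rereference(rec)
        m = rec.montage
        ref = (out.data[m.index("M1")] + out.data[m.index("M2")]) / 2
        assert np.allclose(ref, 0, atol=1e-12)

    def test_known_offset_removed_eog_untouched(self):
        rec = make_recording(np.zeros((63, 500)))
        m = rec.montage
        rec.data[m.index("M1")] = 4.0
        rec.data[m.index("M2")] = 2.0
        rec.data[m.index("FZ")] = 10.0
        rec.data[m.index("VEOG")] = 5.0
        out = tm.rereference(rec)
        assert np.allclose(out.data[m.index("FZ")], 7.0)   # 10 - (4+2)/2
        assert np.allclose(out.data[m.index("VEOG")], 5.0)


def sliding_sd_oracle(data, w, threshold):
    """Naive O(n*w) recomputation of the gliding-window rejection."""
    n = data.shape[1]
    mask = np.zeros(n, dtype=bool)
    for s in range(n - w + 1):
        sd = data[:, s : s + w].std(axis=1)
        if (sd > threshold).any():
            mask[s : s + w] = True
    return mask


class TestRejection:
    def test_constant_recording_clean(self):
        rec = make_recording(np.full((63, 2000), 7.0))
        assert not tm.reject_samples(rec).any()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.normal(0, 12, size=(4, 5000))  # 10 s, 4 channels
        data[2, 2400:2450] += 90.0                # artifact burst
        rec = Recording(
            data=data,
            sample_rate=FS,
            montage=standard_montage(),
            markers=pd.DataFrame(dict(sample=[], is_target=[])),
        )
        # restrict montage bookkeeping: reject works on raw arrays
        got = tm.reject_samples(rec, windows_ms=(200.0, 800.0), threshold_uv=25.0)
        want = sliding_sd_oracle(data, 100, 25.0) | sliding_sd_oracle(data, 400, 25.0)
        assert np.array_equal(got, want)

    def test_step_rejects_covering_windows(self):
        data = np.zeros((63, 3000))
        data[:, 1500:] = 100.0
        rec = make_recording(data)
        mask = tm.reject_samples(rec, windows_ms=(200.0,), threshold_uv=25.0)
        w = 100
        # windows straddling the step with enough samples on both sides
        # (100 µV step: window SD = 100 sqrt(p(1-p)) > 25 for p in (.067, .933))
        assert mask[1450:1550].all()
        assert not mask[: 1500 - w].any()
        assert not mask[1500 + w :].any()
        assert np.array_equal(mask, sliding_sd_oracle(data[:1], w, 25.0))

    def test_boundary_sd_exactly_25_not_rejected(self):
        # alternating ±25 has population SD exactly 25 in every even window
        data = np.tile(np.array([25.0, -25.0]), 1500)[None, :].repeat(63, axis=0)
        rec = make_recording(data)
        assert not tm.reject_samples(rec).any()
        rec.data *= 1.001  # just above threshold -> everything rejected
        assert tm.reject_samples(rec).all()

    def test_window_longer_than_recording_rejected(self):
        rec = make_recording(np.zeros((63, 50)))
        with pytest.raises(PreprocessError):
            tm.reject_samples(rec)


class TestEpoching:
    def test_epoch_shape_and_conservation(self, noisy_recording):
        rec = noisy_recording
        mask = tm.reject_samples(rec)
        markers = select_ending_markers(rec.markers)
        eps = epoch(rec, markers, mask=mask)
        assert eps.data.shape[1:] == (63, 251)  # [-100, 400] ms at 500 Hz inclusive
        assert eps.times_ms[0] == -100.0 and eps.times_ms[-1] == 400.0
        assert eps.n_trials + (~eps.ledger.kept).sum() == len(markers)

    def test_post_target_exclusion(self, noisy_recording):
        rec = noisy_recording
        eps = epoch(rec, select_ending_markers(rec.markers), mask=None)
        dropped = eps.ledger[eps.ledger.reason == "post-target"]
        assert len(dropped) > 0
        targets = rec.markers.loc[rec.markers.is_target.astype(bool), "sample"].to_numpy()
        for s in dropped["sample"]:
            assert ((s > targets) & (s - targets <= 3 * FS)).any()
        # every kept epoch is clear of the 3 s horizon
        for s in eps.ledger.loc[eps.ledger.kept, "sample"]:
            assert not ((s > targets) & (s - targets <= 3 * FS)).any()

    def test_artifact_drop(self, silent_recording):
        rec = silent_recording
        markers = select_ending_markers(rec.markers)
        clean = epoch(rec, markers, mask=None)
        victim = int(clean.ledger.loc[clean.ledger.kept, "sample"].iloc[5])
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[victim + 10] = True
        eps = epoch(rec, markers, mask=mask)
        row = eps.ledger[eps.ledger["sample"] == victim]
        assert list(row.reason) == ["artifact"]

    def test_edge_epoch_dropped_not_error(self, silent_recording):
        rec = silent_recording
        markers = select_ending_markers(rec.markers).copy()
        markers.loc[markers.index[0], "anchor_sample"] = 10  # window under-runs
        eps = epoch(rec, markers, mask=None)
        assert (eps.ledger.reason == "edge").sum() == 1

    def test_root_epochs_follow_standard_triplets_only(self, silent_recording):
        rec = silent_recording
        roots = select_root_markers(rec.markers)
        endings = rec.markers[(rec.markers.position == 3)]
        bad = set(
            endings[
                (endings.ending_tp == 0.1) | (endings.ending_location == "deviant")
            ].triplet_index
        )
        assert all((i - 1) not in bad for i in roots.triplet_index)
        # anchored at the preceding triplet's ending onset
        ending_sample = dict(zip(endings.triplet_index, endings["sample"]))
        for row in roots.itertuples(index=False):
            assert row.anchor_sample == ending_sample[row.triplet_index - 1]


class TestBaseline:
    def test_baseline_mean_zero_and_idempotent(self, noisy_recording):
        eps = epoch(noisy_recording, select_ending_markers(noisy_recording.markers))
        out = tm.baseline_correct(eps)
        sel = (out.times_ms >= -100) & (out.times_ms <= 0)
        assert np.allclose(out.data[:, :, sel].mean(axis=2), 0, atol=1e-10)
        twice = tm.baseline_correct(out)
        assert np.allclose(twice.data, out.data, atol=1e-12)

    def test_constant_offset_removed(self, silent_recording):
        rec = silent_recording
        shifted = Recording(
            data=rec.data + 13.0,
            sample_rate=rec.sample_rate,
            montage=rec.montage,
            markers=rec.markers,
        )
        eps = tm.baseline_correct(epoch(shifted, select_ending_markers(shifted.markers)))
        ref = tm.baseline_correct(epoch(rec, select_ending_markers(rec.markers)))
        assert np.allclose(eps.data, ref.data, atol=1e-9)

    def test_root_path_skips_baseline(self, silent_recording):
        eps = preprocess_roots(silent_recording)
        assert eps.data.shape[2] == 551  # [-100, 1000] ms inclusive
        sel = (eps.times_ms >= -100) & (eps.times_ms <= 0)
        base = eps.data[:, :, sel].mean()
        # high-pass instead of baseline: prestim mean not forced to zero
        assert not np.allclose(eps.data[:, :, sel].mean(axis=2), 0, atol=1e-6)


def test_end_to_end_latency_preservation(short_design, short_block, silent_recording):
    """A noiseless sMMN at 210 ms survives the full chain at 210 ± 2 ms."""
    eps = preprocess_recording(silent_recording)
    import triplet_mmn.stats as st

    low = st.average_condition(eps, ending_tp=0.1, ending_location="standard")
    high = st.average_condition(eps, ending_tp=0.9, ending_location="standard")
    dw = st.difference_wave(low, high)
    pk = st.peak_measure(dw.channel("FZ"), dw.times_ms, (150, 300), "negative")
    assert abs(pk.latency_ms - 210.0) <= 2.0
    cfg = tm.default_erp_config()
    scale = cfg.component("sMMN").block_scaling[0]  # single block -> group 1
    assert pk.amplitude_uv == pytest.approx(-1.50 * scale, abs=0.02)
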