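"""ERP measures and within-subject factorial statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import triplet_mmn as tm
from triplet_mmn.stats import ERP, RepeatedMeasuresAnova, StatsError, peak_measure


def toy_erp(data, times=None, channels=None):
    data = np.asarray(data, float)
    times = np.arange(data.shape[-1]) if times is None else np.asarray(times)
    channels = channels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return ERP(data=data, times_ms=times, channels=channels)


class TestAveragesAndDifferences:
    def test_single_trial_average_is_that_trial(self, silent_recording):
        from triplet_mmn.preprocess import epoch, select_ending_markers

        eps = epoch(silent_recording, select_ending_markers(silent_recording.markers))
        one = eps
        one.data = eps.data[:1]
        one.labels = eps.labels.iloc[:1]
        erp = tm.average_condition(one)
        assert np.array_equal(erp.data, eps.data[0])
        assert erp.n_trials == 1

    def test_no_matching_trials_errors(self, silent_recording):
        from triplet_mmn.preprocess import epoch, select_ending_markers

        eps = epoch(silent_recording, select_ending_markers(silent_recording.markers))
        with pytest.raises(StatsError):
            tm.average_condition(eps, ending_tp=0.42)

    def test_difference_antisymmetry_and_zero(self):
        rng = np.random.default_rng(3)
        a = toy_erp(rng.normal(size=(4, 50)))
        b = toy_erp(rng.normal(size=(4, 50)))
        d1, d2 = tm.difference_wave(a, b), tm.difference_wave(b, a)
        assert np.allclose(d1.data, -d2.data)
        assert np.allclose(tm.difference_wave(a, a).data, 0)

    def test_axis_mismatch_rejected(self):
        a, b = toy_erp(np.zeros((2, 10))), toy_erp(np.zeros((2, 11)))
        with pytest.raises(StatsError):
            tm.difference_wave(a, b)


class TestRoiReduce:
    def test_uniform_field(self, montage):
        erp = toy_erp(np.full((63, 20), 2.5), channels=tuple(montage.channels))
        roi = tm.roi_reduce(erp)
        assert roi.data.shape == (9, 20)
        assert np.allclose(roi.data, 2.5)

    def test_frontal_middle_is_mean_of_listed_electrodes(self, montage):
        rng = np.random.default_rng(0)
        erp = toy_erp(rng.normal(size=(63, 30)), channels=tuple(montage.channels))
        roi = tm.roi_reduce(erp)
        listed = ["F1", "FZ", "F2", "FC1", "FCZ", "FC2"]
        manual = np.mean([erp.channel(c) for c in listed], axis=0)
        assert np.allclose(roi.channel("frontal_middle"), manual)

    def test_locality(self, montage):
        erp = toy_erp(np.zeros((63, 10)), channels=tuple(montage.channels))
        roi0 = tm.roi_reduce(erp).data.copy()
        erp.data[list(montage.channels).index("OZ")] += 9.0
        roi1 = tm.roi_reduce(erp).data
        changed = np.abs(roi1 - roi0).sum(axis=1) > 0
        assert changed.sum() == 1  # only parietal_middle

    def test_missing_electrode_reported(self):
        erp = toy_erp(np.zeros((3, 10)), channels=("FZ", "CZ", "PZ"))
        with pytest.raises(StatsError, match="missing electrodes"):
            tm.roi_reduce(erp)


class TestWindowAndPeak:
    def test_window_mean_boxcar(self):
        times = np.arange(0, 500, 2.0)
        x = np.where((times >= 100) & (times <= 200), 1.0, 0.0)
        assert tm.window_mean(x, times, (100, 200)) == 1.0
        assert tm.window_mean(np.zeros_like(x), times, (100, 200)) == 0.0

    def test_window_mean_gaussian_closed_form(self):
        """Noiseless sMMN kernel's window mean matches the Gaussian integral."""
        from scipy.stats import norm

        times = np.arange(-100, 401, 0.1)
        amp, mu, sig = -1.5, 210.0, 30.0
        kern = amp * np.exp(-((times - mu) ** 2) / (2 * sig**2))
        got = tm.window_mean(kern, times, (180, 260))
        analytic = (
            amp * sig * np.sqrt(2 * np.pi)
            * (norm.cdf(260, mu, sig) - norm.cdf(180, mu, sig)) / 80.0
        )
        assert got == pytest.approx(analytic, rel=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            tm.window_mean(np.zeros(10), np.arange(10.0), (5, 20))

    def test_peak_of_injected_trough(self):
        times = np.arange(0, 400, 2.0)
        x = -2.0 * np.exp(-((times - 200) ** 2) / (2 * 20.0**2))
        pk = tm.peak_measure(x, times, (100, 300), "negative")
        assert (pk.amplitude_uv, pk.latency_ms) == (-2.0, 200.0)

    def test_tie_breaks_to_earlier_latency(self):
        times = np.arange(0, 100, 2.0)
        pk = tm.peak_measure(np.zeros_like(times), times, (20, 80), "negative")
        assert pk.amplitude_uv == 0.0
        assert pk.latency_ms == 20.0


@pytest.mark.parametrize("idx,expected", [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 3)])
def test_group_blocks(idx, expected):
    assert tm.group_blocks(idx) == expected


def test_group_blocks_out_of_range():
    with pytest.raises(StatsError):
        tm.group_blocks(7)


def make_within_data(rng, n_subjects, levels, effects=None):
    """Balanced within-subject dataset; `effects` maps factor tuples to cell shifts."""
    factors = {f"f{i}": list(range(k)) for i, k in enumerate(levels)}
    rows = []
    subj_off = rng.normal(0, 1, n_subjects)
    for s in range(n_subjects):
        for cell in itertools.product(*factors.values()):
            y = subj_off[s] + rng.normal(0, 1)
            if effects:
                for keys, fn in effects.items():
                    y += fn(dict(zip(factors.keys(), cell)))
            rows.append(dict(subject=s, dv=y, **dict(zip(factors.keys(), cell))))
    return pd.DataFrame(rows), list(factors.keys())


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(7)
        df, factors = make_within_data(rng, 10, (2,))
        table = tm.rm_anova(df, "dv", "subject", factors)
        piv = df.pivot_table(index="subject", columns="f0", values="dv")
        t, p = ttest_rel(piv[0], piv[1])
        assert table.F.iloc[0] == pytest.approx(t**2, rel=1e-10)
        assert table.p.iloc[0] == pytest.approx(p, rel=1e-10)

    @pytest.mark.parametrize("levels", [(2, 3), (3, 4), (2, 2, 3)])
    def test_matches_statsmodels_oracle(self, levels):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(11)
        df, factors = make_within_data(
            rng, 6, levels,
            effects={("f0",): lambda c: 0.5 * c["f0"]},
        )
        got = tm.rm_anova(df, "dv", "subject", factors).set_index("effect")
        want = AnovaRM(df, "dv", "subject", within=factors).fit().anova_table
        for effect, row in want.iterrows():
            mine = got.loc[effect.replace(":", " x ")]
            assert mine.F == pytest.approx(row["F Value"], rel=1e-8)
            assert (mine.df_num, mine.df_den) == (row["Num DF"], row["Den DF"])
            assert mine.p == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        df, factors = make_within_data(rng, 5, (2, 3))
        a = tm.rm_anova(df, "dv", "subject", factors)
        b = tm.rm_anova(df.sample(frac=1, random_state=0), "dv", "subject", factors)
        assert np.allclose(a.F, b.F)

    def test_gg_epsilon_bounds_and_summary(self):
        rng = np.random.default_rng(9)
        df, factors = make_within_data(rng, 8, (4,))
        res = RepeatedMeasuresAnova.from_dataframe(df, "dv", "subject", factors).fit()
        row = res.effect("f0")
        assert 1 / 3 <= row.eps_gg <= 1.0
        assert 0.0 <= row.p_gg <= 1.0
        assert "Repeated-measures ANOVA" in res.summary()
        # two-level factors are sphericity-free: epsilon 1, correction inert
        df2, f2 = make_within_data(np.random.default_rng(3), 8, (2,))
        row2 = RepeatedMeasuresAnova(df2, "dv", "subject", f2).fit().effect("f0")
        assert row2.eps_gg == 1.0
        assert row2.p_gg == row2.p

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(2)
        df, factors = make_within_data(rng, 5, (2, 2))
        with pytest.raises(StatsError):
            tm.rm_anova(df.iloc[:-1], "dv", "subject", factors)


class TestPairwiseAndContrasts:
    def test_identical_conditions_t_zero(self):
        df = pd.DataFrame(
            dict(subject=list(range(6)) * 2, cond=[0] * 6 + [1] * 6, dv=[1.0] * 12)
        )
        out = tm.pairwise_comparisons(df, "dv", "subject", "cond")
        assert out.t.iloc[0] == 0.0 and out.p.iloc[0] == 1.0

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        df = pd.DataFrame(
            [dict(subject=s, cond=c, dv=base[s] + 0.7 * c) for s in range(8) for c in (0, 1)]
        )
        out = tm.pairwise_comparisons(df, "dv", "subject", "cond")
        assert out.mean_diff.iloc[0] == pytest.approx(-0.7)
        assert out.p.iloc[0] < 1e-10

    def test_holm_correction_monotone(self):
        rng = np.random.default_rng(4)
        rows = []
        for g in range(3):
            for s in range(6):
                rows.append(dict(subject=s, g=g, cond=0, dv=rng.normal()))
                rows.append(dict(subject=s, g=g, cond=1, dv=rng.normal() + 0.5 * g))
        df = pd.DataFrame(rows)
        out = tm.pairwise_comparisons(df, "dv", "subject", "cond", by="g", correction="holm")
        assert (out.p_holm >= out.p - 1e-12).all()
        assert (out.p_holm <= 1.0).all()

    def test_linear_trend_positive_and_flat(self):
        df = pd.DataFrame(
            [dict(subject=s, lev=l, dv=float(l)) for s in range(5) for l in (0, 1, 2)]
        )
        out = tm.linear_trend_contrast(df, "dv", "subject", "lev")
        assert out["contrast"] > 0 and out["p"] < 1e-6
        flat = df.assign(dv=1.0)
        out = tm.linear_trend_contrast(flat, "dv", "subject", "lev")
        assert out["contrast"] == 0.0

    def test_linear_trend_needs_three_levels(self):
        df = pd.DataFrame(
            [dict(subject=s, lev=l, dv=0.0) for s in range(5) for l in (0, 1)]
        )
        with pytest.raises(StatsError):
            tm.linear_trend_contrast(df, "dv", "subject", "lev")


class TestBehavioralChanceTest:
    def test_exact_chance(self):
        out = tm.behavioral_chance_test([0.5] * 10)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_perfect_performance(self):
        out = tm.behavioral_chance_test([1.0, 1.0, 0.99, 1.0, 0.98, 1.0])
        assert out["p"] < 1e-6 and out["mean"] > 0.99
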