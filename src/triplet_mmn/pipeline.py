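"""End-to-end study runner: paradigm -> audio-free EEG simulation -> ERP chain.

``run_study`` simulates a cohort of subjects (each with their own role
permutation, stimulus streams, and noise), pushes every block through the
preprocessing chain, and accumulates per-subject condition averages for the
2 (transition probability) x 2 (ending location) x 3 (grouped block) design.
The result object exposes grand averages, difference waves (sMMN, phMMN),
tidy window statistics for the factorial ANOVAs, and the study's full
analysis battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ROI_GRID, ROI_MAP, standard_montage
from .paradigm import generate_block, insert_targets, make_design
from .preprocess import preprocess_recording
from .simulate import ErpConfig, NoiseSpec, default_erp_config, simulate_subject
from .stats import (
    ERP,
    RepeatedMeasuresAnova,
    StatsError,
    linear_trend_contrast,
    pairwise_comparisons,
    peak_measure,
    window_mean,
)

__all__ = ["StudyResult", "analyze_study", "run_study"]

TP_LEVELS = (0.9, 0.1)                 # high, low
LOC_LEVELS = ("standard", "deviant")
SMMN_WINDOW_MS = (180.0, 260.0)
PHMMN_WINDOW_MS = (150.0, 220.0)
INTERACTION_WINDOW_MS = (160.0, 260.0)


@dataclass
class StudyResult:
    """Per-subject condition ERPs of a simulated cohort.

    ``erp_sums[s, i_tp, i_loc, i_group]`` holds the summed epochs (channels x
    time) and ``counts`` the kept-trial counts, so condition averages at any
    grouping are trial-weighted.
    """

    erp_sums: np.ndarray        # (n_subj, 2, 2, 3, n_ch, n_times)
    counts: np.ndarray          # (n_subj, 2, 2, 3)
    times_ms: np.ndarray
    channels: tuple
    drop_summary: pd.DataFrame  # drop-reason counts per subject
    master_seed: int

    @property
    def n_subjects(self) -> int:
        return self.erp_sums.shape[0]

    def subject_erp(self, subject: int, tp: float, loc: str, group: int | None = None) -> np.ndarray:
        """Condition average for one subject (channels x time), trial-weighted."""
        i_tp, i_loc = TP_LEVELS.index(tp), LOC_LEVELS.index(loc)
        if group is None:
            s = self.erp_sums[subject, i_tp, i_loc].sum(axis=0)
            n = self.counts[subject, i_tp, i_loc].sum()
        else:
            s = self.erp_sums[subject, i_tp, i_loc, group - 1]
            n = self.counts[subject, i_tp, i_loc, group - 1]
        if n == 0:
            raise StatsError(f"no kept trials for tp={tp}, loc={loc}, group={group}")
        return s / n

    def grand_average(self, tp: float, loc: str, group: int | None = None) -> ERP:
        """Mean over subjects of per-subject condition averages."""
        data = np.mean(
            [self.subject_erp(s, tp, loc, group) for s in range(self.n_subjects)],
            axis=0,
        )
        return ERP(
            data=data,
            times_ms=self.times_ms,
            channels=self.channels,
            n_trials=int(self.counts.sum()),
            condition=f"tp={tp}, loc={loc}, group={group}",
        )

    def grand_difference(
        self, cond_a: tuple, cond_b: tuple, group: int | None = None
    ) -> ERP:
        """Grand average of per-subject (cond_a − cond_b) difference waves."""
        diffs = [
            self.subject_erp(s, *cond_a, group) - self.subject_erp(s, *cond_b, group)
            for s in range(self.n_subjects)
        ]
        return ERP(
            data=np.mean(diffs, axis=0),
            times_ms=self.times_ms,
            channels=self.channels,
            condition=f"{cond_a} - {cond_b}",
        )

    def smmn_wave(self, group: int | None = None) -> ERP:
        """Low minus high TP endings at the standard location."""
        return self.grand_difference((0.1, "standard"), (0.9, "standard"), group)

    def phmmn_wave(self, group: int | None = None) -> ERP:
        """Deviant minus standard location at matched (high) TP.

        High-probability endings give the location contrast uncontaminated by
        the statistical deviance response and with ~9x the trial count of the
        low-probability cell.
        """
        return self.grand_difference((0.9, "deviant"), (0.9, "standard"), group)

    def smmn_peak(self, channel: str = "FZ"):
        wave = self.smmn_wave()
        return peak_measure(
            wave.channel(channel), self.times_ms, SMMN_WINDOW_MS, "negative", channel
        )

    def phmmn_peak(self, channel: str = "FCZ"):
        wave = self.phmmn_wave()
        return peak_measure(
            wave.channel(channel), self.times_ms, PHMMN_WINDOW_MS, "negative", channel
        )

    def window_stats(self, window_ms: tuple, conditions: list | None = None) -> pd.DataFrame:
        """Tidy subject x condition x ROI x block-group window means.

        ``conditions`` is a list of (tp, loc) tuples; default: the full 2 x 2.
        Columns: subject, tp, location, block_group, roi, area, lateralisation,
        amplitude_uv.
        """
        conditions = conditions or [
            (tp, loc) for tp in TP_LEVELS for loc in LOC_LEVELS
        ]
        roi_idx = {
            roi: [self.channels.index(c) for c in chans]
            for roi, chans in ROI_MAP.items()
        }
        rows = []
        for s in range(self.n_subjects):
            for tp, loc in conditions:
                for g in (1, 2, 3):
                    erp = self.subject_erp(s, tp, loc, g)
                    for roi, idx in roi_idx.items():
                        val = window_mean(
                            erp[idx].mean(axis=0), self.times_ms, window_ms
                        )
                        area, lat = ROI_GRID[roi]
                        rows.append(
                            dict(
                                subject=s,
                                tp=tp,
                                location=loc,
                                block_group=g,
                                roi=roi,
                                area=area,
                                lateralisation=lat,
                                amplitude_uv=float(val),
                            )
                        )
        return pd.DataFrame(rows)


def run_study(
    n_subjects: int = 21,
    master_seed: int = 0,
    n_blocks: int = 6,
    triplets_per_block: int = 400,
    erp_config: ErpConfig | None = None,
    noise_spec: NoiseSpec | None = None,
    target_rate: int = 10,
) -> StudyResult:
    """Simulate and preprocess a whole cohort; returns condition ERPs.

    Deterministic in ``master_seed``: every subject's design, streams, and
    noise derive from it through documented seed splitting.
    """
    erp_config = erp_config or default_erp_config()
    noise_spec = noise_spec or NoiseSpec()
    montage = standard_montage()
    n_ch = len(montage.channels)
    sums = counts = times = None
    drop_rows = []
    for s in range(n_subjects):
        design = make_design(
            participant_id=s + 1,
            master_seed=master_seed,
            n_blocks=n_blocks,
            triplets_per_block=triplets_per_block,
            target_rate=target_rate,
        )
        sequences = [
            insert_targets(generate_block(design, b), design)
            for b in range(n_blocks)
        ]
        recordings = simulate_subject(
            design, sequences, erp_config=erp_config, noise_spec=noise_spec,
            montage=montage,
        )
        for rec in recordings:
            eps = preprocess_recording(rec)
            if sums is None:
                times = eps.times_ms
                sums = np.zeros((n_subjects, 2, 2, 3, n_ch, len(times)))
                counts = np.zeros((n_subjects, 2, 2, 3), dtype=int)
            for reason, cnt in eps.ledger.reason.value_counts().items():
                drop_rows.append(
                    dict(subject=s, block=rec.block_index, reason=reason or "kept", n=int(cnt))
                )
            if eps.n_trials == 0:
                continue
            g = int(eps.labels.block_group.iloc[0]) - 1
            tp_i = eps.labels.ending_tp.map({0.9: 0, 0.1: 1}).to_numpy()
            loc_i = eps.labels.ending_location.map(
                {"standard": 0, "deviant": 1}
            ).to_numpy()
            for a in (0, 1):
                for b in (0, 1):
                    sel = (tp_i == a) & (loc_i == b)
                    if sel.any():
                        sums[s, a, b, g] += eps.data[sel].sum(axis=0)
                        counts[s, a, b, g] += int(sel.sum())
    return StudyResult(
        erp_sums=sums,
        counts=counts,
        times_ms=times,
        channels=tuple(montage.channels),
        drop_summary=pd.DataFrame(drop_rows),
        master_seed=master_seed,
    )


def analyze_study(result: StudyResult) -> dict:
    """The study's statistical battery on a simulated cohort.

    Returns a dict with the three ending ANOVAs (statistical, physical,
    interaction), block-wise pairwise comparisons of the sMMN, the linear
    trend over scalp area, and the interaction simple effects.
    """
    out = {}

    stats_smmn = result.window_stats(
        SMMN_WINDOW_MS, conditions=[(0.9, "standard"), (0.1, "standard")]
    )
    out["smmn_anova"] = (
        RepeatedMeasuresAnova.from_dataframe(
            stats_smmn, "amplitude_uv", "subject",
            ["tp", "area", "lateralisation", "block_group"],
        )
        .fit()
    )
    out["smmn_pairwise_by_block"] = pairwise_comparisons(
        stats_smmn.groupby(["subject", "tp", "block_group"], as_index=False)
        .amplitude_uv.mean(),
        "amplitude_uv", "subject", "tp", by="block_group",
    )

    stats_ph = result.window_stats(
        PHMMN_WINDOW_MS, conditions=[(0.9, "standard"), (0.9, "deviant")]
    )
    out["phmmn_anova"] = (
        RepeatedMeasuresAnova.from_dataframe(
            stats_ph, "amplitude_uv", "subject",
            ["location", "area", "lateralisation", "block_group"],
        )
        .fit()
    )

    stats_int = result.window_stats(INTERACTION_WINDOW_MS)
    out["interaction_anova"] = (
        RepeatedMeasuresAnova.from_dataframe(
            stats_int, "amplitude_uv", "subject",
            ["tp", "location", "area", "lateralisation", "block_group"],
        )
        .fit()
    )
    pooled = stats_int.groupby(
        ["subject", "tp", "location"], as_index=False
    ).amplitude_uv.mean()
    out["simple_effects_tp_by_location"] = pairwise_comparisons(
        pooled, "amplitude_uv", "subject", "tp", by="location"
    )

    # anterior-to-posterior gradient of the sMMN (linear trend over scalp area)
    diff = (
        stats_smmn.pivot_table(
            index=["subject", "area"], columns="tp", values="amplitude_uv"
        )
        .reset_index()
    )
    diff["smmn"] = diff[0.1] - diff[0.9]
    diff["area_order"] = diff.area.map({"frontal": 0, "central": 1, "parietal": 2})
    out["smmn_area_linear_trend"] = linear_trend_contrast(
        diff, "smmn", "subject", "area_order"
    )
    return out
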