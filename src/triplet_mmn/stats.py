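"""ERP condition averaging, ROI reduction, window/peak measures, and
within-subject factorial statistics.

The inferential core is a fully-crossed repeated-measures ANOVA implemented
through orthonormal contrasts: for every effect (any subset of the within
factors), an orthonormal contrast basis is formed as the Kronecker product of
per-factor Helmert-type bases (or scaled mean vectors for factors averaged
out), subject-level contrast scores are computed, and the effect is tested
against its own subject-by-effect error stratum.  Greenhouse–Geisser epsilon
is estimated from the covariance of the contrast scores; both uncorrected and
corrected p-values are reported.

Exposed statsmodels-style: ``RepeatedMeasuresAnova.from_dataframe(...)`` →
``.fit()`` → :class:`AnovaResults` with ``.anova_table`` and ``.summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import ROI_MAP

__all__ = [
    "ERP",
    "AnovaResults",
    "PeakMeasure",
    "RepeatedMeasuresAnova",
    "StatsError",
    "average_condition",
    "behavioral_chance_test",
    "difference_wave",
    "group_blocks",
    "linear_trend_contrast",
    "pairwise_comparisons",
    "peak_measure",
    "rm_anova",
    "roi_reduce",
    "window_mean",
]


class StatsError(ValueError):
    """Raised for malformed statistical inputs."""


# ---------------------------------------------------------------- ERP objects

@dataclass
class ERP:
    """Channels x time average with its bookkeeping."""

    data: np.ndarray          # (n_channels, n_times) µV
    times_ms: np.ndarray
    channels: tuple
    n_trials: int = 1
    condition: str = ""
    subject: int | None = None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


def average_condition(epochs, **criteria) -> ERP:
    """Pointwise trial mean over epochs matching the selector."""
    sub = epochs.select(**criteria) if criteria else epochs
    if sub.n_trials == 0:
        raise StatsError(f"no trials match selector {criteria!r}")
    return ERP(
        data=sub.data.mean(axis=0),
        times_ms=sub.times_ms,
        channels=sub.channels,
        n_trials=sub.n_trials,
        condition=str(criteria),
    )


def difference_wave(erp_a: ERP, erp_b: ERP) -> ERP:
    """a − b pointwise (e.g. low-TP minus high-TP endings: the sMMN)."""
    if erp_a.data.shape != erp_b.data.shape or not np.array_equal(
        erp_a.times_ms, erp_b.times_ms
    ):
        raise StatsError("ERP axes do not match")
    return ERP(
        data=erp_a.data - erp_b.data,
        times_ms=erp_a.times_ms,
        channels=erp_a.channels,
        n_trials=min(erp_a.n_trials, erp_b.n_trials),
        condition=f"({erp_a.condition}) - ({erp_b.condition})",
    )


def roi_reduce(erp: ERP, roi_map: dict | None = None) -> ERP:
    """Unweighted mean over each region's electrodes; ROI names become channels."""
    roi_map = roi_map or ROI_MAP
    rows = []
    for roi, chans in roi_map.items():
        missing = [c for c in chans if c not in erp.channels]
        if missing:
            raise StatsError(f"ROI {roi}: missing electrodes {missing}")
        idx = [erp.channels.index(c) for c in chans]
        rows.append(erp.data[idx].mean(axis=0))
    return ERP(
        data=np.stack(rows),
        times_ms=erp.times_ms,
        channels=tuple(roi_map),
        n_trials=erp.n_trials,
        condition=erp.condition,
        subject=erp.subject,
    )


def window_mean(data: np.ndarray, times_ms: np.ndarray, window_ms: tuple) -> np.ndarray:
    """Time-mean over an inclusive window along the last axis."""
    times_ms = np.asarray(times_ms)
    if window_ms[0] < times_ms[0] - 1e-9 or window_ms[1] > times_ms[-1] + 1e-9:
        raise StatsError(f"window {window_ms} outside epoch span")
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    return np.asarray(data)[..., sel].mean(axis=-1)


@dataclass(frozen=True)
class PeakMeasure:
    amplitude_uv: float
    latency_ms: float
    polarity: str
    channel: str = ""


def peak_measure(
    waveform: np.ndarray, times_ms: np.ndarray, window_ms: tuple, polarity: str,
    channel: str = "",
) -> PeakMeasure:
    """Signed extremum and latency within a window; ties go to earlier latency."""
    times_ms = np.asarray(times_ms)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise StatsError(f"window {window_ms} outside epoch span")
    w = np.asarray(waveform)[sel]
    t = times_ms[sel]
    i = int(np.argmin(w)) if polarity == "negative" else int(np.argmax(w))
    return PeakMeasure(
        amplitude_uv=float(w[i]), latency_ms=float(t[i]), polarity=polarity,
        channel=channel,
    )


def group_blocks(block_index: int, n_blocks: int = 6) -> int:
    """Group the 1-based experiment blocks pairwise: {1,2}→1, {3,4}→2, {5,6}→3."""
    if not 1 <= block_index <= n_blocks:
        raise StatsError(f"block index {block_index} out of 1..{n_blocks}")
    return (block_index - 1) * 3 // n_blocks + 1


# ------------------------------------------------- repeated-measures ANOVA

def _orthonormal_basis(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows, each orthogonal to the constant."""
    cols = np.column_stack([np.ones(k)] + [np.eye(k)[:, i] for i in range(k - 1)])
    q, _ = np.linalg.qr(cols)
    return q[:, 1:].T


@dataclass
class AnovaResults:
    """Fitted within-subject factorial ANOVA."""

    anova_table: pd.DataFrame
    factors: dict                  # factor -> levels
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        return self.anova_table.set_index("effect").loc[name]

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA "
            f"({' x '.join(f'{f}({len(l)})' for f, l in self.factors.items())}), "
            f"n = {self.n_subjects} subjects",
            "-" * 78,
        ]
        for _, r in self.anova_table.iterrows():
            lines.append(
                f"{r['effect']:<40} F({r.df_num:g},{r.df_den:g}) = {r.F:8.3f}"
                f"  p = {r.p:.4g}  eps_GG = {r.eps_gg:.3f}  p_GG = {r.p_gg:.4g}"
            )
        return "\n".join(lines)


class RepeatedMeasuresAnova:
    """Fully-crossed within-subject factorial ANOVA model.

    Parameters
    ----------
    data : tidy DataFrame with one row per subject x cell
    dv : dependent-variable column
    subject : subject-identifier column
    within : list of within-subject factor columns

    All subject x cell combinations must be present exactly once (balanced
    complete design); unbalanced designs are rejected.
    """

    def __init__(self, data: pd.DataFrame, dv: str, subject: str, within: list):
        self.dv, self.subject_col, self.within = dv, subject, list(within)
        self.levels = {f: sorted(data[f].unique().tolist()) for f in self.within}
        subjects = sorted(data[subject].unique().tolist())
        if len(subjects) < 2:
            raise StatsError("need at least 2 subjects")
        shape = [len(subjects)] + [len(self.levels[f]) for f in self.within]
        n_cells = int(np.prod(shape[1:]))
        if len(data) != len(subjects) * n_cells:
            raise StatsError("design is not balanced/complete")
        idx = {s: i for i, s in enumerate(subjects)}
        lev_idx = {
            f: {l: i for i, l in enumerate(self.levels[f])} for f in self.within
        }
        cube = np.full(shape, np.nan)
        for row in data.itertuples(index=False):
            d = row._asdict()
            key = (idx[d[subject]],) + tuple(
                lev_idx[f][d[f]] for f in self.within
            )
            cube[key] = d[dv]
        if np.isnan(cube).any():
            raise StatsError("missing cells in the design")
        self.subjects = subjects
        self.Y = cube.reshape(len(subjects), n_cells)  # cells in factor-major order

    @classmethod
    def from_dataframe(cls, data, dv, subject, within) -> "RepeatedMeasuresAnova":
        return cls(data, dv, subject, within)

    def fit(self) -> AnovaResults:
        n = len(self.subjects)
        bases = {f: _orthonormal_basis(len(l)) for f, l in self.levels.items()}
        means = {
            f: np.ones((1, len(l))) / np.sqrt(len(l)) for f, l in self.levels.items()
        }
        rows = []
        for r in range(1, len(self.within) + 1):
            for combo in itertools.combinations(self.within, r):
                M = np.ones((1, 1))
                for f in self.within:
                    M = np.kron(M, bases[f] if f in combo else means[f])
                D = self.Y @ M.T                     # subjects x q contrast scores
                q = D.shape[1]
                dbar = D.mean(axis=0)
                ss_eff = n * float(dbar @ dbar)
                resid = D - dbar
                ss_err = float((resid**2).sum())
                df_num, df_den = q, q * (n - 1)
                F = (ss_eff / df_num) / (ss_err / df_den) if ss_err > 0 else np.inf
                p = float(sps.f.sf(F, df_num, df_den))
                if q > 1:
                    S = np.cov(D.T, ddof=1)
                    eps = float(np.trace(S) ** 2 / (q * np.trace(S @ S)))
                    eps = min(1.0, max(eps, 1.0 / q))
                else:
                    eps = 1.0
                p_gg = float(sps.f.sf(F, df_num * eps, df_den * eps))
                rows.append(
                    dict(
                        effect=" x ".join(combo),
                        F=F,
                        df_num=df_num,
                        df_den=df_den,
                        p=p,
                        eps_gg=eps,
                        p_gg=p_gg,
                        ss_effect=ss_eff,
                        ss_error=ss_err,
                    )
                )
        return AnovaResults(
            anova_table=pd.DataFrame(rows),
            factors=self.levels,
            n_subjects=n,
        )


def rm_anova(data: pd.DataFrame, dv: str, subject: str, within: list) -> pd.DataFrame:
    """Convenience wrapper: fit and return the ANOVA table."""
    return RepeatedMeasuresAnova(data, dv, subject, within).fit().anova_table


def pairwise_comparisons(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    effect: str,
    by: str | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Paired t-tests on a two-level effect, optionally per level of ``by``.

    p-values are raw two-sided by default; ``correction='holm'`` applies a
    Holm adjustment across the levels of ``by``.
    """
    levels = sorted(data[effect].unique().tolist())
    if len(levels) != 2:
        raise StatsError(f"effect {effect!r} must have exactly 2 levels")
    by_levels = sorted(data[by].unique().tolist()) if by else [None]
    rows = []
    for lev in by_levels:
        sub = data if lev is None else data[data[by] == lev]
        piv = sub.pivot_table(index=subject, columns=effect, values=dv)
        if len(piv) < 2:
            raise StatsError("need at least 2 subjects")
        a, b = piv[levels[0]].to_numpy(), piv[levels[1]].to_numpy()
        diff = a - b
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b)
        rows.append(
            dict(
                by=lev,
                contrast=f"{levels[0]} - {levels[1]}",
                mean_diff=float(diff.mean()),
                t=float(t),
                df=len(piv) - 1,
                p=float(p),
            )
        )
    out = pd.DataFrame(rows)
    if correction == "holm":
        order = np.argsort(out.p.to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out.p.iloc[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
    return out


def linear_trend_contrast(
    data: pd.DataFrame, dv: str, subject: str, ordered_factor: str
) -> dict:
    """Orthogonal-polynomial linear contrast per subject, t-tested across subjects."""
    levels = sorted(data[ordered_factor].unique().tolist())
    k = len(levels)
    if k < 3:
        raise StatsError("need at least 3 ordered levels for a linear trend")
    w = np.arange(k, dtype=float) - (k - 1) / 2
    w /= np.sqrt((w**2).sum())
    piv = data.pivot_table(index=subject, columns=ordered_factor, values=dv)[levels]
    scores = piv.to_numpy() @ w
    if np.allclose(scores - scores.mean(), 0):
        t = 0.0 if np.isclose(scores.mean(), 0) else np.inf * np.sign(scores.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = sps.ttest_1samp(scores, 0.0)
    return dict(
        contrast=float(scores.mean()), t=float(t), df=len(scores) - 1, p=float(p)
    )


def behavioral_chance_test(per_subject_proportions, chance: float = 0.5) -> dict:
    """One-sample t-test of per-subject percent-correct against chance."""
    x = np.asarray(per_subject_proportions, float)
    if len(x) < 2:
        raise StatsError("need at least 2 subjects")
    if np.allclose(x, chance):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_1samp(x, chance)
    return dict(
        t=float(t),
        p=float(p),
        mean=float(x.mean()),
        sem=float(x.std(ddof=1) / np.sqrt(len(x))),
        n=len(x),
    )
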