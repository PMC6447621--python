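"""Convenience plots: condition ERPs and the 3 x 3 ROI grid."""

from __future__ import annotations

import numpy as np

from .montage import ROI_MAP
from .stats import ERP, roi_reduce

__all__ = ["plot_erp", "plot_roi_grid"]


def plot_erp(erps: dict, channel: str, ax=None, invert_y: bool = True):
    """Overlay named ERPs at one channel (negativity plotted upward)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, erp in erps.items():
        ax.plot(erp.times_ms, erp.channel(channel), label=name)
    ax.axvline(0, color="k", lw=0.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(channel)
    if invert_y:
        ax.invert_yaxis()
    ax.legend(fontsize=8)
    return ax


def plot_roi_grid(erp: ERP, fig=None):
    """One panel per ROI in the scalp-area x lateralisation layout."""
    import matplotlib.pyplot as plt

    roi = roi_reduce(erp)
    if fig is None:
        fig, axes = plt.subplots(3, 3, figsize=(9, 7), sharex=True, sharey=True)
    else:
        axes = np.array(fig.subplots(3, 3))
    for ax, name in zip(axes.ravel(), ROI_MAP):
        ax.plot(roi.times_ms, roi.channel(name))
        ax.axvline(0, color="k", lw=0.5)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(name, fontsize=8)
        ax.invert_yaxis()
    fig.tight_layout()
    return fig
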