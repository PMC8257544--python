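"""Raster and sweep figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import SpikeTrainSet
from .mea import BurstList

__all__ = ["plot_raster", "plot_weight_profiles"]


def plot_raster(
    spike_set: SpikeTrainSet,
    bursts: dict[int, BurstList] | None = None,
    ax=None,
    title: str | None = None,
    xlim: tuple[float, float] | None = None,
):
    """Spike raster with optional burst-interval bars.

    One row per neuron (excitatory below, inhibitory above, separated by
    a dashed line); burst intervals, keyed by the row to draw them at,
    appear as horizontal bars above the raster.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for nid in sorted(spike_set.trains):
        t = spike_set.trains[nid]
        ax.vlines(t, nid - 0.4, nid + 0.4, color="k", lw=0.3)
    ax.axhline(spike_set.n_exc - 0.5, color="grey", ls="--", lw=0.5)
    if bursts:
        y0 = spike_set.n_neurons + 1
        for k, bl in bursts.items():
            for b in bl.bursts:
                ax.hlines(y0 + k, b.start, b.end, color="m", lw=3)
    ax.set_xlim(xlim if xlim else (0, spike_set.duration))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron id")
    if title:
        ax.set_title(title)
    return ax


def plot_weight_profiles(sweep, metric: str = "MFR", ax=None):
    """Replicate-mean metric vs |W_inh| per C_inh level, with fits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    reports = sweep.fit_reports(metric)
    for c in sweep.c_inh_levels:
        w, y = sweep.weight_profile(c, metric)
        x = np.abs(w)
        ax.plot(x, y, "s", label=f"C_inh={c}")
        rep = reports[c]
        xg = np.linspace(x.min(), x.max(), 100)
        fit = rep.power if rep.selected == "power" else rep.linear
        ax.plot(xg, fit.predict(xg), "r-", lw=1)
    ax.set_xlabel("|W_inh| (mV)")
    ax.set_ylabel("MFR (spikes/s)" if metric == "MFR" else "MBR (bursts/min)")
    ax.legend(fontsize=8)
    return ax
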