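"""Matplotlib views of the uncertainty analyses."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ce_plane(psa, comparator: str, wtp: float, metric: str = "qaly", ax=None):
    """Incremental cost-effectiveness scatter with the WTP line."""
    ax = _get_ax(ax)
    dc, de = psa.incremental(comparator, metric)
    ax.scatter(de, dc, s=8, alpha=0.5)
    lim = max(abs(de).max() * 1.1, 1e-6)
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, color="black", lw=1, label=f"WTP {wtp:,.0f}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"incremental {metric.upper()}s")
    ax.set_ylabel("incremental cost (NT$)")
    ax.set_title(f"vs {comparator}")
    ax.legend()
    return ax


def plot_ceac(ceac_table, ax=None):
    """Cost-effectiveness acceptability curves, one per strategy."""
    ax = _get_ax(ax)
    for col in ceac_table.columns:
        ax.plot(ceac_table.index, ceac_table[col], marker="o", ms=3, label=col)
    ax.set_xlabel("willingness-to-pay (NT$ per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_tornado(entries, ax=None):
    """Horizontal tornado bars, widest at the top."""
    ax = _get_ax(ax)
    entries = list(entries)
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.7, color="steelblue")
    if entries:
        ax.axvline(entries[0].base_icer, color="black", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (NT$ per QALY)")
    return ax
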