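"""Figure helpers: raster + TSR panels and functional-graph renderings."""

from __future__ import annotations

from typing import List, Optional

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .bursts import BinnedActivity, NetworkBurst
from .io import SpikeRaster

__all__ = ["plot_raster_tsr", "plot_functional_graph"]


def plot_raster_tsr(raster: SpikeRaster, binned: BinnedActivity,
                    bursts: Optional[List[NetworkBurst]] = None, ax=None):
    """Two stacked panels: spikes per 50-ms bin on top, raster below.

    Detected bursts are shaded in the TSR panel.  Returns the figure.
    """
    if ax is None:
        fig, (ax_tsr, ax_raster) = plt.subplots(
            2, 1, sharex=True, figsize=(10, 6),
            gridspec_kw={"height_ratios": [1, 2]})
    else:
        ax_tsr = ax_raster = ax
        fig = ax.figure
    ax_tsr.step(binned.bin_times_s, binned.tsr, where="post", lw=0.8,
                color="k")
    ax_tsr.set_ylabel(f"spikes / {binned.bin_width_s * 1e3:.0f} ms")
    if bursts:
        for b in bursts:
            color = "tab:red" if b.size_class == "large" else "tab:orange"
            ax_tsr.axvspan(b.start_s, b.end_s, color=color, alpha=0.3, lw=0)
    for row, eid in enumerate(raster.electrode_ids):
        t = raster.spike_times[eid]
        if t.size:
            ax_raster.vlines(t, row + 0.1, row + 0.9, lw=0.4, color="k")
    ax_raster.set_ylim(0, raster.n_electrodes)
    ax_raster.set_ylabel("electrode")
    ax_raster.set_xlabel("time (s)")
    ax_raster.set_xlim(0, raster.duration_s)
    fig.tight_layout()
    return fig


def plot_functional_graph(graph: nx.DiGraph, ax=None, seed: int = 0,
                          base_size: float = 60.0):
    """Render the functional graph: vertex size proportional to the
    number of significant connections, labels ``Cell X [n]``."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 8))
    else:
        fig = ax.figure
    degrees = {n: graph.nodes[n].get(
        "degree", graph.in_degree(n) + graph.out_degree(n))
        for n in graph.nodes}
    pos = nx.spring_layout(graph, seed=seed)
    sizes = [base_size * (1 + degrees[n]) for n in graph.nodes]
    labels = {n: f"Cell {i + 1} [{degrees[n]}]"
              for i, n in enumerate(graph.nodes)}
    nx.draw_networkx_nodes(graph, pos, node_size=sizes, ax=ax,
                           node_color="tab:blue", alpha=0.8)
    nx.draw_networkx_edges(graph, pos, ax=ax, arrows=True, width=0.6,
                           alpha=0.6, node_size=sizes)
    nx.draw_networkx_labels(graph, pos, labels=labels, font_size=6, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    return fig
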