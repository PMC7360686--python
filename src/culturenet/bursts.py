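"""Network-burst detection from the total spiking rate (TSR).

The TSR is the total number of spikes from all electrodes within fixed
50-ms time bins.  A network burst is the classical population event of
at least four spikes recorded from at least four different electrodes
within one 50-ms bin; maximal runs of contiguous qualifying bins form a
single burst.  Bursts are classified by their peak 50-ms bin count:
*small* (4-100 spikes in 50 ms) versus *large* (101 or more spikes in
50 ms).  Summaries are normalized to the reporting windows used in this
field: small bursts per 5 min, large bursts per 10 min, and mean spikes
per burst counted over the whole burst extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .io import SpikeRaster

__all__ = [
    "BinnedActivity",
    "NetworkBurst",
    "BurstSummary",
    "compute_tsr",
    "detect_network_bursts",
    "summarize_bursts",
    "NetworkBurstModel",
    "NetworkBurstResults",
]

SMALL_BURST_MIN = 4
SMALL_BURST_MAX = 100
LARGE_BURST_MIN = 101


@dataclass
class BinnedActivity:
    """Per-bin total spike counts and distinct-electrode counts."""

    bin_width_s: float
    tsr: np.ndarray               # total spikes per bin
    active_electrodes: np.ndarray  # distinct electrodes firing per bin
    duration_s: float
    n_electrodes: int

    @property
    def n_bins(self) -> int:
        return len(self.tsr)

    @property
    def bin_times_s(self) -> np.ndarray:
        """Left edge of every bin."""
        return np.arange(self.n_bins) * self.bin_width_s


@dataclass
class NetworkBurst:
    """One detected network burst (a maximal run of qualifying bins)."""

    start_bin: int
    end_bin: int          # inclusive
    start_s: float
    end_s: float
    total_spikes: int
    peak_bin_spikes: int
    size_class: str       # "small" | "large"


@dataclass
class BurstSummary:
    """Burst counts in the standard reporting units."""

    n_small: int
    n_large: int
    n_small_per_5min: float
    n_large_per_10min: float
    mean_spikes_per_burst: Optional[float]
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "n_small": self.n_small,
            "n_large": self.n_large,
            "n_small_per_5min": self.n_small_per_5min,
            "n_large_per_10min": self.n_large_per_10min,
            "mean_spikes_per_burst": self.mean_spikes_per_burst,
            "duration_s": self.duration_s,
        }


def compute_tsr(raster: SpikeRaster, bin_width_s: float = 0.05) -> BinnedActivity:
    """Bin all spikes into half-open bins ``[k*w, (k+1)*w)``.

    The last partial bin is included; a spike exactly at ``duration_s``
    is assigned to the last bin.  Spike count is conserved:
    ``sum(tsr) == raster.n_spikes``.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    n_bins = max(1, math.ceil(raster.duration_s / bin_width_s - 1e-9))
    tsr = np.zeros(n_bins, dtype=int)
    active = np.zeros(n_bins, dtype=int)
    for eid in raster.electrode_ids:
        t = raster.spike_times[eid]
        if t.size == 0:
            continue
        idx = np.floor(t / bin_width_s).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        tsr += counts
        active += counts > 0
    return BinnedActivity(bin_width_s, tsr, active,
                          raster.duration_s, raster.n_electrodes)


def _classify(peak: int) -> str:
    return "large" if peak >= LARGE_BURST_MIN else "small"


def detect_network_bursts(
    binned: BinnedActivity,
    min_spikes: int = 4,
    min_electrodes: int = 4,
    max_gap_bins: int = 0,
) -> List[NetworkBurst]:
    """Detect network bursts as maximal runs of qualifying bins.

    A bin qualifies iff ``tsr >= min_spikes`` and
    ``active_electrodes >= min_electrodes``.  With the default
    ``max_gap_bins = 0`` a single sub-threshold bin splits bursts; a
    positive value allows that many sub-threshold bins inside one burst.
    Bursts are returned ordered by start time and never overlap.
    """
    qual = (binned.tsr >= min_spikes) & (binned.active_electrodes >= min_electrodes)
    bursts: List[NetworkBurst] = []
    runs: List[List[int]] = []
    for b in np.nonzero(qual)[0]:
        if runs and b - runs[-1][1] <= max_gap_bins + 1:
            runs[-1][1] = int(b)
        else:
            runs.append([int(b), int(b)])
    w = binned.bin_width_s
    for start, end in runs:
        extent = binned.tsr[start:end + 1]
        bursts.append(NetworkBurst(
            start_bin=start,
            end_bin=end,
            start_s=start * w,
            end_s=(end + 1) * w,
            total_spikes=int(extent.sum()),
            peak_bin_spikes=int(extent.max()),
            size_class=_classify(int(extent.max())),
        ))
    return bursts


def summarize_bursts(
    bursts: List[NetworkBurst],
    duration_s: float,
    spikes_per_burst_scope: str = "all",
) -> BurstSummary:
    """Normalize burst counts to 5- and 10-minute reporting windows.

    ``spikes_per_burst_scope`` selects whether the mean spikes per burst
    averages over all bursts (default) or small bursts only.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if spikes_per_burst_scope not in ("all", "small"):
        raise ValueError("spikes_per_burst_scope must be 'all' or 'small'")
    n_small = sum(1 for b in bursts if b.size_class == "small")
    n_large = sum(1 for b in bursts if b.size_class == "large")
    pool = bursts if spikes_per_burst_scope == "all" else [
        b for b in bursts if b.size_class == "small"]
    mean_spikes = float(np.mean([b.total_spikes for b in pool])) if pool else None
    return BurstSummary(
        n_small=n_small,
        n_large=n_large,
        n_small_per_5min=n_small * 300.0 / duration_s,
        n_large_per_10min=n_large * 600.0 / duration_s,
        mean_spikes_per_burst=mean_spikes,
        duration_s=duration_s,
    )


def bursts_to_frame(bursts: List[NetworkBurst]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.start_s, b.end_s, b.total_spikes, b.peak_bin_spikes, b.size_class)
         for b in bursts],
        columns=["start_s", "end_s", "total_spikes", "peak_bin_spikes", "class"],
    )


class NetworkBurstModel:
    """Network-burst analysis of one spike raster.

    Parameters
    ----------
    raster : SpikeRaster
    bin_width_s : float
        TSR bin width; 0.05 s by convention.
    min_spikes, min_electrodes : int
        Burst criterion: a bin qualifies with at least ``min_spikes``
        spikes over at least ``min_electrodes`` distinct electrodes.
    max_gap_bins : int
        Sub-threshold bins tolerated inside one burst (0 = none).
    """

    def __init__(self, raster: SpikeRaster, bin_width_s: float = 0.05,
                 min_spikes: int = 4, min_electrodes: int = 4,
                 max_gap_bins: int = 0):
        self.raster = raster
        self.bin_width_s = bin_width_s
        self.min_spikes = min_spikes
        self.min_electrodes = min_electrodes
        self.max_gap_bins = max_gap_bins

    def fit(self) -> "NetworkBurstResults":
        binned = compute_tsr(self.raster, self.bin_width_s)
        bursts = detect_network_bursts(
            binned, self.min_spikes, self.min_electrodes, self.max_gap_bins)
        summary = summarize_bursts(bursts, self.raster.duration_s)
        return NetworkBurstResults(self, binned, bursts, summary)


class NetworkBurstResults:
    """Results of :class:`NetworkBurstModel`: binned activity, detected
    bursts, and the normalized summary."""

    def __init__(self, model: NetworkBurstModel, binned: BinnedActivity,
                 bursts: List[NetworkBurst], summary: BurstSummary):
        self.model = model
        self.binned = binned
        self.bursts = bursts
        self.burst_summary = summary

    def to_frame(self) -> pd.DataFrame:
        """Burst table: start_s, end_s, total_spikes, peak_bin_spikes, class."""
        return bursts_to_frame(self.bursts)

    def summary(self) -> str:
        s = self.burst_summary
        mean_sp = ("%.1f" % s.mean_spikes_per_burst
                   if s.mean_spikes_per_burst is not None else "n/a")
        lines = [
            "Network burst analysis",
            "=" * 46,
            f"recording duration           {s.duration_s:10.1f} s",
            f"electrodes                   {self.binned.n_electrodes:10d}",
            f"total spikes                 {int(self.binned.tsr.sum()):10d}",
            f"small bursts                 {s.n_small:10d}",
            f"large bursts                 {s.n_large:10d}",
            f"small bursts / 5 min         {s.n_small_per_5min:10.1f}",
            f"large bursts / 10 min        {s.n_large_per_10min:10.1f}",
            f"mean spikes per burst        {mean_sp:>10}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Raster + TSR panel (spikes/50 ms over time, raster below)."""
        from .plotting import plot_raster_tsr
        return plot_raster_tsr(self.model.raster, self.binned,
                               bursts=self.bursts, ax=ax)
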