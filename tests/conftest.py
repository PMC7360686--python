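"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths:
they enumerate bins, spikes and delays with plain Python loops so that
agreement with the library is a meaningful check.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np
import pytest

from culturenet import SpikeRaster
from culturenet.bursts import NetworkBurst


@pytest.fixture
def hand_raster() -> SpikeRaster:
    """The worked TSR example: spikes A:0.01,0.02  B:0.03  C:0.06."""
    return SpikeRaster(
        ["A", "B", "C"],
        {"A": [0.01, 0.02], "B": [0.03], "C": [0.06]},
        duration_s=0.1,
    )


@pytest.fixture
def hand_trains():
    """The worked delayed-synchrony example (two 3-spike trains)."""
    pre = np.array([0.000, 0.100, 0.200])
    post = np.array([0.005, 0.105, 0.300])
    return pre, post


def random_raster(rng: np.random.Generator, max_electrodes: int = 10,
                  max_duration: float = 60.0) -> SpikeRaster:
    """A random raster with mixed per-electrode rates (may be bursty)."""
    n_el = int(rng.integers(1, max_electrodes + 1))
    duration = float(rng.uniform(1.0, max_duration))
    ids = [f"e{i}" for i in range(n_el)]
    times = {}
    for eid in ids:
        rate = float(rng.uniform(0.0, 5.0))
        n = rng.poisson(rate * duration)
        t = rng.uniform(0.0, duration, size=n)
        # occasionally add a synchronous cluster to exercise burst paths
        if rng.random() < 0.5:
            center = rng.uniform(0.0, duration)
            t = np.concatenate([t, center + rng.uniform(0, 0.04, size=8)])
            t = t[t <= duration]
        times[eid] = t
    return SpikeRaster(ids, times, duration)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_bursts(raster: SpikeRaster, bin_width_s: float = 0.05,
                       min_spikes: int = 4,
                       min_electrodes: int = 4) -> List[NetworkBurst]:
    """Test every bin by interval comparison, then merge contiguous runs."""
    n_bins = max(1, math.ceil(raster.duration_s / bin_width_s - 1e-9))
    per_bin = []
    for b in range(n_bins):
        lo = b * bin_width_s
        hi = (b + 1) * bin_width_s
        count = 0
        electrodes = 0
        for eid in raster.electrode_ids:
            c = 0
            for t in raster.spike_times[eid]:
                in_bin = lo <= t < hi
                if b == n_bins - 1 and t >= hi:  # clipped last partial bin
                    in_bin = True
                if in_bin:
                    c += 1
            count += c
            electrodes += 1 if c > 0 else 0
        per_bin.append((count, electrodes))
    bursts = []
    b = 0
    while b < n_bins:
        cnt, el = per_bin[b]
        if cnt >= min_spikes and el >= min_electrodes:
            start = b
            while b + 1 < n_bins and per_bin[b + 1][0] >= min_spikes \
                    and per_bin[b + 1][1] >= min_electrodes:
                b += 1
            end = b
            extent = [per_bin[k][0] for k in range(start, end + 1)]
            peak = max(extent)
            bursts.append(NetworkBurst(
                start_bin=start, end_bin=end,
                start_s=start * bin_width_s, end_s=(end + 1) * bin_width_s,
                total_spikes=sum(extent), peak_bin_spikes=peak,
                size_class="large" if peak >= 101 else "small"))
        b += 1
    return bursts


def brute_force_count(pre, post, tau, delta) -> int:
    """Quadratic loop: post spikes with any pre spike in the window."""
    n = 0
    for tj in post:
        for ti in pre:
            if tau - delta / 2 <= tj - ti < tau + delta / 2:
                n += 1
                break
    return n


def brute_force_c_matrix(raster: SpikeRaster, taus, delta):
    """Triple loop over (pre, post, tau); returns (C, best_tau, n_synchr)."""
    ids = raster.electrode_ids
    n = len(ids)
    c = np.zeros((n, n))
    best = np.zeros((n, n))
    nsyn = np.zeros((n, n), dtype=int)
    for j in range(n):
        post = raster.spike_times[ids[j]]
        if len(post) == 0:
            continue
        for i in range(n):
            if i == j:
                continue
            pre = raster.spike_times[ids[i]]
            best_count, best_tau = 0, 0.0
            for tau in taus:
                cnt = brute_force_count(pre, post, tau, delta)
                if cnt > best_count:
                    best_count, best_tau = cnt, tau
            if best_count > 0:
                c[i, j] = best_count / len(post)
                best[i, j] = best_tau
                nsyn[i, j] = best_count
    return c, best, nsyn
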