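"""Synthetic MEA recordings and calcium traces with planted ground truth.

The MEA generator emulates a cultured hippocampal network on a
59-electrode array: every electrode fires background spikes as a
homogeneous Poisson process, and a small set of *hub* electrodes
initiates network bursts.  A burst initiation emits a short spike packet
at the hub (10 spikes at 5-ms intervals by default), and every source
spike at electrode i triggers a spike at electrode j with probability
``w_ij`` after the edge's axonal delay plus Gaussian jitter.
Transmission is single-hop by default (followers do not re-propagate),
which keeps the planted connectivity directly recoverable by the
delayed-synchrony estimator.

The calcium generator plants transients with an instant rise and
exponential decay whose decay constant is solved so that the
time-above-threshold equals the requested event duration.  Event times
for active cells form a refractory renewal process (one transient
length plus two frames of dead time, exponential waiting beyond it)
whose mean rate equals the planted events/min; inactive cells are
noise-only.

Per-condition presets plant the group statistics printed for sham,
chronic-Abeta, Abeta+BDNF and 5xFAD cultures at the matching day in
vitro, so analysis-stage recovery can be tested against known truth.
All randomness flows from one seed through per-electrode / per-cell /
per-edge substreams, so outputs are reproducible independent of
iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import CalciumTraceSet, RecordingMetadata, SpikeRaster

__all__ = [
    "NetworkSpec",
    "CalciumSpec",
    "GroundTruth",
    "electrode_labels",
    "hub_network_spec",
    "generate_mea_recording",
    "generate_calcium_traces",
    "condition_preset",
    "preset_names",
]


def electrode_labels(n: int) -> List[str]:
    """Zero-padded electrode labels el01, el02, ..."""
    width = max(2, len(str(n)))
    return [f"el{i + 1:0{width}d}" for i in range(n)]


@dataclass
class NetworkSpec:
    """Planted hub-network specification for the MEA generator.

    ``adjacency`` maps ordered electrode pairs (pre, post) to
    transmission probabilities in [0, 1]; ``delays`` holds the matching
    axonal delays in seconds.  ``burst_rate_per_min`` is the rate of
    burst-initiation events *per hub*; ``burst_packet`` is
    ``(n_spikes, interval_s)`` emitted by the initiating hub.
    """

    n_electrodes: int = 59
    hub_ids: Sequence[str] = ()
    adjacency: Dict[Tuple[str, str], float] = field(default_factory=dict)
    delays: Dict[Tuple[str, str], float] = field(default_factory=dict)
    jitter_sd_s: float = 0.001
    background_rate_hz: float = 0.2
    burst_rate_per_min: float = 0.0
    burst_packet: Tuple[int, float] = (10, 0.005)
    max_hops: int = 1

    def __post_init__(self) -> None:
        self.validate()

    @property
    def electrode_ids(self) -> List[str]:
        return electrode_labels(self.n_electrodes)

    def validate(self) -> None:
        labels = set(electrode_labels(self.n_electrodes))
        if not set(map(str, self.hub_ids)) <= labels:
            raise ValueError("hub_ids must be a subset of the electrode set")
        for (i, j), w in self.adjacency.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"w[{i}->{j}] = {w} outside [0, 1]")
            if {i, j} - labels:
                raise ValueError(f"edge ({i}, {j}) outside the electrode set")
            if self.delays.get((i, j), 0.0) <= 0:
                raise ValueError(f"edge ({i}, {j}) needs a positive delay")
        if self.jitter_sd_s < 0 or self.background_rate_hz < 0 \
                or self.burst_rate_per_min < 0:
            raise ValueError("rates and jitter must be non-negative")
        n, dt = self.burst_packet
        if n < 1 or dt <= 0:
            raise ValueError("burst_packet must be (count >= 1, interval > 0)")
        if self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")


@dataclass
class CalciumSpec:
    """Planted statistics for the calcium-trace generator.

    ``active_fraction`` is the probability a cell is functionally
    active; active cells receive transients at ``event_rate_per_min``
    with time-above-threshold duration ``event_duration_s``.
    ``amplitude`` is the transient peak in dF/F units on a flat baseline
    (raw fluorescence ``baseline`` a.u.) with additive Gaussian noise
    ``noise_sd`` (raw units) and optional linear ``drift_per_min`` (raw
    units per minute).  ``offset_threshold_dff`` is the dF/F level that
    defines where a transient "ends"; it matches the default detector
    threshold (2.5 x the nominal dF/F noise SD).
    """

    n_cells: int = 100
    active_fraction: float = 0.7
    event_rate_per_min: float = 2.0
    event_duration_s: float = 8.0
    amplitude: float = 0.6
    noise_sd: float = 2.0
    baseline: float = 100.0
    drift_per_min: float = 0.0
    duration_s: float = 300.0
    frame_rate_hz: float = 2.0
    offset_threshold_dff: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if min(self.event_rate_per_min, self.event_duration_s,
               self.noise_sd) < 0:
            raise ValueError("rates, durations and noise must be >= 0")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude <= self.offset_threshold_dff:
            raise ValueError(
                "amplitude must exceed offset_threshold_dff, otherwise the "
                "transient never crosses the detection level")

    @property
    def decay_tau_s(self) -> float:
        """Decay constant solved so time above the offset threshold
        equals ``event_duration_s``."""
        return self.event_duration_s / math.log(
            self.amplitude / self.offset_threshold_dff)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class GroundTruth:
    """Planted structure exported alongside a synthetic recording."""

    # MEA part
    hub_ids: Optional[List[str]] = None
    adjacency: Optional[Dict[Tuple[str, str], float]] = None
    delays: Optional[Dict[Tuple[str, str], float]] = None
    burst_initiations: Optional[Dict[str, List[float]]] = None
    # calcium part
    active_cells: Optional[Dict[str, bool]] = None
    event_times: Optional[Dict[str, List[float]]] = None
    event_durations: Optional[Dict[str, List[float]]] = None

    def planted_edges(self) -> List[Tuple[str, str]]:
        return sorted(self.adjacency.keys()) if self.adjacency else []

    def to_json_dict(self) -> dict:
        d: dict = {}
        if self.hub_ids is not None:
            d["hub_ids"] = list(self.hub_ids)
            d["edges"] = [
                {"pre": i, "post": j, "w": w,
                 "delay_s": self.delays[(i, j)]}
                for (i, j), w in sorted(self.adjacency.items())]
            d["burst_initiations"] = {
                h: list(map(float, t))
                for h, t in self.burst_initiations.items()}
        if self.active_cells is not None:
            d["active_cells"] = dict(self.active_cells)
            d["event_times"] = {c: list(map(float, t))
                                for c, t in self.event_times.items()}
            d["event_durations"] = {c: list(map(float, t))
                                    for c, t in self.event_durations.items()}
        return d


# ---------------------------------------------------------------------------
# MEA generator


def _poisson_process(rng: np.random.Generator, rate_hz: float,
                     duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def generate_mea_recording(
    spec: NetworkSpec,
    duration_s: float,
    seed: int,
) -> Tuple[SpikeRaster, GroundTruth]:
    """Simulate one MEA recording from a planted hub network.

    Identical ``(spec, seed)`` gives bit-identical output.  Spikes whose
    transmission delay lands beyond ``duration_s`` are truncated.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    spec.validate()
    ids = spec.electrode_ids
    hubs = [str(h) for h in spec.hub_ids]
    edges = sorted(spec.adjacency.keys())

    root = np.random.SeedSequence(seed)
    bg_seed, burst_seed, trans_seed = root.spawn(3)
    bg_streams = bg_seed.spawn(len(ids))
    hub_streams = burst_seed.spawn(max(1, len(hubs)))
    edge_streams = trans_seed.spawn(max(1, len(edges)))

    spikes: Dict[str, List[np.ndarray]] = {eid: [] for eid in ids}

    # background firing, one independent stream per electrode
    for eid, ss in zip(ids, bg_streams):
        rng = np.random.default_rng(ss)
        spikes[eid].append(_poisson_process(rng, spec.background_rate_hz,
                                            duration_s))

    # burst-initiation packets at hubs
    n_packet, packet_dt = spec.burst_packet
    offsets = np.arange(n_packet) * packet_dt
    initiations: Dict[str, List[float]] = {h: [] for h in hubs}
    for h, ss in zip(hubs, hub_streams):
        rng = np.random.default_rng(ss)
        t0s = _poisson_process(rng, spec.burst_rate_per_min / 60.0, duration_s)
        initiations[h] = [float(t) for t in t0s]
        if t0s.size:
            packet = (t0s[:, None] + offsets[None, :]).ravel()
            spikes[h].append(packet[packet <= duration_s])

    # single-hop (or limited multi-hop) transmission along planted edges;
    # uniform/jitter draws are made for every source spike regardless of w,
    # giving a monotone coupling of transmitted counts in w
    sources = {eid: np.sort(np.concatenate(spikes[eid])) if spikes[eid]
               else np.empty(0) for eid in ids}
    edge_rngs = {e: np.random.default_rng(ss)
                 for e, ss in zip(edges, edge_streams)}
    for _hop in range(spec.max_hops):
        received: Dict[str, List[np.ndarray]] = {eid: [] for eid in ids}
        for (i, j) in edges:
            src = sources[i]
            if src.size == 0:
                continue
            rng = edge_rngs[(i, j)]
            u = rng.random(src.size)
            jit = rng.normal(0.0, spec.jitter_sd_s, src.size)
            sent = u < spec.adjacency[(i, j)]
            arr = src[sent] + spec.delays[(i, j)] + jit[sent]
            arr = arr[(arr >= 0.0) & (arr <= duration_s)]
            received[j].append(arr)
        for eid in ids:
            if received[eid]:
                spikes[eid].extend(received[eid])
        sources = {eid: (np.sort(np.concatenate(received[eid]))
                         if received[eid] else np.empty(0)) for eid in ids}

    spike_times = {eid: np.sort(np.concatenate(spikes[eid])) if spikes[eid]
                   else np.empty(0) for eid in ids}
    raster = SpikeRaster(
        ids, spike_times, duration_s,
        metadata=RecordingMetadata(duration_s=duration_s, electrode_ids=ids))
    truth = GroundTruth(hub_ids=hubs, adjacency=dict(spec.adjacency),
                        delays=dict(spec.delays),
                        burst_initiations=initiations)
    return raster, truth


def hub_network_spec(
    n_electrodes: int = 59,
    n_hubs: int = 5,
    n_followers: int = 10,
    w: float = 0.8,
    delay_min_s: float = 0.002,
    delay_max_s: float = 0.010,
    burst_rate_per_min: float = 8.7,
    background_rate_hz: float = 0.2,
    jitter_sd_s: float = 0.001,
    burst_packet: Tuple[int, float] = (10, 0.005),
) -> NetworkSpec:
    """Build a planted network: ``n_hubs`` hubs, each wired to its own
    block of ``n_followers`` follower electrodes with evenly spaced
    axonal delays in ``[delay_min_s, delay_max_s]``.

    The construction is deterministic (no randomness lives in the spec),
    so the same spec can be replayed under many seeds.
    """
    if n_hubs * (n_followers + 1) > n_electrodes:
        raise ValueError(
            f"{n_hubs} hubs x {n_followers} distinct followers need "
            f"{n_hubs * (n_followers + 1)} electrodes, have {n_electrodes}")
    ids = electrode_labels(n_electrodes)
    hubs = ids[:n_hubs]
    adjacency: Dict[Tuple[str, str], float] = {}
    delays: Dict[Tuple[str, str], float] = {}
    if n_followers == 1:
        steps = np.array([0.5])
    else:
        steps = np.linspace(0.0, 1.0, n_followers)
    for h_idx, h in enumerate(hubs):
        block = ids[n_hubs + h_idx * n_followers:
                    n_hubs + (h_idx + 1) * n_followers]
        for k, f in enumerate(block):
            adjacency[(h, f)] = w
            delays[(h, f)] = delay_min_s + steps[k] * (delay_max_s - delay_min_s)
    return NetworkSpec(
        n_electrodes=n_electrodes, hub_ids=hubs, adjacency=adjacency,
        delays=delays, jitter_sd_s=jitter_sd_s,
        background_rate_hz=background_rate_hz,
        burst_rate_per_min=burst_rate_per_min, burst_packet=burst_packet)


# ---------------------------------------------------------------------------
# calcium generator


def _event_times_renewal(rng: np.random.Generator, rate_per_min: float,
                         duration_s: float, dead_time_s: float) -> np.ndarray:
    """Refractory renewal process with mean rate ``rate_per_min``.

    Gaps are ``dead_time_s`` plus an exponential wait whose mean is
    corrected so the overall mean inter-event interval is
    ``60 / rate_per_min``.
    """
    if rate_per_min <= 0:
        return np.empty(0)
    target_gap = 60.0 / rate_per_min
    exp_mean = target_gap - dead_time_s
    if exp_mean <= 0:
        raise ValueError(
            f"event rate {rate_per_min}/min is infeasible for transients "
            f"with {dead_time_s:.1f}-s dead time")
    times = []
    t = rng.exponential(exp_mean)
    while t <= duration_s:
        times.append(t)
        t += dead_time_s + rng.exponential(exp_mean)
    return np.asarray(times)


def generate_calcium_traces(
    spec: CalciumSpec,
    seed: int,
) -> Tuple[CalciumTraceSet, GroundTruth]:
    """Simulate fluorescence traces with planted transients.

    Each active cell receives refractory-renewal event times at the
    planted rate; every event adds an instant-rise, exponential-decay
    transient scaled so the time above ``offset_threshold_dff`` equals
    the planted duration.  Inactive cells are noise-only.  Identical
    ``(spec, seed)`` gives identical traces.
    """
    spec.validate()
    n_frames = spec.n_frames
    if n_frames < 2:
        raise ValueError("duration_s x frame_rate_hz must give >= 2 frames")
    cell_ids = [f"cell{c + 1:03d}" for c in range(spec.n_cells)]
    t_frames = np.arange(n_frames) / spec.frame_rate_hz

    root = np.random.SeedSequence(seed)
    flag_seed, cells_seed = root.spawn(2)
    active = (np.random.default_rng(flag_seed).random(spec.n_cells)
              < spec.active_fraction)
    cell_streams = cells_seed.spawn(max(1, spec.n_cells))

    dead_time = spec.event_duration_s + 2.0 / spec.frame_rate_hz
    tau_d = spec.decay_tau_s if spec.event_duration_s > 0 else None

    traces = np.empty((spec.n_cells, n_frames))
    event_times: Dict[str, List[float]] = {}
    event_durations: Dict[str, List[float]] = {}
    for c, (cid, ss) in enumerate(zip(cell_ids, cell_streams)):
        rng = np.random.default_rng(ss)
        signal = np.zeros(n_frames)
        times: List[float] = []
        if active[c] and spec.event_rate_per_min > 0 \
                and spec.event_duration_s > 0:
            t0s = _event_times_renewal(rng, spec.event_rate_per_min,
                                       spec.duration_s, dead_time)
            times = [float(t) for t in t0s]
            for t0 in t0s:
                dt = t_frames - t0
                mask = dt >= 0
                signal[mask] += spec.amplitude * np.exp(-dt[mask] / tau_d)
        noise = rng.normal(0.0, spec.noise_sd, n_frames) if spec.noise_sd > 0 \
            else np.zeros(n_frames)
        drift = spec.drift_per_min * t_frames / 60.0
        traces[c] = spec.baseline * (1.0 + signal) + drift + noise
        event_times[cid] = times
        event_durations[cid] = [spec.event_duration_s] * len(times)

    trace_set = CalciumTraceSet(cell_ids, traces,
                                frame_rate_hz=spec.frame_rate_hz,
                                duration_s=spec.duration_s)
    truth = GroundTruth(
        active_cells={cid: bool(a) for cid, a in zip(cell_ids, active)},
        event_times=event_times, event_durations=event_durations)
    return trace_set, truth


# ---------------------------------------------------------------------------
# condition presets

# Calcium entries plant printed group statistics (percent active cells,
# oscillations/min, oscillation duration in s) for the matching group and
# day in vitro; durations marked "derived" use the printed same-day sham
# value or the printed fold-change.  MEA entries are calibrated so the
# planted burst-initiation totals land near the printed small-burst rates
# (bursts/5 min = burst_rate_per_min x n_hubs x 5).
_CAL = dict(n_cells=100, duration_s=300.0, frame_rate_hz=2.0)
_PRESETS: Dict[str, dict] = {
    "sham_DIV21": dict(
        calcium=dict(active_fraction=0.8006, event_rate_per_min=1.94,
                     event_duration_s=8.26, **_CAL),
        mea=dict(n_hubs=5, n_followers=10, w=0.8,
                 burst_rate_per_min=217.5 / 5 / 5)),
    "sham_DIV28": dict(
        calcium=dict(active_fraction=0.687, event_rate_per_min=2.49,
                     event_duration_s=6.2, **_CAL),
        mea=dict(n_hubs=5, n_followers=10, w=0.8,
                 burst_rate_per_min=253.7 / 5 / 5)),
    "abeta_DIV21": dict(
        calcium=dict(active_fraction=0.2901, event_rate_per_min=1.14,
                     event_duration_s=10.3, **_CAL),
        mea=dict(n_hubs=1, n_followers=4, w=0.3,
                 burst_rate_per_min=74.3 / 5)),
    "abeta_DIV28": dict(
        calcium=dict(active_fraction=0.1718, event_rate_per_min=0.35,
                     event_duration_s=13.24, **_CAL),
        mea=dict(n_hubs=1, n_followers=4, w=0.2,
                 burst_rate_per_min=50.1 / 5)),
    "abeta_bdnf_DIV21": dict(
        calcium=dict(active_fraction=0.6931, event_rate_per_min=2.38,
                     event_duration_s=8.26, **_CAL),
        mea=dict(n_hubs=4, n_followers=10, w=0.7,
                 burst_rate_per_min=131.8 / 5 / 4)),
    "fiveXFAD_DIV21": dict(
        calcium=dict(active_fraction=0.443, event_rate_per_min=1.16,
                     event_duration_s=1.55 * 8.26, **_CAL),
        # no MEA recordings exist for this cohort: qualitative stand-in
        mea=dict(n_hubs=1, n_followers=5, w=0.4, burst_rate_per_min=10.0)),
    "fiveXFAD_DIV28": dict(
        calcium=dict(active_fraction=0.355, event_rate_per_min=1.44,
                     event_duration_s=1.75 * 6.2, **_CAL),
        mea=dict(n_hubs=1, n_followers=5, w=0.4, burst_rate_per_min=8.0)),
    "control_DIV21": dict(
        calcium=dict(active_fraction=0.782, event_rate_per_min=1.94,
                     event_duration_s=8.26, **_CAL),
        mea=dict(n_hubs=5, n_followers=10, w=0.8,
                 burst_rate_per_min=217.5 / 5 / 5)),
    "control_DIV28": dict(
        calcium=dict(active_fraction=0.65, event_rate_per_min=2.64,
                     event_duration_s=6.2, **_CAL),
        mea=dict(n_hubs=5, n_followers=10, w=0.8,
                 burst_rate_per_min=253.7 / 5 / 5)),
}


def preset_names() -> List[str]:
    return sorted(_PRESETS.keys())


def condition_preset(name: str) -> Tuple[NetworkSpec, CalciumSpec]:
    """Return the planted (NetworkSpec, CalciumSpec) for a condition token.

    Unknown tokens raise a ValueError listing the registry.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown condition preset {name!r}; valid presets: "
            + ", ".join(preset_names()))
    entry = _PRESETS[name]
    return hub_network_spec(**entry["mea"]), CalciumSpec(**entry["calcium"])
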