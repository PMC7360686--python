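"""Domain containers and text-format readers/writers.

The package works with three kinds of primary data:

* spike rasters from multielectrode-array (MEA) recordings, stored as
  delimited tables of ``(electrode_id, spike_time_s)`` with a JSON
  sidecar holding recording metadata,
* calcium fluorescence trace matrices (one row per cell ROI), and
* directed functional graphs with per-edge synchrony weight and best
  axonal delay, written either as GraphML or as a plain edge-list text
  format that preserves isolated nodes.

Canonical time unit is seconds throughout; acquisition sample indices
are converted on ingest. Electrode labels are opaque strings and matrix
positions are never exposed in files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SpikeRaster",
    "RecordingMetadata",
    "CalciumTraceSet",
    "Violation",
    "read_spike_table",
    "write_spike_table",
    "read_trace_matrix",
    "write_trace_matrix",
    "validate_raster",
    "write_graph",
    "read_graph",
    "validate_graph",
]

# float format that round-trips IEEE doubles exactly through text
_FFMT = "%.17g"


@dataclass
class RecordingMetadata:
    """Acquisition and experimental metadata for one MEA recording.

    Parameters
    ----------
    sampling_rate_hz : float
        Acquisition rate of the amplifier (20 kHz per channel for the
        recordings this package emulates).
    array_pitch_um : float, optional
        Electrode grid spacing in micrometres (200 for an 8x8 array).
    condition_label : str, optional
        Experimental group tag (free text, e.g. ``"sham"``).
    div : int, optional
        Day in vitro of the culture at recording time.
    duration_s : float, optional
        Recording length; required when reading a spike table that has
        no sidecar file.
    electrode_ids : sequence of str, optional
        Declared electrode set.  Electrodes declared here but absent
        from the table are kept as silent electrodes.
    """

    sampling_rate_hz: float = 20000.0
    array_pitch_um: Optional[float] = 200.0
    condition_label: Optional[str] = None
    div: Optional[int] = None
    duration_s: Optional[float] = None
    electrode_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


@dataclass
class SpikeRaster:
    """Per-electrode sorted spike times plus the recording duration.

    ``spike_times`` maps electrode label -> sorted float array of spike
    times in seconds.  Electrodes with no spikes are retained with empty
    arrays (they can never be hubs but remain graph nodes).
    """

    electrode_ids: List[str]
    spike_times: Dict[str, np.ndarray]
    duration_s: float
    metadata: Optional[RecordingMetadata] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        self.electrode_ids = [str(e) for e in self.electrode_ids]
        times = {}
        for eid in self.electrode_ids:
            t = np.asarray(self.spike_times.get(eid, ()), dtype=float)
            times[eid] = np.sort(t)
        self.spike_times = times

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times.values()))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns electrode_id, spike_time_s."""
        rows = [
            (eid, t)
            for eid in self.electrode_ids
            for t in self.spike_times[eid]
        ]
        return pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"])


@dataclass
class CalciumTraceSet:
    """Fluorescence traces, one row per cell ROI, sampled at a fixed rate."""

    cell_ids: List[str]
    traces: np.ndarray
    frame_rate_hz: float = 2.0
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length does not match trace rows")
        if self.duration_s is None:
            self.duration_s = self.n_frames / self.frame_rate_hz
        elif round(self.duration_s * self.frame_rate_hz) != self.n_frames:
            raise ValueError(
                "frames != round(duration_s * frame_rate_hz): "
                f"{self.n_frames} vs {self.duration_s * self.frame_rate_hz}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_raster`."""

    electrode_id: Optional[str]
    rule: str
    severity: str  # "error" | "warning"
    message: str


# ---------------------------------------------------------------------------
# spike tables


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_spike_table(path, metadata: Optional[RecordingMetadata] = None) -> SpikeRaster:
    """Read a delimited ``(electrode_id, spike_time_s)`` table.

    The delimiter is chosen by extension (``.csv`` comma, otherwise
    tab).  If ``<path>.meta.json`` exists it supplies duration,
    declared electrodes and acquisition metadata; an explicit
    ``metadata`` argument overrides the sidecar.  Times are sorted per
    electrode on load; no spike is ever silently dropped.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if metadata is None and side.exists():
        metadata = _metadata_from_json(json.loads(side.read_text()))
    if metadata is None or metadata.duration_s is None:
        raise ValueError(
            f"recording duration unknown for {path}: provide metadata or a "
            f"sidecar file {side.name}"
        )
    duration = float(metadata.duration_s)

    try:
        df = pd.read_csv(path, sep=_sep_for(path),
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["electrode_id", "spike_time_s"])
    required = {"electrode_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.nonzero(~np.isfinite(times.to_numpy()))[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: malformed spike_time_s at line {int(bad[0]) + 2}"
        )
    tvals = times.to_numpy(dtype=float)
    if tvals.size and (tvals.min() < 0 or tvals.max() > duration):
        i = int(np.nonzero((tvals < 0) | (tvals > duration))[0][0])
        raise ValueError(
            f"{path}: spike time {tvals[i]} outside [0, {duration}] "
            f"(electrode {df['electrode_id'].iloc[i]})"
        )

    labels = df["electrode_id"].astype(str).to_numpy()
    electrode_ids: List[str] = (
        [str(e) for e in metadata.electrode_ids]
        if metadata.electrode_ids is not None
        else sorted(set(labels))
    )
    known = set(electrode_ids)
    extra = [l for l in labels if l not in known]
    if extra:
        # table mentions electrodes not declared: keep them, appended
        for l in dict.fromkeys(extra):
            electrode_ids.append(l)
    spike_times = {eid: tvals[labels == eid] for eid in electrode_ids}
    return SpikeRaster(electrode_ids, spike_times, duration, metadata=metadata)


def _metadata_to_json(md: RecordingMetadata) -> dict:
    return {
        "sampling_rate_hz": md.sampling_rate_hz,
        "array_pitch_um": md.array_pitch_um,
        "condition_label": md.condition_label,
        "div": md.div,
        "duration_s": md.duration_s,
        "electrode_ids": list(md.electrode_ids) if md.electrode_ids is not None else None,
    }


def _metadata_from_json(d: dict) -> RecordingMetadata:
    return RecordingMetadata(
        sampling_rate_hz=d.get("sampling_rate_hz", 20000.0),
        array_pitch_um=d.get("array_pitch_um"),
        condition_label=d.get("condition_label"),
        div=d.get("div"),
        duration_s=d.get("duration_s"),
        electrode_ids=d.get("electrode_ids"),
    )


def write_spike_table(raster: SpikeRaster, path, write_sidecar: bool = True) -> None:
    """Write a raster as a delimited table plus a JSON metadata sidecar."""
    path = Path(path)
    df = raster.to_frame()
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FFMT)
    if write_sidecar:
        md = raster.metadata or RecordingMetadata()
        d = _metadata_to_json(md)
        d["duration_s"] = raster.duration_s
        d["electrode_ids"] = list(raster.electrode_ids)
        _sidecar_path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def validate_raster(raster: SpikeRaster) -> List[Violation]:
    """Check the raster invariants; reports rather than raises.

    Returns an empty list iff all invariants hold.  Duplicate identical
    spike times on one electrode are permitted (they contribute to
    counts) but reported at warning level.
    """
    out: List[Violation] = []
    if raster.duration_s <= 0:
        out.append(Violation(None, "duration_positive", "error",
                             f"duration_s = {raster.duration_s}"))
    if raster.n_electrodes != len(raster.electrode_ids):
        out.append(Violation(None, "electrode_count", "error",
                             "n_electrodes != len(electrode_ids)"))
    for eid in raster.electrode_ids:
        t = raster.spike_times[eid]
        if t.size == 0:
            continue
        if t.min() < 0 or t.max() > raster.duration_s:
            out.append(Violation(eid, "time_in_range", "error",
                                 f"spike outside [0, {raster.duration_s}]"))
        if np.any(np.diff(t) < 0):
            out.append(Violation(eid, "sorted_times", "error",
                                 "spike times not sorted"))
        ndup = int(t.size - np.unique(t).size)
        if ndup:
            out.append(Violation(eid, "duplicate_times", "warning",
                                 f"{ndup} duplicated spike time(s)"))
    return out


# ---------------------------------------------------------------------------
# calcium trace matrices


def read_trace_matrix(path, frame_rate_hz: Optional[float] = None) -> CalciumTraceSet:
    """Read a trace matrix: first column cell_id, remaining columns frames."""
    path = Path(path)
    side = _sidecar_path(path)
    if frame_rate_hz is None:
        if side.exists():
            frame_rate_hz = json.loads(side.read_text()).get("frame_rate_hz", 2.0)
        else:
            frame_rate_hz = 2.0
    df = pd.read_csv(path, sep=_sep_for(path),
                     float_precision="round_trip")
    cell_ids = df.iloc[:, 0].astype(str).tolist()
    traces = df.iloc[:, 1:].to_numpy(dtype=float)
    return CalciumTraceSet(cell_ids, traces, frame_rate_hz=float(frame_rate_hz))


def write_trace_matrix(traces: CalciumTraceSet, path, write_sidecar: bool = True) -> None:
    path = Path(path)
    cols = [f"f{i}" for i in range(traces.n_frames)]
    df = pd.DataFrame(traces.traces, columns=cols)
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FFMT)
    if write_sidecar:
        _sidecar_path(path).write_text(json.dumps(
            {"frame_rate_hz": traces.frame_rate_hz,
             "duration_s": traces.duration_s}, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# functional graphs


def _infer_graph_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("edgelist", "graphml"):
            raise ValueError(
                f"unknown graph format {fmt!r}: use 'edgelist' or 'graphml'")
        return fmt
    return "graphml" if path.suffix.lower() == ".graphml" else "edgelist"


def write_graph(graph: nx.DiGraph, path, fmt: Optional[str] = None) -> None:
    """Serialize a functional graph (GraphML or text edge list).

    The edge-list format keeps isolated nodes::

        # nodes
        <id>\t<degree>
        # edges
        <src>\t<dst>\t<weight>\t<tau>
    """
    path = Path(path)
    fmt = _infer_graph_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    lines = ["# nodes"]
    for n in graph.nodes:
        deg = graph.nodes[n].get("degree", graph.in_degree(n) + graph.out_degree(n))
        lines.append(f"{n}\t{deg}")
    lines.append("# edges")
    for u, v, d in graph.edges(data=True):
        w = _FFMT % d.get("weight", 1.0)
        tau = _FFMT % d.get("tau", 0.0)
        lines.append(f"{u}\t{v}\t{w}\t{tau}")
    path.write_text("\n".join(lines) + "\n")


def read_graph(path, fmt: Optional[str] = None) -> nx.DiGraph:
    path = Path(path)
    fmt = _infer_graph_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return nx.DiGraph(g)
    g = nx.DiGraph()
    section = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line == "# nodes":
            section = "nodes"
            continue
        if line == "# edges":
            section = "edges"
            continue
        parts = line.split("\t")
        if section == "nodes":
            g.add_node(parts[0], degree=int(parts[1]))
        elif section == "edges":
            u, v, w, tau = parts
            g.add_edge(u, v, weight=float(w), tau=float(tau))
        else:
            raise ValueError(f"{path}: line outside a section: {line!r}")
    return g


def validate_graph(graph: nx.DiGraph) -> List[str]:
    """Check functional-graph invariants; returns messages (empty = OK)."""
    problems = []
    for u, v, d in graph.edges(data=True):
        w = d.get("weight")
        if w is None or not (0.0 <= w <= 1.0):
            problems.append(f"edge {u}->{v}: weight {w} outside [0, 1]")
    for n in graph.nodes:
        deg = graph.nodes[n].get("degree")
        actual = graph.in_degree(n) + graph.out_degree(n)
        if deg is not None and deg != actual:
            problems.append(f"node {n}: degree attribute {deg} != incident edges {actual}")
    return problems
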