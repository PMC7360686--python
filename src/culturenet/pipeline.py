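"""Config-driven end-to-end runs: simulate/load -> analyze -> report.

A run config declares groups (either condition presets to simulate or
paths to recorded spike tables / trace matrices), the analysis
parameters, an output directory and one master seed.  Every recording
produces a burst summary, a connectivity result with hub table and
GraphML graph, and (when traces exist) a calcium summary; group-level
tables aggregate the per-recording statistics as mean +/- SEM.  All
outputs are listed in a manifest with SHA-256 checksums and the exact
config is echoed, so a rerun with the same config and seed is
byte-identical.  Inferential statistics across groups (ANOVA and post
hoc tests) are deliberately out of scope: the tidy tables are the
interface to external statistics tools.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bursts as _bursts
from . import calcium as _calcium
from . import connectivity as _conn
from . import simulate as _sim
from .io import (SpikeRaster, read_spike_table, read_trace_matrix,
                 write_graph, write_spike_table, write_trace_matrix)

__all__ = ["RunConfig", "GroupConfig", "run_pipeline", "render_figures",
           "PipelineError", "PipelineResult"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage and the recording."""

    def __init__(self, stage: str, recording_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for recording "
                         f"{recording_id!r}: {cause}")
        self.stage = stage
        self.recording_id = recording_id
        self.cause = cause


@dataclass
class GroupConfig:
    """One experimental group: either a preset to simulate or input paths."""

    name: str
    preset: Optional[str] = None
    n_recordings: int = 1
    spike_tables: List[str] = field(default_factory=list)
    trace_matrices: List[str] = field(default_factory=list)
    simulate_calcium: bool = True


@dataclass
class RunConfig:
    groups: List[GroupConfig]
    out_dir: str
    seed: int = 0
    duration_s: float = 300.0
    bin_width_s: float = 0.05
    min_spikes: int = 4
    min_electrodes: int = 4
    tau_min_s: float = 0.001
    tau_max_s: float = 0.020
    tau_step_s: float = 0.001
    delta_s: float = 0.002
    edge_fraction: float = 0.05
    hub_min_connections: int = 10
    threshold_sd: float = 2.5
    min_event_duration_s: float = 1.0
    figures: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        groups = [GroupConfig(**g) for g in d.pop("groups")]
        return cls(groups=groups, **d)

    def to_json_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "groups"}
        d["groups"] = [dict(g.__dict__) for g in self.groups]
        return d

    def delay_params(self) -> _conn.DelayParams:
        grid = np.arange(self.tau_min_s, self.tau_max_s + self.tau_step_s / 2,
                         self.tau_step_s)
        return _conn.DelayParams(tau_grid_s=grid, delta_s=self.delta_s)


@dataclass
class PipelineResult:
    """Report bundle: per-recording records plus group aggregates."""

    out_dir: Path
    records: List[dict]
    aggregates: Dict[str, pd.DataFrame]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _sem(x: pd.Series) -> float:
    x = x.dropna()
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def _derive_seed(master: int, index: int) -> int:
    # stable per-recording seed, kept below 2**31
    return int((master * 100003 + 7919 * index + 1) % (2 ** 31))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every recording of every group and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _json_dump(config.to_json_dict(), out / "config.json")
    params = config.delay_params()
    records: List[dict] = []
    written: List[Path] = [out / "config.json"]
    index = 0

    for group in config.groups:
        inputs: List[dict] = []
        if group.preset is not None:
            for r in range(group.n_recordings):
                inputs.append({"kind": "preset", "replicate": r})
        for p in group.spike_tables:
            inputs.append({"kind": "file", "spike_table": p})

        for inp in inputs:
            rec_id = f"{group.name}_{index:03d}"
            rec_dir = out / rec_id
            rec_dir.mkdir(exist_ok=True)
            seed = _derive_seed(config.seed, index)
            index += 1
            rec: dict = {"recording_id": rec_id, "group": group.name,
                         "seed": seed}

            # --- obtain raster (and traces) -----------------------------
            traces = None
            try:
                if inp["kind"] == "preset":
                    net_spec, cal_spec = _sim.condition_preset(group.preset)
                    raster, truth = _sim.generate_mea_recording(
                        net_spec, config.duration_s, seed)
                    write_spike_table(raster, rec_dir / "raster.tsv")
                    written += [rec_dir / "raster.tsv",
                                rec_dir / "raster.tsv.meta.json"]
                    if group.simulate_calcium:
                        traces, ca_truth = _sim.generate_calcium_traces(
                            cal_spec, seed)
                        write_trace_matrix(traces, rec_dir / "traces.tsv")
                        written += [rec_dir / "traces.tsv",
                                    rec_dir / "traces.tsv.meta.json"]
                        truth_d = truth.to_json_dict()
                        truth_d.update(ca_truth.to_json_dict())
                    else:
                        truth_d = truth.to_json_dict()
                    _json_dump(truth_d, rec_dir / "truth.json")
                    written.append(rec_dir / "truth.json")
                else:
                    raster = read_spike_table(inp["spike_table"])
                    ti = inputs.index(inp)
                    if ti < len(group.trace_matrices):
                        traces = read_trace_matrix(group.trace_matrices[ti])
            except Exception as e:  # noqa: BLE001
                raise PipelineError("input", rec_id, e) from e

            # --- burst analysis -----------------------------------------
            try:
                burst_res = _bursts.NetworkBurstModel(
                    raster, config.bin_width_s, config.min_spikes,
                    config.min_electrodes).fit()
                burst_res.to_frame().to_csv(
                    rec_dir / "bursts.tsv", sep="\t", index=False,
                    float_format="%.17g")
                _json_dump(burst_res.burst_summary.to_dict(),
                           rec_dir / "burst_summary.json")
                written += [rec_dir / "bursts.tsv",
                            rec_dir / "burst_summary.json"]
                rec.update(burst_res.burst_summary.to_dict())
            except Exception as e:  # noqa: BLE001
                raise PipelineError("bursts", rec_id, e) from e

            # --- connectivity -------------------------------------------
            try:
                conn_res = _conn.DelayedSynchronyModel(
                    raster, params,
                    edge_fraction=config.edge_fraction,
                    hub_min_connections=config.hub_min_connections).fit()
                edges = conn_res.select_edges()
                hubs = conn_res.hub_table(edges)
                hubs.to_csv(rec_dir / "hubs.tsv", sep="\t", index=False)
                write_graph(conn_res.graph(edges), rec_dir / "graph.graphml")
                written += [rec_dir / "hubs.tsv", rec_dir / "graph.graphml"]
                rec["n_hubs"] = int(hubs["is_hub"].sum())
                rec["mean_hub_connections"] = hubs.attrs["mean_hub_connections"]
            except Exception as e:  # noqa: BLE001
                raise PipelineError("connectivity", rec_id, e) from e

            # --- calcium -------------------------------------------------
            if traces is not None:
                try:
                    ca_res = _calcium.CalciumEventModel(
                        traces, threshold_sd=config.threshold_sd,
                        min_duration_s=config.min_event_duration_s).fit()
                    ca_res.to_frame().to_csv(
                        rec_dir / "calcium_events.tsv", sep="\t", index=False,
                        float_format="%.17g")
                    _json_dump(ca_res.calcium_summary.to_dict(),
                               rec_dir / "calcium_summary.json")
                    written += [rec_dir / "calcium_events.tsv",
                                rec_dir / "calcium_summary.json"]
                    rec.update({
                        "pct_active_cells":
                            ca_res.calcium_summary.pct_active_cells,
                        "ca_rate_per_min":
                            ca_res.calcium_summary.mean_rate_per_min,
                        "ca_duration_s":
                            ca_res.calcium_summary.mean_duration_s,
                    })
                except Exception as e:  # noqa: BLE001
                    raise PipelineError("calcium", rec_id, e) from e

            records.append(rec)

    # --- aggregates ------------------------------------------------------
    rec_df = pd.DataFrame(records)
    rec_df.to_csv(out / "recordings.tsv", sep="\t", index=False,
                  float_format="%.17g")
    written.append(out / "recordings.tsv")
    agg_cols = [c for c in (
        "n_small_per_5min", "n_large_per_10min", "mean_spikes_per_burst",
        "n_hubs", "mean_hub_connections", "pct_active_cells",
        "ca_rate_per_min", "ca_duration_s") if c in rec_df.columns]
    aggregates: Dict[str, pd.DataFrame] = {}
    if agg_cols:
        grouped = rec_df.groupby("group")[agg_cols]
        agg = pd.concat({"mean": grouped.mean(), "sem": grouped.agg(_sem)},
                        axis=1).swaplevel(axis=1).sort_index(axis=1)
        agg.columns = [f"{stat}_{meas}" for stat, meas in agg.columns]
        agg = agg.reset_index()
        agg.to_csv(out / "group_summary.tsv", sep="\t", index=False,
                   float_format="%.17g")
        written.append(out / "group_summary.tsv")
        aggregates["group_summary"] = agg

    manifest = {
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(set(written))},
        "n_recordings": len(records),
        "seed": config.seed,
    }
    _json_dump(manifest, out / "manifest.json")
    result = PipelineResult(out_dir=out, records=records,
                            aggregates=aggregates, manifest=manifest)
    if config.figures:
        render_figures(result, config)
    return result


def render_figures(result: PipelineResult,
                   config: Optional[RunConfig] = None,
                   layout_seed: int = 0) -> List[Path]:
    """Raster + TSR panel and graph panel per recording (PNG files)."""
    import matplotlib.pyplot as plt

    from .io import read_graph
    from .plotting import plot_functional_graph, plot_raster_tsr

    config = config or RunConfig(groups=[], out_dir=str(result.out_dir))
    paths: List[Path] = []
    for rec in result.records:
        rec_dir = result.out_dir / rec["recording_id"]
        raster_path = rec_dir / "raster.tsv"
        if raster_path.exists():
            raster = read_spike_table(raster_path)
            res = _bursts.NetworkBurstModel(
                raster, config.bin_width_s, config.min_spikes,
                config.min_electrodes).fit()
            fig = res.plot()
            p = rec_dir / "raster_tsr.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
        graph_path = rec_dir / "graph.graphml"
        if graph_path.exists():
            g = read_graph(graph_path)
            fig = plot_functional_graph(g, seed=layout_seed)
            p = rec_dir / "graph.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths
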