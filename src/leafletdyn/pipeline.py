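"""Configuration-driven orchestration: simulate → analyse → report.

A YAML config (validated with pydantic; unknown keys are rejected by name)
describes which stages to run and their parameters.  ``run`` executes the
stages in order, writes TSV/JSON outputs into the output directory and
returns a machine-readable summary embedding the seed and a hash of the
canonical config, so a rerun with the same config and seed is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .fate import enumerate_fates
from .pairs import RDFConfig, cluster_timeseries, radial_distribution
from .synthetic import (
    LangevinParams,
    PairInteraction,
    SimulationComposition,
    simulate_area_traces,
    simulate_fluorescence_traces,
    simulate_solute_trajectories,
    ztraces_from_trajectory,
)
from .transitions import TransitionConfig, height_histogram, summarize_transitions
from .transport import SampleContext, detect_lysis, percent_transport_quench
from .trajectory import write_ztrace_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "load_config", "run"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Strict):
    simulate: bool = True
    transitions: bool = True
    histograms: bool = True
    rdf: bool = True
    clusters: bool = True
    transport: bool = True
    fate: bool = True


class SimulationBlock(_Strict):
    n_replicas: int = 4
    n_steps: int = 50_000
    timestep: float = 0.02
    frame_stride: int = 10
    barrier_height: float = 4.0
    box_xy: float = 6.3
    n_a: int = 1
    n_b: int = 1
    n_c: int = 0
    epsilon: float = 6.0
    kappa: float = 4.0
    sigma_r: float = 1.0
    sigma_z: float = 0.5
    threshold_a: float = 0.7
    threshold_b: float = 0.6
    threshold_c: float = 0.7


class TransportBlock(_Strict):
    n_guvs: int = 20
    noise_sd: float = 0.02
    rate_per_min: float = 0.3
    n_area_traces: int = 10


class RunConfig(_Strict):
    seed: int = 0
    stages: StageToggles = StageToggles()
    simulation: SimulationBlock = SimulationBlock()
    transport: TransportBlock = TransportBlock()
    rdf_mode: str = "full_3d"
    cluster_cutoff: float = 1.0
    histogram_bin_width: float = 0.05


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial-output manifest."""

    def __init__(self, stage: str, manifest: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _composition(sim: SimulationBlock) -> SimulationComposition:
    inter = PairInteraction(
        epsilon=sim.epsilon, kappa=sim.kappa, sigma_r=sim.sigma_r, sigma_z=sim.sigma_z
    )
    present = [s for s, n in (("A", sim.n_a), ("B", sim.n_b), ("C", sim.n_c)) if n > 0]
    # couple unlike pairs only; like pairs stay free, mirroring the much
    # weaker like-pair suppression
    interactions = {
        (a, b): inter for i, a in enumerate(present) for b in present[i + 1 :]
    }
    return SimulationComposition(
        counts={"A": sim.n_a, "B": sim.n_b, "C": sim.n_c},
        thresholds={"A": sim.threshold_a, "B": sim.threshold_b, "C": sim.threshold_c},
        interactions=interactions,
    )


def run(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the configured stages and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    stage = "simulate"
    try:
        replicas = []
        if config.stages.simulate:
            sim = config.simulation
            params = LangevinParams(
                barrier_height=sim.barrier_height,
                n_steps=sim.n_steps,
                timestep=sim.timestep,
                frame_stride=sim.frame_stride,
                box_xy=sim.box_xy,
            )
            comp = _composition(sim)
            for r in range(sim.n_replicas):
                traj, truth = simulate_solute_trajectories(params, comp, config.seed + r)
                traces = ztraces_from_trajectory(traj)
                replicas.append((traj, truth, traces))
                _emit(f"ztrace_rep{r}.tsv", lambda p, tr=traces: write_ztrace_tsv(tr, p))
                _emit(
                    f"ground_truth_rep{r}.json",
                    lambda p, t=truth: p.write_text(
                        json.dumps(t.to_json_dict(), indent=2)
                    ),
                )
            summary["simulate"] = {"n_replicas": sim.n_replicas, "n_steps": sim.n_steps}

        stage = "transitions"
        if config.stages.transitions and replicas:
            sim = config.simulation
            tcfg = TransitionConfig(
                thresholds={
                    "A": sim.threshold_a,
                    "B": sim.threshold_b,
                    "C": sim.threshold_c,
                }
            )
            grouped = {r: traces for r, (_, _, traces) in enumerate(replicas)}
            ts = summarize_transitions(grouped, tcfg)
            _emit(
                "transitions.tsv",
                lambda p: ts.per_molecule.to_csv(p, sep="\t", index=False),
            )
            summary["transitions"] = {
                "mean_count": ts.mean_count,
                "rate_per_us": ts.rate_per_us,
            }

        stage = "histograms"
        if config.stages.histograms and replicas:
            all_a = [tr for (_, _, traces) in replicas for tr in traces if tr.species == "A"]
            if all_a:
                hist = height_histogram(
                    all_a,
                    bin_width=config.histogram_bin_width,
                    mode="intensity_sensitive",
                )
                df = pd.DataFrame(
                    {"abs_z_nm": hist.centers, "probability": hist.probabilities}
                )
                _emit("height_histogram_A.tsv", lambda p: df.to_csv(p, sep="\t", index=False))
                summary["histograms"] = {
                    "peak_abs_z_nm": hist.peak_location(),
                    "mass_share": hist.mass_share,
                }

        stage = "rdf"
        if config.stages.rdf and replicas:
            traj = replicas[0][0]
            solute_species = sorted(
                set(traj.topology["species"]) - {"P"}
            )
            pair = (solute_species[0], solute_species[-1])
            rdf = radial_distribution(traj, pair, RDFConfig(mode=config.rdf_mode))
            df = pd.DataFrame({"r_nm": rdf.r, "g": rdf.g, "count": rdf.pair_counts})
            _emit("rdf.tsv", lambda p: df.to_csv(p, sep="\t", index=False))
            summary["rdf"] = {"pair": list(pair), "n_pairs_used": rdf.n_pairs_used}

        stage = "clusters"
        if config.stages.clusters and replicas:
            cl = cluster_timeseries(replicas[0][0], cutoff=config.cluster_cutoff)
            summary["clusters"] = {
                "mean_largest": float(np.mean(cl.largest_per_frame)),
                "fraction_frames_dimer_or_more": cl.fraction_frames_with_cluster_geq(2),
            }

        stage = "transport"
        if config.stages.transport:
            tp = config.transport
            traces, truth = simulate_fluorescence_traces(
                tp.n_guvs,
                rate_per_min=tp.rate_per_min,
                noise_sd=tp.noise_sd,
                seed=config.seed + 1000,
            )
            i_mean = float(np.mean([t.intensities[0] for t in traces]))
            ctx = SampleContext(i_mean=i_mean)
            rows = [
                {
                    "guv_id": t.guv_id,
                    "percent_transport": percent_transport_quench(t, ctx),
                    "true_percent": 100 * truth[t.guv_id],
                }
                for t in traces
            ]
            df = pd.DataFrame(rows)
            _emit("transport.tsv", lambda p: df.to_csv(p, sep="\t", index=False))
            rmse = float(
                np.sqrt(np.mean((df.percent_transport - df.true_percent) ** 2))
            )
            areas, labels = simulate_area_traces(
                tp.n_area_traces,
                lysing=[(i % 2 == 0) for i in range(tp.n_area_traces)],
                seed=config.seed + 2000,
            )
            calls = [detect_lysis(a)[0] for a in areas]
            summary["transport"] = {
                "recovery_rmse_pct": rmse,
                "lysis_call_accuracy": float(np.mean(np.array(calls) == labels)),
            }

        stage = "fate"
        if config.stages.fate:
            mapping, n_distinct = enumerate_fates()
            fate_table = {"-".join(k): v for k, v in mapping.items()}
            _emit(
                "fates.json",
                lambda p: p.write_text(json.dumps(fate_table, indent=2)),
            )
            summary["fate"] = {"terminal_fates": fate_table, "n_distinct": n_distinct}
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        raise PipelineError(stage, manifest, exc) from exc

    summary["manifest"] = manifest
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
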