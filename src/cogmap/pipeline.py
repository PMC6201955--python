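"""Reproducible end-to-end pipeline runs driven by a single configuration.

A :class:`RunConfig` carries every stage parameter (all defaulting to the
reference analysis values: 0.45 coherence threshold, 0.1 ratio bin width,
6-s windows, 250 frames/s) plus one master seed.  :func:`run_pipeline`
executes simulate → detect → classify → connect → spatial → congruency →
motor as toggled, writes each stage's outputs to the run directory, and
finishes with a manifest recording the package version, the seed, every
parameter used and the SHA-256 of every output file, so that runs are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from . import __version__, io
from .congruency import score_congruency
from .connectivity import coherence_matrix, graph_metrics, threshold_adjacency
from .motor_pattern import analyze_condition
from .response_analysis import (
    ResponseLabel,
    ResponseMap,
    build_ratio_distribution,
    classify_modality,
    unique_responses,
)
from .spatial import angular_variance, population_geometry
from .synthetic_data import (
    PopulationSpec,
    TraceNoiseSpec,
    default_protocols,
    generate_population,
    generate_pyloric,
)
from .trace_processing import DetectionParams, SpikeTrain, process_trace

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("cogmap")

ALL_STAGES = ("simulate", "detect", "classify", "connect", "spatial",
              "congruency", "motor")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 1
    out_dir: str = "cogmap_run"
    stages: tuple[str, ...] = ALL_STAGES
    conditions: tuple[str, ...] = ("IV", "VCN", "bimodal")
    n_trials: int = 3
    population: dict = field(default_factory=dict)   # PopulationSpec overrides
    noise: dict = field(default_factory=dict)        # TraceNoiseSpec overrides
    detection: dict = field(default_factory=dict)    # DetectionParams overrides
    deadband: float = 1.0
    deadband_z: float = 2.5
    bin_width: float = 0.1
    threshold: float = 0.45
    require_significance: bool = False
    exclusion: float = 1.5
    pyloric_effects: dict = field(
        default_factory=lambda: {
            "IV": {"cycle_period": 0.15, "firing_frequency": -0.10},
            "VCN": {"cycle_period": -0.10, "firing_frequency": 0.10},
            "bimodal": {"cycle_period": 0.05},
        }
    )

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        for name, cls in (
            ("population", PopulationSpec),
            ("noise", TraceNoiseSpec),
            ("detection", DetectionParams),
        ):
            sub = getattr(self, name)
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = sorted(set(sub) - valid)
            if bad:
                raise ValueError(f"unknown key(s) in '{name}': {bad}")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - valid)
        if bad:
            raise ValueError(f"unknown configuration key(s): {bad}")
        for key in ("stages", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(seed=self.seed, **self.population)

    def noise_spec(self) -> TraceNoiseSpec:
        return TraceNoiseSpec(**self.noise)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_trains(
    trains_by_sweep: Mapping[str, list[SpikeTrain]]
) -> dict[tuple[str, str], list[SpikeTrain]]:
    """Regroup sweep-wise trains into (neuron, condition) -> trial list."""
    grouped: dict[tuple[str, str], list[SpikeTrain]] = {}
    for sweep_id in sorted(trains_by_sweep):
        condition = sweep_id.split(":")[0]
        for train in trains_by_sweep[sweep_id]:
            grouped.setdefault((train.unit_id, condition), []).append(train)
    return grouped


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocols = default_protocols(config.conditions)
    logger.info("run: seed=%d stages=%s out=%s", config.seed, config.stages, out)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
    }

    traces_by_sweep: dict[str, list] = {}
    truth = None
    if "simulate" in config.stages:
        traces, truth = generate_population(
            config.population_spec(), config.noise_spec(), protocols,
            n_trials=config.n_trials, seed=config.seed,
        )
        for tr in traces:
            traces_by_sweep.setdefault(tr.sweep_id, []).append(tr)
        for sweep_id, sweep_traces in sorted(traces_by_sweep.items()):
            fname = f"traces_{sweep_id.replace(':', '_t')}.csv"
            io.write_traces(out / fname, sweep_traces)
        io.write_ground_truth(out / "ground_truth.json", truth)
        pyloric_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
        rng_seeds = pyloric_seed.generate_state(len(config.conditions))
        for k, condition in enumerate(config.conditions):
            trains = generate_pyloric(
                config.pyloric_effects.get(condition, {}),
                seed=int(rng_seeds[k]) % (2**31),
                protocol=protocols[condition],
            )
            io.write_spikes(
                out / f"pyloric_{condition}.csv",
                [trains[u] for u in sorted(trains)],
            )
    elif {"detect", "connect"} & set(config.stages):
        for path in sorted(out.glob("traces_*.csv")):
            sweep_id = path.stem.removeprefix("traces_").replace("_t", ":")
            traces_by_sweep[sweep_id] = io.read_traces(path, sweep_id=sweep_id)
        if not traces_by_sweep:
            raise FileNotFoundError(
                "stage 'detect'/'connect': no traces found; run 'simulate' "
                "first or point out_dir at existing traces"
            )

    trains_by_sweep: dict[str, list[SpikeTrain]] = {}
    if "detect" in config.stages:
        params = config.detection_params()
        for sweep_id, sweep_traces in sorted(traces_by_sweep.items()):
            trains = [process_trace(tr, params) for tr in sweep_traces]
            trains_by_sweep[sweep_id] = trains
            fname = f"spikes_{sweep_id.replace(':', '_t')}.csv"
            io.write_spikes(out / fname, trains)

    rmap: ResponseMap | None = None
    if "classify" in config.stages:
        if not trains_by_sweep:
            for path in sorted(out.glob("spikes_*.csv")):
                sweep_id = path.stem.removeprefix("spikes_").replace("_t", ":")
                trains_by_sweep[sweep_id] = io.read_spikes(path)
            if not trains_by_sweep:
                raise FileNotFoundError("stage 'classify': no spike trains found")
        grouped = _group_trains(trains_by_sweep)
        rmap = ResponseMap.from_spike_trains(
            grouped, protocols, deadband=config.deadband, z=config.deadband_z,
            xy=truth.xy if truth is not None else None,
        )
        io.write_response_map(out / "response_map.json", rmap)
        io.write_response_map(out / "response_map.csv", rmap)
        modality, proportions = classify_modality(rmap)
        summary: dict = {"modality_percent": proportions}
        for condition in config.conditions:
            summary[f"{condition}_percent"] = rmap.condition_proportions(condition)
        if set(config.conditions) >= {"IV", "VCN", "bimodal"}:
            summary["unique_responses"] = unique_responses(rmap)
        ratios = [
            [rmap.ratio.get((n, c)) for n in rmap.neurons]
            for c in config.conditions
        ]
        dist = build_ratio_distribution(ratios, bin_width=config.bin_width)
        np.savetxt(
            out / "ratio_distribution.csv",
            np.column_stack([dist.bin_edges[:-1], dist.mean_counts, dist.sd_counts]),
            delimiter=",", header="bin_left,mean,sd", comments="", fmt="%.9g",
        )
        io.write_json(out / "classification.json", summary)

    if "connect" in config.stages:
        metrics = {}
        params = config.detection_params()
        for condition in config.conditions:
            sweep_id = f"{condition}:0"
            if sweep_id not in traces_by_sweep:
                raise FileNotFoundError(f"stage 'connect': no traces for {sweep_id}")
            from .trace_processing import remove_drift

            detrended = [
                remove_drift(tr, params.poly_degree)
                for tr in traces_by_sweep[sweep_id]
            ]
            C = coherence_matrix(detrended, window=protocols[condition].stim_on)
            np.savetxt(
                out / f"coherence_{condition}.csv", C.rho, delimiter=",", fmt="%.9g"
            )
            G = threshold_adjacency(
                C, config.threshold, config.require_significance
            )
            io.write_graph(out / f"graph_{condition}.csv", G)
            io.write_graph(out / f"graph_{condition}.graphml", G)
            metrics[condition] = graph_metrics(G)
        io.write_json(out / "connectivity_metrics.json", metrics)

    if "spatial" in config.stages or "congruency" in config.stages:
        if rmap is None:
            rmap_path = out / "response_map.json"
            if not rmap_path.exists():
                raise FileNotFoundError(
                    "stage 'spatial'/'congruency': response_map.json missing; "
                    "run 'classify' first"
                )
            rmap = io.read_response_map(rmap_path)

    if "spatial" in config.stages:
        if not rmap.xy:
            raise ValueError("stage 'spatial': response map carries no coordinates")
        geometry = population_geometry(rmap.xy)
        geometry.to_csv(out / "geometry.csv", index=False, float_format="%.9g")
        by_neuron = geometry.set_index("neuron_id")
        summary = {}
        for condition in config.conditions:
            for label in (ResponseLabel.EXCITED, ResponseLabel.INHIBITED):
                ids = [
                    n for n in rmap.neurons
                    if rmap.labels.get((n, condition)) == label
                ]
                if not ids:
                    continue
                sub = by_neuron.loc[ids]
                angles = sub["angle"].dropna()
                summary[f"{condition}_{label.value}"] = {
                    "n": len(ids),
                    "mean_d_ratio": float(sub["d_ratio"].mean()),
                    "angular_variance": (
                        angular_variance(angles) if len(angles) else None
                    ),
                }
        io.write_json(out / "spatial_summary.json", summary)

    if "congruency" in config.stages:
        report = score_congruency(rmap)
        rows = [
            {"neuron_id": n, "verdict": v, "expected": str(report.expected[n])}
            for n, v in sorted(report.verdicts.items())
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "congruency.csv", index=False)
        io.write_json(out / "congruency.json", report.proportions)

    if "motor" in config.stages:
        changes = {}
        for condition in config.conditions:
            path = out / f"pyloric_{condition}.csv"
            if not path.exists():
                raise FileNotFoundError(f"stage 'motor': {path.name} missing")
            trains = {t.unit_id: t for t in io.read_spikes(path, source="extracellular")}
            results = analyze_condition(
                trains, protocols[condition], exclusion=config.exclusion
            )
            changes[condition] = [
                dataclasses.asdict(r) for r in results
            ]
        io.write_json(out / "motor_norm_delta.json", changes)

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    io.write_json(out / "manifest.json", manifest)
    return manifest
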