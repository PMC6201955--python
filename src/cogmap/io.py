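"""Readers and writers for the pipeline's on-disk formats.

All text formats are comma-separated UTF-8 with a header row, '.' decimal
and times in seconds.  Traces are stored as a matrix (column 0 = time_s,
one column per neuron) in CSV or as HDF5 groups per sweep; spike trains as
two-column CSV (unit_id, time_s); graphs as GraphML or edge-list CSV;
ground truth, response maps and metrics as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import FunctionalGraph
from .response_analysis import ResponseLabel, ResponseMap
from .synthetic_data import GroundTruth
from .trace_processing import FluorescenceTrace, SpikeTrain

__all__ = [
    "write_traces",
    "read_traces",
    "write_traces_h5",
    "read_traces_h5",
    "write_spikes",
    "read_spikes",
    "write_graph",
    "read_graph",
    "write_ground_truth",
    "read_ground_truth",
    "write_response_map",
    "read_response_map",
    "write_json",
]


class ParseError(ValueError):
    """Malformed input file, with record context in the message."""


def write_traces(path: str | pathlib.Path, traces: Sequence[FluorescenceTrace]) -> None:
    """Write one sweep's traces as a delimited matrix (time_s + neurons)."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    lengths = {tr.n_samples for tr in traces}
    rates = {tr.frame_rate for tr in traces}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError("traces in one file must share length and frame rate")
    data = {"time_s": traces[0].times}
    for tr in traces:
        data[str(tr.neuron_id)] = tr.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_traces(path: str | pathlib.Path, sweep_id: str = "0") -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise ParseError(f"{path}: time axis is not uniformly increasing")
    frame_rate = 1.0 / dt.mean()
    return [
        FluorescenceTrace(
            neuron_id=col, samples=df[col].to_numpy(float),
            frame_rate=frame_rate, sweep_id=sweep_id, t0=float(t[0]),
        )
        for col in df.columns
        if col != "time_s"
    ]


def write_traces_h5(
    path: str | pathlib.Path, sweeps: Mapping[str, Sequence[FluorescenceTrace]]
) -> None:
    """HDF5 layout: one group per sweep, one dataset per neuron."""
    with h5py.File(path, "w") as f:
        for sweep_id, traces in sweeps.items():
            grp = f.create_group(str(sweep_id))
            for tr in traces:
                ds = grp.create_dataset(str(tr.neuron_id), data=tr.samples)
                ds.attrs["frame_rate"] = tr.frame_rate
                ds.attrs["t0"] = tr.t0


def read_traces_h5(path: str | pathlib.Path) -> dict[str, list[FluorescenceTrace]]:
    sweeps: dict[str, list[FluorescenceTrace]] = {}
    with h5py.File(path, "r") as f:
        for sweep_id, grp in f.items():
            sweeps[sweep_id] = [
                FluorescenceTrace(
                    neuron_id=name, samples=ds[()],
                    frame_rate=float(ds.attrs["frame_rate"]),
                    sweep_id=sweep_id, t0=float(ds.attrs.get("t0", 0.0)),
                )
                for name, ds in grp.items()
            ]
    return sweeps


def write_spikes(path: str | pathlib.Path, trains: Sequence[SpikeTrain]) -> None:
    rows = [
        {"unit_id": tr.unit_id, "time_s": t} for tr in trains for t in tr.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_spikes(path: str | pathlib.Path, source: str = "optical") -> list[SpikeTrain]:
    df = pd.read_csv(path)
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing '{col}' column")
    trains = []
    for unit_id, group in df.groupby("unit_id", sort=True):
        times = group["time_s"].to_numpy(float)
        if times.size > 1 and np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
            raise ParseError(
                f"{path}: spike times for unit {unit_id!r} not strictly "
                f"increasing near record {bad + 1}"
            )
        trains.append(SpikeTrain(unit_id=str(unit_id), times=times, source=source))
    return trains


def write_graph(path: str | pathlib.Path, G: FunctionalGraph) -> None:
    """GraphML for .graphml paths, edge-list CSV otherwise."""
    path = pathlib.Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(G.to_networkx(), path)
    else:
        edges = [
            {"source": G.ids[i], "target": G.ids[j]}
            for i, j in zip(*np.nonzero(np.triu(G.adjacency)))
        ]
        pd.DataFrame(edges, columns=["source", "target"]).to_csv(path, index=False)


def read_graph(path: str | pathlib.Path, ids: Sequence[str] | None = None) -> FunctionalGraph:
    path = pathlib.Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes())
        A = nx.to_numpy_array(g, nodelist=nodes, dtype=int)
        return FunctionalGraph(ids=list(nodes), adjacency=A, threshold=float("nan"))
    df = pd.read_csv(path)
    if ids is None:
        ids = sorted(set(df["source"]).union(df["target"]))
    index = {n: k for k, n in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)), dtype=int)
    for _, row in df.iterrows():
        i, j = index[row["source"]], index[row["target"]]
        A[i, j] = A[j, i] = 1
    return FunctionalGraph(ids=list(ids), adjacency=A, threshold=float("nan"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, ResponseLabel):
        return obj.value
    return str(obj)


def write_json(path: str | pathlib.Path, payload) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def write_ground_truth(path: str | pathlib.Path, truth: GroundTruth) -> None:
    payload = {
        "modality": truth.modality,
        "labels": {
            f"{n}/{c}": lab.value for (n, c), lab in sorted(truth.labels.items())
        },
        "latency": {
            f"{n}/{c}": lat for (n, c), lat in sorted(truth.latency.items())
        },
        "baseline_rate": truth.baseline_rate,
        "evoked_rate": {
            f"{n}/{c}": r for (n, c), r in sorted(truth.evoked_rate.items())
        },
        "xy": {n: list(p) for n, p in sorted(truth.xy.items())},
        "coupling": truth.coupling,
        "spike_times": {
            f"{n}/{c}": [t.tolist() for t in trials]
            for (n, c), trials in sorted(truth.spike_times.items())
        },
    }
    write_json(path, payload)


def _split_key(key: str) -> tuple[str, str]:
    neuron, _, condition = key.partition("/")
    return neuron, condition


def read_ground_truth(path: str | pathlib.Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        modality=payload["modality"],
        labels={
            _split_key(k): ResponseLabel(v) for k, v in payload["labels"].items()
        },
        spike_times={
            _split_key(k): [np.asarray(t) for t in v]
            for k, v in payload["spike_times"].items()
        },
        latency={_split_key(k): v for k, v in payload["latency"].items()},
        baseline_rate=payload["baseline_rate"],
        evoked_rate={_split_key(k): v for k, v in payload["evoked_rate"].items()},
        xy={n: tuple(p) for n, p in payload["xy"].items()},
        coupling=payload.get("coupling", {}),
    )


def write_response_map(path: str | pathlib.Path, rmap: ResponseMap) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".json":
        payload = {
            "labels": {
                f"{n}/{c}": lab.value for (n, c), lab in sorted(rmap.labels.items())
            },
            "ratio": {f"{n}/{c}": v for (n, c), v in sorted(rmap.ratio.items())},
            "diff": {f"{n}/{c}": v for (n, c), v in sorted(rmap.diff.items())},
            "xy": {n: list(p) for n, p in sorted(rmap.xy.items())},
        }
        write_json(path, payload)
    else:
        rmap.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_response_map(path: str | pathlib.Path) -> ResponseMap:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return ResponseMap(
        labels={
            _split_key(k): ResponseLabel(v) for k, v in payload["labels"].items()
        },
        ratio={_split_key(k): v for k, v in payload.get("ratio", {}).items()},
        diff={_split_key(k): v for k, v in payload.get("diff", {}).items()},
        xy={n: tuple(p) for n, p in payload.get("xy", {}).items()},
    )
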