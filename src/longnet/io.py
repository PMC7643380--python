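"""Plain-text file formats for every pipeline stage.

All artifacts are delimited text or JSON so results diff cleanly and
re-runs with the same seed are byte-identical:

* time series: CSV, header row = node labels, one row per sampled frame;
* square matrices: CSV with matching header row and index column;
* network map: two-column CSV ``node_label,network_name``;
* ``.mlnet`` container: a directory holding one matrix CSV per layer plus
  a ``manifest.json`` with node labels and layer order;
* partitions: long CSV ``rep,node,layer,community`` plus a manifest
  recording parameters and seeds;
* metrics: the tidy long table from :func:`longnet.metrics.metrics_long_table`.

Floats are written with ``repr``-faithful 17-significant-digit formatting,
so reading a file back reproduces the array bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityLayer, MultilayerNetwork, ROITimeSeries
from .modularity import (
    ModularityParams,
    MultilayerPartition,
    OptimizationEnsemble,
)

_FLOAT_FMT = "%.17g"


def read_time_series(path: str | Path, occasion: int = 0) -> ROITimeSeries:
    df = pd.read_csv(path)
    return ROITimeSeries(df.to_numpy(dtype=float), list(df.columns), occasion=occasion)


def write_time_series(ts: ROITimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=ts.node_labels).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Square matrix CSV with header row and matching index column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), list(df.columns.astype(str))


def write_matrix(values: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, float_format=_FLOAT_FMT)


def read_network_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (node_label, network_name)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_network_map(network_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"node_label": list(network_map), "network_name": list(network_map.values())}
    ).to_csv(path, index=False)


def write_mlnet(network: MultilayerNetwork, path: str | Path) -> None:
    """Write a multilayer network as a ``.mlnet`` directory container."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    layer_files = []
    for l, layer in enumerate(network.layers):
        fname = f"layer_{l:02d}.csv"
        write_matrix(layer.weights, layer.node_labels, path / fname)
        layer_files.append(fname)
    write_network_map(network.network_labels, path / "network_map.csv")
    manifest = {
        "format": "mlnet/1",
        "n_nodes": network.n_nodes,
        "n_layers": network.n_layers,
        "layers": layer_files,
        "node_labels": network.node_labels,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_mlnet(path: str | Path) -> MultilayerNetwork:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    layers = []
    for fname in manifest["layers"]:
        w, labels = read_matrix(path / fname)
        layers.append(ConnectivityLayer(w, labels))
    network_map = read_network_map(path / "network_map.csv")
    return MultilayerNetwork(layers, manifest["node_labels"], network_map)


def write_partitions(
    ensemble: OptimizationEnsemble,
    node_labels: list[str],
    path: str | Path,
    base_seed: int | None = None,
) -> None:
    """Long CSV of community assignments plus a JSON manifest of the run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep, res in enumerate(ensemble.results):
        g = res.partition.assignments
        for i, node in enumerate(node_labels):
            for l in range(g.shape[1]):
                rows.append((rep, node, l, int(g[i, l])))
    pd.DataFrame(rows, columns=["rep", "node", "layer", "community"]).to_csv(
        path, index=False
    )
    params = ensemble.results[0].params
    manifest = {
        "n_reps": ensemble.n_reps,
        "mean_Q": ensemble.mean_Q,
        "Q": [r.Q for r in ensemble.results],
        "seeds": [r.seed for r in ensemble.results],
        "base_seed": base_seed,
        "gamma": params.gamma,
        "omega": params.omega,
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def read_partitions(
    path: str | Path,
) -> tuple[list[MultilayerPartition], list[str], dict]:
    """Inverse of :func:`write_partitions`."""
    path = Path(path)
    df = pd.read_csv(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text()
    )
    node_labels = list(dict.fromkeys(df["node"].astype(str)))
    node_idx = {n: i for i, n in enumerate(node_labels)}
    n_layers = int(df["layer"].max()) + 1
    partitions = []
    for rep, sub in df.groupby("rep", sort=True):
        g = np.zeros((len(node_labels), n_layers), dtype=np.int64)
        g[[node_idx[n] for n in sub["node"].astype(str)], sub["layer"].to_numpy()] = sub[
            "community"
        ].to_numpy()
        partitions.append(MultilayerPartition(g))
    return partitions, node_labels, manifest


def params_from_manifest(manifest: dict) -> ModularityParams:
    return ModularityParams(gamma=manifest["gamma"], omega=manifest["omega"])
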