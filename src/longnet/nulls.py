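"""Null models for multilayer networks and real-vs-null comparisons.

Two nulls isolate different aspects of the observed structure:

* the **temporal null** shuffles the order of the layers uniformly at
  random, preserving each layer's connectivity exactly while destroying
  dependence between consecutive time points;
* the **nodal null** permutes, within each layer independently, the
  off-diagonal edge weights over node pairs (symmetrized), preserving the
  layer's weight distribution while destroying its community structure.

Group-level comparisons use Welch's two-sample t test (Satterthwaite
degrees of freedom) and Cohen's d with the conventional small/medium/large
bands at 0.2 / 0.5 / 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .connectome import ConnectivityLayer, MultilayerNetwork
from .metrics import MetricSet, summarize
from .modularity import ModularityParams, repeated_optimization


def temporal_null(
    network: MultilayerNetwork,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> MultilayerNetwork:
    """Reorder the layers by a uniformly random permutation.

    Order-invariant per-layer statistics are untouched; only the temporal
    dependence between adjacent layers is destroyed.  The identity
    permutation is a legal draw.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(network.n_layers)
    layers = [network.layers[i] for i in perm]
    return MultilayerNetwork(layers, list(network.node_labels), dict(network.network_labels))


def nodal_null(
    network: MultilayerNetwork,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> MultilayerNetwork:
    """Permute each layer's off-diagonal weights over node pairs.

    Each layer keeps its exact multiset of upper-triangle weights (hence
    total weight and density) but loses any block/community structure.
    """
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    iu = np.triu_indices(n, k=1)
    layers = []
    for layer in network.layers:
        vals = layer.weights[iu]
        shuffled = vals[rng.permutation(vals.size)]
        w = np.zeros((n, n))
        w[iu] = shuffled
        w = w + w.T
        layers.append(ConnectivityLayer(w, list(layer.node_labels)))
    return MultilayerNetwork(layers, list(network.node_labels), dict(network.network_labels))


_NULL_BUILDERS = {"temporal": temporal_null, "nodal": nodal_null}


def null_ensemble(
    network: MultilayerNetwork,
    kind: str,
    n_null: int = 50,
    n_reps: int = 100,
    base_seed: int | np.random.SeedSequence = 0,
    params: ModularityParams | None = None,
) -> list[MetricSet]:
    """Metrics for ``n_null`` null realizations of one subject's network.

    Each null network gets its own construction seed and its own stream of
    ``n_reps`` optimization seeds, all derived from ``base_seed``, so any
    single null is reproducible in isolation.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if kind not in _NULL_BUILDERS:
        raise ValueError(f"kind must be one of {sorted(_NULL_BUILDERS)}, got {kind!r}")
    ss = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    labels = network.network_label_array()
    out = []
    for child in ss.spawn(n_null):
        build_ss, opt_ss = child.spawn(2)
        null_net = _NULL_BUILDERS[kind](network, build_ss)
        ens = repeated_optimization(null_net, params, n_reps=n_reps, base_seed=opt_ss)
        out.append(summarize(ens, null_net.node_labels, labels))
    return out


@dataclass
class NullComparison:
    """Welch test of a metric's real vs. null per-subject distributions."""

    metric: str
    t: float
    df: float
    p: float
    d: float
    direction: int  # sign of (real mean - null mean)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute standardized mean difference with the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float(abs(x.mean() - y.mean()) / np.sqrt(pooled_var))


def interpret_d(d: float) -> str:
    """Conventional effect-size bands: 0.2 small, 0.5 medium, 0.8 large."""
    if d >= 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    if d >= 0.2:
        return "small"
    return "negligible"


def compare_to_null(
    real_values: np.ndarray,
    null_values: np.ndarray,
    metric: str = "",
) -> NullComparison:
    """Welch's two-sample t test plus Cohen's d for one metric."""
    x = np.asarray(real_values, dtype=float)
    y = np.asarray(null_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    res = _sps.ttest_ind(x, y, equal_var=False)
    return NullComparison(
        metric=metric,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=cohens_d(x, y),
        direction=int(np.sign(x.mean() - y.mean())),
    )


def compare_metric_table(
    real: pd.DataFrame,
    null: pd.DataFrame,
    metrics: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the Welch comparison for several metrics and tabulate.

    ``real`` and ``null`` hold one row per subject and one column per
    metric (null columns are per-subject means over the null ensemble, so
    both samples have the cohort's length).  Significance is assessed at
    alpha / n_metrics.
    """
    thr = alpha / len(metrics)
    rows = []
    for m in metrics:
        c = compare_to_null(real[m].to_numpy(), null[m].to_numpy(), metric=m)
        rows.append(
            {
                "metric": m,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "d": c.d,
                "effect_size": interpret_d(c.d),
                "direction": c.direction,
                "significant": c.p < thr,
            }
        )
    return pd.DataFrame(rows)
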