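"""Temporal community metrics computed from multilayer partitions.

Five node-level quantities characterize how community structure
reconfigures across layers:

* **flexibility** — fraction of the L-1 consecutive-layer transitions at
  which the node changes community;
* **promiscuity** — fraction of all communities in the partition that the
  node joins at least once;
* **cohesion strength** — count of the node's community switches made
  jointly with at least one other node (same source -> target community at
  the same transition); row sums of the pairwise cohesion matrix;
* **disjointedness** — switches made alone (no other node makes the same
  source -> target move at that transition), normalized by L-1;
* **recruitment** — mean module allegiance of the node to the other
  members of its own predefined resting-state network.

The module allegiance matrix gives, for each pair of nodes, the fraction
of (layer, optimization) instances in which the two share a community.
All metrics are averaged across an ensemble of stochastic optimizations
and aggregated from nodes to the seven predefined networks and to a
global (all-node mean) scale.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modularity import MultilayerPartition, OptimizationEnsemble

METRIC_NAMES = (
    "flexibility",
    "promiscuity",
    "cohesion_strength",
    "disjointedness",
    "recruitment",
)


def _nanmean(values: np.ndarray) -> float:
    """nanmean that returns NaN quietly when no finite value exists."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else float("nan")


def node_flexibility(partition: MultilayerPartition) -> np.ndarray:
    """Per-node switch count over consecutive layers, divided by L - 1."""
    g = partition.assignments
    if g.shape[1] < 2:
        raise ValueError("flexibility needs at least 2 layers")
    changes = (g[:, :-1] != g[:, 1:]).sum(axis=1)
    return changes / (g.shape[1] - 1)


def node_promiscuity(partition: MultilayerPartition) -> np.ndarray:
    """Fraction of all K communities that each node visits at least once."""
    g = partition.assignments
    k_total = len(np.unique(g))
    visited = np.array([len(np.unique(row)) for row in g])
    return visited / k_total


def _moves_by_transition(g: np.ndarray):
    """Group movers at each transition by their (source, target) pair."""
    n, L = g.shape
    for l in range(L - 1):
        movers = np.flatnonzero(g[:, l] != g[:, l + 1])
        groups: dict[tuple[int, int], list[int]] = defaultdict(list)
        for i in movers:
            groups[(g[i, l], g[i, l + 1])].append(i)
        yield l, groups


def cohesion_matrix(partition: MultilayerPartition) -> np.ndarray:
    """Pairwise count of joint community switches.

    Entry (i, j) counts the transitions at which nodes i and j move from a
    common community to a common (different) community.  A community that
    splits into subgroups produces cohesive switches for every subgroup of
    size >= 2 even though no pair spans the two subgroups.
    """
    g = partition.assignments
    if g.shape[1] < 2:
        raise ValueError("cohesion needs at least 2 layers")
    coh = np.zeros((g.shape[0], g.shape[0]))
    for _, groups in _moves_by_transition(g):
        for members in groups.values():
            if len(members) < 2:
                continue
            idx = np.array(members)
            coh[np.ix_(idx, idx)] += 1
    np.fill_diagonal(coh, 0.0)
    return coh


def node_cohesion_strength(partition: MultilayerPartition) -> np.ndarray:
    """Row sums of the cohesion matrix (unbounded raw counts)."""
    return cohesion_matrix(partition).sum(axis=1)


def node_disjointedness(partition: MultilayerPartition) -> np.ndarray:
    """Fraction of possible transitions at which the node switches alone.

    A switch is disjoint iff no other node makes the identical
    (source, target) move at that transition; community splits and merges
    therefore contribute zero disjointedness for every participating node.
    """
    g = partition.assignments
    if g.shape[1] < 2:
        raise ValueError("disjointedness needs at least 2 layers")
    lone = np.zeros(g.shape[0])
    for _, groups in _moves_by_transition(g):
        for members in groups.values():
            if len(members) == 1:
                lone[members[0]] += 1
    return lone / (g.shape[1] - 1)


def allegiance(partitions: list[MultilayerPartition] | MultilayerPartition) -> np.ndarray:
    """Module allegiance matrix over an ensemble of partitions.

    Entry (i, j) is the fraction of (layer, run) instances in which nodes
    i and j are assigned to the same community; the diagonal is exactly 1.
    """
    if isinstance(partitions, MultilayerPartition):
        partitions = [partitions]
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].n_nodes
    acc = np.zeros((n, n))
    count = 0
    for p in partitions:
        g = p.assignments
        for l in range(g.shape[1]):
            acc += g[:, l][:, None] == g[:, l][None, :]
            count += 1
    return acc / count


def recruitment(
    allegiance_matrix: np.ndarray,
    network_labels: np.ndarray,
) -> tuple[np.ndarray, pd.Series, float]:
    """Node, network, and global recruitment from an allegiance matrix.

    A node's recruitment is its mean allegiance to same-network peers
    (self excluded).  Nodes whose network has a single member have no
    peers; they get NaN and are excluded from the network and global
    means.
    """
    labels = np.asarray(network_labels)
    n = allegiance_matrix.shape[0]
    if labels.shape[0] != n:
        raise ValueError("network labels must cover all nodes")
    node_vals = np.full(n, np.nan)
    for name in pd.unique(labels):
        members = np.flatnonzero(labels == name)
        if members.size < 2:
            continue
        sub = allegiance_matrix[np.ix_(members, members)]
        node_vals[members] = (sub.sum(axis=1) - np.diag(sub)) / (members.size - 1)
    per_network = pd.Series(
        {name: _nanmean(node_vals[labels == name]) for name in pd.unique(labels)}
    )
    return node_vals, per_network, _nanmean(node_vals)


@dataclass
class MetricSet:
    """Ensemble-averaged metrics at node, network, and global scale."""

    per_node: pd.DataFrame  # index: node labels; columns: METRIC_NAMES
    per_network: pd.DataFrame  # index: network names; columns: METRIC_NAMES
    global_means: pd.Series  # index: METRIC_NAMES
    Q_mean: float
    module_count_mean: float
    allegiance: np.ndarray


def summarize(
    ensemble: OptimizationEnsemble,
    node_labels: list[str],
    network_labels: np.ndarray,
) -> MetricSet:
    """Compute all metrics per optimization run and average across runs.

    Flexibility, promiscuity, cohesion strength and disjointedness are
    computed on each run's partition then averaged.  Allegiance pools all
    (layer, run) instances; recruitment uses the pooled allegiance.  Q and
    the module count are ensemble means.
    """
    partitions = ensemble.partitions
    labels = np.asarray(network_labels)
    per_rep = {
        "flexibility": [node_flexibility(p) for p in partitions],
        "promiscuity": [node_promiscuity(p) for p in partitions],
        "cohesion_strength": [node_cohesion_strength(p) for p in partitions],
        "disjointedness": [node_disjointedness(p) for p in partitions],
    }
    alleg = allegiance(partitions)
    node_recr, _, _ = recruitment(alleg, labels)

    per_node = pd.DataFrame(
        {name: np.mean(vals, axis=0) for name, vals in per_rep.items()},
        index=pd.Index(node_labels, name="node"),
    )
    per_node["recruitment"] = node_recr

    net_index = pd.Index(pd.unique(labels), name="network")
    per_network = pd.DataFrame(
        {
            m: [_nanmean(per_node[m].to_numpy()[labels == g]) for g in net_index]
            for m in METRIC_NAMES
        },
        index=net_index,
    )
    global_means = pd.Series({m: _nanmean(per_node[m].to_numpy()) for m in METRIC_NAMES})
    module_counts = [p.n_communities for p in partitions]
    return MetricSet(
        per_node=per_node,
        per_network=per_network,
        global_means=global_means,
        Q_mean=ensemble.mean_Q,
        module_count_mean=float(np.mean(module_counts)),
        allegiance=alleg,
    )


def metrics_long_table(metric_set: MetricSet, subject: str = "s0") -> pd.DataFrame:
    """Tidy long table: subject, scope (node|network|global), unit, metric, value."""
    rows = []
    for node, vals in metric_set.per_node.iterrows():
        for m in METRIC_NAMES:
            rows.append((subject, "node", node, m, vals[m]))
    for net, vals in metric_set.per_network.iterrows():
        for m in METRIC_NAMES:
            rows.append((subject, "network", net, m, vals[m]))
    for m in METRIC_NAMES:
        rows.append((subject, "global", "all", m, metric_set.global_means[m]))
    rows.append((subject, "global", "all", "Q_mean", metric_set.Q_mean))
    rows.append((subject, "global", "all", "module_count_mean", metric_set.module_count_mean))
    return pd.DataFrame(rows, columns=["subject", "scope", "unit", "metric", "value"])
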