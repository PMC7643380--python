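"""Build positive weighted connectivity layers from ROI time series.

The pipeline here turns per-occasion regional BOLD time series into the
nonnegative, symmetric, zero-diagonal weighted graphs that the multilayer
modularity machinery consumes: Pearson correlation between regional
signals, Fisher r-to-z transformation, and removal of negative weights
(optionally keeping only edges that survive an FDR-corrected significance
threshold on the correlation coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

#: Canonical seven resting-state network names (Yeo-Krienen scheme).
DEFAULT_NETWORKS = ("FPCN", "DMN", "DAN", "SVAN", "LIMB", "SM", "VIS")

#: Correlations are clipped to +/- (1 - _R_CLIP_EPS) before atanh so that
#: perfectly correlated columns yield large finite weights rather than inf.
_R_CLIP_EPS = 1e-7


@dataclass
class ROITimeSeries:
    """A T x N matrix of regional signals for one measurement occasion.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        One column per region, one row per sampled timepoint.
    node_labels : sequence of str
        Unique region identifiers, one per column.
    occasion : int
        Zero-based index of the measurement occasion.
    """

    values: np.ndarray
    node_labels: list[str]
    occasion: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_labels = list(self.node_labels)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match column count")
        if len(set(self.node_labels)) != n:
            raise ValueError("node_labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityLayer:
    """One occasion's weighted functional graph.

    ``weights`` is symmetric with zero diagonal and no negative entries;
    weights live on the Fisher-z scale after the standard construction.
    """

    weights: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = list(self.node_labels)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length does not match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def total_weight(self) -> float:
        """Sum of all entries (twice the sum over unique edges)."""
        return float(self.weights.sum())

    def reordered(self, node_labels: list[str]) -> "ConnectivityLayer":
        """Return a copy with rows/columns permuted to ``node_labels``."""
        idx = [self.node_labels.index(lbl) for lbl in node_labels]
        return ConnectivityLayer(self.weights[np.ix_(idx, idx)], list(node_labels))


@dataclass
class MultilayerNetwork:
    """An ordered stack of connectivity layers over one node set."""

    layers: list[ConnectivityLayer]
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]
    network_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multilayer network needs at least 2 layers")
        if self.node_labels is None:
            self.node_labels = list(self.layers[0].node_labels)
        for i, layer in enumerate(self.layers):
            if layer.node_labels != self.node_labels:
                raise ValueError(f"layer {i} node labels differ from the network's")
        if self.network_labels:
            missing = [n for n in self.node_labels if n not in self.network_labels]
            if missing:
                raise ValueError(f"nodes without a network label: {missing[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def weight_stack(self) -> np.ndarray:
        """All layers as one (L, N, N) array."""
        return np.stack([layer.weights for layer in self.layers])

    def network_label_array(self) -> np.ndarray:
        """Per-node network names in node order."""
        return np.array([self.network_labels[n] for n in self.node_labels])


def correlation_matrix(ts: ROITimeSeries) -> np.ndarray:
    """Pearson correlation between every pair of regional time series.

    Returns the full N x N correlation matrix (diagonal 1).  A region with
    zero temporal variance makes its correlations undefined and raises a
    ``ValueError`` naming the offending node.
    """
    sd = ts.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.node_labels[i] for i in bad]
        raise ValueError(f"zero-variance time series for node(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    # guard against tiny asymmetries from floating point
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, z = atanh(r), with the diagonal forced to 0.

    |r| = 1 is clipped to 1 - 1e-7 so the output stays finite.
    """
    r = np.asarray(r_matrix, dtype=float)
    z = np.arctanh(np.clip(r, -1.0 + _R_CLIP_EPS, 1.0 - _R_CLIP_EPS))
    np.fill_diagonal(z, 0.0)
    return z


def positivize(z_matrix: np.ndarray, node_labels: list[str] | None = None) -> ConnectivityLayer:
    """Zero out negative weights and the diagonal, yielding a valid layer."""
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(z, z.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    w = np.where(z > 0, z, 0.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if node_labels is None:
        node_labels = [f"n{i}" for i in range(z.shape[0])]
    return ConnectivityLayer(w, node_labels)


def fdr_threshold(
    r_matrix: np.ndarray,
    n_samples: int,
    alpha: float = 0.01,
    node_labels: list[str] | None = None,
) -> ConnectivityLayer:
    """Keep only edges whose correlation is FDR-significant, then Fisher-z.

    Two-sided p-values for each unique off-diagonal correlation come from
    the exact t transform ``t = r * sqrt((T-2) / (1-r^2))`` with T-2 degrees
    of freedom; Benjamini-Hochberg runs over the N(N-1)/2 unique pairs.
    Surviving positive correlations are Fisher-z transformed; everything
    else (non-survivors, negative edges, diagonal) is zero.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_samples < 4:
        raise ValueError(f"need at least 4 samples for the t transform, got {n_samples}")
    r = np.asarray(r_matrix, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    n = r.shape[0]
    iu = np.triu_indices(n, k=1)
    rv = np.clip(r[iu], -1.0 + _R_CLIP_EPS, 1.0 - _R_CLIP_EPS)
    df = n_samples - 2
    tstat = rv * np.sqrt(df / (1.0 - rv**2))
    pvals = 2.0 * _sps.t.sf(np.abs(tstat), df)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    keep = reject & (rv > 0)
    w = np.zeros_like(r)
    zvals = np.arctanh(rv[keep])
    w[iu[0][keep], iu[1][keep]] = zvals
    w = w + w.T
    if node_labels is None:
        node_labels = [f"n{i}" for i in range(n)]
    return ConnectivityLayer(w, node_labels)


def assemble_multilayer(
    layers: list[ConnectivityLayer],
    network_map: dict[str, str],
    valid_networks: tuple[str, ...] = DEFAULT_NETWORKS,
) -> MultilayerNetwork:
    """Join per-occasion layers into one multilayer network, keyed by label.

    Layers whose node order differs are aligned by node label; a layer with
    a missing or extra node is an error (subjects must have complete data
    at every occasion).
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    ref = layers[0].node_labels
    ref_set = set(ref)
    aligned = [layers[0]]
    for i, layer in enumerate(layers[1:], start=1):
        cur = set(layer.node_labels)
        if cur != ref_set:
            missing = sorted(ref_set - cur)
            extra = sorted(cur - ref_set)
            raise ValueError(
                f"layer {i} node labels differ from layer 0: "
                f"missing={missing[:5]}, extra={extra[:5]}"
            )
        aligned.append(layer if layer.node_labels == ref else layer.reordered(ref))
    unlabeled = [n for n in ref if n not in network_map]
    if unlabeled:
        raise ValueError(f"network map does not cover nodes: {unlabeled[:5]}")
    bad = sorted({v for v in network_map.values()} - set(valid_networks))
    if bad:
        raise ValueError(f"unknown network names in map: {bad}")
    labels = {n: network_map[n] for n in ref}
    return MultilayerNetwork(aligned, list(ref), labels)


def build_layer(
    ts: ROITimeSeries,
    mode: str = "positive",
    alpha: float = 0.01,
) -> ConnectivityLayer:
    """Time series -> layer in one step.

    ``mode='positive'`` applies correlation -> Fisher z -> negative removal;
    ``mode='fdr'`` additionally keeps only FDR-significant edges at ``alpha``.
    """
    r = correlation_matrix(ts)
    if mode == "positive":
        return positivize(fisher_z(r), ts.node_labels)
    if mode == "fdr":
        return fdr_threshold(r, ts.values.shape[0], alpha, ts.node_labels)
    raise ValueError(f"unknown mode {mode!r}; expected 'positive' or 'fdr'")
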