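"""Graph-theoretic metrics on PLI networks over a sparsity-threshold sweep.

Channels are nodes and PLI values edge weights.  Because no single
proportional threshold is privileged, each metric is evaluated on a sweep of
sparsity values (proportion of strongest edges retained) and summarised by
the trapezoidal area under the metric-vs-sparsity curve (AUC).

Metrics:

* nodal clustering coefficient  C_i = 2 l_i / (k_i (k_i − 1)),
  l_i = number of edges among the neighbours of i, k_i = degree of i;
* network clustering            C_global = mean_i C_i;
* nodal efficiency              E_i = Σ_{j≠i} d_ij⁻¹ / (n − 1),
  d_ij = shortest-path distance (edge length 1 binarised, 1/weight
  weighted; disconnected pairs contribute 0);
* global efficiency             E_global = mean_i E_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import PLIMatrix
from .spectral import RoiSpec


class NetworkError(ValueError):
    pass


DEFAULT_SPARSITIES: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 11)
)  # 0.05 .. 0.50 step 0.05


@dataclass(frozen=True)
class NetworkGraph:
    """Thresholded undirected graph (symmetric, zero diagonal)."""

    adjacency: np.ndarray
    binarized: bool
    sparsity: float

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.float64)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise NetworkError("adjacency must be square")
        if not np.allclose(adj, adj.T) or np.any(np.diag(adj) != 0):
            raise NetworkError("adjacency must be symmetric with zero diagonal")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def threshold_graph(
    pli: PLIMatrix | np.ndarray, sparsity: float, binarize: bool = True
) -> NetworkGraph:
    """Keep the top ``round(s · n(n−1)/2)`` edges by weight.

    Rounding is half-up.  Ties at the cutoff weight are resolved
    deterministically in favour of the edge with the lower node index, then
    the lower partner index.
    """
    w = pli.pli if isinstance(pli, PLIMatrix) else np.asarray(pli, dtype=float)
    n = w.shape[0]
    m = n * (n - 1) // 2
    if not 0 < sparsity <= 1:
        raise NetworkError(f"sparsity must lie in (0, 1], got {sparsity}")
    k = int(math.floor(sparsity * m + 0.5))
    if k < 1:
        raise NetworkError(f"sparsity {sparsity} keeps zero of {m} edges")
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(m), key=lambda e: (-w[iu[e], ju[e]], iu[e], ju[e]))
    adj = np.zeros_like(w)
    for e in order[:k]:
        val = 1.0 if binarize else w[iu[e], ju[e]]
        adj[iu[e], ju[e]] = adj[ju[e], iu[e]] = val
    return NetworkGraph(adj, binarize, sparsity)


def clustering_coefficient(g: NetworkGraph) -> np.ndarray:
    """Nodal clustering C_i; 0 for nodes of degree < 2.

    On binarised graphs this is the printed edge-counting formula.  On
    weighted graphs the geometric-mean (Onnela) generalisation
    C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1)) is used, with
    weights normalised by the maximum weight.
    """
    adj = g.adjacency
    n = g.n_nodes
    present = adj > 0
    k = present.sum(axis=1)
    ci = np.zeros(n)
    if g.binarized:
        a = present.astype(float)
        # diag of A^3 counts closed triangles through each node (×2)
        triangles = np.diag(a @ a @ a)
        with np.errstate(divide="ignore", invalid="ignore"):
            ci = np.where(k >= 2, triangles / (k * (k - 1)), 0.0)
    else:
        wmax = adj.max()
        if wmax > 0:
            cube = np.cbrt(adj / wmax)
            triangles = np.diag(cube @ cube @ cube)
            with np.errstate(divide="ignore", invalid="ignore"):
                ci = np.where(k >= 2, triangles / (k * (k - 1)), 0.0)
    return np.asarray(ci, dtype=float)


def global_clustering(ci: np.ndarray) -> float:
    """C_global: arithmetic mean of the nodal clustering coefficients."""
    ci = np.asarray(ci, dtype=float)
    if ci.size == 0:
        raise NetworkError("empty nodal vector")
    return float(ci.mean())


def _distance_matrix(g: NetworkGraph) -> np.ndarray:
    lengths = np.zeros_like(g.adjacency)
    mask = g.adjacency > 0
    lengths[mask] = 1.0 if g.binarized else 1.0 / g.adjacency[mask]
    # dense csgraph input: zero entries are absent edges
    return shortest_path(lengths, method="D", directed=False)


def nodal_efficiency(g: NetworkGraph) -> np.ndarray:
    """E_i: mean inverse shortest-path distance from node i to all others."""
    n = g.n_nodes
    if n < 2:
        return np.zeros(n)
    d = _distance_matrix(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(ei: np.ndarray) -> float:
    """E_global: arithmetic mean of the nodal efficiencies."""
    ei = np.asarray(ei, dtype=float)
    if ei.size == 0:
        raise NetworkError("empty nodal vector")
    return float(ei.mean())


def metric_auc(values, sparsities) -> float:
    """Trapezoidal integral of a metric over the sparsity sweep."""
    values = np.asarray(values, dtype=float)
    s = np.asarray(sparsities, dtype=float)
    if values.shape != s.shape:
        raise NetworkError("values and sweep lengths differ")
    if np.any(np.diff(s) <= 0):
        raise NetworkError("sparsity sweep must be strictly increasing")
    return float(np.trapezoid(values, s))


def roi_nodal_average(values: np.ndarray, channel_labels, roi: RoiSpec) -> float:
    """Mean of a nodal metric over the ROI nodes (e.g. the motor cluster)."""
    idx = roi.indices(tuple(channel_labels))
    return float(np.asarray(values, dtype=float)[idx].mean())


@dataclass(frozen=True)
class GraphMetricSweep:
    """Per-threshold nodal/global clustering and efficiency, plus AUCs."""

    sparsities: tuple[float, ...]
    nodal_clustering: np.ndarray   # (n_thresholds, n_nodes)
    nodal_efficiency: np.ndarray   # (n_thresholds, n_nodes)
    global_clustering: np.ndarray  # (n_thresholds,)
    global_efficiency: np.ndarray  # (n_thresholds,)
    auc: dict[str, float] = field(default_factory=dict)


def graph_metric_sweep(
    pli: PLIMatrix,
    sparsities=DEFAULT_SPARSITIES,
    binarize: bool = True,
    roi: RoiSpec | None = None,
) -> GraphMetricSweep:
    """Evaluate clustering and efficiency across the sparsity sweep and
    integrate each to its AUC.  When ``roi`` is given, ROI-averaged nodal
    AUCs are included under ``cc_nodal_roi`` / ``eff_nodal_roi``."""
    s = tuple(float(x) for x in sparsities)
    n = pli.pli.shape[0]
    ncs, nes, gcs, ges = [], [], [], []
    for sp in s:
        g = threshold_graph(pli, sp, binarize=binarize)
        ci = clustering_coefficient(g)
        ei = nodal_efficiency(g)
        ncs.append(ci)
        nes.append(ei)
        gcs.append(global_clustering(ci))
        ges.append(global_efficiency(ei))
    nc = np.array(ncs)
    ne = np.array(nes)
    gc = np.array(gcs)
    ge = np.array(ges)
    auc = {
        "cc_global": metric_auc(gc, s),
        "eff_global": metric_auc(ge, s),
    }
    if roi is not None:
        roi_cc = [roi_nodal_average(row, pli.channel_labels, roi) for row in nc]
        roi_ef = [roi_nodal_average(row, pli.channel_labels, roi) for row in ne]
        auc["cc_nodal_roi"] = metric_auc(np.array(roi_cc), s)
        auc["eff_nodal_roi"] = metric_auc(np.array(roi_ef), s)
    return GraphMetricSweep(s, nc, ne, gc, ge, auc)
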