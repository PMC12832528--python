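"""Small-world and nodal topology with degree-preserving null models.

Global metrics: mean clustering coefficient Cp and characteristic path
length Lp, normalized against the mean of an ensemble of degree-preserving
random networks to give gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand> and
the small-world index sigma = gamma/lambda. Nodal metrics: clustering
coefficient (Onnela weighted form or binary), local efficiency
(Latora-Marchiori, on the neighborhood subgraph) and binary degree.
Nodal metrics are reported raw by default; degree is never normalized
(rewiring preserves it exactly, so its null ratio is identically one).
Metrics computed per sparsity level are summarized by trapezoid AUC.

Null networks use Maslov-Sneppen double-edge swaps on the binary topology
with the original weights randomly permuted onto the rewired edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .fc import ConnectivityMatrix
from .stats import trapezoid_auc

logger = logging.getLogger(__name__)

__all__ = [
    "SmallWorldResult",
    "nodal_clustering",
    "characteristic_path_length",
    "nodal_local_efficiency",
    "nodal_degree",
    "degree_preserving_random",
    "small_world",
    "nodal_topology",
    "auc_over_grid",
]


@dataclass
class SmallWorldResult:
    """Null-normalized small-world metrics at one sparsity."""

    gamma: float
    lambda_: float
    sigma: float
    cp: float
    lp: float
    cp_null_mean: float
    lp_null_mean: float


def nodal_clustering(m: ConnectivityMatrix, mode: str = "weighted") -> np.ndarray:
    """Per-node clustering coefficient.

    Binary: triangles / (k(k-1)/2). Weighted (Onnela): geometric-mean
    triangle intensity with weights scaled by the network maximum,
    C_i = (1/(k_i(k_i-1))) * sum_jh (w_ij w_ih w_jh)^(1/3) on scaled
    weights; the denominator uses the binary degree. Nodes with fewer
    than two neighbors get 0.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown mode: {mode!r}")
    w = m.weights
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(m.n_nodes)
    ok = denom > 0
    if mode == "binary":
        tri = np.diagonal(a @ a @ a)
        out[ok] = tri[ok] / denom[ok]
    else:
        mx = w.max()
        if mx == 0:
            return out
        cube = np.cbrt(w / mx)
        tri = np.diagonal(cube @ cube @ cube)
        out[ok] = tri[ok] / denom[ok]
    return out


def _distance_matrix(m: ConnectivityMatrix, mode: str) -> np.ndarray:
    w = m.weights
    if mode == "binary":
        lengths = (w > 0).astype(float)
        return shortest_path(csr_matrix(lengths), method="D", unweighted=True)
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return shortest_path(csr_matrix(lengths), method="D")


def characteristic_path_length(m: ConnectivityMatrix,
                               mode: str = "weighted") -> float:
    """Mean shortest-path length over connected ordered node pairs.

    Weighted paths use edge lengths 1/w. Disconnected pairs are excluded;
    their count is logged so harmonic-mean efficiency can be cross-checked.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown mode: {mode!r}")
    if m.n_edges == 0:
        raise ValueError("network has no edges")
    d = _distance_matrix(m, mode)
    n = m.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int(off.sum() - finite.sum())
    if n_excluded:
        logger.debug("path length: %d disconnected ordered pairs excluded",
                     n_excluded)
    return float(d[finite].mean())


def nodal_local_efficiency(m: ConnectivityMatrix,
                           mode: str = "weighted") -> np.ndarray:
    """Latora-Marchiori local efficiency of each node's neighborhood.

    E_loc,i = mean over ordered pairs of neighbors of i of 1/d_jh, with
    d computed inside the neighbor subgraph (disconnected pairs contribute
    zero). Nodes with fewer than two neighbors get 0.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown mode: {mode!r}")
    w = m.weights
    out = np.zeros(m.n_nodes)
    for i in range(m.n_nodes):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = ConnectivityMatrix(w[np.ix_(nbrs, nbrs)],
                                 [str(j) for j in nbrs])
        d = _distance_matrix(sub, mode)
        off = ~np.eye(nbrs.size, dtype=bool)
        inv = np.zeros_like(d)
        finite = np.isfinite(d) & (d > 0)
        inv[finite] = 1.0 / d[finite]
        out[i] = inv[off].mean()
    return out


def nodal_degree(m: ConnectivityMatrix) -> np.ndarray:
    """Binary degree: number of nonzero edges per node."""
    return (m.weights > 0).sum(axis=1)


def degree_preserving_random(m: ConnectivityMatrix, n_networks: int = 1000,
                             n_swap_factor: int = 10,
                             seed=0) -> list[ConnectivityMatrix]:
    """Maslov-Sneppen rewired ensemble preserving the degree sequence.

    For each null network, ``n_swap_factor * n_edges`` double-edge swaps
    are attempted on the binary topology (rejecting self-loops and
    multi-edges), then the original edge weights are randomly permuted
    onto the rewired edges. If no swap ever succeeds (for example a star
    graph), the original network is returned with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = m.n_nodes
    ii, jj = np.nonzero(np.triu(m.weights, 1))
    weights = m.weights[ii, jj]
    n_edges = ii.size
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    nulls = []
    for _ in range(n_networks):
        heads = ii.copy()
        tails = jj.copy()
        edge_set = set(zip(heads.tolist(), tails.tolist()))
        attempts = n_swap_factor * n_edges
        pick = rng.integers(0, n_edges, size=(attempts, 2))
        flip = rng.random(attempts) < 0.5
        n_success = 0
        for t in range(attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = heads[e1], tails[e1]
            c, d = heads[e2], tails[e2]
            if flip[t]:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in edge_set or new2 in edge_set or new1 == new2:
                continue
            edge_set.discard((a, b))
            edge_set.discard((min(c, d), max(c, d)) if flip[t] else (c, d))
            edge_set.add(new1)
            edge_set.add(new2)
            heads[e1], tails[e1] = new1
            heads[e2], tails[e2] = new2
            n_success += 1
        if n_success == 0:
            logger.warning("no successful swaps; returning original topology")
        out = np.zeros((n, n))
        perm = rng.permutation(n_edges)
        out[heads, tails] = weights[perm]
        out = out + out.T
        nulls.append(ConnectivityMatrix(out, list(m.node_labels),
                                        sparsity=m.sparsity))
    return nulls


def small_world(m: ConnectivityMatrix, nulls: list[ConnectivityMatrix],
                mode: str = "weighted") -> SmallWorldResult:
    """gamma, lambda and sigma = gamma/lambda against a null ensemble."""
    cp = float(nodal_clustering(m, mode).mean())
    lp = characteristic_path_length(m, mode)
    cp_null = float(np.mean([nodal_clustering(x, mode).mean() for x in nulls]))
    lp_null = float(np.mean([characteristic_path_length(x, mode) for x in nulls]))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null ensemble mean is zero; cannot normalize")
    gamma = cp / cp_null
    lam = lp / lp_null
    return SmallWorldResult(gamma, lam, gamma / lam, cp, lp, cp_null, lp_null)


def nodal_topology(m: ConnectivityMatrix, mode: str = "weighted",
                   nulls: list[ConnectivityMatrix] | None = None) -> dict:
    """Per-node clustering, local efficiency and degree.

    With a null ensemble, clustering and local efficiency are also
    returned normalized by the null means (degree is never normalized:
    degree-preserving rewiring fixes it exactly, so its ratio is
    identically one). Raw values are the default report quantities.
    """
    out = {
        "clustering": nodal_clustering(m, mode),
        "local_efficiency": nodal_local_efficiency(m, mode),
        "degree": nodal_degree(m),
    }
    if nulls:
        cp_null = np.mean([nodal_clustering(x, mode) for x in nulls], axis=0)
        el_null = np.mean([nodal_local_efficiency(x, mode) for x in nulls],
                          axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["clustering_normalized"] = np.where(
                cp_null > 0, out["clustering"] / cp_null, np.nan)
            out["local_efficiency_normalized"] = np.where(
                el_null > 0, out["local_efficiency"] / el_null, np.nan)
    return out


def auc_over_grid(values, grid) -> float:
    """Trapezoid AUC of a metric sampled over the sparsity grid."""
    return trapezoid_auc(np.asarray(grid, dtype=float),
                         np.asarray(values, dtype=float))
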