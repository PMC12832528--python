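"""Network-based statistics (NBS) on a subnetwork of major connector hubs.

Edge-wise one-tailed permutation tests on group mean connectivity
differences, a primary threshold (p < 0.005 uncorrected) defining
suprathreshold edges, extraction of connected components of those edges,
and family-wise-error correction of each component's edge count against
the permutation null distribution of the maximum component size. One
analysis is run per direction of effect, each at one-tailed alpha 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

__all__ = [
    "NBSComponent",
    "NBSResult",
    "edgewise_group_p",
    "suprathreshold_components",
    "nbs",
]


@dataclass
class NBSComponent:
    """One suprathreshold connected component."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    size: int                    # edge count
    corrected_p: float
    significant: bool


@dataclass
class NBSResult:
    components: list[NBSComponent]
    direction: str
    n_perm: int
    alpha: float

    @property
    def significant_components(self) -> list[NBSComponent]:
        return [c for c in self.components if c.significant]


def _stack_to_edges(stack: np.ndarray) -> tuple[np.ndarray, tuple]:
    """(n_subjects, N, N) -> (n_subjects, E) upper-triangle edge matrix."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("stack must be (n_subjects, N, N)")
    iu = np.triu_indices(stack.shape[1], 1)
    return stack[:, iu[0], iu[1]], iu


def _group_indices(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pat = np.flatnonzero(labels == "patient")
    ctrl = np.flatnonzero(labels == "control")
    if pat.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    return pat, ctrl


def _edge_stat(a: np.ndarray, b: np.ndarray, statistic: str) -> np.ndarray:
    """Per-edge group statistic: mean difference or two-sample pooled t."""
    diff = a.mean(axis=0) - b.mean(axis=0)
    if statistic == "mean_diff":
        return diff
    n1, n2 = a.shape[0], b.shape[0]
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1)
           + (n2 - 1) * b.var(axis=0, ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    return t


def _perm_stats(data: np.ndarray, pat: np.ndarray, ctrl: np.ndarray,
                direction: str, n_perm: int, rng: np.random.Generator,
                statistic: str = "mean_diff") -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted signed group statistics per edge."""
    if direction not in ("patient_greater", "control_greater"):
        raise ValueError(f"unknown direction: {direction!r}")
    if statistic not in ("mean_diff", "t"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    sign = 1.0 if direction == "patient_greater" else -1.0
    observed = sign * _edge_stat(data[pat], data[ctrl], statistic)
    n_total = data.shape[0]
    n_pat = pat.size
    perm = np.empty((n_perm, data.shape[1]))
    for k in range(n_perm):
        idx = rng.permutation(n_total)
        perm[k] = sign * _edge_stat(data[idx[:n_pat]], data[idx[n_pat:]],
                                    statistic)
    return observed, perm


def edgewise_group_p(stack, labels, direction: str = "patient_greater",
                     n_perm: int = 5000, seed=0,
                     statistic: str = "mean_diff") -> np.ndarray:
    """One-tailed permutation p-value per edge, as a symmetric matrix.

    p = (1 + #{permuted stat >= observed stat}) / (1 + n_perm).
    ``statistic`` selects the group mean difference (default) or a
    pooled-variance t-statistic.
    """
    data, iu = _stack_to_edges(stack)
    pat, ctrl = _group_indices(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed, perm = _perm_stats(data, pat, ctrl, direction, n_perm, rng,
                                 statistic)
    p_edge = (1.0 + np.sum(perm >= observed, axis=0)) / (1.0 + n_perm)
    n = stack[0].shape[0]
    p = np.ones((n, n))
    p[iu] = p_edge
    p[(iu[1], iu[0])] = p_edge
    np.fill_diagonal(p, 1.0)
    return p


def _components_from_mask(mask: np.ndarray, iu) -> list[tuple[list[int], list[tuple[int, int]]]]:
    """Connected components (>= 1 edge) of the suprathreshold edge graph."""
    if not mask.any():
        return []
    n = int(iu[1].max()) + 1
    adj = np.zeros((n, n), dtype=bool)
    src, dst = iu[0][mask], iu[1][mask]
    adj[src, dst] = True
    adj[dst, src] = True
    n_comp, assign = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        nodes = np.flatnonzero(assign == c)
        if nodes.size < 2:
            continue
        in_comp = np.isin(src, nodes)
        edges = list(zip(src[in_comp].tolist(), dst[in_comp].tolist()))
        if edges:
            out.append((nodes.tolist(), edges))
    return out


def suprathreshold_components(edge_p: np.ndarray, primary_p: float = 0.005):
    """Connected components of edges with p < primary_p.

    Returns a list of (node list, edge list) pairs; sizes are edge counts.
    """
    edge_p = np.asarray(edge_p, dtype=float)
    if not np.allclose(edge_p, edge_p.T):
        raise ValueError("edge p matrix must be symmetric")
    iu = np.triu_indices(edge_p.shape[0], 1)
    mask = edge_p[iu] < primary_p
    return _components_from_mask(mask, iu)


def _max_component_size(mask: np.ndarray, iu) -> int:
    comps = _components_from_mask(mask, iu)
    return max((len(edges) for _, edges in comps), default=0)


def nbs(stack, labels, primary_p: float = 0.005, n_perm: int = 5000,
        alpha: float = 0.025, direction: str = "patient_greater",
        seed=0, statistic: str = "mean_diff") -> NBSResult:
    """Full NBS run in one direction.

    The same seeded permutation sequence yields the edge-level p-values
    and the max-component-size null: each permutation's statistics are
    converted to edge p-values by their rank among all permutations, the
    primary threshold applied, and the largest component recorded. A
    component of size s gets corrected p = (1 + #{max_null >= s}) / (1 + n_perm).
    """
    data, iu = _stack_to_edges(stack)
    pat, ctrl = _group_indices(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed, perm = _perm_stats(data, pat, ctrl, direction, n_perm, rng,
                                 statistic)

    p_obs = (1.0 + np.sum(perm >= observed, axis=0)) / (1.0 + n_perm)
    observed_comps = _components_from_mask(p_obs < primary_p, iu)

    # rank each permutation's statistic among all permutations per edge:
    # count of permuted stats >= this one (self excluded, as for observed)
    cnt_ge = rankdata(-perm, axis=0, method="max")
    p_perm = cnt_ge / (1.0 + n_perm)
    null_max = np.array([_max_component_size(p_perm[k] < primary_p, iu)
                         for k in range(n_perm)])

    components = []
    for nodes, edges in observed_comps:
        size = len(edges)
        corr_p = (1.0 + np.sum(null_max >= size)) / (1.0 + n_perm)
        components.append(NBSComponent(nodes, edges, size, float(corr_p),
                                       bool(corr_p < alpha)))
    components.sort(key=lambda c: -c.size)
    return NBSResult(components, direction, n_perm, alpha)
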