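"""Functional connectivity matrix construction and proportional thresholding.

A subject's regional time series become an undirected, weighted,
nonnegative connectivity matrix: pairwise Pearson correlation, Fisher
z-transform, optional standardization of the subject's edge distribution,
and rectification of negative edges to zero. Matrices are then thresholded
proportionally — keeping the strongest fraction S of all possible edges —
over a grid of sparsity values so that every subject's network has the
same number of edges at each grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectTimeSeries",
    "ConnectivityMatrix",
    "SparsityGrid",
    "compute_fc_matrix",
    "threshold_proportional",
]

#: correlations are clipped to +-(1 - R_CLIP) before the Fisher transform
#: so that duplicated series yield a large but finite weight
R_CLIP = 1e-7


@dataclass
class SubjectTimeSeries:
    """One subject's T x N node signal table."""

    data: np.ndarray                 # shape (T, N)
    node_labels: list[str]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (T, N) array")
        if self.data.shape[1] != len(self.node_labels):
            raise ValueError("node_labels length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted network with zero diagonal.

    ``sparsity`` is the fraction of possible edges retained, or ``None``
    for an unthresholded matrix.
    """

    weights: np.ndarray
    node_labels: list[str]
    sparsity: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length must match matrix size")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero edges (unordered pairs)."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class SparsityGrid:
    """Ordered grid of proportional-threshold levels.

    Defaults cover 5-30% of the strongest edges in 1% steps, with 15%
    as the single reference level used for module and hub statistics.
    """

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(5, 31) / 100.0, 2))
    reference_sparsity: float = 0.15

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("sparsity values must lie in (0, 1)")
        self.values = v


def compute_fc_matrix(ts: SubjectTimeSeries, standardize: bool = True,
                      rectify_on: str = "standardized") -> ConnectivityMatrix:
    """Pearson -> Fisher z -> (optional) z-scoring -> negative rectification.

    Pairwise Pearson correlations between node series are clipped to
    ``+-(1 - 1e-7)`` and Fisher z-transformed. With ``standardize`` the
    subject's upper-triangle z-values are scaled to zero mean and unit
    variance. Edges that are negative under the ``rectify_on`` convention
    ('standardized': the z-scored value; 'raw': the raw Fisher z, i.e.
    the correlation sign) are set to zero; remaining negatives are floored
    at zero so the output weights are always nonnegative.
    """
    if rectify_on not in ("raw", "standardized"):
        raise ValueError(f"unknown rectify_on: {rectify_on!r}")
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contain non-finite values")
    constant = np.ptp(x, axis=0) == 0
    if np.any(constant):
        bad = [ts.node_labels[i] for i in np.flatnonzero(constant)]
        raise ValueError(f"constant time series for node(s): {bad}")

    r = np.corrcoef(x, rowvar=False)
    np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)

    iu = np.triu_indices(z.shape[0], 1)
    if standardize:
        edge = z[iu]
        scaled = (z - edge.mean()) / edge.std()
        values = scaled
    else:
        values = z
    reference = values if rectify_on == "standardized" else z
    out = np.where(reference < 0, 0.0, values)
    out = np.maximum(out, 0.0)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, list(ts.node_labels), sparsity=None)


def n_edges_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """Number of retained edges K = floor(S * N(N-1)/2)."""
    e_max = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * e_max))


def threshold_proportional(m: ConnectivityMatrix,
                           sparsity: float) -> ConnectivityMatrix:
    """Keep the K = floor(S*N(N-1)/2) strongest edges, zero the rest.

    Retained weights are unchanged (the network stays weighted). Ties at
    the cut are broken by lexicographic node-pair order, which makes the
    retained edge sets nested across increasing sparsity levels.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = m.n_nodes
    k = n_edges_at_sparsity(n, sparsity)
    iu = np.triu_indices(n, 1)
    w = m.weights[iu]
    n_positive = int(np.count_nonzero(w > 0))
    if n_positive < k:
        achievable = n_positive / (n * (n - 1) // 2)
        raise ValueError(
            f"only {n_positive} positive edges available; requested sparsity "
            f"{sparsity:.3f} needs {k} (achievable sparsity {achievable:.4f})")
    # stable ordering: descending weight, ties by (i, j) lexicographic;
    # upper-triangle indices are already lexicographic, so a stable sort
    # on -w alone preserves that order within ties
    order = np.argsort(-w, kind="stable")
    keep = order[:k]
    out = np.zeros_like(m.weights)
    out[iu[0][keep], iu[1][keep]] = w[keep]
    out = out + out.T
    result = ConnectivityMatrix(out, list(m.node_labels), sparsity=sparsity)
    _warn_if_disconnected(result)
    return result


def _warn_if_disconnected(m: ConnectivityMatrix) -> None:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(csr_matrix(m.weights), directed=False)
    if n_comp > 1:
        logger.warning(
            "thresholded network at sparsity %s is disconnected "
            "(%d components)", m.sparsity, n_comp)
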