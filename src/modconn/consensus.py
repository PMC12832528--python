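"""Consensus Louvain community detection and the group partition template.

The Louvain algorithm is stochastic: different node orders give different
local optima. To obtain a stable partition, it is run many times on each
subject's thresholded network, the runs are summarized in an agreement
(consensus) matrix of pairwise co-assignment frequencies, the matrix is
thresholded at tau and re-clustered, and the loop repeats until every run
returns the same partition (equivalently, the agreement matrix is binary
block-diagonal). Subject-level agreement matrices are averaged across the
pooled cohort and the same consensus iteration applied to the average,
yielding one group-level template partition that is then imposed on every
subject for all downstream module statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .fc import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "AgreementMatrix",
    "ConsensusConfig",
    "louvain",
    "agreement",
    "consensus_partition",
    "group_template",
]


@dataclass
class Partition:
    """Node -> module assignment with canonical contiguous labels from 1."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = canonicalize_labels(np.asarray(self.labels, dtype=int))

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def modules(self) -> list[np.ndarray]:
        """Node indices of each module, in label order."""
        return [np.flatnonzero(self.labels == m)
                for m in range(1, self.n_modules + 1)]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by first appearance in node order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass
class AgreementMatrix:
    """Pairwise co-assignment frequencies across a set of partitions."""

    co_assignment: np.ndarray
    n_partitions: int

    def is_binary(self) -> bool:
        d = self.co_assignment
        return bool(np.all((d == 0.0) | (d == 1.0)))


@dataclass
class ConsensusConfig:
    """Consensus-procedure parameters.

    ``n_runs`` Louvain repetitions per iteration (study value 1000),
    agreement threshold ``tau`` = 0.2, Louvain ``resolution`` = 1.0,
    and a hard cap on consensus iterations.
    """

    n_runs: int = 1000
    tau: float = 0.2
    resolution: float = 1.0
    max_iterations: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")


class ConsensusError(RuntimeError):
    """Raised when the consensus iteration fails to converge."""

    def __init__(self, message: str, agreement_matrix: AgreementMatrix):
        super().__init__(message)
        self.agreement_matrix = agreement_matrix


def _to_graph(weights: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(weights.shape[0]))
    ii, jj = np.nonzero(np.triu(weights, 1))
    g.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(),
                                  weights[ii, jj].tolist()))
    return g


def louvain(m: ConnectivityMatrix | np.ndarray, resolution: float = 1.0,
            seed: int = 0) -> Partition:
    """One seeded Louvain run (greedy modularity with node aggregation).

    Isolated nodes end up in singleton modules. Deterministic given seed.
    """
    weights = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    g = _to_graph(weights)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed))
    labels = np.empty(weights.shape[0], dtype=int)
    for k, nodes in enumerate(communities):
        labels[list(nodes)] = k + 1
    return Partition(labels)


def _louvain_runs(weights: np.ndarray, n_runs: int, resolution: float,
                  seeds: np.ndarray) -> np.ndarray:
    """Stack of label vectors from n_runs seeded Louvain runs."""
    g = _to_graph(weights)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    n = weights.shape[0]
    out = np.empty((n_runs, n), dtype=int)
    for r in range(n_runs):
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(seeds[r]))
        for k, nodes in enumerate(communities):
            out[r, list(nodes)] = k + 1
    return out


def agreement(partitions) -> AgreementMatrix:
    """Fraction of partitions assigning each node pair to the same module."""
    stacks = []
    for p in partitions:
        labels = p.labels if isinstance(p, Partition) else np.asarray(p)
        stacks.append(labels)
    if not stacks:
        raise ValueError("need at least one partition")
    arr = np.asarray(stacks)
    if arr.ndim != 2:
        raise ValueError("partitions must share one node set")
    co = np.zeros((arr.shape[1], arr.shape[1]))
    for labels in arr:
        co += labels[:, None] == labels[None, :]
    co /= arr.shape[0]
    return AgreementMatrix(co, arr.shape[0])


def _consensus_iterate(d: np.ndarray, cfg: ConsensusConfig,
                       seed_base: int) -> Partition:
    """Threshold-recluster loop on an agreement matrix until all runs agree.

    Entries <= tau are zeroed before each re-clustering pass. Nodes left
    isolated by the thresholding keep singleton modules (the Louvain pass
    assigns them their own community).
    """
    n = d.shape[0]
    last = AgreementMatrix(d, 0)
    for it in range(cfg.max_iterations):
        dt = np.where(d > cfg.tau, d, 0.0)
        np.fill_diagonal(dt, 0.0)
        if not dt.any():
            # fully disagreeing runs: every node its own module
            return Partition(np.arange(1, n + 1))
        seeds = seed_base + 10_000 * (it + 1) + np.arange(cfg.n_runs)
        runs = _louvain_runs(dt, cfg.n_runs, cfg.resolution, seeds)
        if all(np.array_equal(runs[0], r) for r in runs[1:]):
            return Partition(runs[0])
        last = agreement(runs)
        d = last.co_assignment
    raise ConsensusError(
        f"consensus did not converge in {cfg.max_iterations} iterations", last)


def consensus_partition(m: ConnectivityMatrix,
                        cfg: ConsensusConfig) -> Partition:
    """Consensus partition of a single network.

    Runs Louvain ``n_runs`` times on the network, then iterates the
    agreement-threshold-recluster loop until all runs coincide.
    """
    seeds = cfg.seed + np.arange(cfg.n_runs)
    runs = _louvain_runs(m.weights, cfg.n_runs, cfg.resolution, seeds)
    if all(np.array_equal(runs[0], r) for r in runs[1:]):
        return Partition(runs[0])
    d = agreement(runs).co_assignment
    return _consensus_iterate(d, cfg, cfg.seed)


def subject_agreement(m: ConnectivityMatrix, cfg: ConsensusConfig,
                      subject_index: int = 0) -> AgreementMatrix:
    """Agreement matrix of ``n_runs`` Louvain runs on one subject's network.

    Run r of subject s uses seed ``cfg.seed + s * 10**6 + r`` so the whole
    cohort procedure is reproducible and streams never collide.
    """
    seeds = cfg.seed + subject_index * 1_000_000 + np.arange(cfg.n_runs)
    runs = _louvain_runs(m.weights, cfg.n_runs, cfg.resolution, seeds)
    return agreement(runs)


def group_template(subject_matrices, cfg: ConsensusConfig) -> Partition:
    """Group-level community template from all subjects' networks.

    Each subject contributes an agreement matrix over ``n_runs`` Louvain
    runs; the matrices are averaged across the pooled cohort (both groups)
    and the consensus iteration applied to the average.
    """
    matrices = list(subject_matrices)
    if not matrices:
        raise ValueError("need at least one subject matrix")
    n = matrices[0].n_nodes
    labels0 = matrices[0].node_labels
    mean_d = np.zeros((n, n))
    for s, m in enumerate(matrices):
        if m.n_nodes != n or m.node_labels != labels0:
            raise ValueError("all subject matrices must share one node set")
        mean_d += subject_agreement(m, cfg, s).co_assignment
    mean_d /= len(matrices)
    # seeds for the group-level reruns live above the per-subject ladder
    return _consensus_iterate(mean_d, cfg, cfg.seed + len(matrices) * 1_000_000)
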