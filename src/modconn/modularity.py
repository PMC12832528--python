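"""Modularity Q and average strength of modular interaction (ASMI).

Q is Newman's weighted modularity of a fixed partition, computed per
subject at every sparsity level and summarized by its trapezoidal AUC
over the grid. ASMI between two modules is the sum of the weights of
their connecting (suprathreshold) edges divided by the number of those
edges — a mean connecting-edge strength, evaluated at the single
reference sparsity. Group differences in ASMI are assessed per module
pair by two-tailed label-permutation tests on the group mean difference,
Benjamini-Hochberg corrected across the pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .consensus import Partition
from .fc import ConnectivityMatrix
from .stats import fdr_bh, trapezoid_auc

logger = logging.getLogger(__name__)

__all__ = [
    "ModularityResult",
    "ModuleInteractionTable",
    "modularity_q",
    "q_curve_and_auc",
    "asmi",
    "asmi_group_test",
]


@dataclass
class ModularityResult:
    """One subject's Q over the sparsity grid with its AUC."""

    sparsities: np.ndarray
    q_values: np.ndarray
    q_auc: float
    q_at_reference: float


@dataclass
class ModuleInteractionTable:
    """ASMI and connecting-edge counts per unordered module pair.

    Pairs without any connecting edge have ``asmi[pair] = nan`` and
    ``edge_counts[pair] = 0``.
    """

    asmi: dict[tuple[int, int], float]
    edge_counts: dict[tuple[int, int], int]


def modularity_q(m: ConnectivityMatrix, p: Partition) -> float:
    """Weighted Newman modularity of partition ``p`` on network ``m``.

    Q = (1/2W) sum_ij [w_ij - s_i s_j / 2W] delta(c_i, c_j), with s the
    node strengths and 2W the total matrix weight.
    """
    w = m.weights
    if p.n_nodes != m.n_nodes:
        raise ValueError("partition must cover all nodes")
    total = w.sum()  # = 2W
    if total == 0:
        raise ValueError("network has zero total weight")
    strength = w.sum(axis=1)
    q = 0.0
    for nodes in p.modules():
        block = w[np.ix_(nodes, nodes)].sum()
        s_mod = strength[nodes].sum()
        q += block / total - (s_mod / total) ** 2
    return float(q)


def q_curve_and_auc(matrices_by_sparsity: dict[float, ConnectivityMatrix],
                    template: Partition,
                    reference_sparsity: float = 0.15) -> ModularityResult:
    """Q at every grid sparsity under a fixed template, with trapezoid AUC."""
    if len(matrices_by_sparsity) < 2:
        raise ValueError("AUC needs at least two sparsity levels")
    sparsities = np.array(sorted(matrices_by_sparsity))
    q_values = np.array([modularity_q(matrices_by_sparsity[s], template)
                         for s in sparsities])
    auc = trapezoid_auc(sparsities, q_values)
    ref_idx = int(np.argmin(np.abs(sparsities - reference_sparsity)))
    return ModularityResult(sparsities, q_values, auc, float(q_values[ref_idx]))


def asmi(m: ConnectivityMatrix, p: Partition) -> ModuleInteractionTable:
    """Average strength of modular interaction for every module pair.

    ASMI(A, B) = sum of weights of nonzero edges between A and B divided
    by the count of those edges. Each unordered node pair counts once.
    """
    if p.n_modules < 2:
        raise ValueError("partition must have at least 2 modules")
    if p.n_nodes != m.n_nodes:
        raise ValueError("partition must cover all nodes")
    w = m.weights
    modules = p.modules()
    values: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for (a, nodes_a), (b, nodes_b) in combinations(enumerate(modules, 1), 2):
        block = w[np.ix_(nodes_a, nodes_b)]
        n_edges = int(np.count_nonzero(block))
        counts[(a, b)] = n_edges
        values[(a, b)] = float(block.sum() / n_edges) if n_edges else float("nan")
    return ModuleInteractionTable(values, counts)


def asmi_group_test(controls: list[ModuleInteractionTable],
                    patients: list[ModuleInteractionTable],
                    n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-pair two-tailed permutation test on group mean ASMI difference.

    The statistic is mean(patient) - mean(control); p-values use the +1
    correction and are BH-adjusted across the module pairs. Pairs that
    are undefined (no connecting edge) in any subject are excluded with
    a warning.
    """
    if not controls or not patients:
        raise ValueError("both groups must be nonempty")
    pairs = sorted(controls[0].asmi)
    usable: list[tuple[int, int]] = []
    for pair in pairs:
        vals = [t.asmi[pair] for t in controls + patients]
        if any(np.isnan(v) for v in vals):
            logger.warning("module pair %s undefined in some subject; excluded",
                           pair)
            continue
        usable.append(pair)
    if not usable:
        raise ValueError("no module pair defined in every subject")

    ctrl = np.array([[t.asmi[pair] for pair in usable] for t in controls])
    pat = np.array([[t.asmi[pair] for pair in usable] for t in patients])
    n_pat = pat.shape[0]
    pooled = np.vstack([pat, ctrl])
    observed = pat.mean(axis=0) - ctrl.mean(axis=0)

    rng = np.random.default_rng(seed)
    n_total = pooled.shape[0]
    exceed = np.zeros(len(usable))
    for _ in range(n_perm):
        idx = rng.permutation(n_total)
        diff = pooled[idx[:n_pat]].mean(axis=0) - pooled[idx[n_pat:]].mean(axis=0)
        exceed += np.abs(diff) >= np.abs(observed)
    raw_p = (1.0 + exceed) / (1.0 + n_perm)
    adj_p = fdr_bh(raw_p)

    return pd.DataFrame({
        "module_pair": [f"{a}-{b}" for a, b in usable],
        "patient_mean": pat.mean(axis=0),
        "patient_sd": pat.std(axis=0, ddof=1),
        "control_mean": ctrl.mean(axis=0),
        "control_sd": ctrl.std(axis=0, ddof=1),
        "mean_difference": observed,
        "p_raw": raw_p,
        "p_fdr": adj_p,
    })
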