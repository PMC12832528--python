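"""Connector-hub analysis: participation coefficient, within-module degree.

Under the fixed group template, each node's participation coefficient
(PC, Guimera-Amaral) measures how evenly its connections spread across
modules, and the within-module degree z-score (WMD) standardizes its
within-module connectivity against the other nodes of its module.
Connector hubs (CHs) are nodes with PC > 0.3 and WMD > mean + SD of the
subject's WMD distribution. The PC/WMD ratio of a CH quantifies the
balance of its between- versus within-module communication; group
comparisons use the pooled CH/non-CH count table (chi-square) and a
two-sample t-test on subject-level mean ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import Partition
from .fc import ConnectivityMatrix
from .stats import TestResult, chi_square_2x2, t_test_from_summary

logger = logging.getLogger(__name__)

__all__ = [
    "NodalHubMetrics",
    "ChFrequencyTable",
    "participation_coefficient",
    "within_module_degree_z",
    "select_connector_hubs",
    "compute_hub_metrics",
    "ch_count_test",
    "pc_wmd_ratio_test",
    "ch_frequency_ranking",
]

PC_THRESHOLD = 0.3


@dataclass
class NodalHubMetrics:
    """Per-node hub metrics of one subject at a fixed sparsity."""

    pc: np.ndarray
    wmd: np.ndarray
    is_ch: np.ndarray
    node_labels: list[str]

    @property
    def ch_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.is_ch)

    def mean_pc_wmd_ratio(self) -> float:
        """Mean PC/WMD over this subject's connector hubs (nan if none).

        A CH with WMD <= 0 cannot arise when mean + SD > 0, but is
        guarded against and excluded with a warning.
        """
        idx = self.ch_nodes
        if idx.size == 0:
            return float("nan")
        wmd = self.wmd[idx]
        ok = wmd > 0
        if not np.all(ok):
            logger.warning("excluding %d connector hub(s) with WMD <= 0",
                           int(np.sum(~ok)))
            idx = idx[ok]
            if idx.size == 0:
                return float("nan")
        return float(np.mean(self.pc[idx] / self.wmd[idx]))


@dataclass
class ChFrequencyTable:
    """How many subjects designate each node a connector hub."""

    counts: pd.Series        # node label -> count, in original node order
    top_set: list[str]       # labels of the floor(top_fraction * N) nodes


def _module_connection(w: np.ndarray, p: Partition, mode: str) -> np.ndarray:
    """kappa[i, s]: connection of node i to module s (strength or count)."""
    if mode not in ("strength", "binary"):
        raise ValueError(f"unknown mode: {mode!r}")
    a = w if mode == "strength" else (w > 0).astype(float)
    n_modules = p.n_modules
    kappa = np.empty((w.shape[0], n_modules))
    for s, nodes in enumerate(p.modules()):
        kappa[:, s] = a[:, nodes].sum(axis=1)
    return kappa


def participation_coefficient(m: ConnectivityMatrix, p: Partition,
                              mode: str = "strength") -> np.ndarray:
    """PC_i = 1 - sum_s (kappa_is / k_i)^2; zero for isolated nodes."""
    kappa = _module_connection(m.weights, p, mode)
    k = kappa.sum(axis=1)
    pc = np.zeros(m.n_nodes)
    connected = k > 0
    frac = kappa[connected] / k[connected, None]
    pc[connected] = 1.0 - np.sum(frac * frac, axis=1)
    return pc


def within_module_degree_z(m: ConnectivityMatrix, p: Partition,
                           mode: str = "strength") -> np.ndarray:
    """z-score of within-module connectivity against the node's own module.

    Uses the population (divide-by-n) standard deviation; modules of size
    one, or whose within-module degrees are all equal, get z = 0.
    """
    kappa = _module_connection(m.weights, p, mode)
    z = np.zeros(m.n_nodes)
    for s, nodes in enumerate(p.modules()):
        within = kappa[nodes, s]
        sd = within.std()
        if nodes.size > 1 and sd > 0:
            z[nodes] = (within - within.mean()) / sd
    return z


def select_connector_hubs(pc: np.ndarray, wmd: np.ndarray,
                          pc_threshold: float = PC_THRESHOLD) -> np.ndarray:
    """Boolean CH mask: PC > threshold and WMD > mean + SD (strict).

    The WMD moments are taken over all nodes of the subject, with the
    population standard deviation.
    """
    pc = np.asarray(pc, dtype=float)
    wmd = np.asarray(wmd, dtype=float)
    if pc.shape != wmd.shape:
        raise ValueError("pc and wmd must have the same length")
    cut = wmd.mean() + wmd.std()
    return (pc > pc_threshold) & (wmd > cut)


def compute_hub_metrics(m: ConnectivityMatrix, p: Partition,
                        mode: str = "strength",
                        pc_threshold: float = PC_THRESHOLD) -> NodalHubMetrics:
    """PC, WMD and the CH flag for one subject's thresholded network."""
    pc = participation_coefficient(m, p, mode)
    wmd = within_module_degree_z(m, p, mode)
    is_ch = select_connector_hubs(pc, wmd, pc_threshold)
    return NodalHubMetrics(pc, wmd, is_ch, list(m.node_labels))


def ch_count_test(control_metrics: list[NodalHubMetrics],
                  patient_metrics: list[NodalHubMetrics]) -> tuple[np.ndarray, TestResult]:
    """Chi-square on pooled CH / non-CH node counts per group.

    Counts pool over subjects x nodes; rows = (control, patient),
    columns = (CH, non-CH).
    """
    if not control_metrics or not patient_metrics:
        raise ValueError("both groups must be nonempty")

    def pooled(metrics):
        ch = sum(int(m.is_ch.sum()) for m in metrics)
        total = sum(m.is_ch.size for m in metrics)
        return ch, total - ch

    table = np.array([pooled(control_metrics), pooled(patient_metrics)])
    return table, chi_square_2x2(table)


def pc_wmd_ratio_test(control_metrics: list[NodalHubMetrics],
                      patient_metrics: list[NodalHubMetrics]) -> dict:
    """Two-sample t-test on subject-level mean PC/WMD ratios of CHs.

    Each subject contributes the mean ratio over its own connector hubs;
    subjects without any CH are excluded with a warning. Returns group
    summaries and the pooled-variance t-test result.
    """
    def subject_means(metrics, group):
        vals = np.array([m.mean_pc_wmd_ratio() for m in metrics])
        missing = np.isnan(vals)
        if missing.any():
            logger.warning("%d %s subject(s) without connector hubs excluded",
                           int(missing.sum()), group)
        return vals[~missing]

    ctrl = subject_means(control_metrics, "control")
    pat = subject_means(patient_metrics, "patient")
    if ctrl.size < 2 or pat.size < 2:
        raise ValueError("need at least 2 subjects with hubs per group")
    res = t_test_from_summary(ctrl.mean(), ctrl.std(ddof=1), ctrl.size,
                              pat.mean(), pat.std(ddof=1), pat.size)
    return {
        "control_mean": float(ctrl.mean()),
        "control_sd": float(ctrl.std(ddof=1)),
        "control_n": int(ctrl.size),
        "patient_mean": float(pat.mean()),
        "patient_sd": float(pat.std(ddof=1)),
        "patient_n": int(pat.size),
        "t": res.statistic,
        "p": res.p,
    }


def ch_frequency_ranking(all_metrics: list[NodalHubMetrics],
                         top_fraction: float = 0.25) -> ChFrequencyTable:
    """Count CH designations per node over the pooled cohort; take top 25%.

    Nodes are ranked by descending count with ties broken by original
    node order; the top set holds floor(top_fraction * N) labels
    (22 of 90 at the default fraction).
    """
    if not all_metrics:
        raise ValueError("need at least one subject")
    labels = all_metrics[0].node_labels
    counts = np.zeros(len(labels), dtype=int)
    for m in all_metrics:
        if m.node_labels != labels:
            raise ValueError("all subjects must share one node set")
        counts += m.is_ch.astype(int)
    n_top = int(np.floor(top_fraction * len(labels)))
    order = np.argsort(-counts, kind="stable")   # stable => ties by node order
    top = [labels[i] for i in order[:n_top]]
    return ChFrequencyTable(pd.Series(counts, index=labels), top)
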