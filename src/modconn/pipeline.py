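"""Pipeline orchestration, configuration and plain-text I/O.

Runs the full analysis sequence on a cohort of node time series (or
precomputed connectivity matrices): FC construction -> group community
template -> modularity Q / ASMI -> connector hubs -> NBS on the major-hub
subnetwork -> small-world topology. Every stage writes TSV/JSON outputs
and the resolved configuration is echoed next to them, so a run is fully
determined by its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cns
from . import hubs as hub_mod
from . import modularity as mod
from . import topology as topo
from .nbs import nbs as run_nbs
from .fc import (ConnectivityMatrix, SparsityGrid, SubjectTimeSeries,
                 compute_fc_matrix, threshold_proportional)
from .stats import t_test_from_summary, trapezoid_auc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline",
           "read_time_series", "write_matrix", "read_matrix",
           "read_group_labels", "write_partition", "read_partition"]


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Defaults are the study's analysis settings: sparsity 5-30% step 1%
    with 15% reference, 1000 Louvain runs with tau = 0.2, PC > 0.3 and
    top 25% hub selection, 1000 degree-preserving nulls, 5000
    permutations. ``scaled_down()`` gives a cheaper profile (100 runs,
    1000 permutations, 100 nulls) for constrained environments; it is
    not the study's parameter set.
    """

    grid: SparsityGrid = field(default_factory=SparsityGrid)
    n_louvain_runs: int = 1000
    tau: float = 0.2
    resolution: float = 1.0
    pc_threshold: float = 0.3
    top_fraction: float = 0.25
    n_null_networks: int = 1000
    n_swap_factor: int = 10
    n_perm: int = 5000
    nbs_primary_p: float = 0.005
    nbs_alpha: float = 0.025
    hub_mode: str = "strength"
    topology_mode: str = "weighted"
    seed: int = 0

    def scaled_down(self) -> "PipelineConfig":
        return dataclasses.replace(self, n_louvain_runs=100, n_perm=1000,
                                   n_null_networks=100)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"values": self.grid.values.tolist(),
                     "reference_sparsity": self.grid.reference_sparsity}
        return d


# ---------------------------------------------------------------------------
# plain-text I/O

def read_time_series(path) -> SubjectTimeSeries:
    """Read a time-series TSV (header = node labels, rows = time points)."""
    df = pd.read_csv(path, sep="\t")
    sid = Path(path).stem.replace("_timeseries", "")
    return SubjectTimeSeries(df.to_numpy(float), list(df.columns), sid)


def write_matrix(m: ConnectivityMatrix, path) -> None:
    """Write a matrix TSV with node labels as header and first column."""
    df = pd.DataFrame(m.weights, index=m.node_labels, columns=m.node_labels)
    df.to_csv(path, sep="\t")
    meta = {"sparsity": m.sparsity, "n_nodes": m.n_nodes, "n_edges": m.n_edges}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_matrix(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = Path(str(path) + ".json")
    sparsity = None
    if sidecar.exists():
        sparsity = json.loads(sidecar.read_text()).get("sparsity")
    return ConnectivityMatrix(df.to_numpy(float), list(df.columns), sparsity)


def read_group_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["subject_id"].astype(str), df["group"].astype(str)))


def write_partition(p: cns.Partition, node_labels: list[str], path) -> None:
    pd.DataFrame({"node_label": node_labels, "module": p.labels}).to_csv(
        path, sep="\t", index=False)


def read_partition(path) -> tuple[cns.Partition, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return cns.Partition(df["module"].to_numpy(int)), list(df["node_label"])


# ---------------------------------------------------------------------------
# orchestration

def _load_cohort(input_dir: Path) -> tuple[list[SubjectTimeSeries], dict[str, str]]:
    groups = read_group_labels(input_dir / "groups.tsv")
    subjects = []
    for sid in groups:
        ts_path = input_dir / f"{sid}_timeseries.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time series for {sid}: {ts_path}")
        ts = read_time_series(ts_path)
        ts.group = groups[sid]
        subjects.append(ts)
    n_nodes = {ts.n_nodes for ts in subjects}
    if len(n_nodes) != 1:
        raise ValueError(f"subjects disagree on node count: {sorted(n_nodes)}")
    return subjects, groups


def run_pipeline(config: PipelineConfig, input_dir, output_dir) -> dict:
    """Execute the full analysis and write a report bundle.

    Returns the summary report (also written as ``report.json``).
    """
    input_dir = Path(input_dir)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    subjects, groups = _load_cohort(input_dir)
    logger.info("loaded %d subjects (%d nodes)", len(subjects),
                subjects[0].n_nodes)

    # stage 1: FC construction and thresholding
    raw = [compute_fc_matrix(ts) for ts in subjects]
    ref_s = config.grid.reference_sparsity
    at_ref = [threshold_proportional(m, ref_s) for m in raw]

    # stage 2: group community template at the reference sparsity
    ccfg = cns.ConsensusConfig(n_runs=config.n_louvain_runs, tau=config.tau,
                               resolution=config.resolution, seed=config.seed)
    template = cns.group_template(at_ref, ccfg)
    write_partition(template, raw[0].node_labels, out / "group_template.tsv")
    logger.info("group template: %d modules", template.n_modules)

    # stage 3: modularity Q curves / AUC and ASMI at the reference sparsity
    is_control = np.array([ts.group == "control" for ts in subjects])
    q_auc = np.empty(len(subjects))
    q_ref = np.empty(len(subjects))
    for i, m in enumerate(raw):
        by_s = {s: threshold_proportional(m, s) for s in config.grid.values}
        res = mod.q_curve_and_auc(by_s, template, ref_s)
        q_auc[i], q_ref[i] = res.q_auc, res.q_at_reference

    def group_stats(vals):
        c, p = vals[is_control], vals[~is_control]
        t = t_test_from_summary(c.mean(), c.std(ddof=1), c.size,
                                p.mean(), p.std(ddof=1), p.size)
        return {"control_mean": float(c.mean()), "control_sd": float(c.std(ddof=1)),
                "patient_mean": float(p.mean()), "patient_sd": float(p.std(ddof=1)),
                "t": t.statistic, "p": t.p}

    tables = [mod.asmi(m, template) for m in at_ref]
    ctrl_tables = [t for t, c in zip(tables, is_control) if c]
    pat_tables = [t for t, c in zip(tables, is_control) if not c]
    asmi_df = mod.asmi_group_test(ctrl_tables, pat_tables,
                                  n_perm=config.n_perm, seed=config.seed)
    asmi_df.to_csv(out / "asmi_group_test.tsv", sep="\t", index=False)

    # stage 4: connector hubs at the reference sparsity
    metrics = [hub_mod.compute_hub_metrics(m, template, config.hub_mode,
                                           config.pc_threshold)
               for m in at_ref]
    ctrl_metrics = [m for m, c in zip(metrics, is_control) if c]
    pat_metrics = [m for m, c in zip(metrics, is_control) if not c]
    ch_table, ch_chi2 = hub_mod.ch_count_test(ctrl_metrics, pat_metrics)
    ratio = hub_mod.pc_wmd_ratio_test(ctrl_metrics, pat_metrics)
    ranking = hub_mod.ch_frequency_ranking(metrics, config.top_fraction)
    ranking.counts.rename("ch_count").to_csv(out / "ch_frequency.tsv", sep="\t")

    # stage 5: NBS on the major-hub subnetwork
    labels = raw[0].node_labels
    top_idx = [labels.index(lbl) for lbl in ranking.top_set]
    stack = np.stack([m.weights[np.ix_(top_idx, top_idx)] for m in at_ref])
    subj_groups = np.array([ts.group for ts in subjects])
    nbs_results = {}
    for direction in ("patient_greater", "control_greater"):
        res = run_nbs(stack, subj_groups, primary_p=config.nbs_primary_p,
                      n_perm=config.n_perm, alpha=config.nbs_alpha,
                      direction=direction, seed=config.seed)
        nbs_results[direction] = [
            {"nodes": [ranking.top_set[i] for i in c.nodes],
             "edges": [[ranking.top_set[i], ranking.top_set[j]]
                       for i, j in c.edges],
             "size": c.size, "corrected_p": c.corrected_p,
             "significant": c.significant}
            for c in res.components]

    # stage 6: small-world topology at the reference sparsity
    rng = np.random.default_rng(config.seed)
    sw = {"control": [], "patient": []}
    for m, ts in zip(at_ref, subjects):
        nulls = topo.degree_preserving_random(
            m, config.n_null_networks, config.n_swap_factor, rng)
        r = topo.small_world(m, nulls, config.topology_mode)
        sw[ts.group].append(r)

    def sw_summary(rs):
        return {k: float(np.mean([getattr(r, k) for r in rs]))
                for k in ("gamma", "lambda_", "sigma")}

    report = {
        "n_subjects": len(subjects),
        "n_nodes": subjects[0].n_nodes,
        "template_n_modules": template.n_modules,
        "q_auc": group_stats(q_auc),
        "q_at_reference": group_stats(q_ref),
        "asmi": asmi_df.to_dict(orient="records"),
        "ch_count_table": ch_table.tolist(),
        "ch_count_chi2": {"statistic": ch_chi2.statistic, "p": ch_chi2.p},
        "pc_wmd_ratio": ratio,
        "major_hubs": ranking.top_set,
        "nbs": nbs_results,
        "small_world": {g: sw_summary(rs) for g, rs in sw.items()},
        "seed": config.seed,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default))
    logger.info("report written to %s", out / "report.json")
    return json.loads(json.dumps(report, default=_json_default))


def _json_default(obj):
    """Coerce numpy scalars/arrays left in stage outputs to JSON types."""
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
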