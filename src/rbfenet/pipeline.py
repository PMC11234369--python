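"""Full-analysis orchestration: one call from edge records to report tables.

``run_full_analysis`` composes the stages — repeat aggregation, consensus,
convergence filtering, per-target network reconstruction, edge- and
node-level metrics with bootstrap intervals, significance matrices, outlier
ratios, accuracy-determinant correlations and (when parameter assignments
are supplied) the per-parameter ΔRMSE attribution — and writes every table
plus a machine-readable manifest to an output directory.  Given the same
inputs and seed the report bundle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (
    ALPHA_MAX,
    SIGMA_MAX,
    aggregate_repeats,
    consensus,
    convergence_filter,
)
from .io import BenchmarkDataset, write_table
from .network import node_estimates
from .params import cluster_parameters, delta_rmse, edge_usages, mcc_matrix, usage_matrix
from .stats import (
    determinant_correlations,
    metric_with_ci,
    outlier_ratio,
    rank_metrics,
    significance_matrix,
    weighted_tau_overall,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one full analysis run."""

    forcefields: list[str] | None = None  # None = all present
    consensus_members: list[str] | None = None  # None = skip consensus
    alpha_max: float = ALPHA_MAX
    sigma_max: float = SIGMA_MAX
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    ff_pair: tuple[str, str] | None = None  # (older, newer) for parameter ΔRMSE
    params_on_converged_only: bool = True
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.alpha_max <= 0 or self.sigma_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ReportBundle:
    """In-memory results of a full analysis (mirrors the on-disk CSVs)."""

    edge_estimates: pd.DataFrame
    converged: pd.DataFrame
    not_converged: pd.DataFrame
    node_table: pd.DataFrame
    edge_metrics: pd.DataFrame
    node_metrics: pd.DataFrame
    overall_tau: pd.DataFrame
    significance_edge: pd.DataFrame
    significance_node: pd.DataFrame
    outlier_ratios: pd.DataFrame
    outlier_summary: pd.DataFrame
    correlations: pd.DataFrame
    filtered_metrics: pd.DataFrame
    parameter_effects: pd.DataFrame | None
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            name: getattr(self, name)
            for name in (
                "edge_estimates", "converged", "not_converged", "node_table",
                "edge_metrics", "node_metrics", "overall_tau",
                "significance_edge", "significance_node",
                "outlier_ratios", "outlier_summary", "correlations",
                "filtered_metrics",
            )
        }
        if self.parameter_effects is not None:
            out["parameter_effects"] = self.parameter_effects
        return out


def _edge_metric_rows(est: pd.DataFrame, cfg: RunConfig, subset: str = "all") -> list[dict]:
    rows = []
    for ff, grp in est.groupby("forcefield", sort=True):
        scopes = [("ALL", grp)] + [(t, g) for t, g in grp.groupby("target", sort=True)]
        for scope, g in scopes:
            if len(g) < 2:
                continue
            for metric in ("rmse", "mue"):
                r = metric_with_ci(
                    metric, g["ddg_mean"].to_numpy(), g["ddg_exp"].to_numpy(),
                    n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed,
                    stat_level="edge", scope=scope,
                )
                rows.append({"forcefield": ff, "subset": subset, **dataclasses.asdict(r)})
    return rows


def _node_metric_rows(nodes: pd.DataFrame, cfg: RunConfig) -> tuple[list[dict], list[dict]]:
    rows, tau_rows = [], []
    for ff, grp in nodes.groupby("forcefield", sort=True):
        per_target = []
        for target, g in grp.groupby("target", sort=True):
            if len(g) < 3:
                continue
            for metric in ("rmse", "mue"):
                r = metric_with_ci(
                    metric, g["dg_calc"].to_numpy(), g["dg_exp"].to_numpy(),
                    n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed,
                    stat_level="node", scope=target,
                )
                rows.append({"forcefield": ff, **dataclasses.asdict(r)})
            tau, rho = rank_metrics(g["dg_calc"].to_numpy(), g["dg_exp"].to_numpy())
            rows.append({"forcefield": ff, "metric": "kendall_tau", "value": tau,
                         "ci_low": np.nan, "ci_high": np.nan, "n": len(g),
                         "level": "node", "scope": target})
            rows.append({"forcefield": ff, "metric": "spearman_rho", "value": rho,
                         "ci_low": np.nan, "ci_high": np.nan, "n": len(g),
                         "level": "node", "scope": target})
            if np.isfinite(tau):
                per_target.append((len(g), tau))
        for metric in ("rmse", "mue"):
            r = metric_with_ci(
                metric, grp["dg_calc"].to_numpy(), grp["dg_exp"].to_numpy(),
                n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed,
                stat_level="node", scope="ALL",
            )
            rows.append({"forcefield": ff, **dataclasses.asdict(r)})
        if per_target:
            tau_rows.append(
                {"forcefield": ff, "tau_overall": weighted_tau_overall(per_target),
                 "n_targets": len(per_target), "n_ligands": int(sum(n for n, _ in per_target))}
            )
    return rows, tau_rows


def run_full_analysis(dataset: BenchmarkDataset, config: RunConfig | None = None) -> ReportBundle:
    """Run every analysis stage on one benchmark dataset."""
    cfg = config or RunConfig()
    dataset.validate()
    edges = dataset.edges
    if cfg.forcefields:
        edges = edges[edges["forcefield"].isin(cfg.forcefields)]
    logger.info("read %d edge records, %d force fields", len(edges), edges["forcefield"].nunique())

    est = aggregate_repeats(edges, dataset.leg_alphas)
    if cfg.consensus_members:
        cons = consensus(edges, members=cfg.consensus_members)
        est = pd.concat([est, cons[est.columns.intersection(cons.columns)]], ignore_index=True)
    converged, not_converged = convergence_filter(est, cfg.alpha_max, cfg.sigma_max)
    logger.info("convergence filter: %d converged, %d not", len(converged), len(not_converged))

    # node reconstruction per force field
    node_pieces = []
    for ff, grp in est.groupby("forcefield", sort=True):
        nodes = node_estimates(grp, dataset.experiments)
        nodes.insert(0, "forcefield", ff)
        node_pieces.append(nodes)
    node_table = pd.concat(node_pieces, ignore_index=True)

    edge_rows = _edge_metric_rows(est, cfg, subset="all")
    conv_union = pd.concat([converged, not_converged])
    filtered_rows = []
    for subset, sub in (("converged", converged), ("not_converged", not_converged)):
        pmx = sub[sub["alpha_mean"].notna()] if subset == "converged" else sub
        if len(pmx):
            filtered_rows += _edge_metric_rows(pmx, cfg, subset=subset)
    node_rows, tau_rows = _node_metric_rows(node_table, cfg)

    # significance matrices on shared items
    def deviations_pivot(df: pd.DataFrame, idx: list[str], calc: str, exp: str) -> pd.DataFrame:
        d = df.copy()
        d["deviation"] = d[calc] - d[exp]
        return d.pivot_table(index=idx, columns="forcefield", values="deviation")

    sig_edge = significance_matrix(
        deviations_pivot(est, ["target", "ligand_a", "ligand_b"], "ddg_mean", "ddg_exp"),
        metric="rmse", n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed,
    ).to_frame()
    sig_node = significance_matrix(
        deviations_pivot(node_table, ["target", "ligand"], "dg_calc", "dg_exp"),
        metric="rmse", n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed + 1,
    ).to_frame()

    # outlier ratios and determinant correlations on the primary force field
    primary = sorted(est["forcefield"].unique())[0]
    prim = est[est["forcefield"] == primary].copy()
    prim["deviation"] = prim["ddg_mean"] - prim["ddg_exp"]
    ratios, summary = outlier_ratio(prim[["target", "deviation"]])
    prim["abs_deviation"] = prim["deviation"].abs()
    prim["ddg_pred"] = prim["ddg_mean"].abs()
    corr_input = prim.rename(columns={})
    if "heavy_atom_change" not in corr_input.columns:
        corr_input["heavy_atom_change"] = np.nan
    try:
        correlations, _ = determinant_correlations(corr_input)
    except Exception:  # too few complete edges
        correlations = pd.DataFrame()

    parameter_effects = None
    if dataset.assignments and cfg.ff_pair:
        ff1, ff2 = cfg.ff_pair
        base = conv_union if not cfg.params_on_converged_only else converged
        shared = base.pivot_table(
            index=["target", "ligand_a", "ligand_b"], columns="forcefield", values="ddg_mean"
        )[[ff1, ff2]].dropna()
        exp = base.drop_duplicates(["target", "ligand_a", "ligand_b"]).set_index(
            ["target", "ligand_a", "ligand_b"]
        )["ddg_exp"]
        shared = shared.join(exp).dropna()
        key = shared.reset_index()[["target", "ligand_a", "ligand_b"]]
        usages = edge_usages(key, dataset.assignments)
        mat = usage_matrix(usages)
        mat = mat.loc[pd.MultiIndex.from_frame(key)]
        effects = delta_rmse(
            (shared[ff1] - shared["ddg_exp"]).to_numpy(),
            (shared[ff2] - shared["ddg_exp"]).to_numpy(),
            mat, n_boot=cfg.n_boot, level=cfg.ci_level, seed=cfg.seed,
        )
        if mat.shape[1] >= 2 and len(effects):
            baseline = effects.attrs.get("baseline_delta_rmse")
            clusters = cluster_parameters(mcc_matrix(mat), seed=cfg.seed)
            effects = effects.merge(
                clusters.rename("cluster_id").reset_index().rename(columns={"index": "parameter"}),
                on="parameter", how="left",
            )
            effects.attrs["baseline_delta_rmse"] = baseline
            effects["baseline_delta_rmse"] = baseline
        parameter_effects = effects

    manifest = {
        "package": "rbfenet",
        "version": __version__,
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "ci_level": cfg.ci_level,
        "alpha_max": cfg.alpha_max,
        "sigma_max": cfg.sigma_max,
        "n_edge_records": int(len(edges)),
        "n_edges": int(est[["target", "ligand_a", "ligand_b"]].drop_duplicates().shape[0]),
        "n_ligands": int(len(dataset.experiments)),
        "n_targets": int(dataset.experiments["target"].nunique()),
        "forcefields": sorted(est["forcefield"].unique().tolist()),
        "n_converged": int(len(converged)),
        "n_not_converged": int(len(not_converged)),
    }

    bundle = ReportBundle(
        edge_estimates=est,
        converged=converged,
        not_converged=not_converged,
        node_table=node_table,
        edge_metrics=pd.DataFrame(edge_rows),
        node_metrics=pd.DataFrame(node_rows),
        overall_tau=pd.DataFrame(tau_rows),
        significance_edge=sig_edge,
        significance_node=sig_node,
        outlier_ratios=ratios,
        outlier_summary=summary,
        correlations=correlations,
        filtered_metrics=pd.DataFrame(filtered_rows),
        parameter_effects=parameter_effects,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        write_bundle(bundle, cfg.outdir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write every report table plus the manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables().items():
        write_table(table, outdir / f"{name}.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
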