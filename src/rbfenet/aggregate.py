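"""Per-edge aggregation over repeats, convergence filtering, and consensus.

An edge is one alchemical perturbation between two ligands of one target,
simulated in several independent repeats with one force field.  The edge
estimate is the mean ΔΔG over repeats with the sample (n−1) standard
deviation σ(ΔΔG) as its error estimate, plus the mean of the per-leg
overlap diagnostics α.  The two-criterion convergence filter keeps edges
with α < 0.8 and σ(ΔΔG) < 1.5 kcal/mol (both strict); no cycle-closure
correction is ever applied.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_KEY = ["target", "ligand_a", "ligand_b", "forcefield"]

#: convergence thresholds: overlap diagnostic and repeat scatter (kcal/mol)
ALPHA_MAX = 0.8
SIGMA_MAX = 1.5

#: default consensus members (three independent public force fields)
CONSENSUS_MEMBERS = ("OpenFF-2.0", "GAFF2.1x", "CGenFF-MATCH")


def aggregate_repeats(
    records: pd.DataFrame,
    leg_alphas: pd.DataFrame | None = None,
    alpha_reduce: str = "mean",
) -> pd.DataFrame:
    """Collapse per-repeat ΔΔG records into per-edge estimates.

    Parameters
    ----------
    records
        Long table with columns target, ligand_a, ligand_b, forcefield,
        repeat, ddg_calc [, ddg_exp].
    leg_alphas
        Optional per-leg α values (columns as ``records`` plus leg, alpha);
        up to 6 rows per edge (3 repeats × complex/solvent legs).
    alpha_reduce
        ``"mean"`` (default) averages α over legs; ``"max"`` takes the worst
        leg instead.

    Returns
    -------
    One row per edge with ddg_mean, ddg_sigma (sample SD, 0 with a warning
    for single repeats), alpha_mean (NaN when no α supplied), n_repeats.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    mixed = records.groupby(EDGE_KEY, sort=False)
    agg = mixed["ddg_calc"].agg(ddg_mean="mean", ddg_sigma="std", n_repeats="size")
    single = agg["n_repeats"] == 1
    if single.any():
        logger.warning("%d edges have a single repeat; sigma set to 0", int(single.sum()))
    agg["ddg_sigma"] = agg["ddg_sigma"].fillna(0.0)
    out = agg.reset_index()
    for passthrough in ("ddg_exp", "heavy_atom_change"):
        if passthrough in records.columns:
            out[passthrough] = mixed[passthrough].first().to_numpy()
    if leg_alphas is not None and len(leg_alphas):
        if alpha_reduce not in {"mean", "max"}:
            raise ValueError(f"unknown alpha_reduce {alpha_reduce!r}")
        reducer = leg_alphas.groupby(EDGE_KEY, sort=False)["alpha"]
        alpha = (reducer.mean() if alpha_reduce == "mean" else reducer.max()).rename(
            "alpha_mean"
        )
        out = out.merge(alpha.reset_index(), on=EDGE_KEY, how="left")
    else:
        out["alpha_mean"] = np.nan
    return out


def convergence_filter(
    estimates: pd.DataFrame,
    alpha_max: float = ALPHA_MAX,
    sigma_max: float = SIGMA_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition edges into (converged, not_converged).

    Converged requires *both* strict inequalities: alpha_mean < alpha_max and
    ddg_sigma < sigma_max.  Edges with missing α can never be converged
    (conservative: the diagnostic was not computed, so sampling quality is
    unknown).  The partition is exhaustive and disjoint, and relaxing either
    threshold can only grow the converged set.
    """
    alpha = estimates["alpha_mean"]
    sigma = estimates["ddg_sigma"]
    missing = alpha.isna()
    if missing.any():
        logger.warning(
            "%d edges lack alpha; routed to not_converged", int(missing.sum())
        )
    converged_mask = (~missing) & (alpha < alpha_max) & (sigma < sigma_max)
    est = estimates.copy()
    est["converged"] = converged_mask
    return est[converged_mask].copy(), est[~converged_mask].copy()


def consensus(
    per_ff_records: pd.DataFrame,
    members: Sequence[str] = CONSENSUS_MEMBERS,
    repeat_selector: str = "first_repeat",
    label: str = "Consensus",
) -> pd.DataFrame:
    """Unweighted per-edge average over several force fields.

    By default each member contributes its *first* repeat, so the consensus
    costs the same total sampling time as one three-repeat calculation; with
    ``repeat_selector="mean"`` the member mean over repeats is used instead.
    Only edges present for every member enter; the number dropped is logged.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("consensus needs at least 2 member force fields")
    sub = per_ff_records[per_ff_records["forcefield"].isin(members)]
    missing = set(members) - set(sub["forcefield"].unique())
    if missing:
        raise ValueError(f"member force fields absent from records: {sorted(missing)}")
    if repeat_selector == "first_repeat":
        first = sub.groupby(EDGE_KEY, sort=False)["repeat"].transform("min")
        vals = sub[sub["repeat"] == first]
    elif repeat_selector == "mean":
        keep = [c for c in sub.columns if c in EDGE_KEY + ["ddg_calc", "ddg_exp"]]
        vals = (
            sub[keep]
            .groupby(EDGE_KEY, sort=False, as_index=False)
            .agg({"ddg_calc": "mean", **({"ddg_exp": "first"} if "ddg_exp" in keep else {})})
        )
    else:
        raise ValueError(f"unknown repeat_selector {repeat_selector!r}")

    edge_cols = ["target", "ligand_a", "ligand_b"]
    counts = vals.groupby(edge_cols, sort=False)["forcefield"].nunique()
    complete = counts[counts == len(members)].index
    dropped = int((counts != len(members)).sum())
    if dropped:
        logger.info("consensus: dropped %d edges missing in some member", dropped)
    vals = vals.set_index(edge_cols).loc[complete].reset_index()
    agg = {"ddg_calc": "mean"}
    if "ddg_exp" in vals.columns:
        agg["ddg_exp"] = "first"
    out = vals.groupby(edge_cols, sort=False, as_index=False).agg(agg)
    out = out.rename(columns={"ddg_calc": "ddg_mean"})
    out.insert(3, "forcefield", label)
    out["ddg_sigma"] = np.nan
    out["alpha_mean"] = np.nan
    out["n_repeats"] = 1 if repeat_selector == "first_repeat" else np.nan
    out.attrs["members"] = members
    out.attrs["repeat_selector"] = repeat_selector
    out.attrs["dropped_edges"] = dropped
    return out
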