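"""Force-field parameter attribution of prediction error.

Each ligand carries a multiset of force-field parameter IDs (e.g. ``b18``,
``t106``).  An edge *involves* parameter p when the counts of p differ
between its two end states — p is changed, created, or annihilated by the
perturbation.  Per-parameter error is the RMSE over the edges involving the
parameter; comparing two force-field versions per parameter,

    ΔRMSE(p) = RMSE_FF1(p) − RMSE_FF2(p),

with FF1 the older version, so a positive ΔRMSE means the newer force field
improved on edges involving p.  Significance is a paired bootstrap over the
parameter's edge subset, with the whole-set ΔRMSE reported as the reference
line for version-to-version comparisons.  Because
parameters are used in recurring combinations (a functional group perturbs
its bond, angle and torsion terms together), co-usage is quantified with the
Matthews correlation coefficient of the binary usage vectors and grouped by
spectral clustering.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

logger = logging.getLogger(__name__)

N_MIN_EDGES = 3  # below this a per-parameter RMSE is flagged low-support


def perturbed_parameters(assign_a: Counter, assign_b: Counter) -> set[str]:
    """Parameter IDs whose multiset counts differ between the two end states.

    Symmetric in its arguments: covers parameters changed in count, created,
    or annihilated by the perturbation.
    """
    keys = set(assign_a) | set(assign_b)
    return {p for p in keys if assign_a.get(p, 0) != assign_b.get(p, 0)}


def edge_usages(
    edges: pd.DataFrame, assignments: Mapping[tuple[str, str], Counter]
) -> pd.DataFrame:
    """Per-edge perturbed parameter sets for a table of unique edges.

    Returns columns target, ligand_a, ligand_b, perturbed (frozenset).
    """
    rows = []
    for _, row in edges[["target", "ligand_a", "ligand_b"]].drop_duplicates().iterrows():
        a = assignments.get((row["target"], row["ligand_a"]), Counter())
        b = assignments.get((row["target"], row["ligand_b"]), Counter())
        rows.append(
            {
                "target": row["target"],
                "ligand_a": row["ligand_a"],
                "ligand_b": row["ligand_b"],
                "perturbed": frozenset(perturbed_parameters(a, b)),
            }
        )
    return pd.DataFrame(rows)


def usage_matrix(usages: pd.DataFrame) -> pd.DataFrame:
    """Binary edges × parameters matrix; 1 iff the parameter is perturbed.

    Columns are sorted lexicographically; parameters perturbed on no edge are
    absent by construction.  The row index is a MultiIndex on
    (target, ligand_a, ligand_b).
    """
    if usages.empty:
        raise ValueError("no edges")
    all_params = sorted(set().union(*usages["perturbed"]))
    if not all_params:
        logger.warning("no parameter is perturbed on any edge")
    index = pd.MultiIndex.from_frame(usages[["target", "ligand_a", "ligand_b"]])
    mat = pd.DataFrame(0, index=index, columns=all_params, dtype=int)
    for i, pert in enumerate(usages["perturbed"]):
        if pert:
            mat.iloc[i, [all_params.index(p) for p in sorted(pert)]] = 1
    return mat


def mcc(u: np.ndarray, v: np.ndarray) -> float:
    """Matthews correlation coefficient of two binary vectors.

    Returns 0.0 (with a warning) when any marginal is zero, where the
    coefficient is formally undefined.
    """
    u = np.asarray(u, dtype=int)
    v = np.asarray(v, dtype=int)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    tp = int(np.sum((u == 1) & (v == 1)))
    tn = int(np.sum((u == 0) & (v == 0)))
    fp = int(np.sum((u == 0) & (v == 1)))
    fn = int(np.sum((u == 1) & (v == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("MCC undefined (zero marginal); returning 0")
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_matrix(usage: pd.DataFrame) -> pd.DataFrame:
    """Pairwise MCC between parameter usage columns (unit diagonal)."""
    cols = list(usage.columns)
    arr = usage.to_numpy(dtype=int)
    out = np.eye(len(cols))
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            out[i, j] = out[j, i] = mcc(arr[:, i], arr[:, j])
    return pd.DataFrame(out, index=cols, columns=cols)


def _eigengap_k(affinity: np.ndarray, k_max: int) -> int:
    """Pick k by the largest eigengap of the normalized graph Laplacian."""
    d = affinity.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    lap = np.eye(len(affinity)) - d_inv_sqrt[:, None] * affinity * d_inv_sqrt[None, :]
    evals = np.sort(np.linalg.eigvalsh(lap))
    gaps = np.diff(evals)[1:k_max]  # gap after eigenvalue k, k = 2..k_max
    return int(np.argmax(gaps)) + 2


def cluster_parameters(
    corr: pd.DataFrame, n_clusters: int | str = "auto", seed: int = 0
) -> pd.Series:
    """Spectral clustering of parameters on the affinity (MCC + 1)/2.

    ``n_clusters="auto"`` selects k in [2, min(15, P−1)] by the largest
    eigengap of the normalized Laplacian.  Labels are deterministic given the
    seed and returned indexed by parameter ID.
    """
    p = corr.shape[0]
    if p < 2:
        raise ValueError("need at least 2 parameters to cluster")
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T):
        raise ValueError("correlation matrix must be symmetric")
    affinity = (corr.to_numpy(float) + 1.0) / 2.0
    np.fill_diagonal(affinity, 1.0)
    k_max = min(15, p - 1)
    k = _eigengap_k(affinity, k_max) if n_clusters == "auto" else int(n_clusters)
    k = max(2, min(k, p))
    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    labels = sc.fit_predict(affinity)
    return pd.Series(labels, index=corr.index, name="cluster_id")


def rmse_per_parameter(
    deviations: pd.Series | np.ndarray,
    usage: pd.DataFrame,
    n_min: int = N_MIN_EDGES,
) -> pd.DataFrame:
    """RMSE over the edges involving each parameter.

    ``deviations`` is aligned positionally with the usage-matrix rows
    (calc − exp, kcal/mol).  Parameters with no edges are dropped; those with
    fewer than ``n_min`` edges carry a low-support flag.
    """
    dev = np.asarray(deviations, float)
    if dev.shape[0] != usage.shape[0]:
        raise ValueError("deviations not aligned with usage-matrix rows")
    rows = []
    arr = usage.to_numpy(dtype=bool)
    for j, p in enumerate(usage.columns):
        sel = arr[:, j]
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            {
                "parameter": p,
                "n_edges": n,
                "rmse": float(np.sqrt(np.mean(dev[sel] ** 2))),
                "low_support": n < n_min,
            }
        )
    return pd.DataFrame(rows)


def delta_rmse(
    dev_ff1: pd.Series | np.ndarray,
    dev_ff2: pd.Series | np.ndarray,
    usage: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    n_min: int = N_MIN_EDGES,
    reference: float = 0.0,
) -> pd.DataFrame:
    """Per-parameter ΔRMSE = RMSE_FF1(p) − RMSE_FF2(p) with significance.

    Both deviation vectors must be aligned with the same usage matrix (same
    edge set for both force fields).  The paired bootstrap resamples each
    parameter's edge subset jointly for the two force fields; an effect is
    significant when the 95% percentile interval of ΔRMSE(p) excludes
    ``reference`` (zero by default).  The whole-set ΔRMSE over all edges is
    reported alongside as ``baseline_delta_rmse`` — the conventional
    reference line when plotting per-parameter effects against the overall
    version-to-version change.
    """
    d1, d2 = np.asarray(dev_ff1, float), np.asarray(dev_ff2, float)
    if d1.shape != d2.shape or d1.shape[0] != usage.shape[0]:
        raise ValueError("force-field deviation vectors must share the edge set")
    baseline = float(np.sqrt(np.mean(d1**2)) - np.sqrt(np.mean(d2**2)))
    rng = np.random.default_rng(seed)
    arr = usage.to_numpy(dtype=bool)
    alo, ahi = (1 - level) / 2, (1 + level) / 2
    rows = []
    for j, p in enumerate(usage.columns):
        sel = np.flatnonzero(arr[:, j])
        n = sel.size
        if n == 0:
            continue
        r1 = float(np.sqrt(np.mean(d1[sel] ** 2)))
        r2 = float(np.sqrt(np.mean(d2[sel] ** 2)))
        idx = sel[rng.integers(0, n, size=(n_boot, n))]
        boot = np.sqrt(np.mean(d1[idx] ** 2, axis=1)) - np.sqrt(np.mean(d2[idx] ** 2, axis=1))
        lo, hi = np.quantile(boot, [alo, ahi])
        rows.append(
            {
                "parameter": p,
                "n_edges": n,
                "rmse_ff1": r1,
                "rmse_ff2": r2,
                "delta_rmse": r1 - r2,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > reference or hi < reference),
                "low_support": n < n_min,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline_delta_rmse"] = baseline
    return out
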