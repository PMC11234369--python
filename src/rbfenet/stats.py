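"""Error and ranking metrics with bootstrap confidence intervals.

Statistics exist at two levels: *edges* (relative ΔΔG of perturbations) and
*nodes* (absolute ΔG of ligands, after network reconstruction).  Aggregated
accuracy is reported as RMSE and MUE; ranking quality as Kendall's τ (tie
corrected, τ-b) and Spearman's ρ per target, with the overall τ the
ligand-count-weighted mean over targets:

    τ_overall = Σ_t (N_t / N) τ_t,   N = Σ_t N_t.

All intervals are 95% percentile bootstrap intervals from 1000 resamples,
and pairwise force-field comparisons use a paired bootstrap on the shared
items: the difference is significant when its 95% interval excludes zero.
Bootstrap draws index a canonically sorted view of the data, so results are
bit-reproducible under a fixed seed and invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

N_BOOT = 1000
CI_LEVEL = 0.95


class StatisticError(ValueError):
    """A statistic is undefined on the supplied data."""


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float
    ci_low: float
    ci_high: float
    n: int
    level: str = "edge"  # edge | node
    scope: str = "ALL"


def rmse(calc: np.ndarray, ref: np.ndarray) -> float:
    calc, ref = np.asarray(calc, float), np.asarray(ref, float)
    if calc.shape != ref.shape:
        raise StatisticError("length mismatch between calc and ref")
    if calc.size < 1:
        raise StatisticError("empty sample")
    return float(np.sqrt(np.mean((calc - ref) ** 2)))


def mue(calc: np.ndarray, ref: np.ndarray) -> float:
    calc, ref = np.asarray(calc, float), np.asarray(ref, float)
    if calc.shape != ref.shape:
        raise StatisticError("length mismatch between calc and ref")
    if calc.size < 1:
        raise StatisticError("empty sample")
    return float(np.mean(np.abs(calc - ref)))


def rank_metrics(calc: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Kendall τ-b and Spearman ρ; NaN (flagged by a warning) when undefined."""
    calc, ref = np.asarray(calc, float), np.asarray(ref, float)
    if calc.size < 3:
        raise StatisticError("need >= 3 items for ranking metrics")
    if np.allclose(calc, calc[0]) or np.allclose(ref, ref[0]):
        logger.warning("constant vector: ranking metrics undefined")
        return np.nan, np.nan
    tau = sps.kendalltau(calc, ref, variant="b").statistic
    rho = sps.spearmanr(calc, ref).statistic
    return float(tau), float(rho)


def weighted_tau_overall(per_target: Sequence[tuple[int, float]]) -> float:
    """Ligand-count-weighted mean of per-target Kendall τ values.

    Targets whose τ is undefined (NaN) are excluded and the weights of the
    remainder renormalized, with a warning.
    """
    if not per_target:
        raise StatisticError("no per-target values")
    arr = np.asarray(per_target, dtype=float)
    ns, taus = arr[:, 0], arr[:, 1]
    if (ns < 1).any():
        raise StatisticError("target ligand counts must be >= 1")
    ok = np.isfinite(taus)
    if not ok.all():
        logger.warning("excluding %d undefined per-target tau values", int((~ok).sum()))
    if not ok.any():
        raise StatisticError("all per-target tau values undefined")
    return float(np.sum(ns[ok] * taus[ok]) / np.sum(ns[ok]))


def _canonical_order(data: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically so bootstrap output ignores input order."""
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[0] == 1:
        data = data.T
    return data[np.lexsort(data.T[::-1])]


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``statistic`` over resampling units.

    ``data`` has one resampling unit per row; the statistic receives the
    resampled array.  The point value is computed on the full sample.  An
    error is raised when the statistic is undefined (NaN) on more than 20%
    of resamples.
    """
    data = _canonical_order(data)
    n = data.shape[0]
    if n < 2:
        raise StatisticError("need >= 2 resampling units")
    value = float(statistic(data))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = statistic(data[rng.integers(0, n, n)])
    bad = ~np.isfinite(boot)
    if bad.mean() > 0.2:
        raise StatisticError(f"statistic undefined on {bad.mean():.0%} of resamples")
    boot = boot[~bad]
    lo, hi = np.quantile(boot, [(1 - level) / 2, (1 + level) / 2])
    return value, float(lo), float(hi)


def metric_with_ci(
    metric: str,
    calc: np.ndarray,
    ref: np.ndarray,
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
    stat_level: str = "edge",
    scope: str = "ALL",
) -> MetricResult:
    """Bootstrap a paired error/ranking metric, resampling (calc, ref) pairs."""
    fns: dict[str, Callable[[np.ndarray], float]] = {
        "rmse": lambda d: rmse(d[:, 0], d[:, 1]),
        "mue": lambda d: mue(d[:, 0], d[:, 1]),
        "kendall_tau": lambda d: rank_metrics(d[:, 0], d[:, 1])[0],
        "spearman_rho": lambda d: rank_metrics(d[:, 0], d[:, 1])[1],
        "pearson_r": lambda d: float(sps.pearsonr(d[:, 0], d[:, 1]).statistic),
    }
    if metric not in fns:
        raise ValueError(f"unknown metric {metric!r}")
    data = np.column_stack([np.asarray(calc, float), np.asarray(ref, float)])
    value, lo, hi = bootstrap_ci(fns[metric], data, n_boot=n_boot, level=level, seed=seed)
    return MetricResult(metric, value, lo, hi, n=data.shape[0], level=stat_level, scope=scope)


@dataclass
class SignificanceMatrix:
    """Pairwise force-field comparison: who wins, and is it significant."""

    labels: list[str]
    winner: pd.DataFrame  # entries: left | down | tie
    significant: pd.DataFrame  # boolean
    metric: str
    values: pd.Series  # per-FF metric value on the shared items

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.labels:
            for j in self.labels:
                rows.append(
                    {
                        "ff_row": i,
                        "ff_col": j,
                        "winner": self.winner.loc[i, j],
                        "significant": bool(self.significant.loc[i, j]),
                        "metric": self.metric,
                    }
                )
        return pd.DataFrame(rows)


def significance_matrix(
    per_ff_deviations: pd.DataFrame,
    metric: str = "rmse",
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> SignificanceMatrix:
    """Paired bootstrap significance of metric differences between force fields.

    ``per_ff_deviations``: one row per shared item (edge or node), one column
    per force field, entries calc − exp deviations.  Rows with any NaN are
    dropped (inner join on items; the drop count is logged).  For each pair
    the shared items are resampled jointly and the metric difference
    recomputed; the difference is significant when the 95% percentile interval
    excludes 0, and the winner is the lower-error force field.
    """
    if per_ff_deviations.shape[1] < 2:
        raise ValueError("need at least 2 force fields")
    dev = per_ff_deviations.dropna()
    dropped = len(per_ff_deviations) - len(dev)
    if dropped:
        logger.info("significance: dropped %d items not shared by all FFs", dropped)
    dev = dev.sort_index()
    labels = list(dev.columns)
    fn = {"rmse": lambda a: np.sqrt(np.mean(a**2, axis=-1)), "mue": lambda a: np.mean(np.abs(a), axis=-1)}[metric]
    arr = dev.to_numpy(float)  # items x ffs
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = fn(arr[idx].transpose(0, 2, 1))  # n_boot x ffs
    values = pd.Series(fn(arr.T), index=labels)
    winner = pd.DataFrame("tie", index=labels, columns=labels)
    signif = pd.DataFrame(False, index=labels, columns=labels)
    alo, ahi = (1 - level) / 2, (1 + level) / 2
    for i, fi in enumerate(labels):
        for j, fj in enumerate(labels[: i]):
            diff = boot[:, i] - boot[:, j]
            lo, hi = np.quantile(diff, [alo, ahi])
            sig = bool(lo > 0 or hi < 0)
            win_i = values[fi] < values[fj]
            signif.loc[fi, fj] = signif.loc[fj, fi] = sig
            if values[fi] != values[fj]:
                winner.loc[fi, fj] = "left" if win_i else "down"
                winner.loc[fj, fi] = "down" if win_i else "left"
    return SignificanceMatrix(labels, winner, signif, metric, values)


def outlier_ratio(
    edge_deviations: pd.DataFrame,
    thresholds: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target fraction of edges with |deviation| below each threshold.

    ``edge_deviations``: columns target, deviation.  Returns the per-target
    ratio table and a box-plot style distribution summary over targets
    (linear-interpolation quartiles; whiskers at 1.5×IQR clipped to data).
    """
    rows = []
    for target, grp in edge_deviations.groupby("target", sort=True):
        dev = np.abs(grp["deviation"].to_numpy(float))
        for t in thresholds:
            rows.append({"target": target, "threshold": t, "ratio": float((dev < t).mean())})
    ratios = pd.DataFrame(rows)
    summaries = []
    for t, grp in ratios.groupby("threshold", sort=True):
        r = grp["ratio"].to_numpy()
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = r[(r >= lo_fence) & (r <= hi_fence)]
        summaries.append(
            {
                "threshold": t,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_targets": len(r),
            }
        )
    return ratios, pd.DataFrame(summaries)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def determinant_correlations(
    edge_table: pd.DataFrame,
    features: Sequence[str] = ("heavy_atom_change", "abs_deviation", "ddg_pred", "alpha_mean"),
    n_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between per-edge accuracy determinants.

    Correlation and its two-sided p-value (t transform, n−2 df) are computed
    on the raw data; for display each pair is also reduced to ``n_bins``
    equal-count bins of the x feature with per-bin mean and SD of y.
    Constant features yield NaN correlations, flagged in the output.
    """
    present = [f for f in features if f in edge_table.columns]
    df = edge_table[present].dropna()
    if len(df) < n_bins:
        raise StatisticError(f"need >= {n_bins} complete edges")
    corr_rows, bin_rows = [], []
    for i, fx in enumerate(present):
        for fy in present[i + 1 :]:
            x, y = df[fx].to_numpy(float), df[fy].to_numpy(float)
            if np.allclose(x, x[0]) or np.allclose(y, y[0]):
                corr_rows.append(
                    {"x": fx, "y": fy, "pearson_r": np.nan, "p_value": np.nan,
                     "stars": "", "n": len(x), "undefined": True}
                )
                continue
            res = sps.pearsonr(x, y)
            corr_rows.append(
                {"x": fx, "y": fy, "pearson_r": float(res.statistic),
                 "p_value": float(res.pvalue), "stars": _stars(res.pvalue),
                 "n": len(x), "undefined": False}
            )
            bins = pd.qcut(pd.Series(x).rank(method="first"), n_bins, labels=False)
            for b in range(n_bins):
                sel = bins.to_numpy() == b
                bin_rows.append(
                    {"x": fx, "y": fy, "bin": b,
                     "x_mean": float(x[sel].mean()), "y_mean": float(y[sel].mean()),
                     "y_sd": float(y[sel].std(ddof=1)) if sel.sum() > 1 else 0.0}
                )
    return pd.DataFrame(corr_rows), pd.DataFrame(bin_rows)
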