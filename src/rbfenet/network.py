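"""Maximum-likelihood reconstruction of per-ligand ΔG from the edge network.

Each target's perturbation graph has ligands as nodes and measured relative
binding free energies ΔΔG as directed edge values.  With Gaussian edge errors
of variance σ², the maximum-likelihood node values x minimize

    Σ_edges w_ij (ΔΔG_ij − (x_j − x_i))²,    w_ij = 1/σ_ij²,

which is a weighted graph-Laplacian linear system.  The solution is defined
only up to an additive constant per connected component (the gauge); node
*differences* are gauge-invariant.  For comparison with experiment the gauge
is fixed per component so the mean predicted ΔG equals the mean experimental
ΔG of the same ligands.  Node uncertainties come from the diagonal of the
Laplacian pseudoinverse (the error covariance of the weighted least-squares
fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: variance floor (kcal/mol) so a zero-σ edge cannot get infinite weight
SIGMA_FLOOR = 0.1


@dataclass
class PerturbationGraph:
    """Per-target ligand graph with inverse-variance edge weights."""

    target: str
    graph: nx.Graph  # edge attrs: ddg (oriented u->v), weight

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_graph(
    estimates: pd.DataFrame, target: str | None = None, sigma_floor: float = SIGMA_FLOOR
) -> PerturbationGraph:
    """Build the perturbation graph for one target (and one force field).

    Edge weight is 1/max(σ, σ_floor)².  Antiparallel duplicates are folded
    onto one orientation (reversal negates ΔΔG) and parallel measurements are
    merged by inverse-variance pooling: ddg = Σwᵢddgᵢ/Σwᵢ, weight = Σwᵢ.
    """
    if estimates.empty:
        raise ValueError("no edges")
    targets = estimates["target"].unique()
    if target is None:
        if len(targets) != 1:
            raise ValueError(f"estimates span several targets {sorted(targets)}")
        target = targets[0]
    g = nx.Graph()
    sigma = estimates.get("ddg_sigma")
    if sigma is None:
        sigma = pd.Series(np.nan, index=estimates.index)
    w = 1.0 / np.maximum(sigma.fillna(sigma_floor).to_numpy(dtype=float), sigma_floor) ** 2
    if not np.all(np.isfinite(w) & (w > 0)):
        raise ValueError("non-finite edge weights")
    for (_, row), wi in zip(estimates.iterrows(), w):
        a, b, ddg = row["ligand_a"], row["ligand_b"], float(row["ddg_mean"])
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if g.has_edge(a, b):
            # canonical orientation is the first-seen source; reversal negates
            e = g.edges[a, b]
            signed = ddg if e["source"] == a else -ddg
            tot = e["weight"] + wi
            e["ddg"] = (e["ddg"] * e["weight"] + signed * wi) / tot
            e["weight"] = tot
        else:
            g.add_edge(a, b, ddg=ddg, weight=wi, source=a)
    return PerturbationGraph(target=str(target), graph=g)


def estimate_node_dg(pgraph: PerturbationGraph) -> pd.DataFrame:
    """Solve the weighted least-squares node values, one gauge per component.

    Within each connected component the weighted Laplacian system L x = b with
    b_i = Σ_j w_ij ΔΔG(j→i is negative incidence) is solved with the minimum
    norm (component mean zero) gauge via the pseudoinverse; uncertainties are
    sqrt(diag(L⁺)).  Isolated nodes cannot occur by construction; a component
    of size 1 would be a single ligand with no edges.
    """
    g = pgraph.graph
    rows = []
    for comp_id, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        nodes = sorted(comp)
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        lap = np.zeros((n, n))
        b = np.zeros(n)
        for u, v, data in g.subgraph(comp).edges(data=True):
            src = data["source"]
            dst = v if u == src else u
            i, j, w, d = idx[src], idx[dst], data["weight"], data["ddg"]
            # oriented edge src->dst carries ddg = x_dst - x_src
            lap[i, i] += w
            lap[j, j] += w
            lap[i, j] -= w
            lap[j, i] -= w
            b[i] -= w * d
            b[j] += w * d
        if n == 1:
            x = np.array([0.0])
            unc = np.array([np.inf])
        else:
            pinv = np.linalg.pinv(lap, hermitian=True)
            x = pinv @ b  # min-norm solution: component mean is 0
            unc = np.sqrt(np.maximum(np.diag(pinv), 0.0))
        for node, xi, ui in zip(nodes, x, unc):
            rows.append(
                {
                    "target": pgraph.target,
                    "ligand": node,
                    "dg_calc": float(xi),
                    "dg_uncertainty": float(ui),
                    "component_id": comp_id,
                }
            )
    return pd.DataFrame(rows)


def center_to_experiment(nodes: pd.DataFrame, experiments: pd.DataFrame) -> pd.DataFrame:
    """Shift each component so mean(dg_calc) matches mean(dg_exp).

    A single additive constant per connected component anchors the relative
    scale to experiment; differences between ligands are untouched.  Every
    ligand must have an experimental value.
    """
    exp = experiments.set_index(["target", "ligand"])["dg_exp"]
    out = nodes.copy()
    key = list(zip(out["target"], out["ligand"]))
    missing = [k for k in key if k not in exp.index]
    if missing:
        raise ValueError(f"no experimental ΔG for ligands {missing[:5]}")
    out["dg_exp"] = [float(exp.loc[k]) for k in key]
    for (_, _), grp in out.groupby(["target", "component_id"], sort=False):
        shift = grp["dg_exp"].mean() - grp["dg_calc"].mean()
        out.loc[grp.index, "dg_calc"] = grp["dg_calc"] + shift
        logger.debug("component shift %.4f kcal/mol", shift)
    return out


def node_estimates(
    estimates: pd.DataFrame,
    experiments: pd.DataFrame,
    sigma_floor: float = SIGMA_FLOOR,
) -> pd.DataFrame:
    """End-to-end per-target node reconstruction for one force field.

    Convenience wrapper: build graph → solve → center, concatenated over the
    targets present in ``estimates``.
    """
    pieces = []
    for target, grp in estimates.groupby("target", sort=False):
        pg = build_graph(grp, target=target, sigma_floor=sigma_floor)
        nodes = estimate_node_dg(pg)
        pieces.append(center_to_experiment(nodes, experiments))
    return pd.concat(pieces, ignore_index=True)
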