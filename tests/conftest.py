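"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: the Bennett
oracle is a refining grid search over a freshly written self-consistency
residual, the network oracle solves the dense weighted normal equations with
``numpy.linalg.lstsq``, and the Kendall oracle enumerates concordant and
discordant pairs directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

KB = 0.0019872041  # kcal/(mol K)


# ---------------------------------------------------------------- oracles


def bar_residual_oracle(dg: np.ndarray, wf: np.ndarray, wr: np.ndarray, beta: float):
    """Bennett self-consistency residual, written independently (log-sum form)."""
    dg = np.atleast_1d(np.asarray(dg, float))[:, None]
    m = np.log(len(wf) / len(wr)) / beta
    fwd = (1.0 / (1.0 + np.exp(np.clip(beta * (m + wf[None, :] - dg), -700, 700)))).sum(axis=1)
    rev = (1.0 / (1.0 + np.exp(np.clip(-beta * (m - wr[None, :] - dg), -700, 700)))).sum(axis=1)
    return fwd - rev


def bar_grid_oracle(wf, wr, temperature=298.0, tol=1e-9) -> float:
    """ΔG by successive grid refinement on the Bennett residual's sign change."""
    wf, wr = np.asarray(wf, float), np.asarray(wr, float)
    beta = 1.0 / (KB * temperature)
    lo = min(wf.min(), (-wr).min()) - 50.0
    hi = max(wf.max(), (-wr).max()) + 50.0
    while hi - lo > tol:
        grid = np.linspace(lo, hi, 41)
        res = bar_residual_oracle(grid, wf, wr, beta)
        sign_change = np.nonzero(np.diff(np.sign(res)) != 0)[0]
        if len(sign_change) == 0:  # fall back to smallest |residual|
            k = int(np.argmin(np.abs(res)))
            lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 40)]
        else:
            k = int(sign_change[0])
            lo, hi = grid[k], grid[k + 1]
    return 0.5 * (lo + hi)


def gaussian_intersection_grid_oracle(m1, s1, m2, s2) -> float:
    """Density-intersection abscissa by dense grid between the means."""
    from scipy.stats import norm

    lo, hi = min(m1, m2) - 1e-6, max(m1, m2) + 1e-6
    x = np.linspace(lo, hi, 2_000_001)
    return float(x[np.argmin(np.abs(norm.pdf(x, m1, s1) - norm.pdf(x, m2, s2)))])


def network_lstsq_oracle(edges, weights, n_nodes) -> np.ndarray:
    """Weighted least-squares node values via the dense incidence matrix.

    ``edges`` is a list of (i, j, ddg) with ddg = x_j − x_i.  The gauge is
    fixed by appending the constraint mean(x) = 0 with a heavy weight.
    Returns mean-zero node values (single connected component assumed).
    """
    m = len(edges)
    a = np.zeros((m + 1, n_nodes))
    b = np.zeros(m + 1)
    for row, ((i, j, d), w) in enumerate(zip(edges, weights)):
        sw = np.sqrt(w)
        a[row, i] = -sw
        a[row, j] = sw
        b[row] = sw * d
    big = 1e6
    a[m, :] = big / n_nodes
    b[m] = 0.0
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    return x - x.mean()


def kendall_pair_oracle(x, y) -> float:
    """τ-b by explicit enumeration of all pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = len(x) * (len(x) - 1) / 2
    return (nc - nd) / np.sqrt((n0 - tx) * (n0 - ty))


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact noisy benchmark shared by read-only tests."""
    from rbfenet.synth import SyntheticConfig, generate_benchmark

    cfg = SyntheticConfig(n_targets=4, ligands_per_target=(8, 12), seed=7)
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def zero_noise_benchmark():
    from rbfenet.synth import generate_benchmark, zero_noise_config

    cfg = zero_noise_config(seed=11, n_targets=3, ligands_per_target=(6, 9))
    return generate_benchmark(cfg)
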