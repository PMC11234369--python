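"""Free energy estimation from nonequilibrium work distributions.

An alchemical leg is sampled in both directions: forward work values for the
A→B switch and reverse work values for the B→A switch (stored raw, i.e. the
work actually performed in the B→A direction; they are negated whenever
compared against forward works).  The Crooks fluctuation theorem links the two
distributions to the equilibrium free energy difference; its maximum-likelihood
estimator is the Bennett acceptance ratio (BAR) applied to work values.

The module provides

* :func:`estimate_cft_ml` — the Crooks/Bennett maximum-likelihood estimate,
* :func:`estimate_cgi` — the Crooks Gaussian-intersection fallback,
* :func:`overlap_alpha` — the overlap-based convergence diagnostic α ∈ [−1, 1],
* :func:`combine_legs` — thermodynamic-cycle combination of complex and
  solvent legs into an edge ΔΔG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

#: Boltzmann constant in kcal/(mol K)
KB_KCAL_MOL_K = 0.0019872041

#: default simulation temperature, kelvin
DEFAULT_TEMPERATURE = 298.0


class EstimationError(RuntimeError):
    """The requested estimator cannot be applied to these work samples."""


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse work samples for one alchemical leg.

    ``forward_work`` holds A→B work values and ``reverse_work`` raw B→A work
    values, both in kcal/mol at the given temperature.
    """

    forward_work: np.ndarray
    reverse_work: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_work", np.asarray(self.forward_work, dtype=float))
        object.__setattr__(self, "reverse_work", np.asarray(self.reverse_work, dtype=float))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("forward_work", "reverse_work"):
            w = getattr(self, name)
            if w.size and not np.isfinite(w).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL_MOL_K * self.temperature)

    def swapped(self) -> "WorkSet":
        """The same leg viewed in the opposite direction (B→A)."""
        return WorkSet(self.reverse_work, self.forward_work, self.temperature)


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A per-leg free energy estimate with its convergence diagnostic."""

    dg: float  # kcal/mol
    uncertainty: float  # kcal/mol, bootstrap standard error
    method: str  # cft_ml | cgi | jarzynski_fwd | jarzynski_rev
    alpha: float  # overlap convergence measure in [-1, 1]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.alpha <= 1.0 + 1e-12:
            raise ValueError(f"alpha {self.alpha} outside [-1, 1]")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def _bar_residual(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float, m: float) -> float:
    """Bennett self-consistency residual; monotonically increasing in dg."""
    fwd = expit(-beta * (m + wf - dg)).sum()
    rev = expit(beta * (m - wr - dg)).sum()
    return fwd - rev


def _solve_bar(wf: np.ndarray, wr: np.ndarray, beta: float, tol: float = 1e-10) -> float:
    nf, nr = len(wf), len(wr)
    m = np.log(nf / nr) / beta
    span = np.concatenate([wf, -wr])
    lo, hi = span.min() - 50.0, span.max() + 50.0
    f_lo, f_hi = _bar_residual(lo, wf, wr, beta, m), _bar_residual(hi, wf, wr, beta, m)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise EstimationError(
            "Bennett condition not bracketable (no forward/reverse overlap); "
            "consider the Gaussian-intersection estimator (estimate_cgi)"
        )
    return brentq(_bar_residual, lo, hi, args=(wf, wr, beta, m), xtol=tol)


def _bootstrap_se(
    wf: np.ndarray,
    wr: np.ndarray,
    beta: float,
    solver,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        bf = wf[rng.integers(0, len(wf), len(wf))]
        br = wr[rng.integers(0, len(wr), len(wr))]
        try:
            vals[b] = solver(bf, br, beta)
        except EstimationError:
            vals[b] = np.nan
    vals = vals[np.isfinite(vals)]
    return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def estimate_cft_ml(
    works: WorkSet, n_boot: int = 200, seed: int = 0
) -> FreeEnergyEstimate:
    """Crooks maximum-likelihood (Bennett) free energy estimate for one leg.

    Solves, with β = 1/(k_B T), M = ln(n_f/n_r)/β, forward works W_f and raw
    reverse works W_r::

        Σ_f 1/(1 + exp(β(M + W_f − ΔG))) = Σ_r 1/(1 + exp(−β(M − W_r − ΔG)))

    by bracketed root search (the left side grows and the right side falls
    monotonically in ΔG, so the root is unique).  Uncertainty is a seeded
    nonparametric bootstrap standard error over the work samples.

    Raises
    ------
    EstimationError
        If a direction has fewer than 2 samples (a one-sided Jarzynski
        estimate would be needed) or the distributions have zero overlap.
    """
    wf, wr = works.forward_work, works.reverse_work
    if len(wf) < 2 or len(wr) < 2:
        raise EstimationError(
            "need >= 2 samples in each direction for the ML estimator; "
            "use a one-sided Jarzynski estimate for one-directional data"
        )
    dg = _solve_bar(wf, wr, works.beta)
    se = _bootstrap_se(wf, wr, works.beta, _solve_bar, n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(
        dg=dg, uncertainty=se, method="cft_ml",
        alpha=overlap_alpha(works), temperature=works.temperature,
    )


def _gaussian_intersection(m1: float, s1: float, m2: float, s2: float) -> float:
    """Intersection abscissa of two Gaussian densities, between the means.

    With equal variances the intersection is the midpoint.  Otherwise the
    quadratic (1/s1² − 1/s2²)x² − 2(m1/s1² − m2/s2²)x + (m1²/s1² − m2²/s2²
    − 2 ln(s2/s1)) = 0 has two roots and the one between the means is taken;
    if neither lies between (possible only when the means coincide), the root
    closest to the midpoint is used.
    """
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log(s2 / s1)
    disc = b * b - 4 * a * c
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    lo, hi = min(m1, m2), max(m1, m2)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size:
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def estimate_cgi(works: WorkSet, n_boot: int = 200, seed: int = 0) -> FreeEnergyEstimate:
    """Crooks Gaussian-intersection (CGI) estimate: fallback when overlap is poor.

    Fits Gaussians to the forward works and to the negated reverse works; the
    abscissa where the two densities intersect estimates ΔG.  With equal
    fitted variances this is exactly the midpoint of the two means.  Degenerate
    (zero-variance) samples also fall back to the midpoint.
    """
    wf, wr = works.forward_work, works.reverse_work
    if len(wf) < 2 or len(wr) < 2:
        raise EstimationError("need >= 2 samples in each direction")

    def solve(bf: np.ndarray, br: np.ndarray, beta: float) -> float:
        m1, s1 = bf.mean(), bf.std(ddof=1)
        m2, s2 = (-br).mean(), (-br).std(ddof=1)
        if s1 < 1e-12 or s2 < 1e-12:
            return 0.5 * (m1 + m2)
        return _gaussian_intersection(m1, s1, m2, s2)

    dg = solve(wf, wr, works.beta)
    se = _bootstrap_se(wf, wr, works.beta, solve, n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(
        dg=dg, uncertainty=se, method="cgi",
        alpha=overlap_alpha(works), temperature=works.temperature,
    )


def _gaussian_ovl(m1: float, s1: float, m2: float, s2: float) -> float:
    """Overlap coefficient ∫ min(f, g) of two Gaussian densities (analytic)."""
    if np.isclose(s1, s2):
        d = abs(m1 - m2)
        return float(2.0 * norm.cdf(-d / (2.0 * s1)))
    # two crossing points; between them the density with the larger variance
    # is the smaller one iff s2 > s1 (narrow beats wide near its own mean)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log(s2 / s1)
    disc = max(b * b - 4 * a * c, 0.0)
    x1, x2 = sorted([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    narrow, wide = ((m1, s1), (m2, s2)) if s1 < s2 else ((m2, s2), (m1, s1))
    # outside (x1, x2): narrow density is the minimum; inside: wide density
    ovl = (
        norm.cdf(x1, *narrow)
        + (1.0 - norm.cdf(x2, *narrow))
        + (norm.cdf(x2, *wide) - norm.cdf(x1, *wide))
    )
    return float(min(max(ovl, 0.0), 1.0))


def overlap_alpha(works: WorkSet) -> float:
    """Overlap convergence measure α = 1 − 2·OVL ∈ [−1, 1]; lower is better.

    OVL is the overlap coefficient (integral of the pointwise minimum) of
    Gaussian fits to the forward and negated-reverse work densities.  Perfect
    overlap gives α = −1, disjoint distributions α → 1.  α is invariant under
    a common shift of both distributions.  Zero-variance fits degrade to an
    indicator overlap: α = −1 if the means coincide, else +1.
    """
    wf, nwr = works.forward_work, -works.reverse_work
    if len(wf) < 2 or len(nwr) < 2:
        raise EstimationError("need >= 2 samples in each direction for alpha")
    m1, s1 = wf.mean(), wf.std(ddof=1)
    m2, s2 = nwr.mean(), nwr.std(ddof=1)
    if s1 < 1e-12 or s2 < 1e-12:
        return -1.0 if np.isclose(m1, m2) else 1.0
    return 1.0 - 2.0 * _gaussian_ovl(m1, s1, m2, s2)


@dataclass(frozen=True)
class CombinedEdge:
    """ΔΔG fragment produced by combining the two legs of one repeat."""

    ddg_calc: float  # kcal/mol
    uncertainty: float  # kcal/mol
    leg_alphas: tuple[float, float]  # (complex, solvent)


def combine_legs(
    complex_leg: FreeEnergyEstimate, solvent_leg: FreeEnergyEstimate
) -> CombinedEdge:
    """Thermodynamic-cycle combination: ΔΔG = ΔG_complex − ΔG_solvent.

    Uncertainties add in quadrature; the per-leg α values are retained so the
    edge-level convergence mean can be taken over all legs of all repeats.
    """
    if not np.isclose(complex_leg.temperature, solvent_leg.temperature):
        raise ValueError(
            f"leg temperatures differ: {complex_leg.temperature} K vs "
            f"{solvent_leg.temperature} K"
        )
    return CombinedEdge(
        ddg_calc=complex_leg.dg - solvent_leg.dg,
        uncertainty=float(np.hypot(complex_leg.uncertainty, solvent_leg.uncertainty)),
        leg_alphas=(complex_leg.alpha, solvent_leg.alpha),
    )
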