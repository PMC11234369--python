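# Methods

This note records the models, conventions and numerical choices behind
`rbfenet`, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

An *edge* is an alchemical perturbation between two ligands of one target;
a *node* is a ligand. All free energies are kept in kcal/mol internally
(readers convert kJ/mol at the boundary with the exact factor 4.184). The
sign convention is ΔΔG(A→B) = ΔG_bind(B) − ΔG_bind(A), equivalently
ΔG_complex − ΔG_solvent around the thermodynamic cycle; reversing an edge
negates its value. Reverse nonequilibrium works are stored as the raw work
of the B→A switch and negated whenever compared against forward works.
Labels are opaque case-sensitive strings. Temperature defaults to 298 K
with k_B = 0.0019872041 kcal/(mol·K).

## Free energy estimation from work values

**Crooks ML / Bennett.** For forward works W_f and raw reverse works W_r,
the estimate solves

    Σ_f 1/(1+exp(β(M + W_f − ΔG))) = Σ_r 1/(1+exp(−β(M − W_r − ΔG))),

with M = ln(n_f/n_r)/β. The left side is increasing and the right side
decreasing in ΔG, so the root is unique; it is found by bracketed Brent
search on [min(works) − 50, max(works) + 50] kcal/mol to 1e−10. Zero
overlap between the two distributions makes the equation unbracketable and
raises a diagnostic error recommending the Gaussian-intersection fallback;
a direction with fewer than two samples raises an error pointing at
one-sided (Jarzynski) estimation instead. Per-leg uncertainty is a seeded
nonparametric bootstrap standard error over the work samples (200
resamples by default); no analytic per-leg error model is assumed.

**CGI fallback.** Gaussians are fitted to the forward and negated-reverse
works; ΔG is the density-intersection abscissa (the root of the quadratic
lying between the means; with equal variances, exactly the midpoint).
Zero-variance fits degrade to the midpoint.

**Overlap diagnostic α.** α := 1 − 2·OVL, where OVL ∈ [0, 1] is the
overlap coefficient (integral of the pointwise minimum) of the two fitted
Gaussians, computed analytically from the crossing points. This places α
in [−1, 1], −1 for perfect overlap, → +1 for disjoint distributions, is
invariant under a common shift, and increases monotonically with mean
separation — all the properties the downstream 0.8 threshold relies on.
The functional form is isolated behind one function so an alternative
overlap measure can be swapped in without touching the filter.
Zero-variance fits use indicator overlap (α = −1 iff the means coincide).

**Legs → edge.** ΔΔG = ΔG_complex − ΔG_solvent, uncertainties in
quadrature; leg temperatures must match; per-leg α values are carried
along for edge-level averaging.

## Aggregation, convergence filter, consensus

Repeats are combined by the arithmetic mean with the (n−1) sample standard
deviation σ(ΔΔG) as error estimate (σ = 0 with a warning for a single
repeat). The edge-level α is the mean of up to six per-leg values
(3 repeats × complex/solvent); a per-leg maximum is available behind a
flag for a more conservative reading.

An edge is *converged* iff **both** α < 0.8 and σ(ΔΔG) < 1.5 kcal/mol hold
strictly; boundary values are not converged, and edges with no α (e.g.
imported results that never carried the diagnostic) can never be converged.
The partition is exhaustive and disjoint, and relaxing either threshold can
only grow the converged set.

The consensus estimate is the unweighted per-edge mean over a member list
(default: three independent force fields), each contributing its first
repeat so total sampling cost matches a single three-repeat calculation;
edges missing in any member are dropped with a logged count. Averaging k
unbiased members with independent equal noise reduces RMSE by √k; the
pipeline verifies ≈ √3 for the default triple.

## Network maximum likelihood

Per target and force field, parallel/antiparallel duplicate edges are
pooled by inverse variance with weights w = 1/max(σ, 0.1 kcal/mol)² — the
floor prevents a zero-σ edge from dominating. Node values minimize
Σ w_ij (ΔΔG_ij − (x_j − x_i))²; the weighted-Laplacian system is solved
per connected component via the pseudoinverse, whose minimum-norm solution
fixes the gauge at component mean zero and whose diagonal provides the
error variances. Each component is then shifted by one constant so its
mean predicted ΔG equals the mean experimental ΔG of the same ligands
(for a connected target this is the per-target experimental mean); node
*differences* are independent of gauge and centering. A consistent
(cycle-error-free) graph is reproduced exactly; under i.i.d. edge noise the
expected squared node error equals trace(L⁺)/n, which the tests verify
against simulation.

## Statistics

Edge-level accuracy is RMSE/MUE of ΔΔG against experiment; node level uses
the reconstructed ΔG. Ranking quality per target uses Kendall τ-b (tie
corrected — experimental affinities often tie after rounding) and Spearman
ρ, requiring ≥ 3 ligands; the overall ranking number is the
ligand-count-weighted mean τ over targets, with undefined per-target values
excluded and weights renormalized (logged).

All intervals are 95% percentile bootstrap intervals from 1000 resamples
(percentile rather than BCa: simplest defensible choice, and exactly
seed-reproducible). Edge statistics resample edges; node statistics
resample ligands. Resampling always indexes a canonically sorted view of
the data, so results are independent of input row order and bit-stable
under a fixed seed. A statistic undefined on more than 20% of resamples is
an error, not a silent NaN.

Force-field comparisons use a paired bootstrap on the items shared by all
force fields (inner join, dropped items logged): the shared items are
resampled jointly, the metric difference recomputed, and a pair is
significantly different when the 95% interval of the difference excludes
zero; the winner is the lower-error member. Outlier-ratio curves report
the per-target fraction of edges with |error| below 1–4 kcal/mol, with
box summaries using linear-interpolation quartiles and 1.5×IQR whiskers.
Accuracy-determinant correlations (heavy-atom change, |error|, |ΔΔG|, α)
are Pearson r on raw data with t-transform p-values (n−2 df) and
significance stars at 0.05/0.01/0.001; 20 equal-count bins are produced
for display only.

## Parameter attribution

An edge involves parameter p when the multiset counts of p differ between
the end-state assignments (changed, created, or annihilated); an edge
counts once regardless of how many atoms use p. Per-parameter error is the
RMSE over the involving edges (fewer than 3 edges ⇒ low-support flag), and
the version comparison is ΔRMSE(p) = RMSE_FF1(p) − RMSE_FF2(p) with FF1
the older version, so positive means the newer version improved. The
paired bootstrap resamples the parameter's edge subset jointly for both
force fields; the effect is significant when its 95% interval excludes
zero. The whole-set ΔRMSE is computed from the data and reported as the
conventional reference line for plots (callers can also test against it
via the `reference` argument, but a parameter with zero true effect
genuinely differs from a nonzero whole-set change, so that stricter test
flags nulls at well above the nominal rate and is not the default). By
default the analysis runs on the converged subset; a flag lifts the
filter. Co-usage between parameters is the Matthews correlation of the
binary edge-usage vectors (0 returned, flagged, on a zero marginal);
parameters are grouped by spectral clustering on the affinity (MCC+1)/2,
with k chosen by the largest eigengap of the normalized Laplacian in
[2, min(15, P−1)] unless given. The number of clusters and the affinity
transform are explicit knobs, as no canonical choice exists.

## Synthetic benchmarks

The generator emulates the statistical structure of a multi-target
benchmark, not its chemistry. Per target: true ΔG ~ Normal(−10, 1.5²)
kcal/mol; experimental values add Normal(0, 0.4) noise (a realistic
affinity-measurement scale); the perturbation graph is a random spanning
tree plus extra edges to an average density of 1.87 edges/ligand. Default
scale — 22 targets, 20–35 ligands each, 3 repeats — lands within a few
percent of 600 ligands and 1100 edges. Each ligand draws a parameter
multiset from a block-structured catalogue (four-parameter blocks of
bond/angle/torsion/improper IDs that travel together), which gives the
MCC/clustering stage real planted structure. Each edge carries a
heavy-atom-change covariate (truncated geometric) that inflates noise, not
bias — larger perturbations converge worse rather than err systematically.

Per force field and repeat, ΔΔG_calc = true ΔΔG + Σ planted biases of the
perturbed parameters + Normal(0, (σ_base + σ_atom·Δatoms)²). Default
profiles: two versions of one family (the older carrying ~0.6–1.0 kcal/mol
biases on four parameters, the newer retaining one reduced bias), an
independent third profile, and a low-noise reference; base noise ≈ 1.0
kcal/mol matches the error scale public force fields show in practice. A
configured fraction of edges per force field (default 0.2–0.25) is
"nonconverged": 2.5× noise and per-leg α drawn above 0.8, while converged
edges draw α well below it. Work-sample generation uses the unique
Gaussian pair satisfying the Crooks relation: forward ~ N(ΔG + w_d, σ_W²),
reverse ~ N(−ΔG + w_d, σ_W²) with σ_W² = 2 w_d/β.

Everything is a pure function of the seed, and all planted quantities are
returned, so downstream tests are parameter-recovery tests. What passing
tests show: the estimators, filter, network solver, bootstrap machinery and
attribution logic recover planted structure at realistic scales. What they
do not show: behaviour under real-data pathologies absent from the
generator — non-Gaussian work distributions, correlated errors between
force fields, experimental-assay systematics, broken or sparse perturbation
maps, or repeat-to-repeat scatter much smaller than the total error (here
each repeat draws the full noise independently, so the spread across
repeats and the accuracy of the repeat mean are tied together in a way real
simulations need not obey).

## Problem sizes in tests and the acceptance script

The verification suite uses sizes chosen to make the statistical assertions
sharp while remaining quick on one CPU: 200 work sets of n = 5000 for
estimator consistency, 100 noisy 60-node/110-edge graphs against the
Laplacian-pseudoinverse prediction plus 20 dense-oracle comparisons, 500
outer replicates for bootstrap coverage, 200 null seeds for the
significance test's false-positive rate, 50 benchmark realizations for the
convergence-filter ordering, 50 planted-bias realizations of 200 edges for
attribution, and the full default benchmark (twice, byte-compared) for
end-to-end reproducibility. The acceptance script repeats the same checks
at slightly reduced counts (40 work sets, 200 coverage/null replicates)
alongside the complete default-benchmark analysis.
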