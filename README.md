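# rbfenet

Network analysis of **relative binding free energy (RBFE) benchmarks** — the
statistical layer that sits between alchemical free energy simulations and a
verdict on force-field quality.

Large-scale RBFE studies compute, for hundreds of ligand pairs (A, B)
binding dozens of protein targets, the relative binding free energy
ΔΔG(A→B) = ΔG_bind(B) − ΔG_bind(A) with several force fields and repeats.
Turning those raw numbers into statements like *"force field X is
significantly more accurate than Y"* or *"the error concentrates on edges
perturbing parameter b18"* requires a chain of estimators and statistics,
all of which this package implements:

* **Work → ΔΔG.** Per-leg free energies from forward/reverse nonequilibrium
  work samples via the Crooks-fluctuation-theorem maximum-likelihood
  (Bennett acceptance ratio) estimator, with the Crooks Gaussian
  intersection as fallback and the overlap diagnostic
  α = 1 − 2·OVL ∈ [−1, 1] (lower is better).
* **Repeats → edges.** Mean ΔΔG over repeats with the sample standard
  deviation σ(ΔΔG) as error estimate; a two-criterion convergence filter
  (α < 0.8 and σ(ΔΔG) < 1.5 kcal/mol, both strict) separates
  sampling problems from force-field error. No cycle-closure correction.
* **Edges → nodes.** Per-target maximum-likelihood reconstruction of ligand
  ΔG values from the perturbation graph: x̂ minimizes
  Σ w_ij (ΔΔG_ij − (x_j − x_i))², solved through the weighted graph
  Laplacian with uncertainties from its pseudoinverse, anchored to the
  experimental mean.
* **Metrics.** Edge- and node-level RMSE/MUE, Kendall τ-b and Spearman ρ per
  target, and the ligand-count-weighted overall
  τ = Σ_t (N_t/N)·τ_t; 95% percentile bootstrap intervals
  (1000 resamples) and paired-bootstrap significance matrices between force
  fields; outlier-ratio curves and accuracy-determinant correlations.
* **Consensus.** The unweighted per-edge average over several force fields
  (first repeat each), which trades three repeats of one model for one
  repeat of three models at the same cost.
* **Parameter attribution.** Per-edge perturbed-parameter sets (multiset
  difference of the end-state assignments), Matthews-correlation co-usage
  with spectral clustering, and the per-parameter version-to-version error
  change ΔRMSE(p) = RMSE_FF1(p) − RMSE_FF2(p) with bootstrap significance.
* **Synthetic benchmarks.** A generator that emulates the full statistical
  structure of a ~22-target / ~600-ligand / ~1100-edge benchmark — planted
  node ΔG values, Crooks-consistent work distributions, parameter-bias
  blocks, nonconverged edges with inflated noise — so every stage is
  testable as a parameter-recovery problem.

## Worked example

```python
from rbfenet.synth import SyntheticConfig, generate_benchmark
from rbfenet.pipeline import RunConfig, run_full_analysis

dataset, truth = generate_benchmark(SyntheticConfig(seed=42))
bundle = run_full_analysis(dataset, RunConfig(
    n_boot=1000, seed=42,
    consensus_members=["FF-A-2.0", "FF-B", "FF-REF"],
    ff_pair=("FF-A-1.0", "FF-A-2.0"),
))
print(bundle.edge_metrics.query("scope == 'ALL' and metric == 'rmse'")
      [["forcefield", "value", "ci_low", "ci_high", "n"]].round(2))
```

prints the edge-level RMSE (kcal/mol) of each force-field profile against
experiment, with 95% bootstrap intervals over 1102 edges:

```
forcefield  value  ci_low  ci_high     n
 Consensus   1.10    1.05     1.14  1102
  FF-A-1.0   1.63    1.55     1.70  1102
  FF-A-2.0   1.29    1.21     1.36  1102
      FF-B   1.40    1.33     1.47  1102
    FF-REF   0.77    0.74     0.81  1102
```

The consensus average beats every open profile it is built from, the
low-noise reference profile wins outright, and the "older" FF-A-1.0 — which
carries planted biases on four parameter blocks — trails its successor.
`bundle.parameter_effects` attributes that gap to specific parameters: the
block around `b00` (planted bias +1.0 kcal/mol) shows the largest
significantly positive ΔRMSE (0.61, CI [0.45, 0.76]), and spectral
clustering groups it with the co-perturbed members of its block.
`bundle.overall_tau` gives the ligand-weighted ranking quality
(e.g. τ = 0.74 for the consensus over 590 ligands).

The same pipeline is scriptable from the shell:

```bash
rbfenet simulate --seed 42 --outdir bench/
rbfenet report bench/edges.csv bench/experimental.csv \
    --alphas bench/leg_alphas.csv --assignments bench/assignments.csv \
    --ff-pair FF-A-1.0,FF-A-2.0 --seed 42 --outdir report/
```

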