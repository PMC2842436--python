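# mixedclr

Gene regulatory network inference from perturbation expression data:
mutual-information scoring with B-spline density smoothing, CLR-style
background correction including a **mixed dynamic/static variant**,
knock-out/knock-down filtration, and per-target sparse ODE regression
(Inferelator-style) with cross-validated L1 shrinkage — plus a synthetic
benchmark generator and precision–recall evaluation tools.

## The problem

Given expression observations of N genes — perturbed time courses sampled
at regular intervals, a wild-type steady state, and steady states with
each gene knocked out (level forced to ~0) or knocked down (forced to
~half wild type) — rank all N(N−1) ordered gene pairs *j → i* by
confidence that regulator *j* directly controls target *i*. This is the
deliverable of the DREAM-style *in silico* network challenges, and the
package is aimed at anyone benchmarking network-inference methods on such
data or applying them to comparable perturbation compendia.

## The method

Transcription of each target is approximated by a linear additive ODE

    dx_i/dt = −x_i/τ + Σ_j β_ij x_j ,

with τ the mRNA decay time scale (default 10 min). Within each time
course a forward finite difference defines a *response*
y_i(t_k) = (x_i(t_{k+1}) − x_i(t_k))/Δt + x_i(t_k)/τ paired with
*time-lagged* explanatory variables χ_j = x_j(t_k); at steady state the
derivative vanishes and y_i = x_i/τ. The pipeline has three stages:

1. **Mixed-CLR.** Mutual information is estimated with a B-spline
   smoothed histogram (10 bins, third-order splines), both *statically*
   between expression profiles (M^s) and *dynamically* between each
   response/explanatory pair (M^d, asymmetric). Each pair is scored by
   the CLR pseudo z-score z_ij = √(z_row² + z_col²), where z_row is the
   positive z-score of M^d[i,j] against target i's dynamic-MI row and
   z_col against regulator j's *static*-MI column (the expected
   distribution of spurious dependencies). Plain CLR and dynamic-CLR are
   available as baselines.
2. **Perturbation filtration.** An edge j → i is sent to the tail of the
   list (score −1) iff knocking *j* out **and** knocking it down both
   change x_i by less than a cutoff θ relative to wild type. By default
   θ is placed so that about one third of all ordered pairs are filtered.
3. **Sparse ODE regression.** For each target, the up-to-P = 10 highest
   positively-scored candidate regulators enter an L1-constrained least
   squares fit of the ODE design, Σ|β| ≤ s·Σ|β_ols|, solved on the
   LARS-lasso path; the shrinkage s ∈ [0,1] is chosen by 10-fold
   cross-validation (one-standard-error rule). Nonzero weights are
   converted to confidences by equal-rank substitution from the filtered
   score matrix and added back, pushing doubly-supported edges up the
   final ranking.

Evaluation reports AUPR (primary), AUROC, precision at fixed recall,
the fraction of identified true edges whose score beats their reversal
(causality resolution), and relative rank error (rank/K) versus node
degree.

## Worked example

Simulate a 20-gene benchmark, infer a network, and score it:

```sh
mixedclr simulate --n 20 --networks 1 --seed 5 --out demo/bench
mixedclr infer --data demo/bench/network_1 --out demo/run --seed 5
mixedclr evaluate --predictions demo/run/predictions.tsv \
    --gold demo/bench/network_1/goldstandard.tsv --n 20 --report pr,roc,causality
```

The infer step logs its stage diagnostics —

```
INFO mixedclr.pipeline: stage 1 (mixed): scored 380 pairs
INFO mixedclr.pipeline: stage 2: filtered 127 pairs (theta=0.09541)
INFO mixedclr.pipeline: stage 3: mean candidate-set size 6.4, mean s 0.81
```

(127/380 ≈ one third of ordered pairs filtered; on average 6.4 candidate
regulators per target survive to the regression, which keeps 81% of the
unpenalised coefficient mass) — and the evaluation prints

```json
{
  "aupr": 0.3619145715398483,
  "precision_at_recall_0.02": 1.0,
  "precision_at_recall_0.05": 1.0,
  "auroc": 0.7661764705882355,
  "causality_fraction": 0.8888888888888888,
  "causality_correct": 24,
  "causality_identified": 27
}
```

so the top of the list is exactly right (precision 1.0 at low recall),
and 24 of the 27 identified true edges are ranked above their reversal.
The same run is available from Python:

```python
from mixedclr import GRNPipeline, make_benchmark_suite, pr_curve

network, dataset, gold = make_benchmark_suite(n_networks=1, n_genes=20, seed=5)[0]
pipe = GRNPipeline(mode="pipeline", random_state=5).fit(dataset)
print(pr_curve(pipe.ranking_, gold).aupr)
```

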