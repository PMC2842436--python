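# Methods

## Model and assumptions

The package infers a directed gene regulatory network from perturbation
expression data under a deliberately simple dynamical model: each
target's mRNA level obeys a linear additive ODE,

    dx_i/dt = −x_i/τ + Σ_j β_ij x_j ,

with a single global first-order decay time scale τ and a sparse weight
matrix β (no auto-regulation: β_ii = 0 throughout, and self-pairs are
excluded from every score matrix, ranking and background statistic).
The model is target-centric — one uncoupled equation per gene — so model
complexity grows with in-degree but not with out-degree. Interaction
terms between regulators, protein intermediates and condition-specific
kinetics are all outside the model class.

Time-series observations enter through a forward finite difference:
within an experiment, each consecutive pair of observations contributes
a response row y_i = (x_i(t_{k+1}) − x_i(t_k))/Δt_k + x_i(t_k)/τ aligned
with time-lagged explanatory values χ_j = x_j(t_k). Δt is taken per
transition from the recorded times, so unequal sampling is supported;
transitions never cross experiment boundaries. Steady-state experiments
contribute y_i = x_i/τ against χ_j = x_j. The time lag is what gives
every "dynamic" quantity in the package its ability to resolve edge
direction: a regulator precedes the rate change of its target, not the
other way around.

Expression values are expected in [0, 1] (the convention of the *in
silico* challenge dialect this package reads and writes); the readers
warn, but do not fail or rescale, when values fall outside that range.

## Pipeline stages and their parameters

**Stage 1 — mutual information and background correction.**
Pairwise MI is estimated with a B-spline smoothed histogram: each sample
is spread over adjacent bins with weights from a clamped uniform
B-spline basis (partition of unity), and MI is the plug-in estimate on
the smoothed joint table, in nats. Defaults: `bins=10`, `order=3`
(quadratic splines). With `order=1` the estimator reduces exactly to the
classical histogram MI, which the tests exploit as an oracle. Each
variable is min–max rescaled to the basis domain before evaluation; a
constant variable puts all mass in the first bin deterministically.
Because the basis is clamped, edge bins have smaller integrals than
interior bins, so even uniform data does not produce equal bin
occupancies — a property of the cited estimator, not a defect.

The natural-log base is a free choice: MI base rescaling cancels inside
z-scores, so scores are unaffected. Background correction computes, for
each entry, a positive z-score against the target's row and the
regulator's column backgrounds and combines them as √(z_row² + z_col²).
Backgrounds use the sample SD (ddof = 1) over off-diagonal entries, the
entry itself included (including vs excluding it differs by O(1/N)); a
zero-variance background yields z = 0 rather than ±∞. Column statistics
are computed as row statistics of the transpose so that on a symmetric
MI matrix the static-CLR score matrix is *bitwise* symmetric — exactly
symmetric scores resolve no directionality, and the causality analysis
depends on that being exact, not approximate.

Mixed-CLR scores the *dynamic* MI value against the target's dynamic-MI
row and the regulator's *static*-MI column. The static column stands in
for the distribution of spurious (indirect or co-regulation)
dependencies. This assumes dynamic and static MI values share a range;
when dynamic values sit mostly below the static column means, the second
z-score clips to zero and mixed-CLR degenerates gracefully into a
dynamic-row-only score. When a dataset contains no time series at all,
the dynamic pairs are just steady states rescaled by 1/τ, and the
implementation delegates mixed-CLR to plain CLR so the equivalence is
exact rather than within rounding.

**τ (minutes, default 10).** Sets the decay term x/τ relative to the
finite difference. The default is in the range of common bacterial mRNA
half-lives (half-life = τ·ln 2 ≈ 7 min) and of the same order as the
default 20-minute sampling interval. An error in τ rescales the
steady-state response rows exactly by a constant (verified as a test
property), so downstream selection — which is scale-free through the
relative L1 constraint and rank substitution — is insensitive to
moderate misspecification.

**Stage 2 — perturbation filtration.** For each ordered pair, the
relative change |x_i(perturbed j) − x_i^wt| / x_i^wt is computed for the
knock-out and knock-down of j; the edge is filtered (score −1, tail of
the list) iff *both* fall below θ. Absolute change is used because
deleting a repressor raises its target. If only one perturbation block
exists, it alone decides; if x_i^wt = 0 the change is defined as 0 when
the perturbed value is also 0 and +∞ otherwise, keeping the rule
deterministic. Instead of an absolute default θ, the default operating
point filters approximately one third of all ordered pairs
(`filter_fraction=1/3`), with θ placed midway between the two order
statistics of the combined (max of KO/KD) change that bracket the
requested count; `theta` overrides with an absolute cutoff. Filtration
is monotone in θ and never reorders surviving edges.

**Stage 3 — sparse ODE regression.** Per target, the up-to-P = 10
regulators with the largest strictly positive filtered scores become
candidates (ties toward the lowest gene index; an empty candidate set
yields an all-zero model). Coefficients minimise the residual sum of
squares subject to Σ|β| ≤ s·Σ|β_ols|, read off the LARS-lasso path,
which is piecewise linear in the constraint bound, so interpolating
between path knots is exact. β_ols is the minimum-L2-norm least-squares
solution (deterministic under rank deficiency); s = 1 returns it, s = 0
returns zeros. No intercept is fitted (the ODE has no basal term in the
inference model) and variables are used unstandardised — inputs live in
[0, 1] and the constraint is relative to β_ols, so scaling largely
cancels.

s is selected per target on a 21-point grid (0.00–1.00, step 0.05) by
10-fold cross-validation of held-out residual squared error. The
default rule takes the smallest s within one standard error of the
minimum ("smallest with good generalisation"); `cv_rule="min"` takes the
arg-min. Fold assignment keeps whole provenance groups together — all
transitions of one time-series experiment share a fold — because
temporally adjacent rows are strongly dependent and would otherwise leak
across folds; when there are fewer groups than folds, contiguous row
blocks are used. Steady-state rows in which the *target itself* is
clamped are excluded from that target's fit by default
(`exclude_self_perturbation`): the intervention, not the transcription
model, sets those levels. Fold assignment is seeded, so fits are
reproducible.

Weight-to-confidence conversion sorts nonzero |β| descending (ties by
regulator then target index) and assigns the k-th largest strictly
positive filtered score, matrix-wide, with duplicates consumed with
multiplicity; the final score matrix is the elementwise sum. Filtered
(−1) entries can never be candidates, so they receive no boost and stay
at the tail. The final list orders all N(N−1) pairs by score descending
with (regulator, target) index as the deterministic tie-break.

## Evaluation conventions

AUPR uses stepwise interpolation — precision at each prefix that gains a
true positive, weighted by its recall increment (equivalently, average
precision over the full ranking); AUPR is interpolation-sensitive, so
the convention matters when comparing to other tools. AUROC uses the
trapezoid rule. An edge counts as *identified* for causality resolution
when its final score is strictly positive, and as *resolved* when it
strictly beats its reversal; ties are unresolved, which is what makes
exactly-symmetric static CLR resolve nothing. Relative rank error is
rank/K with K = N(N−1); the degree analysis correlates per-network
median error with median nonzero in-/out-degree across an ensemble
(Spearman).

## The synthetic benchmark

The generator emulates the *experiment designs* of the challenge data —
wild type, one knock-out and one knock-down steady state per gene
(clamped to 0 and half wild type), and perturbed time courses sampled
every `dt=20` minutes — on sparse random networks (default 2 edges/gene,
70% activating) whose kinetics are the same linear ODE the pipeline
assumes, with basal production added so the fixed point is positive.
Weights are damped geometrically (and the damping logged) until the
system is stable with a strictly positive steady state. Time courses
start from the fixed point perturbed multiplicatively per gene
(±75% by default) and are propagated exactly via the matrix exponential;
an optional Hill-saturation mode introduces model mismatch and is
integrated numerically. All observations are rescaled into [0, 1] by the
global maximum, then corrupted with additive Gaussian noise (default SD
0.025) and clipped back to [0, 1]. Hub-mode topology draws regulators
with heavy-tailed propensities and a restrictable regulator pool;
`target_indegree` fixes every in-degree exactly, which the degree
analyses use.

What the generator does *not* emulate: the thermodynamic mRNA+protein
simulator behind the original challenge data, realistic noise structure
(multiplicative, count-based), condition-dependent kinetics, or
topologies extracted from real organisms. Passing benchmarks here shows
the pipeline recovers networks when its model class is (close to)
well-specified at realistic noise; it does not certify performance on
real expression compendia.

Benchmark problem sizes used by the test suite and `scripts/acceptance.py`:
five 50-gene networks (23 time courses × 21 points, full KO/KD, noise SD
0.025) for the method-comparison, data-partition, causality and
MI-separation analyses; six 40-gene networks with fixed in-degrees 1–6
and eighteen hub-mode 40-gene networks (six regulator-pool sizes × three
replicates, 10 courses × 11 points) for the degree analyses. These sizes
make the qualitative orderings stable across seeds while keeping a full
run in the minutes range.

## Known limitations

* The L1 constraint with P = 10 candidates is deliberately parsimonious
  and under-selects regulators of high in-degree targets; ranking error
  grows with in-degree accordingly.
* Mixed-CLR's static-column background assumes dynamic and static MI
  share a range; when they do not, it degenerates to dynamic-row
  scoring (handled, but then the "mixed" aspect adds nothing).
* With coarse sampling relative to τ, the finite-difference response is
  a crude derivative estimate, and time-series-only data carries little
  signal — consistent with knock-out data dominating the data-partition
  comparison.
* The KO/KD filter is a point comparison with no significance test; at
  aggressive θ it will discard weak true edges.
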