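# Methods

## Measurement model

Both instruments are scored under item response theory on a common
logit metric. A polytomous item with discrimination `a` and ordered
step difficulties `b_1..b_m` follows the generalized partial credit
model (GPCM):

    P(X = x | θ) = exp(Σ_{v≤x} a (θ − b_v)) / Σ_{c=0..m} exp(Σ_{v≤c} a (θ − b_v)),

with the empty sum equal to zero, so categories run 0 (lowest
function) to m. A dichotomous Rasch item is the `m = 1`, `a = 1`
special case, `P(1) = logistic(θ − δ)`. The discrimination column of
the 34-item ADL bank is the slope `a` itself — no 1.7 logistic/ogive
scaling constant is applied, since the parameters are printed on the
logit metric. Category sums are accumulated in log space with
max-subtraction, so user-supplied banks with extreme parameters do not
overflow.

Fisher item information is `a²·Var(X | θ)` (for Rasch items,
`P(1 − P)`); test information adds over administered items. The code
verifies the identity I(θ) = −E[∂²/∂θ² log P(X; θ)] by finite
differences in the test suite.

## Person estimators

* **MLE** — Newton–Raphson on the log-likelihood from a start of 0,
  with a bisection safeguard whenever a step leaves the current
  bracket (the gradient `Σ a_i (x_i − E_i)` is strictly decreasing, so
  bracketing is exact); convergence at |Δθ| < 1e-6, at most 50
  iterations. All-minimum/all-maximum patterns have no interior
  maximum and return the trait bound ±4 with `at_boundary=True`.
  SEM = 1/√(test information) at the estimate.
* **MAP** — the same machinery on log-likelihood + log N(0,1) density;
  SEM = 1/√(test information + 1), the posterior curvature with a
  unit-variance prior. Defined for every pattern, including the empty
  one (prior mode 0).
* **EAP** — posterior mean over 61 equally spaced nodes on [−4, 4]
  with standard-normal weights, renormalized; SEM is the posterior SD.
  The node count is a numerical choice, not a modeling one: against a
  100 001-node oracle the 61-node mean agrees to ~1e-3 on realistic
  patterns (tested), which is two orders below the SEMs involved.

Person reliability on the unit-variance trait is `1 − SEM²`; the
reliability stop threshold 0.90 therefore corresponds to
SEM ≤ √0.1 ≈ 0.316. The trait bound ±4.0 (clamping, boundary patterns,
quadrature range) is comfortable for an N(0,1) population — every
cutpoint of interest lies within ±2.

## Adaptive administration

The first item is drawn uniformly at random from the pool
(seed-controlled; it can be pinned for clinical determinism). Each
subsequent item maximizes Fisher information at the current provisional
measure, ties broken by bank position. The provisional measure is the
session estimator's own estimate; under MLE an extreme early pattern
contributes its boundary value until an interior maximum appears.

The stop rule requires at least 7 items and then, by default, **both**

* person reliability ≥ 0.90, and
* `resi` < 0.05, where `resi` is the mean of the last three absolute
  changes in the provisional measure,

with bank exhaustion ending a session regardless. The conjunctive
combination is the package's resolution of an ambiguity in how the two
precision clauses interact: with these banks it yields a mean adaptive
length of ~13–14 of 34 ADL items (a ~60% saving) and, on the 23-item
CADL — whose total information cannot reach reliability 0.90 —
full-bank administration. The disjunctive reading
(`StopRule(require_both=False)`) is retained as an option; it shortens
ADL sessions to ~9 items. Two diagnostics are carried per step: `resi`
as above, and `corr`, the Pearson correlation of the last five
provisional measures with their step numbers — a flat trend signals a
settled estimate.

Person fit uses standardized residuals `z_i = (x_i − E_i)/√W_i` at the
final measure: outfit MNSQ is the mean of `z²`, infit MNSQ the
information-weighted ratio `Σ(x_i − E_i)²/ΣW_i`; responses with
|z| ≥ 2.0 are flagged as unexpected. Items whose score variance
vanishes at the evaluated measure are excluded with a warning rather
than contributing unbounded terms.

## The simulation design

The synthetic cohort is the study condition, not a tunable: 1000
person measures drawn from N(0,1), one complete response matrix per
scale generated by inverse-CDF sampling from the model category
probabilities, with a single uniform stream consumed persons-major so
every matrix is bit-reproducible from its seed. The same cohort of
true measures is reused across the three scales (the same simulated
persons re-measured); response draws use independent substreams. All
substreams descend from one base seed via named `SeedSequence` keys.

During the CAT-vs-NAT comparison the adaptive sessions **redraw** each
administered item's answer from the model at the person's true measure,
i.e. CAT and NAT are two independent test sittings. This is what makes
the comparison meaningful on a weakly informative scale: the
correlation between two independently estimated measure sets is bounded
by the product of their reliabilities (≈ 0.6 for the CADL), while
replaying the very same responses would push all correlations toward 1
by construction. Replay (`redraw=False`) is available to isolate
item-selection effects from response noise. The comparison reports two
correlations per cell: CAT vs the full-bank estimates (`pearson_r`) and
CAT vs the generating measures (`pearson_r_true`), the recovery
correlation that is this design's primary benchmark.

Equivalence uses a per-person two-sample z test,
`z = (θ_CAT − θ_NAT)/√(SEM²_CAT + SEM²_NAT)`, |z| > 1.96 at the 5%
level; the "different number ratio" is the percentage of significant
persons, with < 5% read as CAT ≡ NAT. Efficiency is
`100·(L − mean items)/L`. Cronbach's α uses `n − 1` sample variances on
the raw category matrix.

What the generator does **not** emulate: non-normal trait
distributions, differential item functioning between subgroups beyond
the two printed sex-specific parameterizations, rater effects, missing
data, or local dependence among items. Passing tests therefore show
that the engine is correct under the stated model, not that real
stroke cohorts satisfy it.

## Norm-referenced cutpoints

Without a gold-standard diagnosis there is no empirical ROC curve, so
strata are derived from the norm itself:

1. reliability → number of distinguishable strata via the separation
   index G = √(rel/(1 − rel)) and H = floor((4G + 1)/3)
   (0.67 → 2, 0.80 → 3, 0.90 → 4, 0.94 → 5, 0.96 → 6, 0.97 → 7);
2. 1-D k-means on the person measures. In one dimension the optimal
   partition is contiguous on sorted data, so the package computes the
   **global** optimum by dynamic programming — deterministic, no
   initialization, and verified against exhaustive enumeration on tiny
   inputs. Cluster SDs come from each cluster's own members (singleton
   clusters fall back to the pooled SD);
3. between each adjacent pair of clusters, fit a normal to each and
   grid-search the cut c maximizing Sp(c) + Se(c), where
   Sp = Φ((c − μ_lo)/σ_lo) and Se = 1 − Φ((c − μ_hi)/σ_hi). The grid
   step is 0.01 logits (0.1 T units), matching two-decimal reporting;
   the argmax provably coincides with the equal-density crossing of the
   two normals, which the tests confirm against an analytic root;
4. cuts are reported in logits and as T scores, T = 50 + 10·θ.

The upper cluster anchors "sensitivity" (its mass above the cut) and
the lower cluster "specificity" (mass below); this positive-direction
convention is a documented reading, not forced by the construction.
For the shipped study the stratum count is fixed at four for every
scale — the conservative convention for instruments whose published
reliabilities are ≥ 0.90 — rather than recomputed from each simulated
matrix (the simulated CADL α ≈ 0.6 alone would imply two strata).
Cutpoints default to full-bank measures per estimator; CAT-based
measures are selectable and give cuts within about half a T unit of
the full-bank ones on these banks.

Known limitation: measures estimated from an N(0,1) cohort are close
to symmetric, so the derived cuts are close to symmetric around T = 50
(ADL middle cut ≈ 51). MLE measure sets include ±4 boundary estimates,
which inflate the extreme clusters' SDs and pull their
specificity/sensitivity to ≈ 0.88; the Bayesian estimators stay above
0.90 throughout.

## Problem sizes and determinism

The shipped study runs 3 scales × 3 estimators at n = 1000 (the design
size) in roughly a minute on one CPU; the acceptance script runs the
subset of cells its summary quantities need (~30 s). Unit tests use
cohorts of 200–10 000 where a distributional property needs the larger
n. Every public entry point that consumes randomness takes an explicit
seed; identical configuration and seed reproduce byte-identical
matrices, sessions, and CSV reports.
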