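# Methods

## The dependency model

Two gene expression profiles x, y over n experimental conditions are
compared under two hypotheses. Under dependence, the paired points
(xᵢ, yᵢ) are modeled by a bivariate Gaussian mixture with G components,
each with its own weight, mean, and fully unconstrained 2×2 covariance
(volume, shape, and orientation all vary per component — the most general
parameterization, chosen because little is known a priori about the joint
shape of expression profiles). Under independence, each profile is modeled
separately by a univariate unequal-variance Gaussian mixture. Each of the
three models is fitted by EM for every component count in a search range,
and the count with the best BIC is kept, independently for the joint and
the two marginal fits.

BIC uses the maximize convention 2·ln L̂ − k·ln n. Free parameters are
counted as (G−1) weights + G·d means + G·d(d+1)/2 covariance entries:
3G−1 univariate, 6G−1 bivariate. The score

    D = BIC(M_xy) − BIC(M_x) − BIC(M_y)

is symmetric in (x, y), positive when joint modeling survives the dimension
penalty, and reduces analytically — when the search is pinned to G = 1 — to
−n·ln(1−r̂²) − ln n, where r̂ is the sample (MLE) correlation: a penalized
Gaussian likelihood-ratio test of independence. This identity is used as an
exact oracle in the test suite. The unpenalized variant
llr = ln L̂_xy − ln L̂_x − ln L̂_y is exposed as an alternative score and
satisfies D = 2·llr − Δk·ln n with Δk = k_xy − k_x − k_y.

A mixture component groups the conditions in which the two genes co-vary in
one particular regime, so the fitted joint model doubles as a clustering of
experiments: responsibilities give soft memberships, the argmax gives hard
cluster labels (ties resolve to the lower component index), and the
per-cluster empirical means of both genes summarize each regime. Model
means are reported alongside the empirical hard-member means, which are the
primary summary because they describe the actual conditions assigned to the
cluster.

## EM implementation and numerical choices

* **Initialization.** Seeded k-means++ center selection on the raw points,
  hard assignment to the nearest center, and empirical weights/means/
  covariances as the starting point. Each component count is fitted with
  `n_restarts` (default 5) independent initializations and the best
  log-likelihood run is kept. G = 1 has a closed-form MLE, so a single run
  suffices. All uniforms consumed by the seeding are pre-drawn from a
  `numpy` generator keyed by (seed, G, restart index); the EM kernels are
  pure functions of data and those uniforms, making every fit bit-exactly
  reproducible.
* **Convergence.** Relative log-likelihood change below 1e-6 (default) or
  500 iterations; non-convergence returns the best iterate flagged
  `converged=False`. The per-iteration log-likelihood trace is monitored;
  the largest observed decrease is reported on the model and asserted
  ≤ 1e-8 in tests (EM is monotone up to floating-point slack; the
  covariance floor below is a projection that could in principle break
  monotonicity, which is why it is monitored rather than assumed).
* **Degeneracy.** Covariance matrices are floored at a minimum eigenvalue
  of 1e-6 × the mean per-dimension data variance (absolute fallback 1e-6
  for constant data), via a closed-form 2×2 eigendecomposition. Duplicate
  or near-duplicate profiles therefore still score instead of failing;
  requesting more components than distinct points is an error, and the
  component search simply truncates at the number of distinct points.
* **Model selection.** Search G = 1..9 by default; BIC ties break toward
  the smaller G. Equal BIC is a measure-zero event but the tie-break keeps
  selection deterministic.
* **Symmetry.** The joint fit canonicalizes the column order of (x, y) by
  byte comparison and the score is evaluated in canonical operand order, so
  D(x, y) == D(y, x) holds bit-exactly, not merely to rounding.
* **Batch scoring.** Each pair derives its own fit seed from a CRC of the
  sorted gene names XORed with the base seed, so results are independent of
  evaluation order and of which other pairs are scored.

## Baselines

Euclidean distance, Pearson correlation, and Kendall's tau-b are the
textbook statistics (scipy implementations); constant/all-tied profiles
raise rather than silently returning 0. Mutual information discretizes each
profile independently into 10 equal-width bins over its own observed range
(equal-frequency binning available as an option) and evaluates the double
sum over the joint count table in nats, with 0·log 0 = 0. Orientation
metadata records that dbomm/llr/mi/cor treat larger values as dependent
while euc/tau treat smaller values as dependent; |r| and |τ| ranking
transforms are available where an unsigned dependence ranking is wanted.

## Network evaluation

Real interactions are the curated TF→target edges; background is every
other TF×gene pair (no self-pairs). The real-vs-background comparison is a
one-sided Welch (unequal-variance) two-sample t-test with the alternative
set by the measure's orientation; Welch is used because the two populations
have no reason to share a variance. PR curves rank the scored pairs by
dependency, emit one point per distinct score value, and count a pair as a
true positive when it matches a curated edge in either direction (the
measures are symmetric); FN counts against all curated edges among the
evaluated genes. An empty prediction set defines precision as 1.0
(flagged). AUPR integrates precision over recall by trapezoid, anchoring
the curve at recall 0 with the precision of its most stringent point —
hence a random ranking integrates to ≈ prevalence and a single-point curve
at full recall to its own precision. Network inference keeps pairs strictly
beyond the threshold (0 by default for the BIC-difference score, where it
marks the point at which joint modeling wins), orients edges TF→gene, emits
TF–TF pairs in both directions (the measure is symmetric and gives no
direction), and drops non-TF pairs with a logged count.

## Synthetic benchmark generator

`simulate_network` draws TF→gene edges with preferential attachment on TF
out-degree, giving the hub-heavy topologies characteristic of curated
regulatory networks. Any TF→gene pair (including both TF–TF directions) is
feasible. `simulate_expression` gives every gene an intrinsic per-condition
activity u ~ U(0,1); a regulated gene's signal is the mean of per-edge Hill
responses u^h/(u^h + K^h) (K ~ U(0.3, 0.7), h ~ U(2, 4)), inverted for the
30% of edges drawn as repressions; a regulated TF mixes regulation 50/50
with its own intrinsic activity so cyclic TF–TF motifs stay well-defined.
Expression is base + span·signal with base ~ U(6, 9) and span ~ U(2, 4) —
a log-intensity-like scale. At noise 0 the map from activities to targets
is deterministic and monotone per edge.

The single noise knob drives two perturbations: *biological* noise
multiplies the regulated signal component by exp(N(0, noise_level)), and
*experimental* noise adds N(0, noise_level × per-gene noise-free sd) to the
final value. Applying the multiplicative term to the signal component
rather than to the absolute expression level keeps the 0–60% range
informative and the 80% level clearly degraded, matching the qualitative
robustness profile the score is designed to have; the mapping from the
nominal percentage to variance is a package choice and is echoed in the
dataset's params block. What the generator does **not** emulate: mRNA
kinetics or time-course dynamics, combinatorial promoter logic beyond
additive Hill terms, probe-level measurement artifacts, and missing values.
Passing benchmarks on this generator therefore demonstrates correct
recovery of nonlinear, condition-dependent, noisy dependencies with a known
gold standard — not performance on any particular real compendium.

`make_pair` plants conditionally dependent pairs for unit-level validation:
G component means on a regular polygon of radius 4 (unit within-component
variances, within-component correlation `within_r`). The polygon makes the
between-component covariance exactly zero, so the global correlation is
weak while the conditional dependence is strong — the regime a mixture
score must detect and a global correlation cannot. The independent variant
keeps the same marginals but decouples the component and noise draws.

## Evaluation protocol sizes

The validation analyses (test suite and `scripts/acceptance.py`) use: 100
random datasets (n ∈ {20, 100, 500}) for the closed-form oracle; 20
replicates for model-selection rates (two components at means 0/8, n = 400;
single Gaussian, n = 500) with mean recovery checked at n = 5000; 200 + 200
dependent/independent pairs (n = 100, 3 components, r = 0.8) for
discrimination, scored with component search 1..5 and 3 restarts; the
noise sweep on the default network (100 genes, 10 TFs, 150 edges, 100
conditions, noise ∈ {0, .2, .4, .6, .8}, 5 seeds), with AUPR estimated over
all 150 gold edges plus 300 sampled background pairs per dataset and
component search 1..4 with 2 restarts — background subsampling and the
reduced search change the AUPR's prevalence baseline, not the comparison
across noise levels, and keep the sweep a few minutes on one CPU; and 20
replicates (n = 120) for condition-clustering recovery (ARI ≥ 0.8).

## Known limitations

* Only 1-D marginals and 2-D joints: the score is strictly pairwise, and
  indirect dependencies (co-regulated targets) score as dependent just as
  direct ones do — it is a dependency measure, not a full network
  inference procedure.
* BIC's n·ln n penalty assumes i.i.d. conditions; strongly replicated or
  autocorrelated condition sets will overstate the effective sample size.
* The covariance floor biases components fitted on near-degenerate data;
  this is the intended trade-off for never failing on duplicate profiles.
* Equal-width MI binning is sensitive to outliers stretching the range;
  the equal-frequency option mitigates this at the cost of comparability
  with the default.
* The EM restarts bound, not eliminate, the risk of local optima; the
  sklearn cross-check in the test suite guards the well-separated regime
  only.
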