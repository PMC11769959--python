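# Methods

## Data model and normalization

The primary input is a samples × metabolites table of non-negative
concentrations with a stage label and replicate id per sample, plus an
ordered stage sequence whose consecutive pairs define the transitions.
Loading rejects missing values by default and names the offending cell;
half-minimum imputation per metabolite is available behind an explicit
flag. Concentrations are used as given — no unit handling.

Normalization is a single global column z-scoring with the population
standard deviation (ddof = 0; ddof = 1 is a switch). It is computed once on
the full dataset; per-transition analyses re-center on their sample subset
but keep the global scaling by default (a within-pair re-standardization
mode exists). Constant columns are kept as all-zero, flagged, and can never
gain network edges; dropping them would misalign metabolite indices across
the pipeline. Writing uses `%.17g` and reading uses round-trip float
parsing, so save/load is bit-exact.

## PCA

PCA is computed by SVD of the centered matrix. Explained variances follow
the ddof = 1 convention, so they sum to the total sample variance. Each
loading column is flipped so its largest-magnitude entry is positive, which
makes output deterministic across SVD backends.

For a transition (a, b), the discriminating component is the one maximizing
|mean score(b) − mean score(a)| / pooled within-stage sd (ties → lowest
index; a component with zero pooled sd but nonzero mean difference counts
as perfect separation). It is then oriented so stage b's mean score is not
smaller than stage a's. The paper-level convention of always using the
first component is available by reading `component_index` and the full
loadings; the separation-maximizing default protects the binary-association
reading when the pair's first variance direction is replicate noise rather
than stage. Note a consequence of the deterministic sign convention:
negating the data matrix leaves loadings unchanged and negates scores, so
the orientation re-flip inverts stage assignments — which is the correct
semantics, since negation reverses which stage each metabolite is elevated
in. Swapping (a, b) negates signed scores and deltas but leaves each
metabolite associated with the same stage name.

## Graphical lasso

The estimator maximizes `log det Θ − tr(SΘ) − α‖Θ‖₁,off`. The penalty is
off-diagonal only by default (a flag penalizes the diagonal too). The
solver is blockwise coordinate descent on the working covariance W: each
row/column subproblem is an L1-regularized quadratic solved by cyclic
coordinate descent (numba-compiled inner loop with a pure-Python fallback),
with the precision matrix maintained through the partitioned-inverse
identities and warm-started across sweeps. Initialization shrinks
off-diagonals by 0.95 for positive-definite safety. Convergence is declared
when the surrogate duality gap `tr(SΘ) − p + α‖Θ‖₁,off` drops below `tol`
(default 1e-4) or after `max_iter` sweeps (default 250). On return Θ is
symmetrized and W is recomputed as its exact inverse, so `W·Θ = I` holds to
machine precision. α = 0 returns the direct inverse and requires a
nonsingular S. The per-sweep penalized log-likelihood is recorded in
`objective_history`; tests assert it is non-decreasing.

Correctness is established two independent ways: closed forms (the p = 2
soft-thresholding solution; the diagonal solution whenever α dominates all
off-diagonal covariances), and a proximal-gradient oracle implemented in
the test suite with a different algorithm, matched entrywise on a battery
of seeded problems (observed agreement ~1e-7, asserted at 1e-3).
scikit-learn's GraphicalLasso is used as a further cross-check in one test
but never inside the package.

## Penalty selection

The full-dataset penalty is chosen by K-fold cross-validation (default 5
folds from a seeded permutation): fit on the training covariance, score
`log det Θ − tr(S_test Θ)` on the held-out covariance, refine a log-spaced
grid (4 rounds × 4 points, from α_max = max off-diagonal |S_ij| down to
α_max/100) around the running best. Deterministic per seed; the full
α → score table is returned for provenance. Per-transition fits use a fixed
α = 0.9 default: pair subsets of a handful of replicates per stage are too
small for stable cross-validation.

**Known limitation.** Held-out-likelihood cross-validation is a *prediction*
criterion, and it systematically selects a weaker penalty than edge-support
recovery wants. On synthetic data (p = 30, edge density 0.05, n = 500) the
CV penalty yields support-recovery F1 ≈ 0.45, while the same solver at the
best penalty in hindsight reaches F1 ≈ 0.93; scikit-learn's GraphicalLassoCV
selects essentially the same penalty and F1. The acceptance script reports
both numbers side by side (`support_recovery_f1_cv_*` vs
`support_recovery_f1_oracle_median`) rather than hiding the gap. Users who
need support recovery rather than predictive fit should increase α beyond
the CV choice or use a stability-based selector (out of scope here).

## Transition overlay

Each transition's annotated network records, for *every* metabolite
(isolated ones included): the assigned stage, the signed loading on the
selected component, the score intensity `|loading| / max |loading|` (0/0 →
0) — max-normalized per transition so panels are comparable in [0, 1] — the
signed stage-mean delta, its magnitude and sign. Transition edges come from
an independent pair-specific GLASSO fit by default; an intersection mode
restricts them to background edges. The background network is fitted once
per run and shared by all transitions (hash-equal by construction).
Non-consecutive pairs are supported behind a flag but off by default.
Exports: GraphML with node/edge attributes and layer tags, flat CSV
node/edge tables, and a provenance JSON sufficient to reproduce a run
byte-identically.

## Pattern screen

A template is a dash-separated numeric profile aligned to the stage order.
By default each sample inherits its stage's level and Pearson r is computed
across samples, so replicate variance penalizes noisy matches; a
stage-means mode correlates per-stage mean profiles instead. p-values come
from the t distribution with n − 2 df; constant metabolites are reported as
r = 0, p = 1 with a flag rather than NaN. Spearman and a Benjamini–Hochberg
q-value column are optional. Template screening is invariant to positive
affine rescaling of the template.

## Synthetic data

The generator draws n_rep samples per stage from N(μ_s, Σ) with Σ = Θ⁻¹ for
a planted sparse Θ: Erdős–Rényi support at a chosen edge density,
off-diagonal magnitudes uniform in [0.1, 0.4] with random signs, diagonal
set to absolute row sum + 0.5 (strict diagonal dominance ⇒ positive
definite for every seed). Marker shifts are specified in within-stage
sd units, scaled by each feature's marginal sd at draw time, and persist
from the transition's later stage onward (step profiles; matching the
interpretation of patterns like `1-1-1-2-2`). All randomness flows through
one seeded generator.

Defaults mirror the scale of the motivating study design: 5 ordered stages,
single-digit replicates per stage (3–8 biological replicates is typical for
NMR cell-culture metabolomics), p of a few dozen metabolites, 3σ marker
effects. What the generator does *not* emulate: non-Gaussian concentration
distributions, heteroscedastic technical noise, peak-overlap artifacts of
NMR quantification, or missing values. Passing tests therefore demonstrate
algorithmic correctness under the model's own assumptions, not robustness
to real NMR noise.

Problem sizes in the tests and the acceptance script (p ≤ 40, n ≤ 500, 10
seeds per stochastic claim) were chosen so every claim is measurable with
comfortable statistical margins while a full run stays in the seconds-to-
minutes range on a single CPU.

## Numerical choices

- Edge threshold 1e-8 on |Θ_ij| (numerical zero): coordinate descent
  produces exact zeros, so the threshold only guards round-off.
- Degenerate inputs: zero separation on every component → rejected;
  constant features → flagged, zeroed, retained; empty networks → valid,
  rendered as an empty canvas with a warning.
- Inner lasso tolerance 1e-7 on coefficient change, max 1000 passes;
  outer duality-gap tolerance 1e-4, 250 sweeps.
- Label equivariance under metabolite permutation is exact only at the
  optimum; at the default gap tolerance the sweep order leaves O(1e-5)
  differences, so comparisons across column orders should tighten `tol`.

## Visualization

Node layout is a seeded force-directed (spring) layout computed once on the
background graph and reused across all transitions of a run, so panels are
directly comparable. Solid/dashed encodes the partial-correlation sign,
line width its magnitude, node size the delta magnitude mapped affinely
into a configurable range, node color the assigned stage with grey for
background-only elements. Every rendered value is co-written to CSV
(coordinates, edge styles, clustered heatmap matrix with leaf order, PCA
scores); acceptance binds to tables, never pixels. The heatmap clusters
metabolites by average-linkage hierarchical clustering on Euclidean
distances with samples grouped in stage order.
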