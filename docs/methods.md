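# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Connectome construction

Frame censoring marks a frame bad when FD > `fd_thresh` (default 0.3 mm)
or DVARS > `dvars_thresh` (default 50), together with `n_before = 1`
frame before and `n_after = 2` frames after, clipped at run boundaries.
Surviving good segments shorter than `min_segment = 5` frames are also
censored. A run is excluded when more than half its frames are censored
or its maximum FD exceeds 5 mm; a participant is excluded from a brain
state with less than 4 minutes of usable data summed over surviving
runs. FC is the Pearson correlation over usable frames only (censored
rows simply do not enter the estimator — no interpolation), and runs
are combined as `tanh(mean(atanh(r)))` with |r| clipped to `1 − 1e−7`
so perfect correlations keep finite z-scores.

Edges are the strict lower triangle in row-major order — edge (i, j),
i > j, sits at index `i(i−1)/2 + j` — and the diagonal never enters any
vector, kernel, feature, or block average. Network-block summaries
average over unique region pairs: a G-group labeling yields
`G(G+1)/2` unique blocks (171 at the full scale of 18 groups);
within-group blocks use unordered pairs without double counting, and a
singleton group's within-block value is flagged missing rather than
invented.

## Prediction

Kernel ridge regression with a correlation kernel: similarity between
two participants is the Pearson correlation of their edge vectors.
Behavior is mean-centered on the training set before the dual solve
(`α = (K + λI)⁻¹ (y − ȳ)`); the training mean is the intercept. The
kernel receives a jitter of `1e−8 · trace(K)/n` before factorization;
indefiniteness beyond that tolerance is an error, not a repair.

Cross-validation is leave-`k_test`-site-clusters-out. Sites are merged
greedily into `n_clusters = 10` clusters — sites sorted by descending
size, each assigned to the currently smallest cluster, names breaking
ties — which satisfies the constraints (no split sites, balanced
clusters) deterministically. All `C(10, 3) = 120` combinations form the
outer folds. Within each fold's 7 training clusters, λ (13 log-spaced
values, `1e−4 … 1e4`) is selected by leave-one-cluster-out CV
maximizing the Fisher-averaged validation correlation; ties resolve
toward larger λ (more regularization), then toward lower weight-vector
entropy. Head-motion confounds (mean FD and DVARS, plus optionally age
and sex) are regressed from behavior per fold with coefficients
estimated on the training clusters and applied to the test clusters.

The multikernel model is a convex combination `K = Σ_s w_s K_s` with
*w* on a simplex grid (default step 0.25; 0.5 in the heavier
simulation experiments), searched jointly with λ in the same inner
loop. This formulation reduces exactly to single-kernel models at the
simplex vertices and leaves the dual solve unchanged; per-state
penalties λ_s are a possible alternative formulation that we did not
adopt. The Mean-FC control Fisher-averages FC across the four states
per participant before the single-kernel path. Linear ridge is solved
in the dual on train-standardized edges (the linear kernel), with
primal weights recovered as `X'α` for weight-based comparisons.

Accuracy per fold is the Pearson correlation between observed
(residualized) and predicted behavior, plus a coefficient of
determination whose baseline is the training-set mean of the
residualized behavior — an honest out-of-sample reference; the
test-set mean would leak. Correlations aggregate across folds or
measures by Fisher-z averaging. Accuracies are undefined (recorded
missing, never zero-filled) for constant vectors or fewer than three
test points.

## Interpretation

Haufe inversion computes, per fold, the sample covariance (ddof = 1)
between each edge's FC across training participants and the model's
predictions on those same participants — one feature matrix per brain
state per behavior, averaged across folds. No normalization by the
prediction variance is applied; the covariance itself carries the sign
semantics (positive feature: higher FC predicts higher behavior).
Suppressor inputs — helpful for prediction only by cancelling noise —
receive zero covariance, which the test suite checks analytically.

Feature similarity between behaviors is the Pearson correlation of
edge features concatenated across states. Behaviors are clustered with
UPGMA (average linkage) on distance `1 − similarity`; scipy's
deterministic implementation handles merge ties. Sign consistency
between two block matrices is the fraction of unique blocks with equal
sign; exact zeros agree only with zeros (a measure-zero event in
floats, handled conservatively), and missing blocks are excluded
pairwise. The analytic chance level for sign agreement with pooled
positive fraction p is `p² + (1 − p)²`.

Block-level significance uses a permutation test: behavior is shuffled
across participants *within each site* (sites are the exchangeable
blocks once site offsets exist), the fold models are refit on the
permuted behavior reusing each fold's already-selected hyperparameters,
re-inverted, block-averaged, and compared two-tailed by absolute value
with the add-one estimator `p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`.
Re-searching hyperparameters per permutation is statistically cleaner
but ~200× more expensive; under the null the hyperparameters are
ancillary, and the refits are fully vectorized across permutations via
a cached Cholesky factorization per fold. Conjunction maps keep a
block only if it is significant in all four states with the same sign
everywhere, carrying the cross-state mean; region maps sum positive and
(absolute) negative feature values across each region's row with
percentile ranks across regions.

## Transfer

Model transfer predicts a target behavior as the arithmetic mean of
donor models' test-fold predictions, z-scored within fold first
(behaviors live on different scales; correlation-based accuracy is
scale-free, so this only equalizes donor influence). Feature transfer
averages donor predictive features across donors and states, selects
the top 10% of edges by absolute feature value (boundary ties break
toward the lower edge index), and scores each participant as mean FC
over positive-feature edges minus mean FC over negative-feature edges,
with participant FC Fisher-averaged across the four states. Both
routes use only training-fold information; a bit-equality test corrupts
all test-fold FC rows and verifies nothing changes.

## Inference

Above-chance accuracy: within-site permutation of behavior, the entire
nested CV repeated per shuffle (one-tailed, add-one estimator).
Model comparison: the corrected resampled t-test on paired per-fold
accuracy differences, `t = mean(d) / sqrt((1/K + n_test/n_train)
var(d))` with df = K − 1, two-tailed; the test/train ratio uses average
per-fold participant counts (3/7 of the cohort under equal clusters).
Fold accuracies share training data, so the uncorrected t is
anti-conservative; the corrected version is validated in simulation to
reject at or below the nominal level under an i.i.d. null. Its
Gaussianity assumption is checked with a one-sample KS test on the
standardized differences; because mean and SD are estimated from the
same data, this check is conservative (the Lilliefors effect) — it
under-rejects normal data, which is the safe direction for a
validation check. FDR control is Benjamini–Hochberg step-up per test
family, returning both the rejection mask and the realized p-threshold.

## Synthetic cohort design

The generator works in Fisher-z space — signals add there and pass
through `tanh` — so FC entries stay in (−1, 1) by construction. For
participant p, state s, edge e:

    z = μ_e + u_pe + Σ_d L_pd β_de · c_ds + Σ_m η_pm γ_me · c_ds
        + 0.05 · fd̃_p + ε_pse,

with baseline μ_e ~ N(0.15, 0.2²), stable individual profile
u_pe ~ N(0, 0.25²) plus stable noise N(0, 0.1²), domain latent factors
L_pd ~ N(0, 1) loading with effects β ~ N(0, 0.15²) on a planted core
of `edge_signal_density = 5%` of edges per domain (cores disjoint
across domains), measure-specific factors η on measure-specific edges,
optional per-state signal multipliers c_ds (all 1 by default), a
uniform motion shift, and state modulation ε ~ N(0, 0.05²). Behaviors
are `y = L·√w + η·√(1−w) + confound + site offset + noise` with
within-domain overlap w = 0.8, site offsets N(0, 0.25²), noise
N(0, 0.75²), and a motion term calibrated to a target FD–behavior
correlation of 0.2. Sites are balanced; mean FD is lognormal around
0.15 mm with DVARS tracking it.

These magnitudes were chosen once for testability — a dominant
individual FC component with much smaller state modulation, planted
signal strong enough that the prediction, interpretation and transfer
machinery must recover it cleanly, and realistic confound/site
structure — not to mimic empirical effect sizes, which are far weaker
(observed-vs-predicted correlations in the 0.1–0.5 range in real
cohorts versus ~0.7 here). The generator omits hemodynamics,
parcellation geometry, family/heritability structure, scanner
differences, and non-Gaussian behavior distributions; passing tests
therefore demonstrate the correctness and calibration of the machinery,
not expected real-data effect sizes.

## Problem sizes

The default experimental scale is 400 participants, 60 regions
(1770 edges), 6 network groups, 10 sites mapping 1:1 onto 10
site-clusters, and 4 states — full nested CV over all 120 folds runs in
seconds per behavior for single-kernel models. Simulation experiments
(20-seed structure recovery, 200-repetition permutation calibration)
thin the 120 folds evenly to 6–20 and use the 0.5 simplex step; fold
thinning changes only the precision of the fold average, not the
procedure. The permutation engine shares per-fold eigendecompositions
across permutations and evaluates all shuffles of a batch with matrix
products, which is what makes 200 × 100 full CV evaluations affordable.

## Known limitations

* The multikernel objective is the convex-combination surrogate
  described above; richer formulations (per-kernel penalties, learned
  kernel scalings) are out of scope.
* Confounds are regressed from behavior only, never from FC.
* Block-permutation refits reuse selected hyperparameters (see above).
* `generate_timeseries_run` draws i.i.d. Gaussian frames from a
  nearest-PSD-repaired target correlation — no autocorrelation, so
  effective degrees of freedom are optimistic relative to real fMRI.
* The stratified matching utility reports infeasibility rather than
  adaptively re-binning; choosing bins is the caller's job.
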