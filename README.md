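# connpredict

Behavioral prediction from multi-state functional connectomes, with
interpretable predictive-feature maps.

## What this package does

In large developmental neuroimaging cohorts, a child's functional
connectivity (FC) — the matrix of Pearson correlations between
region-averaged fMRI time series — carries individual-specific signal that
predicts cognition, personality and mental-health measures. This package
implements that full analysis chain for researchers who want to run it,
stress-test it, or teach it without access-restricted data:

1. **Connectome construction** — motion censoring of frame-level time
   series (FD > 0.3 mm or DVARS > 50, spread one frame back and two
   forward; surviving segments shorter than 5 frames dropped; runs with
   more than half their frames censored or max FD > 5 mm removed;
   participants need ≥ 4 min of usable data per brain state), Pearson FC
   over usable frames, Fisher r-to-z run averaging.
2. **Prediction** — kernel ridge regression (KRR) with a correlation
   kernel under leave-3-site-clusters-out nested cross-validation.
   Sites are merged into 10 site-clusters and never split across the
   train/test boundary; head motion (mean FD, DVARS) is regressed from
   behavior with train-fold coefficients only. Model families:
   per-state kernels (rest, MID, SST, N-back), a multikernel convex
   combination of all four, a Mean-FC control, and linear ridge.
3. **Interpretation** — Haufe inversion of fitted models into
   edge-level predictive-feature matrices (covariance between each
   edge's FC and the model's training predictions), network-block
   summaries, sign-consistency proportions against an analytic chance
   level, UPGMA clustering of behaviors by feature similarity,
   within-site permutation tests per block, cross-state conjunctions,
   and region-level predictability maps.
4. **Generalization** — cross-behavior transfer of fitted models
   (averaged donor predictions) and of top-10% predictive-feature edges
   (aggregate FC score), always selecting on training folds only.
5. **Inference** — within-site permutation nulls for accuracy, the
   corrected resampled t-test for model comparisons (variance inflated
   by `1/K + n_test/n_train`), a KS Gaussianity check, and
   Benjamini–Hochberg FDR.

Because the motivating cohort data are access-restricted, the package
ships a first-class **synthetic cohort generator** with planted ground
truth: multi-state FC sharing a dominant individual component, behaviors
organized into domains driven by latent factors that load on planted
edge sets, a motion confound touching both FC and behavior, and site
structure with additive offsets. Every analysis above is validated by
recovering that ground truth.

## The model

For a test participant *t* with connectome FC_t, KRR predicts

    ŷ_t = Σ_i  α_i · Similarity(FC_i, FC_t) + ȳ_train,

where the similarity is the Pearson correlation between vectorized FC
matrices, and the dual coefficients solve
`α = (K + λI)⁻¹ (y − ȳ)` on the training kernel. The multikernel
variant replaces K with `Σ_s w_s K_s` over brain states, with the
simplex weights *w* and λ chosen by leave-one-cluster-out inner CV.
Fitted models are inverted into predictive features per edge *j* and
state *s*:

    a_{s,j} = cov( x_{s,j}, ŷ )   over training participants,

which, unlike raw weights, assigns zero to suppressor inputs.

## Worked example

```python
from connpredict.synthetic import CohortConfig, generate_cohort
from connpredict.prediction import build_site_clusters, enumerate_folds, nested_cv
from connpredict.interpretation import haufe_invert

cfg = CohortConfig(seed=7, measures_per_domain={"cognition": 3,
                                                "personality": 3,
                                                "mental_health": 3})
conn, behavior, meta, truth = generate_cohort(cfg)       # 400 participants
clusters, _ = build_site_clusters(meta["site"], n_clusters=10, min_size=1)
folds = enumerate_folds(10, 3)                           # 120 folds
confounds = meta[["mean_fd", "mean_dvars"]].to_numpy()

res = nested_cv(conn, behavior.y("cognition_01"), clusters, folds[:12],
                family="multikernel", weight_step=0.5,
                confounds=confounds, return_models=True)
print(f"mean r = {res.mean_accuracy():.3f}")             # mean r = 0.710
features = haufe_invert(conn, res, "cognition_01")       # 4 feature matrices
```

The printed accuracy is the Fisher-z average across folds of the
correlation between observed (motion-residualized) and predicted
behavior on held-out site clusters. On this synthetic cohort the
planted brain–behavior signal is strong by design, so r ≈ 0.7; a
pure-noise behavior run through the identical pipeline lands near 0
(`analysis/03_predict_behaviors.py` prints r = 0.019, permutation
p = 0.38, while the three signal behaviors all hit the p = 0.01 floor
of a 99-permutation within-site null).

## Analysis scripts

Numbered drivers under `analysis/` reproduce each stage end to end and
write tables to `results/`:

| script | what it shows |
|---|---|
| `01_simulate_cohort.py` | generator regime checks (state stability, domain structure, motion confound) |
| `02_qc_fc.py` | censoring/QC accounting and FC recovery from simulated time series |
| `03_predict_behaviors.py` | model-family comparison, permutation and corrected-t tests |
| `04_interpret_features.py` | feature similarity, UPGMA clusters, block significance, sign consistency, region maps |
| `05_transfer_across_behaviors.py` | model- and feature-transfer by donor domain |
| `06_matched_subsample.py` | stratified demographic matching control |

A `connpredict` CLI wraps the same steps (`synthesize`, `predict`,
`match`, `run-all`); see `connpredict --help`.

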