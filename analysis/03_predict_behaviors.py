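#!/usr/bin/env python
"""Compare prediction model families under site-clustered nested CV.

Fits each single-state kernel model (rest, MID, SST, N-back), the
multikernel combination, the Mean-FC control and linear ridge for three
behaviors (one per domain) on the default cohort, tests each against a
within-site permutation null, compares families pairwise with the
corrected resampled t-test (with the KS Gaussianity check), and applies
FDR. Writes accuracy, permutation and comparison tables.
"""

import itertools
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from connpredict.prediction import (
    BatchedNestedCV,
    build_site_clusters,
    correlation_kernel,
    enumerate_folds,
    nested_cv,
)
from connpredict.stats import (
    corrected_resampled_ttest,
    fdr_bh,
    gaussianity_check,
    permutation_null_accuracy,
)
from connpredict.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
MEASURES = ["cognition_01", "personality_01", "mental_health_01"]


def main(seed: int = 7) -> None:
    cfg = CohortConfig(
        seed=seed,
        measures_per_domain={"cognition": 3, "personality": 3, "mental_health": 3},
    )
    conn, behavior, meta, truth = generate_cohort(cfg)
    clusters, _ = build_site_clusters(meta["site"], n_clusters=10, min_size=1)
    folds = [enumerate_folds(10, 3)[i] for i in range(0, 120, 10)]  # 12 folds
    conf = meta[["mean_fd", "mean_dvars"]].to_numpy()
    sites = meta["site"].to_numpy()

    families = [("single_kernel", s) for s in conn.states] + [
        ("multikernel", None), ("mean_fc", None), ("linear_ridge", "rest"),
    ]
    acc_rows, fold_r = [], {}
    for measure in MEASURES:
        y = behavior.y(measure)
        for family, state in families:
            res = nested_cv(conn, y, clusters, folds, family=family, state=state,
                            weight_step=0.5, confounds=conf)
            name = state if family == "single_kernel" else family
            fold_r[(measure, name)] = np.asarray(res.r)
            acc_rows.append(dict(measure=measure, model=name,
                                 mean_r=res.mean_accuracy(), mean_cod=res.mean_cod()))
            print(f"{measure:18s} {name:13s} r={res.mean_accuracy():.3f} "
                  f"COD={res.mean_cod():.3f}")
    acc = pd.DataFrame(acc_rows)

    # permutation tests against chance (rest kernel pipeline)
    K = correlation_kernel(conn.state_edges("rest"))
    engine = BatchedNestedCV(K, clusters, folds, confounds=conf, cache=True)
    perm_rows = []
    for measure in MEASURES + ["noise"]:
        y = (behavior.y(measure) if measure != "noise"
             else np.random.default_rng(seed).standard_normal(conn.n_participants))
        p, obs, _ = permutation_null_accuracy(engine.evaluate, y, sites,
                                              n_perm=99, seed=seed + 5)
        perm_rows.append(dict(measure=measure, observed_r=obs, p=p))
    perm = pd.DataFrame(perm_rows)
    mask, thresh = fdr_bh(perm["p"].to_numpy(), q=0.05)
    perm["significant"] = mask

    # pairwise family comparisons on paired fold differences
    n_test = np.mean([sum(np.isin(clusters, f.test_clusters)) for f in folds])
    n_train = conn.n_participants - n_test
    comp_rows = []
    models = ["rest", "N-back", "multikernel", "mean_fc"]
    for measure in MEASURES:
        for a, b in itertools.combinations(models, 2):
            d = fold_r[(measure, a)] - fold_r[(measure, b)]
            t, p = corrected_resampled_ttest(d, n_test=n_test, n_train=n_train)
            ks_stat, ks_p = gaussianity_check(d)
            comp_rows.append(dict(measure=measure, model_a=a, model_b=b,
                                  mean_diff=d.mean(), t=t, p=p, ks_p=ks_p))
    comp = pd.DataFrame(comp_rows)
    comp["significant"], _ = fdr_bh(comp["p"].to_numpy(), q=0.05)

    OUT.mkdir(exist_ok=True)
    acc.to_csv(OUT / "model_accuracy.csv", index=False)
    perm.to_csv(OUT / "accuracy_permutation.csv", index=False)
    comp.to_csv(OUT / "model_comparison.csv", index=False)
    print("\npermutation tests:")
    print(perm.to_string(index=False))
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
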