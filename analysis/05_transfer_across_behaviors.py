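#!/usr/bin/env python
"""Cross-behavior generalization of models and of top predictive features.

For each target behavior, donors from the same domain and from the
other domains transfer either (a) their models' averaged test-fold
predictions, or (b) an aggregate-FC predictor built from the top 10% of
their averaged predictive-feature edges. Writes a long-format table of
per-fold transfer accuracies by donor domain.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from connpredict.generalization import (
    cross_behavior_feature_predict,
    cross_behavior_model_predict,
    donor_features_per_fold,
)
from connpredict.interpretation import per_fold_haufe
from connpredict.prediction import (
    aggregate_accuracy,
    build_site_clusters,
    enumerate_folds,
    nested_cv,
)
from connpredict.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 7) -> None:
    cfg = CohortConfig(
        seed=seed,
        measures_per_domain={"cognition": 3, "personality": 3, "mental_health": 3},
    )
    conn, behavior, meta, truth = generate_cohort(cfg)
    clusters, _ = build_site_clusters(meta["site"], n_clusters=10, min_size=1)
    folds = [enumerate_folds(10, 3)[i] for i in range(0, 120, 20)]
    conf = meta[["mean_fd", "mean_dvars"]].to_numpy()

    fits = {
        m: nested_cv(conn, behavior.y(m), clusters, folds, family="multikernel",
                     weight_step=0.5, confounds=conf, return_models=True)
        for m in behavior.measures
    }
    haufe_cache = {m: per_fold_haufe(conn, fits[m]) for m in behavior.measures}

    rows = []
    domains = sorted({behavior.domain_of(m) for m in behavior.measures})
    for target in behavior.measures:
        t_dom = behavior.domain_of(target)
        for donor_dom in domains:
            donors = [m for m in behavior.measures_in(donor_dom) if m != target]
            if not donors:
                continue
            rs_model = cross_behavior_model_predict(
                fits[target], [fits[m] for m in donors]
            )
            fold_feats = donor_features_per_fold([haufe_cache[m] for m in donors])
            rs_feat = cross_behavior_feature_predict(
                fits[target], fold_feats, conn, top_frac=0.10
            )
            for mode, rs in [("model", rs_model), ("feature", rs_feat)]:
                for fold, r in zip(fits[target].folds, rs):
                    rows.append(
                        dict(target=target, donor_domain=donor_dom,
                             same_domain=donor_dom == t_dom, mode=mode,
                             fold=fold.fold_id, r=r)
                    )

    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "transfer.csv", index=False)
    summary = (
        df.groupby(["mode", "same_domain"])["r"]
        .apply(aggregate_accuracy)
        .rename("fisher_mean_r")
        .reset_index()
    )
    summary.to_csv(OUT / "transfer_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
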