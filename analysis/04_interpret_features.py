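#!/usr/bin/env python
"""Invert fitted models into predictive features and map their structure.

Multikernel models for all nine behaviors are Haufe-inverted into
edge-level predictive-feature matrices per brain state. The script then
computes the behavior x behavior feature-similarity matrix and its
UPGMA clustering, network-block averages with within-site permutation
p-values, sign-consistency proportions against the analytic chance
level, cross-state conjunction maps, and region-level predictability
sums. All outputs are long-format CSVs.
"""

import itertools
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from connpredict.connectome import NetworkLabeling, block_average, block_upper_values
from connpredict.interpretation import (
    block_significance,
    cluster_behaviors,
    conjunction_across_states,
    consistency_chance_level,
    domain_average_features,
    haufe_invert,
    region_predictability,
    sign_consistency,
    similarity_matrix,
)
from connpredict.prediction import build_site_clusters, enumerate_folds, nested_cv
from connpredict.stats import fdr_bh
from connpredict.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 7) -> None:
    cfg = CohortConfig(
        seed=seed,
        measures_per_domain={"cognition": 3, "personality": 3, "mental_health": 3},
    )
    conn, behavior, meta, truth = generate_cohort(cfg)
    clusters, _ = build_site_clusters(meta["site"], n_clusters=10, min_size=1)
    folds = [enumerate_folds(10, 3)[i] for i in range(0, 120, 20)]  # 6 folds
    conf = meta[["mean_fd", "mean_dvars"]].to_numpy()
    labels = NetworkLabeling(
        np.repeat([f"net{g:02d}" for g in range(cfg.n_networks)],
                  cfg.n_regions // cfg.n_networks)
    )

    fits, feats = {}, {}
    for m in behavior.measures:
        fits[m] = nested_cv(conn, behavior.y(m), clusters, folds,
                            family="multikernel", weight_step=0.5,
                            confounds=conf, return_models=True)
        feats[m] = haufe_invert(conn, fits[m], m)
        print(f"fit+invert {m}: r={fits[m].mean_accuracy():.3f}")

    measures = behavior.measures
    sim = similarity_matrix([feats[m] for m in measures])
    pd.DataFrame(sim, index=measures, columns=measures).to_csv(
        OUT / "feature_similarity.csv"
    )
    _, flat = cluster_behaviors(sim, k=3)
    pd.DataFrame({"measure": measures, "cluster": flat}).to_csv(
        OUT / "behavior_clusters.csv", index=False
    )

    # sign consistency between behavior pairs at the block level
    blocks = {
        m: {s: block_average(feats[m].matrix(s), labels) for s in conn.states}
        for m in measures
    }
    pooled = np.concatenate(
        [block_upper_values(blocks[m][s]) for m in measures for s in conn.states]
    )
    chance = consistency_chance_level(pooled)
    cons_rows = []
    for a, b in itertools.combinations(measures, 2):
        prop = np.mean(
            [sign_consistency(blocks[a][s], blocks[b][s]) for s in conn.states]
        )
        cons_rows.append(
            dict(measure_a=a, measure_b=b,
                 same_domain=behavior.domain_of(a) == behavior.domain_of(b),
                 consistency=prop, chance_level=chance)
        )
    cons = pd.DataFrame(cons_rows)
    cons.to_csv(OUT / "sign_consistency.csv", index=False)
    print(f"\nchance level: {100 * chance:.2f}%")
    print(cons.groupby("same_domain")["consistency"].mean())

    # block permutation tests for one behavior per domain + conjunction maps
    block_rows, region_rows = [], []
    for m in ["cognition_01", "personality_01", "mental_health_01"]:
        sig_out = block_significance(conn, behavior.y(m), fits[m], labels,
                                     meta["site"].to_numpy(), confounds=conf,
                                     n_perm=199, seed=seed)
        pmats = {s: sig_out[s][1] for s in conn.states}
        iu = np.triu_indices(labels.n_groups)
        allp = np.concatenate([pmats[s][iu] for s in conn.states])
        _, thresh = fdr_bh(allp, q=0.05)
        masks = {
            s: (pmats[s] <= thresh) if np.isfinite(thresh)
            else np.zeros_like(pmats[s], bool)
            for s in conn.states
        }
        for s in conn.states:
            obs, pv = sig_out[s]
            for a, b in zip(*iu):
                block_rows.append(
                    dict(measure=m, state=s, group_a=labels.groups[a],
                         group_b=labels.groups[b], value=obs[a, b], p=pv[a, b],
                         significant=bool(masks[s][a, b]))
                )
        conj = conjunction_across_states({s: sig_out[s][0] for s in conn.states}, masks)
        region_feats = domain_average_features([feats[m]]).matrix(conn.states[0])
        maps = region_predictability(region_feats)
        for r in range(cfg.n_regions):
            region_rows.append(
                dict(measure=m, region=r, positive_sum=maps["positive"][r],
                     negative_sum=maps["negative"][r],
                     positive_pct=maps["positive_pct"][r],
                     negative_pct=maps["negative_pct"][r],
                     n_conjunction_blocks=int((conj != 0).sum() // 2))
            )
    pd.DataFrame(block_rows).to_csv(OUT / "block_significance.csv", index=False)
    pd.DataFrame(region_rows).to_csv(OUT / "region_predictability.csv", index=False)
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
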