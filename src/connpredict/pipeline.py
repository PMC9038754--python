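"""End-to-end orchestration: synthesize -> predict -> interpret -> transfer -> stats.

Driven by a nested config dict (YAML-friendly). Each stage writes
long-format CSVs under the output directory and appends to a run
manifest; a stage failure halts the run with the manifest recording the
stages completed so far.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import interpretation as interp
from . import generalization as gen
from . import stats as st
from .connectome import NetworkLabeling, block_average
from .containers import align_cohort
from .io import RunManifest, write_cohort
from .prediction import (
    BatchedNestedCV,
    build_site_clusters,
    correlation_kernel,
    enumerate_folds,
    nested_cv,
)
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("connpredict")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},
    "clusters": {"n_clusters": 10, "min_size": 150},
    "predict": {
        "k_test": 3,
        "families": ["single_kernel", "multikernel", "mean_fc"],
        "states": None,  # None = all states for single_kernel
        "measures": None,  # None = all measures
        "weight_step": 0.25,
        "max_folds": None,  # optionally subsample folds evenly
    },
    "interpret": {"n_perm": 200, "alpha_q": 0.05},
    "transfer": {"top_frac": 0.10},
    "stats": {"n_perm": 99},
    "write_cohort": False,
}


def _merge_config(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if key not in out:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(out[key], dict):
            for k2, v2 in val.items():
                if k2 not in out[key] and key != "cohort":
                    raise KeyError(f"unknown config key: {key}.{k2}")
                out[key][k2] = v2
        else:
            out[key] = val
    return out


def _default_labels(n_regions: int, n_networks: int) -> NetworkLabeling:
    """Contiguous equal-size network assignment for synthetic cohorts."""
    base = np.array_split(np.arange(n_regions), n_networks)
    labels = np.empty(n_regions, dtype=object)
    for g, idx in enumerate(base):
        labels[idx] = f"net{g:02d}"
    return NetworkLabeling(labels)


def _pick_folds(folds, max_folds):
    if max_folds is None or max_folds >= len(folds):
        return folds
    sel = np.linspace(0, len(folds) - 1, max_folds).round().astype(int)
    return [folds[i] for i in np.unique(sel)]


def run_pipeline(config: dict, outdir) -> RunManifest:
    cfg = _merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, cfg["seed"])

    try:
        # --- synthesize -------------------------------------------------
        manifest.start("synthesize")
        cohort_cfg = CohortConfig(seed=cfg["seed"], **cfg["cohort"])
        connectomes, behavior, meta, truth = generate_cohort(cohort_cfg)
        connectomes, behavior, meta, n_dropped = align_cohort(connectomes, behavior, meta)
        labels = _default_labels(cohort_cfg.n_regions, cohort_cfg.n_networks)
        if cfg["write_cohort"]:
            write_cohort(out / "cohort", connectomes, behavior, meta, truth)
        manifest.finish("synthesize", n_participants=len(meta), n_dropped=n_dropped)

        # --- folds ------------------------------------------------------
        clusters, site_map = build_site_clusters(
            meta["site"], n_clusters=cfg["clusters"]["n_clusters"],
            min_size=cfg["clusters"]["min_size"],
        )
        meta = meta.assign(site_cluster=clusters)
        folds = enumerate_folds(cfg["clusters"]["n_clusters"], cfg["predict"]["k_test"])
        folds = _pick_folds(folds, cfg["predict"]["max_folds"])
        confounds = meta[["mean_fd", "mean_dvars"]].to_numpy()

        # --- predict ----------------------------------------------------
        manifest.start("predict")
        measures = cfg["predict"]["measures"] or behavior.measures
        rows, results = [], {}
        for measure in measures:
            y = behavior.y(measure)
            for family in cfg["predict"]["families"]:
                states = (
                    cfg["predict"]["states"] or connectomes.states
                    if family == "single_kernel"
                    else [None]
                )
                for state in states:
                    res = nested_cv(
                        connectomes, y, clusters, folds, family=family, state=state,
                        weight_step=cfg["predict"]["weight_step"],
                        confounds=confounds, return_models=True,
                    )
                    key = (measure, family, state or "all")
                    results[key] = res
                    for i, fold in enumerate(res.folds):
                        rows.append(
                            dict(measure=measure, family=family, state=state or "all",
                                 fold=fold.fold_id, r=res.r[i], cod=res.cod[i],
                                 lam=res.selected_lambda[i])
                        )
                    log.info("predict %s %s %s: r=%.3f", measure, family, state,
                             res.mean_accuracy())
        acc = pd.DataFrame(rows)
        acc.to_csv(out / "accuracy.csv", index=False)
        manifest.finish("predict", n_models=len(results))

        # --- stats: above-chance permutation tests (multikernel) --------
        manifest.start("stats")
        stat_rows = []
        for measure in measures:
            K = correlation_kernel(connectomes.state_edges(connectomes.states[0]))
            engine = BatchedNestedCV(K, clusters, folds, confounds=confounds, cache=False)
            p, obs, _ = st.permutation_null_accuracy(
                engine.evaluate, behavior.y(measure), meta["site"].to_numpy(),
                n_perm=cfg["stats"]["n_perm"], seed=cfg["seed"] + 17,
            )
            stat_rows.append(dict(measure=measure, observed_r=obs, p=p))
        stat_df = pd.DataFrame(stat_rows)
        mask, thresh = st.fdr_bh(stat_df["p"].to_numpy(), q=cfg["interpret"]["alpha_q"])
        stat_df["significant"] = mask
        stat_df.to_csv(out / "accuracy_permutation.csv", index=False)
        manifest.finish("stats", fdr_threshold=thresh)

        # --- interpret --------------------------------------------------
        manifest.start("interpret")
        family_for_interp = (
            "multikernel" if "multikernel" in cfg["predict"]["families"]
            else cfg["predict"]["families"][0]
        )
        features = {}
        for measure in measures:
            key = (measure, family_for_interp, "all")
            if key not in results:
                key = next(k for k in results if k[0] == measure)
            features[measure] = interp.haufe_invert(connectomes, results[key], measure)
        sim = interp.similarity_matrix([features[m] for m in measures])
        pd.DataFrame(sim, index=measures, columns=measures).to_csv(out / "feature_similarity.csv")
        Z, flat = interp.cluster_behaviors(sim, k=min(3, len(measures)))
        pd.DataFrame({"measure": measures, "cluster": flat}).to_csv(
            out / "behavior_clusters.csv", index=False
        )
        block_rows = []
        for measure in measures:
            for s in connectomes.states:
                blocks = block_average(features[measure].matrix(s), labels)
                iu = np.triu_indices(labels.n_groups)
                for a, b, v in zip(iu[0], iu[1], blocks[iu]):
                    block_rows.append(
                        dict(measure=measure, state=s, group_a=labels.groups[a],
                             group_b=labels.groups[b], value=v)
                    )
        pd.DataFrame(block_rows).to_csv(out / "block_features.csv", index=False)
        manifest.finish("interpret")

        # --- transfer ---------------------------------------------------
        manifest.start("transfer")
        trans_rows = []
        by_domain: dict = {}
        for m in measures:
            by_domain.setdefault(behavior.domain_of(m), []).append(m)
        for target in measures:
            t_dom = behavior.domain_of(target)
            t_key = (target, family_for_interp, "all")
            if t_key not in results:
                t_key = next(k for k in results if k[0] == target)
            t_res = results[t_key]
            for donor_dom, members in by_domain.items():
                donors = [m for m in members if m != target]
                if not donors:
                    continue
                d_res = []
                for m in donors:
                    k = (m, family_for_interp, "all")
                    if k not in results:
                        k = next(kk for kk in results if kk[0] == m)
                    d_res.append(results[k])
                rs = gen.cross_behavior_model_predict(t_res, d_res)
                for fold, r in zip(t_res.folds, rs):
                    trans_rows.append(
                        dict(target=target, donor_domain=donor_dom,
                             same_domain=donor_dom == t_dom, mode="model",
                             fold=fold.fold_id, r=r)
                    )
        pd.DataFrame(trans_rows).to_csv(out / "transfer.csv", index=False)
        manifest.finish("transfer")
    except Exception:
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
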