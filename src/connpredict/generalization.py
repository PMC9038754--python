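"""Cross-behavior transfer of fitted models and of top predictive features.

Two transfer routes, both strictly leakage-free (everything that enters
a test-fold prediction is derived from that fold's training clusters):

* *Model transfer* — a target behavior is predicted by averaging the
  test-fold predictions of the models fitted to the other (donor)
  behaviors; donors never include the target.
* *Feature transfer* — donor predictive-feature matrices are averaged
  across donors and brain states; the top fraction of edges by absolute
  feature value is selected, and each participant's predictor is the
  mean FC over selected positive-feature edges minus the mean FC over
  selected negative-feature edges. Accuracy is a Pearson correlation,
  so the aggregate's scale is irrelevant.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ConnectomeSet
from .prediction import PredictionResult, accuracy_metrics

__all__ = [
    "cross_behavior_model_predict",
    "cross_behavior_feature_predict",
    "aggregate_fc_predictor",
    "select_top_edges",
]


def _check_same_folds(target: PredictionResult, donors: list) -> None:
    t_ids = [f.fold_id for f in target.folds]
    for d in donors:
        if [f.fold_id for f in d.folds] != t_ids:
            raise ValueError("donor and target must share identical fold splits")


def cross_behavior_model_predict(
    target: PredictionResult,
    donors: list,
) -> list:
    """Predict the target behavior as the average of donor-model
    predictions, per fold.

    Donor predictions are z-scored within each fold before averaging
    (behaviors live on different scales); accuracy is the Pearson r with
    the target's residualized observed values.

    Returns a list of per-fold correlations.
    """
    if not donors:
        raise ValueError("empty donor set")
    if any(d is target for d in donors):
        raise ValueError("donor set must not include the target behavior")
    _check_same_folds(target, donors)
    rs = []
    for k in range(len(target.folds)):
        preds = []
        for d in donors:
            p = np.asarray(d.predicted[k], dtype=float)
            sd = p.std()
            preds.append((p - p.mean()) / sd if sd > 0 else p - p.mean())
        combined = np.mean(preds, axis=0)
        train_mean = float(np.mean(target.observed[k]))
        r, _ = accuracy_metrics(target.observed[k], combined, train_mean)
        rs.append(r)
    return rs


def select_top_edges(features: np.ndarray, top_frac: float = 0.10):
    """Indices of the ``top_frac`` edges by |feature|, split by feature
    sign. Boundary ties break toward the lower edge index."""
    f = np.asarray(features, dtype=float)
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    n_top = max(1, int(round(top_frac * f.size)))
    order = np.lexsort((np.arange(f.size), -np.abs(f)))
    top = order[:n_top]
    pos = top[f[top] > 0]
    neg = top[f[top] < 0]
    return np.sort(pos), np.sort(neg)


def aggregate_fc_predictor(
    edge_fc: np.ndarray,
    features: np.ndarray,
    top_frac: float = 0.10,
) -> np.ndarray:
    """Per-participant aggregate FC score from donor features.

    ``edge_fc`` is (n_participants, E); the score is the mean FC over
    selected positive-feature edges minus the mean over selected
    negative-feature edges. If every selected edge shares one sign, the
    absent sign contributes 0 (with a warning).
    """
    pos, neg = select_top_edges(features, top_frac)
    if pos.size == 0 or neg.size == 0:
        warnings.warn("all selected edges share one sign; the other term is 0", stacklevel=2)
    pos_term = edge_fc[:, pos].mean(axis=1) if pos.size else 0.0
    neg_term = edge_fc[:, neg].mean(axis=1) if neg.size else 0.0
    return pos_term - neg_term


def cross_behavior_feature_predict(
    target: PredictionResult,
    donor_fold_features: list,
    connectomes: ConnectomeSet,
    top_frac: float = 0.10,
) -> list:
    """Feature-transfer accuracy per fold.

    ``donor_fold_features`` supplies, for each fold, the donor predictive
    features already averaged across donors and across brain states
    (each an (E,) vector computed from that fold's training data only).
    The participant-level FC entering the aggregate is the Fisher-z mean
    across the four states.

    Returns a list of per-fold correlations with the target's
    residualized observed values.
    """
    if len(donor_fold_features) != len(target.folds):
        raise ValueError("need one donor feature vector per fold")
    mean_edges = connectomes.mean_state_edges()
    rs = []
    for k in range(len(target.folds)):
        feats = np.asarray(donor_fold_features[k], dtype=float)
        test_idx = target.models[k].test_idx if target.models else None
        if test_idx is None:
            raise ValueError("target result must carry fold models (return_models=True)")
        agg = aggregate_fc_predictor(mean_edges[test_idx], feats, top_frac)
        train_mean = float(np.mean(target.observed[k]))
        r, _ = accuracy_metrics(target.observed[k], agg, train_mean)
        rs.append(r)
    return rs


def donor_features_per_fold(per_fold_feature_sets: list) -> list:
    """Average per-fold Haufe features over donors and states.

    ``per_fold_feature_sets`` is a list over donors; each element is a
    list over folds of (n_states, E) arrays (see
    :func:`connpredict.interpretation.per_fold_haufe`). Returns a list
    over folds of (E,) vectors.
    """
    if not per_fold_feature_sets:
        raise ValueError("empty donor set")
    n_folds = len(per_fold_feature_sets[0])
    out = []
    for k in range(n_folds):
        stacked = np.stack([d[k] for d in per_fold_feature_sets])  # (donors, states, E)
        out.append(stacked.mean(axis=(0, 1)))
    return out
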