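"""Model interpretation: predictive-feature matrices and their statistics.

A fitted predictive model is inverted with the Haufe approach: the
predictive-feature value of an edge is the sample covariance between
that edge's FC across training participants and the model's predicted
behavior on those same participants. Unlike raw regression weights,
these features are robust to suppressor variables — an input that helps
prediction only by cancelling noise receives a feature value of zero.

Features are computed per fold on training data only and averaged across
folds, yielding one symmetric region x region matrix per behavior and
brain state. Downstream statistics summarize features at the
network-block level (within/between 18 groups at full scale), test
blocks with within-site permutation nulls, measure sign consistency
between behaviors against an analytic chance level, cluster behaviors by
feature similarity (UPGMA), and form cross-state conjunction maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average as upgma_linkage, fcluster
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import squareform

from .connectome import BlockAverager, NetworkLabeling, devectorize_fc
from .containers import ConnectomeSet
from .prediction import PredictionResult, correlation_kernel

__all__ = [
    "PredictiveFeatures",
    "haufe_features",
    "haufe_invert",
    "per_fold_haufe",
    "feature_similarity",
    "similarity_matrix",
    "sign_consistency",
    "consistency_chance_level",
    "cluster_behaviors",
    "block_significance",
    "conjunction_across_states",
    "region_predictability",
    "domain_average_features",
]


@dataclass
class PredictiveFeatures:
    """Haufe-inverted edge-level features for one behavior.

    ``edge_features`` holds one edge vector per state
    (n_states, n_edges); ``matrix(state)`` expands to the symmetric
    region x region form with zero diagonal.
    """

    behavior: str
    states: list
    edge_features: np.ndarray
    n_regions: int
    family: str = ""
    n_folds: int = 0

    def __post_init__(self) -> None:
        self.edge_features = np.asarray(self.edge_features, dtype=float)
        if not np.all(np.isfinite(self.edge_features)):
            raise ValueError("predictive features must be finite")

    def matrix(self, state: str) -> np.ndarray:
        vec = self.edge_features[self.states.index(state)]
        return devectorize_fc(vec, self.n_regions, diag=0.0)

    def concat_vector(self) -> np.ndarray:
        """Edge features concatenated across states (Fig.-4-style view)."""
        return self.edge_features.ravel()

    def state_vector(self, state: str) -> np.ndarray:
        return self.edge_features[self.states.index(state)]


def haufe_features(X: np.ndarray, yhat: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Covariance of each column of X with the model predictions.

    ``X`` is (n_train, E); ``yhat`` the predictions on those same
    training participants. Returns an (E,) feature vector.
    """
    X = np.asarray(X, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training participants")
    if yhat.shape[0] != n:
        raise ValueError("yhat must be computed on the same participants as X")
    Xc = X - X.mean(axis=0)
    yc = yhat - yhat.mean()
    return Xc.T @ yc / (n - ddof)


def per_fold_haufe(connectomes: ConnectomeSet, result: PredictionResult) -> list:
    """Per-fold Haufe features, one (n_states, E) array per fitted fold."""
    if not result.models:
        raise ValueError("PredictionResult carries no fold models; rerun with return_models=True")
    out = []
    for model in result.models:
        feats = np.stack(
            [
                haufe_features(
                    connectomes.state_edges(s)[model.train_idx], model.yhat_train
                )
                for s in connectomes.states
            ]
        )
        out.append(feats)
    return out


def haufe_invert(
    connectomes: ConnectomeSet,
    result: PredictionResult,
    behavior: str = "",
) -> PredictiveFeatures:
    """Fold-averaged predictive-feature matrices for one behavior,
    one per brain state."""
    per_fold = per_fold_haufe(connectomes, result)
    return PredictiveFeatures(
        behavior=behavior,
        states=list(connectomes.states),
        edge_features=np.mean(per_fold, axis=0),
        n_regions=connectomes.n_regions,
        family=result.family,
        n_folds=len(per_fold),
    )


def feature_similarity(a, b, mode: str = "concat_states") -> float:
    """Pearson correlation between two sets of predictive features.

    ``concat_states`` correlates the edge vectors concatenated across
    brain states; ``per_state`` expects single edge vectors.
    """
    if isinstance(a, PredictiveFeatures):
        if a.edge_features.shape != b.edge_features.shape:
            raise ValueError("feature shapes differ")
        if mode == "concat_states":
            va, vb = a.concat_vector(), b.concat_vector()
        else:
            raise ValueError("pass edge vectors directly for per-state mode")
    else:
        va, vb = np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel()
        if va.shape != vb.shape:
            raise ValueError("feature shapes differ")
    return float(np.corrcoef(va, vb)[0, 1])


def similarity_matrix(features: list) -> np.ndarray:
    """Behavior x behavior similarity: correlation of state-concatenated
    predictive features for every pair."""
    vecs = np.stack([f.concat_vector() for f in features])
    return np.corrcoef(vecs)


def sign_consistency(blocks_a: np.ndarray, blocks_b: np.ndarray) -> float:
    """Fraction of unique network blocks whose feature signs agree.

    Exact zeros agree only with zeros; missing (NaN) blocks are excluded
    pairwise.
    """
    a = np.asarray(blocks_a, dtype=float)
    b = np.asarray(blocks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("block matrices differ in shape")
    if a.ndim == 2:
        iu = np.triu_indices(a.shape[0])
        a, b = a[iu], b[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no valid blocks to compare")
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} block(s) excluded as missing", stacklevel=2)
    return float(np.mean(np.sign(a[ok]) == np.sign(b[ok])))


def consistency_chance_level(block_values) -> float:
    """Analytic chance level of sign agreement.

    With a pooled positive-block fraction p, two independent draws agree
    with probability ``p^2 + (1-p)^2`` (49.3% positive gives 50.01%).
    """
    v = np.asarray(block_values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty block pool")
    p = float(np.mean(v > 0))
    return p**2 + (1 - p) ** 2


def cluster_behaviors(similarity: np.ndarray, k: int | None = None):
    """UPGMA (average-linkage) hierarchical clustering of behaviors on
    correlation distance ``1 - similarity``.

    Returns ``(linkage_matrix, flat_labels)``; ``flat_labels`` is None
    unless ``k`` is given.
    """
    s = np.asarray(similarity, dtype=float)
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = upgma_linkage(squareform(d, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return Z, labels


def _within_site_permutation(rng: np.random.Generator, sites: np.ndarray, n_perm: int):
    """Column-stacked permutations that shuffle only within each site."""
    n = len(sites)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(sites):
        idx = np.flatnonzero(sites == s)
        if len(idx) < 2:
            continue  # singleton sites cannot contribute a shuffle
        for k in range(n_perm):
            perms[k, idx] = rng.permutation(idx)
    return perms


def block_significance(
    connectomes: ConnectomeSet,
    y,
    result: PredictionResult,
    labels: NetworkLabeling,
    sites,
    confounds=None,
    n_perm: int = 2000,
    seed: int = 0,
    batch: int = 50,
):
    """Permutation test of block-averaged predictive features.

    The null shuffles behavior across participants within each site and
    re-runs fit-and-invert on every fold, reusing each fold's selected
    hyperparameters (re-searching them per permutation is configurable
    upstream but ancillary under the null). Two-tailed add-one p-values
    per unique block, separately for each brain state.

    Returns
    -------
    dict state -> (observed_blocks (G, G), pvals (G, G))
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives unstable p-values", stacklevel=2)
    if not result.models:
        raise ValueError("need fold models (return_models=True)")
    y = np.asarray(y, dtype=float)
    sites = np.asarray(sites)
    rng = np.random.default_rng(seed)
    averager = BlockAverager(labels)
    states = list(connectomes.states)
    n_states = len(states)
    nb = averager.n_blocks

    # fold-level caches: kernel factorization at the selected hyperparameters
    fold_cache = []
    for model in result.models:
        tr = model.train_idx
        if result.family == "mean_fc":
            Kw = correlation_kernel(connectomes.mean_state_edges()[tr])
        elif result.family == "linear_ridge":
            raise NotImplementedError(
                "block_significance supports the kernel families; invert the "
                "linear model separately"
            )
        else:
            Kw = sum(
                w * correlation_kernel(connectomes.state_edges(s)[tr])
                for s, w in model.state_weights.items()
                if w > 0
            )
        n = len(tr)
        A = Kw + (model.lam + 1e-8 * np.trace(Kw) / n) * np.eye(n)
        fold_cache.append((model, Kw, cho_factor(A, lower=True)))

    def _fold_blocks(Y: np.ndarray) -> np.ndarray:
        """(n_states, n_blocks, P) fold-averaged block features for each
        behavior column in Y."""
        P = Y.shape[1]
        acc = np.zeros((n_states, nb, P))
        for model, Kw, cf in fold_cache:
            tr, te = model.train_idx, model.test_idx
            if confounds is not None:
                X = np.column_stack([np.ones(len(tr)), np.asarray(confounds)[tr]])
                coefs, *_ = np.linalg.lstsq(X, Y[tr], rcond=None)
                Ytr = Y[tr] - X @ coefs
            else:
                Ytr = Y[tr]
            mu = Ytr.mean(axis=0)
            alpha = cho_solve(cf, Ytr - mu)
            yhat = Kw @ alpha + mu
            yc = yhat - yhat.mean(axis=0)
            for si, s in enumerate(states):
                Xs = connectomes.state_edges(s)[tr]
                Xc = Xs - Xs.mean(axis=0)
                feats = Xc.T @ yc / (len(tr) - 1)  # (E, P)
                acc[si] += averager(feats.T).T
        return acc / len(fold_cache)

    obs = _fold_blocks(y[:, None])[:, :, 0]  # (n_states, n_blocks)
    exceed = np.zeros_like(obs)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = _within_site_permutation(rng, sites, b)
        Y = y[perms].T  # (n, b)
        null = _fold_blocks(Y)  # (n_states, nb, b)
        exceed += (np.abs(null) >= np.abs(obs)[:, :, None]).sum(axis=2)
        done += b
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    out = {}
    for si, s in enumerate(states):
        out[s] = (averager.to_matrix(obs[si]), averager.to_matrix(pvals[si]))
    return out


def conjunction_across_states(block_mats: dict, sig_masks: dict) -> np.ndarray:
    """Cross-state conjunction: keep a block's cross-state mean only if it
    is significant in every state with the same sign everywhere; all
    other blocks are zeroed."""
    if set(block_mats) != set(sig_masks):
        raise ValueError("state sets differ between blocks and masks")
    states = list(block_mats)
    stack = np.stack([np.asarray(block_mats[s], dtype=float) for s in states])
    sig = np.stack([np.asarray(sig_masks[s], dtype=bool) for s in states])
    all_sig = sig.all(axis=0)
    signs = np.sign(stack)
    same_sign = (signs == signs[0]).all(axis=0) & (signs[0] != 0)
    keep = all_sig & same_sign & np.isfinite(stack).all(axis=0)
    out = np.zeros(stack.shape[1:])
    out[keep] = stack.mean(axis=0)[keep]
    return out


def region_predictability(feature_matrix: np.ndarray):
    """Region-level predictability maps from a region x region feature
    matrix: per region, the sum of positive entries of its row, the sum
    of absolute negative entries, and percentile ranks of both.

    Returns dict with ``positive``, ``negative``, ``positive_pct``,
    ``negative_pct`` arrays.
    """
    m = np.asarray(feature_matrix, dtype=float)
    pos = np.where(m > 0, m, 0.0).sum(axis=1)
    neg = np.abs(np.where(m < 0, m, 0.0)).sum(axis=1)

    def _pct(v):
        order = v.argsort(kind="stable").argsort(kind="stable")
        return 100.0 * order / max(len(v) - 1, 1)

    return {
        "positive": pos,
        "negative": neg,
        "positive_pct": _pct(pos),
        "negative_pct": _pct(neg),
    }


def domain_average_features(
    features: list,
    normalize: bool = False,
) -> PredictiveFeatures:
    """Equal-weight elementwise mean of predictive features across the
    behaviors of one domain (only successfully predicted behaviors should
    be passed in). With ``normalize``, each state's matrix is divided by
    its own standard deviation for display."""
    if not features:
        raise ValueError("empty domain: no features to average")
    shapes = {f.edge_features.shape for f in features}
    if len(shapes) != 1:
        raise ValueError("feature shapes differ across behaviors")
    avg = np.mean([f.edge_features for f in features], axis=0)
    if normalize:
        sd = avg.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        avg = avg / sd
    first = features[0]
    return PredictiveFeatures(
        behavior="+".join(f.behavior for f in features),
        states=list(first.states),
        edge_features=avg,
        n_regions=first.n_regions,
        family=first.family,
        n_folds=first.n_folds,
    )
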