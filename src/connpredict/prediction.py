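"""Behavioral prediction from multi-state FC under site-clustered nested CV.

The estimator is kernel ridge regression (KRR) with a correlation kernel:
similarity between two participants is the Pearson correlation of their
vectorized FC matrices. A test participant's behavior is predicted as a
regularized similarity-weighted combination of training participants'
behavior. Four model families share one cross-validation harness:

* ``single_kernel`` — KRR on one brain state's FC;
* ``multikernel``   — KRR on a convex combination of the per-state
  kernels, ``K = sum_s w_s K_s`` with ``w`` on a simplex grid, jointly
  grid-searched with the ridge penalty by inner cross-validation;
* ``mean_fc``       — KRR on the Fisher-z average FC across states;
* ``linear_ridge``  — primal ridge on standardized edge features
  (solved in the dual via the linear kernel).

Cross-validation is leave-``k_test``-site-clusters-out: sites are merged
into clusters of at least ``min_size`` participants, every combination
of ``k_test`` clusters forms one test fold, and sites are never split
across the train/test boundary. Head-motion confounds (mean FD, DVARS)
are regressed from behavior with coefficients estimated on the training
clusters only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .connectome import fisher_average
from .containers import ConnectomeSet

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "FoldSpec",
    "FoldModel",
    "PredictionResult",
    "build_site_clusters",
    "enumerate_folds",
    "regress_confounds",
    "correlation_kernel",
    "simplex_grid",
    "fit_krr",
    "krr_predict",
    "nested_cv",
    "accuracy_metrics",
    "aggregate_accuracy",
    "BatchedNestedCV",
]

#: 13 log-spaced ridge penalties covering under- to over-regularized fits.
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 4, 13))


@dataclass(frozen=True)
class FoldSpec:
    """One outer split: which site clusters are held out."""

    fold_id: int
    test_clusters: tuple
    train_clusters: tuple

    def __post_init__(self) -> None:
        if set(self.test_clusters) & set(self.train_clusters):
            raise ValueError("train and test clusters overlap")


@dataclass
class FoldModel:
    """A fitted (multi)kernel ridge model for one fold."""

    fold_id: int
    family: str
    lam: float
    state_weights: dict
    alpha: np.ndarray  # dual coefficients over training participants
    y_train_mean: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    yhat_train: np.ndarray  # model predictions on its own training set
    confound_coefs: np.ndarray | None = None
    primal_weights: np.ndarray | None = None  # linear_ridge only


@dataclass
class PredictionResult:
    """Per-fold predictions and accuracies from one nested-CV run."""

    family: str
    folds: list = field(default_factory=list)  # FoldSpec
    observed: list = field(default_factory=list)  # residualized y, per fold
    predicted: list = field(default_factory=list)
    r: list = field(default_factory=list)
    cod: list = field(default_factory=list)
    selected_lambda: list = field(default_factory=list)
    selected_weights: list = field(default_factory=list)
    models: list = field(default_factory=list)  # FoldModel, optional

    def mean_accuracy(self) -> float:
        return aggregate_accuracy(self.r)

    def mean_cod(self) -> float:
        vals = np.asarray(self.cod, dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def build_site_clusters(
    site_labels,
    n_clusters: int = 10,
    min_size: int = 150,
):
    """Merge sites into ``n_clusters`` site-clusters of at least
    ``min_size`` participants each; a site is never split.

    Greedy assignment: sites sorted by descending size (name as the
    deterministic tie-break) are placed one by one into the currently
    smallest cluster.

    Returns
    -------
    clusters : (n_participants,) int array of cluster indices (0-based)
    site_to_cluster : dict
    """
    site_labels = np.asarray(site_labels)
    n = len(site_labels)
    if n < n_clusters:
        raise ValueError(f"{n} participants cannot fill {n_clusters} clusters")
    names, counts = np.unique(site_labels, return_counts=True)
    if len(names) < n_clusters:
        raise ValueError(
            f"{len(names)} sites cannot form {n_clusters} clusters without splitting"
        )
    order = sorted(range(len(names)), key=lambda i: (-counts[i], str(names[i])))
    sizes = np.zeros(n_clusters, dtype=int)
    site_to_cluster = {}
    for i in order:
        target = int(np.argmin(sizes))
        site_to_cluster[names[i]] = target
        sizes[target] += counts[i]
    if sizes.min() < min_size:
        warnings.warn(
            f"smallest site-cluster has {sizes.min()} < {min_size} participants; "
            "proceeding with relaxed minimum",
            stacklevel=2,
        )
    clusters = np.array([site_to_cluster[s] for s in site_labels], dtype=int)
    return clusters, site_to_cluster


def enumerate_folds(n_clusters: int, k_test: int) -> list:
    """All C(n_clusters, k_test) leave-``k_test``-clusters-out folds, in
    deterministic lexicographic order. (10, 3) yields 120 folds."""
    if k_test >= n_clusters:
        raise ValueError("k_test must be smaller than n_clusters")
    if k_test < 1:
        raise ValueError("k_test must be positive")
    all_c = tuple(range(n_clusters))
    folds = []
    for fid, test in enumerate(itertools.combinations(all_c, k_test)):
        train = tuple(c for c in all_c if c not in test)
        folds.append(FoldSpec(fold_id=fid, test_clusters=test, train_clusters=train))
    return folds


def _design(confounds: np.ndarray) -> np.ndarray:
    x = np.asarray(confounds, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def regress_confounds(y, confounds, train_idx, test_idx):
    """OLS confound removal with train-estimated coefficients.

    Coefficients (with intercept) are fit on the training participants
    only and applied to both sets, so no test information leaks into the
    residualization.

    Returns ``(y_train_resid, y_test_resid, coefs)``.
    """
    y = np.asarray(y, dtype=float)
    X = _design(confounds)
    Xtr = X[train_idx]
    rank = np.linalg.matrix_rank(Xtr)
    if rank < Xtr.shape[1]:
        sd = Xtr[:, 1:].std(axis=0)
        bad = [int(i) for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"confound design rank {rank} < {Xtr.shape[1]}; "
            f"zero-variance/collinear columns: {bad if bad else 'non-trivial collinearity'}"
        )
    coefs, *_ = np.linalg.lstsq(Xtr, y[train_idx], rcond=None)
    return (
        y[train_idx] - Xtr @ coefs,
        y[test_idx] - X[test_idx] @ coefs,
        coefs,
    )


def correlation_kernel(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between rows of A and rows of B.

    This is the FC similarity kernel: entry (i, t) is the correlation of
    participant i's and participant t's edge vectors.
    """
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)

    def _standardize(x):
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            rows = np.flatnonzero(sd.ravel() == 0).tolist()
            raise ValueError(f"zero-variance edge vector(s) at rows {rows}")
        return xc / (sd * np.sqrt(x.shape[1]))

    K = _standardize(A) @ _standardize(B).T
    if B is A:
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
    return K


def simplex_grid(n: int, step: float = 0.25) -> list:
    """All weight vectors on the n-simplex with coordinates in multiples
    of ``step`` summing to 1 (single-kernel vertices included)."""
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    units = int(round(1.0 / step))
    if abs(units * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer")
    grids = []
    for combo in itertools.combinations_with_replacement(range(n), units):
        w = np.bincount(combo, minlength=n) * step
        grids.append(w)
    return grids


def _jitter(K: np.ndarray) -> float:
    return 1e-8 * np.trace(K) / K.shape[0]


def fit_krr(K_train: np.ndarray, y_train: np.ndarray, lam: float):
    """Closed-form kernel ridge solve.

    y is mean-centered on the training set; the training mean is the
    intercept added back at prediction time. A jitter of
    ``1e-8 * trace(K)/n`` guards numerically semi-definite kernels; a
    kernel that is indefinite beyond that tolerance raises.

    Returns ``(alpha, y_mean)`` with ``alpha = (K + lam*I)^-1 (y - mean)``.
    """
    K = np.asarray(K_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be positive")
    n = K.shape[0]
    ymean = float(y.mean())
    A = K + (lam + _jitter(K)) * np.eye(n)
    try:
        c = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("kernel is not positive semidefinite beyond jitter tolerance") from exc
    alpha = cho_solve(c, y - ymean)
    return alpha, ymean


def krr_predict(K_cross: np.ndarray, alpha: np.ndarray, y_mean: float) -> np.ndarray:
    """Predict with a fitted KRR model: ``K_cross @ alpha + y_mean``."""
    return np.asarray(K_cross) @ alpha + y_mean


def accuracy_metrics(observed, predicted, train_mean: float):
    """Prediction accuracy: Pearson r between observed and predicted,
    and the coefficient of determination against the training-set mean
    (out-of-sample baseline).

    Returns ``(r, cod)``; r is NaN when undefined (constant vectors or
    fewer than 3 test points).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size < 3:
        return float("nan"), float("nan")
    denom = np.sum((o - train_mean) ** 2)
    cod = 1.0 - np.sum((o - p) ** 2) / denom if denom > 0 else float("nan")
    if o.std() == 0 or p.std() == 0:
        return float("nan"), cod
    r = float(np.corrcoef(o, p)[0, 1])
    return r, cod


def aggregate_accuracy(r_values, return_n: bool = False):
    """Fisher-z average of correlations, excluding missing values."""
    r = np.asarray(list(r_values), dtype=float)
    ok = np.isfinite(r)
    if not ok.any():
        out = float("nan")
        return (out, 0) if return_n else out
    out = float(fisher_average(r[ok]))
    return (out, int(ok.sum())) if return_n else out


def _weight_entropy(w: np.ndarray) -> float:
    p = w[w > 0]
    return float(-(p * np.log(p)).sum())


def _inner_folds(train_clusters, clusters):
    """Leave-one-cluster-out splits within the training clusters."""
    out = []
    for held in train_clusters:
        fit_c = [c for c in train_clusters if c != held]
        fit_idx = np.flatnonzero(np.isin(clusters, fit_c))
        val_idx = np.flatnonzero(clusters == held)
        out.append((fit_idx, val_idx))
    return out


def _eig_predict(K_fit, K_cross, y_fit, lambda_grid):
    """Predictions on a validation set for every lambda via one
    eigendecomposition of the fit-set kernel."""
    n = K_fit.shape[0]
    evals, V = np.linalg.eigh(K_fit + _jitter(K_fit) * np.eye(n))
    ymean = y_fit.mean()
    t = V.T @ (y_fit - ymean)
    G = K_cross @ V
    preds = {}
    for lam in lambda_grid:
        preds[lam] = G @ (t / (evals + lam)) + ymean
    return preds


def _state_kernels(connectomes: ConnectomeSet, family: str, state: str | None):
    if family == "single_kernel":
        if state is None:
            raise ValueError("single_kernel requires a state")
        return {state: correlation_kernel(connectomes.state_edges(state))}
    if family == "multikernel":
        return {s: correlation_kernel(connectomes.state_edges(s)) for s in connectomes.states}
    if family == "mean_fc":
        return {"mean_fc": correlation_kernel(connectomes.mean_state_edges())}
    raise ValueError(f"unknown kernel family {family!r}")


def nested_cv(
    connectomes: ConnectomeSet,
    y,
    clusters,
    folds,
    family: str = "single_kernel",
    state: str | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    weight_step: float = 0.25,
    confounds=None,
    return_models: bool = False,
) -> PredictionResult:
    """Leave-k-site-clusters-out nested cross-validation.

    For every outer fold: confounds are regressed from behavior with
    train-estimated coefficients; the ridge penalty (and, for
    ``multikernel``, the simplex kernel weights) is selected by
    leave-one-cluster-out CV within the training clusters, maximizing
    the Fisher-averaged validation correlation (ties resolved toward
    larger lambda, then lower weight entropy); the model is refit on the
    full training set and applied to the held-out clusters.
    """
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters, dtype=int)
    lambda_grid = sorted(lambda_grid)
    if not lambda_grid:
        raise ValueError("empty lambda grid")

    if family == "linear_ridge":
        kernels = None
        edges_all = np.concatenate(
            [connectomes.state_edges(s) for s in connectomes.states], axis=1
        ) if state is None else connectomes.state_edges(state)
    else:
        kernels = _state_kernels(connectomes, family, state)
        edges_all = None
    state_names = list(kernels) if kernels else []
    if family == "multikernel" and len(state_names) > 1:
        weight_vectors = simplex_grid(len(state_names), weight_step)
        if not weight_vectors:
            raise ValueError("empty weight grid")
    else:
        weight_vectors = [np.ones(max(len(state_names), 1))]

    result = PredictionResult(family=family)
    for fold in folds:
        train_idx = np.flatnonzero(np.isin(clusters, fold.train_clusters))
        test_idx = np.flatnonzero(np.isin(clusters, fold.test_clusters))
        if len(set(clusters[train_idx])) < 3:
            raise ValueError("need at least 3 training clusters for the inner loop")

        if confounds is not None:
            y_tr, y_te, coefs = regress_confounds(y, confounds, train_idx, test_idx)
        else:
            y_tr, y_te, coefs = y[train_idx], y[test_idx], None

        if y_tr.std() == 0:
            warnings.warn(
                f"fold {fold.fold_id}: behavior constant on training set; skipped",
                stacklevel=2,
            )
            continue

        # map global indices to within-train positions
        pos = {g: i for i, g in enumerate(train_idx)}
        inner = _inner_folds(fold.train_clusters, clusters)

        if family == "linear_ridge":
            mu = edges_all[train_idx].mean(axis=0)
            sd = edges_all[train_idx].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (edges_all[train_idx] - mu) / sd
            Xte = (edges_all[test_idx] - mu) / sd
            E = Xtr.shape[1]
            K_full = (Xtr @ Xtr.T) / E
            K_cross_te = (Xte @ Xtr.T) / E
            kern_train = {"_linear": K_full}
            kern_cross = {"_linear": K_cross_te}
        else:
            kern_train = {s: K[np.ix_(train_idx, train_idx)] for s, K in kernels.items()}
            kern_cross = {s: K[np.ix_(test_idx, train_idx)] for s, K in kernels.items()}

        names = list(kern_train)
        best = None  # (z, lam, -entropy, w)
        for w in weight_vectors:
            Kw = sum(w[i] * kern_train[s] for i, s in enumerate(names))
            per_lambda_r = {lam: [] for lam in lambda_grid}
            for fit_g, val_g in inner:
                fit_l = np.array([pos[g] for g in fit_g])
                val_l = np.array([pos[g] for g in val_g])
                preds = _eig_predict(
                    Kw[np.ix_(fit_l, fit_l)],
                    Kw[np.ix_(val_l, fit_l)],
                    y_tr[fit_l],
                    lambda_grid,
                )
                for lam in lambda_grid:
                    r, _ = accuracy_metrics(
                        y_tr[val_l], preds[lam], float(y_tr[fit_l].mean())
                    )
                    per_lambda_r[lam].append(r)
            for lam in lambda_grid:
                z = aggregate_accuracy(per_lambda_r[lam])
                z = -np.inf if not np.isfinite(z) else z
                key = (z, lam, -_weight_entropy(w))
                if best is None or key > best[0]:
                    best = (key, lam, w)
        _, lam_sel, w_sel = best

        Kw_train = sum(w_sel[i] * kern_train[s] for i, s in enumerate(names))
        Kw_cross = sum(w_sel[i] * kern_cross[s] for i, s in enumerate(names))
        alpha, ymean = fit_krr(Kw_train, y_tr, lam_sel)
        pred_te = krr_predict(Kw_cross, alpha, ymean)
        yhat_tr = krr_predict(Kw_train, alpha, ymean)
        r, cod = accuracy_metrics(y_te, pred_te, ymean)

        result.folds.append(fold)
        result.observed.append(y_te)
        result.predicted.append(pred_te)
        result.r.append(r)
        result.cod.append(cod)
        result.selected_lambda.append(lam_sel)
        weights = {s: float(w_sel[i]) for i, s in enumerate(names)}
        result.selected_weights.append(weights)
        if return_models:
            primal = None
            if family == "linear_ridge":
                primal = Xtr.T @ alpha / E
            result.models.append(
                FoldModel(
                    fold_id=fold.fold_id,
                    family=family,
                    lam=lam_sel,
                    state_weights=weights,
                    alpha=alpha,
                    y_train_mean=ymean,
                    train_idx=train_idx,
                    test_idx=test_idx,
                    yhat_train=yhat_tr,
                    confound_coefs=coefs,
                    primal_weights=primal,
                )
            )
    return result


class BatchedNestedCV:
    """Nested CV evaluated for many behavior vectors over one fixed kernel.

    Permutation nulls and repeated-simulation calibrations re-run the
    same cross-validation with the kernel unchanged and only the behavior
    permuted, so the per-fold eigendecompositions can be shared across
    evaluations and the lambda search vectorized over columns. The
    selection rule (Fisher-averaged inner correlation, ties toward larger
    lambda) matches :func:`nested_cv` for the single-kernel family.
    """

    def __init__(
        self,
        K: np.ndarray,
        clusters,
        folds,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        confounds=None,
        cache: bool = True,
    ) -> None:
        self.K = np.asarray(K, dtype=float)
        self.clusters = np.asarray(clusters, dtype=int)
        self.folds = list(folds)
        self.lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
        self.confounds = None if confounds is None else np.asarray(confounds, dtype=float)
        self.cache = cache
        self._cache: dict = {}

    def _decomp(self, key, idx_fit, idx_val):
        if key in self._cache:
            return self._cache[key]
        Kf = self.K[np.ix_(idx_fit, idx_fit)]
        evals, V = np.linalg.eigh(Kf + _jitter(Kf) * np.eye(len(idx_fit)))
        G = self.K[np.ix_(idx_val, idx_fit)] @ V
        out = (evals, V, G)
        if self.cache:
            self._cache[key] = out
        return out

    def evaluate(self, Y: np.ndarray) -> np.ndarray:
        """Fisher-averaged accuracy across folds for each column of Y.

        Parameters
        ----------
        Y : (n_participants, P) array (a 1-D vector is treated as P=1).

        Returns
        -------
        (P,) array of Fisher-mean correlations.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        P = Y.shape[1]
        lambdas = self.lambda_grid
        nl = len(lambdas)
        z_sum = np.zeros(P)
        z_cnt = np.zeros(P)
        for fold in self.folds:
            tr = np.flatnonzero(np.isin(self.clusters, fold.train_clusters))
            te = np.flatnonzero(np.isin(self.clusters, fold.test_clusters))
            if self.confounds is not None:
                X = _design(self.confounds)
                coefs, *_ = np.linalg.lstsq(X[tr], Y[tr], rcond=None)
                Ytr = Y[tr] - X[tr] @ coefs
                Yte = Y[te] - X[te] @ coefs
            else:
                Ytr, Yte = Y[tr], Y[te]

            pos = {g: i for i, g in enumerate(tr)}
            zin = np.zeros((nl, P))
            zin_cnt = np.zeros((nl, P))
            for held in fold.train_clusters:
                fit_g = tr[~np.isin(self.clusters[tr], [held])]
                val_g = np.flatnonzero(self.clusters == held)
                evals, V, G = self._decomp(("in", fold.fold_id, held), fit_g, val_g)
                fit_l = np.array([pos[g] for g in fit_g])
                val_l = np.array([pos[g] for g in val_g])
                yf = Ytr[fit_l]
                mu = yf.mean(axis=0)
                T = V.T @ (yf - mu)
                yv = Ytr[val_l]
                yv_c = yv - yv.mean(axis=0)
                yv_sd = yv.std(axis=0)
                for li, lam in enumerate(lambdas):
                    pred = G @ (T / (evals[:, None] + lam)) + mu
                    pc = pred - pred.mean(axis=0)
                    psd = pc.std(axis=0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = (yv_c * pc).mean(axis=0) / (yv_sd * psd)
                    ok = np.isfinite(r) & (len(val_l) >= 3)
                    rz = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
                    zin[li, ok] += rz[ok]
                    zin_cnt[li, ok] += 1
            with np.errstate(invalid="ignore"):
                zmean = zin / zin_cnt
            zmean[~np.isfinite(zmean)] = -np.inf
            sel = np.zeros(P, dtype=int)
            bestz = np.full(P, -np.inf)
            for li in range(nl):  # ascending lambda; >= keeps the larger lambda on ties
                better = zmean[li] >= bestz
                sel[better] = li
                bestz[better] = zmean[li][better]

            evals, V, G = self._decomp(("out", fold.fold_id), tr, te)
            mu = Ytr.mean(axis=0)
            T = V.T @ (Ytr - mu)
            pred = np.empty((len(te), P))
            for li in np.unique(sel):
                cols = np.flatnonzero(sel == li)
                pred[:, cols] = G @ (T[:, cols] / (evals[:, None] + lambdas[li])) + mu[cols]
            oc = Yte - Yte.mean(axis=0)
            osd = Yte.std(axis=0)
            pc = pred - pred.mean(axis=0)
            psd = pc.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (oc * pc).mean(axis=0) / (osd * psd)
            ok = np.isfinite(r) & (len(te) >= 3)
            rz = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
            z_sum[ok] += rz[ok]
            z_cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            return np.tanh(z_sum / z_cnt)
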