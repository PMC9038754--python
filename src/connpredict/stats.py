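"""Hypothesis testing for prediction accuracies and feature statistics.

* Above-chance accuracy: permutation test that shuffles behavior within
  each acquisition site (the exchangeable blocks under site effects) and
  re-runs the full cross-validation pipeline per shuffle.
* Model comparison: the corrected resampled t-test on paired per-fold
  accuracy differences — fold accuracies overlap in training data, so
  the naive one-sample t is anti-conservative; the variance is inflated
  by ``(1/K + n_test/n_train)`` (Nadeau-Bengio correction).
* The Gaussianity assumption of that t-test is checked with a
  one-sample Kolmogorov-Smirnov test.
* Multiplicity is controlled with the Benjamini-Hochberg step-up at
  q < 0.05, applied per test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "FoldDifferenceSeries",
    "within_site_permutations",
    "permutation_null_accuracy",
    "corrected_resampled_ttest",
    "gaussianity_check",
    "fdr_bh",
]


@dataclass
class FoldDifferenceSeries:
    """Paired per-fold metric differences plus representative fold sizes."""

    d: np.ndarray
    n_test: float
    n_train: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.size < 2:
            raise ValueError("need at least 2 folds")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("fold differences must be finite")


def within_site_permutations(y, sites, n_perm: int, rng) -> np.ndarray:
    """(n, n_perm) matrix of behavior vectors shuffled within site.

    Singleton sites cannot be shuffled and keep their value in every
    permutation (logged via warning once).
    """
    y = np.asarray(y, dtype=float)
    sites = np.asarray(sites)
    out = np.tile(y[:, None], (1, n_perm))
    singletons = 0
    for s in np.unique(sites):
        idx = np.flatnonzero(sites == s)
        if len(idx) < 2:
            singletons += 1
            continue
        for k in range(n_perm):
            out[idx, k] = y[rng.permutation(idx)]
    if singletons:
        warnings.warn(
            f"{singletons} singleton site(s) contribute no permutation", stacklevel=2
        )
    return out


def permutation_null_accuracy(
    evaluate,
    y,
    sites,
    n_perm: int = 1000,
    seed: int = 0,
):
    """One-tailed permutation p-value for above-chance accuracy.

    ``evaluate`` maps an (n, P) matrix of behavior columns to a (P,)
    vector of accuracies (e.g. ``BatchedNestedCV.evaluate``); the
    observed behavior and all within-site shuffles are evaluated through
    the identical pipeline. Add-one estimator:
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.

    Returns ``(p, observed_accuracy, null_accuracies)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perms = within_site_permutations(y, sites, n_perm, rng)
    acc = np.asarray(evaluate(np.column_stack([y, perms])), dtype=float)
    observed, null = acc[0], acc[1:]
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), float(observed), null


def corrected_resampled_ttest(d, n_test=None, n_train=None):
    """Corrected resampled t-test on per-fold paired differences.

    ``t = mean(d) / sqrt((1/K + n_test/n_train) * var(d))`` with the
    unbiased variance and K-1 degrees of freedom; two-tailed p. The
    test-to-train ratio uses the (average) per-fold participant counts.

    Accepts a :class:`FoldDifferenceSeries` or ``(d, n_test, n_train)``.
    """
    if isinstance(d, FoldDifferenceSeries):
        series = d
    else:
        series = FoldDifferenceSeries(d=np.asarray(d, dtype=float), n_test=n_test, n_train=n_train)
    dv = series.d
    K = dv.size
    var = dv.var(ddof=1)
    if np.ptp(dv) == 0:
        warnings.warn("zero variance in fold differences", stacklevel=2)
        if dv.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(dv.mean()) * np.inf), 0.0
    factor = 1.0 / K + series.n_test / series.n_train
    t = dv.mean() / np.sqrt(factor * var)
    p = 2.0 * sps.t.sf(abs(t), df=K - 1)
    return float(t), float(p)


def gaussianity_check(d):
    """One-sample KS test of standardized fold differences against the
    standard normal. Returns ``(ks_statistic, p)``; degenerate input
    (zero variance) returns NaNs with a warning."""
    dv = np.asarray(d, dtype=float)
    sd = dv.std(ddof=1)
    if dv.size < 3 or np.ptp(dv) == 0:
        warnings.warn("degenerate fold-difference series; KS check skipped", stacklevel=2)
        return float("nan"), float("nan")
    z = (dv - dv.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return float(stat), float(p)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns ``(mask, threshold)`` where ``threshold`` is the largest
    rejected p-value (NaN if nothing is rejected). NaN p-values are
    never rejected and do not count toward the family size.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    ok = np.isfinite(p)
    m = int(ok.sum())
    mask = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return mask.reshape(np.shape(pvals)), float("nan")
    order = np.argsort(p[ok])
    sorted_p = p[ok][order]
    crit = q * (np.arange(1, m + 1) / m)
    below = sorted_p <= crit
    if not below.any():
        return mask.reshape(np.shape(pvals)), float("nan")
    k_max = int(np.max(np.flatnonzero(below)))
    threshold = float(sorted_p[k_max])
    mask[ok] = p[ok] <= threshold
    return mask.reshape(np.shape(pvals)), threshold
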