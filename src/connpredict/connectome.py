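"""Quality control and functional-connectivity construction.

Turns region-averaged fMRI time series into censored, run-averaged
Pearson functional-connectivity (FC) matrices, and provides the canonical
edge vectorization and network-block summarization used everywhere
downstream.

Conventions
-----------
* An *edge* is one unordered region pair. Edge vectors are the strict
  lower triangle of the FC matrix in row-major order, i.e. the entry for
  (row i, column j) with i > j appears at position ``i*(i-1)/2 + j``.
  The diagonal (self-correlation) never enters any vector, kernel,
  feature, or block average.
* Correlations are averaged in Fisher-z space: ``tanh(mean(atanh(r)))``,
  with |r| clipped just below 1 so the transform stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeriesRun",
    "FCMatrix",
    "NetworkLabeling",
    "censor_frames",
    "run_passes_qc",
    "state_passes_qc",
    "compute_fc",
    "average_fc",
    "vectorize_fc",
    "devectorize_fc",
    "n_edges",
    "fisher_average",
    "block_average",
    "block_average_vector",
]

#: |r| is clipped to 1 - ATANH_CLIP before the r-to-z transform so that
#: perfectly (anti)correlated edges keep a finite z-score.
ATANH_CLIP = 1e-7


@dataclass
class ROITimeSeriesRun:
    """One fMRI run: region-averaged signals plus motion-quality traces.

    Parameters
    ----------
    signals : (n_frames, n_regions) array
        Region-averaged BOLD time series.
    fd : (n_frames,) array
        Framewise displacement in mm (non-negative).
    dvars : (n_frames,) array
        Frame-to-frame differentiated signal variance.
    censor_mask : (n_frames,) boolean array
        True where the frame is usable.
    """

    signals: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    censor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        n = self.signals.shape[0]
        if self.censor_mask is None:
            self.censor_mask = censor_frames(self.fd, self.dvars)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if not (len(self.fd) == len(self.dvars) == len(self.censor_mask) == n):
            raise ValueError("fd, dvars and censor_mask must match frame count")
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signals.shape[1]


@dataclass
class FCMatrix:
    """Symmetric region-by-region Pearson correlation matrix for one state."""

    values: np.ndarray
    state: str = ""
    n_frames_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix diagonal must be 1")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


class NetworkLabeling:
    """Region -> network-group assignment (18 groups at full scale).

    Parameters
    ----------
    labels : sequence of str
        One group name per region, in region order.
    """

    def __init__(self, labels) -> None:
        self.labels = np.asarray(list(labels), dtype=object)
        self.groups = sorted(set(self.labels))
        self._codes = np.array([self.groups.index(g) for g in self.labels])

    @classmethod
    def from_csv(cls, path) -> "NetworkLabeling":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("label file needs columns region_name,group_name")
        return cls(df.iloc[:, 1].astype(str).tolist())

    def to_csv(self, path, region_names=None) -> None:
        names = region_names or [f"region_{i:03d}" for i in range(len(self.labels))]
        pd.DataFrame({"region_name": names, "group_name": self.labels}).to_csv(
            path, index=False
        )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def codes(self) -> np.ndarray:
        return self._codes


def censor_frames(
    fd,
    dvars,
    fd_thresh: float = 0.3,
    dvars_thresh: float = 50.0,
    n_before: int = 1,
    n_after: int = 2,
    min_segment: int = 5,
) -> np.ndarray:
    """Mark motion-contaminated frames as unusable.

    Frames with FD above ``fd_thresh`` (mm) or DVARS above ``dvars_thresh``
    are outliers; the ``n_before`` preceding and ``n_after`` following
    frames are censored with them. Any surviving run of good frames
    shorter than ``min_segment`` is censored too.

    Returns
    -------
    (n_frames,) boolean array, True where the frame is usable.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.size == 0:
        raise ValueError("empty motion traces")
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have equal length")
    bad = (fd > fd_thresh) | (dvars > dvars_thresh)
    n = len(bad)
    spread = bad.copy()
    for i in np.flatnonzero(bad):
        lo = max(0, i - n_before)
        hi = min(n, i + n_after + 1)
        spread[lo:hi] = True
    good = ~spread
    # kill good segments shorter than min_segment
    i = 0
    while i < n:
        if good[i]:
            j = i
            while j < n and good[j]:
                j += 1
            if j - i < min_segment:
                good[i:j] = False
            i = j
        else:
            i += 1
    return good


def run_passes_qc(
    mask,
    fd,
    max_censored_frac: float = 0.5,
    max_fd: float = 5.0,
) -> bool:
    """Run-level exclusion: drop runs with over half their frames censored
    or a maximum FD above ``max_fd`` mm."""
    mask = np.asarray(mask, dtype=bool)
    fd = np.asarray(fd, dtype=float)
    if mask.shape != fd.shape:
        raise ValueError("mask and fd must have equal length")
    censored_frac = 1.0 - mask.mean()
    return not (censored_frac > max_censored_frac or fd.max() > max_fd)


def state_passes_qc(masks, tr_seconds: float, min_seconds: float = 240.0) -> bool:
    """Participant-level inclusion for one state: at least ``min_seconds``
    (default 4 minutes) of usable data summed over surviving runs."""
    total = sum(int(np.asarray(m, dtype=bool).sum()) for m in masks)
    return total * tr_seconds >= min_seconds


def compute_fc(run: ROITimeSeriesRun, state: str = "") -> FCMatrix:
    """Pearson FC over usable frames only (censored frames are ignored)."""
    usable = run.censor_mask
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError(f"only {n_used} usable frames; need at least 3")
    x = run.signals[usable]
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"region(s) {flat.tolist()} constant over usable frames"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, state=state, n_frames_used=n_used)


def fisher_average(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """tanh(mean(atanh(r))) with |r| clipped to 1 - 1e-7."""
    z = np.arctanh(np.clip(values, -1 + ATANH_CLIP, 1 - ATANH_CLIP))
    return np.tanh(z.mean(axis=axis))


def average_fc(runs: list[FCMatrix]) -> FCMatrix:
    """Average FC matrices across runs via Fisher's r-to-z transform."""
    if not runs:
        raise ValueError("need at least one run")
    shapes = {m.values.shape for m in runs}
    if len(shapes) != 1:
        raise ValueError(f"mismatched FC shapes: {sorted(shapes)}")
    stack = np.stack([m.values for m in runs])
    avg = fisher_average(stack, axis=0)
    np.fill_diagonal(avg, 1.0)
    return FCMatrix(
        values=avg,
        state=runs[0].state,
        n_frames_used=sum(m.n_frames_used for m in runs),
    )


def n_edges(n_regions: int) -> int:
    """Number of unique off-diagonal region pairs."""
    return n_regions * (n_regions - 1) // 2


def vectorize_fc(fc, atol: float = 1e-8) -> np.ndarray:
    """Strict lower triangle, row-major: entry (i, j), i > j, at index
    ``i*(i-1)/2 + j``."""
    m = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    idx = np.tril_indices(m.shape[0], k=-1)
    return m[idx]


def devectorize_fc(vec, n_regions: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`; returns a symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_edges(n_regions):
        raise ValueError(
            f"expected {n_edges(n_regions)} edges for {n_regions} regions, got {vec.size}"
        )
    m = np.zeros((n_regions, n_regions))
    idx = np.tril_indices(n_regions, k=-1)
    m[idx] = vec
    m = m + m.T
    np.fill_diagonal(m, diag)
    return m


def block_average(matrix: np.ndarray, labels: NetworkLabeling) -> np.ndarray:
    """Average a symmetric region-level matrix within/between network groups.

    Entry (a, b) is the mean over unique region pairs with one endpoint in
    group a and the other in group b; within-group entries average the
    unique pairs inside the group (no diagonal, no double counting).
    Singleton groups have no within-group pair; their diagonal entry is NaN.

    Returns a symmetric (G, G) matrix with ``G*(G+1)/2`` unique blocks.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if labels.n_regions != m.shape[0]:
        raise ValueError("labels must cover all regions")
    g = labels.n_groups
    codes = labels.codes
    out = np.full((g, g), np.nan)
    members = [np.flatnonzero(codes == a) for a in range(g)]
    for a in range(g):
        ia = members[a]
        for b in range(a, g):
            ib = members[b]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(
                        f"group {labels.groups[a]!r} is a singleton; "
                        "within-group block undefined",
                        stacklevel=2,
                    )
                    continue
                sub = m[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                val = sub[iu].mean()
            else:
                val = m[np.ix_(ia, ib)].mean()
            out[a, b] = out[b, a] = val
    return out


def block_average_vector(edge_vec: np.ndarray, labels: NetworkLabeling) -> np.ndarray:
    """:func:`block_average` applied to an edge vector (avoids building the
    square matrix); used in permutation loops."""
    return block_average(
        devectorize_fc(edge_vec, labels.n_regions, diag=0.0), labels
    )


class BlockAverager:
    """Precomputed edge -> network-block map for fast repeated averaging.

    Maps each of the E edges to one of the ``G*(G+1)/2`` unique blocks so
    that block averages of many edge vectors (e.g. permutation nulls)
    reduce to one matrix product. Block order matches
    :func:`block_upper_values` (upper triangle incl. diagonal, row-major).
    """

    def __init__(self, labels: NetworkLabeling) -> None:
        self.labels = labels
        g = labels.n_groups
        codes = labels.codes
        r = labels.n_regions
        ii, jj = np.tril_indices(r, k=-1)
        a = np.minimum(codes[ii], codes[jj])
        b = np.maximum(codes[ii], codes[jj])
        # unique-block index of pair (a, b), a <= b, in upper-tri row-major order
        self.edge_block = (a * (2 * g - a + 1)) // 2 + (b - a)
        self.n_blocks = g * (g + 1) // 2
        self.counts = np.bincount(self.edge_block, minlength=self.n_blocks)
        grp_a = np.concatenate([[x] * (g - x) for x in range(g)])
        grp_b = np.concatenate([np.arange(x, g) for x in range(g)])
        self.block_groups = list(zip(grp_a.tolist(), grp_b.tolist()))

    def __call__(self, edge_values: np.ndarray) -> np.ndarray:
        """Average edge values into unique blocks.

        Parameters
        ----------
        edge_values : (..., E) array

        Returns
        -------
        (..., n_blocks) array; empty blocks (singleton groups) are NaN.
        """
        v = np.asarray(edge_values, dtype=float)
        flat = v.reshape(-1, v.shape[-1])
        sums = np.zeros((flat.shape[0], self.n_blocks))
        for k in range(flat.shape[0]):
            sums[k] = np.bincount(
                self.edge_block, weights=flat[k], minlength=self.n_blocks
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / self.counts
        return means.reshape(v.shape[:-1] + (self.n_blocks,))

    def to_matrix(self, block_values: np.ndarray) -> np.ndarray:
        """Expand unique-block values back into a symmetric (G, G) matrix."""
        g = self.labels.n_groups
        out = np.full((g, g), np.nan)
        iu = np.triu_indices(g)
        out[iu] = block_values
        out[(iu[1], iu[0])] = block_values
        return out


def block_upper_values(blocks: np.ndarray) -> np.ndarray:
    """Unique-block values (upper triangle incl. diagonal) of a (G, G)
    block matrix, row-major."""
    g = blocks.shape[0]
    iu = np.triu_indices(g)
    return blocks[iu]
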