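"""Discretization of 1-D vectors: three-centroid k-means and thresholding.

The association machinery never works with raw continuous values: a
signature's per-sample exposures (or one gene's expression values) are
partitioned into ZERO / MID / HIGH groups by Lloyd's algorithm with
k = 3, deterministically initialised at the minimum, mean and maximum
of the observed values.  The two extreme groups form the universe of
every hypergeometric test downstream.

The initialisation and tie rules here are part of the method, not an
implementation detail, so the iteration is written out rather than
delegated to a generic clustering library:

* centroids start at (min, mean, max) — no random restarts;
* each point goes to the nearest centroid, ties broken toward the
  lower centroid so zero-inflated exposure vectors keep their zeros in
  the ZERO cluster;
* clusters that empty out keep their previous centroid (no reseeding);
* convergence is exact assignment stability, capped at 100 iterations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ZERO, TriClusterAssignment

MAX_ITER = 100


def kmeans3(values) -> TriClusterAssignment:
    """Cluster a 1-D vector into ZERO/MID/HIGH by 3-centroid k-means.

    Parameters
    ----------
    values
        1-D array-like of finite values; a pandas Series keeps its
        index on the returned assignment.  Missing values must be
        excluded by the caller.

    Returns
    -------
    TriClusterAssignment
        Labels (0=ZERO, 1=MID, 2=HIGH, ordered by centroid), the final
        centroids, a degeneracy flag (fewer than three distinct input
        values) and the iteration count.
    """
    index = values.index if isinstance(values, pd.Series) else None
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("kmeans3 requires at least one value")
    if not np.isfinite(x).all():
        raise ValueError("kmeans3 requires finite values; drop missing first")

    degenerate = np.unique(x).size < 3
    labels, centroids, iters = _lloyd(x[None, :])
    return TriClusterAssignment(
        labels=labels[0],
        centroids=centroids[0],
        degenerate=degenerate,
        iterations=int(iters[0]),
        index=index,
    )


def kmeans3_batch(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise :func:`kmeans3` over a 2-D array (features x samples).

    Returns ``(labels, centroids, degenerate)`` where ``labels`` is
    (n_rows, n_samples) int8, ``centroids`` is (n_rows, 3) and
    ``degenerate`` flags rows with fewer than three distinct values.
    Used by the expression-association path, which clusters thousands
    of genes with identical semantics to the single-vector call.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("expected a non-empty 2-D array")
    if not np.isfinite(x).all():
        raise ValueError("finite values required")
    labels, centroids, _ = _lloyd(x)
    sorted_rows = np.sort(x, axis=1)
    distinct = (np.diff(sorted_rows, axis=1) > 0).sum(axis=1) + 1
    return labels, centroids, distinct < 3


def _lloyd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Lloyd iteration over rows of ``x`` (rows x samples)."""
    centroids = np.stack(
        [x.min(axis=1), x.mean(axis=1), x.max(axis=1)], axis=1
    )  # (r, 3), ascending by construction
    # argmin returns the first minimum, i.e. ties go to the lower centroid
    labels = np.argmin(np.abs(x[:, :, None] - centroids[:, None, :]), axis=2)
    iters = np.zeros(x.shape[0], dtype=int)
    active = np.ones(x.shape[0], dtype=bool)
    for _ in range(MAX_ITER):
        if not active.any():
            break
        rows = np.flatnonzero(active)
        sub = x[rows]
        sub_labels = labels[rows]
        new_centroids = centroids[rows].copy()
        for c in range(3):
            mask = sub_labels == c
            counts = mask.sum(axis=1)
            sums = np.where(mask, sub, 0.0).sum(axis=1)
            nonempty = counts > 0
            new_centroids[nonempty, c] = sums[nonempty] / counts[nonempty]
        new_labels = np.argmin(
            np.abs(sub[:, :, None] - new_centroids[:, None, :]), axis=2
        )
        changed = (new_labels != sub_labels).any(axis=1)
        centroids[rows] = new_centroids
        labels[rows] = new_labels
        iters[rows] += 1
        active[rows] = changed
    return labels.astype(np.int8), centroids, iters


def binarize_signature(weights, threshold: float):
    """Binarize signature weights by a strictly-greater threshold.

    A weight is set to 1 when it exceeds ``threshold`` (strictly), 0
    otherwise; missing weights propagate as missing.  ``threshold``
    must lie in (0, 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(weights, pd.Series):
        out = (weights > threshold).astype(float)
        out[weights.isna()] = np.nan
        return out
    w = np.asarray(weights, dtype=float)
    out = (w > threshold).astype(float)
    out[np.isnan(w)] = np.nan
    return out


def within_cluster_sse(values, labels, centroids=None) -> float:
    """Within-cluster sum of squared deviations from cluster means."""
    x = np.asarray(values, dtype=float).ravel()
    lab = np.asarray(labels).ravel()
    sse = 0.0
    for c in np.unique(lab):
        pts = x[lab == c]
        if pts.size:
            sse += float(((pts - pts.mean()) ** 2).sum())
    return sse
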