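"""Permutation null generation and the empirical FDR estimator.

Raw hypergeometric p-values from the association tests are not
uniform under the null (discrete support, min-taking over thresholds,
feature correlation), so significance cutoffs are calibrated
empirically: the per-signature exposure vector's sample labels are
shuffled (breaking the exposure-feature joint while preserving each
marginal) and the complete association procedure — clustering,
counting, both tails, threshold minimum for expression — is re-run on
each shuffle.  The estimated false discovery rate at a p-value
threshold theta is

    fdr(theta) = A(theta) / max(A(theta), O(theta))

where ``O`` counts observed p-values at or below theta and ``A`` is the
mean such count across the permutations (defined as 0 when ``A`` is 0).
Ten permutations are the default.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import AlterationMatrix

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 10


def shuffle_exposures(exposures: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Independently permute each signature column over the samples.

    Missing weights travel with their values, so each signature keeps
    its multiset of weights (and its missingness count) while losing
    any relation to sample identity.
    """
    shuffled = {}
    for signature in exposures.columns:
        values = exposures[signature].to_numpy(copy=True)
        rng.shuffle(values)
        shuffled[signature] = values
    return pd.DataFrame(shuffled, index=exposures.index)


def permuted_pvalues(
    associate: Callable[..., pd.DataFrame],
    features,
    exposures: pd.DataFrame,
    n_perm: int = N_PERMUTATIONS,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> list[np.ndarray]:
    """Re-run an association procedure on label-shuffled exposures.

    Parameters
    ----------
    associate
        ``associate_binary`` or ``associate_expression`` (or any
        callable with the signature ``(features, exposures, **kwargs)``
        returning a records frame with a ``p_min`` column).
    features
        The feature table passed through unchanged (an
        :class:`~sigassoc.containers.AlterationMatrix` or an
        expression DataFrame).
    n_perm
        Number of independent shuffles (default 10).

    Returns
    -------
    list of ndarray
        One pooled array of ``p_min`` values per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    collections: list[np.ndarray] = []
    for i in range(n_perm):
        shuffled = shuffle_exposures(exposures, rng)
        records = associate(features, shuffled, **kwargs)
        collections.append(records["p_min"].to_numpy(dtype=float))
    return collections


def estimate_fdr(
    observed: np.ndarray,
    permuted: Sequence[np.ndarray],
    thetas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Empirical FDR curve over p-value thresholds.

    For each threshold: ``O`` = count of observed p-values <= theta,
    ``A`` = mean count across the permuted collections, ``fdr`` =
    ``A / max(A, O)`` (0 when ``A`` is 0).  The curve is evaluated on
    ``thetas`` (if given) plus every distinct observed p-value, in
    decreasing threshold order.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        return pd.DataFrame(columns=["theta", "observed", "permuted_mean", "fdr"])
    if not permuted:
        raise ValueError("at least one permuted collection required")
    grid = np.unique(observed)
    if thetas is not None:
        grid = np.unique(np.concatenate([grid, np.asarray(thetas, dtype=float)]))
    grid = grid[::-1]  # decreasing thresholds

    obs_sorted = np.sort(observed)
    O = np.searchsorted(obs_sorted, grid, side="right")
    perm_sorted = [np.sort(p) for p in permuted]
    A = np.mean(
        [np.searchsorted(p, grid, side="right") for p in perm_sorted], axis=0
    )
    with np.errstate(invalid="ignore"):
        fdr = np.where(A > 0, A / np.maximum(A, O), 0.0)
    return pd.DataFrame(
        {"theta": grid, "observed": O.astype(int), "permuted_mean": A, "fdr": fdr}
    )


def fdr_at(curve: pd.DataFrame, theta: float) -> float:
    """FDR at the largest tabulated threshold <= ``theta``.

    Falls back to recomputation semantics: thresholds smaller than the
    smallest tabulated value return 0 observed / 0 permuted, i.e. 0.
    """
    below = curve[curve["theta"] <= theta]
    if below.empty:
        return 0.0
    return float(below.iloc[0]["fdr"])
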