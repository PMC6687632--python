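"""Comutation screening: pairwise chi-square with a randomization null.

Two genes comutate when their carrier sets co-occur more often than
their marginal frequencies predict; mutual exclusivity is the opposite
pattern.  Each pair is scored by the Pearson chi-square statistic on
its 2x2 carrier table *without* continuity correction — calibration is
not asymptotic but empirical: every gene's carrier labels are shuffled
independently (preserving per-gene carrier counts, destroying pairwise
structure) and the pairwise p-values from 100 such dataset
randomizations are aggregated into a null distribution.  The declared
significance rule is raw p < 0.001, validated against that null.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AlterationMatrix

logger = logging.getLogger(__name__)

N_RANDOMIZATIONS = 100
COMUTATION_ALPHA = 0.001


def _pairwise_chisq(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Chi-square statistic and p for every row pair of a binary matrix.

    Returns ``(chi2, p, counts)`` as condensed upper-triangle arrays;
    ``counts`` maps the four 2x2 cells to condensed arrays.  Degenerate
    pairs (a gene carried by none or all samples) get chi2 = 0, p = 1.
    """
    g, n = data.shape
    x = data.astype(np.int64)
    both = x @ x.T
    totals = x.sum(axis=1)
    iu = np.triu_indices(g, k=1)
    both = both[iu].astype(float)
    ta, tb = totals[iu[0]].astype(float), totals[iu[1]].astype(float)
    a_only = ta - both
    b_only = tb - both
    neither = n - both - a_only - b_only
    # chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)] for the 2x2 table
    det = both * neither - a_only * b_only
    margins = ta * (n - ta) * tb * (n - tb)
    degenerate = margins == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(degenerate, 0.0, n * det**2 / np.where(margins == 0, 1, margins))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    counts = {"both": both, "a_only": a_only, "b_only": b_only, "neither": neither}
    return chi2, p, counts


def comutation_chisq(matrix: AlterationMatrix, gene_a: str, gene_b: str) -> dict:
    """Pearson chi-square (no continuity correction) for one gene pair.

    Returns a record dict with the 2x2 table cells, the statistic and
    the raw p-value.  A gene carried by no sample or by every sample is
    degenerate: ``p_raw = 1`` and ``degenerate = True``.
    """
    for gene in (gene_a, gene_b):
        if gene not in matrix.feature_ids:
            raise KeyError(f"gene {gene!r} absent from matrix")
    if matrix.data.shape[1] < 4:
        raise ValueError("comutation test needs a universe of >= 4 samples")
    data = matrix.data.loc[[gene_a, gene_b]].to_numpy()
    chi2, p, counts = _pairwise_chisq(data)
    totals = data.sum(axis=1)
    degenerate = bool(totals.min() == 0 or totals.max() == data.shape[1])
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "both": int(counts["both"][0]),
        "a_only": int(counts["a_only"][0]),
        "b_only": int(counts["b_only"][0]),
        "neither": int(counts["neither"][0]),
        "chi2": float(chi2[0]),
        "p_raw": float(p[0]),
        "degenerate": degenerate,
    }


def randomized_null_comutation(
    matrix: AlterationMatrix,
    n_rand: int = N_RANDOMIZATIONS,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = COMUTATION_ALPHA,
) -> tuple[pd.DataFrame, np.ndarray]:
    """All-pairs comutation screen calibrated by dataset randomization.

    Observed pairwise chi-square p-values are computed once; then each
    of ``n_rand`` randomizations shuffles every gene's carrier labels
    independently and recomputes all pairwise p-values, aggregating
    them into one empirical null of ``n_rand * G*(G-1)/2`` values.  A
    pair is significant when its observed raw p < ``alpha``; the
    fraction of null p-values below ``alpha`` is logged as a check of
    that rule.

    Returns ``(records, null_pvalues)``.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if matrix.n_features < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    data = matrix.data.to_numpy()
    genes = matrix.feature_ids.to_numpy()
    chi2, p, counts = _pairwise_chisq(data)

    null_parts = []
    shuffled = data.copy()
    for _ in range(n_rand):
        for row in shuffled:
            rng.shuffle(row)
        null_parts.append(_pairwise_chisq(shuffled)[1])
    null_pvalues = np.concatenate(null_parts)
    null_rate = float((null_pvalues < alpha).mean())
    logger.info(
        "randomization null: %.4f%% of %d null pairs below alpha=%g",
        100 * null_rate,
        null_pvalues.size,
        alpha,
    )

    iu = np.triu_indices(len(genes), k=1)
    records = pd.DataFrame(
        {
            "gene_a": genes[iu[0]],
            "gene_b": genes[iu[1]],
            "both": counts["both"].astype(int),
            "a_only": counts["a_only"].astype(int),
            "b_only": counts["b_only"].astype(int),
            "neither": counts["neither"].astype(int),
            "chi2": chi2,
            "p_raw": p,
            "p_null": np.searchsorted(np.sort(null_pvalues), p, side="right")
            / null_pvalues.size,
            "significant": p < alpha,
        }
    )
    return records, null_pvalues


def exclusivity_counts(matrix: AlterationMatrix, genes: list[str]) -> tuple[int, int]:
    """Descriptive coverage/overlap summary for a gene set.

    Returns ``(n_samples_covered, n_overlapping)``: samples carrying at
    least one of the genes, and samples carrying two or more (the
    overlap that breaks mutual exclusivity).  No p-value is attached.
    """
    if not genes:
        return 0, 0
    missing = [g for g in genes if g not in matrix.feature_ids]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    hits = matrix.data.loc[genes].sum(axis=0)
    return int((hits >= 1).sum()), int((hits >= 2).sum())
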