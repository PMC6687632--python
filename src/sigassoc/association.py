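"""Hypergeometric association of binary features with exposure clusters.

The core statistic: for one signature, samples are split into ZERO /
MID / HIGH exposure clusters (:func:`sigassoc.discretize.kmeans3`) and
the universe of the test is the union of the two extreme clusters.
For a binary feature with ``K`` carriers in that universe of size
``N``, the number of carriers ``k`` inside the HIGH cluster (size
``n``) follows, under the null of no association, the hypergeometric
distribution ``Hypergeom(N, K, n)``; both tail probabilities are
reported (over-representation P(X >= k) and under-representation
P(X <= k)), always exactly — calibration is delegated to the
permutation machinery, never to an asymptotic approximation.

Expression features invert the construction: each gene's expression
vector is clustered, exposures are binarized at four thresholds
(0.05, 0.1, 0.2, 0.5), and binarized positives are counted across the
expression extremes; the feature-level statistic is the minimum tail
probability across the thresholds.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HIGH, ZERO, AlterationMatrix
from .discretize import binarize_signature, kmeans3, kmeans3_batch

logger = logging.getLogger(__name__)

EXPRESSION_THRESHOLDS = (0.05, 0.1, 0.2, 0.5)

#: default significance cutoffs (raw p, calibrated by permutation FDR)
CUTOFF_BINARY = 0.0003
CUTOFF_EXPRESSION = 1e-5

#: signature-correlation flagging rule
CORRELATION_R = 0.2
CORRELATION_P = 1e-6

RECORD_COLUMNS = [
    "feature_id",
    "feature_kind",
    "signature_id",
    "N",
    "K",
    "n",
    "k",
    "p_over",
    "p_under",
    "p_min",
    "direction",
    "informative",
]


def hypergeom_tails(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities.

    For ``X ~ Hypergeom(N, K, n)`` (``N`` population, ``K`` positives,
    ``n`` draws) returns ``(P(X >= k), P(X <= k))``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= max(0, K + n - N)):
        raise ValueError(f"invalid hypergeometric counts k={k} K={K} n={n} N={N}")
    dist = stats.hypergeom(N, K, n)
    return float(dist.sf(k - 1)), float(dist.cdf(k))


def _tails_vectorized(k, K, n, N):
    p_over = stats.hypergeom.sf(k - 1, N, K, n)
    p_under = stats.hypergeom.cdf(k, N, K, n)
    return p_over, p_under


def associate_binary(
    features: AlterationMatrix, exposures: pd.DataFrame
) -> pd.DataFrame:
    """Test every binary feature against every signature's extreme clusters.

    Per signature, samples without a weight are excluded, the remaining
    exposures are clustered and features are counted over the
    ZERO-union-HIGH universe.  Signatures whose clustering is
    degenerate (or lacks an extreme cluster) are skipped.  Features
    with no carrier in a universe are emitted with ``p_over = 1`` and
    ``informative = False``.

    Returns one row per (feature, signature) with the counts, both
    tails, ``p_min`` (smaller tail) and its direction.
    """
    records: list[pd.DataFrame] = []
    for signature in exposures.columns:
        weights = exposures[signature].dropna()
        samples = weights.index.intersection(features.samples)
        if len(samples) == 0:
            logger.info("signature %s: no overlapping samples; skipped", signature)
            continue
        assignment = kmeans3(weights.loc[samples])
        if not assignment.has_extremes():
            logger.info("signature %s: degenerate clustering; skipped", signature)
            continue
        labels = assignment.labels
        universe = samples[(labels == ZERO) | (labels == HIGH)]
        high = samples[labels == HIGH]
        sub = features.data.loc[:, universe].to_numpy()
        k = features.data.loc[:, high].to_numpy().sum(axis=1)
        K = sub.sum(axis=1)
        N, n = len(universe), len(high)
        p_over, p_under = _tails_vectorized(k, K, n, N)
        frame = pd.DataFrame(
            {
                "feature_id": features.feature_ids,
                "feature_kind": features.kind,
                "signature_id": signature,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_over": p_over,
                "p_under": p_under,
                "p_min": np.minimum(p_over, p_under),
                "direction": np.where(p_over <= p_under, "over", "under"),
                "informative": K > 0,
            }
        )
        records.append(frame)
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(records, ignore_index=True)


def associate_expression(
    expr: pd.DataFrame,
    exposures: pd.DataFrame,
    thresholds: tuple[float, ...] = EXPRESSION_THRESHOLDS,
    return_detail: bool = False,
):
    """Associate expression features with binarized signature exposures.

    Each expression feature (row of ``expr``) is clustered into three
    groups; the universe is its LOW-union-HIGH extreme clusters.  Each
    signature is binarized at every threshold (weight strictly greater
    than the threshold) and the positives are counted across the
    expression extremes: ``K`` positives in the universe, ``k`` in the
    expression-HIGH cluster.  The per-(feature, signature) statistic is
    ``p_min``, the minimum tail probability across thresholds, with the
    achieving threshold recorded.

    Constant (degenerate) expression features are skipped.  Samples are
    restricted per signature to those with a non-missing weight.
    """
    summaries: list[pd.DataFrame] = []
    details: list[pd.DataFrame] = []
    for signature in exposures.columns:
        weights = exposures[signature].dropna()
        samples = weights.index.intersection(expr.columns)
        if len(samples) < 3:
            logger.info("signature %s: too few samples for expression test", signature)
            continue
        sub_expr = expr.loc[:, samples]
        labels, _, degenerate = kmeans3_batch(sub_expr.to_numpy())
        usable = ~degenerate
        usable &= (labels == ZERO).any(axis=1) & (labels == HIGH).any(axis=1)
        n_skipped = int((~usable).sum())
        if n_skipped:
            logger.info(
                "signature %s: %d degenerate expression feature(s) skipped",
                signature,
                n_skipped,
            )
        if not usable.any():
            continue
        labels = labels[usable]
        feature_ids = sub_expr.index[usable]
        u_mask = (labels == ZERO) | (labels == HIGH)  # (f, s)
        h_mask = labels == HIGH
        N = u_mask.sum(axis=1)
        n = h_mask.sum(axis=1)
        binarized = np.stack(
            [binarize_signature(weights.loc[samples], t).to_numpy() for t in thresholds]
        )  # (t, s)
        K = u_mask.astype(np.int64) @ binarized.T  # (f, t)
        k = h_mask.astype(np.int64) @ binarized.T
        p_over, p_under = _tails_vectorized(k, K, n[:, None], N[:, None])
        tail_min = np.minimum(p_over, p_under)  # (f, t)
        best = np.argmin(tail_min, axis=1)
        rows = np.arange(len(feature_ids))
        summary = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "feature_kind": "expression",
                "signature_id": signature,
                "N": N,
                "K": K[rows, best],
                "n": n,
                "k": k[rows, best],
                "p_over": p_over[rows, best],
                "p_under": p_under[rows, best],
                "p_min": tail_min[rows, best],
                "direction": np.where(
                    p_over[rows, best] <= p_under[rows, best], "over", "under"
                ),
                "ms_threshold": np.asarray(thresholds)[best],
                "informative": K.max(axis=1) > 0,
            }
        )
        summaries.append(summary)
        if return_detail:
            for ti, t in enumerate(thresholds):
                details.append(
                    pd.DataFrame(
                        {
                            "feature_id": feature_ids,
                            "signature_id": signature,
                            "ms_threshold": t,
                            "N": N,
                            "K": K[:, ti],
                            "n": n,
                            "k": k[:, ti],
                            "p_over": p_over[:, ti],
                            "p_under": p_under[:, ti],
                        }
                    )
                )
    empty_cols = RECORD_COLUMNS + ["ms_threshold"]
    summary_out = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=empty_cols)
    )
    if return_detail:
        detail_out = (
            pd.concat(details, ignore_index=True) if details else pd.DataFrame()
        )
        return summary_out, detail_out
    return summary_out


def signature_correlations(
    exposures: pd.DataFrame,
    mutation_burden: pd.Series | None = None,
    r_cutoff: float = CORRELATION_R,
    p_cutoff: float = CORRELATION_P,
) -> pd.DataFrame:
    """Pairwise Pearson correlation screen across signatures.

    Complete-pairs Pearson r with a two-sided t-test per pair; a pair
    is flagged when ``|r| > r_cutoff`` and ``p < p_cutoff``.  When a
    burden series is given it is appended as an extra column
    (``mutation_burden``) and correlated identically.
    """
    table = exposures.copy()
    if mutation_burden is not None:
        table["mutation_burden"] = mutation_burden.reindex(table.index).astype(float)
    rows = []
    for a, b in itertools.combinations(table.columns, 2):
        pair = table[[a, b]].dropna()
        if len(pair) < 3:
            rows.append((a, b, np.nan, np.nan, len(pair), False))
            continue
        if pair[a].nunique() < 2 or pair[b].nunique() < 2:
            rows.append((a, b, np.nan, np.nan, len(pair), False))
            continue
        r, p = stats.pearsonr(pair[a], pair[b])
        rows.append((a, b, float(r), float(p), len(pair), abs(r) > r_cutoff and p < p_cutoff))
    return pd.DataFrame(
        rows, columns=["signature_a", "signature_b", "r", "p", "n_pairs", "flagged"]
    )


def region_expression_check(
    carriers: pd.Series, expr: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Rank-sum check of per-gene expression between region carriers.

    For each gene in ``genes`` present in ``expr``, compares expression
    in carrier vs non-carrier samples with a two-sided Wilcoxon
    rank-sum (Mann-Whitney) test — exact null when both groups have at
    most 10 samples and no ties, normal approximation with continuity
    correction otherwise.  ``direction`` is the sign of the carrier
    minus non-carrier median difference (``up``/``down``/None).
    """
    carriers = carriers.astype(bool)
    samples = carriers.index.intersection(expr.columns)
    carrier_samples = samples[carriers.loc[samples]]
    other_samples = samples[~carriers.loc[samples]]
    if len(carrier_samples) == 0 or len(other_samples) == 0:
        raise ValueError("region needs at least one carrier and one non-carrier")
    rows = []
    for gene in genes:
        if gene not in expr.index:
            logger.info("gene %s absent from expression table; skipped", gene)
            continue
        x = expr.loc[gene, carrier_samples].to_numpy(dtype=float)
        y = expr.loc[gene, other_samples].to_numpy(dtype=float)
        shift = float(np.median(x) - np.median(y))
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:  # constant gene: no evidence either way
            rows.append((gene, 0.0, None, 1.0))
            continue
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
        direction = None if shift == 0 else ("up" if shift > 0 else "down")
        rows.append((gene, shift, direction, float(min(res.pvalue, 1.0))))
    return pd.DataFrame(rows, columns=["gene", "median_shift", "direction", "p"])


def significant(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Subset association records to raw ``p_min`` below ``cutoff``."""
    if records.empty:
        return records
    return records[records["p_min"] < cutoff].sort_values("p_min", ignore_index=True)
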