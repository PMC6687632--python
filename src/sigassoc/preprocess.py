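"""Preprocessing filters and binary-matrix construction.

Turns the raw catalogs into the aligned binary feature matrices the
association tests consume:

* hypermutated tumors (more than 500 distinct nonsilently mutated
  genes) are removed before any counting — they otherwise dominate
  every per-gene test;
* genes become binary features (any nonsilent mutation) and genes
  mutated in fewer than three samples are dropped;
* copy-number segment means are thresholded at +/-0.5 to call
  amplifications and deletions, which are analysed separately; the
  region atoms are breakpoint-delimited and neighbouring regions with
  near-identical carrier sets are merged (OR of carriers);
* expression layers are quantile-normalized across samples;
* clinical fields become one dummy feature per stratum.

Coordinates are 1-based inclusive throughout (the common SEG dialect).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AlterationMatrix

logger = logging.getLogger(__name__)

HYPERMUTATION_MAX_GENES = 500
MIN_MUTATED_SAMPLES = 3
CNA_CUTOFF = 0.5
MIN_CNA_ALTERATIONS = 3
MERGE_MAX_DIFF = 1


def filter_hypermutated(
    catalog: pd.DataFrame, max_genes: int = HYPERMUTATION_MAX_GENES
) -> pd.DataFrame:
    """Drop hypermutated samples from a mutation catalog.

    A sample is hypermutated when it carries nonsilent mutations in
    more than ``max_genes`` distinct genes (strictly more; exactly
    ``max_genes`` is retained).
    """
    if max_genes < 1:
        raise ValueError("max_genes must be >= 1")
    if catalog.empty:
        logger.warning("empty mutation catalog")
        return catalog.copy()
    nonsilent = catalog[catalog["variant_class"] == "nonsilent"]
    genes_per_sample = nonsilent.groupby("sample")["gene"].nunique()
    hyper = genes_per_sample.index[genes_per_sample > max_genes]
    if len(hyper):
        logger.info(
            "removing %d hypermutated sample(s): %s", len(hyper), ", ".join(hyper)
        )
    return catalog[~catalog["sample"].isin(hyper)].reset_index(drop=True)


def build_mutation_matrix(
    catalog: pd.DataFrame,
    min_samples: int = MIN_MUTATED_SAMPLES,
    samples: pd.Index | None = None,
) -> AlterationMatrix:
    """Binary gene x sample matrix from a (hypermutation-filtered) catalog.

    A sample carries a gene when it has at least one nonsilent mutation
    in it; silent-only genes and genes carried by fewer than
    ``min_samples`` samples are dropped.  ``samples`` fixes the column
    universe (defaults to the samples present in the catalog).
    """
    nonsilent = catalog[catalog["variant_class"] == "nonsilent"]
    if samples is None:
        samples = pd.Index(sorted(catalog["sample"].unique()))
    else:
        samples = pd.Index(samples)
        nonsilent = nonsilent[nonsilent["sample"].isin(samples)]
    if nonsilent.empty:
        logger.warning("no nonsilent mutations; empty mutation matrix")
        return AlterationMatrix(
            pd.DataFrame(index=pd.Index([], name="gene"), columns=samples, dtype=np.int8),
            "mutation",
        )
    carriers = pd.crosstab(nonsilent["gene"], nonsilent["sample"]).clip(upper=1)
    carriers = carriers.reindex(columns=samples, fill_value=0)
    keep = carriers.sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("no genes mutated in >= %d samples", min_samples)
    matrix = carriers.loc[keep].sort_index()
    matrix.index.name = "gene"
    return AlterationMatrix(matrix, "mutation")


def _atomize(segments: pd.DataFrame) -> dict[str, np.ndarray]:
    """Breakpoint-delimited atoms per chromosome (union over samples)."""
    atoms: dict[str, np.ndarray] = {}
    for chrom, group in segments.groupby("chrom", sort=True):
        cuts = np.unique(
            np.concatenate([group["start"].to_numpy(), group["end"].to_numpy() + 1])
        )
        atoms[chrom] = cuts
    return atoms


def call_cna_matrix(
    segments: pd.DataFrame,
    cutoff: float = CNA_CUTOFF,
    min_alterations: int = MIN_CNA_ALTERATIONS,
    samples: pd.Index | None = None,
) -> tuple[AlterationMatrix, AlterationMatrix]:
    """Call amplification and deletion carriers from segment means.

    Region atoms are delimited by the union of all sample breakpoints
    per chromosome.  A sample is an amplification carrier in an atom
    when its covering segment mean is >= +``cutoff`` and a deletion
    carrier when it is <= -``cutoff`` (inclusive comparisons).
    Overlapping segments within a sample resolve to the
    maximum-magnitude mean.  Atoms carried by fewer than
    ``min_alterations`` samples are dropped per matrix.

    Returns separate amplification and deletion matrices, each with a
    per-feature regions table.
    """
    if not np.isfinite(segments["seg_mean"]).all():
        raise ValueError("non-finite segment means")
    if samples is None:
        samples = pd.Index(sorted(segments["sample"].unique()))
    else:
        samples = pd.Index(samples)
        segments = segments[segments["sample"].isin(samples)]
    sample_pos = {s: i for i, s in enumerate(samples)}

    feature_ids: list[str] = []
    region_rows: list[tuple[str, int, int]] = []
    values_blocks: list[np.ndarray] = []
    overlap_logged = False
    for chrom, cuts in _atomize(segments).items():
        if len(cuts) < 2:
            continue
        starts, ends = cuts[:-1], cuts[1:] - 1
        values = np.zeros((len(starts), len(samples)))
        chrom_segs = segments[segments["chrom"] == chrom]
        for row in chrom_segs.itertuples(index=False):
            lo = np.searchsorted(starts, row.start, side="left")
            hi = np.searchsorted(starts, row.end, side="right")
            j = sample_pos[row.sample]
            current = values[lo:hi, j]
            replace = np.abs(row.seg_mean) > np.abs(current)
            if (current[replace] != 0).any() and not overlap_logged:
                logger.info("overlapping segments resolved by max-magnitude mean")
                overlap_logged = True
            current[replace] = row.seg_mean
            values[lo:hi, j] = current
        for s, e in zip(starts, ends):
            feature_ids.append(f"{chrom}:{s}-{e}")
            region_rows.append((chrom, int(s), int(e)))
        values_blocks.append(values)

    if not values_blocks:
        empty = pd.DataFrame(columns=samples, dtype=np.int8)
        return (
            AlterationMatrix(empty, "amplification"),
            AlterationMatrix(empty.copy(), "deletion"),
        )

    all_values = np.vstack(values_blocks)
    index = pd.Index(feature_ids, name="region")
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end"], index=index)

    out = []
    for kind, carriers in (
        ("amplification", all_values >= cutoff),
        ("deletion", all_values <= -cutoff),
    ):
        data = pd.DataFrame(carriers.astype(np.int8), index=index, columns=samples)
        keep = data.sum(axis=1) >= min_alterations
        out.append(AlterationMatrix(data.loc[keep], kind, regions.loc[keep]))
    return out[0], out[1]


def merge_equivalent_regions(
    matrix: AlterationMatrix, max_diff: int = MERGE_MAX_DIFF
) -> AlterationMatrix:
    """Merge neighbouring regions carrying near-identical samples.

    Adjacent regions (same chromosome, sorted by start) whose carrier
    sets differ by at most ``max_diff`` samples (symmetric difference)
    are collapsed into one feature spanning both, with carriers the OR
    (union) of the two.  Merging repeats to a fixpoint, so the result
    is idempotent under re-application.
    """
    if matrix.regions is None:
        raise ValueError("region merging requires a regions table")
    if matrix.kind not in ("amplification", "deletion"):
        raise ValueError("region merging applies to copy-number matrices only")
    if matrix.n_features == 0:
        return matrix
    order = matrix.regions.sort_values(["chrom", "start"]).index
    data = matrix.data.loc[order].to_numpy().astype(np.int8)
    regions = matrix.regions.loc[order]
    chroms = regions["chrom"].to_numpy()
    starts = regions["start"].to_numpy().copy()
    ends = regions["end"].to_numpy().copy()
    rows = [data[i] for i in range(len(order))]
    spans = list(zip(chroms, starts, ends))

    changed = True
    while changed:
        changed = False
        merged_rows: list[np.ndarray] = []
        merged_spans: list[tuple[str, int, int]] = []
        i = 0
        while i < len(rows):
            row, (chrom, s, e) = rows[i], spans[i]
            j = i + 1
            while j < len(rows) and spans[j][0] == chrom:
                diff = int(np.abs(rows[j] - row).sum())
                if diff <= max_diff:
                    row = np.maximum(row, rows[j])  # OR of carriers
                    s, e = min(s, spans[j][1]), max(e, spans[j][2])
                    changed = True
                    j += 1
                else:
                    break
            merged_rows.append(row)
            merged_spans.append((chrom, s, e))
            i = j
        rows, spans = merged_rows, merged_spans

    index = pd.Index([f"{c}:{s}-{e}" for c, s, e in spans], name="region")
    out_data = pd.DataFrame(np.vstack(rows), index=index, columns=matrix.samples)
    out_regions = pd.DataFrame(spans, columns=["chrom", "start", "end"], index=index)
    return AlterationMatrix(out_data, matrix.kind, out_regions)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a features x samples expression matrix.

    Each column is mapped onto the reference distribution given by the
    across-column mean of sorted values, so all columns share one value
    multiset afterwards.  Ties within a column receive the mean of
    their tied reference values (average-rank rule).
    """
    if table.shape[1] < 2:
        logger.warning("quantile normalization skipped: fewer than two samples")
        return table.copy()
    if table.isna().any().any():
        raise ValueError("missing values not supported in quantile normalization")
    x = table.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average tied reference values so equal inputs map to equal outputs
        svals = col[order]
        k = 0
        while k < len(svals):
            m = k
            while m + 1 < len(svals) and svals[m + 1] == svals[k]:
                m += 1
            if m > k:
                assigned[order[k : m + 1]] = reference[k : m + 1].mean()
            k = m + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=table.index, columns=table.columns)


# categorical stratifications for the clinical dummy features
_POSITIVE = frozenset({"positive", "pos", "+", "yes", "1", "true"})
_RACE_LEVELS = {
    "white": "race_white",
    "black": "race_black",
    "black or african american": "race_black",
    "asian": "race_asian",
    "latino": "race_latino",
    "hispanic": "race_latino",
    "hispanic or latino": "race_latino",
}


def _is_positive(value) -> bool:
    return str(value).strip().lower() in _POSITIVE


def clinical_dummies(clinical: pd.DataFrame) -> AlterationMatrix:
    """Stratify clinical fields into binary dummy features.

    Strata: age above its 50% / 75% quantiles (strictly above), ER/PR/
    cytokeratin positivity, one dummy per HER2 IHC level (0-3), nodes
    (none / 1-4 / more than 4), margin, menopause, and race (white /
    black / Asian / Latino).  Missing values contribute 0 (logged);
    unrecognized category levels are skipped with a log line.  Dummies
    without any carrier are dropped.
    """
    samples = clinical.index
    features: dict[str, pd.Series] = {}

    def zeros() -> pd.Series:
        return pd.Series(0, index=samples, dtype=np.int8)

    cols = {c.lower(): c for c in clinical.columns}

    if "age" in cols:
        age = pd.to_numeric(clinical[cols["age"]], errors="coerce")
        n_missing = int(age.isna().sum())
        if n_missing:
            logger.info("age missing for %d sample(s); coded 0", n_missing)
        for q, name in ((0.50, "age_gt_q50"), (0.75, "age_gt_q75")):
            cut = age.quantile(q)
            feat = zeros()
            feat[age > cut] = 1
            features[name] = feat

    for field, name in (
        ("er", "er_positive"),
        ("pr", "pr_positive"),
        ("cytokeratin", "cytokeratin_positive"),
        ("margin", "margin_positive"),
        ("menopause", "menopause"),
    ):
        if field in cols:
            raw = clinical[cols[field]]
            feat = zeros()
            feat[raw.map(_is_positive).fillna(False)] = 1
            features[name] = feat

    if "her2" in cols:
        her2 = pd.to_numeric(clinical[cols["her2"]], errors="coerce")
        bad = her2.notna() & ~her2.isin([0, 1, 2, 3])
        if bad.any():
            logger.info("unrecognized HER2 level(s) skipped: %s", her2[bad].unique())
        for level in (0, 1, 2, 3):
            feat = zeros()
            feat[her2 == level] = 1
            features[f"her2_{level}"] = feat

    if "nodes" in cols:
        nodes = pd.to_numeric(clinical[cols["nodes"]], errors="coerce")
        strata = {
            "nodes_none": nodes == 0,
            "nodes_1to4": (nodes >= 1) & (nodes <= 4),
            "nodes_gt4": nodes > 4,
        }
        for name, mask in strata.items():
            feat = zeros()
            feat[mask.fillna(False)] = 1
            features[name] = feat

    if "race" in cols:
        raw = clinical[cols["race"]].astype(str).str.strip().str.lower()
        known = raw.map(_RACE_LEVELS)
        unknown = raw[known.isna() & raw.notna() & (raw != "nan")].unique()
        if len(unknown):
            logger.info("unrecognized race level(s) skipped: %s", list(unknown))
        for name in sorted(set(_RACE_LEVELS.values())):
            feat = zeros()
            feat[known == name] = 1
            features[name] = feat

    if not features:
        raise ValueError("no recognized clinical columns")
    data = pd.DataFrame(features).T
    data = data.loc[data.sum(axis=1) > 0]
    data.index.name = "stratum"
    return AlterationMatrix(data, "clinical")


def mutation_burden(catalog: pd.DataFrame, samples: pd.Index | None = None) -> pd.Series:
    """Per-sample count of nonsilent mutation records.

    Samples absent from the catalog (but listed in ``samples``) get 0.
    """
    nonsilent = catalog[catalog["variant_class"] == "nonsilent"]
    counts = nonsilent.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(pd.Index(samples), fill_value=0)
    return counts.astype(int).rename("mutation_burden")
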