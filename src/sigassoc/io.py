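"""Readers and writers for the tabular dialects the pipeline consumes.

All inputs are tab-separated text:

* exposure table — samples x signatures matrix of weights in [0, 1]
  (deconstructSigs-style output, e.g. columns ``Sig.2.APOBEC``), with
  empty cells / NA marking samples lacking a signature estimate;
* MAF subset — somatic mutations with ``Tumor_Sample_Barcode``,
  ``Hugo_Symbol`` and ``Variant_Classification`` columns;
* SEG — copy-number segments with ``Sample``, ``Chromosome``,
  ``Start``, ``End``, ``Segment_Mean`` (1-based inclusive coordinates);
* feature matrix — features as rows, samples as columns, header row of
  sample ids (used for expression layers and for writing results);
* clinical table — one row per sample with the demographic /
  receptor-status columns used to build dummy variables.

TCGA-style sample barcodes encode aliquot detail beyond the patient
sample; barcodes are truncated to a configurable prefix (default 12
characters, the TCGA participant id) so tables join on a shared
universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default barcode prefix length used to join samples across tables
BARCODE_PREFIX = 12

#: MAF Variant_Classification values treated as silent (non-coding-changing);
#: anything else is a coding-changing, i.e. nonsilent, event.
SILENT_CLASSES = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
    }
)

MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")
SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Segment_Mean")


def truncate_barcode(barcodes, prefix: int = BARCODE_PREFIX):
    """Truncate sample barcodes to their joining prefix."""
    return pd.Index(barcodes).astype(str).str[:prefix]


def read_exposures(path, prefix: int = BARCODE_PREFIX) -> pd.DataFrame:
    """Read a samples x signatures weight table.

    Weights must be in [0, 1] where present; per-sample sums may not
    exceed 1 (within rounding).  Missing cells stay NaN — a sample with
    no signature estimate is excluded per analysis, not imputed.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = truncate_barcode(table.index, prefix)
    if not table.index.is_unique:
        raise ValueError("duplicate sample ids in exposure table after truncation")
    values = table.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if present.any():
        if values[present].min() < 0 or values[present].max() > 1 + 1e-6:
            raise ValueError("exposure weights must lie in [0, 1]")
    sums = np.where(present, values, 0.0).sum(axis=1)
    if (sums > 1 + 1e-6).any():
        raise ValueError("per-sample exposure weights sum above 1")
    return table.astype(float)


def classify_variant(variant_classification: str) -> str:
    """Map a MAF Variant_Classification string to silent/nonsilent."""
    return "silent" if variant_classification in SILENT_CLASSES else "nonsilent"


def read_maf(path, prefix: int = BARCODE_PREFIX) -> pd.DataFrame:
    """Read a MAF subset into a long-form mutation catalog.

    Returns a DataFrame with columns ``sample``, ``gene``,
    ``variant_class`` (silent/nonsilent), de-duplicated on those three
    columns.
    """
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF file lacks required columns {missing}")
    catalog = pd.DataFrame(
        {
            "sample": truncate_barcode(maf["Tumor_Sample_Barcode"], prefix),
            "gene": maf["Hugo_Symbol"].astype(str),
            "variant_class": maf["Variant_Classification"].map(classify_variant),
        }
    )
    return catalog.drop_duplicates(ignore_index=True)


def read_seg(path, prefix: int = BARCODE_PREFIX) -> pd.DataFrame:
    """Read a SEG file of copy-number segments.

    Coordinates are 1-based inclusive.  Returns columns ``sample``,
    ``chrom``, ``start``, ``end``, ``seg_mean``.
    """
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"SEG file lacks required columns {missing}")
    out = pd.DataFrame(
        {
            "sample": truncate_barcode(seg["Sample"], prefix),
            "chrom": seg["Chromosome"].astype(str),
            "start": seg["Start"].astype(np.int64),
            "end": seg["End"].astype(np.int64),
            "seg_mean": seg["Segment_Mean"].astype(float),
        }
    )
    if (out["start"] > out["end"]).any():
        raise ValueError("SEG segments with start > end")
    if not np.isfinite(out["seg_mean"]).all():
        raise ValueError("non-finite segment means")
    return out


def read_matrix(path, prefix: int | None = BARCODE_PREFIX) -> pd.DataFrame:
    """Read a features x samples TSV matrix (header row of sample ids)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if prefix is not None:
        table.columns = truncate_barcode(table.columns, prefix)
    if not table.columns.is_unique:
        # aliquot-level duplicates collapse onto one sample: keep the first
        logger.warning("duplicate sample columns after truncation; keeping first")
        table = table.loc[:, ~table.columns.duplicated()]
    return table.astype(float)


def write_matrix(table: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV."""
    table.to_csv(path, sep="\t")


def read_clinical(path, prefix: int = BARCODE_PREFIX) -> pd.DataFrame:
    """Read a clinical table indexed by sample id (first column)."""
    clin = pd.read_csv(path, sep="\t", index_col=0)
    clin.index = truncate_barcode(clin.index, prefix)
    if not clin.index.is_unique:
        logger.warning("duplicate clinical rows after truncation; keeping first")
        clin = clin.loc[~clin.index.duplicated()]
    return clin


def sample_universe(
    exposures: pd.DataFrame,
    catalog: pd.DataFrame,
    segments: pd.DataFrame,
    mrna: pd.DataFrame,
) -> pd.Index:
    """Shared sample universe for every analysis.

    Samples must appear in the mutation, copy-number and mRNA layers
    and carry at least one non-missing signature estimate; miRNA and
    protein layers are optional and do not restrict the universe.
    """
    with_ms = exposures.index[exposures.notna().any(axis=1)]
    universe = (
        pd.Index(with_ms)
        .intersection(pd.Index(catalog["sample"].unique()))
        .intersection(pd.Index(segments["sample"].unique()))
        .intersection(mrna.columns)
    )
    return universe.sort_values()
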