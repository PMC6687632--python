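"""Core in-memory containers shared across the pipeline.

Tables are plain pandas objects wherever possible:

* signature exposures — ``DataFrame`` samples x signatures, weights in
  [0, 1], ``NaN`` marking a missing estimate;
* mutation catalogs — long-form ``DataFrame`` with columns
  ``sample``, ``gene``, ``variant_class`` (``silent``/``nonsilent``);
* expression — ``DataFrame`` features x samples.

Binary alteration features carry extra per-feature metadata (kind,
genomic region), so they get a small dataclass wrapper around the
0/1 carrier matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised feature kinds for binary alteration features
FEATURE_KINDS = ("mutation", "amplification", "deletion", "clinical")

REGION_COLUMNS = ("chrom", "start", "end")


@dataclass
class AlterationMatrix:
    """Binary features x samples carrier matrix.

    Parameters
    ----------
    data
        0/1 integer DataFrame, one row per feature, one column per
        sample.  Feature ids are the row index and must be unique.
    kind
        One of :data:`FEATURE_KINDS`; a matrix holds a single kind
        (mutations, amplifications, deletions or clinical dummies are
        analysed separately).
    regions
        Optional per-feature genomic spans (columns ``chrom``,
        ``start``, ``end``; 1-based inclusive coordinates), indexed
        like ``data``.  Present for copy-number feature matrices.
    """

    data: pd.DataFrame
    kind: str
    regions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.data.index.is_unique:
            raise ValueError("feature ids must be unique")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("carrier matrix must be binary")
        self.data = self.data.astype(np.int8)
        if self.regions is not None:
            missing = [c for c in REGION_COLUMNS if c not in self.regions.columns]
            if missing:
                raise ValueError(f"regions table lacks columns {missing}")
            if not self.regions.index.equals(self.data.index):
                self.regions = self.regions.loc[self.data.index]

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def carrier_counts(self) -> pd.Series:
        return self.data.sum(axis=1)

    def restrict_samples(self, samples) -> "AlterationMatrix":
        """Subset to ``samples`` (order preserved); absent samples error."""
        sub = self.data.loc[:, list(samples)]
        regions = None if self.regions is None else self.regions.copy()
        return AlterationMatrix(sub, self.kind, regions)

    def drop_empty_features(self) -> "AlterationMatrix":
        keep = self.data.sum(axis=1) > 0
        regions = None if self.regions is None else self.regions.loc[keep]
        return AlterationMatrix(self.data.loc[keep], self.kind, regions)


# cluster labels for the three-centroid discretization
ZERO, MID, HIGH = 0, 1, 2
LABEL_NAMES = {ZERO: "ZERO", MID: "MID", HIGH: "HIGH"}


@dataclass
class TriClusterAssignment:
    """Result of three-centroid k-means on a 1-D vector.

    ``labels`` holds 0 (ZERO), 1 (MID) or 2 (HIGH) per input point,
    named by ascending centroid.  ``degenerate`` is set when the input
    had fewer than three distinct values, in which case downstream
    association tests skip the vector.
    """

    labels: np.ndarray
    centroids: np.ndarray
    degenerate: bool
    iterations: int
    index: pd.Index | None = field(default=None, repr=False)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def cluster_sizes(self) -> tuple[int, int, int]:
        return tuple(int((self.labels == c).sum()) for c in (ZERO, MID, HIGH))

    def has_extremes(self) -> bool:
        """True when both extreme clusters are non-empty and usable."""
        sizes = self.cluster_sizes
        return not self.degenerate and sizes[ZERO] > 0 and sizes[HIGH] > 0

    def to_frame(self) -> pd.DataFrame:
        """Two-column export (sample_id, label) for TSV round-trips."""
        idx = self.index if self.index is not None else pd.RangeIndex(len(self.labels))
        return pd.DataFrame(
            {"sample_id": idx, "label": [LABEL_NAMES[l] for l in self.labels]}
        )
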