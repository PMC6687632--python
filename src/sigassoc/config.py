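"""Run configuration: every named threshold, with YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All inputs and thresholds of an end-to-end pipeline run.

    Defaults are the published operating points: 500-gene hypermutation
    cutoff, 3-sample gene filter, |0.5| copy-number cutoff with a
    3-carrier minimum and one-sample region merging, exposure
    binarization thresholds (0.05, 0.1, 0.2, 0.5), significance
    cutoffs 3e-4 (binary layers) and 1e-5 (expression), 10
    permutations for the FDR estimate, 100 comutation randomizations
    with rule p < 0.001.
    """

    # input paths (None = layer absent; miRNA/protein are optional)
    exposures: str | None = None
    mutations: str | None = None
    copynumber: str | None = None
    mrna: str | None = None
    mirna: str | None = None
    protein: str | None = None
    clinical: str | None = None
    output_dir: str = "sigassoc_results"

    # preprocessing
    hypermutation_max_genes: int = 500
    min_mutated_samples: int = 3
    cna_cutoff: float = 0.5
    min_cna_alterations: int = 3
    merge_max_diff: int = 1
    barcode_prefix: int = 12

    # association
    ms_thresholds: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5)
    cutoff_binary: float = 0.0003
    cutoff_expression: float = 1e-5

    # calibration
    n_permutations: int = 10
    n_randomizations: int = 100
    comutation_alpha: float = 0.001

    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.hypermutation_max_genes >= 1, "hypermutation_max_genes >= 1"),
            (self.min_mutated_samples >= 1, "min_mutated_samples >= 1"),
            (self.cna_cutoff > 0, "cna_cutoff > 0"),
            (self.min_cna_alterations >= 1, "min_cna_alterations >= 1"),
            (self.merge_max_diff >= 0, "merge_max_diff >= 0"),
            (
                all(0 < t < 1 for t in self.ms_thresholds),
                "ms_thresholds in (0, 1)",
            ),
            (0 < self.cutoff_binary < 1, "cutoff_binary in (0, 1)"),
            (0 < self.cutoff_expression < 1, "cutoff_expression in (0, 1)"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.n_randomizations >= 1, "n_randomizations >= 1"),
            (0 < self.comutation_alpha < 1, "comutation_alpha in (0, 1)"),
        ]
        for ok, rule in checks:
            if not ok:
                raise ValueError(f"config violates {rule}")
        self.ms_thresholds = tuple(float(t) for t in self.ms_thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["ms_thresholds"] = list(self.ms_thresholds)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
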