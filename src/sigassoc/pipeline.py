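"""End-to-end orchestration: preprocess -> associate -> calibrate -> comut.

:func:`run_pipeline` reads the input tables named in a
:class:`~sigassoc.config.RunConfig`, applies every preprocessing
filter, runs the association tests on each layer, calibrates them with
the permutation FDR, screens mutation comutation, and writes TSV
result tables plus a run log to the configured output directory.
Every stage is also usable on its own from the library API.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cooccurrence, io, preprocess, significance
from .config import RunConfig

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full association pipeline per ``config``.

    Returns a dict of the in-memory result tables; everything is also
    written under ``config.output_dir``.  Missing mandatory layers
    (exposures, mutations, copy number, mRNA) raise; optional layers
    (miRNA, protein, clinical) are skipped with a warning.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _attach_run_log(outdir)
    logger.info("seed=%d", config.seed)

    for layer in ("exposures", "mutations", "copynumber", "mrna"):
        if getattr(config, layer) is None:
            raise ValueError(f"mandatory input layer missing: {layer}")

    prefix = config.barcode_prefix
    exposures = io.read_exposures(config.exposures, prefix)
    catalog = io.read_maf(config.mutations, prefix)
    segments = io.read_seg(config.copynumber, prefix)
    mrna = io.read_matrix(config.mrna, prefix)

    catalog = preprocess.filter_hypermutated(catalog, config.hypermutation_max_genes)
    universe = io.sample_universe(exposures, catalog, segments, mrna)
    if len(universe) == 0:
        raise ValueError("empty sample universe after alignment")
    logger.info("sample universe: %d samples", len(universe))
    exposures = exposures.loc[universe]

    mut = preprocess.build_mutation_matrix(
        catalog, config.min_mutated_samples, samples=universe
    )
    amp, dele = preprocess.call_cna_matrix(
        segments, config.cna_cutoff, config.min_cna_alterations, samples=universe
    )
    amp = preprocess.merge_equivalent_regions(amp, config.merge_max_diff)
    dele = preprocess.merge_equivalent_regions(dele, config.merge_max_diff)
    logger.info(
        "features: %d mutated genes, %d amplified regions, %d deleted regions",
        mut.n_features,
        amp.n_features,
        dele.n_features,
    )

    expression_layers = {"mrna": mrna.loc[:, universe]}
    for name, path in (("mirna", config.mirna), ("protein", config.protein)):
        if path is None:
            logger.warning("optional layer %s absent; skipped", name)
            continue
        table = io.read_matrix(path, prefix)
        missing = universe.difference(table.columns)
        if len(missing):
            logger.warning(
                "optional layer %s lacks %d universe samples; restricting",
                name,
                len(missing),
            )
        expression_layers[name] = table.loc[:, universe.intersection(table.columns)]
    expression_layers = {
        name: preprocess.quantile_normalize(tab) for name, tab in expression_layers.items()
    }

    results: dict = {"universe": universe}
    seed_seq = np.random.SeedSequence(config.seed)

    binary_layers = {"mutation": mut, "amplification": amp, "deletion": dele}
    if config.clinical is not None:
        clinical = io.read_clinical(config.clinical, prefix)
        clinical = clinical.loc[clinical.index.intersection(universe)]
        binary_layers["clinical"] = preprocess.clinical_dummies(clinical).restrict_samples(
            clinical.index
        )
    else:
        logger.warning("optional layer clinical absent; skipped")

    for name, matrix in binary_layers.items():
        records = association.associate_binary(matrix, exposures.loc[matrix.samples])
        _write(records, outdir / f"associations_{name}.tsv")
        sig = association.significant(records, config.cutoff_binary)
        _write(sig, outdir / f"significant_{name}.tsv")
        perms = significance.permuted_pvalues(
            association.associate_binary,
            matrix,
            exposures.loc[matrix.samples],
            n_perm=config.n_permutations,
            seed=seed_seq.spawn(1)[0],
        )
        curve = significance.estimate_fdr(
            records["p_min"].to_numpy(),
            perms,
            thetas=[config.cutoff_binary],
        )
        _write(curve, outdir / f"fdr_{name}.tsv")
        logger.info(
            "layer %s: %d records, %d significant at p<%g (fdr %.3f)",
            name,
            len(records),
            len(sig),
            config.cutoff_binary,
            significance.fdr_at(curve, config.cutoff_binary),
        )
        results[name] = records
        results[f"significant_{name}"] = sig
        results[f"fdr_{name}"] = curve
        if matrix.regions is not None and not records.empty:
            manhattan = records.merge(
                matrix.regions.reset_index().rename(columns={"region": "feature_id"}),
                on="feature_id",
            )
            manhattan["neg_log10_p"] = -np.log10(manhattan["p_min"])
            _write(
                manhattan[["chrom", "start", "end", "signature_id", "neg_log10_p"]],
                outdir / f"manhattan_{name}.tsv",
            )

    for name, table in expression_layers.items():
        records = association.associate_expression(
            table, exposures, thresholds=config.ms_thresholds
        )
        _write(records, outdir / f"associations_{name}.tsv")
        sig = association.significant(records, config.cutoff_expression)
        _write(sig, outdir / f"significant_{name}.tsv")
        perms = significance.permuted_pvalues(
            association.associate_expression,
            table,
            exposures,
            n_perm=config.n_permutations,
            seed=seed_seq.spawn(1)[0],
            thresholds=config.ms_thresholds,
        )
        curve = significance.estimate_fdr(
            records["p_min"].to_numpy(), perms, thetas=[config.cutoff_expression]
        )
        _write(curve, outdir / f"fdr_{name}.tsv")
        logger.info(
            "layer %s: %d records, %d significant at p<%g (fdr %.3f)",
            name,
            len(records),
            len(sig),
            config.cutoff_expression,
            significance.fdr_at(curve, config.cutoff_expression),
        )
        results[name] = records
        results[f"significant_{name}"] = sig
        results[f"fdr_{name}"] = curve

    burden = preprocess.mutation_burden(catalog, samples=universe)
    correlations = association.signature_correlations(exposures, burden)
    _write(correlations, outdir / "signature_correlations.tsv")
    results["signature_correlations"] = correlations

    comut_genes = _comutation_gene_set(results, mut)
    if len(comut_genes) >= 2:
        records, null_p = cooccurrence.randomized_null_comutation(
            _subset_matrix(mut, comut_genes),
            n_rand=config.n_randomizations,
            seed=seed_seq.spawn(1)[0],
            alpha=config.comutation_alpha,
        )
        _write(records, outdir / "comutation.tsv")
        null_summary = pd.DataFrame(
            {
                "quantile": [0.001, 0.01, 0.05, 0.5],
                "null_p": np.quantile(null_p, [0.001, 0.01, 0.05, 0.5]),
            }
        )
        _write(null_summary, outdir / "comutation_null_summary.tsv")
        results["comutation"] = records
    else:
        logger.warning("fewer than two genes eligible for comutation screen")

    return results


def _subset_matrix(matrix, genes):
    from .containers import AlterationMatrix

    return AlterationMatrix(matrix.data.loc[genes], matrix.kind)


def _comutation_gene_set(results: dict, mut, cap: int = 60) -> list[str]:
    """Genes screened for comutation: significant ones, topped up by frequency."""
    sig = results.get("significant_mutation")
    genes: list[str] = []
    if sig is not None and not sig.empty:
        genes = list(dict.fromkeys(sig["feature_id"]))
    if len(genes) < 2:
        by_freq = mut.carrier_counts().sort_values(ascending=False)
        genes = list(dict.fromkeys(genes + list(by_freq.index[:cap])))
    return genes[:cap]


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False)
    logger.info("wrote %s (%d rows)", path.name, len(table))


def _attach_run_log(outdir: Path) -> None:
    """Mirror pipeline logging into <outdir>/run.log."""
    root = logging.getLogger("sigassoc")
    root.setLevel(logging.INFO)
    path = str(outdir / "run.log")
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == str(Path(path).resolve())
        for h in root.handlers
    ):
        handler = logging.FileHandler(path, mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(handler)
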