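"""Additive simulation model for pipeline validation and fixtures.

A synthetic signature exposure is built from four components —
mutations, copy-number regions, over-expressed genes and
under-expressed genes.  A scenario plants ``G`` causal features per
class (4G in total).  A subject that carries any planted mutated gene
or altered region, or whose value in any planted expression gene lies
in the top (over) / bottom (under) ``T``% of subjects, receives that
component's positive contribution; the exposure is the weighted sum of
the four component indicators plus uniform noise, clipped to [0, 1]:

    w = clip( sum_c weight_c * I_c + U(0, noise_scale), 0, 1 )

Background features carry no signal.  The generator emits the same
in-memory tables (and, via :func:`write_dataset`, the same file
dialects) the readers consume, so a simulated dataset exercises the
entire pipeline; sensitivity is the fraction of the 4G planted
features recovered as significant at the default cutoffs.

Defaults (package choices; configurable per scenario): 800 subjects,
0.05 planted alteration prevalence, 0.02 background alteration rate,
500 background features per layer, equal component weights of 0.25,
noise uniform on [0, 0.1], standard-normal expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import association, preprocess
from .containers import AlterationMatrix

logger = logging.getLogger(__name__)

SIGNATURE_ID = "Sig.SIM"
CLASSES = ("mutation", "cna", "over_expression", "under_expression")

DEFAULT_G_GRID = (5, 10, 20)
DEFAULT_T_GRID = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one additive-model simulation.

    ``n_planted`` is G (planted features per class) and
    ``tail_percent`` is T (the expression tail width, in percent).
    """

    n_planted: int = 5
    tail_percent: float = 10.0
    n_subjects: int = 800
    background_rate: float = 0.02
    n_background_features: int = 500
    component_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_scale: float = 0.1
    planted_prevalence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted < 1:
            raise ValueError("n_planted (G) must be >= 1")
        if not 0 < self.tail_percent <= 50:
            raise ValueError("tail_percent (T) must lie in (0, 50]")
        if any(w < 0 for w in self.component_weights):
            raise ValueError("component weights must be non-negative")
        expected = self.n_subjects * self.planted_prevalence
        if expected < 3:
            logger.warning(
                "expected planted carriers per feature (%.1f) below 3; "
                "planted alterations may not survive the frequency filter",
                expected,
            )


@dataclass
class SimulatedDataset:
    """One realisation of a scenario, in pipeline-ready tables."""

    scenario: SimulationScenario
    exposures: pd.DataFrame  # subjects x 1 signature
    catalog: pd.DataFrame  # long-form mutation catalog
    segments: pd.DataFrame  # SEG-style copy-number segments
    expression: pd.DataFrame  # genes x subjects
    planted_genes: list[str]
    planted_regions: pd.DataFrame  # chrom/start/end/kind per planted region
    planted_over: list[str]
    planted_under: list[str]

    @property
    def planted_total(self) -> int:
        return (
            len(self.planted_genes)
            + len(self.planted_regions)
            + len(self.planted_over)
            + len(self.planted_under)
        )


@dataclass
class SimulationOutcome:
    """Sensitivity of the pipeline on one simulated dataset."""

    scenario: SimulationScenario
    sensitivity_overall: float
    sensitivity_by_class: dict[str, float]
    detected_ids: dict[str, list[str]]
    planted_ids: dict[str, list[str]]


def _region_table(n_regions: int) -> pd.DataFrame:
    """Non-overlapping 100-kb region slots cycling over 22 chromosomes."""
    chroms = [str((i % 22) + 1) for i in range(n_regions)]
    slots = [i // 22 for i in range(n_regions)]
    starts = [s * 2_000_000 + 1 for s in slots]
    ends = [s + 99_999 for s in starts]
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Draw one dataset from the additive model.

    Planted binary features use ``planted_prevalence``; background
    features use ``background_rate``.  Copy-number regions alternate
    amplification (+) and deletion (-) signs.  Expression values are
    standard normal per gene; the planted tails are defined on the
    realised values (empirical T% quantiles).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    subjects = pd.Index([f"S{i:04d}" for i in range(sc.n_subjects)], name="sample")
    G, nb = sc.n_planted, sc.n_background_features

    # --- mutations -----------------------------------------------------
    planted_genes = [f"GENE_P{i:03d}" for i in range(G)]
    background_genes = [f"GENE_B{i:04d}" for i in range(nb)]
    planted_mut = rng.random((G, sc.n_subjects)) < sc.planted_prevalence
    background_mut = rng.random((nb, sc.n_subjects)) < sc.background_rate
    rows = []
    for gene, carriers in zip(planted_genes, planted_mut):
        rows.extend((subjects[j], gene, "nonsilent") for j in np.flatnonzero(carriers))
    for gene, carriers in zip(background_genes, background_mut):
        rows.extend((subjects[j], gene, "nonsilent") for j in np.flatnonzero(carriers))
    # sprinkle silent records so the nonsilent-only filters are exercised
    silent = rng.random((nb, sc.n_subjects)) < 0.005
    for gene, carriers in zip(background_genes, silent):
        rows.extend((subjects[j], gene, "silent") for j in np.flatnonzero(carriers))
    catalog = pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])
    i_mut = planted_mut.any(axis=0)

    # --- copy-number regions ------------------------------------------
    regions = _region_table(G + nb)
    planted_regions = regions.iloc[:G].copy()
    planted_regions["kind"] = [
        "amplification" if i % 2 == 0 else "deletion" for i in range(G)
    ]
    region_sign = np.array(
        [1.0 if i % 2 == 0 else -1.0 for i in range(G + nb)]
    )
    region_carriers = np.empty((G + nb, sc.n_subjects), dtype=bool)
    region_carriers[:G] = rng.random((G, sc.n_subjects)) < sc.planted_prevalence
    region_carriers[G:] = rng.random((nb, sc.n_subjects)) < sc.background_rate
    seg_rows = []
    for r in range(G + nb):
        means = region_sign[r] * (0.8 + rng.uniform(0, 0.4, size=sc.n_subjects))
        for j in np.flatnonzero(region_carriers[r]):
            seg_rows.append(
                (
                    subjects[j],
                    regions.at[r, "chrom"],
                    regions.at[r, "start"],
                    regions.at[r, "end"],
                    means[j],
                )
            )
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "seg_mean"]
    )
    i_cna = region_carriers[:G].any(axis=0)

    # --- expression ----------------------------------------------------
    planted_over = [f"EXPR_O{i:03d}" for i in range(G)]
    planted_under = [f"EXPR_U{i:03d}" for i in range(G)]
    background_expr = [f"EXPR_B{i:04d}" for i in range(nb)]
    gene_index = pd.Index(planted_over + planted_under + background_expr, name="gene")
    values = rng.standard_normal((len(gene_index), sc.n_subjects))
    expression = pd.DataFrame(values, index=gene_index, columns=subjects)
    tail = sc.tail_percent / 100.0
    over_vals = values[:G]
    under_vals = values[G : 2 * G]
    over_cut = np.quantile(over_vals, 1 - tail, axis=1, keepdims=True)
    under_cut = np.quantile(under_vals, tail, axis=1, keepdims=True)
    i_over = (over_vals >= over_cut).any(axis=0)
    i_under = (under_vals <= under_cut).any(axis=0)

    # --- additive exposure ---------------------------------------------
    w = sc.component_weights
    noise = rng.uniform(0, sc.noise_scale, size=sc.n_subjects)
    exposure = np.clip(
        w[0] * i_mut + w[1] * i_cna + w[2] * i_over + w[3] * i_under + noise, 0.0, 1.0
    )
    exposures = pd.DataFrame({SIGNATURE_ID: exposure}, index=subjects)

    return SimulatedDataset(
        scenario=sc,
        exposures=exposures,
        catalog=catalog,
        segments=segments,
        expression=expression,
        planted_genes=planted_genes,
        planted_regions=planted_regions,
        planted_over=planted_over,
        planted_under=planted_under,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset in the dialects the readers consume."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.exposures.rename_axis("sample").to_csv(
        outdir / "exposures.tsv", sep="\t"
    )
    maf = dataset.catalog.rename(
        columns={
            "sample": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "variant_class": "Variant_Classification",
        }
    )
    maf["Variant_Classification"] = maf["Variant_Classification"].map(
        {"nonsilent": "Missense_Mutation", "silent": "Silent"}
    )
    maf.to_csv(outdir / "mutations.maf.tsv", sep="\t", index=False)
    seg = dataset.segments.rename(
        columns={
            "sample": "Sample",
            "chrom": "Chromosome",
            "start": "Start",
            "end": "End",
            "seg_mean": "Segment_Mean",
        }
    )
    seg.to_csv(outdir / "copynumber.seg.tsv", sep="\t", index=False)
    dataset.expression.to_csv(outdir / "expression.tsv", sep="\t")
    dataset.planted_regions.to_csv(outdir / "planted_regions.tsv", sep="\t", index=False)


def run_association_suite(
    dataset: SimulatedDataset,
    cutoff_binary: float = association.CUTOFF_BINARY,
    cutoff_expression: float = association.CUTOFF_EXPRESSION,
) -> dict[str, pd.DataFrame]:
    """Run the preprocessing and association stages on a dataset.

    Returns the per-layer association record frames (keys ``mutation``,
    ``amplification``, ``deletion``, ``expression``) plus the
    significant subsets (``significant_<layer>``).
    """
    catalog = preprocess.filter_hypermutated(dataset.catalog)
    subjects = dataset.exposures.index
    mut = preprocess.build_mutation_matrix(catalog, samples=subjects)
    amp, dele = preprocess.call_cna_matrix(dataset.segments, samples=subjects)
    amp = preprocess.merge_equivalent_regions(amp)
    dele = preprocess.merge_equivalent_regions(dele)
    expr = preprocess.quantile_normalize(dataset.expression)

    out: dict[str, pd.DataFrame] = {}
    for layer, matrix in (("mutation", mut), ("amplification", amp), ("deletion", dele)):
        records = association.associate_binary(matrix, dataset.exposures)
        out[layer] = records
        out[f"significant_{layer}"] = association.significant(records, cutoff_binary)
        out[f"matrix_{layer}"] = matrix
    records = association.associate_expression(expr, dataset.exposures)
    out["expression"] = records
    out["significant_expression"] = association.significant(records, cutoff_expression)
    return out


def _detected_regions(
    significant: pd.DataFrame,
    matrix: AlterationMatrix,
    planted: pd.DataFrame,
    kind: str,
) -> list[str]:
    """Planted regions overlapped by a significant (possibly merged) feature."""
    hits: list[str] = []
    planted_kind = planted[planted["kind"] == kind]
    if significant.empty or planted_kind.empty:
        return hits
    sig_regions = matrix.regions.loc[
        matrix.regions.index.intersection(significant["feature_id"])
    ]
    for row in planted_kind.itertuples():
        same_chrom = sig_regions[sig_regions["chrom"] == row.chrom]
        overlap = (same_chrom["start"] <= row.end) & (same_chrom["end"] >= row.start)
        if overlap.any():
            hits.append(f"{row.chrom}:{row.start}-{row.end}")
    return hits


def evaluate_sensitivity(
    dataset: SimulatedDataset,
    cutoff_binary: float = association.CUTOFF_BINARY,
    cutoff_expression: float = association.CUTOFF_EXPRESSION,
    results: dict[str, pd.DataFrame] | None = None,
) -> SimulationOutcome:
    """Fraction of planted features recovered as significant.

    A planted mutated gene or expression gene counts as detected when
    its association record clears the layer cutoff; a planted region
    counts when any significant region feature of the matching class
    overlaps it (region features may have merged with neighbours).
    """
    if results is None:
        results = run_association_suite(dataset, cutoff_binary, cutoff_expression)

    sig_mut = set(results["significant_mutation"]["feature_id"])
    detected_mut = [g for g in dataset.planted_genes if g in sig_mut]

    detected_amp = _detected_regions(
        results["significant_amplification"],
        results["matrix_amplification"],
        dataset.planted_regions,
        "amplification",
    )
    detected_del = _detected_regions(
        results["significant_deletion"],
        results["matrix_deletion"],
        dataset.planted_regions,
        "deletion",
    )
    sig_expr = set(results["significant_expression"]["feature_id"])
    detected_over = [g for g in dataset.planted_over if g in sig_expr]
    detected_under = [g for g in dataset.planted_under if g in sig_expr]

    planted_region_ids = [
        f"{r.chrom}:{r.start}-{r.end}" for r in dataset.planted_regions.itertuples()
    ]
    planted = {
        "mutation": dataset.planted_genes,
        "cna": planted_region_ids,
        "over_expression": dataset.planted_over,
        "under_expression": dataset.planted_under,
    }
    detected = {
        "mutation": detected_mut,
        "cna": detected_amp + detected_del,
        "over_expression": detected_over,
        "under_expression": detected_under,
    }
    by_class = {
        c: len(detected[c]) / len(planted[c]) if planted[c] else float("nan")
        for c in CLASSES
    }
    total_planted = sum(len(v) for v in planted.values())
    total_detected = sum(len(v) for v in detected.values())
    return SimulationOutcome(
        scenario=dataset.scenario,
        sensitivity_overall=total_detected / total_planted,
        sensitivity_by_class=by_class,
        detected_ids=detected,
        planted_ids=planted,
    )


def run_grid(
    g_values=DEFAULT_G_GRID,
    t_values=DEFAULT_T_GRID,
    n_replicates: int = 100,
    seed: int = 0,
    **scenario_kwargs,
) -> pd.DataFrame:
    """Mean sensitivity per (G, T) scenario over seeded replicates.

    Returns one row per grid cell with the mean and standard deviation
    of overall sensitivity and the per-class means.  The same ``seed``
    reproduces the same table.
    """
    if not len(g_values) or not len(t_values):
        raise ValueError("non-empty G and T grids required")
    master = np.random.default_rng(seed)
    rows = []
    for g in g_values:
        for t in t_values:
            sens = []
            by_class = {c: [] for c in CLASSES}
            for _ in range(n_replicates):
                rep_seed = int(master.integers(2**31))
                scenario = SimulationScenario(
                    n_planted=g, tail_percent=t, seed=rep_seed, **scenario_kwargs
                )
                outcome = evaluate_sensitivity(simulate_dataset(scenario))
                sens.append(outcome.sensitivity_overall)
                for c in CLASSES:
                    by_class[c].append(outcome.sensitivity_by_class[c])
            row = {
                "G": g,
                "T": t,
                "n_replicates": n_replicates,
                "mean_sensitivity": float(np.mean(sens)),
                "sd_sensitivity": float(np.std(sens, ddof=1)) if len(sens) > 1 else float("nan"),
            }
            row.update(
                {f"mean_{c}": float(np.nanmean(by_class[c])) for c in CLASSES}
            )
            rows.append(row)
            logger.info(
                "grid cell G=%d T=%g: mean sensitivity %.3f", g, t, row["mean_sensitivity"]
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture generators for calibration checks


def null_binary_dataset(
    n_samples: int = 200,
    n_features: int = 500,
    carrier_rate: float = 0.1,
    seed: int = 0,
    n_signatures: int = 30,
) -> tuple[AlterationMatrix, pd.DataFrame]:
    """Pure-null fixture: binary features independent of exposures.

    Emulates the calibration setting of the real analysis: a full
    complement of signatures (30, the standard catalog size) whose
    per-layer p-values are pooled, each with a zero-inflated exposure
    vector (40% exact zeros, the rest uniform) mimicking real weight
    vectors; features are iid Bernoulli(``carrier_rate``).  The
    per-sample sum-to-at-most-one constraint of real weight tables is
    not enforced — the discretization is per-signature and never sees
    the sum.
    """
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample")
    columns = {}
    for s in range(n_signatures):
        weights = rng.uniform(0, 1, size=n_samples)
        weights[rng.random(n_samples) < 0.4] = 0.0
        columns[f"Sig.{s + 1}" if n_signatures > 1 else SIGNATURE_ID] = weights
    exposures = pd.DataFrame(columns, index=samples)
    data = (rng.random((n_features, n_samples)) < carrier_rate).astype(np.int8)
    matrix = AlterationMatrix(
        pd.DataFrame(
            data,
            index=pd.Index([f"G{i:04d}" for i in range(n_features)], name="gene"),
            columns=samples,
        ),
        "mutation",
    )
    return matrix, exposures


def planted_binary_dataset(
    n_samples: int = 200,
    n_features: int = 500,
    n_planted: int = 20,
    carrier_rate: float = 0.1,
    seed: int = 0,
    n_signatures: int = 30,
) -> tuple[AlterationMatrix, pd.DataFrame, list[str]]:
    """Null fixture with strongly associated planted features.

    The planted features' carriers are drawn from the top quartile of
    the first signature's exposures, so their association with its
    HIGH cluster is extreme; the remaining features are pure noise as
    in :func:`null_binary_dataset`.
    """
    rng = np.random.default_rng(seed)
    matrix, exposures = null_binary_dataset(
        n_samples, n_features, carrier_rate, seed, n_signatures
    )
    weights = exposures.iloc[:, 0].to_numpy()
    top = np.argsort(weights)[-n_samples // 4 :]
    data = matrix.data.to_numpy().copy()
    n_carriers = max(3, int(round(carrier_rate * n_samples)))
    planted_ids = []
    for i in range(n_planted):
        carriers = rng.choice(top, size=min(n_carriers, len(top)), replace=False)
        data[i, :] = 0
        data[i, carriers] = 1
        planted_ids.append(matrix.feature_ids[i])
    out = AlterationMatrix(
        pd.DataFrame(data, index=matrix.feature_ids, columns=matrix.samples),
        "mutation",
    )
    return out, exposures, planted_ids
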