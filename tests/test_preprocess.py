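"""Preprocessing filters, CNA calling/merging and normalization."""

import numpy as np
import pandas as pd
import pytest

from sigassoc.containers import AlterationMatrix
from sigassoc.preprocess import (
    build_mutation_matrix,
    call_cna_matrix,
    clinical_dummies,
    filter_hypermutated,
    merge_equivalent_regions,
    mutation_burden,
    quantile_normalize,
)

from conftest import make_matrix


def _catalog_with_gene_count(sample: str, n_genes: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": sample,
            "gene": [f"g{i}" for i in range(n_genes)],
            "variant_class": "nonsilent",
        }
    )


class TestHypermutationFilter:
    def test_501_genes_removed_500_retained(self):
        catalog = pd.concat(
            [_catalog_with_gene_count("hyper", 501), _catalog_with_gene_count("ok", 500)],
            ignore_index=True,
        )
        out = filter_hypermutated(catalog, max_genes=500)
        assert set(out["sample"]) == {"ok"}

    def test_silent_mutations_do_not_count(self):
        catalog = _catalog_with_gene_count("s", 400)
        silent = _catalog_with_gene_count("s", 300).assign(
            gene=lambda d: "x" + d["gene"], variant_class="silent"
        )
        out = filter_hypermutated(pd.concat([catalog, silent]), max_genes=500)
        assert set(out["sample"]) == {"s"}

    def test_empty_catalog_identity(self):
        empty = pd.DataFrame(columns=["sample", "gene", "variant_class"])
        assert filter_hypermutated(empty).empty

    def test_order_invariance(self, toy_catalog):
        shuffled = toy_catalog.sample(frac=1, random_state=0)
        a = filter_hypermutated(toy_catalog, max_genes=1)
        b = filter_hypermutated(shuffled, max_genes=1)
        assert set(a["sample"]) == set(b["sample"])


class TestMutationMatrix:
    def test_min_sample_boundary(self, toy_catalog):
        m = build_mutation_matrix(toy_catalog, min_samples=3)
        # g1 in 4 samples kept; g2 in 2 dropped; g3 silent-only dropped
        assert list(m.feature_ids) == ["g1"]
        assert m.data.loc["g1"].sum() == 4

    def test_exactly_three_samples_included(self, toy_catalog):
        extra = pd.DataFrame(
            [["s3", "g2", "nonsilent"]], columns=["sample", "gene", "variant_class"]
        )
        m = build_mutation_matrix(pd.concat([toy_catalog, extra]), min_samples=3)
        assert set(m.feature_ids) == {"g1", "g2"}

    def test_silent_only_gene_excluded_even_if_common(self):
        catalog = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(10)],
                "gene": "g_silent",
                "variant_class": "silent",
            }
        )
        m = build_mutation_matrix(catalog, min_samples=3)
        assert m.n_features == 0

    def test_sample_order_permutation_commutes(self, toy_catalog):
        a = build_mutation_matrix(toy_catalog)
        b = build_mutation_matrix(toy_catalog.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCnaCalling:
    def test_cutoff_calls(self, toy_segments):
        amp, dele = call_cna_matrix(toy_segments, min_alterations=1)
        first_amp = amp.data.loc["1:100-199"]
        assert first_amp["s1"] == 1 and first_amp["s2"] == 1
        assert first_amp["s4"] == 0  # 0.3 below both cutoffs
        assert dele.data.loc["1:100-199", "s3"] == 1
        assert "1:200-299" not in dele.feature_ids  # no deletion carriers there

    def test_inclusive_cutoff(self):
        seg = pd.DataFrame(
            [["s1", "1", 1, 10, 0.5], ["s2", "1", 1, 10, -0.5]],
            columns=["sample", "chrom", "start", "end", "seg_mean"],
        )
        amp, dele = call_cna_matrix(seg, min_alterations=1)
        assert amp.data.loc["1:1-10", "s1"] == 1
        assert dele.data.loc["1:1-10", "s2"] == 1

    def test_min_alterations_filter(self, toy_segments):
        amp, _ = call_cna_matrix(toy_segments, min_alterations=3)
        assert "1:100-199" not in amp.feature_ids  # only two amp carriers
        assert "1:200-299" in amp.feature_ids  # three carriers (0.55 >= 0.5)

    def test_segment_splitting_invariance(self):
        whole = pd.DataFrame(
            [["s1", "1", 1, 100, 0.8], ["s2", "1", 1, 100, 0.9]],
            columns=["sample", "chrom", "start", "end", "seg_mean"],
        )
        split = pd.DataFrame(
            [
                ["s1", "1", 1, 50, 0.8],
                ["s1", "1", 51, 100, 0.8],
                ["s2", "1", 1, 100, 0.9],
            ],
            columns=["sample", "chrom", "start", "end", "seg_mean"],
        )
        amp_w, _ = call_cna_matrix(whole, min_alterations=1)
        amp_s, _ = call_cna_matrix(split, min_alterations=1)
        # the split introduces an extra breakpoint but every atom keeps the
        # carriers of the segment covering it
        assert amp_w.n_features == 1 and amp_s.n_features == 2
        for _, row in amp_s.data.iterrows():
            assert (row == amp_w.data.iloc[0]).all()

    def test_overlap_resolved_by_max_magnitude(self):
        seg = pd.DataFrame(
            [["s1", "1", 1, 100, 0.2], ["s1", "1", 1, 100, -0.9]],
            columns=["sample", "chrom", "start", "end", "seg_mean"],
        )
        amp, dele = call_cna_matrix(seg, min_alterations=1)
        assert amp.n_features == 0
        assert dele.data.loc["1:1-100", "s1"] == 1


class TestRegionMerging:
    samples = ["s1", "s2", "s3", "s4"]

    def _matrix(self, rows):
        regions = pd.DataFrame(
            {
                "chrom": "1",
                "start": [100 * (i + 1) for i in range(len(rows))],
                "end": [100 * (i + 1) + 99 for i in range(len(rows))],
            },
            index=pd.Index([f"r{i}" for i in range(len(rows))], name="region"),
        )
        data = pd.DataFrame(rows, index=regions.index, columns=self.samples)
        return AlterationMatrix(data, "amplification", regions)

    def test_one_sample_difference_merged_with_or(self):
        m = self._matrix([[1, 1, 1, 0], [1, 1, 0, 0]])
        out = merge_equivalent_regions(m)
        assert out.n_features == 1
        assert list(out.data.iloc[0]) == [1, 1, 1, 0]
        assert out.regions.iloc[0]["start"] == 100 and out.regions.iloc[0]["end"] == 299

    def test_identical_carriers_merged_unchanged(self):
        m = self._matrix([[1, 0, 1, 0], [1, 0, 1, 0]])
        out = merge_equivalent_regions(m)
        assert out.n_features == 1
        assert list(out.data.iloc[0]) == [1, 0, 1, 0]

    def test_symmetric_difference_two_not_merged(self):
        m = self._matrix([[1, 1, 0, 0], [0, 0, 1, 1]])
        out = merge_equivalent_regions(m)
        assert out.n_features == 2

    def test_idempotent_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rows = (rng.random((8, 4)) < 0.5).astype(int)
            m = self._matrix(list(rows))
            once = merge_equivalent_regions(m)
            twice = merge_equivalent_regions(once)
            pd.testing.assert_frame_equal(once.data, twice.data)

    def test_different_chromosomes_never_merge(self):
        regions = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [100, 100], "end": [199, 199]},
            index=pd.Index(["r0", "r1"], name="region"),
        )
        data = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0]], index=regions.index, columns=self.samples
        )
        out = merge_equivalent_regions(AlterationMatrix(data, "deletion", regions))
        assert out.n_features == 2

    def test_rejects_non_cna_matrix(self):
        m = make_matrix({"g1": [1, 0]}, ["s1", "s2"], kind="mutation")
        with pytest.raises(ValueError):
            merge_equivalent_regions(m)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        t = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(t), t)

    def test_two_column_hand_example(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(t)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_ties_share_mean_reference_value(self):
        # reference = mean sorted = (1.5, 2.5, 4.5); the tied 1s in column a
        # take mean(1.5, 2.5) = 2.0
        t = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(t)
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out["b"], [1.5, 2.5, 4.5])

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(50, 6)))
        out = quantile_normalize(t).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_single_sample_returned_unchanged(self):
        t = pd.DataFrame({"a": [3.0, 1.0]})
        pd.testing.assert_frame_equal(quantile_normalize(t), t)


class TestClinicalDummies:
    def _clinical(self):
        return pd.DataFrame(
            {
                "age": [40, 50, 60, 80, np.nan],
                "er": ["Positive", "Negative", "Positive", None, "Positive"],
                "her2": [3, 2, 1, 0, None],
                "nodes": [0, 2, 5, 4, None],
                "race": ["White", "Black", "Asian", "Latino", "Martian"],
            },
            index=[f"s{i}" for i in range(5)],
        )

    def test_her2_level_dummies(self):
        m = clinical_dummies(self._clinical())
        assert m.data.loc["her2_3", "s0"] == 1
        assert m.data.loc["her2_2", "s0"] == 0
        assert m.data.loc["her2_0", "s3"] == 1

    def test_nodes_strata(self):
        m = clinical_dummies(self._clinical())
        assert m.data.loc["nodes_gt4", "s2"] == 1
        assert m.data.loc["nodes_1to4", "s2"] == 0
        assert m.data.loc["nodes_1to4", "s3"] == 1  # nodes = 4 inclusive
        assert m.data.loc["nodes_none", "s0"] == 1

    def test_age_quantile_strictly_above(self):
        clin = pd.DataFrame({"age": [40.0, 50.0, 60.0]}, index=["a", "b", "c"])
        m = clinical_dummies(clin)
        # Q50 = 50; sample exactly at the quantile is not "higher than"
        assert m.data.loc["age_gt_q50", "b"] == 0
        assert m.data.loc["age_gt_q50", "c"] == 1

    def test_missing_coded_zero_and_unknown_levels_skipped(self):
        m = clinical_dummies(self._clinical())
        assert m.data.loc["er_positive", "s3"] == 0  # missing ER
        carriers = m.data.loc[[f for f in m.feature_ids if f.startswith("race_")]]
        assert carriers["s4"].sum() == 0  # unrecognized race level

    def test_carrierless_dummies_dropped(self):
        clin = pd.DataFrame({"er": ["Negative", "Negative"]}, index=["a", "b"])
        m = clinical_dummies(clin)
        assert m.n_features == 0


class TestMutationBurden:
    def test_nonsilent_only(self, toy_catalog):
        burden = mutation_burden(toy_catalog)
        assert burden["s1"] == 2  # 2 nonsilent, silent g3 not counted
        assert burden["s4"] == 1

    def test_absent_sample_zero(self, toy_catalog):
        burden = mutation_burden(toy_catalog, samples=pd.Index(["s1", "s9"]))
        assert burden["s9"] == 0

    def test_empty_catalog_all_zero(self):
        empty = pd.DataFrame(columns=["sample", "gene", "variant_class"])
        burden = mutation_burden(empty, samples=pd.Index(["a", "b"]))
        assert (burden == 0).all()
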