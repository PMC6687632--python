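"""Hypergeometric association tests, correlation and rank-sum screens."""

import math

import numpy as np
import pandas as pd
import pytest

from sigassoc.association import (
    associate_binary,
    associate_expression,
    hypergeom_tails,
    region_expression_check,
    signature_correlations,
    significant,
)

from conftest import make_matrix


def enumerated_tails(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact tails by direct enumeration of the hypergeometric pmf.

    Independent oracle: integer combinatorics only, no scipy.
    """
    denom = math.comb(N, n)
    pmf = {
        i: math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(max(0, K + n - N), min(K, n) + 1)
    }
    over = sum(v for i, v in pmf.items() if i >= k) / denom
    under = sum(v for i, v in pmf.items() if i <= k) / denom
    return over, under


class TestHypergeomTails:
    def test_zero_successes_full_over_tail(self):
        assert hypergeom_tails(0, 3, 4, 10)[0] == pytest.approx(1.0)

    def test_known_enumeration_value(self):
        # C(4,4)*C(6,1)/C(10,5) = 6/252 = 1/42
        p_over, _ = hypergeom_tails(4, 4, 5, 10)
        assert p_over == pytest.approx(1 / 42, abs=1e-15)

    def test_degenerate_support(self):
        p_over, p_under = hypergeom_tails(5, 5, 5, 5)
        assert p_over == pytest.approx(1.0) and p_under == pytest.approx(1.0)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            hypergeom_tails(5, 4, 5, 10)

    def test_matches_enumeration_on_sample(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            expected = enumerated_tails(k, K, n, N)
            got = hypergeom_tails(k, K, n, N)
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_monotone_in_k_and_shared_atom(self):
        K, n, N = 6, 8, 20
        overs, unders = [], []
        for k in range(0, min(K, n) + 1):
            o, u = hypergeom_tails(k, K, n, N)
            overs.append(o)
            unders.append(u)
            assert o + u >= 1.0 - 1e-12  # both tails include P(X = k)
        assert all(a >= b - 1e-15 for a, b in zip(overs, overs[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(unders, unders[1:]))


@pytest.fixture
def triple_cluster_exposures():
    samples = [f"s{i}" for i in range(12)]
    weights = [0.0] * 4 + [0.5] * 4 + [1.0] * 4
    return pd.DataFrame({"Sig.A": weights}, index=samples)


class TestAssociateBinary:
    def test_feature_matching_high_cluster_hits_floor(self, triple_cluster_exposures):
        samples = list(triple_cluster_exposures.index)
        carriers = [0] * 8 + [1] * 4
        m = make_matrix({"gene": carriers}, samples)
        rec = associate_binary(m, triple_cluster_exposures).iloc[0]
        # all K = n = 4 carriers in HIGH within a universe of N = 8:
        # the minimum achievable over-tail is 1 / C(8, 4)
        assert rec["p_over"] == pytest.approx(1 / math.comb(8, 4), abs=1e-12)
        assert rec["direction"] == "over"

    def test_no_carriers_in_universe_uninformative(self, triple_cluster_exposures):
        samples = list(triple_cluster_exposures.index)
        carriers = [0] * 4 + [1] * 4 + [0] * 4  # only MID samples carry
        m = make_matrix({"gene": carriers}, samples)
        rec = associate_binary(m, triple_cluster_exposures).iloc[0]
        assert rec["p_over"] == pytest.approx(1.0)
        assert not rec["informative"]

    def test_under_representation_detected(self, triple_cluster_exposures):
        samples = list(triple_cluster_exposures.index)
        carriers = [1] * 4 + [0] * 8  # carriers exactly the ZERO cluster
        m = make_matrix({"gene": carriers}, samples)
        rec = associate_binary(m, triple_cluster_exposures).iloc[0]
        assert rec["direction"] == "under"
        assert rec["p_under"] == pytest.approx(1 / math.comb(8, 4), abs=1e-12)

    def test_degenerate_signature_skipped(self):
        samples = ["a", "b", "c", "d"]
        exposures = pd.DataFrame({"Sig.const": [0.2] * 4}, index=samples)
        m = make_matrix({"g": [1, 0, 1, 0]}, samples)
        assert associate_binary(m, exposures).empty

    def test_missing_weights_excluded_per_signature(self, triple_cluster_exposures):
        exposures = triple_cluster_exposures.copy()
        exposures.iloc[0, 0] = np.nan
        samples = list(exposures.index)
        m = make_matrix({"g": [1] * 12}, samples)
        rec = associate_binary(m, exposures).iloc[0]
        assert rec["N"] == 7  # one ZERO sample dropped for missing weight

    def test_invariant_to_sample_and_feature_order(self, triple_cluster_exposures):
        rng = np.random.default_rng(0)
        samples = list(triple_cluster_exposures.index)
        data = {f"g{i}": list((rng.random(12) < 0.4).astype(int)) for i in range(6)}
        m = make_matrix(data, samples)
        rec = associate_binary(m, triple_cluster_exposures)
        perm = rng.permutation(12)
        m2 = make_matrix(
            {k: list(np.array(v)[perm]) for k, v in reversed(data.items())},
            list(np.array(samples)[perm]),
        )
        rec2 = associate_binary(m2, triple_cluster_exposures)
        merged = rec.merge(rec2, on="feature_id", suffixes=("", "_p"))
        assert np.allclose(merged["p_over"], merged["p_over_p"])
        assert np.allclose(merged["p_under"], merged["p_under_p"])


class TestAssociateExpression:
    def _toy(self):
        samples = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(
            {"geneX": [0.0] * 4 + [5.0] * 4 + [10.0] * 4}, index=samples
        ).T
        weights = [0.0] * 8 + [0.2] * 4  # positives exactly the expression-HIGH
        exposures = pd.DataFrame({"Sig.A": weights}, index=samples)
        return expr, exposures

    def test_positives_in_expression_high_cluster(self):
        expr, exposures = self._toy()
        rec = associate_expression(expr, exposures).iloc[0]
        # K = k = 4, n = 4, N = 8: p_over = hypergeom floor 1/C(8,4)
        assert rec["p_min"] == pytest.approx(1 / math.comb(8, 4), abs=1e-12)
        assert rec["direction"] == "over"
        assert rec["ms_threshold"] in (0.05, 0.1)

    def test_constant_feature_skipped(self):
        samples = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame({"flat": [1.0] * 6}, index=samples).T
        exposures = pd.DataFrame({"Sig.A": [0, 0, 0, 0.5, 1, 1]}, index=samples)
        assert associate_expression(expr, exposures).empty

    def test_empty_positive_threshold_does_not_dominate(self):
        expr, exposures = self._toy()
        # no weight exceeds 0.5, so that threshold contributes p = 1 both ways
        summary, detail = associate_expression(expr, exposures, return_detail=True)
        at_half = detail[detail["ms_threshold"] == 0.5]
        assert (at_half["p_over"] == 1.0).all()
        assert summary.iloc[0]["p_min"] < 1.0

    def test_detail_minimum_matches_summary(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.normal(size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=samples,
        )
        exposures = pd.DataFrame({"Sig.A": rng.uniform(0, 1, 30)}, index=samples)
        summary, detail = associate_expression(expr, exposures, return_detail=True)
        for _, row in summary.iterrows():
            sub = detail[detail["feature_id"] == row["feature_id"]]
            assert row["p_min"] == pytest.approx(
                min(sub["p_over"].min(), sub["p_under"].min()), abs=1e-12
            )


class TestSignatureCorrelations:
    def test_identical_vectors_flagged(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=50)
        table = pd.DataFrame({"A": v, "B": v})
        rec = signature_correlations(table).iloc[0]
        assert rec["r"] == pytest.approx(1.0)
        assert rec["flagged"]

    def test_negation_gives_minus_one(self):
        v = np.linspace(0, 1, 20)
        table = pd.DataFrame({"A": v, "B": 1 - v})
        assert signature_correlations(table).iloc[0]["r"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([0.1, 0.4, 0.35, 0.8, 0.2, 0.9, 0.05, 0.6, 0.3, 0.7])
        b = np.array([0.2, 0.5, 0.3, 0.9, 0.1, 0.8, 0.15, 0.55, 0.35, 0.6])
        expected = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        rec = signature_correlations(pd.DataFrame({"A": a, "B": b})).iloc[0]
        assert rec["r"] == pytest.approx(expected, abs=1e-12)

    def test_burden_appended_and_correlated(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(30)]
        table = pd.DataFrame({"A": rng.uniform(size=30)}, index=idx)
        burden = pd.Series(rng.integers(0, 100, 30), index=idx)
        rec = signature_correlations(table, mutation_burden=burden)
        assert set(rec["signature_b"]) == {"mutation_burden"}

    def test_too_few_pairs_not_flagged(self):
        table = pd.DataFrame({"A": [0.1, np.nan, 0.3], "B": [np.nan, 0.2, 0.4]})
        rec = signature_correlations(table).iloc[0]
        assert np.isnan(rec["r"]) and not rec["flagged"]


class TestRegionExpressionCheck:
    def _inputs(self, carrier_vals, other_vals):
        samples = [f"c{i}" for i in range(len(carrier_vals))] + [
            f"n{i}" for i in range(len(other_vals))
        ]
        carriers = pd.Series(
            [1] * len(carrier_vals) + [0] * len(other_vals), index=samples
        )
        expr = pd.DataFrame(
            {"gene": list(carrier_vals) + list(other_vals)}, index=samples
        ).T
        return carriers, expr

    def test_identical_groups_p_one(self):
        carriers, expr = self._inputs([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        rec = region_expression_check(carriers, expr, ["gene"]).iloc[0]
        assert rec["p"] == pytest.approx(1.0)
        assert rec["direction"] is None

    def test_exact_rank_sum_enumeration(self):
        # complete separation of 3 vs 3: the most extreme of C(6,3) = 20
        # equally likely rank arrangements, two-sided p = 2/20
        carriers, expr = self._inputs([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        rec = region_expression_check(carriers, expr, ["gene"]).iloc[0]
        assert rec["p"] == pytest.approx(0.1, abs=1e-12)
        assert rec["direction"] == "up"

    def test_deleted_region_gene_lower_in_carriers(self):
        carriers, expr = self._inputs([1.0, 2.0, 1.5], [5.0, 6.0, 7.0, 8.0])
        rec = region_expression_check(carriers, expr, ["gene"]).iloc[0]
        assert rec["direction"] == "down"

    def test_absent_gene_skipped(self):
        carriers, expr = self._inputs([1.0, 2.0], [3.0, 4.0])
        out = region_expression_check(carriers, expr, ["gene", "ghost"])
        assert list(out["gene"]) == ["gene"]

    def test_requires_both_groups(self):
        carriers, expr = self._inputs([1.0, 2.0], [])
        with pytest.raises(ValueError):
            region_expression_check(carriers, expr, ["gene"])


def test_significant_subsets_and_sorts():
    rec = pd.DataFrame({"feature_id": ["a", "b", "c"], "p_min": [0.5, 1e-6, 1e-4]})
    out = significant(rec, 0.0003)
    assert list(out["feature_id"]) == ["b", "c"]
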