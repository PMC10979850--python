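import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import locindex as L
from locindex.localization import Label, LocalizationTable, bonferroni


def make_table(sample_id, beta, li_by_tx):
    ids = sorted(li_by_tx)
    li = np.array([li_by_tx[t] for t in ids], float)
    records = pd.DataFrame(
        {"li": li, "naive_li": li, "label": L.classify(li)},
        index=pd.Index(ids, name="transcript_id"),
    )
    return LocalizationTable(sample_id, beta, records)


class TestWorkedTwoGeneExample:
    """Two equal-length genes; cell type 2 holds 80% of its RNA in the cytosol.

    The naive index computed from fraction read counts alone misstates the
    cytosolic molecule fractions (0.6 and 0.9); with beta known, the
    localization index recovers them exactly.
    """

    def test_expected_counts(self, fig1):
        np.testing.assert_allclose(
            L.expected_fraction_counts(fig1["type2"]["m_n"], fig1["lengths"], 1000),
            [666.6667, 333.3333], rtol=1e-4,
        )
        np.testing.assert_allclose(
            L.expected_fraction_counts(fig1["type2"]["m_c"], fig1["lengths"], 1000),
            [250.0, 750.0],
        )

    def test_naive_index_cell_type2(self, fig1):
        n = L.expected_fraction_counts(fig1["type2"]["m_n"], fig1["lengths"], 1000)
        c = L.expected_fraction_counts(fig1["type2"]["m_c"], fig1["lengths"], 1000)
        naive = L.naive_localization_index(n, c)
        assert round(naive[0], 2) == 0.27  # gene A looks nuclear, wrongly
        assert round(naive[1], 2) == 0.69

    def test_naive_index_cell_type1_is_true_fraction(self, fig1):
        n = L.expected_fraction_counts(fig1["type1"]["m_n"], fig1["lengths"], 1000)
        c = L.expected_fraction_counts(fig1["type1"]["m_c"], fig1["lengths"], 1000)
        naive = L.naive_localization_index(n, c)
        assert round(naive[1], 2) == 0.45
        assert round(naive[0], 2) == 0.60  # at beta=0.5 naive equals truth

    def test_localization_index_with_beta(self, fig1):
        n = L.expected_fraction_counts(fig1["type2"]["m_n"], fig1["lengths"], 1000)
        c = L.expected_fraction_counts(fig1["type2"]["m_c"], fig1["lengths"], 1000)
        li = L.localization_index(n, c, beta=0.8)
        assert round(li[0], 2) == 0.60
        assert round(li[1], 2) == 0.90


class TestExpectedFractionCounts:
    def test_single_transcript_takes_all_reads(self):
        np.testing.assert_allclose(L.expected_fraction_counts([7], [300], 500), [500.0])

    def test_length_weighting(self):
        np.testing.assert_allclose(
            L.expected_fraction_counts([10, 10], [1, 3], 1000), [250.0, 750.0]
        )

    def test_all_zero_molecules_rejected(self):
        with pytest.raises(ValueError):
            L.expected_fraction_counts([0, 0], [100, 100], 1000)


class TestLocalizationIndex:
    def test_zero_cytosol_gives_zero(self):
        assert L.localization_index(5.0, 0.0, 0.5) == 0.0

    def test_both_zero_is_undefined(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(L.localization_index(0.0, 0.0, 0.5))

    @given(
        n=st.floats(0.0, 1e4),
        c=st.floats(0.0, 1e4),
        beta=st.floats(0.01, 0.99),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_properties(self, n, c, beta, scale):
        if n + c == 0:
            return
        # beta = 0.5 reduces to the naive index
        assert L.localization_index(n, c, 0.5) == pytest.approx(
            L.naive_localization_index(n, c)
        )
        li = L.localization_index(n, c, beta)
        assert 0.0 <= li <= 1.0
        # invariant under joint rescaling of the fraction FPKMs
        assert L.localization_index(n * scale, c * scale, beta) == pytest.approx(li, rel=1e-9)
        # complementarity: swapping fractions and beta gives 1 - LI
        assert L.localization_index(c, n, 1.0 - beta) + li == pytest.approx(1.0, abs=1e-9)

    @given(n=st.floats(0.1, 1e3), c=st.floats(0.1, 1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing_in_beta(self, n, c):
        betas = np.linspace(0.05, 0.95, 10)
        lis = [L.localization_index(n, c, b) for b in betas]
        assert all(b > a for a, b in zip(lis, lis[1:]))


class TestClassify:
    @pytest.mark.parametrize(
        "li,label",
        [
            (0.39, Label.NUCLEAR),
            (0.61, Label.CYTOSOLIC),
            (0.5, Label.INTERMEDIATE),
            (0.4, Label.INTERMEDIATE),
            (0.6, Label.INTERMEDIATE),
            (np.nan, Label.UNDEFINED),
        ],
    )
    def test_thresholds(self, li, label):
        assert L.classify(li) is label

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            L.classify(0.5, lower=0.6, upper=0.4)


class TestReplicateConsensus:
    def test_averages_and_intersects(self):
        t1 = make_table("r1", 0.8, {"A": 0.6, "B": 0.2})
        t2 = make_table("r2", 0.8, {"A": 0.8, "C": 0.9})
        merged = L.replicate_consensus([t1, t2])
        assert list(merged.transcript_ids) == ["A"]
        assert merged.records.loc["A", "li"] == pytest.approx(0.7)

    def test_single_table_unchanged(self):
        t1 = make_table("r1", 0.7, {"A": 0.6})
        assert L.replicate_consensus([t1]) is t1

    def test_empty_intersection(self):
        t1 = make_table("r1", 0.7, {"A": 0.6})
        t2 = make_table("r2", 0.7, {"B": 0.6})
        with pytest.raises(L.QuantDataError):
            L.replicate_consensus([t1, t2])


class TestConsistencySummary:
    def test_always_cytosolic_binning(self):
        tables = {
            f"cond{i}": make_table(f"cond{i}", 0.7, {"X": li})
            for i, li in enumerate([0.7, 0.8, 0.9])
        }
        summary = L.consistency_summary(tables)
        assert summary.loc[3, "n_always_cytosolic"] == 1
        assert summary.loc[3, "n_always_nuclear"] == 0

    def test_mixed_transcript_counts_in_neither(self):
        tables = {
            "c1": make_table("c1", 0.7, {"X": 0.7}),
            "c2": make_table("c2", 0.7, {"X": 0.3}),
        }
        summary = L.consistency_summary(tables)
        assert summary.loc[2, "n_always_cytosolic"] == 0
        assert summary.loc[2, "n_always_nuclear"] == 0
        assert summary.loc[2, "n_expressed"] == 1

    def test_constructed_proportion(self):
        """50 transcripts in all 10 conditions, 36 always cytosolic -> 72%."""
        rng = np.random.default_rng(4)
        li = {}
        for i in range(50):
            if i < 36:
                values = rng.uniform(0.55, 0.95, 10)
            else:
                values = np.concatenate([rng.uniform(0.0, 0.45, 5), rng.uniform(0.55, 0.95, 5)])
            li[f"T{i:02d}"] = values
        tables = {
            f"cond{k}": make_table(
                f"cond{k}", 0.75, {tx: v[k] for tx, v in li.items()}
            )
            for k in range(10)
        }
        summary = L.consistency_summary(tables)
        assert summary.loc[10, "n_expressed"] == 50
        assert summary.loc[10, "prop_always_cytosolic"] == pytest.approx(0.72)

    def test_threshold_tie_counted_in_both(self):
        tables = {"c1": make_table("c1", 0.6, {"X": 0.5})}
        summary = L.consistency_summary(tables)
        assert summary.loc[1, "n_always_cytosolic"] == 1
        assert summary.loc[1, "n_always_nuclear"] == 1
        assert summary.loc[1, "n_ties"] == 1


class TestStrongLocalizers:
    def make_conditions(self, values_by_tx):
        n_cond = max(len(v) for v in values_by_tx.values())
        tables = {}
        for k in range(n_cond):
            sub = {tx: v[k] for tx, v in values_by_tx.items() if len(v) > k}
            tables[f"c{k}"] = make_table(f"c{k}", 0.7, sub)
        return tables

    def test_strong_cytosolic(self):
        tables = self.make_conditions({"A": [0.92, 0.95, 0.99, 0.93, 0.97, 0.96]})
        cyto, nuc = L.strong_localizers(tables)
        assert cyto == {"A"} and nuc == set()

    def test_too_few_conditions_excluded(self):
        tables = self.make_conditions({"A": [0.99, 0.99, 0.99, 0.99]})
        cyto, _ = L.strong_localizers(tables, min_conditions=5)
        assert cyto == set()

    def test_one_low_condition_excludes(self):
        tables = self.make_conditions({"A": [0.95, 0.95, 0.89, 0.95, 0.95]})
        cyto, _ = L.strong_localizers(tables)
        assert cyto == set()

    def test_strong_nuclear(self):
        tables = self.make_conditions({"A": [0.1, 0.2, 0.05, 0.25, 0.29]})
        _, nuc = L.strong_localizers(tables)
        assert nuc == {"A"}


def hypergeom_tail_by_enumeration(N, K, n, k_obs):
    """P(X >= k_obs) for X hypergeometric, by exhaustive counting."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, k) * comb(N - K, n - k)
        for k in range(k_obs, min(K, n) + 1)
    ) / total


class TestEnrichmentRatio:
    def test_ratio_double(self):
        spec = [True] * 20 + [False] * 80
        glob = [True] * 100 + [False] * 900
        ratio, _ = L.enrichment_ratio(spec, glob)
        assert ratio == pytest.approx(2.0)

    def test_identity(self):
        glob = [True] * 4 + [False] * 6
        ratio, p = L.enrichment_ratio(glob, glob)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_small_case_matches_enumeration(self):
        spec = [True, True, True, False, False]
        glob = [True] * 4 + [False] * 6
        ratio, p = L.enrichment_ratio(spec, glob)
        assert ratio == pytest.approx((3 / 5) / (4 / 10))
        assert p == pytest.approx(hypergeom_tail_by_enumeration(10, 4, 5, 3), rel=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(15, 6, 7, 4), (12, 3, 5, 1), (9, 9, 4, 4), (15, 1, 8, 0)])
    def test_enumeration_grid(self, N, K, n, k):
        spec = [True] * k + [False] * (n - k)
        glob = [True] * K + [False] * (N - K)
        _, p = L.enrichment_ratio(spec, glob)
        assert p == pytest.approx(hypergeom_tail_by_enumeration(N, K, n, k), rel=1e-12)

    def test_empty_specific_signaled(self):
        with pytest.raises(ValueError, match="empty"):
            L.enrichment_ratio([], [True, False])

    def test_bonferroni_clipped(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.4], 3), [0.03, 1.0])
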