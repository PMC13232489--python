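"""Inventory curation, summary distributions, enrichment and accrual models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endotag.fixtures import InventorySpec, make_inventory_fixture
from endotag.survey import (
    AlleleRecord,
    benjamini_hochberg,
    category_proportion,
    cumulative_accrual,
    dedup_alleles,
    discovery_curve_fit,
    enrichment_table,
    linear_fit,
    merge_sources,
    summarize_inventory,
)


def rec(gene="gx", tags=("GFP",), pos=("C",), source="literature", allele=None,
        year=None):
    return AlleleRecord(
        gene_id=gene,
        gene_name=gene,
        tags=frozenset(tags),
        tag_positions=frozenset(pos),
        source=source,
        allele_designation=allele,
        year=year,
    )


class TestDedup:
    def test_earliest_publication_kept(self):
        a = rec(year=2018, allele="qy1")
        b = rec(year=2021, allele="qy2")
        (kept,) = dedup_alleles([b, a])
        assert kept.year == 2018

    def test_different_tags_both_kept(self):
        out = dedup_alleles([rec(tags=("GFP",)), rec(tags=("mNG",))])
        assert len(out) == 2

    def test_identical_records_keep_one_deterministically(self):
        a = rec(year=2020, allele="qy2")
        b = rec(year=2020, allele="qy1")
        (kept,) = dedup_alleles([a, b])
        assert kept.allele_designation == "qy1"

    def test_idempotent(self):
        records = [rec(year=y, allele=f"a{y}") for y in (2015, 2018, 2020)]
        once = dedup_alleles(records)
        assert dedup_alleles(once) == once


class TestMergeSources:
    def test_overlap_counts(self):
        lit = [rec(gene=f"g{i}", allele=f"a{i}") for i in (1, 2, 3)]
        cgc = [rec(gene="g3", allele="a3", source="CGC"),
               rec(gene="g4", allele="a4", source="CGC")]
        _, summary = merge_sources(lit, cgc)
        assert summary["genes"] == {"literature_only": 2, "cgc_only": 1, "both": 1}
        assert summary["alleles"] == {"literature_only": 2, "cgc_only": 1, "both": 1}

    def test_designation_free_records_match_on_gene_tag_position(self):
        lit = [rec(gene="g1")]
        cgc = [rec(gene="g1", source="CGC")]
        _, summary = merge_sources(lit, cgc)
        assert summary["alleles"]["both"] == 1

    def test_empty_cgc_all_literature_only(self):
        _, summary = merge_sources([rec(gene="g1", allele="a1")], [])
        assert summary["alleles"] == {"literature_only": 1, "cgc_only": 0, "both": 0}

    def test_gene_conflict_warns_and_literature_wins(self):
        lit = [rec(gene="g1", allele="a1")]
        cgc = [rec(gene="g2", allele="a1", source="CGC")]
        merged, summary = merge_sources(lit, cgc)
        assert summary["warnings"]
        both = merged[merged["source_class"] == "both"]
        assert list(both["gene_id"]) == ["g1"]


class TestSummarize:
    def test_constructed_allele_count_distribution(self):
        records = []
        for i in range(7):
            records.append(rec(gene=f"s{i}", allele=f"x{i}"))
        for i in range(2):
            records += [rec(gene=f"d{i}", tags=("GFP",), allele=f"y{i}"),
                        rec(gene=f"d{i}", tags=("mNG",), allele=f"z{i}")]
        records += [rec(gene="t", tags=(tg,), allele=f"w{tg}")
                    for tg in ("GFP", "mNG", "HA")]
        s = summarize_inventory(records)
        assert s.alleles_per_gene_pct == {"1": 70.0, "2": 20.0, "3": 10.0, "4+": 0.0}

    def test_multi_position_allele_counts_as_multiple(self):
        s = summarize_inventory([rec(pos=("N", "C"))])
        assert s.position_pct["multiple"] == 100.0

    def test_empty_inventory_no_crash(self):
        s = summarize_inventory([])
        assert s.n_genes == 0 and s.alleles_per_gene_pct == {}

    def test_distributions_sum_to_100(self):
        fix = make_inventory_fixture(InventorySpec(seed=5, n_genes=200))
        s = summarize_inventory(fix.records)
        assert sum(s.alleles_per_gene_pct.values()) == pytest.approx(100, abs=0.1)
        assert sum(s.position_pct.values()) == pytest.approx(100, abs=0.1)
        assert sum(s.tag_type_pct.values()) == pytest.approx(100, abs=0.1)


class TestCategoryProportion:
    @pytest.mark.parametrize(
        "t,n,expected",
        [(25, 29, 86.2), (0, 75, 0.0), (29, 29, 100.0), (69, 133, 51.9),
         (154, 314, 49.0), (390, 6508, 6.0), (62, 217, 28.6), (813, 4517, 18.0)],
    )
    def test_rounded_percentages(self, t, n, expected):
        assert category_proportion(t, n) == expected

    def test_round_half_away_from_zero(self):
        assert category_proportion(1, 8, 2) == 12.5
        assert category_proportion(5, 1000) == 0.5  # 0.5 rounds up, not to even

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            category_proportion(0, 0)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration over tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        )
    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def test_fully_tagged_category_caps_at_plus_seven(self):
        df = enrichment_table([("t1", "x", 29, 29)], 100, 1000)
        assert df.loc[0, "log2_or_capped"] == 7.0
        assert math.isinf(df.loc[0, "odds_ratio"])

    def test_untagged_category_caps_at_minus_seven(self):
        df = enrichment_table([("t1", "x", 0, 75)], 100, 1000)
        assert df.loc[0, "log2_or_capped"] == -7.0
        assert df.loc[0, "odds_ratio"] == 0.0

    def test_finite_or_is_uncapped_log2(self):
        df = enrichment_table([("t1", "x", 10, 50)], 100, 1000)
        odds = (10 * (950 - 90)) / (40 * 90)
        assert df.loc[0, "odds_ratio"] == pytest.approx(odds)
        assert df.loc[0, "log2_or_capped"] == pytest.approx(math.log2(odds))

    def test_worked_small_table_matches_enumeration(self):
        # table [[3,1],[1,3]]: t=3, n=4, T=4, N=8
        df = enrichment_table([("t1", "x", 3, 4)], 4, 8)
        assert df.loc[0, "p_value"] == pytest.approx(
            fisher_two_sided_oracle(3, 1, 1, 3)
        )

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_fisher_p_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(4, 200))
        n = data.draw(st.integers(1, N))
        T = data.draw(st.integers(0, N))
        t = data.draw(st.integers(max(0, T + n - N), min(n, T)))
        df = enrichment_table([("t1", "x", t, n)], T, N)
        a, b, c, d = t, n - t, T - t, (N - n) - (T - t)
        assert df.loc[0, "p_value"] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative cell"):
            enrichment_table([("t1", "x", 5, 10)], 4, 100)  # T < t


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), q_sm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestAccrual:
    def test_noiseless_line_recovered_exactly(self):
        years = np.arange(2015, 2026)
        cumulative = pd.Series(203 * (years - 2015) + 40, index=years)
        slope, intercept, r2 = linear_fit(cumulative)
        assert slope == pytest.approx(203) and r2 == pytest.approx(1.0)

    def test_gene_counted_once_in_earliest_year(self):
        records = [rec(gene="g1", allele="a", year=2018),
                   rec(gene="g1", allele="b", tags=("mNG",), year=2021),
                   rec(gene="g2", allele="c", year=2021)]
        acc = cumulative_accrual(records)
        assert acc[2018] == 1 and acc[2021] == 2

    def test_noisy_slope_recovered_within_5_percent(self):
        rng = np.random.default_rng(1)
        years = np.arange(2012, 2026)
        y = 150 * (years - 2012) + 30 + rng.normal(0, 5, size=len(years))
        slope, _, _ = linear_fit(pd.Series(y, index=years))
        assert abs(slope - 150) / 150 < 0.05

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            linear_fit(pd.Series([5], index=[2020]))


class TestDiscoveryCurve:
    def test_noiseless_parameters_recovered(self):
        x = np.arange(10, 3001, 10, dtype=float)
        y = 1700 * (1 - np.exp(-x / 1050))
        fit = discovery_curve_fit(x, y)
        assert fit.parameters["g_max"] == pytest.approx(1700, rel=1e-4)
        assert fit.parameters["tau"] == pytest.approx(1050, rel=1e-4)

    def test_papers_for_fraction_closed_form(self):
        x = np.arange(10, 3001, 10, dtype=float)
        y = 1700 * (1 - np.exp(-x / 1050))
        fit = discovery_curve_fit(x, y)
        assert fit.papers_for_fraction(0.9) == pytest.approx(
            fit.parameters["tau"] * math.log(10)
        )

    def test_decreasing_series_rejected(self):
        with pytest.raises(ValueError):
            discovery_curve_fit([1, 2, 3], [5, 4, 3])
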