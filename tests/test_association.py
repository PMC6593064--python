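"""Association module: odds ratios, Woolf intervals, chi-square, Fisher
exact and Hardy-Weinberg tests, and the full per-SNP table builder."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import oracle_fisher
from seedshift.association import (AssociationError, Contingency2x2, GenotypeTable,
                                   alleles_from_genotypes, analyze_snp, build_table1,
                                   chisq_test_2x2, fisher_exact_2x2, hwe_test,
                                   odds_ratio_ci, reports_to_frame, round_half_up,
                                   tables_from_counts)

cells = st.integers(min_value=1, max_value=50)


class TestAllelesFromGenotypes:
    def test_published_counts(self, rs4937333_table):
        t = alleles_from_genotypes(rs4937333_table)
        # minor (T) alleles: cases 2*21+24=66, controls 2*3+24=30
        assert (t.a, t.b, t.c, t.d) == (66, 30, 66, 54)

    @pytest.mark.parametrize("case,control,expected", [
        ((10, 0, 0), (8, 0, 0), (0, 0, 20, 16)),    # all hom-ref: no alt alleles
        ((0, 10, 0), (0, 10, 0), (10, 10, 10, 10)),  # all het: equal alleles
    ])
    def test_boundary_tables(self, case, control, expected):
        gt = GenotypeTable("s", ("CC", "CT", "TT"), case, control)
        t = alleles_from_genotypes(gt)
        assert (t.a, t.b, t.c, t.d) == expected

    def test_non_biallelic_rejected(self):
        with pytest.raises(AssociationError):
            GenotypeTable("s", ("AA", "AG", "CC"), (1, 1, 1), (1, 1, 1))


class TestOddsRatioCI:
    @pytest.mark.parametrize("table,or_,lo,hi", [
        ((66, 30, 66, 54), 1.800, 1.026, 3.157),   # allele T vs C
        ((21, 3, 21, 15), 5.000, 1.259, 19.860),   # TT vs CC
        ((24, 24, 21, 15), 0.714, 0.299, 1.707),   # CT vs CC
        ((18, 9, 39, 30), 1.538, 0.606, 3.903),    # GA vs GG
        ((9, 3, 39, 30), 2.308, 0.574, 9.271),     # AA vs GG
        ((36, 15, 96, 69), 1.725, 0.876, 3.395),   # allele A vs G
    ])
    def test_published_intervals(self, table, or_, lo, hi):
        res = odds_ratio_ci(Contingency2x2(*table))
        assert round_half_up(res.odds_ratio) == pytest.approx(or_)
        assert round_half_up(res.ci_low) == pytest.approx(lo)
        assert round_half_up(res.ci_high) == pytest.approx(hi)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_symmetric_table_is_null(self):
        res = odds_ratio_ci(Contingency2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_undefined_unless_haldane(self):
        t = Contingency2x2(5, 0, 3, 7)
        res = odds_ratio_ci(t)
        assert res.odds_ratio is None and not res.ci_defined
        res2 = odds_ratio_ci(t, haldane=True)
        assert res2.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @settings(max_examples=60, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_swap_invariances(self, a, b, c, d):
        """Swapping columns or rows inverts the OR and preserves p-values;
        the CI maps to reciprocals in reverse order."""
        t = Contingency2x2(a, b, c, d)
        base = odds_ratio_ci(t)
        for swapped in (t.swapped_columns(), t.swapped_rows()):
            res = odds_ratio_ci(swapped)
            assert res.odds_ratio == pytest.approx(1 / base.odds_ratio)
            assert res.ci_low == pytest.approx(1 / base.ci_high)
            assert res.ci_high == pytest.approx(1 / base.ci_low)
            assert res.p_chisq == pytest.approx(base.p_chisq)
            assert res.p_fisher == pytest.approx(base.p_fisher, rel=1e-9)


class TestChisq:
    @pytest.mark.parametrize("table", [
        (66, 30, 66, 54), (21, 3, 21, 15), (7, 12, 30, 2), (40, 40, 41, 39),
    ])
    def test_matches_closed_form(self, table):
        a, b, c, d = table
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = chisq_test_2x2(Contingency2x2(a, b, c, d))
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)), rel=1e-12)

    def test_published_allele_test(self):
        chi2, p = chisq_test_2x2(Contingency2x2(66, 30, 66, 54))
        assert chi2 == pytest.approx(4.2432, abs=5e-4)
        assert p == pytest.approx(0.0394, abs=5e-4)

    def test_proportional_table_is_exactly_null(self):
        chi2, p = chisq_test_2x2(Contingency2x2(20, 10, 40, 20))
        assert chi2 == 0.0 and p == 1.0

    def test_continuity_correction_shrinks_statistic(self):
        t = Contingency2x2(21, 3, 21, 15)
        plain, _ = chisq_test_2x2(t)
        corrected, _ = chisq_test_2x2(t, continuity=True)
        assert plain == pytest.approx(5.8333, abs=5e-4)
        assert corrected < plain

    def test_zero_margin_signalled(self):
        chi2, p = chisq_test_2x2(Contingency2x2(0, 0, 5, 5))
        assert math.isnan(chi2) and p is None


class TestFisher:
    @pytest.mark.parametrize("table", [
        (21, 3, 21, 15), (5, 0, 0, 5), (10, 10, 10, 10), (66, 30, 66, 54),
        (1, 9, 11, 3), (2, 2, 2, 2), (12, 0, 4, 9),
    ])
    def test_matches_exact_enumeration(self, table):
        p = fisher_exact_2x2(Contingency2x2(*table))
        assert p == pytest.approx(oracle_fisher(*table), rel=1e-7)
        assert p == pytest.approx(stats.fisher_exact(
            [[table[0], table[1]], [table[2], table[3]]])[1], rel=1e-6)

    def test_symmetric_table(self):
        assert fisher_exact_2x2(Contingency2x2(10, 10, 10, 10)) == pytest.approx(1.0)


class TestHWE:
    def test_published_control_group(self):
        # expected counts from p_hat = 0.643: direct goodness-of-fit arithmetic
        res = hwe_test((15, 24, 3), "control")
        n, p_hat = 42, (2 * 15 + 24) / 84
        exp = [p_hat**2 * n, 2 * p_hat * (1 - p_hat) * n, (1 - p_hat) ** 2 * n]
        chi2 = sum((o - e) ** 2 / e for o, e in zip((15, 24, 3), exp))
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.chi2 == pytest.approx(2.51, abs=5e-3)
        assert res.p > 0.05

    def test_exact_hw_proportions(self):
        assert hwe_test((25, 50, 25)).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_no_heterozygotes(self):
        # p_hat = 0.5, expected (25, 50, 25): chi2 = n
        assert hwe_test((50, 0, 50)).chi2 == pytest.approx(100.0)

    def test_monomorphic_inapplicable(self):
        res = hwe_test((60, 0, 0))
        assert not res.applicable and res.chi2 is None and res.p is None

    @settings(max_examples=40, derandomize=True)
    @given(h1=st.integers(0, 40), het=st.integers(1, 40), h2=st.integers(0, 40))
    def test_allele_relabel_invariance(self, h1, het, h2):
        assert hwe_test((h1, het, h2)).chi2 == pytest.approx(
            hwe_test((h2, het, h1)).chi2, rel=1e-9)


class TestBuildTable1:
    @staticmethod
    def records_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
        rows = []
        k = 0
        snps = counts["snp_id"].unique()
        per_sample: dict = {}
        for snp, grp in counts.groupby("snp_id", sort=False):
            idx = {"case": 0, "control": 0}
            for r in grp.itertuples():
                for group, n in (("case", r.case_n), ("control", r.control_n)):
                    for _ in range(int(n)):
                        sid = f"{group}{idx[group]:03d}"
                        per_sample.setdefault((sid, group), {})[snp] = r.genotype
                        idx[group] += 1
        for (sid, group), genos in per_sample.items():
            rows.append({"sample_id": sid, "group": group, **genos})
        return pd.DataFrame(rows)

    def test_full_published_table(self, table1_counts):
        reports = build_table1(self.records_from_counts(table1_counts))
        by_id = {r.table.snp_id: r for r in reports}
        assert sum(r.monomorphic for r in reports) == 6
        rs = by_id["rs4937333"]
        assert round_half_up(rs.allele_result.odds_ratio) == 1.800
        assert round_half_up(rs.genotype_results[1].odds_ratio) == 5.000
        assert rs.table.genotype_labels == ("CC", "CT", "TT")
        rs2 = by_id["rs1128334"]
        assert round_half_up(rs2.allele_result.odds_ratio) == 1.725
        frame = reports_to_frame(reports)
        mono = frame[frame["snp_id"] == "rs1128355"]
        assert mono["odds_ratio"].isna().all()

    def test_empty_records(self):
        reports = build_table1(pd.DataFrame(columns=["sample_id", "group", "rsX"]))
        assert reports == []

    def test_missing_genotypes_excluded_pairwise(self):
        df = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                           "group": ["case", "case", "control", "control"],
                           "rsX": ["CT", None, "CC", "TT"]})
        reports = build_table1(df)
        assert reports[0].n_missing == 1
        assert reports[0].table.n_cases == 1

    def test_inconsistent_alleles_rejected(self):
        df = pd.DataFrame({"sample_id": ["a", "b", "c"],
                           "group": ["case", "case", "control"],
                           "rsX": ["CT", "AG", "CC"]})
        with pytest.raises(AssociationError, match="more than two alleles"):
            build_table1(df)

    def test_counts_input_matches_record_input(self, table1_counts):
        from_counts = {t.snp_id: t for t in tables_from_counts(table1_counts)}
        from_records = {r.table.snp_id: r.table
                        for r in build_table1(self.records_from_counts(table1_counts))}
        assert from_counts == from_records
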