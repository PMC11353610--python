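import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import hypergeom

from snprulemine.association_stats import (
    Contingency2x2,
    GenotypeCounts,
    allele_association,
    association_table,
    count_alleles,
    fisher_exact,
    genotype_association,
    hwe_test,
    model_association,
    odds_ratio_woolf,
)


class TestHwe:
    def test_exact_hwe_proportions_give_zero_statistic(self):
        res = hwe_test(GenotypeCounts(25, 50, 25))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_het_deficit_hand_computed(self):
        # p = q = 0.5, expected (25, 50, 25): chi2 = 1 + 2 + 1 = 4
        res = hwe_test(GenotypeCounts(30, 40, 30))
        assert res.chi_square == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_no_heterozygotes_extreme(self):
        res = hwe_test(GenotypeCounts(100, 0, 100))
        assert res.chi_square == pytest.approx(200.0)
        assert res.expected == pytest.approx((50.0, 100.0, 50.0))

    def test_monomorphic_flagged_with_p_one(self):
        res = hwe_test(GenotypeCounts(80, 0, 0))
        assert res.monomorphic
        assert res.p_value == 1.0

    def test_expected_counts_sum_to_total(self):
        res = hwe_test(GenotypeCounts(33, 41, 26))
        assert sum(res.expected) == pytest.approx(100.0)

    def test_null_rejection_rate_calibrated(self):
        # HWE sampling at n=200, maf=0.3: type-I error near nominal 0.05
        rng = np.random.default_rng(2024)
        probs = (0.49, 0.42, 0.09)
        reps = 2000
        counts = rng.multinomial(200, probs, size=reps)
        rejections = sum(
            hwe_test(GenotypeCounts(*row)).p_value < 0.05 for row in counts
        )
        assert 0.03 <= rejections / reps <= 0.07


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(Contingency2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfect_separation_small_n(self):
        # both one-sided extremes of the hypergeometric at n=20
        assert fisher_exact(Contingency2x2(10, 0, 0, 10)) == pytest.approx(
            2 / 184756, rel=1e-9)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact(Contingency2x2(0, 0, 5, 5)) == 1.0

    @pytest.mark.parametrize("table", [
        (3, 5, 7, 2), (1, 9, 4, 6), (8, 2, 3, 10), (0, 6, 5, 4),
    ])
    def test_matches_exhaustive_enumeration(self, table):
        # sum hypergeometric probabilities <= that of the observed table
        a, b, c, d = table
        row1, col1, n = a + b, a + c, a + b + c + d
        p_obs = hypergeom.pmf(a, n, col1, row1)
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)
        p_exhaustive = sum(
            p for k in range(lo, hi + 1)
            if (p := hypergeom.pmf(k, n, col1, row1)) <= p_obs * (1 + 1e-9)
        )
        assert fisher_exact(Contingency2x2(a, b, c, d)) == pytest.approx(
            p_exhaustive, rel=1e-9)


class TestOddsRatio:
    def test_symmetric_table_is_unity(self):
        assert odds_ratio_woolf(Contingency2x2(7, 7, 7, 7)).odds_ratio == pytest.approx(1.0)

    def test_reported_rule_cluster_table(self):
        # 57/4 rule-positive vs 251/201 rule-negative subjects
        res = odds_ratio_woolf(Contingency2x2(57, 4, 251, 201))
        assert res.odds_ratio == pytest.approx(11.41, abs=0.005)
        assert res.ci_low == pytest.approx(4.07, abs=0.005)
        assert res.ci_high == pytest.approx(31.99, rel=1e-3)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_zero_cell_without_haldane_flagged(self):
        res = odds_ratio_woolf(Contingency2x2(5, 0, 5, 5))
        assert res.degenerate
        assert math.isinf(res.odds_ratio)

    def test_haldane_correction_gives_finite_ci(self):
        res = odds_ratio_woolf(Contingency2x2(5, 0, 5, 5), haldane=True)
        assert not res.degenerate
        assert 0 < res.ci_low < res.odds_ratio < res.ci_high < math.inf

    @pytest.mark.parametrize("a,b,c,d", [(3, 4, 5, 6), (10, 2, 8, 9), (1, 1, 7, 3)])
    def test_orientation_inversion(self, a, b, c, d):
        # swapping exposure rows inverts the OR
        fwd = odds_ratio_woolf(Contingency2x2(a, b, c, d)).odds_ratio
        rev = odds_ratio_woolf(Contingency2x2(c, d, a, b)).odds_ratio
        assert fwd * rev == pytest.approx(1.0)


@pytest.fixture
def study_counts_cohort(cohort_from_text):
    """Small cohort with known per-SNP genotype composition."""
    header = "subject_id,status,sex,age,rs1800795,rs2834167\n"
    rows = []
    comp = [
        # (status, rs1800795, rs2834167, copies)
        ("Yes", "G/G", "G/G", 4), ("Yes", "G/C", "A/G", 3), ("Yes", "C/C", "A/A", 1),
        ("No", "G/G", "A/A", 2), ("No", "G/C", "A/G", 4), ("No", "C/C", "G/G", 2),
    ]
    i = 0
    for status, g1, g2, n in comp:
        for _ in range(n):
            i += 1
            rows.append(f"s{i},{status},F,40,{g1},{g2}")
    return cohort_from_text(header + "\n".join(rows))


class TestCohortLevel:
    def test_count_alleles_two_per_subject(self, study_counts_cohort):
        counts = count_alleles(study_counts_cohort, "rs1800795", "case")
        # cases: 4 G/G + 3 G/C + 1 C/C -> G = 11, C = 5
        assert (counts.major, counts.minor) == (11, 5)

    def test_allele_association_orientation(self, study_counts_cohort):
        res = allele_association(study_counts_cohort, "rs1800795", "G")
        # (11/5) / (8/8) = 2.2
        assert res.odds_ratio == pytest.approx(2.2)
        inv = allele_association(study_counts_cohort, "rs1800795", "C")
        assert res.odds_ratio * inv.odds_ratio == pytest.approx(1.0)

    def test_genotype_one_vs_rest(self, study_counts_cohort):
        res = genotype_association(study_counts_cohort, "rs2834167", "G/G")
        # cases 4 vs 4, controls 2 vs 6 -> OR = (4/4)/(2/6) = 3
        assert res.odds_ratio == pytest.approx(3.0)

    def test_dominant_and_recessive_collapse(self, study_counts_cohort):
        dom = model_association(study_counts_cohort, "rs2834167", "dominant")
        # minor(G) carriers: cases 4+3=7 vs 1; controls 2+4=6 vs 2
        assert dom.odds_ratio == pytest.approx((7 / 1) / (6 / 2))
        rec = model_association(study_counts_cohort, "rs2834167", "recessive")
        assert rec.odds_ratio == pytest.approx((4 / 4) / (2 / 6))

    def test_association_table_structure_and_consistency(self, study_counts_cohort):
        df = association_table(study_counts_cohort)
        # 13 panel SNPs x (2 allele rows + 3 genotype rows)
        assert len(df) == 13 * 5
        block = df[(df.rsid == "rs1800795") & (df.level == "allele")]
        assert block.cases_n.tolist() == [11, 5]
        # per-group frequencies sum to 1 within each SNP block
        for _, grp in df[df.level == "genotype"].groupby("rsid"):
            s = grp.cases_freq.to_numpy().sum()  # NaN-propagating sum
            if s == s:  # skip all-missing SNPs
                assert s == pytest.approx(1.0)
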