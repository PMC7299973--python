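"""Validation statistics: contingency tests, LD, permutation log-rank, two-SNP groups."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from snpsurv.association import (
    GROUP_BASELINE,
    GROUP_SNP1_HOM,
    GROUP_SNP2_HOM,
    GROUP_UNASSIGNED,
    adjusted_scan,
    chisq_contingency,
    combined_group_association,
    fisher_exact_rxc,
    genotype_distribution_fisher,
    ld_pair,
    permutation_corrected_logrank,
    two_snp_groups,
)
from snpsurv.io import ClinicalTable
from snpsurv.simulate import EffectSpec, SNPSpec, simulate_cohort, table1_fixtures

from conftest import make_clinical, make_gm


def fisher_fraction_oracle(table) -> Fraction:
    """Exact-rational conditional p by brute enumeration (independent route)."""
    t = np.asarray(table, dtype=int)
    r, c = t.shape
    row, col = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(cells) -> Fraction:
        num = Fraction(1)
        for m in row:
            num *= factorial(int(m))
        for m in col:
            num *= factorial(int(m))
        den = Fraction(factorial(n))
        for x in cells:
            den *= factorial(int(x))
        return num / den

    p_obs = prob(t.ravel())
    total = Fraction(0)
    ranges = [range(min(row[i], col[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for free in itertools.product(*ranges):
        cells = np.zeros((r, c), dtype=int)
        cells[: r - 1, : c - 1] = np.reshape(free, (r - 1, c - 1))
        cells[: r - 1, c - 1] = row[: r - 1] - cells[: r - 1, : c - 1].sum(axis=1)
        cells[r - 1] = col - cells[: r - 1].sum(axis=0)
        if (cells < 0).any():
            continue
        p = prob(cells.ravel())
        if p <= p_obs:
            total += p
    return total


class TestFisherExact:
    def test_2x2_matches_hypergeometric(self):
        t = [[1, 9], [11, 3]]
        assert fisher_exact_rxc(t) == pytest.approx(scipy_fisher(t)[1], rel=1e-9)

    def test_proportional_rows_give_one(self):
        assert fisher_exact_rxc([[10, 20], [30, 60]]) == pytest.approx(1.0)

    def test_identical_genotype_distributions_give_one(self):
        assert fisher_exact_rxc([[12, 12], [20, 20], [4, 4]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [5, 2]],
            [[2, 5, 3], [6, 1, 4]],
            [[4, 2, 1], [2, 5, 3], [1, 2, 6]],
        ],
    )
    def test_rxc_matches_fraction_oracle(self, table):
        expected = float(fisher_fraction_oracle(table))
        assert fisher_exact_rxc(table) == pytest.approx(expected, rel=1e-7)

    def test_grid_of_2x2_matches_scipy(self):
        for a, b, c, d in itertools.product(range(0, 13, 3), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            t = [[a, b], [c, d]]
            assert fisher_exact_rxc(t) == pytest.approx(
                scipy_fisher(t)[1], rel=1e-8, abs=1e-12
            ), t

    def test_oversized_table_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            fisher_exact_rxc(np.ones((4, 4), dtype=int))


class TestChisq:
    def test_yates_statistic_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(1, 40, (2, 2))
            s_y, _, _ = chisq_contingency(t, yates_for_2x2=True)
            s_u, _, _ = chisq_contingency(t, yates_for_2x2=False)
            assert s_y <= s_u + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_contingency([[0, 0], [3, 4]])

    def test_cohort_characteristic_tables(self):
        # published cohort-characteristics p-values at printed rounding
        fx = table1_fixtures()
        assert chisq_contingency(fx["backbone"].values)[2] == pytest.approx(0.042, abs=5e-4)
        assert chisq_contingency(fx["kras_with_unknown"].values)[2] == pytest.approx(0.10, abs=5e-3)
        assert chisq_contingency(fx["adjuvant"].values)[2] == pytest.approx(1.0, abs=1e-6)


class TestLdPair:
    def test_snp_with_itself(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.binomial(2, 0.3, (200, 1)).astype(float))
        ld = ld_pair(gm, "rs0", "rs0")
        assert ld.D_prime == pytest.approx(1.0, abs=1e-9)
        assert ld.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_near_zero(self):
        specs = [SNPSpec("a", 0.3), SNPSpec("b", 0.4)]
        gm, _ = simulate_cohort(5000, specs, [], seed=14)
        ld = ld_pair(gm, "a", "b")
        assert abs(ld.r) < 0.05

    def test_no_double_het_equals_direct_counting(self):
        # genotypes constructed so no patient is het at both loci: phases
        # are unambiguous and EM must equal the direct haplotype count
        g1 = np.array([0, 0, 2, 2, 1, 1, 0, 2, 1, 0], dtype=float)
        g2 = np.array([0, 2, 0, 2, 0, 2, 1, 1, 0, 1], dtype=float)
        gm = make_gm(np.column_stack([g1, g2]))
        ld = ld_pair(gm, "rs0", "rs1")
        # direct count: each genotype pair contributes two known haplotypes
        counts = {(0, 0): 0.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 0.0}
        for a, b in zip(g1.astype(int), g2.astype(int)):
            a1 = [1, 1] if a == 2 else ([1, 0] if a == 1 else [0, 0])
            b1 = [1, 1] if b == 2 else ([1, 0] if b == 1 else [0, 0])
            counts[(a1[0], b1[0])] += 1
            counts[(a1[1], b1[1])] += 1
        for k, v in counts.items():
            assert ld.haplotype_freqs[k] == pytest.approx(v / 20, abs=1e-9)

    def test_monomorphic_rejected(self):
        gm = make_gm(np.column_stack([np.zeros(10), np.ones(10)]))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(gm, "rs0", "rs1")

    def test_r_bounded_by_d_prime(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            specs = [SNPSpec("a", 0.2), SNPSpec("b", 0.35)]
            gm, _ = simulate_cohort(300, specs, [], seed=seed)
            ld = ld_pair(gm, "a", "b")
            assert abs(ld.r) <= ld.D_prime + 1e-9


class TestPermutationLogrank:
    def test_degenerate_single_group_rejected(self, planted_cohort):
        gm, ct = planted_cohort
        mono = make_gm(np.zeros((gm.n_patients, 1)))
        from snpsurv.io import GenotypeMatrix

        mono = GenotypeMatrix(gm.patient_ids, mono.snps, mono.codes)
        with pytest.raises(ValueError, match="single group"):
            permutation_corrected_logrank(mono, "rs0", ct, B=10)

    def test_deterministic_given_seed(self, planted_cohort):
        gm, ct = planted_cohort
        a = permutation_corrected_logrank(gm, "rs1", ct, B=200, seed=5)
        b = permutation_corrected_logrank(gm, "rs1", ct, B=200, seed=5)
        assert a == b

    def test_strong_effect_gets_floor_p(self):
        # a genotype that perfectly orders survival: corrected p at the floor
        n = 60
        g = np.repeat([0.0, 2.0], n // 2)
        gm = make_gm(g[:, None])
        t = np.concatenate([np.arange(1, 31), np.arange(100, 130)]).astype(float)
        ct = make_clinical(t, np.ones(n, int), gm)
        raw, corr = permutation_corrected_logrank(gm, "rs0", ct, B=1000, seed=2)
        assert raw < 1e-10
        assert corr <= 0.001

    def test_invariant_to_category_relabelling(self, planted_cohort):
        gm, ct = planted_cohort
        _, corr = permutation_corrected_logrank(gm, "rs2", ct, B=300, seed=9)
        flipped = make_gm(2.0 - gm.codes[:, [2]])
        from snpsurv.io import GenotypeMatrix

        flipped = GenotypeMatrix(gm.patient_ids, flipped.snps, flipped.codes)
        _, corr_f = permutation_corrected_logrank(flipped, "rs0", ct, B=300, seed=9)
        assert corr == pytest.approx(corr_f)


class TestTwoSnpGroups:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            (2, 2, GROUP_SNP1_HOM),   # SNP1 homozygote takes precedence
            (2, 0, GROUP_SNP1_HOM),
            (1, 2, GROUP_SNP2_HOM),
            (0, 2, GROUP_SNP2_HOM),
            (0, 0, GROUP_BASELINE),
            (1, 1, GROUP_BASELINE),
            (np.nan, 0, GROUP_UNASSIGNED),
            (0, np.nan, GROUP_UNASSIGNED),
            (2, np.nan, GROUP_SNP1_HOM),  # SNP2 not needed once SNP1 decides
        ],
    )
    def test_label_rules(self, g1, g2, expected):
        gm = make_gm(np.array([[g1, g2]]))
        assert two_snp_groups(gm, "rs0", "rs1")[0] == expected


class TestCombinedGroups:
    def _setup(self, n=300, seed=17, hr2=3.0):
        specs = [SNPSpec("a", 0.35), SNPSpec("b", 0.35)]
        gm, ct = simulate_cohort(
            n, specs, [EffectSpec("b", "recessive", np.log(hr2))], seed=seed
        )
        return gm, ct

    def test_recovers_planted_group_hazard(self):
        gm, ct = self._setup()
        labels = two_snp_groups(gm, "a", "b")
        res = combined_group_association(labels, ct)
        row = res.contrasts.set_index("group").loc[GROUP_SNP2_HOM]
        assert row["estimable"]
        assert row["ci_low"] < 3.0 < row["ci_high"]

    def test_patient_order_invariance(self):
        gm, ct = self._setup(n=150)
        labels = two_snp_groups(gm, "a", "b")
        res1 = combined_group_association(labels, ct)
        rng = np.random.default_rng(0)
        perm = rng.permutation(150)
        ct2 = ClinicalTable(ct.data.iloc[perm].reset_index(drop=True))
        res2 = combined_group_association(labels[perm], ct2)
        np.testing.assert_allclose(
            res1.contrasts["hr"], res2.contrasts["hr"], rtol=1e-8
        )
        assert res1.logrank[0] == pytest.approx(res2.logrank[0], rel=1e-9)

    def test_all_baseline_inestimable(self):
        gm = make_gm(np.zeros((30, 2)))
        t = np.arange(1.0, 31)
        ct = make_clinical(t, np.ones(30, int), gm)
        labels = two_snp_groups(gm, "rs0", "rs1")
        res = combined_group_association(labels, ct, covariate_preset=[])
        assert not res.contrasts["estimable"].any()

    def test_empty_baseline_rejected(self):
        gm = make_gm(np.full((10, 2), 2.0))
        ct = make_clinical(np.arange(1.0, 11), np.ones(10, int), gm)
        labels = two_snp_groups(gm, "rs0", "rs1")
        with pytest.raises(ValueError, match="baseline"):
            combined_group_association(labels, ct, covariate_preset=[])


class TestAdjustedScan:
    def test_subgroup_bookkeeping(self, planted_cohort):
        gm, ct = planted_cohort
        n_wt = int((ct.data["kras"] == "wt").sum())
        out = adjusted_scan(["rs0"], gm, ct, covariate_preset=["age"],
                            subgroup=("kras", "wt"), models=("dominant",))
        assert out.loc[0, "n"] == n_wt

    def test_monomorphic_in_subgroup_flagged(self, planted_cohort):
        gm, ct = planted_cohort
        from snpsurv.io import GenotypeMatrix

        codes = gm.codes.copy()
        codes[:, 1] = 0.0  # monomorphic SNP
        gm2 = GenotypeMatrix(gm.patient_ids, gm.snps.copy(), codes)
        out = adjusted_scan(["rs1"], gm2, ct, covariate_preset=["age"],
                            subgroup=("kras", "wt"), models=("dominant",))
        assert not out.loc[0, "estimable"]
        assert "empty genotype group" in out.loc[0, "message"]

    def test_identical_cohort_fisher_is_one(self, planted_cohort):
        gm, _ = planted_cohort
        assert genotype_distribution_fisher(gm, gm, "rs0") == pytest.approx(1.0)
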