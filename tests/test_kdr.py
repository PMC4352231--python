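import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import resistkit as rk
from resistkit.datasets import load_kdr_allele_counts
from resistkit.kdr import HAPLOTYPES, genotype_counts

from oracles import clopper_pearson_oracle, fisher_two_sided_oracle, grid_haplotype_mle


def row(wt, mut, locus="L1014F", status="control", site="VK7", rnd="Jul-11"):
    return rk.AlleleCountRow(site, rnd, status, locus, wt, mut)


class TestAlleleFrequency:
    def test_published_representative_cell(self):
        res = rk.allele_frequency(row(22, 102))
        assert round(res.f, 3) == 0.823

    def test_boundary_all_mutant(self):
        res = rk.allele_frequency(row(0, 50))
        assert res.f == 1.0 and res.ci_high == 1.0

    def test_clopper_pearson_matches_beta_oracle(self):
        res = rk.allele_frequency(row(22, 102))
        lo, hi = clopper_pearson_oracle(102, 124)
        assert res.ci_low == pytest.approx(lo, abs=1e-6)
        assert res.ci_high == pytest.approx(hi, abs=1e-6)

    def test_method_resolution_against_published_interval(self):
        """Clopper-Pearson is the closer method to the published 0.744-0.886
        (it reproduces the lower bound exactly; Wilson matches neither)."""
        cp = rk.allele_frequency(row(22, 102), "clopper_pearson")
        wi = rk.allele_frequency(row(22, 102), "wilson")
        dev = lambda r: max(abs(r.ci_low - 0.744), abs(r.ci_high - 0.886))
        assert round(cp.ci_low, 3) == 0.744
        assert dev(cp) < dev(wi)
        assert dev(cp) <= 0.0015

    def test_all_published_frequencies_reproduced_at_3dp(self):
        tab = load_kdr_allele_counts()
        for r in tab.itertuples():
            res = rk.allele_frequency(
                row(r.count_wildtype, r.count_mutant, r.locus, r.status, r.site, r.period)
            )
            assert round(res.f, 3) == r.printed_f, r

    def test_ci_contains_point_estimate_and_stays_in_unit_interval(self):
        for wt, mut in [(0, 10), (10, 0), (3, 7), (50, 50)]:
            for method in ("clopper_pearson", "wilson"):
                res = rk.allele_frequency(row(wt, mut), method)
                assert 0.0 <= res.ci_low <= res.f <= res.ci_high <= 1.0

    def test_zero_alleles_is_error(self):
        with pytest.raises(ValueError, match="zero alleles"):
            rk.allele_frequency(row(0, 0))

    def test_clopper_pearson_coverage_at_table_sample_size(self):
        """Simulated coverage >= 95% at n = 124 across true frequencies."""
        rng = np.random.default_rng(0)
        n = 124
        for f in np.arange(0.1, 0.95, 0.1):
            xs = rng.binomial(n, f, size=500)
            cover = 0
            for x in np.unique(xs):
                lo, hi = clopper_pearson_oracle(int(x), n)
                cover += ((lo <= f) & (f <= hi)) * (xs == x).sum()
            assert cover / 500 >= 0.95 - 0.02  # binomial error margin


class TestFisherSurvivalTest:
    def test_published_october_2011_significance_call(self):
        dead = row(42, 194, status="dead", rnd="Oct-11")
        surv = row(15, 133, status="survivor", rnd="Oct-11")
        p, orat = rk.fisher_survival_test(dead, surv)
        assert p == pytest.approx(0.04, abs=0.005)
        assert p < 0.05
        assert orat > 1  # mutant allele enriched in survivors

    def test_identical_proportions_give_p_one(self):
        p, orat = rk.fisher_survival_test(
            row(10, 30, status="dead"), row(10, 30, status="survivor")
        )
        assert p == pytest.approx(1.0)
        assert orat == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        table = [(3, 7, 8, 2), (0, 5, 5, 0), (1, 1, 1, 1), (12, 3, 4, 9)]
        for a, b, c, d in table:
            p, _ = rk.fisher_survival_test(
                row(b, a, status="dead"), row(d, c, status="survivor")
            )
            # oracle on the (mut, wt) x (dead, surv) table
            assert p == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-12
            )

    def test_zero_cell_gets_haldane_correction(self):
        p, orat = rk.fisher_survival_test(
            row(10, 0, status="dead"), row(5, 5, status="survivor")
        )
        assert np.isfinite(orat) and orat > 1

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="locus"):
            rk.fisher_survival_test(
                row(1, 2, locus="L1014F", status="dead"),
                row(1, 2, locus="N1575Y", status="survivor"),
            )

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=25)] * 4).filter(
            lambda t: (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0
        )
    )
    def test_invariance_under_row_and_column_swaps(self, t):
        a, b, c, d = t
        p0, _ = rk.fisher_survival_test(
            row(b, a, status="dead"), row(d, c, status="survivor")
        )
        # swap rows (dead <-> survivor)
        p1, _ = rk.fisher_survival_test(
            row(d, c, status="dead"), row(b, a, status="survivor")
        )
        # swap columns (wildtype <-> mutant)
        p2, _ = rk.fisher_survival_test(
            row(a, b, status="dead"), row(c, d, status="survivor")
        )
        assert p0 == pytest.approx(p1, abs=1e-12)
        assert p0 == pytest.approx(p2, abs=1e-12)


class TestChiSquareHomogeneity:
    def test_identical_rows_are_homogeneous(self):
        stat, df, p, warn = rk.chi_square_homogeneity([row(10, 30), row(10, 30)])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_two_by_two_equals_squared_z(self):
        r1, r2 = row(30, 70), row(45, 55)
        stat, df, p, _ = rk.chi_square_homogeneity([r1, r2])
        p1, p2, n1, n2 = 0.7, 0.55, 100, 100
        pool = (70 + 55) / 200
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z**2, rel=1e-12)

    def test_three_by_two_hand_computation(self):
        rows = [row(10, 20), row(15, 15), row(20, 10)]
        stat, df, p, _ = rk.chi_square_homogeneity(rows)
        assert df == 2
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-12)

    def test_low_expected_count_flagged(self):
        _, _, _, warn = rk.chi_square_homogeneity([row(0, 1), row(1, 150)])
        assert warn


def geno_frame(counts):
    """Expand a {(g1014, g1575): n} dict to a genotype table."""
    rows = []
    i = 0
    for (g1, g2), n in counts.items():
        for _ in range(n):
            i += 1
            rows.append((f"S{i}", "VK7", "Oct-11", "control", g1, g2))
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "site", "round", "status",
                 "genotype_1014", "genotype_1575"],
    )


class TestEMHaplotypes:
    def test_no_double_heterozygotes_equals_direct_counting(self):
        g = geno_frame({("FF", "NN"): 10, ("LF", "NN"): 6, ("FF", "NY"): 4})
        fit = rk.em_haplotype_frequencies(g)
        # 40 haplotypes: F-N = 2*10 + 6 + 4 = 30, L-N = 6, F-Y = 4
        assert fit.frequencies["F-N"] == pytest.approx(30 / 40)
        assert fit.frequencies["L-N"] == pytest.approx(6 / 40)
        assert fit.frequencies["F-Y"] == pytest.approx(4 / 40)
        assert fit.frequencies["L-Y"] == pytest.approx(0.0)

    def test_matches_grid_search_oracle_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for i in range(50):
            # random genotype counts, n <= 40, ensuring some double hets
            counts = np.zeros((3, 3))
            n = rng.integers(8, 41)
            idx = rng.integers(0, 3, size=(n, 2))
            for a, b in idx:
                counts[a, b] += 1
            fit = rk.em_haplotype_frequencies(counts, tol=1e-12)
            grid_freqs, grid_ll = grid_haplotype_mle(counts)
            assert np.abs(fit.as_array() - grid_freqs).max() <= 1e-3, i
            # and EM never undershoots the grid's likelihood meaningfully
            assert fit.log_likelihood >= grid_ll - 1e-6

    def test_loglik_monotone_and_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 10, size=(3, 3)).astype(float)
            if counts.sum() == 0:
                continue
            fit = rk.em_haplotype_frequencies(counts)
            tr = fit.loglik_trace
            assert all(b >= a - 1e-9 for a, b in zip(tr, tr[1:]))
            assert sum(fit.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_structural_zero_recovered(self):
        params = rk.GenotypeSimParams(
            haplotype_freqs={"L-N": 0.15, "F-N": 0.55, "F-Y": 0.30},
            n_per_arm=5000, seed=2,
        )
        fit = rk.em_haplotype_frequencies(rk.simulate_genotypes(params))
        assert fit.frequencies["L-Y"] <= 0.005

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="no specimens"):
            rk.em_haplotype_frequencies(np.zeros((3, 3)))

    def test_triallelic_codes_need_opt_in(self):
        g = geno_frame({("FF", "NN"): 3})
        g.loc[0, "genotype_1014"] = "LS"
        with pytest.raises(ValueError, match="1014S"):
            genotype_counts(g)
        counts = genotype_counts(g, allow_triallelic=True)
        # LS collapses to LL; the other two specimens stay FF
        assert counts.sum() == 3 and counts[0, 0] == 1 and counts[2, 0] == 2


class TestHaplotypeAssociation:
    def test_hand_cross_product_on_unambiguous_data(self):
        # survivors: 15 FF/YY + 35 FF/NN ; dead: 5 FF/YY + 45 FF/NN
        # F-Y counts: 30 vs 10 of 100 haplotypes per arm -> OR = (30*90)/(70*10)
        surv = geno_frame({("FF", "YY"): 15, ("FF", "NN"): 35})
        surv["status"] = "survivor"
        dead = geno_frame({("FF", "YY"): 5, ("FF", "NN"): 45})
        dead["status"] = "dead"
        out = rk.haplotype_association(pd.concat([surv, dead], ignore_index=True))
        fy = out.set_index("haplotype").loc["F-Y"]
        assert fy["odds_ratio"] == pytest.approx((30 * 90) / (70 * 10), rel=1e-9)

    def test_identical_distributions_give_null(self):
        grp = geno_frame({("FF", "NY"): 10, ("LF", "NN"): 10, ("FF", "NN"): 20})
        surv = grp.copy(); surv["status"] = "survivor"
        dead = grp.copy(); dead["status"] = "dead"
        out = rk.haplotype_association(pd.concat([surv, dead], ignore_index=True))
        assert np.allclose(out["odds_ratio"], 1.0, atol=1e-9)
        assert np.allclose(out["chi_square"], 0.0, atol=1e-9)

    def test_per_group_mode_runs_and_agrees_on_unambiguous_data(self):
        surv = geno_frame({("FF", "YY"): 15, ("FF", "NN"): 35})
        surv["status"] = "survivor"
        dead = geno_frame({("FF", "YY"): 5, ("FF", "NN"): 45})
        dead["status"] = "dead"
        both = pd.concat([surv, dead], ignore_index=True)
        pooled = rk.haplotype_association(both, em_mode="pooled")
        grouped = rk.haplotype_association(both, em_mode="per_group")
        assert np.allclose(
            pooled["odds_ratio"], grouped["odds_ratio"], rtol=1e-9
        )

    def test_empty_group_rejected(self):
        surv = geno_frame({("FF", "NN"): 5})
        surv["status"] = "survivor"
        with pytest.raises(ValueError, match="non-empty"):
            rk.haplotype_association(surv)

    def test_planted_or_recovered_in_band(self):
        """Planted per-copy survival OR 2.7 for F-Y is recovered near its
        marginal (allelic) value over repeated simulation."""
        ors = []
        for s in range(40):
            g = rk.simulate_genotypes(
                rk.GenotypeSimParams(
                    survival_odds_ratio_per_haplotype={"F-Y": 2.7},
                    n_per_arm=2000, seed=1000 + s,
                )
            )
            out = rk.haplotype_association(g)
            ors.append(float(out.set_index("haplotype").loc["F-Y", "odds_ratio"]))
        assert 2.2 <= np.median(ors) <= 3.3
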