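"""Pedigree relationship matrix and the mixed-model association machinery:
tabular-method values against textbook cases and a gene-dropping Monte Carlo
oracle, OLS equivalence in the degenerate case, LRT properties, coding
symmetry, and the targeted 2-SNP / interaction models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from feednet.gwas import (
    Pedigree,
    PedigreeError,
    PedigreeMixedLM,
    build_nrm,
    default_trait_fixed_effects,
    fit_null_model,
    run_gwas,
)
from feednet.gwas import test_interaction as interaction_test
from feednet.gwas import test_snp as snp_test
from feednet.gwas import test_two_snp as two_snp_test


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


FIVE_ANIMAL = ped_frame(
    [
        ("S", "0", "0"),
        ("D", "0", "0"),
        ("C1", "S", "D"),
        ("C2", "S", "D"),
        ("X", "C1", "C2"),  # offspring of full sibs
    ]
)


class TestRelationshipMatrix:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(ped_frame([("A", "0", "0"), ("B", "0", "0")]))
        A = build_nrm(ped)
        assert np.allclose(A.to_numpy(), np.eye(2))

    def test_textbook_relationships(self):
        A = build_nrm(Pedigree(FIVE_ANIMAL))
        assert A.loc["S", "C1"] == pytest.approx(0.5)  # parent-offspring
        assert A.loc["C1", "C2"] == pytest.approx(0.5)  # full sibs
        assert A.loc["X", "X"] == pytest.approx(1.25)  # inbred: 1 + 0.5*0.5
        assert A.loc["S", "D"] == pytest.approx(0.0)

    def test_half_sibs(self):
        ped = Pedigree(
            ped_frame(
                [
                    ("S", "0", "0"),
                    ("D1", "0", "0"),
                    ("D2", "0", "0"),
                    ("H1", "S", "D1"),
                    ("H2", "S", "D2"),
                ]
            )
        )
        A = build_nrm(ped)
        assert A.loc["H1", "H2"] == pytest.approx(0.25)

    def test_against_gene_dropping_oracle(self):
        """Expected relationship = 2 x kinship estimated by allele dropping."""
        ped = Pedigree(FIVE_ANIMAL)
        A = build_nrm(ped)
        rng = np.random.default_rng(42)
        n_loci = 40_000
        # drop alleles locus-by-locus; founder alleles get unique labels
        counter = 0
        alleles = {}
        for animal, sire, dam in ped.df[["animal", "sire", "dam"]].itertuples(
            index=False
        ):
            gam = []
            for parent in (sire, dam):
                if parent == "0":
                    gam.append(np.full(n_loci, counter))
                    counter += 1
                else:
                    h = alleles[parent]
                    pick = rng.integers(0, 2, n_loci)
                    gam.append(np.where(pick == 0, h[0], h[1]))
            alleles[animal] = gam
        for a in ("S", "C1", "C2", "X"):
            for b in ("C1", "C2", "X"):
                ha, hb = alleles[a], alleles[b]
                ibd = sum(
                    (ha[i] == hb[j]).mean() for i in range(2) for j in range(2)
                )
                kin = ibd / 4.0
                if a == b:
                    kin = (2 + (ha[0] == ha[1]).mean() * 2) / 4.0
                assert 2 * kin == pytest.approx(A.loc[a, b], abs=0.02)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError):
            Pedigree(ped_frame([("A", "B", "0"), ("B", "A", "0")]))


def simulate_mixed(rng, n=200, h2=0.5, beta_snp=0.0, maf=0.3):
    """Half-sib families -> non-trivial A; returns y, X, snp, A."""
    n_sires = 20
    rows = [(f"S{i}", "0", "0") for i in range(n_sires)]
    rows += [(f"D{i}", "0", "0") for i in range(n)]
    rows += [(f"P{i}", f"S{i % n_sires}", f"D{i}") for i in range(n)]
    ped = Pedigree(ped_frame(rows))
    A = build_nrm(ped)
    ids = [f"P{i}" for i in range(n)]
    A_sub = A.loc[ids, ids].to_numpy()
    L = np.linalg.cholesky(A_sub + 1e-10 * np.eye(n))
    u = L @ rng.standard_normal(n) * np.sqrt(h2)
    e = rng.standard_normal(n) * np.sqrt(1 - h2)
    snp = rng.binomial(2, maf, n) - 1.0
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([1.0, 0.5]) + beta_snp * snp + u + e
    return y, X, snp, A_sub


class TestMixedModel:
    def test_identity_A_equals_ols(self, rng):
        """With A = I and variance ratio 0, the LRT p matches the OLS F test."""
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        snp = rng.binomial(2, 0.4, n) - 1.0
        y = X @ np.array([2.0, 1.0]) + 0.3 * snp + rng.standard_normal(n)
        model = PedigreeMixedLM(y, X, np.eye(n))
        null = model.fit(lambda_=0.0)
        res = snp_test(null, snp)
        ols_null = sm.OLS(y, X).fit()
        ols_full = sm.OLS(y, np.column_stack([X, snp])).fit()
        lrt_ols = 2 * (ols_full.llf - ols_null.llf)
        assert res.lrt == pytest.approx(lrt_ols, abs=1e-6)
        assert res.effect == pytest.approx(ols_full.params[-1], abs=1e-8)

    def test_identity_A_flags_unidentifiable_split(self, rng):
        n = 60
        y = rng.standard_normal(n)
        model = PedigreeMixedLM(y, np.ones((n, 1)), np.eye(n))
        fit = model.fit()
        assert any("unidentifiable" in f for f in fit.flags)

    def test_variance_ratio_recovered(self):
        """sigma2_u/sigma2_e = 1 on 500 animals in full-sib families is
        recovered within a factor of 2 in most replicates, with an unbiased
        centre (the ratio's ML sampling spread at this size is wide)."""
        n_fam, fam_size = 50, 10
        rows = []
        for f in range(n_fam):
            rows += [(f"S{f}", "0", "0"), (f"D{f}", "0", "0")]
            rows += [(f"P{f}_{i}", f"S{f}", f"D{f}") for i in range(fam_size)]
        ped = Pedigree(ped_frame(rows))
        ids = [f"P{f}_{i}" for f in range(n_fam) for i in range(fam_size)]
        A = build_nrm(ped).loc[ids, ids].to_numpy()
        n = len(ids)
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        eig = np.linalg.eigh(A)
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(30):
            y = 2.0 + L @ rng.standard_normal(n) + rng.standard_normal(n)
            fit = PedigreeMixedLM(y, np.ones((n, 1)), A, eig=eig).fit()
            ratios.append(fit.lambda_)
        ratios = np.array(ratios)
        assert np.mean((ratios >= 0.5) & (ratios <= 2.0)) >= 0.8
        assert 0.6 <= np.median(ratios) <= 1.6

    def test_zero_variance_trait_rejected(self):
        with pytest.raises(ValueError):
            PedigreeMixedLM(np.ones(10), np.ones((10, 1)), np.eye(10))

    def test_lrt_nonnegative_and_effect_recovery(self, rng):
        y, X, snp, A = simulate_mixed(rng, n=300, h2=0.4, beta_snp=0.5)
        null = fit_null_model(y, X, A)
        res = snp_test(null, snp)
        assert res.lrt >= -1e-6
        assert abs(res.effect - 0.5) < 3 * res.se
        assert res.p_value < 0.05

    def test_coding_symmetry(self, rng):
        """Flipping allele coding negates g and leaves the p-value unchanged."""
        y, X, snp, A = simulate_mixed(rng, n=150, h2=0.3, beta_snp=0.4)
        null = fit_null_model(y, X, A)
        res1 = snp_test(null, snp)
        res2 = snp_test(null, -snp)
        assert res2.effect == pytest.approx(-res1.effect, rel=1e-9)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-9)

    def test_monomorphic_flagged(self, rng):
        y, X, _, A = simulate_mixed(rng, n=80)
        null = fit_null_model(y, X, A)
        res = snp_test(null, np.zeros(80))
        assert not res.testable
        assert res.p_value == 1.0

    def test_collinear_with_fixed_effect_flagged(self, rng):
        y, X, _, A = simulate_mixed(rng, n=80)
        null = fit_null_model(y, X, A)
        res = snp_test(null, X[:, 1])
        assert not res.testable and res.flag == "collinear"

    def test_missing_genotypes_mean_imputed(self, rng):
        y, X, snp, A = simulate_mixed(rng, n=200, h2=0.3, beta_snp=0.5)
        null = fit_null_model(y, X, A)
        snp_missing = snp.copy()
        snp_missing[:10] = np.nan
        res = snp_test(null, snp_missing)
        assert res.testable
        assert abs(res.effect - 0.5) < 4 * res.se


class TestTwoSnpModels:
    def test_joint_estimates_match_single_for_independent_loci(self, rng):
        n = 400
        y, X, snp_a, A = simulate_mixed(rng, n=n, h2=0.3, beta_snp=0.6)
        snp_b = rng.binomial(2, 0.4, n) - 1.0
        y = y + 0.4 * snp_b
        null = fit_null_model(y, X, A)
        single_a = snp_test(null, snp_a)
        single_b = snp_test(null, snp_b)
        res_a, res_b, _ = two_snp_test(null, snp_a, snp_b)
        assert res_a.effect == pytest.approx(single_a.effect, abs=2 * single_a.se)
        assert res_b.effect == pytest.approx(single_b.effect, abs=2 * single_b.se)

    def test_identical_snps_collinear(self, rng):
        y, X, snp, A = simulate_mixed(rng, n=100)
        null = fit_null_model(y, X, A)
        res_a, res_b, _ = two_snp_test(null, snp, snp)
        assert not res_a.testable and res_a.flag == "collinear"

    def test_null_effect_within_2se_of_zero(self, rng):
        n = 300
        y, X, snp_a, A = simulate_mixed(rng, n=n, h2=0.3, beta_snp=0.5)
        snp_b = rng.binomial(2, 0.3, n) - 1.0  # no effect
        null = fit_null_model(y, X, A)
        _, res_b, _ = two_snp_test(null, snp_a, snp_b)
        assert abs(res_b.effect) < 3 * res_b.se


class TestInteractionModel:
    def test_epistasis_detected(self, rng):
        n = 1000
        rows = [(f"P{i}", "0", "0") for i in range(n)]
        ped = Pedigree(ped_frame(rows))
        A = np.eye(n)
        snp_a = rng.binomial(2, 0.5, n) - 1.0
        snp_b = rng.binomial(2, 0.5, n) - 1.0
        y = 0.3 * snp_a + 0.3 * snp_b + 1.0 * snp_a * snp_b + rng.standard_normal(n)
        null = PedigreeMixedLM(y, np.ones((n, 1)), A).fit(lambda_=0.0)
        res = interaction_test(null, snp_a, snp_b)
        assert res.testable
        assert res.p_value < 1e-6
        assert abs(res.effect - 1.0) < 3 * res.se

    def test_monomorphic_partner_untestable(self, rng):
        y, X, snp, A = simulate_mixed(rng, n=80)
        null = fit_null_model(y, X, A)
        res = interaction_test(null, snp, np.zeros(80))
        assert not res.testable


class TestGwasScan:
    def test_trait_config_and_bookkeeping(self, small_study, derived_phenotypes):
        config = default_trait_fixed_effects(["RFI", "Arg"])
        assert config["RFI"] == ["birth_year", "season"]
        assert config["Arg"] == ["sampling_year", "measurement_day"]

    def test_row_count_and_determinism(self, small_study, derived_phenotypes):
        pheno, _ = derived_phenotypes
        g = small_study.f2_genotypes().subset(
            snps=small_study.genotypes.snp_ids[:50]
        )
        config = default_trait_fixed_effects(["RFI", "dEI"])
        r1 = run_gwas(pheno, g, config, small_study.relationship,
                      traits=["RFI", "dEI"])
        r2 = run_gwas(pheno, g, config, small_study.relationship,
                      traits=["RFI", "dEI"])
        assert len(r1) == 100
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_trait_config_rejected(self, small_study, derived_phenotypes):
        pheno, _ = derived_phenotypes
        g = small_study.f2_genotypes()
        with pytest.raises(KeyError, match="ADG"):
            run_gwas(pheno, g, {"RFI": ["birth_year"]},
                     small_study.relationship, traits=["ADG"])
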