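"""Synthetic-cohort generator: frequencies, ancestry tracks, genotypes,
relatives, covariates and phenotypes."""

import numpy as np
import pandas as pd
import pytest

from admixjoint import (
    AdmixtureParams,
    CohortSimulator,
    PhenotypeModel,
    simulate_ancestral_frequencies,
    simulate_covariates_ut,
    simulate_genotypes,
    simulate_local_ancestry,
    simulate_phenotype,
    simulate_relatives,
)
from admixjoint.sim import DEFAULT_CHROM_LENGTHS, SimulatedCohort


class TestAncestralFrequencies:
    def test_fst_zero_identical(self):
        m = simulate_ancestral_frequencies(500, fst=0.0, seed=1)
        assert np.array_equal(m.freq_pop1, m.freq_pop2)

    def test_balding_nichols_variance_identity(self):
        """E[(p1-p2)^2 / (p0(1-p0))] = 2F under the construction (Monte Carlo).

        Computed against the known base frequency; clipping at 0.01 biases the
        statistic slightly downward, hence the tolerance band.
        """
        fst = 0.15
        rng = np.random.default_rng(123)
        # independent Monte-Carlo oracle of the same construction
        p0 = rng.uniform(0.05, 0.95, 20_000)
        a = p0 * (1 - fst) / fst
        b = (1 - p0) * (1 - fst) / fst
        d = rng.beta(a, b) - rng.beta(a, b)
        oracle = np.mean(d**2 / (p0 * (1 - p0)))
        assert oracle == pytest.approx(2 * fst, rel=0.05)
        # the generator reproduces the same standardized differentiation
        m = simulate_ancestral_frequencies(20_000, fst=fst, seed=9)
        pbar = (m.freq_pop1 + m.freq_pop2) / 2
        stat = np.mean((m.freq_pop1 - m.freq_pop2) ** 2 / (pbar * (1 - pbar)))
        assert stat == pytest.approx(oracle, rel=0.15)

    def test_deterministic(self):
        a = simulate_ancestral_frequencies(100, fst=0.1, seed=5)
        b = simulate_ancestral_frequencies(100, fst=0.1, seed=5)
        assert np.array_equal(a.freq_pop1, b.freq_pop1)
        assert np.array_equal(a.snp_positions, b.snp_positions)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_ancestral_frequencies(10, fst=1.0)
        with pytest.raises(ValueError):
            simulate_ancestral_frequencies(0, fst=0.1)

    def test_positions_monotone_within_chromosome(self):
        m = simulate_ancestral_frequencies(1000, fst=0.1, seed=2)
        for c in np.unique(m.snp_chrom):
            assert (np.diff(m.snp_positions[m.snp_chrom == c]) >= 0).all()


class TestLocalAncestry:
    def test_alpha_one_all_two(self):
        m = simulate_ancestral_frequencies(200, fst=0.1, seed=3)
        local, _ = simulate_local_ancestry(m, AdmixtureParams(alpha=1.0, seed=3), 10)
        assert (local.to_numpy() == 2).all()

    def test_mean_matches_alpha(self):
        m = simulate_ancestral_frequencies(300, fst=0.1, seed=4)
        local, _ = simulate_local_ancestry(m, AdmixtureParams(alpha=0.8, seed=4), 400)
        assert local.to_numpy().mean() / 2 == pytest.approx(0.8, abs=0.01)

    def test_switch_count_expectation(self):
        """Mean diploid switch count ~= 2 L g * 2 alpha (1-alpha).

        Markers are dense enough here that nearly every ancestry change is
        visible between adjacent SNPs; the marker grid can only hide switches,
        hence the asymmetric tolerance.
        """
        from admixjoint import count_ancestry_switches

        alpha, g = 0.8, 7
        m = simulate_ancestral_frequencies(4000, fst=0.1, seed=6)
        local, _ = simulate_local_ancestry(
            m, AdmixtureParams(alpha=alpha, generations=g, seed=6), 300
        )
        eff = count_ancestry_switches(local, m.snp_table())
        L = sum(DEFAULT_CHROM_LENGTHS)
        expected = 2 * L * g * 2 * alpha * (1 - alpha)
        assert 0.80 * expected <= eff.t_adm <= 1.02 * expected


class TestGenotypes:
    @staticmethod
    def _model_with_freqs(p1, p2, n_snps):
        m = simulate_ancestral_frequencies(n_snps, fst=0.1, seed=7)
        m.freq_pop1 = np.full(n_snps, p1)
        m.freq_pop2 = np.full(n_snps, p2)
        return m

    def test_fully_informative_marker(self):
        m = self._model_with_freqs(0.99, 0.01, 50)
        m.freq_pop1[:] = 1 - 1e-12
        m.freq_pop2[:] = 1e-12
        local, haps = simulate_local_ancestry(m, AdmixtureParams(alpha=0.5, seed=8), 30)
        geno, _ = simulate_genotypes(m, haps, seed=8, missing_rate=0.0)
        assert np.array_equal(geno.to_numpy(), local.to_numpy().astype(float))

    def test_uninformative_marker_independent_of_ancestry(self):
        m = self._model_with_freqs(0.5, 0.5, 2000)
        local, haps = simulate_local_ancestry(m, AdmixtureParams(alpha=0.5, seed=9), 50)
        geno, _ = simulate_genotypes(m, haps, seed=9, missing_rate=0.0)
        r = np.corrcoef(geno.to_numpy().ravel(), local.to_numpy().ravel())[0, 1]
        assert abs(r) < 0.01

    def test_no_missing_at_rate_zero(self):
        m = self._model_with_freqs(0.7, 0.3, 100)
        _, haps = simulate_local_ancestry(m, AdmixtureParams(seed=10), 20)
        geno, _ = simulate_genotypes(m, haps, seed=10, missing_rate=0.0)
        assert np.isfinite(geno.to_numpy()).all()

    def test_shape_mismatch_rejected(self):
        m = self._model_with_freqs(0.7, 0.3, 100)
        _, haps = simulate_local_ancestry(m, AdmixtureParams(seed=10), 5)
        with pytest.raises(ValueError):
            simulate_genotypes(m, haps[..., :50], seed=0)

    def test_hwe_holds_in_founders(self):
        """Unlinked neutral markers in unrelated founders: exact-test rejection
        rate stays near nominal."""
        from admixjoint import hwe_exact_test

        cohort = CohortSimulator(n_ind=150, n_snps=400, n_related=0, seed=20,
                                 missing_rate=0.0, fst=0.0).simulate()
        rejected = 0
        for c in cohort.genotypes.columns:
            g = cohort.genotypes[c].to_numpy()
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                               int((g == 2).sum()))
            rejected += p < 0.05
        # binomial(400, ~0.05); exact test is conservative so low counts are fine
        assert rejected <= 40


class TestRelatives:
    def test_identity_when_no_relatives(self, small_cohort):
        out = simulate_relatives(small_cohort, 0, 0, seed=0)
        assert out is small_cohort

    def test_pedigree_and_shapes(self, small_cohort):
        assert len(small_cohort.pedigree) == 12
        assert small_cohort.genotypes.shape[0] == 100
        assert small_cohort.local_ancestry.shape == small_cohort.genotypes.shape

    def test_too_many_relatives_rejected(self):
        cohort = CohortSimulator(n_ind=10, n_snps=50, n_related=0, seed=1).simulate()
        with pytest.raises(ValueError):
            simulate_relatives(cohort, n_parent_offspring=6, seed=1)

    def test_genotype_ancestry_consistency_in_children(self, small_cohort):
        """Children's diploid codes equal their haploid track sums."""
        la = small_cohort.local_ancestry.to_numpy()
        haps = small_cohort.hap_ancestry
        assert np.array_equal(la, haps.sum(axis=1))


class TestCovariates:
    def test_defaults_match_cohort_scale(self):
        df = simulate_covariates_ut(5000, seed=11)
        assert df["ut_other"].mean() == pytest.approx(1.48, abs=0.1)
        assert df["ut_self"].mean() == pytest.approx(1.62, abs=0.1)
        assert df["ut_self"].between(0, 9).all()
        assert df["ut_other"].between(0, 9).all()
        assert df["age"].between(25, 65).all()
        assert df["sex"].isin([0, 1]).all()
        assert df["bmi"].mean() == pytest.approx(32.4, abs=1.0)

    def test_reproducible(self):
        a = simulate_covariates_ut(50, seed=12)
        b = simulate_covariates_ut(50, seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_covariates_ut(10, age_sd=-1)


class TestPhenotype:
    @staticmethod
    def _mini_cohort(n=40, m=30, seed=13):
        return CohortSimulator(n_ind=n, n_snps=m, n_related=0, seed=seed,
                               missing_rate=0.0).simulate()

    def test_all_zero_betas_no_noise_constant(self):
        cohort = self._mini_cohort()
        model = PhenotypeModel(intercept=120.0, beta_age=0, beta_sex=0,
                               beta_edu=0, beta_bmi=0, noise_sd=0.0)
        out = simulate_phenotype(cohort, model, seed=1)
        assert np.allclose(out["sbp_latent"], 120.0)

    def test_linearity_of_snp_effect(self):
        cohort = self._mini_cohort()
        base = PhenotypeModel(beta_age=0, beta_sex=0, beta_edu=0, beta_bmi=0,
                              noise_sd=0.0, causal_snps={5: 5.0})
        doubled = PhenotypeModel(beta_age=0, beta_sex=0, beta_edu=0, beta_bmi=0,
                                 noise_sd=0.0, causal_snps={5: 10.0})
        y1 = simulate_phenotype(cohort, base, seed=2)["sbp_latent"]
        y2 = simulate_phenotype(cohort, doubled, seed=2)["sbp_latent"]
        g = cohort.genotypes.iloc[:, 5]
        contrast1 = y1[g == 2].mean() - y1[g == 0].mean()
        contrast2 = y2[g == 2].mean() - y2[g == 0].mean()
        assert contrast1 == pytest.approx(10.0)
        assert contrast2 == pytest.approx(2 * contrast1)

    def test_medication_roundtrip(self):
        """raw + offset*med equals the latent adjusted-scale phenotype."""
        cohort = self._mini_cohort(seed=14)
        model = PhenotypeModel()
        out = simulate_phenotype(cohort, model, seed=3)
        back = out["sbp_raw"] + model.med_offset * out["med_flag"]
        assert np.allclose(back, out["sbp_latent"])

    def test_causal_index_out_of_range(self):
        cohort = self._mini_cohort()
        with pytest.raises(ValueError):
            simulate_phenotype(cohort, PhenotypeModel(causal_snps={999: 1.0}), seed=4)


class TestCohortSimulator:
    def test_stated_world_defaults(self):
        sim = CohortSimulator()
        assert sim.n_ind == 157
        assert sim.n_related == 37
        assert sim.alpha == 0.8
        assert sim.generations == 7
        assert sim.n_snps == 27_559

    def test_medicated_fraction_near_target(self):
        cohort = CohortSimulator(n_ind=500, n_snps=100, n_related=0, seed=15).simulate()
        assert cohort.samples["med_flag"].mean() == pytest.approx(48 / 157, abs=0.08)

    def test_deterministic(self):
        a = CohortSimulator(n_ind=40, n_snps=60, n_related=5, seed=16).simulate()
        b = CohortSimulator(n_ind=40, n_snps=60, n_related=5, seed=16).simulate()
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_roundtrip_files(self, tmp_path, small_cohort):
        from admixjoint import read_genotypes, write_cohort

        paths = write_cohort(small_cohort, tmp_path)
        geno, _ = read_genotypes(paths["genotypes"])
        pd.testing.assert_frame_equal(geno, small_cohort.genotypes, check_names=False)
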