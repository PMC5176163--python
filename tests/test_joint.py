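"""Bayesian joint mapping: UT coding, stratified fits, IVW, ABF, posteriors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from admixjoint import (
    CohortSimulator,
    JointAdmixtureAssociation,
    adjust_bp_for_medication,
    approx_bayes_factor,
    count_ancestry_switches,
    dichotomize_ut,
    global_ancestry,
    ivw_combine,
    model3_maf_filter,
    posterior_from_prior,
    stratified_association,
)
from admixjoint.joint import StratumFit
from admixjoint.scan import SCAN_COVARIATES


class TestDichotomize:
    @pytest.mark.parametrize(
        "count,scheme,expected",
        [
            (0, "no_yes", 0), (0, "low_high", 0),
            (1, "no_yes", 1), (2, "no_yes", 1),
            (2, "low_high", 0), (3, "low_high", 1), (9, "low_high", 1),
        ],
    )
    def test_boundaries(self, count, scheme, expected):
        assert dichotomize_ut(count, scheme) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dichotomize_ut(10, "no_yes")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            dichotomize_ut(1, "maybe")


class TestIvw:
    def test_single_stratum_passthrough(self):
        beta, se, z, p = ivw_combine([StratumFit(1, 30, 2.5, 0.8)])
        assert beta == pytest.approx(2.5)
        assert se == pytest.approx(0.8)

    def test_equal_weights(self):
        fits = [StratumFit(0, 20, 1.0, 1.0), StratumFit(2, 20, 3.0, 1.0)]
        beta, se, _, _ = ivw_combine(fits)
        assert beta == pytest.approx(2.0)
        assert se == pytest.approx(1 / math.sqrt(2))

    def test_hand_computed_weights(self):
        fits = [StratumFit(0, 20, 0.0, 1.0), StratumFit(2, 20, 2.0, 0.5)]
        beta, se, _, _ = ivw_combine(fits)
        assert beta == pytest.approx(1.6)
        assert se == pytest.approx(1 / math.sqrt(5), abs=1e-4)  # 0.4472

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ivw_combine([StratumFit(0, 10, 1.0, 0.0)])


class TestAbf:
    def test_point_null_prior_is_uninformative(self):
        assert approx_bayes_factor(3.0, 1.0, 0.0) == 1.0

    def test_null_data_shrink_belief(self):
        abf = approx_bayes_factor(0.0, 1.0, 4.0)
        assert abf == pytest.approx(math.sqrt(1 / 5))
        assert abf < 1.0

    def test_closed_form_z2(self):
        # se=1, W=1, z=2: ABF = (1/sqrt(2)) * e
        assert approx_bayes_factor(2.0, 1.0, 1.0) == pytest.approx(math.e / math.sqrt(2))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            approx_bayes_factor(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            approx_bayes_factor(np.nan, 1.0, 1.0)

    @given(st.floats(0.1, 50.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    @settings(deadline=None, max_examples=60)
    def test_scale_invariance(self, scale, se, w_ratio):
        """Posterior machinery depends only on z and W/se^2: rescaling (beta,
        se) by a common factor while rescaling W by its square changes nothing."""
        beta = 1.7 * se
        a = approx_bayes_factor(beta, se, w_ratio * se**2)
        b = approx_bayes_factor(beta * scale, se * scale, w_ratio * (se * scale) ** 2)
        assert a == pytest.approx(b, rel=1e-9)


class TestPosterior:
    def test_uninformative_everything(self):
        assert posterior_from_prior(0.5, 1.0) == pytest.approx(0.5)

    def test_odds_arithmetic(self):
        # prior odds 1/99 times ABF 99 = even odds
        assert posterior_from_prior(0.01, 99.0) == pytest.approx(0.5)

    def test_monotone_in_abf(self):
        posts = [posterior_from_prior(0.05, a) for a in (0.5, 1, 5, 50, 5000)]
        assert posts == sorted(posts)
        assert posterior_from_prior(0.05, math.inf) == 1.0

    def test_threshold_abf_identity(self):
        """Posterior 0.5 corresponds exactly to ABF = (1-pi)/pi."""
        for pi in (0.01, 0.2, 0.4):
            assert posterior_from_prior(pi, (1 - pi) / pi) == pytest.approx(0.5)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            posterior_from_prior(0.0, 2.0)


def _flat_covariates(rng, n):
    df = pd.DataFrame(
        {
            "global_ancestry": rng.uniform(0.6, 0.95, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.normal(41, 12, n),
            "education": rng.normal(13, 2.4, n),
            "bmi": rng.normal(32, 9, n),
        },
        index=[f"i{k}" for k in range(n)],
    )
    for j in range(1, 11):
        df[f"pc{j}"] = rng.normal(0, 0.1, n)
    return df


class TestStratifiedAssociation:
    def test_single_stratum_equals_unstratified(self):
        """Everyone in one stratum: the stratified fit IS the plain fit."""
        from admixjoint import fit_ols

        rng = np.random.default_rng(14)
        n = 60
        C = rng.normal(size=(n, 3))
        g = rng.integers(0, 3, n).astype(float)
        y = 120 + 2 * g + rng.normal(0, 5, n)
        la = np.full(n, 1.0)
        fits, reason = stratified_association(y, g, la, C, model=1)
        assert reason == ""
        assert len(fits) == 1
        X = np.column_stack([np.ones(n), g, C])
        ref = fit_ols(y, X, names=["c", "genotype", "a", "b", "d"])[1]
        assert fits[0].beta == pytest.approx(ref.beta, rel=1e-10)
        assert fits[0].se == pytest.approx(ref.se, rel=1e-10)

    def test_no_variance_excluded(self):
        rng = np.random.default_rng(15)
        n = 60
        C = rng.normal(size=(n, 2))
        g = np.ones(n)  # monomorphic within every stratum
        la = rng.integers(0, 3, n).astype(float)
        y = rng.normal(120, 10, n)
        fits, reason = stratified_association(y, g, la, C, model=1)
        assert fits == []
        assert reason == "no stratum variance"

    def test_small_strata_dropped(self):
        rng = np.random.default_rng(16)
        n = 40
        C = rng.normal(size=(n, 2))
        g = rng.integers(0, 3, n).astype(float)
        la = np.r_[np.zeros(5), np.ones(n - 5)]  # stratum 0 below min_n
        y = rng.normal(120, 10, n)
        fits, _ = stratified_association(y, g, la, C, model=1, min_stratum_n=10)
        assert {f.stratum for f in fits} == {1}

    def test_homogeneous_effect_across_strata(self):
        """Equal planted effect in all strata: no significant heterogeneity."""
        rng = np.random.default_rng(18)
        n = 600
        C = rng.normal(size=(n, 2))
        la = rng.integers(0, 3, n).astype(float)
        g = rng.integers(0, 3, n).astype(float)
        y = 100 + 3.0 * g + C @ [1.0, -2.0] + rng.normal(0, 8, n)
        fits, _ = stratified_association(y, g, la, C, model=1)
        assert len(fits) == 3
        betas = np.array([f.beta for f in fits])
        ses = np.array([f.se for f in fits])
        w = 1 / ses**2
        pooled = (w * betas).sum() / w.sum()
        q = float((w * (betas - pooled) ** 2).sum())  # Cochran's Q, df=2
        from scipy import stats
        assert stats.chi2.sf(q, df=2) > 0.01


class TestMafFilterModel3:
    def test_strict_boundary(self):
        n = 200
        g_low = np.r_[np.ones(40), np.zeros(160)]        # MAF 0.10 exactly
        g_high = np.r_[np.ones(44), np.zeros(156)]       # MAF 0.11
        geno = pd.DataFrame({"boundary": g_low, "keep": g_high})
        kept = model3_maf_filter(geno, 0.10)
        assert list(kept) == ["keep"]

    def test_count_matches_direct_oracle(self, small_cohort):
        from admixjoint import compute_maf

        geno = small_cohort.genotypes
        kept = model3_maf_filter(geno, 0.10)
        direct = [c for c in geno.columns if compute_maf(geno[c]) > 0.10]
        assert list(kept) == direct


def _fit_joint(cohort, model=1, ut_variable=None, ut_coding="count", response="sbp"):
    samples = adjust_bp_for_medication(cohort.samples)
    samples["global_ancestry"] = global_ancestry(cohort.local_ancestry)
    for j in range(1, 11):
        samples[f"pc{j}"] = 0.0
    cov = tuple(c for c in SCAN_COVARIATES if not c.startswith("pc"))
    eff = count_ancestry_switches(cohort.local_ancestry, cohort.snps)
    est = JointAdmixtureAssociation(
        model=model, ut_variable=ut_variable, ut_coding=ut_coding, covariates=cov
    ).fit(cohort.genotypes, samples[f"{response}_adj"],
          local_ancestry=cohort.local_ancestry, samples=samples,
          effective_tests=eff)
    return est


class TestJointStatistic:
    def test_posterior_in_unit_interval_and_rule(self, small_cohort):
        est = _fit_joint(small_cohort)
        post = est.results_["joint_posterior"].dropna()
        assert ((post >= 0) & (post <= 1)).all()
        sig = est.results_["significant"]
        assert (sig == (est.results_["joint_posterior"] >= 0.5)).reindex(post.index).all()

    def test_monotone_in_admixture_prior(self):
        """Same association evidence, larger admixture posterior -> larger joint
        posterior (the design intent: ancestry-supported regions win)."""
        from admixjoint.joint import BayesConfig, approx_bayes_factor, posterior_from_prior

        W = 9.0
        beta, se = 4.0, 1.5
        abf = approx_bayes_factor(beta, se, W)
        ratio = 350.0
        posts = []
        for p_adm in (0.01, 0.05, 0.2, 0.6, 0.95):
            pi = min(max(p_adm / ratio, 1e-12), 1 - 1e-12)
            posts.append(posterior_from_prior(pi, abf))
        assert posts == sorted(posts)

    def test_monotone_in_z(self):
        from admixjoint.joint import approx_bayes_factor, posterior_from_prior

        W, se, pi = 9.0, 1.5, 1e-3
        posts = [
            posterior_from_prior(pi, approx_bayes_factor(z * se, se, W))
            for z in (0.0, 1.0, 2.0, 3.0, 5.0, 8.0)
        ]
        assert posts == sorted(posts)

    def test_model2_requires_ut(self, small_cohort):
        with pytest.raises(ValueError, match="ut_variable"):
            _fit_joint(small_cohort, model=2)

    def test_model3_filters_maf(self, small_cohort):
        est = _fit_joint(small_cohort, model=3, ut_variable="ut_other",
                         ut_coding="no_yes")
        kept = model3_maf_filter(small_cohort.genotypes, 0.10)
        assert set(est.results_.index) == set(kept)

    def test_planted_effect_found(self):
        sim = CohortSimulator(
            n_ind=250, n_snps=80, n_related=0, seed=77, missing_rate=0.0,
        )
        sim.sbp_model.causal_snps = {40: 9.0}
        sim.sbp_model.noise_sd = 10.0
        cohort = sim.simulate()
        est = _fit_joint(cohort)
        target = cohort.genotypes.columns[40]
        assert est.results_.loc[target, "significant"]
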