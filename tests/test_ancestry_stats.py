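"""Conditional averages, omega weights, LD estimation, LAACor quantities."""

import numpy as np
import pytest

import admixpgs as ap
from admixpgs.ancestry_stats import average_effects_batch, genome_wide_laacor_from_terms
from admixpgs.effects import draw_ancestral_effects_batch


def _la_from_calls(calls, abar=None):
    calls = np.asarray(calls, dtype=np.int8)
    g = None
    if abar is not None:
        g = ap.GlobalAncestryVector(abar)
    return ap.LocalAncestryPanel(calls, global_ancestry=g)


class TestConditionalAlleleFrequencies:
    def test_single_ancestry_flags_missing(self):
        hap = ap.HaplotypePanel(np.ones((2, 1, 2), dtype=np.int8))
        la = _la_from_calls(np.ones((2, 1, 2)))
        est = ap.conditional_allele_frequencies(hap, la)
        assert est.f_afr[0] == 1.0
        assert np.isnan(est.f_eur[0])

    def test_hand_tabulation(self):
        # haplotypes (ind, hap): calls (1,1,0,0), alleles (1,0,1,1)
        calls = np.array([[[1, 1]], [[0, 0]]])
        alleles = np.array([[[1, 0]], [[1, 1]]])
        est = ap.conditional_allele_frequencies(
            ap.HaplotypePanel(alleles.astype(np.int8)), _la_from_calls(calls)
        )
        assert est.f_afr[0] == pytest.approx(0.5)
        assert est.f_eur[0] == pytest.approx(1.0)


class TestEstimateLD:
    def test_perfect_ld(self, small_cohort):
        la, hap = small_cohort["la"], small_cohort["hap"]
        lam = ap.estimate_ld(hap, hap, la, "afr")
        np.testing.assert_allclose(lam, 1.0)

    def test_hand_counts(self):
        # 20 African haplotypes: n11=4, n10=4, n01=2, n00=10
        # f=0.4, f'=0.3, P(1,1)=0.2 -> lambda = 0.08/sqrt(0.24*0.21)
        xc = np.array([1] * 8 + [0] * 12)
        xt = np.array([1] * 4 + [0] * 4 + [1] * 2 + [0] * 10)
        shape = (10, 1, 2)
        c = ap.HaplotypePanel(xc.reshape(shape).astype(np.int8))
        t = ap.HaplotypePanel(xt.reshape(shape).astype(np.int8))
        la = _la_from_calls(np.ones(shape))
        lam = ap.estimate_ld(c, t, la, "afr")
        assert lam[0] == pytest.approx(0.08 / np.sqrt(0.24 * 0.21))

    def test_symmetry_and_label_swap_invariance(self, small_cohort, rng):
        la = small_cohort["la"]
        a = ap.HaplotypePanel((rng.random(la.calls.shape) < 0.4).astype(np.int8))
        b_all = (rng.random(la.calls.shape) < 0.5) | (a.alleles == 1)
        b = ap.HaplotypePanel(b_all.astype(np.int8))
        lam_ab = ap.estimate_ld(a, b, la, "eur")
        lam_ba = ap.estimate_ld(b, a, la, "eur")
        np.testing.assert_allclose(lam_ab, lam_ba)
        flipped = ap.estimate_ld(
            ap.HaplotypePanel(1 - a.alleles), ap.HaplotypePanel(1 - b.alleles), la, "eur"
        )
        np.testing.assert_allclose(lam_ab, flipped, atol=1e-12)

    def test_monomorphic_stratum_raises(self):
        shape = (5, 1, 2)
        c = ap.HaplotypePanel(np.ones(shape, dtype=np.int8))
        t = ap.HaplotypePanel(np.zeros(shape, dtype=np.int8))
        la = _la_from_calls(np.ones(shape))
        with pytest.raises(ValueError, match="monomorphic"):
            ap.estimate_ld(c, t, la, "afr")


class TestConditionalAverageEffects:
    def test_local_model_recovers_ancestral_effects(self, small_cohort):
        la = small_cohort["la"]
        rng = np.random.default_rng(3)
        eff = ap.AncestralEffects(
            beta_eur=rng.normal(size=la.p), beta_afr=rng.normal(size=la.p)
        )
        field = ap.individual_effects("local", eff, la)
        cae = ap.conditional_average_effects(field)
        np.testing.assert_allclose(cae.avg_afr, eff.beta_afr, atol=1e-12)
        np.testing.assert_allclose(cae.avg_eur, eff.beta_eur, atol=1e-12)

    def test_global_model_constant_ancestry(self):
        m = 0.7
        calls = np.array([[[1, 0]], [[0, 1]], [[1, 1]]])
        la = _la_from_calls(calls, abar=[m, m, m])
        eff = ap.AncestralEffects(beta_eur=[1.0], beta_afr=[3.0])
        cae = ap.conditional_average_effects(ap.individual_effects("global", eff, la))
        expected = 1.0 * (1 - m) + 3.0 * m
        assert cae.avg_afr[0] == pytest.approx(expected)
        assert cae.avg_eur[0] == pytest.approx(expected)

    def test_matches_bruteforce_carrier_loop(self, small_cohort):
        la = small_cohort["la"]
        rng = np.random.default_rng(4)
        eff = ap.AncestralEffects(
            beta_eur=rng.normal(size=la.p), beta_afr=rng.normal(size=la.p)
        )
        field = ap.individual_effects("global", eff, la)
        cae = ap.conditional_average_effects(field)
        vals = field.materialize()
        for j in (0, la.p // 2, la.p - 1):
            num, cnt = 0.0, 0
            for i in range(la.n):
                for h in range(2):
                    if la.calls[i, j, h] == 1:
                        num += vals[i, j, h]
                        cnt += 1
            assert cae.avg_afr[j] == pytest.approx(num / cnt)


class TestOmegaWeights:
    def test_constant_ancestry(self):
        calls = np.array([[[1, 0]], [[1, 1]]])
        la = _la_from_calls(calls, abar=[0.6, 0.6])
        om = ap.omega_weights(la)
        for w, expected in ((om.w1, 0.4), (om.w2, 0.6), (om.w3, 0.4), (om.w4, 0.6)):
            assert w[0] == pytest.approx(expected)

    def test_complementary_weights(self, small_cohort):
        om = ap.omega_weights(small_cohort["la"], small_cohort["global_ancestry"])
        np.testing.assert_allclose(om.w1 + om.w2, 1.0)
        np.testing.assert_allclose(om.w3 + om.w4, 1.0)
        for w in (om.w1, om.w2, om.w3, om.w4):
            assert np.all((w >= 0) & (w <= 1))

    def test_identity_against_averaging_oracle(self, small_cohort):
        la, g = small_cohort["la"], small_cohort["global_ancestry"]
        rng = np.random.default_rng(5)
        be = rng.normal(size=la.p)
        ba = rng.normal(size=la.p)
        om = ap.omega_weights(la, g)
        avg_afr, avg_eur = average_effects_batch("global", be, ba, om)
        eff = ap.AncestralEffects(beta_eur=be, beta_afr=ba)
        cae = ap.conditional_average_effects(ap.individual_effects("global", eff, la))
        np.testing.assert_allclose(avg_afr, cae.avg_afr, atol=1e-10)
        np.testing.assert_allclose(avg_eur, cae.avg_eur, atol=1e-10)


class TestAverageEffectCovariance:
    def test_constant_ancestry_perfect_correlation(self):
        calls = np.ones((4, 3, 2), dtype=np.int8)
        calls[0] = 0
        la = _la_from_calls(calls, abar=[0.5] * 4)
        om = ap.omega_weights(la)
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=2.0, tau=0.3)
        rep = ap.average_effect_covariance(om, cov)
        np.testing.assert_allclose(rep.laacor_per_variant, 1.0)

    def test_rho_one_equal_variances(self, small_cohort):
        om = ap.omega_weights(small_cohort["la"], small_cohort["global_ancestry"])
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.0, tau=1.0)
        rep = ap.average_effect_covariance(om, cov)
        np.testing.assert_allclose(rep.laacor_per_variant, 1.0, atol=1e-10)

    def test_monte_carlo_covariance_agreement(self):
        # Empirical covariance of conditional average effects over many
        # effect redraws should match the closed-form (u, v, w) terms.
        g = ap.sample_global_ancestry(400, seed=6)
        la = ap.sample_local_ancestry(g, 60, seed=7)
        om = ap.omega_weights(la, g)
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.3, tau=0.5)
        rep = ap.average_effect_covariance(om, cov)
        rng = np.random.default_rng(8)
        be, ba = draw_ancestral_effects_batch(cov, 60, 10000, rng)
        avg_afr, avg_eur = average_effects_batch("global", be, ba, om)
        u_emp = avg_afr.var(axis=1)
        v_emp = avg_eur.var(axis=1)
        w_emp = np.mean(avg_afr * avg_eur, axis=1) - avg_afr.mean(1) * avg_eur.mean(1)
        assert np.sum(u_emp) == pytest.approx(np.sum(rep.u), rel=0.03)
        assert np.sum(v_emp) == pytest.approx(np.sum(rep.v), rel=0.03)
        assert np.sum(w_emp) == pytest.approx(np.sum(rep.w), rel=0.03)


class TestGenomeWideLAACor:
    def test_identical_omegas_rho_one(self):
        u = np.full(5, 2.0)
        assert genome_wide_laacor_from_terms(u, u, u) == pytest.approx(1.0)

    def test_local_model_recovers_rho(self):
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.0, tau=0.5)
        rng = np.random.default_rng(9)
        be, ba = draw_ancestral_effects_batch(cov, 2000, 1, rng)
        avg_afr, avg_eur = average_effects_batch("local", be[:, 0], ba[:, 0])
        emp = ap.empirical_genome_wide_laacor(avg_afr, avg_eur)
        assert emp == pytest.approx(0.5, abs=0.06)

    def test_pooled_close_to_empirical_over_redraws(self):
        g = ap.sample_global_ancestry(1000, seed=10)
        la = ap.sample_local_ancestry(g, 500, seed=11)
        om = ap.omega_weights(la, g)
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.0, tau=0.4)
        rep = ap.average_effect_covariance(om, cov)
        rng = np.random.default_rng(12)
        be, ba = draw_ancestral_effects_batch(cov, 500, 50, rng)
        avg_afr, avg_eur = average_effects_batch("global", be, ba, om)
        emp = np.asarray(ap.empirical_genome_wide_laacor(avg_afr, avg_eur))
        se = emp.std(ddof=1) / np.sqrt(emp.size)
        assert abs(emp.mean() - rep.laacor_genomewide_closed) < 3 * se + 1e-3

    def test_per_variant_global_laacor_at_least_rho(self):
        # Averaging over local ancestry can only increase similarity.
        for rho in (0.0, 0.3, 0.7, 0.95):
            g = ap.sample_global_ancestry(800, seed=13)
            la = ap.sample_local_ancestry(g, 100, seed=14)
            om = ap.omega_weights(la, g)
            cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.2, tau=rho * np.sqrt(1.2))
            rep = ap.average_effect_covariance(om, cov)
            assert np.all(rep.laacor_per_variant >= rho - 1e-9)

    def test_tagging_scope_depressed_by_ld_discordance(self):
        # Local-model tagging LAACor: equal theta across ancestries keeps
        # the across-variant correlation at rho; discordant LD depresses it.
        cov = ap.BaseCovariance(sigma2_eur=1.0, sigma2_afr=1.0, tau=0.9)
        rng = np.random.default_rng(15)
        be, ba = draw_ancestral_effects_batch(cov, 3000, 1, rng)
        be, ba = be[:, 0], ba[:, 0]
        theta_e = rng.uniform(0.5, 1.0, 3000)
        matched = ap.empirical_genome_wide_laacor(ba * theta_e, be * theta_e)
        theta_a = theta_e * rng.uniform(0.2, 1.0, 3000)
        discordant = ap.empirical_genome_wide_laacor(ba * theta_a, be * theta_e)
        assert matched == pytest.approx(0.9, abs=0.05)
        assert discordant < matched - 0.02

    def test_all_missing_rejected(self):
        nan = np.full(3, np.nan)
        with pytest.raises(ValueError):
            genome_wide_laacor_from_terms(nan, nan, nan)
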