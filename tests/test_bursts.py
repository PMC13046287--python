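"""Burst-parameter estimators, their error formulas, ranking, and the
realistic marginalized-MLE workflow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telenb import (
    BurstEstimate,
    BurstTruth,
    CandidateModel,
    CaptureModel,
    GeneFit,
    QuadratureSpec,
    TelegraphParams,
    burst_from_effective_nb,
    burst_relative_errors,
    classify_and_extract,
    effective_nb_params,
    evaluate_inference,
    fit_gene_mle,
    fit_model_to_pmf,
    normalization_factors,
    observed_pmf_telegraph_beta,
    observed_moments_telegraph_beta,
    rank_gene_pairs,
)
from telenb.selection import FitResult


class TestEffectiveNBBursts:
    def test_direct_substitution(self):
        est = burst_from_effective_nb(0.3, 10.0, 15.0)
        assert est.beta_f == pytest.approx(0.3 * 11.0 / 0.7, rel=1e-14)
        assert est.beta_s == pytest.approx(15.0 * 0.7 / 11.0, rel=1e-14)

    def test_identity_with_effective_nb_params(self):
        fon, nsig, rho = 0.42, 27.0, 15.0
        est = burst_from_effective_nb(fon, nsig, rho)
        nb = effective_nb_params(TelegraphParams.from_fon_nsigma(rho, fon, nsig))
        assert est.beta_f == pytest.approx(nb.r, rel=1e-12)
        assert est.beta_s == pytest.approx((1.0 - nb.p) / nb.p, rel=1e-12)

    def test_bursting_limit_estimates_become_exact(self):
        """sigma_off >> sigma_on: estimates converge to the true burst
        frequency sigma_on and size rho/sigma_off."""
        rho = 15.0
        for nsig in (10.0, 100.0, 1000.0):
            fon = 0.1 / nsig  # sigma_on = 0.1 fixed, sigma_off ~ nsig
            p = TelegraphParams.from_fon_nsigma(rho, fon, nsig)
            est = burst_from_effective_nb(fon, nsig, rho)
            truth = BurstTruth.from_telegraph(p)
            if nsig == 1000.0:
                assert est.beta_f == pytest.approx(truth.beta_f_true, rel=2e-2)
                assert est.beta_s == pytest.approx(truth.beta_s_true, rel=2e-2)

    def test_fon_near_one_rejected(self):
        with pytest.raises(ValueError):
            burst_from_effective_nb(1.0 - 1e-15, 10.0, 15.0)


class TestRelativeErrorFormulas:
    @given(fon=st.floats(0.01, 0.99), nsig=st.floats(0.05, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_formulas_match_brute_force(self, fon, nsig):
        """Closed-form REs equal |estimate - truth| / truth computed from the
        estimators and the telegraph truth, and RE(size) < 1 always."""
        rho = 15.0
        re_s, re_f = burst_relative_errors(fon, nsig)
        est = burst_from_effective_nb(fon, nsig, rho)
        tr = BurstTruth.from_telegraph(TelegraphParams.from_fon_nsigma(rho, fon, nsig))
        assert float(re_s) == pytest.approx(
            abs(est.beta_s - tr.beta_s_true) / tr.beta_s_true, rel=1e-12, abs=1e-12
        )
        assert float(re_f) == pytest.approx(
            abs(est.beta_f - tr.beta_f_true) / tr.beta_f_true, rel=1e-12, abs=1e-12
        )
        assert float(re_s) < 1.0

    def test_vanishing_errors_limit(self):
        re_s, re_f = burst_relative_errors(1e-6, 1e8)
        assert float(re_s) < 1e-5
        assert float(re_f) < 1e-5

    def test_errors_increase_with_fon(self):
        fons = np.array([0.1, 0.3, 0.5, 0.7])
        re_s, re_f = burst_relative_errors(fons, 10.0)
        assert np.all(np.diff(re_s) > 0)
        assert np.all(np.diff(re_f) > 0)


class _FixedSampler:
    """Region-sampler stub returning a fixed list of (f_on, N_sigma) genes."""

    def __init__(self, fons, nsigs):
        self.fons = np.asarray(fons, dtype=float)
        self.nsigs = np.asarray(nsigs, dtype=float)
        self._i = 0

    def sample(self, n, rng):
        idx = (np.arange(n) + self._i) % self.fons.size
        self._i += n
        return self.fons[idx], self.nsigs[idx]


class TestRanking:
    def test_identical_genes_count_as_correct(self):
        sampler = _FixedSampler([0.3], [10.0])
        res = rank_gene_pairs(sampler, 15.0, 10, seed=0)
        assert res.pct_correct_freq == 100.0
        assert res.pct_correct_size == 100.0

    def test_categories_partition_pairs(self):
        rng_sampler = _FixedSampler([0.1, 0.5, 0.3, 0.7], [3.0, 40.0, 10.0, 200.0])
        res = rank_gene_pairs(rng_sampler, 15.0, 200, seed=1)
        assert sum(res.categories_freq.values()) == 200
        assert sum(res.categories_size.values()) == 200
        assert 0.0 <= res.pct_correct_size <= 100.0

    def test_empty_mask_rejected(self):
        from telenb import RegionSampler

        with pytest.raises(ValueError):
            RegionSampler(np.array([1.0, 2.0]), np.array([0.3, 0.5]),
                          np.zeros((2, 2), dtype=bool))


class TestNormalizationFactors:
    def test_equal_totals_give_unit_factors(self):
        betas = normalization_factors(np.full(10, 500))
        assert np.allclose(betas, 1.0)
        scaled = normalization_factors(np.full(10, 500), mean_pcap=0.3)
        assert np.allclose(scaled, 0.3)

    def test_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        betas = normalization_factors(rng.integers(100, 2000, size=300))
        assert betas.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalization_factors([100, 0, 50])

    def test_totals_track_capture_probability(self, reference_genome):
        """On the 2800-gene reference genome, per-cell totals are a strong
        proxy for the true capture probability."""
        betas = normalization_factors(reference_genome.observed_counts.sum(axis=0))
        r = np.corrcoef(betas, reference_genome.pcap_per_cell)[0, 1]
        assert r > 0.9


class TestIdealCorrectedInference:
    @pytest.mark.parametrize("a,b", [(15.0, 35.0), (60.0, 140.0), (3.0, 9.0)])
    def test_corrected_nb_mom_independent_of_capture_shape(self, a, b,
                                                           tele_intermediate):
        """Moment-matching the capture-corrected NB to the capture-corrected
        telegraph truth returns the effective-NB (r_e, p_e) regardless of the
        Beta shape parameters: the correction is exact."""
        cap = CaptureModel.beta(a, b)
        truth = observed_pmf_telegraph_beta(tele_intermediate, cap, method="quad")
        moments = observed_moments_telegraph_beta(tele_intermediate, cap)[:2]
        fit = fit_model_to_pmf(CandidateModel("nb", corrected=True), truth,
                               method="mom", capture=cap, truth_moments=moments)
        expected = effective_nb_params(tele_intermediate)
        assert fit.theta[0] == pytest.approx(expected.r, abs=1e-10)
        assert fit.theta[1] == pytest.approx(expected.p, abs=1e-10)


def _unit_density():
    # normalization factors concentrated at 1 (no capture variability)
    return CaptureModel.empirical(
        density=lambda x: np.full_like(np.asarray(x, float), 1.0 / 0.02),
        bounds=(0.99, 1.01),
    )


class TestGeneMLE:
    def test_poisson_mle_recovers_sample_mean(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(4.0, size=2000)
        fit = fit_gene_mle(counts, CandidateModel("poisson", corrected=True),
                           _unit_density(), QuadratureSpec(8))
        assert fit.theta[0] == pytest.approx(counts.mean(), rel=1e-3)

    def test_deterministic_given_fixed_starts(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(4.0, size=300)
        cfg = {"maxiter": 200}
        a = fit_gene_mle(counts, CandidateModel("nb", corrected=True),
                         _unit_density(), QuadratureSpec(8), cfg)
        b = fit_gene_mle(counts, CandidateModel("nb", corrected=True),
                         _unit_density(), QuadratureSpec(8), cfg)
        assert a.theta == b.theta
        assert a.criterion == b.criterion

    def test_poisson_truth_selects_poisson(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(3.0, size=1500)
        dens = _unit_density()
        quad = QuadratureSpec(8)
        cfg = {"maxiter": 250, "fatol": 1e-8, "xatol": 1e-4}
        fits = {k: fit_gene_mle(counts, CandidateModel(k, corrected=True),
                                dens, quad, cfg)
                for k in ("telegraph", "nb", "poisson")}
        gf = classify_and_extract("g0", fits)
        assert gf.selected == "poisson"
        assert gf.selected_fit.criterion == min(
            f.criterion for f in fits.values() if f.converged
        )


class TestRealisticWorkflow:
    def test_mini_genome_nb_selection_and_burst_accuracy(self):
        """End-to-end marginalized-MLE workflow on a small synthetic genome:
        normalization factors from totals, KDE density, three corrected fits
        per gene, BIC selection.  A nonzero subset of genes selects the NB
        model, and for those genes the telegraph-model burst-frequency
        estimates are more accurate than the NB-model ones."""
        from telenb import GenomeConfig, simulate_genome

        gc = GenomeConfig(n_cells=400, fon_set=(0.1, 0.3, 0.5),
                          genes_per_fon=4, seed=42)
        ds = simulate_genome(gc)
        betas = normalization_factors(ds.observed_counts.sum(axis=0), mean_pcap=0.3)
        dens = CaptureModel.empirical(samples=betas)
        quad = QuadratureSpec(24)
        cfg = {"maxiter": 250, "fatol": 1e-8, "xatol": 1e-4}
        gene_fits, truths = [], {}
        for g in range(gc.n_genes):
            fits = {k: fit_gene_mle(ds.observed_counts[g],
                                    CandidateModel(k, corrected=True),
                                    dens, quad, cfg)
                    for k in ("telegraph", "nb", "poisson")}
            gf = classify_and_extract(ds.gene_names[g], fits)
            assert gf.selected_fit.criterion == min(
                f.criterion for f in fits.values() if f.converged)
            gene_fits.append(gf)
            truths[ds.gene_names[g]] = BurstTruth.from_telegraph(ds.gene_params[g])
        n_nb = sum(g.selected == "nb" for g in gene_fits)
        assert n_nb > 0
        rep = evaluate_inference(gene_fits, truths, seed=0, n_pair_sets=300)
        assert np.median(rep["telegraph"]["re_freq"]) < np.median(rep["nb"]["re_freq"])


class TestEvaluateInference:
    @staticmethod
    def _gene(name, bf_true, bs_true, bf_est, bs_est):
        fit = FitResult(CandidateModel("nb", corrected=True), (bf_est, bs_est),
                        0.0, criterion=0.0)
        gf = GeneFit(gene=name, fits={"nb": fit}, selected="nb",
                     bursts={"nb": BurstEstimate(bf_est, bs_est, "nb")})
        truth = BurstTruth(beta_f_true=bf_true, beta_s_true=bs_true)
        return gf, truth

    def test_perfect_estimates_give_zero_flips_and_zero_re(self):
        genes, truths = [], {}
        rng = np.random.default_rng(0)
        for i in range(20):
            bf, bs = rng.uniform(0.5, 5.0), rng.uniform(1.0, 10.0)
            g, t = self._gene(f"g{i}", bf, bs, bf, bs)
            genes.append(g)
            truths[g.gene] = t
        rep = evaluate_inference(genes, truths, seed=1, n_pair_sets=500)
        assert rep["nb"]["pct_flipped_freq"] == 0.0
        assert rep["nb"]["pct_flipped_size"] == 0.0
        assert np.all(rep["nb"]["re_freq"] == 0.0)

    def test_flip_percentage_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(5)
        genes, truths = [], {}
        for i in range(15):
            bf, bs = rng.uniform(0.5, 5.0), rng.uniform(1.0, 10.0)
            g, t = self._gene(f"g{i}", bf, bs, bf * rng.uniform(0.5, 2.0),
                              bs * rng.uniform(0.5, 2.0))
            genes.append(g)
            truths[g.gene] = t
        rep1 = evaluate_inference(genes, truths, seed=2, n_pair_sets=400)
        rep2 = evaluate_inference(genes[::-1], truths, seed=2, n_pair_sets=400)
        # same gene population, same pair count: flip rates agree statistically
        assert abs(rep1["nb"]["pct_flipped_freq"] - rep2["nb"]["pct_flipped_freq"]) < 10.0

    def test_too_few_nb_genes_warns(self):
        g, t = self._gene("g0", 1.0, 2.0, 1.0, 2.0)
        rep = evaluate_inference([g], {"g0": t}, seed=0)
        assert "warning" in rep["nb"]
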