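"""Least-squares fitting, BIC selection, bootstrap, and the delayed-input workflow."""

import numpy as np
import pytest

from agekin.cmodel import ModelTemplate, build_template, observed_curve
from agekin.curves import GrowthModel, LabelingCurve
from agekin.fitting import (
    FitError, FitOptions, bic_score, bootstrap, estimate_growth, estimate_input,
    fit, fit_proteome, naive_log_linear, reduced_parameters, reference_curve,
    run_workflow, select_model, select_reference_proteins,
)
from agekin.simulate import simulate_proteome

TIMES = np.linspace(0.0, 480.0, 12)
OPTS = FitOptions(seed=0)


def noisy_curve(model, noise_sd, seed, times=TIMES, sid="x"):
    rng = np.random.default_rng(seed)
    exact = observed_curve(model, times)
    return LabelingCurve(sid, times,
                         np.clip(exact + rng.normal(0, noise_sd, len(times)), 0, 1))


class TestEstimateGrowth:
    def test_exact_exponential(self):
        t = np.linspace(0, 480, 10)
        g = estimate_growth(t, 0.1 * np.exp(0.0058 * t))
        assert g.mu == pytest.approx(0.0058, abs=1e-12)
        assert g.source == "fitted"

    def test_constant_biomass(self):
        g = estimate_growth([0.0, 100, 200], [0.5, 0.5, 0.5])
        assert g.mu == pytest.approx(0.0, abs=1e-15)

    def test_noisy_series_recovery(self):
        rng = np.random.default_rng(21)
        t = np.linspace(0, 480, 10)
        b = 0.1 * np.exp(0.005 * t) * np.exp(rng.normal(0, 0.02, 10))
        g = estimate_growth(t, b)
        assert g.mu == pytest.approx(0.005, rel=0.05)

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(FitError):
            estimate_growth([0.0, 1, 2], [1.0, 0.0, 0.5])


class TestFit:
    def test_noise_free_one_state_exact_recovery(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.0)
        m = build_template(tpl, pool_rates=(0.01,), pool_fractions=(1.0,))
        c = LabelingCurve("x", np.linspace(0, 480, 10),
                          observed_curve(m, np.linspace(0, 480, 10)))
        res = fit(tpl, c, OPTS)
        assert res.converged
        assert res.pool_rates[0] == pytest.approx(0.01, rel=1e-4)
        assert res.rss < 10 * 1e-12    # below the BIC floor scale

    def test_two_pool_recovery_mean_age_robust(self):
        # individual rates of a 2-pool fit carry sampling noise, but the
        # reduced mean age (the integral quantity) is recovered tightly
        mu = 0.005
        tpl = ModelTemplate(input_states=0, protein_pools=2, mu=mu)
        m = build_template(tpl, pool_rates=(0.02, 0.002), pool_fractions=(0.3, 0.7))
        c = noisy_curve(m, 0.01, seed=1)
        res = fit(tpl, c, FitOptions(seed=1))
        true_age = 0.3 / 0.025 + 0.7 / 0.007
        assert reduced_parameters(res).mean_age == pytest.approx(true_age, rel=0.1)
        for est, truth in zip(res.pool_rates, (0.02, 0.002)):
            assert truth / 2 < est < truth * 2
        assert res.pool_rates[0] > res.pool_rates[1]     # canonical ordering

    def test_underdetermined_rejected(self):
        tpl = ModelTemplate(input_states=2, protein_pools=3, mu=0.005)
        c = LabelingCurve("x", np.linspace(0, 100, 5), np.exp(-0.01 * np.linspace(0, 100, 5)))
        with pytest.raises(FitError):
            fit(tpl, c, OPTS)

    def test_determinism(self):
        tpl = ModelTemplate(input_states=0, protein_pools=2, mu=0.005)
        m = build_template(tpl, pool_rates=(0.02, 0.002), pool_fractions=(0.3, 0.7))
        c = noisy_curve(m, 0.01, seed=2)
        a, b = fit(tpl, c, FitOptions(seed=5)), fit(tpl, c, FitOptions(seed=5))
        assert a.pool_rates == b.pool_rates and a.rss == b.rss


class TestBic:
    def test_reference_value(self):
        assert bic_score(0.001, 12, 3) == pytest.approx(-105.26, abs=0.005)

    def test_monotone_in_rss_and_penalized_in_k(self):
        assert bic_score(0.0005, 12, 3) < bic_score(0.001, 12, 3)
        assert (bic_score(0.001, 12, 4) - bic_score(0.001, 12, 3)
                == pytest.approx(np.log(12)))

    def test_floor_keeps_noise_free_fits_finite(self):
        assert np.isfinite(bic_score(0.0, 12, 3))


class TestSelectModel:
    def test_one_pool_data_selects_one_pool(self):
        mu = 0.005
        tpls = [ModelTemplate(input_states=0, protein_pools=p, mu=mu)
                for p in (1, 2, 3)]
        m = build_template(tpls[0], pool_rates=(0.005,), pool_fractions=(1.0,))
        best, table = select_model(tpls, noisy_curve(m, 0.01, seed=2), OPTS)
        assert best.template.protein_pools == 1
        assert len(table) == 3

    def test_separated_two_pool_data_selects_two_pool(self):
        mu = 0.005
        tpls = [ModelTemplate(input_states=0, protein_pools=p, mu=mu)
                for p in (1, 2, 3)]
        m = build_template(tpls[1], pool_rates=(0.03, 0.003), pool_fractions=(0.5, 0.5))
        best, _ = select_model(tpls, noisy_curve(m, 0.01, seed=3), OPTS)
        assert best.template.protein_pools == 2

    def test_tie_resolved_toward_fewer_parameters(self):
        # noise-free 1-pool data: both templates hit the RSS floor, so the
        # near-tie must resolve to the simpler model
        tpls = [ModelTemplate(input_states=0, protein_pools=p, mu=0.005)
                for p in (1, 2)]
        m = build_template(tpls[0], pool_rates=(0.01,), pool_fractions=(1.0,))
        c = LabelingCurve("x", TIMES, observed_curve(m, TIMES))
        best, _ = select_model(tpls, c, OPTS)
        assert best.template.protein_pools == 1


class TestBootstrap:
    def test_low_noise_mean_age_cv_small(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.0)
        m = build_template(tpl, pool_rates=(0.01,), pool_fractions=(1.0,))
        c = noisy_curve(m, 0.005, seed=4, times=np.linspace(0, 480, 25))
        summ = bootstrap(tpl, c, n_boot=200, seed=7, options=OPTS)
        assert not summ.unreliable
        assert summ.cv("mean_age") < 0.05

    def test_zero_resamples_rejected(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.0)
        c = LabelingCurve("x", TIMES, np.exp(-0.01 * TIMES))
        with pytest.raises(FitError):
            bootstrap(tpl, c, n_boot=0, seed=1)

    def test_seed_determinism(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.0)
        m = build_template(tpl, pool_rates=(0.01,), pool_fractions=(1.0,))
        c = noisy_curve(m, 0.01, seed=5)
        a = bootstrap(tpl, c, n_boot=25, seed=9, options=OPTS)
        b = bootstrap(tpl, c, n_boot=25, seed=9, options=OPTS)
        assert a.stats == b.stats


class TestReferenceSelection:
    def _dataset_and_fits(self, n=20):
        ds = simulate_proteome(n, TIMES, mu=0.005, seed=6, noise_sd=0.005)
        tpl = ModelTemplate(input_states=1, protein_pools=1, mu=0.005)
        fits = {sid: fit(tpl, ds.curves[sid], OPTS) for sid in ds.species()}
        return ds, fits

    def test_argmax_when_single_slot(self):
        ds, fits = self._dataset_and_fits()
        refs = select_reference_proteins(ds, fits, top_n_abundant=20,
                                         top_frac_age=0.05, bic_cutoff=0.0)
        assert len(refs) == 1
        from agekin.fitting import observed_mean_age
        ages = {s: observed_mean_age(f.model) for s, f in fits.items()}
        assert refs[0] == max(ages, key=ages.get)

    def test_all_species_failing_cutoff_is_staged_error(self):
        ds, fits = self._dataset_and_fits()
        with pytest.raises(FitError, match="BIC cutoff"):
            select_reference_proteins(ds, fits, bic_cutoff=-1e9)


class TestEstimateInput:
    def test_two_state_input_recovery(self):
        mu = 0.005
        tpl = ModelTemplate(input_states=2, protein_pools=1, mu=mu,
                            nondegraded=True)
        m = build_template(tpl, input_rates=(0.02, 0.05), pool_fractions=(1.0,))
        c = noisy_curve(m, 0.005, seed=4, sid="reference")
        best, a_input, table = estimate_input(c, GrowthModel(mu), options=OPTS)
        assert best.template.input_states == 2
        assert a_input == pytest.approx(70.0, rel=0.15)

    def test_direct_input_detected(self):
        mu = 0.005
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=mu)
        m = build_template(tpl, pool_rates=(0.01,), pool_fractions=(1.0,))
        best, a_input, _ = estimate_input(noisy_curve(m, 0.005, seed=8),
                                          GrowthModel(mu), options=OPTS)
        assert best.template.input_states == 0 and a_input == 0.0

    def test_pure_dilution_curve_is_nondegraded(self):
        mu = 0.005
        c = LabelingCurve("ref", TIMES, np.exp(-mu * TIMES))
        best, a_input, _ = estimate_input(c, GrowthModel(mu), options=OPTS)
        assert a_input == 0.0
        par = reduced_parameters(best)
        assert par.mean_age == pytest.approx(1 / mu, rel=1e-6)


class TestProteomeFit:
    def test_nondegraded_species_age_at_dilution_limit(self):
        mu = 0.005
        ds = simulate_proteome(10, TIMES, mu=mu, seed=9, noise_sd=0.005,
                               frac_nondegraded=0.2, frac_two_pool=0.0)
        pf = fit_proteome(ds, input_rates=(0.02, 0.05), pool_options=(1, 2),
                          options=OPTS)
        nondeg = [s for s, v in ds.truth["species"].items()
                  if v["kind"] == "nondegraded"]
        for sid in nondeg:
            ratio = pf.parameters[sid]["mean_age_over_mu_inv"]
            assert 0.9 <= ratio <= 1.0

    def test_naive_log_linear_bias_on_delayed_data(self):
        mu = 0.005
        ds = simulate_proteome(12, TIMES, mu=mu, seed=10, noise_sd=0.005)
        for sid, c in ds.curves.items():
            tr = ds.truth["species"][sid]
            true_reduced = sum(w / (d + mu) for d, w in
                               zip(tr["pool_rates"], tr["pool_fractions"]))
            assert naive_log_linear(c)["mean_age"] > true_reduced

    def test_failures_collected_not_fatal(self):
        ds = simulate_proteome(3, TIMES, mu=0.005, seed=11, noise_sd=0.005)
        short = np.linspace(0, 480, 4)      # too few points for 2/3-pool fits
        ds.curves = {s: LabelingCurve(s, short, np.interp(short, c.times, c.values))
                     for s, c in ds.curves.items()}
        pf = fit_proteome(ds, input_rates=(0.02, 0.05), pool_options=(3,),
                          options=OPTS)
        assert len(pf.failures) == 3 and not pf.fits


def test_workflow_end_to_end_recovers_generator():
    mu = 0.005
    ds = simulate_proteome(16, TIMES, mu=mu, seed=12, noise_sd=0.008)
    res = run_workflow(ds, top_n_abundant=16, top_frac_age=0.1, bic_cutoff=-50.0,
                       options=OPTS, n_boot=0)
    assert res["growth"].mu == pytest.approx(mu, rel=0.1)
    assert res["input_fit"].template.input_states in (2, 3)
    assert res["input_mean_age"] == pytest.approx(70.0, rel=0.25)
    assert len(res["proteome"].fits) == 16
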