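"""Compartmental-model algebra against matrix-arithmetic and ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from agekin.cmodel import (
    CompartmentalModel, ModelError, ModelTemplate, build_template,
    compose_delayed, input_mean_age, labeling, mean_ages, observed_curve,
    reduce, system_parameters, validate,
)
from agekin.curves import mean_age as curve_mean_age

# per-hour chain expressed in minutes
CHAIN_M = np.array([[-1.0, 0.0], [2.0, -2.0]]) / 60.0
CHAIN_S = np.array([2 / 3, 1 / 3])


def chain_model(mu=0.0):
    return CompartmentalModel(M=CHAIN_M, s=CHAIN_S, mu=mu)


def models_battery():
    """Valid test models: chains, parallel pools, growth, repeated eigenvalues."""
    out = {"chain": chain_model()}
    out["independent"] = CompartmentalModel(M=-np.eye(2) / 60, s=[0.5, 0.5])
    out["parallel"] = CompartmentalModel(
        M=np.diag([-0.002, -0.02]), s=[0.7, 0.3])
    r = np.array([3.0, 3.0, 3.0]) / 60      # repeated eigenvalues
    M3 = np.diag(-r)
    M3[1, 0], M3[2, 1] = r[1], r[2]
    out["repeated_chain"] = CompartmentalModel(M=M3, s=[1 / 3] * 3)
    tpl = ModelTemplate(input_states=2, protein_pools=2, mu=0.005)
    out["growing_template"] = build_template(
        tpl, input_rates=(0.02, 0.05), pool_rates=(0.01, 0.001),
        pool_fractions=(0.4, 0.6))
    return out


class TestValidate:
    def test_chain_report_matches_direct_arithmetic(self):
        rep = validate(chain_model())
        assert sorted(np.round(rep.eigenvalues.real * 60, 9)) == [-2.0, -1.0]
        np.testing.assert_allclose(rep.mass_balance_residual * 60, [0.0, -2 / 3],
                                   atol=1e-12)
        assert rep.ok

    def test_independent_pools_valid(self):
        assert validate(CompartmentalModel(M=-np.eye(2), s=[0.5, 0.5])).ok

    def test_growth_violating_eigenvalue_bound(self):
        m = CompartmentalModel(M=-np.eye(2) / 60, s=[0.5, 0.5], mu=1.5 / 60)
        rep = validate(m)
        assert not rep.eigen_ok and not rep.ok

    @pytest.mark.parametrize("name,model", models_battery().items())
    def test_battery_all_valid(self, name, model):
        assert validate(model).ok, name


class TestLabeling:
    def test_scalar_exponential(self):
        m = CompartmentalModel(M=[[-0.01]], s=[1.0])
        _, sys_curve = labeling(m, [0.0, 50.0, 100.0])
        np.testing.assert_allclose(sys_curve.values,
                                   np.exp(-0.01 * np.array([0, 50, 100])),
                                   atol=1e-12)

    def test_chain_downstream_closed_form(self):
        per_state, _ = labeling(chain_model(), [0.0, 60.0])
        assert per_state[1].values[1] == pytest.approx(2 * np.e**-1 - np.e**-2,
                                                       abs=1e-9)

    @pytest.mark.parametrize("name,model", models_battery().items())
    def test_starts_fully_labeled_and_nonincreasing(self, name, model):
        t = np.linspace(0, 600, 61)
        per_state, sys_curve = labeling(model, t)
        for c in per_state + [sys_curve]:
            assert c.values[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(c.values) <= 1e-12)

    @pytest.mark.parametrize("name,model", models_battery().items())
    def test_matches_ode_integration_oracle(self, name, model):
        t = np.linspace(0, 400, 21)
        sol = solve_ivp(lambda _, f: model.M @ f, (0, t[-1]), np.ones(model.n),
                        t_eval=t, rtol=1e-10, atol=1e-12)
        per_state, _ = labeling(model, t)
        F = np.stack([c.values for c in per_state], axis=1)
        np.testing.assert_allclose(F, sol.y.T, atol=1e-6)

    def test_sum_of_exponentials_structure(self):
        # distinct eigenvalues: curves equal sum(c_i e^{lambda_i t}) exactly
        m = chain_model()
        lam, V = np.linalg.eig(m.M)
        c = np.linalg.solve(V, np.ones(2))
        t = np.linspace(0, 300, 31)
        rebuilt = np.real((V * c) @ np.exp(np.outer(lam, t))).T
        per_state, _ = labeling(m, t)
        F = np.stack([x.values for x in per_state], axis=1)
        np.testing.assert_allclose(F, rebuilt, atol=1e-8)


class TestMeanAges:
    def test_scalar(self):
        m = CompartmentalModel(M=[[-0.01]], s=[1.0])
        per, system = mean_ages(m)
        assert per[0] == pytest.approx(100.0) and system == pytest.approx(100.0)

    def test_chain_matrix_inverse_oracle(self):
        per, system = mean_ages(chain_model())
        np.testing.assert_allclose(per / 60, [1.0, 1.5], atol=1e-12)
        assert system / 60 == pytest.approx(7 / 6)

    def test_parallel_weighted(self):
        m = CompartmentalModel(M=np.diag([-0.002, -0.02]), s=[0.7, 0.3])
        per, system = mean_ages(m)
        np.testing.assert_allclose(per, [500.0, 50.0])
        assert system == pytest.approx(365.0)

    @pytest.mark.parametrize("name,model", models_battery().items())
    def test_consistent_with_curve_auc(self, name, model):
        # Table-form mean age equals the area under the system curve
        _, system = mean_ages(model)
        t_max = 30.0 / abs(max(model.eigenvalues().real))
        _, sys_curve = labeling(model, np.linspace(0, t_max, 2001))
        assert curve_mean_age(sys_curve) == pytest.approx(system, rel=0.005)


class TestSystemParameters:
    def test_scalar_closed_forms(self):
        m = CompartmentalModel(M=[[-0.01]], s=[1.0])
        p = system_parameters(m)
        assert p.mean_residence_time == pytest.approx(100.0)
        assert p.expected_decay_rate == pytest.approx(0.01)
        assert p.half_life == pytest.approx(np.log(2) / 0.01, abs=1e-4)

    def test_chain(self):
        p = system_parameters(chain_model())
        assert p.expected_decay_rate * 60 == pytest.approx(2 / 3)
        assert p.mean_residence_time / 60 == pytest.approx(1.5)

    def test_growth_diluted_decay(self):
        lam, mu = 0.01, 0.004
        m = CompartmentalModel(M=[[-lam]], s=[1.0], mu=mu)
        p = system_parameters(m)
        assert p.expected_decay_rate == pytest.approx(lam - mu)

    def test_growth_forms_match_numerical_quadrature(self):
        model = models_battery()["growing_template"]
        mu = model.mu
        t = np.linspace(0, 12000, 120001)
        _, sys_curve = labeling(model, t)
        fs = sys_curve.values
        dfs = np.gradient(fs, t, edge_order=2)
        lr_quad = np.trapezoid(np.exp(mu * t) * fs, t)
        tbar_quad = np.trapezoid(np.exp(mu * t) * dfs, t) / dfs[0]
        p = system_parameters(model)
        assert p.mean_rrtl == pytest.approx(lr_quad, rel=0.005)
        assert p.mean_residence_time == pytest.approx(tbar_quad, rel=0.005)

    def test_conditioned_parameters_memoryless_check(self):
        m = CompartmentalModel(M=[[-0.01]], s=[1.0])
        p = system_parameters(m, conditioning_age=60.0)
        assert p.conditioned_decay_rate == pytest.approx(0.01)
        assert p.conditioned_residence_time == pytest.approx(160.0, rel=1e-6)

    def test_conditioning_age_beyond_support(self):
        m = CompartmentalModel(M=[[-1.0]], s=[1.0])
        with pytest.raises(ModelError):
            system_parameters(m, conditioning_age=1e5)


class TestReduce:
    def test_chain_observed_downstream(self):
        red = reduce(chain_model(), [False, True])
        np.testing.assert_allclose(red.M * 60, [[-2.0]])
        per, system = mean_ages(red)
        assert system / 60 == pytest.approx(0.5)   # 1.5 - 1.0 (input age removed)

    def test_observe_all_identity(self):
        m = chain_model()
        red = reduce(m, [True, True])
        np.testing.assert_allclose(red.M, m.M)
        np.testing.assert_allclose(red.s, m.s)

    def test_parallel_single_pool(self):
        m = CompartmentalModel(M=np.diag([-0.002, -0.02]), s=[0.7, 0.3])
        red = reduce(m, [True, False])
        np.testing.assert_allclose(red.M, [[-0.002]])
        np.testing.assert_allclose(red.s, [1.0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ModelError):
            reduce(chain_model(), [False, False])


class TestComposeDelayed:
    def test_serial_closed_form(self):
        # hours scale; f_in = e^{-t}, f_red = e^{-2t} -> f = 2e^{-t} - e^{-2t}
        grid = np.linspace(0, 10, 401)
        f = compose_delayed(lambda t: np.exp(-t), lambda t: np.exp(-2 * t), grid)
        np.testing.assert_allclose(f, 2 * np.exp(-grid) - np.exp(-2 * grid),
                                   atol=1e-4)

    def test_fast_input_limit_is_identity(self):
        # a step-like input (rate >> reduced-system rate) adds no delay
        grid = np.linspace(0, 10, 4001)
        f = compose_delayed(lambda t: np.exp(-50.0 * t),
                            lambda t: np.exp(-2 * t), grid, refine=8, tol=1e-3)
        np.testing.assert_allclose(f, np.exp(-2 * grid), atol=0.05)

    def test_mean_age_additivity(self):
        from agekin.curves import LabelingCurve
        grid = np.linspace(0, 20, 2001)
        f = compose_delayed(lambda t: np.exp(-t), lambda t: np.exp(-2 * t), grid)
        total = curve_mean_age(LabelingCurve("conv", grid, np.clip(f, 0, 1)))
        assert total == pytest.approx(1.0 + 0.5, rel=0.005)

    def test_coarse_grid_rejected(self):
        grid = np.linspace(0, 10, 5)
        with pytest.raises(ModelError):
            compose_delayed(lambda t: np.exp(-t), lambda t: np.exp(-2 * t),
                            grid, refine=1, tol=1e-6)

    def test_reduce_then_compose_recovers_chain_output(self):
        # consistency check: observed state of the full chain equals the
        # composition of the input curve with the reduced-system curve
        m = chain_model()
        grid = np.linspace(0, 600, 601)
        per_state, _ = labeling(m, grid)
        red = reduce(m, [False, True])
        _, red_curve = labeling(red, grid)
        f = compose_delayed(per_state[0].values, red_curve.values, grid)
        np.testing.assert_allclose(f, per_state[1].values, atol=1e-4)


class TestBuildTemplate:
    def test_direct_single_pool(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.0)
        m = build_template(tpl, pool_rates=(0.01,), pool_fractions=(1.0,))
        np.testing.assert_allclose(m.M, [[-0.01]])

    def test_one_state_input_closed_form(self):
        a, b = 0.05, 0.01
        tpl = ModelTemplate(input_states=1, protein_pools=1, mu=0.0)
        m = build_template(tpl, input_rates=(a,), pool_rates=(b,),
                           pool_fractions=(1.0,))
        t = np.linspace(0, 400, 41)
        expected = (b * np.exp(-a * t) - a * np.exp(-b * t)) / (b - a)
        np.testing.assert_allclose(observed_curve(m, t), expected, atol=1e-9)

    def test_input_chain_mean_age_is_sum_of_stage_means(self):
        tpl = ModelTemplate(input_states=2, protein_pools=1, mu=0.005)
        assert input_mean_age(tpl, (0.02, 0.05)) == pytest.approx(70.0)
        m = build_template(tpl, input_rates=(0.02, 0.05), pool_rates=(0.01,),
                           pool_fractions=(1.0,))
        per, _ = mean_ages(m)
        assert per[1] == pytest.approx(70.0)    # terminal input state age

    def test_templates_are_mass_balanced(self):
        for mu in (0.0, 0.005):
            for k, p in [(0, 1), (1, 2), (2, 2), (3, 3)]:
                tpl = ModelTemplate(input_states=k, protein_pools=p, mu=mu)
                m = build_template(
                    tpl, input_rates=(0.08, 0.04, 0.02)[:k],
                    pool_rates=(0.02, 0.005, 0.001)[:p],
                    pool_fractions=(0.5, 0.3, 0.2)[:p])
                assert validate(m).ok, (mu, k, p)

    def test_nondegraded_pool_washes_out_at_growth_rate(self):
        tpl = ModelTemplate(input_states=0, protein_pools=1, mu=0.005,
                            nondegraded=True)
        m = build_template(tpl, pool_fractions=(1.0,))
        t = np.linspace(0, 600, 7)
        np.testing.assert_allclose(observed_curve(m, t), np.exp(-0.005 * t),
                                   atol=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ModelError):
            ModelTemplate(input_states=4, protein_pools=1)
        with pytest.raises(ModelError):
            ModelTemplate(input_states=0, protein_pools=0)


class TestModelConfigRoundTrip:
    def test_yaml_round_trip_bit_exact(self, tmp_path):
        from agekin.io import read_model_config, write_model_config
        model = models_battery()["growing_template"]
        path = tmp_path / "model.yaml"
        write_model_config(model, path)
        back = read_model_config(path)
        assert np.array_equal(back.M, model.M)
        assert np.array_equal(back.s, model.s)
        assert back.mu == model.mu
        assert np.array_equal(back.observed, model.observed)
        assert back.labels == model.labels
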