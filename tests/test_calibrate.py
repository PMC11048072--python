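"""Cost function, global fitting, AIC, viable-space sampling and ensembles."""

import numpy as np
import pandas as pd
import pytest

from chometab.calibrate import (
    CalibrationResult,
    EnsembleModel,
    ViableSpaceError,
    build_ensemble,
    compute_aic,
    cost_function,
    ensemble_predict,
    fit_parameters,
    global_sensitivity,
    sample_viable_space,
)
from chometab.kinetics import ModelStructure, reference_parameters


def make_result(structure_id=1, cost=1.0, n_obs=100, n_params=3, seed=0, params=None):
    return CalibrationResult(
        structure_id=structure_id,
        params=params or reference_parameters(),
        cost=cost,
        n_obs=n_obs,
        n_params=n_params,
        converged=True,
        seed=seed,
    )


class TestCostFunction:
    def test_perfect_fit_zero_cost(self):
        t = np.arange(5) * 24.0
        df = pd.DataFrame({"Glc": np.linspace(40, 10, 5)}, index=t)
        assert cost_function(df, df) == 0.0

    def test_one_scale_offset_costs_one(self):
        t = np.arange(5) * 24.0
        obs = pd.DataFrame({"Glc": [10.0, 20.0, 40.0, 20.0, 10.0]}, index=t)
        sim = obs.copy()
        sim.iloc[0, 0] += 40.0  # off by exactly scale = max|obs|
        assert cost_function(sim, obs) == pytest.approx(1.0)

    def test_random_perturbation_matches_double_loop(self):
        rng = np.random.default_rng(8)
        t = np.arange(13) * 24.0
        obs = pd.DataFrame(
            {s: rng.uniform(1, 50, 13) for s in ["Glc", "Lac", "X"]}, index=t
        )
        sim = obs + rng.normal(0, 3, obs.shape)
        got = cost_function(sim, obs)
        expected = 0.0
        for col in obs.columns:
            scale = obs[col].abs().max()
            for k in range(len(t)):
                expected += ((sim[col].iloc[k] - obs[col].iloc[k]) / scale) ** 2
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_state_skipped_with_warning(self):
        t = np.arange(3) * 24.0
        obs = pd.DataFrame({"Glc": [1.0, 2.0, 3.0], "Pyr": [1.0, 1.0, 1.0]}, index=t)
        sim = pd.DataFrame({"Glc": [1.0, 2.0, 3.0]}, index=t)
        with pytest.warns(UserWarning, match="missing"):
            assert cost_function(sim, obs) == 0.0


class TestFitParameters:
    def test_quadratic_surrogate_recovers_minimum(self):
        target = 0.37

        def cost(theta):
            return (theta[0] - target) ** 2

        res = fit_parameters(
            ModelStructure(1),
            data=None,
            bounds={"vmax_gly": (0.01, 1.0)},
            budget=400,
            seed=0,
            cost_fn=cost,
        )
        assert res.params.vmax_gly == pytest.approx(target, abs=1e-6)
        assert res.cost < 1e-10

    def test_seed_reproducibility(self):
        def cost(theta):
            return (theta[0] - 0.2) ** 2 + (theta[1] - 3.0) ** 2

        kw = dict(
            data=None,
            bounds={"vmax_gly": (0.01, 1.0), "km_lac": (0.1, 10.0)},
            budget=200,
            cost_fn=cost,
        )
        a = fit_parameters(ModelStructure(1), seed=3, **kw)
        b = fit_parameters(ModelStructure(1), seed=3, **kw)
        assert a.params == b.params and a.cost == b.cost

    def test_budget_floor_enforced(self):
        with pytest.raises(ValueError):
            fit_parameters(
                ModelStructure(1), None, {"vmax_gly": (0.1, 1.0)}, budget=10,
                cost_fn=lambda th: th[0],
            )


class TestAic:
    def test_cost_equal_n_and_zero_params(self):
        res = make_result(cost=100.0, n_obs=100, n_params=0)
        assert compute_aic(res) == pytest.approx(0.0)

    def test_extra_parameter_adds_two(self):
        a = make_result(cost=50.0, n_obs=100, n_params=3)
        b = make_result(cost=50.0, n_obs=100, n_params=4)
        assert compute_aic(b) - compute_aic(a) == pytest.approx(2.0)

    def test_three_extra_parameters_add_six(self):
        a = make_result(cost=50.0, n_obs=100, n_params=3)
        b = make_result(cost=50.0, n_obs=100, n_params=6)
        assert compute_aic(b) - compute_aic(a) == pytest.approx(6.0)

    def test_small_sample_correction(self):
        res = make_result(cost=10.0, n_obs=20, n_params=4)
        plain = compute_aic(res)
        corr = compute_aic(res, corrected=True)
        assert corr - plain == pytest.approx(2 * 4 * 5 / (20 - 4 - 1))

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            compute_aic(make_result(cost=1.0, n_obs=4, n_params=4))

    def test_irrelevant_parameter_never_improves_aic(self):
        """Fit a linear surrogate with and without a dead parameter: the
        fit quality cannot improve, so AIC must increase."""
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 50)
        y = 2.0 * x + 0.01 * rng.standard_normal(50)

        def cost1(theta):
            return float(np.sum((theta[0] * x - y) ** 2))

        def cost2(theta):
            return float(np.sum((theta[0] * x + theta[1] * 0.0 - y) ** 2))

        r1 = fit_parameters(ModelStructure(1), None, {"a": (0.1, 10.0)},
                            budget=300, seed=0, cost_fn=cost1, free=("a",))
        r2 = fit_parameters(ModelStructure(1), None,
                            {"a": (0.1, 10.0), "b": (0.1, 10.0)},
                            budget=300, seed=0, cost_fn=cost2, free=("a", "b"))
        r1 = CalibrationResult(1, reference_parameters(), r1.cost, 50, 1, True, 0)
        r2 = CalibrationResult(1, reference_parameters(), r2.cost, 50, 2, True, 0)
        assert compute_aic(r2) >= compute_aic(r1) + 1.9


class TestViableSpace:
    def test_spherical_cost_recovers_ball_radius(self):
        d = 3
        radius = 0.5  # threshold 0.25 on sum(x^2) -> ball of radius 0.5

        def cost(x):
            return float(np.sum(x**2))

        samples, ranges = sample_viable_space(
            cost,
            x0=np.zeros(d),
            bounds=np.array([[-2.0, 2.0]] * d),
            cost_threshold=radius**2,
            n_samples=1500,
            seed=0,
            n_walk=3000,
        )
        for i in range(d):
            assert ranges["min"].iloc[i] == pytest.approx(-radius, abs=0.05)
            assert ranges["max"].iloc[i] == pytest.approx(radius, abs=0.05)

    def test_threshold_below_minimum_fails(self):
        with pytest.raises(ViableSpaceError):
            sample_viable_space(
                lambda x: float(np.sum(x**2)) + 1.0,
                x0=np.zeros(2),
                bounds=np.array([[-1, 1], [-1, 1]]),
                cost_threshold=0.5,
                seed=0,
            )

    def test_banana_valley_samples_verify_threshold(self):
        def rosen(x):
            return float((1 - x[0]) ** 2 + 5.0 * (x[1] - x[0] ** 2) ** 2)

        samples, _ = sample_viable_space(
            rosen,
            x0=np.array([1.0, 1.0]),
            bounds=np.array([[-2.0, 2.0], [-1.0, 3.0]]),
            cost_threshold=1.0,
            n_samples=300,
            seed=1,
            n_walk=2000,
        )
        ok = np.mean([rosen(s) <= 1.0 + 1e-12 for s in samples])
        assert ok >= 0.95
        assert len(samples) >= 300
        # bit-identical for a fixed seed
        again, _ = sample_viable_space(
            rosen,
            x0=np.array([1.0, 1.0]),
            bounds=np.array([[-2.0, 2.0], [-1.0, 3.0]]),
            cost_threshold=1.0,
            n_samples=300,
            seed=1,
            n_walk=2000,
        )
        np.testing.assert_array_equal(samples, again)


class TestEnsemble:
    def test_keeps_five_lowest_cost_sets(self):
        results = [make_result(cost=c) for c in [7, 3, 5, 1, 6, 2, 4]]
        ens = build_ensemble(results)
        assert len(ens.members) == 5
        assert ens.member_costs == [1, 2, 3, 4, 5]

    def test_structure_dropped_beyond_delta_aic(self):
        good = make_result(structure_id=1, cost=10.0)
        bad = make_result(structure_id=2, cost=10.0 * np.exp(50 / 100.0))  # dAIC = 50
        ens = build_ensemble([good, bad], delta_aic=10.0)
        assert ens.selected_structures == [1]

    def test_identical_members_allowed(self):
        results = [make_result(cost=1.0) for _ in range(3)]
        ens = build_ensemble(results)
        assert len(ens.members) == 3

    def test_predict_identical_members_zero_band(self, hsd_setup):
        spec, sched, init = hsd_setup
        ens = EnsembleModel(
            members=[(ModelStructure(1), reference_parameters())] * 2,
            member_costs=[0.0, 0.0],
            selected_structures=[1],
        )
        t_grid = np.arange(0, 121, 24.0)
        mean, lo, hi = ensemble_predict(ens, sched, t_grid, init)
        np.testing.assert_allclose(lo.to_numpy(), hi.to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(mean.to_numpy(), lo.to_numpy(), rtol=1e-12)

    def test_mean_equals_brute_force_average(self, hsd_setup):
        """15-member ensemble: pointwise mean equals an independent average."""
        spec, sched, init = hsd_setup
        rng = np.random.default_rng(0)
        members = []
        for _ in range(15):
            p = reference_parameters().replace(
                vmax_gly=0.2 * float(np.exp(rng.uniform(-0.2, 0.2)))
            )
            members.append((ModelStructure(1), p))
        ens = EnsembleModel(members, [0.0] * 15, [1])
        t_grid = np.arange(0, 73, 24.0)
        mean, lo, hi = ensemble_predict(ens, sched, t_grid, init)

        from chometab.calibrate import simulate_at

        preds = [simulate_at(s, p, sched, t_grid, init) for s, p in members]
        stack = np.stack([p.to_numpy() for p in preds])
        np.testing.assert_allclose(mean.to_numpy(), stack.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(lo.to_numpy(), stack.min(axis=0), rtol=1e-12)
        np.testing.assert_allclose(hi.to_numpy(), stack.max(axis=0), rtol=1e-12)


class TestGlobalSensitivity:
    def test_dead_parameter_has_zero_mu_star(self):
        def f(p):
            return 3.0 * p["a"]

        out = global_sensitivity(f, {"a": (0, 1), "dead": (0, 1)}, n_trajectories=6, seed=0)
        assert out.loc["dead", "mu_star"] == pytest.approx(0.0, abs=1e-12)
        assert out.index[0] == "a"

    def test_linear_function_effect_ratio(self):
        def f(p):
            return 3.0 * p["a"] + p["b"]

        out = global_sensitivity(f, {"a": (0, 1), "b": (0, 1)}, n_trajectories=20, seed=1)
        assert out.loc["a", "mu_star"] / out.loc["b", "mu_star"] == pytest.approx(
            3.0, rel=0.05
        )

    def test_reference_model_ranks_shift_parameters_highly(self, hsd_setup, ref_params):
        """Smoke ranking: the glycolysis capacity and the LDH feedback
        constant land in the top half for the trajectory-mismatch cost."""
        from chometab.calibrate import observed_dataframe, simulate_at, cost_function
        from chometab.synthetic import default_spec, generate_dataset

        spec, sched, init = hsd_setup
        meas, _ = generate_dataset(spec, seed=0)
        obs = observed_dataframe(meas)
        times = obs.index.to_numpy()

        names = ["vmax_gly", "ki_lac", "km_glu", "km_ile", "m_asp", "kx_ser"]
        ranges = {n: (getattr(ref_params, n) * 0.5, getattr(ref_params, n) * 2.0)
                  for n in names}

        def f(pdict):
            p = ref_params.replace(**pdict)
            sim = simulate_at(ModelStructure(1), p, sched, times, init)
            return cost_function(sim, obs)

        out = global_sensitivity(f, ranges, n_trajectories=4, seed=0)
        ranking = list(out.index)
        assert ranking.index("vmax_gly") < len(names) // 2
        assert ranking.index("ki_lac") < len(names) // 2
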