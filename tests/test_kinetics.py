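"""Rate laws, ODE right-hand side and event-driven fed-batch simulation."""

import numpy as np
import pytest

import chometab.kinetics as K
from chometab.feedscan import detect_lactate_shift
from chometab.kinetics import (
    Bolus,
    FeedSchedule,
    ModelStructure,
    ParameterSet,
    StateVector,
    apply_bolus,
    growth_rate,
    ode_rhs,
    rate_glycolysis,
    rate_lactate_production,
    rate_lactate_uptake,
    rate_pyruvate_to_tca,
    reaction_rates,
    reference_parameters,
    simulate,
)


def state(**kw) -> StateVector:
    base = dict(
        Glc=20.0, Pyr=1.0, Lac=10.0, Amm=2.0, Asn=5.0, Asp=2.0, Glu=2.0,
        Ser=3.0, Ile=2.0, Leu=2.0, X=4.0, mAb=500.0, V=1.5,
    )
    base.update(kw)
    return StateVector(**base)


class TestRateLaws:
    def test_glycolysis_zero_glucose(self, ref_params):
        assert rate_glycolysis(state(Glc=0.0), ref_params) == 0.0

    def test_glycolysis_saturation_limit(self, ref_params):
        r = rate_glycolysis(state(Glc=1e9, Asn=1e9), ref_params)
        assert r == pytest.approx(ref_params.vmax_gly, rel=1e-6)

    def test_glycolysis_half_saturation_product(self, ref_params):
        r = rate_glycolysis(
            state(Glc=ref_params.km_glc, Asn=ref_params.ka_asn_gly), ref_params
        )
        assert r == pytest.approx(ref_params.vmax_gly / 4.0)

    def test_ldh_no_inhibition_at_zero_lactate(self, ref_params):
        p = ref_params
        r = rate_lactate_production(state(Lac=0.0), p)
        assert r == pytest.approx(p.vmax_ldh * 1.0 / (p.km_pyr_ldh + 1.0))

    @pytest.mark.parametrize("n_lac", [1.0, 2.0, 3.7])
    def test_ldh_half_inhibition_at_ki(self, ref_params, n_lac):
        p = ref_params.replace(n_lac=n_lac)
        full = rate_lactate_production(state(Lac=0.0), p)
        half = rate_lactate_production(state(Lac=p.ki_lac), p)
        assert half == pytest.approx(full / 2.0)

    def test_ldh_hill_exponent_two_double_ki(self, ref_params):
        p = ref_params.replace(n_lac=2.0)
        full = rate_lactate_production(state(Lac=0.0), p)
        r = rate_lactate_production(state(Lac=2 * p.ki_lac), p)
        assert r == pytest.approx(full / 5.0)  # 1/(1+2^2)

    def test_lactate_uptake_zero_lactate(self, ref_params):
        assert rate_lactate_uptake(state(Lac=0.0), ref_params, 0.1) == 0.0

    def test_lactate_uptake_max_when_glycolysis_off(self, ref_params):
        r = rate_lactate_uptake(state(Lac=1e9), ref_params, 0.0)
        assert r == pytest.approx(ref_params.vmax_lup, rel=1e-6)

    def test_lactate_uptake_strictly_decreasing_in_glycolysis(self, ref_params):
        s = state(Lac=15.0)
        rates = [
            rate_lactate_uptake(s, ref_params, rg)
            for rg in np.linspace(0.0, 0.5, 100)
        ]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_tca_no_inhibition_without_asparagine(self, ref_params):
        p = ref_params
        r = rate_pyruvate_to_tca(state(Asn=0.0, Pyr=1.0), p)
        assert r == pytest.approx(p.vmax_tca * 1.0 / (p.km_pyr_tca + 1.0))

    def test_tca_half_inhibition_at_ki(self, ref_params):
        p = ref_params
        r0 = rate_pyruvate_to_tca(state(Asn=0.0), p)
        r = rate_pyruvate_to_tca(state(Asn=p.ki_asn_tca), p)
        assert r == pytest.approx(r0 / 2.0)

    def test_tca_quarter_at_both_half_constants(self, ref_params):
        p = ref_params
        r = rate_pyruvate_to_tca(state(Pyr=p.km_pyr_tca, Asn=p.ki_asn_tca), p)
        assert r == pytest.approx(p.vmax_tca / 4.0)


class TestOdeRhs:
    def test_no_cells_no_feed_metabolites_frozen(self, ref_params):
        y = state(X=0.0).to_array()
        dy = ode_rhs(0.0, y, ref_params, ModelStructure(1), FeedSchedule())
        np.testing.assert_allclose(dy[:10], 0.0, atol=1e-15)

    def test_washout_closed_form(self, ref_params):
        """Cell-free continuous feed relaxes C towards C_feed exponentially."""
        sched = FeedSchedule(continuous_rate=0.01, composition={"Glc": 100.0})
        init = state(X=0.0, Glc=10.0, Pyr=0, Lac=0, Amm=0, Asn=0, Asp=0,
                     Glu=0, Ser=0, Ile=0, Leu=0, mAb=0.0, V=1.0)
        traj = simulate(ModelStructure(1), ref_params, sched, (0.0, 48.0), init)
        t = 48.0
        V0, F, Cf = 1.0, 0.01, 100.0
        # dC/dt = (F/V)(Cf - C), V = V0 + F t  =>  C = Cf - (Cf-C0) V0/V
        expected = Cf - (Cf - 10.0) * V0 / (V0 + F * t)
        assert traj.samples["Glc"].iloc[-1] == pytest.approx(expected, rel=1e-6)

    def test_carbon_ledger_of_lumped_reactions(self, ref_params):
        """Carbon leaving the tracked states equals carbon routed to the
        documented sinks (TCA/CO2, biomass, unmodelled TCA pool)."""
        carbon = {"Glc": 6, "Pyr": 3, "Lac": 3, "Asn": 4, "Asp": 4, "Glu": 5,
                  "Ser": 3, "Ile": 6, "Leu": 6}
        rng = np.random.default_rng(1)
        for variant in (1, 2, 3):
            structure = ModelStructure(variant)
            s = state(**{k: float(v) for k, v in zip(
                ("Glc", "Pyr", "Lac", "Amm", "Asn", "Asp", "Glu", "Ser", "Ile", "Leu"),
                rng.uniform(0.5, 20, 10))})
            r = reaction_rates(s, ref_params, structure)
            mu = r["mu"]
            p = ref_params
            net = {
                "Glc": -r["r_gly"] - mu / p.y_x_glc,
                "Pyr": 2 * r["r_gly"] + r["r_lup"] - r["r_ldh"] - r["r_tca"]
                + (r["r_ser"] if structure.ser_to_pyr else 0.0),
                "Lac": r["r_ldh"] - r["r_lup"],
                "Asn": -r["r_asn"] - p.m_asn * mu,
                "Asp": r["r_asn"] - r["r_aspglu"] + r["r_gluasp"] - p.m_asp * mu,
                "Glu": r["r_aspglu"] - r["r_gluasp"] - r["r_glu"] - p.m_glu * mu,
                "Ser": -r["r_ser"] - p.m_ser * mu,
                "Ile": -r["r_ile"] - p.m_ile * mu,
                "Leu": -r["r_leu"] - p.m_leu * mu,
            }
            tracked_carbon_rate = sum(carbon[k] * v for k, v in net.items())
            # documented sinks: pyruvate oxidised in the TCA lump, glutamate
            # carbon handed to the TCA pool, Ser/Ile/Leu skeletons consumed
            # (unless Ser routes to pyruvate in variant 3), the 1-C TCA top-up
            # of the Asp->Glu transamination, and growth-linked drains
            sinks = (
                3 * r["r_tca"]
                + 5 * r["r_glu"]
                + (0.0 if structure.ser_to_pyr else 3 * r["r_ser"])
                + 6 * r["r_ile"]
                + 6 * r["r_leu"]
                - 1 * r["r_aspglu"]
                + 1 * r["r_gluasp"]
                + mu * (6 / p.y_x_glc + 4 * p.m_asn + 4 * p.m_asp + 5 * p.m_glu
                        + 3 * p.m_ser + 6 * p.m_ile + 6 * p.m_leu)
            )
            assert tracked_carbon_rate == pytest.approx(-sinks, rel=1e-12)


class TestSimulate:
    def test_zero_initial_state_stays_zero(self, ref_params):
        init = StateVector(*([0.0] * 12 + [1.0]))
        traj = simulate(ModelStructure(1), ref_params, FeedSchedule(), (0, 120), init)
        assert np.abs(traj.states.drop(columns="V").to_numpy()).max() == 0.0

    def test_bolus_mixing_formula_exact(self, ref_params):
        init = state(X=0.0, mAb=0.0)
        y = init.to_array()
        out = apply_bolus(y, 0.5, {"Glc": 100.0})
        V = init.V
        assert out[12] == pytest.approx(V + 0.5)
        assert out[0] == pytest.approx((init.Glc * V + 100.0 * 0.5) / (V + 0.5))
        assert out[2] == pytest.approx(init.Lac * V / (V + 0.5))

    def test_single_bolus_in_cell_free_broth(self, ref_params):
        sched = FeedSchedule(boluses=[Bolus(24.0, 0.3, {"Lac": 50.0})])
        init = state(X=0.0, Lac=2.0, V=1.2)
        traj = simulate(ModelStructure(1), ref_params, sched, (0, 48), init)
        after = traj.samples.loc[24.0]
        assert after["Lac"] == pytest.approx((2.0 * 1.2 + 50.0 * 0.3) / 1.5)
        assert after["V"] == pytest.approx(1.5)

    def test_reference_lactate_shift_sign_change(self, hsd_reference_trajectory):
        """HSD control: net lactate flux changes sign (production->uptake)."""
        assert detect_lactate_shift(hsd_reference_trajectory) is not None

    def test_glucose_controller_keeps_glucose_above_threshold(
        self, hsd_reference_trajectory
    ):
        glc = hsd_reference_trajectory.states["Glc"].to_numpy()
        assert glc.min() >= 11.0 * (1 - 1e-6)
        assert len(hsd_reference_trajectory.bolus_log) > 0

    def test_bolus_mass_audit(self, ref_params):
        """Total volume and substance added equals the bolus ledger."""
        sched = FeedSchedule(
            continuous_rate=0.002,
            feed_start=24.0,
            composition={"Glc": 150.0},
            glucose_control=(11.0, 33.0, 2775.0),
            boluses=[Bolus(48.0, 0.03, {"Asn": 100.0})],
        )
        init = state()
        traj = simulate(ModelStructure(1), ref_params, sched, (0, 240), init)
        v_added = sum(b.volume for b in traj.bolus_log)
        t_end = 240.0
        fed = 0.002 * (t_end - 24.0)
        assert traj.samples["V"].iloc[-1] == pytest.approx(
            init.V + fed + v_added, rel=1e-6
        )
        asn_added = sum(b.volume * b.composition.get("Asn", 0.0) for b in traj.bolus_log)
        assert asn_added == pytest.approx(0.03 * 100.0)

    def test_positivity_over_random_parameter_sets(self, hsd_setup):
        spec, sched, init = hsd_setup
        rng = np.random.default_rng(0)
        base = reference_parameters().to_dict()
        for _ in range(25):
            kw = {k: v * np.exp(rng.uniform(-0.7, 0.7)) for k, v in base.items()}
            kw["n_lac"] = max(1.0, kw["n_lac"])
            traj = simulate(ModelStructure(1), ParameterSet(**kw), sched, (0, 288), init)
            assert traj.states[list(K.STATE_NAMES[:12])].to_numpy().min() >= -1e-9

    def test_span_outside_two_weeks_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate(ModelStructure(1), ref_params, FeedSchedule(), (0, 400), state())


class TestLactateShiftMechanism:
    def test_clamped_asparagine_abolishes_shift(self, hsd_setup, ref_params):
        """Holding Asn at its (high) initial value keeps glycolysis active
        and the net lactate flux never turns durably negative."""
        spec, sched, init = hsd_setup
        orig = K.ode_rhs

        def clamped(t, y, p, structure, schedule):
            dy = orig(t, y, p, structure, schedule)
            dy[4] = 0.0
            return dy

        orig_fast = K._fast_rhs
        try:
            def fast_clamped(p, structure, schedule):
                inner = orig_fast(p, structure, schedule)

                def rhs(t, y):
                    dy = inner(t, y)
                    dy[4] = 0.0
                    return dy

                return rhs

            K._fast_rhs = fast_clamped
            traj = simulate(ModelStructure(1), ref_params, sched, (0, 288), init)
        finally:
            K._fast_rhs = orig_fast
        assert detect_lactate_shift(traj) is None

    def test_lower_glycolysis_never_delays_shift(self, hsd_setup, ref_params):
        spec, sched, init = hsd_setup
        days = []
        for vg in np.linspace(0.04, ref_params.vmax_gly, 10):
            traj = simulate(
                ModelStructure(1), ref_params.replace(vmax_gly=vg), sched, (0, 288), init
            )
            d = detect_lactate_shift(traj)
            days.append(np.inf if d is None else d)
        assert all(a <= b for a, b in zip(days, days[1:]))


class TestStructuresAndParams:
    def test_variant_flags(self):
        assert not ModelStructure(1).aspglu_reversible
        assert ModelStructure(2).aspglu_reversible
        assert ModelStructure(3).ser_to_pyr
        with pytest.raises(ValueError):
            ModelStructure(4)

    def test_reverse_transamination_only_in_variant_two(self, ref_params):
        s = state()
        assert reaction_rates(s, ref_params, ModelStructure(1))["r_gluasp"] == 0.0
        assert reaction_rates(s, ref_params, ModelStructure(2))["r_gluasp"] > 0.0

    def test_parameter_yaml_round_trip(self, tmp_path, ref_params):
        path = tmp_path / "p.yaml"
        ref_params.to_yaml(path)
        back = ParameterSet.from_yaml(path)
        assert back == ref_params

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(vmax_gly=-1.0).validate()
        with pytest.raises(ValueError):
            ParameterSet(n_lac=0.5).validate()

    def test_schedule_component_scaling(self):
        sched = FeedSchedule(
            composition={"Asn": 40.0, "Glc": 150.0},
            boluses=[Bolus(24.0, 0.03, {"Asn": 100.0, "Ile": 40.0})],
        )
        scaled = sched.scale_component("Asn", 2.0)
        assert scaled.composition["Asn"] == 80.0
        assert scaled.composition["Glc"] == 150.0
        assert scaled.boluses[0].composition == {"Asn": 200.0, "Ile": 40.0}
        # original untouched
        assert sched.composition["Asn"] == 40.0
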