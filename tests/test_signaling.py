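"""Signaling layer: competitive inhibition, activation ODEs, steady states."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tkisim import signaling as sig


def make_inh(ki=10.0, km=5.0, tki=0.0, variant="standard"):
    return sig.InhibitionParams(
        ki_tki=ki, atp_affinity=km, tki=tki, formula_variant=variant
    )


class TestPhosphoFraction:
    def test_symmetry_case_no_drug(self):
        # ATP at its half-saturation constant, no drug: half-phosphorylated
        assert sig.phospho_fraction(make_inh(km=5.0, tki=0.0), atp=5.0) == pytest.approx(0.5)

    def test_closed_form_at_tki_equal_ki(self):
        # atp=1e-3 M, Km=5e-6 M, tki=Ki doubles the Km term:
        # 1e-3/(1e-3 + 1e-5) evaluated independently by hand
        value = sig.phospho_fraction(
            make_inh(ki=7.0, km=5e-6 * 1e9, tki=7.0), atp=1e-3 * 1e9
        )
        assert value == pytest.approx(1e-3 / (1e-3 + 1e-5), rel=1e-12)
        assert value == pytest.approx(0.990099, abs=1e-5)

    def test_as_printed_variant_doubles_constant(self):
        standard = sig.phospho_fraction(make_inh(tki=0.0), atp=5.0)
        printed = sig.phospho_fraction(make_inh(tki=0.0, variant="as_printed"), atp=5.0)
        assert standard == pytest.approx(0.5)
        assert printed == pytest.approx(5.0 / (5.0 + 10.0))
        assert printed < standard

    def test_limit_no_drug_standard(self):
        inh = make_inh(ki=3.0, km=2.0, tki=0.0)
        assert sig.phospho_fraction(inh, atp=8.0) == pytest.approx(8.0 / 10.0)

    @pytest.mark.parametrize("bad", [
        dict(ki=0.0), dict(ki=-1.0), dict(km=0.0), dict(tki=-0.1),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            make_inh(**bad)

    def test_strictly_decreasing_in_tki(self):
        values = [
            sig.phospho_fraction(make_inh(tki=t), atp=100.0)
            for t in np.linspace(0.0, 500.0, 50)
        ]
        assert np.all(np.diff(values) < 0)

    def test_monotone_in_all_arguments(self):
        base = dict(ki=10.0, km=5.0, tki=50.0)
        f0 = sig.phospho_fraction(make_inh(**base), atp=100.0)
        assert sig.phospho_fraction(make_inh(**{**base, "km": 6.0}), atp=100.0) < f0
        assert sig.phospho_fraction(make_inh(**{**base, "ki": 20.0}), atp=100.0) > f0
        assert sig.phospho_fraction(make_inh(**base), atp=150.0) > f0


class TestKiTable:
    def test_lookup_matches_published_values(self):
        assert sig.ki_lookup("gefitinib", "wild_type") == pytest.approx(16.0)
        assert sig.ki_lookup("gefitinib", "ex19del", t790m=True) == pytest.approx(43.0)
        assert sig.ki_lookup("osimertinib", "ex19del", t790m=True) == pytest.approx(0.032)
        assert sig.ki_lookup("osimertinib", "ex21ins") == pytest.approx(0.97)
        assert sig.ki_lookup("gefitinib", "ex20_resistant") == pytest.approx(26.0)

    def test_az5104_shares_osimertinib_values(self):
        for mut in ("ex19del", "wild_type", "ex20_sensitive"):
            assert sig.ki_lookup("az5104", mut) == sig.ki_lookup("osimertinib", mut)

    def test_atp_affinity_back_derivation_wild_type(self):
        # wild type: Ki 16 nM over ratio 3.2e-3 -> Km_ATP 5.0e3 nM
        assert sig.atp_affinity_from_row(16.0, 3.2e-3) == pytest.approx(5.0e3)

    def test_atp_affinity_near_drug_independent(self):
        # Km_ATP is a kinase property: both drug rows should imply the same
        # value (within print precision) for every mutation except the
        # flagged exon-19-del gefitinib row
        for mut in ("ex19del+t790m", "ex21ins+t790m", "ex20_sensitive",
                    "ex20_resistant", "ex21ins"):
            gef = sig.KI_TABLE_NM[("gefitinib", mut)] / sig.KI_OVER_ATP_AFFINITY[
                ("gefitinib", mut)]
            osi = sig.KI_TABLE_NM[("osimertinib", mut)] / sig.KI_OVER_ATP_AFFINITY[
                ("osimertinib", mut)]
            assert gef == pytest.approx(osi, rel=0.05)

    def test_t790m_ratio_ordering_for_gefitinib(self):
        # the gatekeeper mutation degrades the reversible drug ~1000-fold
        ratio_gef = sig.KI_OVER_ATP_AFFINITY[("gefitinib", "ex19del+t790m")]
        ratio_osi = sig.KI_OVER_ATP_AFFINITY[("osimertinib", "ex19del+t790m")]
        assert ratio_gef / ratio_osi > 1000

    def test_unknown_pair_raises(self):
        with pytest.raises(KeyError):
            sig.ki_lookup("gefitinib", "ex20_sensitive", t790m=True)
        with pytest.raises(KeyError):
            sig.ki_lookup("erlotinib", "ex19del")


class TestOdeRhs:
    def test_pure_decay_with_zero_inputs(self):
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=0.0)
        state = sig.SignalingState(ras_active=3e-6, pi3k_active=2e-6)
        d_ras, d_pi3k = sig.ode_rhs(state, params, rec, pf=1.0)
        assert d_ras == pytest.approx(-params.kda_ras * 3e-6)
        # PI3K still sees the RAS coupling term
        expected = (params.pi3k_total - 2e-6) * params.ka_pi3k_by_ras * 3e-6 \
            - params.kda_pi3k * 2e-6
        assert d_pi3k == pytest.approx(expected)

    def test_published_rate_constants_hand_evaluation(self):
        # one arbitrary state evaluated symbolically with the published
        # kdaRas = 1 /s and kaRasByEGFR = 1.89e6 L/mol/s
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=1e-7, atp=1e-3)
        state = sig.SignalingState(ras_active=4e-6, pi3k_active=0.0)
        pf = 0.5
        d_ras, _ = sig.ode_rhs(state, params, rec, pf)
        by_hand = (1e-5 - 4e-6) * (1.89e6 * 1e-7 * 0.5) - 4e-6 * 1.0
        assert d_ras == pytest.approx(by_hand, rel=1e-12)

    def test_constant_drive_analytic_steady_state(self):
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=2e-7, cmet_active=1e-8)
        pf = 0.7
        a = (params.ka_ras_by_met * rec.cmet_active
             + params.ka_ras_by_vegfr * rec.vegfr_active
             + params.ka_ras_by_egfr * rec.egfr_active * pf)
        expected = params.ras_total * a / (a + params.kda_ras)
        ss = sig.steady_state(params, rec, pf)
        assert ss.ras_active == pytest.approx(expected, rel=1e-12)
        d_ras, d_pi3k = sig.ode_rhs(ss, params, rec, pf)
        assert abs(d_ras) < 1e-10 * params.ras_total
        assert abs(d_pi3k) < 1e-10 * params.pi3k_total


def _integrate_to_steady(params, rec, pf, horizon=200.0):
    def rhs(t, y):
        state = sig.SignalingState(ras_active=y[0], pi3k_active=y[1])
        return sig.ode_rhs(state, params, rec, pf)

    sol = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0], rtol=1e-10, atol=1e-16)
    return sol.y[:, -1]


class TestSteadyState:
    def test_zero_inputs_gives_zero(self):
        ss = sig.steady_state(
            sig.SignalingParams(), sig.ReceptorInputs(egfr_active=0.0), pf=1.0
        )
        assert ss.ras_active == 0.0 and ss.pi3k_active == 0.0

    def test_half_activation_symmetry(self):
        # activation sum equal to the deactivation rate -> half the pool active
        params = sig.SignalingParams()
        egfr = params.kda_ras / params.ka_ras_by_egfr
        ss = sig.steady_state(params, sig.ReceptorInputs(egfr_active=egfr), pf=1.0)
        assert ss.ras_active == pytest.approx(params.ras_total / 2, rel=1e-12)

    def test_matches_integration_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = sig.SignalingParams(
                ka_ras_by_met=10 ** rng.uniform(3, 7),
                ka_ras_by_egfr=10 ** rng.uniform(3, 7),
                ka_pi3k_by_egfr=10 ** rng.uniform(3, 7),
                ka_pi3k_by_ras=10 ** rng.uniform(3, 6),
                kda_ras=10 ** rng.uniform(-1, 1),
                kda_pi3k=10 ** rng.uniform(-1, 1),
            )
            rec = sig.ReceptorInputs(
                egfr_active=10 ** rng.uniform(-9, -6),
                cmet_active=10 ** rng.uniform(-10, -8),
            )
            pf = rng.uniform(0.0, 1.0)
            ss = sig.steady_state(params, rec, pf)
            ras, pi3k = _integrate_to_steady(params, rec, pf)
            assert ss.ras_active == pytest.approx(ras, rel=1e-6, abs=1e-18)
            assert ss.pi3k_active == pytest.approx(pi3k, rel=1e-6, abs=1e-18)

    def test_two_state_pool_conserved_along_trajectory(self):
        # active never exceeds the total pool during transient dynamics
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=1e-6, cmet_active=1e-7)

        def rhs(t, y):
            state = sig.SignalingState(ras_active=y[0], pi3k_active=y[1])
            return sig.ode_rhs(state, params, rec, 1.0)

        sol = solve_ivp(rhs, (0.0, 50.0), [0.0, 0.0], rtol=1e-8, atol=1e-14,
                        dense_output=True)
        traj = sol.sol(np.linspace(0, 50, 200))
        assert np.all(traj[0] <= params.ras_total * (1 + 1e-8))
        assert np.all(traj[1] <= params.pi3k_total * (1 + 1e-8))
        assert np.all(traj >= -1e-12)


class TestNormalizedSignal:
    def test_no_drug_gives_unity(self):
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=1e-7)
        ref = sig.steady_state(params, rec, pf=0.9)
        assert sig.normalized_signal(ref, ref) == pytest.approx(1.0)

    def test_inert_drug_gives_unity(self):
        # infinite Ki: phospho-fraction unchanged regardless of exposure
        inh0 = sig.InhibitionParams(ki_tki=1e308, atp_affinity=5e3, tki=1e6)
        inh_free = sig.InhibitionParams(ki_tki=1e308, atp_affinity=5e3, tki=0.0)
        pf_drug = sig.phospho_fraction(inh0, atp=1e6)
        pf_free = sig.phospho_fraction(inh_free, atp=1e6)
        assert pf_drug == pytest.approx(pf_free, rel=1e-12)

    def test_monotone_decrease_toward_bypass_floor(self):
        params = sig.SignalingParams()
        rec = sig.ReceptorInputs(egfr_active=2e-7, cmet_active=1e-9)
        ref = sig.steady_state(params, rec, pf=0.9)
        values = []
        for pf in (0.9, 0.5, 0.2, 0.05, 0.001):
            state = sig.steady_state(params, rec, pf)
            values.append(sig.normalized_signal(state, ref))
        assert np.all(np.diff(values) < 0)
        floor_state = sig.steady_state(params, rec, 0.0)
        floor = sig.normalized_signal(floor_state, ref)
        assert values[-1] > floor > 0.0

    def test_zero_reference_rejected(self):
        zero = sig.SignalingState(ras_active=0.0, pi3k_active=0.0)
        with pytest.raises(ValueError):
            sig.normalized_signal(zero, zero)
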