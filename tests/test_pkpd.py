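"""Structural model closed forms, ODE solutions, and translation transforms."""

import numpy as np
import pytest

from pops.errors import ConfigurationError
from pops.pkpd import (
    AllometricSpec,
    EmaxParams,
    OneCompOralParams,
    PartitionParams,
    Regimen,
    TMDDParams,
    TurnoverParams,
    allometric_scale,
    auc_interval,
    conc_profile_onecomp,
    css_average,
    emax_effect,
    emax_inverse,
    required_central_inhibition,
    site_free_concentration,
    tmdd_profile,
    turnover_profile,
    turnover_steady_state,
)


class TestCssAverage:
    def test_closed_form(self):
        assert css_average(Regimen(dose=240.0, tau=24.0), 10.0) == pytest.approx(1.0)

    def test_zero_dose(self):
        assert css_average(Regimen(dose=0.0, tau=24.0), 5.0) == 0.0

    def test_linearity_in_dose(self):
        c1 = css_average(Regimen(dose=100.0, tau=12.0), 7.0)
        c2 = css_average(Regimen(dose=200.0, tau=12.0), 7.0)
        assert c2 == pytest.approx(2 * c1)


class TestOneCompProfile:
    p = OneCompOralParams(cl_f=10.0, v_f=100.0, ka=1.0)

    def test_iv_bolus_initial_condition(self):
        reg = Regimen(dose=50.0, tau=24.0, route="iv_bolus")
        c = conc_profile_onecomp(self.p, reg, np.array([0.0]))
        assert c[0] == pytest.approx(50.0 / 100.0)

    def test_steady_state_auc_matches_css(self):
        # superpose many doses, integrate the last interval
        reg = Regimen(dose=120.0, tau=24.0, route="oral", n_doses=60)
        t0 = 59 * 24.0
        times = np.linspace(t0, t0 + 24.0, 2000)
        c = conc_profile_onecomp(self.p, reg, times)
        auc = auc_interval(times, c, t0, t0 + 24.0)
        assert auc == pytest.approx(css_average(reg, self.p.cl_f) * 24.0, rel=1e-3)

    def test_washout_to_zero(self):
        reg = Regimen(dose=100.0, tau=24.0, route="oral")
        c = conc_profile_onecomp(self.p, reg, np.array([2000.0]))
        assert c[0] == pytest.approx(0.0, abs=1e-9)

    def test_equal_rates_limit_continuous(self):
        # ka == ke uses the limiting form and stays close to ka = ke*(1+eps)
        p_eq = OneCompOralParams(cl_f=10.0, v_f=100.0, ka=0.1)
        p_near = OneCompOralParams(cl_f=10.0, v_f=100.0, ka=0.1000001)
        reg = Regimen(dose=100.0, tau=24.0, route="oral")
        t = np.linspace(0, 48, 50)
        c_eq = conc_profile_onecomp(p_eq, reg, t)
        c_near = conc_profile_onecomp(p_near, reg, t)
        assert np.allclose(c_eq, c_near, rtol=1e-4)
        assert (c_eq >= 0).all()


class TestSiteFreeConcentration:
    def test_identity_with_no_binding(self):
        part = PartitionParams(fu=1.0, kp_uu=1.0)
        assert site_free_concentration(3.0, part, "brain") == pytest.approx(3.0)

    def test_product_of_factors(self):
        part = PartitionParams(fu=0.1, kp_uu=0.5)
        assert site_free_concentration(10.0, part, "brain") == pytest.approx(0.5)

    def test_kp_uu_range_scales_output(self):
        # a compound whose partition coefficient spans 0.35-0.50
        for kp in (0.35, 0.50):
            part = PartitionParams(fu=0.2, kp_uu=kp)
            out = site_free_concentration(10.0, part, "brain")
            assert out == pytest.approx(10.0 * 0.2 * kp)

    def test_missing_partition_parameter(self):
        with pytest.raises(ConfigurationError):
            site_free_concentration(1.0, PartitionParams(fu=0.5), "brain")


class TestEmax:
    p = EmaxParams(emax=1.0, ec50=2.0)

    def test_zero_concentration(self):
        assert emax_effect(0.0, self.p) == 0.0

    def test_half_maximal_at_ec50(self):
        assert emax_effect(2.0, self.p) == pytest.approx(0.5)

    def test_ninety_percent_at_9x_ec50(self):
        assert emax_effect(9 * 2.0, self.p) == pytest.approx(0.9)

    def test_inverse_half_max(self):
        assert emax_inverse(0.5, self.p) == pytest.approx(2.0)

    def test_inverse_of_zero(self):
        assert emax_inverse(0.0, self.p) == 0.0

    def test_unreachable_effect(self):
        with pytest.raises(ValueError):
            emax_inverse(1.0, self.p)

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.3])
    def test_roundtrip_identity(self, hill):
        p = EmaxParams(emax=0.8, ec50=3.0, hill=hill)
        effects = np.linspace(0.01, 0.79, 25)
        back = emax_effect(emax_inverse(effects, p), p)
        assert np.allclose(back, effects, atol=1e-9)


class TestRequiredCentralInhibition:
    @pytest.mark.parametrize("fold,expected", [(1.0, 0.0), (2.0, 0.5), (3.0, 2.0 / 3.0)])
    def test_values(self, fold, expected):
        assert required_central_inhibition(fold) == pytest.approx(expected)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            required_central_inhibition(0.9)


class TestTurnover:
    def test_baseline_preserved_without_drug(self):
        p = TurnoverParams(kin=5.0, kout=0.5, mode="inhibit-production",
                           drug=EmaxParams(emax=0.8, ec50=1.0))
        t = np.linspace(0, 50, 30)
        r = turnover_profile(p, lambda t: 0.0, t)
        assert np.allclose(r, p.r0, rtol=1e-6)

    def test_inhibit_production_steady_state(self):
        p = TurnoverParams(kin=5.0, kout=0.5, mode="inhibit-production",
                           drug=EmaxParams(emax=0.8, ec50=1.0))
        # constant C = IC50 -> E = 0.4 -> steady state 0.6 * R0
        t_ss = 10 * np.log(2) / p.kout
        r = turnover_profile(p, lambda t: 1.0, np.array([0.0, t_ss]))
        assert r[-1] == pytest.approx(0.6 * p.r0, rel=5e-3)
        assert turnover_steady_state(p, 1.0) == pytest.approx(0.6 * p.r0)

    def test_stimulate_production_saturating_limit(self):
        p = TurnoverParams(kin=2.0, kout=0.2, mode="stimulate-production",
                           drug=EmaxParams(emax=3.0, ec50=1.0))
        t_ss = 10 * np.log(2) / p.kout
        r = turnover_profile(p, lambda t: 1e9, np.array([0.0, t_ss]))
        assert r[-1] == pytest.approx(4.0 * p.r0, rel=5e-3)

    def test_transit_chain_delays_but_converges(self):
        drug = EmaxParams(emax=0.5, ec50=1.0)
        fast = TurnoverParams(kin=1.0, kout=0.3, mode="inhibit-production", drug=drug)
        slow = TurnoverParams(kin=1.0, kout=0.3, mode="inhibit-production", drug=drug, n_transit=3)
        t = np.linspace(0, 30 * np.log(2) / 0.3, 120)
        r_fast = turnover_profile(fast, lambda t: 1.0, t)
        r_slow = turnover_profile(slow, lambda t: 1.0, t)
        # same steady state, slower approach
        assert r_slow[-1] == pytest.approx(r_fast[-1], rel=5e-3)
        early = t < 2.0
        assert (r_slow[early] >= r_fast[early] - 1e-9).all()


def two_comp_iv_closed_form(dose, cl, v1, q, v2, t):
    """Independent biexponential solution for a linear two-compartment IV bolus."""
    k10, k12, k21 = cl / v1, q / v1, q / v2
    b = k10 + k12 + k21
    disc = np.sqrt(b * b - 4 * k10 * k21)
    lam1, lam2 = (b + disc) / 2, (b - disc) / 2
    c0 = dose / v1
    a = c0 * (k21 - lam1) / (lam2 - lam1)
    bb = c0 * (k21 - lam2) / (lam1 - lam2)
    return a * np.exp(-lam1 * t) + bb * np.exp(-lam2 * t)


class TestTMDD:
    params = dict(cl=0.3, v1=3.0, q=0.2, v2=4.0, kdeg=0.1, kint=0.05)

    def test_no_target_reduces_to_linear_two_compartment(self):
        p = TMDDParams(ksyn=0.0, kon=1.0, koff=0.1, **self.params)
        reg = Regimen(dose=10.0, tau=240.0, route="iv_bolus")
        t = np.linspace(0.0, 200.0, 60)
        prof = tmdd_profile(p, reg, t)
        expected = two_comp_iv_closed_form(10.0, p.cl, p.v1, p.q, p.v2, t)
        assert np.allclose(prof["free_drug"], expected, rtol=1e-3)

    def test_bolus_initial_condition_full_model(self):
        p = TMDDParams(ksyn=0.5, kon=0.5, koff=0.05, **self.params)
        reg = Regimen(dose=12.0, tau=240.0, route="iv_bolus")
        prof = tmdd_profile(p, reg, np.array([1e-8, 1.0]))
        assert prof["free_drug"][0] == pytest.approx(12.0 / 3.0, rel=1e-3)

    def test_baseline_target_without_drug(self):
        p = TMDDParams(ksyn=0.5, kon=0.5, koff=0.05, **self.params)
        reg = Regimen(dose=0.0, tau=240.0, route="iv_bolus")
        prof = tmdd_profile(p, reg, np.linspace(0.0, 100.0, 20))
        assert np.allclose(prof["free_target"], p.r0, rtol=1e-6)

    def test_mass_balance_full_model(self):
        p = TMDDParams(ksyn=0.4, kon=0.8, koff=0.05, **self.params)
        reg = Regimen(dose=20.0, tau=240.0, route="iv_bolus")
        t = np.linspace(0.0, 300.0, 40)
        prof = tmdd_profile(p, reg, t)
        in_system = prof["free_drug"] * p.v1 + prof["peripheral_amount"] + prof["complex"] * p.v1
        total = in_system + prof["eliminated"] + prof["internalized"]
        assert np.allclose(total, 20.0, rtol=1e-6)

    def test_qss_tracks_full_model(self):
        full = TMDDParams(ksyn=0.4, kon=100.0, koff=10.0, **self.params)
        qss = TMDDParams(ksyn=0.4, kss=(10.0 + self.params["kint"]) / 100.0, **self.params)
        reg = Regimen(dose=20.0, tau=240.0, route="iv_bolus")
        t = np.linspace(1.0, 200.0, 30)
        cf = tmdd_profile(full, reg, t)["free_drug"]
        cq = tmdd_profile(qss, reg, t)["free_drug"]
        assert np.allclose(cf, cq, rtol=0.05)

    def test_states_non_negative_and_occupancy_bounded(self):
        p = TMDDParams(ksyn=0.5, kon=0.5, koff=0.05, **self.params)
        reg = Regimen(dose=15.0, tau=120.0, route="iv_bolus", n_doses=2)
        prof = tmdd_profile(p, reg, np.linspace(0.0, 400.0, 80))
        for key in ("free_drug", "free_target", "complex"):
            assert (prof[key] >= -1e-9).all()
        assert ((prof["occupancy"] >= 0) & (prof["occupancy"] <= 1 + 1e-9)).all()


class TestAllometry:
    def test_identity_same_weight(self):
        assert allometric_scale(2.0, "clearance-like", 70.0, 70.0) == pytest.approx(2.0)

    def test_mouse_to_human_clearance(self):
        scaled = allometric_scale(1.0, "clearance-like", 3.0, 70.0)
        assert scaled == pytest.approx((70.0 / 3.0) ** 0.75, rel=1e-9)
        assert scaled == pytest.approx(10.6, abs=0.1)

    def test_volume_scales_linearly(self):
        assert allometric_scale(5.0, "volume-like", 10.0, 70.0) == pytest.approx(35.0)


class TestAucInterval:
    def test_rectangle(self):
        t = np.linspace(0, 24, 25)
        assert auc_interval(t, np.full_like(t, 3.0), 0.0, 24.0) == pytest.approx(72.0)

    def test_monoexponential_closed_form(self):
        ke, c0, tau = 0.2, 5.0, 24.0
        t = np.linspace(0, tau, 100)
        auc = auc_interval(t, c0 * np.exp(-ke * t), 0.0, tau)
        assert auc == pytest.approx(c0 / ke * (1 - np.exp(-ke * tau)), rel=1e-3)

    def test_zero_series(self):
        t = np.linspace(0, 10, 11)
        assert auc_interval(t, np.zeros_like(t), 0.0, 10.0) == 0.0

    def test_reversed_interval_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            auc_interval(t, np.ones_like(t), 5.0, 5.0)


def test_dose_linearity_of_exposure_models():
    """Linear models double every exposure output when the dose doubles."""
    p = OneCompOralParams(cl_f=8.0, v_f=60.0, ka=1.2)
    t = np.linspace(0, 48, 97)
    c1 = conc_profile_onecomp(p, Regimen(dose=100.0, tau=24.0, n_doses=2), t)
    c2 = conc_profile_onecomp(p, Regimen(dose=200.0, tau=24.0, n_doses=2), t)
    assert np.allclose(c2, 2 * c1, rtol=1e-12)
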