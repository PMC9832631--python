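"""Nested Monte-Carlo estimator: oracle equivalence, calibration, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from pops.criteria import Condition, CriteriaSet, Criterion
from pops.distributions import BSVSpec, UncertaintyDist, cv_to_lognormal_sigma, point
from pops.engine import (
    EndpointModel,
    SimulationPlan,
    compute_pops,
    optimal_dose,
    proportion_bands,
    simulate_population,
    subject_rng,
    uncertainty_rng,
)
from pops.errors import ConfigurationError
from pops.pkpd import Regimen
from pops.structural import get_model


def make_plan(doses, m=4, n=8, seed=0, tau=24.0, crn=True):
    return SimulationPlan(
        m=m, n=n, seed=seed, common_random_numbers=crn,
        regimens=tuple(Regimen(dose=d, tau=tau) for d in doses),
    )


def auc_model(cl=10.0, cv=30.0):
    return EndpointModel(
        structural=get_model("onecomp_auc"),
        fixed={"cl_f": cl},
        bsv=BSVSpec(cv={"cl_f": cv}),
    )


def benefit_on_auc(threshold, n=0.5):
    return CriteriaSet((
        Criterion("benefit", "benefit", (Condition("auc_tau", ">=", threshold),), n),
    ))


def risk_on_auc(threshold, n=0.1):
    return CriteriaSet((
        Criterion("risk", "risk", (Condition("auc_tau", ">", threshold),), n),
    ))


class TestSimulatePopulation:
    def test_no_bsv_all_rows_identical(self):
        model = auc_model(cv=0.0)
        omega = model.bsv.realize(uncertainty_rng(0, 0))
        frame = simulate_population(model, {"cl_f": 10.0}, omega, 6, subject_rng(0, 0),
                                    Regimen(dose=100.0, tau=24.0))
        assert frame["auc_tau"].nunique() == 1
        assert frame["auc_tau"].iloc[0] == pytest.approx(10.0)

    def test_bsv_cv_recovery(self):
        model = auc_model(cv=30.0)
        omega = model.bsv.realize(uncertainty_rng(0, 0))
        frame = simulate_population(model, {"cl_f": 10.0}, omega, 100_000, subject_rng(0, 0),
                                    Regimen(dose=100.0, tau=24.0))
        cl = 100.0 / frame["auc_tau"]
        cv = cl.std() / cl.mean() * 100
        assert abs(cv - 30.0) < 0.03 * 30.0

    def test_same_seed_identical_matrix(self):
        model = auc_model()
        omega = model.bsv.realize(uncertainty_rng(3, 1))
        a = simulate_population(model, {"cl_f": 8.0}, omega, 50, subject_rng(3, 1),
                                Regimen(dose=10.0, tau=24.0))
        b = simulate_population(model, {"cl_f": 8.0}, omega, 50, subject_rng(3, 1),
                                Regimen(dose=10.0, tau=24.0))
        pd.testing.assert_frame_equal(a, b)


def brute_force_pops(plan, fixed, specs, cv_percent, criteria_list):
    """Independent naive nested double loop with the pinned substream discipline.

    criteria_list: (endpoint, comparator, threshold_dist, n_dist, kind) tuples.
    Returns (pops_per_dose, fractions[replicate, dose, criterion]).
    """
    sigma = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    omega = np.array([[sigma**2]])
    n_doses = len(plan.regimens)
    passes = np.zeros((plan.m, n_doses), dtype=bool)
    fractions = np.zeros((plan.m, n_doses, len(criteria_list)))
    comp = {">": np.greater, ">=": np.greater_equal, "<": np.less, "<=": np.less_equal}
    for i in range(plan.m):
        r_u = np.random.default_rng(np.random.SeedSequence((plan.seed, 0, i)))
        theta = dict(fixed)
        for name, dist in specs.items():
            theta[name] = float(np.asarray(dist.sample(r_u, size=1))[0])
        realized = []
        for endpoint, comparator, kdist, ndist, kind in criteria_list:
            k = float(kdist.sample(r_u))
            n_req = float(ndist.sample(r_u))
            realized.append((endpoint, comparator, k, n_req, kind))
        r_s = np.random.default_rng(np.random.SeedSequence((plan.seed, 1, i)))
        etas = r_s.multivariate_normal(np.zeros(1), omega, size=plan.n,
                                       check_valid="ignore", method="eigh")
        cl = theta["cl_f"] * np.exp(etas[:, 0])
        for d, reg in enumerate(plan.regimens):
            auc = reg.dose / cl
            ok_all = True
            for c, (endpoint, comparator, k, n_req, kind) in enumerate(realized):
                frac = float(np.mean(comp[comparator](auc, k)))
                fractions[i, d, c] = frac
                ok = frac >= n_req if kind == "benefit" else frac < n_req
                ok_all = ok_all and ok
            passes[i, d] = ok_all
    return passes.mean(axis=0), fractions


class TestOracleEquivalence:
    def test_bit_exact_against_naive_double_loop(self):
        plan = make_plan([50.0, 100.0, 200.0], m=6, n=4, seed=123)
        specs = {"cl_f": UncertaintyDist("lognormal", {"mu": np.log(10.0), "sigma": 0.2})}
        kdist = UncertaintyDist("uniform", {"lower": 5.0, "upper": 15.0})
        criteria = benefit_on_auc(kdist, n=0.5)
        model = auc_model(cl=10.0, cv=30.0)
        curve = compute_pops(plan, model, criteria, specs)
        expected_pops, expected_frac = brute_force_pops(
            plan, {"cl_f": 10.0}, specs, 30.0,
            [("auc_tau", ">=", kdist, point(0.5), "benefit")],
        )
        assert np.array_equal(curve.pops, expected_pops)
        assert np.array_equal(curve.fractions["benefit"], expected_frac[:, :, 0])

    def test_bit_exact_with_joint_benefit_and_risk(self):
        plan = make_plan([20.0, 80.0, 320.0], m=8, n=5, seed=7)
        kdist = UncertaintyDist("normal", {"mean": 10.0, "sd": 2.0})
        criteria = CriteriaSet((
            Criterion("benefit", "benefit", (Condition("auc_tau", ">=", kdist),), 0.5),
            Criterion("risk", "risk", (Condition("auc_tau", ">", point(30.0)),), 0.2),
        ))
        model = auc_model(cl=10.0, cv=25.0)
        curve = compute_pops(plan, model, criteria, {})
        expected_pops, _ = brute_force_pops(
            plan, {"cl_f": 10.0}, {}, 25.0,
            [("auc_tau", ">=", kdist, point(0.5), "benefit"),
             ("auc_tau", ">", point(30.0), point(0.2), "risk")],
        )
        assert np.array_equal(curve.pops, expected_pops)


class TestDegenerateCollapse:
    def test_point_priors_give_indicator_pops(self):
        plan = make_plan([100.0, 500.0], m=5, n=20, seed=0)
        model = auc_model(cv=0.0)
        # deterministic AUC = dose/10: 10 then 50; threshold 20 splits them
        criteria = benefit_on_auc(point(20.0), n=0.5)
        curve = compute_pops(plan, model, criteria, {})
        assert set(np.unique(curve.pops)) <= {0.0, 1.0}
        assert list(curve.pops) == [0.0, 1.0]

    def test_impossible_criterion_gives_zero(self):
        plan = make_plan([1.0, 10.0], m=4, n=10)
        criteria = benefit_on_auc(point(1e9), n=0.5)
        curve = compute_pops(plan, auc_model(), criteria, {})
        assert (curve.pops == 0.0).all()


class TestMonotonicity:
    def test_benefit_only_non_decreasing_in_dose(self):
        plan = make_plan([25.0, 50.0, 100.0, 200.0, 400.0], m=100, n=100, seed=5)
        criteria = benefit_on_auc(UncertaintyDist("uniform", {"lower": 5, "upper": 20}), n=0.8)
        curve = compute_pops(plan, auc_model(), criteria, {})
        assert (np.diff(curve.pops) >= 0).all()

    def test_risk_only_non_increasing_in_dose(self):
        plan = make_plan([25.0, 50.0, 100.0, 200.0, 400.0], m=100, n=100, seed=5)
        criteria = risk_on_auc(UncertaintyDist("uniform", {"lower": 10, "upper": 40}), n=0.1)
        curve = compute_pops(plan, auc_model(), criteria, {})
        assert (np.diff(curve.pops) <= 0).all()

    def test_tightening_benefit_never_increases_pops(self):
        plan = make_plan([50.0, 100.0, 200.0], m=60, n=50, seed=11)
        model = auc_model()
        loose = compute_pops(plan, model, benefit_on_auc(point(8.0), n=0.7), {})
        tight = compute_pops(plan, model, benefit_on_auc(point(12.0), n=0.7), {})
        assert (tight.pops <= loose.pops).all()


class TestProportionBands:
    def test_identical_replicates_zero_width(self):
        med, lo, hi = proportion_bands(np.full(30, 0.4))
        assert med == lo == hi == 0.4

    def test_percentile_rule_type7(self):
        fracs = np.arange(100) / 100.0
        med, lo, hi = proportion_bands(fracs, level=90.0)
        assert lo == pytest.approx(np.percentile(fracs, 5))
        assert hi == pytest.approx(np.percentile(fracs, 95))
        assert med == pytest.approx(0.495)

    def test_bounded_in_unit_interval(self):
        r = np.random.default_rng(0)
        med, lo, hi = proportion_bands(r.uniform(size=200))
        assert 0.0 <= lo <= med <= hi <= 1.0


class TestOptimalDose:
    def _curve_with_pops(self, pops):
        plan = make_plan(list(range(1, len(pops) + 1)), m=1, n=1)
        curve = compute_pops(plan, auc_model(cv=0.0), benefit_on_auc(point(1e9)), {})
        object.__setattr__(curve, "pops", np.asarray(pops, dtype=float))
        return curve

    def test_monotone_curve_picks_last(self):
        assert optimal_dose(self._curve_with_pops([0.1, 0.5, 0.9]))[0] == 3

    def test_flat_curve_ties_to_lowest(self):
        assert optimal_dose(self._curve_with_pops([0.4, 0.4, 0.4]))[0] == 1

    def test_interior_argmax(self):
        pops = [0.1, 0.7, 0.95, 0.6, 0.2]
        dose, val = optimal_dose(self._curve_with_pops(pops))
        assert (dose, val) == (3, 0.95)
        assert val == max(pops)


class TestValidation:
    def test_unknown_uncertainty_parameter_rejected(self):
        plan = make_plan([10.0])
        with pytest.raises(ConfigurationError, match="unknown to model"):
            compute_pops(plan, auc_model(), benefit_on_auc(point(1.0)),
                         {"nope": point(1.0)})

    def test_criterion_endpoint_must_exist(self):
        plan = make_plan([10.0])
        criteria = CriteriaSet((
            Criterion("b", "benefit", (Condition("missing", ">=", point(1.0)),), 0.5),
        ))
        with pytest.raises(ConfigurationError, match="missing"):
            compute_pops(plan, auc_model(), criteria, {})


class TestConvergence:
    def test_doubling_n_shrinks_fraction_se(self):
        kdist = point(10.0)
        curves = {}
        for n in (50, 200):
            plan = make_plan([100.0], m=200, n=n, seed=21)
            curves[n] = compute_pops(plan, auc_model(), benefit_on_auc(kdist, n=0.5), {})
        se_small = curves[50].fractions["benefit"][:, 0].std()
        se_large = curves[200].fractions["benefit"][:, 0].std()
        # quadrupling N should halve the per-replicate binomial noise
        assert se_large < se_small * 0.7

    def test_pops_stable_under_m_growth(self):
        kdist = UncertaintyDist("uniform", {"lower": 8.0, "upper": 14.0})
        plan_small = make_plan([100.0], m=300, n=50, seed=31)
        plan_big = make_plan([100.0], m=1200, n=50, seed=31)
        criteria = benefit_on_auc(kdist, n=0.5)
        p_small = compute_pops(plan_small, auc_model(), criteria, {}).pops[0]
        p_big = compute_pops(plan_big, auc_model(), criteria, {}).pops[0]
        se = np.sqrt(p_small * (1 - p_small) / 300)
        assert abs(p_big - p_small) < 3 * se


def test_crn_reuses_subjects_across_doses():
    """With common random numbers the same replicate passes contiguously in dose."""
    plan_crn = make_plan([10.0, 20.0, 40.0], m=30, n=40, seed=2, crn=True)
    curve = compute_pops(plan_crn, auc_model(cv=0.0), benefit_on_auc(point(2.0), n=1.0), {})
    # deterministic model: fractions are 0/1 steps, identical across replicates
    for d in range(3):
        assert curve.fractions["benefit"][:, d].std() == 0.0
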