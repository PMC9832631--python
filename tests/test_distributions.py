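"""Sampling families, BSV conventions, and reproducibility contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pops.distributions import (
    BSVSpec,
    CorrelationSpec,
    UncertaintyDist,
    cv_to_lognormal_sigma,
    draw_fixed_effects,
    draw_subject_etas,
    point,
    scaled_beta,
    weighted_categorical,
)
from pops.errors import ConfigurationError, NumericError


def rng(seed=0):
    return np.random.default_rng(seed)


class TestCvToLognormalSigma:
    @pytest.mark.parametrize(
        "cv,expected",
        [(0.0, 0.0), (30.0, 0.2936), (100.0, 0.8326)],
    )
    def test_closed_form(self, cv, expected):
        assert cv_to_lognormal_sigma(cv) == pytest.approx(expected, abs=5e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_to_lognormal_sigma(-1.0)


class TestFamilies:
    def test_point_mass_identity(self):
        specs = {"a": point(1.5), "b": point(-2.0)}
        draws = draw_fixed_effects(specs, M=7, rng=rng())
        assert (draws["a"] == 1.5).all() and (draws["b"] == -2.0).all()

    def test_uniform_bounds_and_mean(self):
        # a translation-uncertainty range for an unbound partition coefficient
        d = UncertaintyDist("uniform", {"lower": 0.45, "upper": 0.75})
        x = d.sample(rng(1), size=10_000)
        assert x.min() >= 0.45 and x.max() <= 0.75
        se = (0.75 - 0.45) / np.sqrt(12 * x.size)
        assert abs(x.mean() - 0.60) < 3 * se

    def test_lognormal_median_cv_parameterisation(self):
        d = UncertaintyDist("lognormal", {"median": 2.0, "cv_percent": 30.0})
        assert d.params["mu"] == pytest.approx(np.log(2.0))
        assert d.params["sigma"] == pytest.approx(cv_to_lognormal_sigma(30.0))
        x = d.sample(rng(2), size=100_000)
        assert np.median(x) == pytest.approx(2.0, rel=0.02)

    def test_weighted_categorical_frequencies(self):
        d = weighted_categorical([1.0, 2.0, 3.0], [60, 30, 10])
        x = d.sample(rng(3), size=100_000)
        for value, p in [(1.0, 0.6), (2.0, 0.3), (3.0, 0.1)]:
            se = np.sqrt(p * (1 - p) / x.size)
            assert abs(np.mean(x == value) - p) < 3 * se

    def test_weighted_categorical_degenerate(self):
        assert weighted_categorical([5.0], [1.0]).sample(rng()) == 5.0
        d = weighted_categorical([1.0, 2.0, 3.0], [0, 0, 1])
        assert (d.sample(rng(), size=100) == 3.0).all()

    def test_weighted_categorical_negative_weight(self):
        with pytest.raises(ValueError):
            weighted_categorical([1.0, 2.0], [1.0, -0.5])

    def test_unknown_family(self):
        with pytest.raises(ConfigurationError):
            UncertaintyDist("triangular", {"a": 1})


class TestScaledBeta:
    def test_support_containment(self):
        d = scaled_beta(mode=2.0, lower=1.0, upper=16.0)
        x = d.sample(rng(4), size=100_000)
        assert x.min() >= 1.0 and x.max() <= 16.0

    def test_empirical_mode_near_requested(self):
        d = scaled_beta(mode=2.0, lower=1.0, upper=16.0)
        x = d.sample(rng(5), size=100_000)
        counts, edges = np.histogram(x, bins=40)
        peak = np.argmax(counts)
        width = edges[1] - edges[0]
        # peak bin within one bin width of the analytic mode
        assert edges[peak] - width <= 2.0 <= edges[peak + 1] + width

    def test_boundary_mode_monotone_decreasing_density(self):
        d = scaled_beta(mode=1.0, lower=1.0, upper=16.0)
        x = d.sample(rng(6), size=100_000)
        counts, _ = np.histogram(x, bins=8)
        assert (np.diff(counts) <= 0).all()

    def test_mode_outside_support(self):
        with pytest.raises(ValueError):
            scaled_beta(mode=20.0, lower=1.0, upper=16.0)


class TestDrawFixedEffects:
    def test_correlated_lognormal_pair(self):
        # e.g. Emax and EC50 estimated jointly share estimation correlation
        specs = {
            "emax": UncertaintyDist("lognormal", {"mu": 0.0, "sigma": 0.3}),
            "ec50": UncertaintyDist("lognormal", {"mu": 1.0, "sigma": 0.5}),
        }
        corr = CorrelationSpec(("emax", "ec50"), np.array([[1.0, 0.9], [0.9, 1.0]]))
        draws = draw_fixed_effects(specs, corr, M=100_000, rng=rng(7))
        r = np.corrcoef(np.log(draws["emax"]), np.log(draws["ec50"]))[0, 1]
        assert abs(r - 0.9) < 0.02

    def test_marginals_preserved_under_correlation(self):
        specs = {
            "a": UncertaintyDist("normal", {"mean": 1.0, "sd": 0.2}),
            "b": UncertaintyDist("lognormal", {"mu": 0.0, "sigma": 0.25}),
        }
        corr = CorrelationSpec(("a", "b"), np.array([[1.0, -0.5], [-0.5, 1.0]]))
        draws = draw_fixed_effects(specs, corr, M=100_000, rng=rng(8))
        assert draws["a"].mean() == pytest.approx(1.0, abs=0.01)
        assert np.log(draws["b"]).std() == pytest.approx(0.25, rel=0.02)

    def test_correlation_over_uniform_rejected(self):
        specs = {"a": UncertaintyDist("uniform", {"lower": 0, "upper": 1}), "b": point(1.0)}
        corr = CorrelationSpec(("a", "b"), np.eye(2))
        with pytest.raises(ConfigurationError):
            draw_fixed_effects(specs, corr, M=10, rng=rng())

    def test_reproducible_given_seed(self):
        specs = {"a": UncertaintyDist("normal", {"mean": 0, "sd": 1})}
        d1 = draw_fixed_effects(specs, M=50, rng=rng(9))
        d2 = draw_fixed_effects(specs, M=50, rng=rng(9))
        assert (d1 == d2).all().all()


class TestSubjectEtas:
    def test_zero_omega_gives_exact_zeros(self):
        etas = draw_subject_etas(np.zeros((2, 2)), 100, rng())
        assert (etas == 0.0).all() and etas.shape == (100, 2)

    def test_variance_recovery(self):
        sigma2 = 0.09
        etas = draw_subject_etas(np.array([[sigma2]]), 100_000, rng(10))
        assert abs(etas.var() - sigma2) / sigma2 < 0.03

    def test_same_seed_identical(self):
        omega = np.array([[0.1, 0.02], [0.02, 0.05]])
        a = draw_subject_etas(omega, 1000, rng(11))
        b = draw_subject_etas(omega, 1000, rng(11))
        assert (a == b).all()

    def test_non_psd_rejected_with_echo(self):
        omega = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NumericError, match="positive semidefinite"):
            draw_subject_etas(omega, 10, rng())


class TestBSVSpec:
    def test_lognormal_bsv_preserves_median(self):
        spec = BSVSpec(cv={"cl": 30.0})
        realized = spec.realize(rng())
        etas = draw_subject_etas(realized.omega, 100_000, rng(12))
        values = realized.apply({"cl": 10.0}, etas)["cl"]
        assert np.median(values) == pytest.approx(10.0, rel=0.01)

    def test_cv_recovery_30_percent(self):
        spec = BSVSpec(cv={"cl": 30.0})
        realized = spec.realize(rng())
        etas = draw_subject_etas(realized.omega, 100_000, rng(13))
        values = realized.apply({"cl": 10.0}, etas)["cl"]
        cv = values.std() / values.mean() * 100
        assert abs(cv - 30.0) < 0.03 * 30.0

    def test_uncertain_cv_realized_per_draw(self):
        spec = BSVSpec(cv={"cl": UncertaintyDist("uniform", {"lower": 10, "upper": 50})})
        cvs = {spec.realize(rng(s)).cv_percent["cl"] for s in range(5)}
        assert len(cvs) > 1
        assert all(10 <= c <= 50 for c in cvs)

    def test_normal_scale_proportional(self):
        spec = BSVSpec(cv={"e0": 20.0}, scale={"e0": "normal"})
        realized = spec.realize(rng())
        etas = np.array([[-0.5], [0.0], [0.5]])
        values = realized.apply({"e0": 4.0}, etas)["e0"]
        assert values == pytest.approx([2.0, 4.0, 6.0])


@settings(max_examples=30, deadline=None)
@given(
    cv=st.floats(min_value=1.0, max_value=120.0),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_lognormal_cv_roundtrip_property(cv, seed):
    """Analytic CV of exp(N(0, sigma(cv)^2)) matches the requested CV."""
    sigma = cv_to_lognormal_sigma(cv)
    analytic_cv = np.sqrt(np.exp(sigma**2) - 1.0) * 100
    assert analytic_cv == pytest.approx(cv, rel=1e-9)
    x = np.random.default_rng(seed).lognormal(0.0, sigma, size=2000)
    assert (x > 0).all()
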