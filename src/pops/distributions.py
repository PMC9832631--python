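"""Uncertainty and variability distributions.

Two kinds of randomness enter a PoPS computation and both are represented
here:

* *uncertainty* — what is not known about a quantity that has a single true
  value: a fixed-effect parameter (typical clearance, potency), a translation
  factor (an unbound partition coefficient), a success-criterion threshold or
  its required proportion.  These are outer-loop priors, one draw per
  simulated trial (replicate).
* *between-subject variability* (BSV) — real differences among patients
  within one trial, expressed as random effects ``eta ~ N(0, Omega)`` applied
  multiplicatively (log-normal scale, the default for positive PK/PD
  parameters) or additively-proportionally (normal scale, for baselines that
  may change sign).

The supported prior families are the ones translational benefit-risk
assessments actually use: point mass, normal, log-normal, uniform (a stated
range with no preferred value), a beta distribution rescaled to an arbitrary
support and parameterised by its mode (an expert prior of the form "most
likely X, occasionally much more"), and a weighted categorical over a few
discrete candidate values (e.g. animal-species exposure limits weighted by
presumed human relevance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericError

__all__ = [
    "UncertaintyDist",
    "BSVSpec",
    "RealizedBSV",
    "ParameterDraw",
    "CorrelationSpec",
    "cv_to_lognormal_sigma",
    "scaled_beta",
    "weighted_categorical",
    "point",
    "draw_fixed_effects",
    "draw_subject_etas",
]

FAMILIES = ("point", "normal", "lognormal", "uniform", "scaled_beta", "weighted_categorical")


def cv_to_lognormal_sigma(cv_percent: float) -> float:
    """Log-scale SD of a log-normal with the given percent coefficient of variation.

    ``sigma = sqrt(ln(1 + (cv/100)^2))``; e.g. a 30% CV maps to 0.2936.
    """
    if cv_percent < 0:
        raise ValueError(f"CV% must be non-negative, got {cv_percent}")
    f = cv_percent / 100.0
    return math.sqrt(math.log1p(f * f))


def _scaled_beta_shapes(mode: float, lower: float, upper: float, concentration: float) -> tuple[float, float]:
    # mode on [0,1]; alpha+beta = concentration, density mode at m requires
    # m = (alpha-1)/(alpha+beta-2), hence alpha = m*(c-2)+1.
    m = (mode - lower) / (upper - lower)
    a = m * (concentration - 2.0) + 1.0
    b = (1.0 - m) * (concentration - 2.0) + 1.0
    return a, b


@dataclass(frozen=True)
class UncertaintyDist:
    """A prior/uncertainty distribution for a scalar quantity.

    Parameters are family-specific:

    ====================  =================================================
    family                params
    ====================  =================================================
    point                 value
    normal                mean, sd
    lognormal             mu, sigma (log scale) — or median, cv_percent
    uniform               lower, upper
    scaled_beta           mode, lower, upper, concentration (default 4)
    weighted_categorical  values, weights
    ====================  =================================================
    """

    family: str
    params: Mapping[str, object]
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; known: {', '.join(FAMILIES)}"
            )
        p = dict(self.params)
        if self.family == "point":
            self._require(p, "value")
        elif self.family == "normal":
            self._require(p, "mean", "sd")
            if p["sd"] < 0:
                raise ConfigurationError("normal sd must be >= 0")
        elif self.family == "lognormal":
            if "median" in p:
                if p["median"] <= 0:
                    raise ConfigurationError("lognormal median must be > 0")
                p["mu"] = math.log(p["median"])
                if "cv_percent" in p:
                    p["sigma"] = cv_to_lognormal_sigma(p["cv_percent"])
            self._require(p, "mu", "sigma")
            if p["sigma"] < 0:
                raise ConfigurationError("lognormal sigma must be >= 0")
            object.__setattr__(self, "params", p)
        elif self.family == "uniform":
            self._require(p, "lower", "upper")
            if not p["lower"] < p["upper"]:
                raise ConfigurationError(f"uniform requires lower < upper, got {p}")
        elif self.family == "scaled_beta":
            self._require(p, "mode", "lower", "upper")
            p.setdefault("concentration", 4.0)
            if not p["lower"] < p["upper"]:
                raise ConfigurationError("scaled_beta requires lower < upper")
            if not p["lower"] <= p["mode"] <= p["upper"]:
                raise ValueError(
                    f"scaled_beta mode {p['mode']} outside support [{p['lower']}, {p['upper']}]"
                )
            if p["concentration"] <= 2:
                raise ConfigurationError("scaled_beta concentration must be > 2")
            object.__setattr__(self, "params", p)
        elif self.family == "weighted_categorical":
            self._require(p, "values", "weights")
            values, weights = list(p["values"]), [float(w) for w in p["weights"]]
            if len(values) != len(weights):
                raise ConfigurationError("values and weights must have equal length")
            if any(w < 0 for w in weights):
                raise ValueError(f"weights must be non-negative, got {weights}")
            if sum(weights) <= 0:
                raise ConfigurationError("weights must sum to a positive number")
            object.__setattr__(self, "params", {"values": values, "weights": weights})

    @staticmethod
    def _require(p: Mapping[str, object], *keys: str) -> None:
        missing = [k for k in keys if k not in p]
        if missing:
            raise ConfigurationError(f"missing distribution parameter(s): {', '.join(missing)}")

    # -- sampling ---------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; scalar if ``size`` is None."""
        p = self.params
        if self.family == "point":
            v = p["value"]
            return v if size is None else np.full(size, v, dtype=float)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        if self.family == "uniform":
            return rng.uniform(p["lower"], p["upper"], size=size)
        if self.family == "scaled_beta":
            a, b = _scaled_beta_shapes(p["mode"], p["lower"], p["upper"], p["concentration"])
            return p["lower"] + (p["upper"] - p["lower"]) * rng.beta(a, b, size=size)
        # weighted_categorical
        w = np.asarray(p["weights"], dtype=float)
        idx = rng.choice(len(w), size=size, p=w / w.sum())
        values = np.asarray(p["values"], dtype=float)
        return float(values[idx]) if size is None else values[idx]

    def transform_standard_normal(self, z):
        """Map standard-normal draws to this marginal (normal/lognormal only).

        Used to impose a Gaussian dependence structure on correlated priors.
        """
        p = self.params
        if self.family == "normal":
            return p["mean"] + p["sd"] * z
        if self.family == "lognormal":
            return np.exp(p["mu"] + p["sigma"] * z)
        raise ConfigurationError(
            f"correlated draws require normal or lognormal marginals, got {self.family!r}"
        )

    def mean(self) -> float:
        """Analytic mean (not defined for weighted_categorical of non-numeric values)."""
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family == "normal":
            return float(p["mean"])
        if self.family == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)
        if self.family == "uniform":
            return (p["lower"] + p["upper"]) / 2.0
        if self.family == "scaled_beta":
            a, b = _scaled_beta_shapes(p["mode"], p["lower"], p["upper"], p["concentration"])
            return p["lower"] + (p["upper"] - p["lower"]) * a / (a + b)
        w = np.asarray(p["weights"], dtype=float)
        return float(np.average(np.asarray(p["values"], dtype=float), weights=w))

    def to_config(self) -> dict:
        """Serializable ``{family, params, units}`` echo (provenance header)."""
        return {"family": self.family, "params": dict(self.params), "units": self.units}


def point(value: float, units: str = "") -> UncertaintyDist:
    """A degenerate (point-mass) distribution: always returns ``value``."""
    return UncertaintyDist("point", {"value": value}, units)


def scaled_beta(
    mode: float, lower: float, upper: float, concentration: float = 4.0, units: str = ""
) -> UncertaintyDist:
    """Beta distribution rescaled to ``[lower, upper]`` with density mode at ``mode``.

    ``concentration`` (= alpha + beta, > 2) controls how sharply the density
    concentrates at the mode.  With the mode near the lower bound the density
    decreases monotonically toward the upper bound — the "most likely small,
    occasionally large" expert-prior shape.
    """
    return UncertaintyDist(
        "scaled_beta",
        {"mode": mode, "lower": lower, "upper": upper, "concentration": concentration},
        units,
    )


def weighted_categorical(
    values: Sequence[float], weights: Sequence[float], units: str = ""
) -> UncertaintyDist:
    """Discrete prior drawing ``values[k]`` with probability ``weights[k]/sum``."""
    return UncertaintyDist("weighted_categorical", {"values": list(values), "weights": list(weights)}, units)


# ---------------------------------------------------------------------------
# correlated fixed-effect priors


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation over a named subset of parameters (Gaussian dependence)."""

    parameters: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "parameters", tuple(self.parameters))
        k = len(self.parameters)
        if m.shape != (k, k):
            raise ConfigurationError(f"correlation matrix shape {m.shape} != ({k}, {k})")
        _validate_correlation(m)


def _validate_correlation(m: np.ndarray) -> None:
    if not np.allclose(m, m.T, atol=1e-12):
        raise ConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ConfigurationError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ConfigurationError("correlation matrix must be positive semidefinite")


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Square root L with L @ L.T = m, tolerating PSD-singular matrices."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def draw_fixed_effects(
    specs: Mapping[str, UncertaintyDist],
    correlation: CorrelationSpec | None = None,
    M: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw M outer replicates of the fixed-effect / translation parameters.

    Each column follows its marginal family.  Parameters named by
    ``correlation`` are drawn jointly through a Gaussian copula on the
    (log-)scale and must be normal or log-normal; the rest are independent.

    Draw order is pinned for reproducibility: one multivariate block for the
    correlated subset first, then the remaining parameters in ``specs``
    insertion order.
    """
    if M < 1:
        raise ConfigurationError(f"M must be >= 1, got {M}")
    if rng is None:
        raise ConfigurationError("a seeded numpy Generator is required")
    for name, dist in specs.items():
        if not isinstance(dist, UncertaintyDist):
            raise ConfigurationError(f"spec for {name!r} is not an UncertaintyDist")

    out: dict[str, np.ndarray] = {}
    corr_names: tuple[str, ...] = ()
    if correlation is not None:
        corr_names = correlation.parameters
        unknown = [n for n in corr_names if n not in specs]
        if unknown:
            raise ConfigurationError(f"correlation names not in specs: {unknown}")
        L = _psd_factor(correlation.matrix)
        z = rng.standard_normal((M, len(corr_names))) @ L.T
        for j, name in enumerate(corr_names):
            out[name] = specs[name].transform_standard_normal(z[:, j])
    for name, dist in specs.items():
        if name in corr_names:
            continue
        out[name] = np.asarray(dist.sample(rng, size=M), dtype=float)
    return pd.DataFrame(out, columns=list(specs))


def draw_subject_etas(omega: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """N multivariate-normal random-effect vectors, zero mean, covariance ``omega``."""
    if N < 1:
        raise ConfigurationError(f"N must be >= 1, got {N}")
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    k = omega.shape[0]
    if omega.shape != (k, k):
        raise NumericError(f"omega must be square, got shape {omega.shape}")
    if not np.allclose(omega, omega.T, atol=1e-12):
        raise NumericError(f"omega must be symmetric:\n{omega}")
    if np.linalg.eigvalsh(omega).min() < -1e-10:
        raise NumericError(f"omega is not positive semidefinite:\n{omega}")
    if not omega.any():
        return np.zeros((N, k))
    return rng.multivariate_normal(np.zeros(k), omega, size=N, check_valid="ignore", method="eigh")


# ---------------------------------------------------------------------------
# between-subject variability


@dataclass(frozen=True)
class BSVSpec:
    """Between-subject variability specification.

    ``cv`` maps parameter name to a percent CV — either a number or an
    UncertaintyDist when the magnitude of the variability is itself uncertain
    (an outer-loop draw).  ``scale`` selects, per parameter, how the random
    effect perturbs the typical value:

    * ``lognormal`` (default): subject value = typical * exp(eta); the CV maps
      to a log-scale SD of sqrt(ln(1+(cv/100)^2)) and the median is preserved.
    * ``normal``: subject value = typical * (1 + eta), eta SD = cv/100; for
      quantities that may legitimately cross zero.
    """

    cv: Mapping[str, object] = field(default_factory=dict)
    scale: Mapping[str, str] = field(default_factory=dict)
    correlation: CorrelationSpec | None = None

    def __post_init__(self) -> None:
        for name, s in self.scale.items():
            if s not in ("lognormal", "normal"):
                raise ConfigurationError(f"bsv scale for {name!r} must be lognormal or normal")
        for name, c in self.cv.items():
            if not isinstance(c, UncertaintyDist) and c < 0:
                raise ConfigurationError(f"bsv cv for {name!r} must be >= 0, got {c}")
        if self.correlation is not None:
            unknown = [n for n in self.correlation.parameters if n not in self.cv]
            if unknown:
                raise ConfigurationError(f"bsv correlation names without a cv entry: {unknown}")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.cv)

    def scale_of(self, name: str) -> str:
        return self.scale.get(name, "lognormal")

    def realize(self, rng: np.random.Generator) -> "RealizedBSV":
        """Resolve any uncertain CVs (one outer draw) into a concrete Omega."""
        cvs = {
            name: float(c.sample(rng)) if isinstance(c, UncertaintyDist) else float(c)
            for name, c in self.cv.items()
        }
        sds = np.array(
            [
                cv_to_lognormal_sigma(cvs[n]) if self.scale_of(n) == "lognormal" else cvs[n] / 100.0
                for n in self.parameters
            ]
        )
        k = len(sds)
        corr = np.eye(k)
        if self.correlation is not None:
            idx = {n: i for i, n in enumerate(self.parameters)}
            for a, na in enumerate(self.correlation.parameters):
                for b, nb in enumerate(self.correlation.parameters):
                    corr[idx[na], idx[nb]] = self.correlation.matrix[a, b]
        omega = np.outer(sds, sds) * corr
        return RealizedBSV(
            parameters=self.parameters,
            omega=omega,
            scales=tuple(self.scale_of(n) for n in self.parameters),
            cv_percent=cvs,
        )


@dataclass(frozen=True)
class RealizedBSV:
    """One outer replicate's concrete BSV covariance and how to apply it."""

    parameters: tuple[str, ...]
    omega: np.ndarray
    scales: tuple[str, ...]
    cv_percent: Mapping[str, float]

    def apply(self, theta: Mapping[str, float], etas: np.ndarray) -> dict[str, np.ndarray]:
        """Per-subject parameter arrays from typical values + random effects.

        Parameters without a BSV entry are broadcast as constants.
        """
        n = etas.shape[0] if etas.size else 1
        out: dict[str, np.ndarray] = {}
        for j, (name, scale) in enumerate(zip(self.parameters, self.scales)):
            tv = float(theta[name])
            if scale == "lognormal":
                out[name] = tv * np.exp(etas[:, j])
            else:
                out[name] = tv * (1.0 + etas[:, j])
        for name, tv in theta.items():
            if name not in out:
                out[name] = np.full(n, float(tv))
        return out


@dataclass(frozen=True)
class ParameterDraw:
    """Everything realized for one outer replicate: theta_i, Omega_i, (K_i, n_i)."""

    index: int
    theta: Mapping[str, float]
    bsv: RealizedBSV
    criteria: tuple  # of criteria.RealizedCriterion
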