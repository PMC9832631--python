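"""The nested Monte-Carlo PoPS estimator.

The estimator runs M outer replicates (virtual trials), each carrying one
joint draw of everything that is *uncertain* — fixed-effect and translation
parameters theta_i, the between-subject covariance Omega_i, and the success
criteria realizations (K_i, n_i) — and, inside each replicate, N subjects
whose endpoints are computed from theta_i perturbed by random effects
eta_j ~ N(0, Omega_i).  Each replicate's population is checked against its
criteria realization; PoPS at a dose is the fraction M'/M of replicates that
pass every criterion jointly.

Seeding discipline (pinned, so an independent re-implementation can match
bit for bit): replicate i draws its uncertainty quantities from
``default_rng(SeedSequence((seed, 0, i)))`` in the order fixed effects ->
BSV realization -> criteria realizations, and its subject random effects
from ``default_rng(SeedSequence((seed, 1, i)))``.  Under common random
numbers (the default) the same draws are reused across doses, so
PoPS-versus-dose differences reflect dose, not sampling noise; in
independent mode subject effects use ``SeedSequence((seed, 1, i, d))`` for
dose index d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import CriteriaSet, RealizedCriterion, criteria_pass, realize_criteria, subject_mask
from .distributions import (
    BSVSpec,
    CorrelationSpec,
    ParameterDraw,
    RealizedBSV,
    UncertaintyDist,
    draw_fixed_effects,
    draw_subject_etas,
)
from .errors import ConfigurationError, EngineError
from .pkpd import Regimen
from .structural import StructuralModel

__all__ = [
    "SimulationPlan",
    "EndpointModel",
    "PoPSCurve",
    "ScenarioResult",
    "simulate_population",
    "compute_pops",
    "proportion_bands",
    "scenario_analysis",
    "optimal_dose",
    "uncertainty_rng",
    "subject_rng",
]


def uncertainty_rng(seed: int, i: int) -> np.random.Generator:
    """Outer-replicate substream for fixed effects, BSV and criteria draws."""
    return np.random.default_rng(np.random.SeedSequence((seed, 0, i)))


def subject_rng(seed: int, i: int, dose_index: int | None = None) -> np.random.Generator:
    """Subject-level substream; dose-indexed when common random numbers are off."""
    key = (seed, 1, i) if dose_index is None else (seed, 1, i, dose_index)
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class SimulationPlan:
    """Trial-simulation sizes and the dose grid."""

    m: int
    n: int
    regimens: tuple[Regimen, ...]
    seed: int = 0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ConfigurationError(f"M and N must be >= 1, got M={self.m}, N={self.n}")
        object.__setattr__(self, "regimens", tuple(self.regimens))
        if not self.regimens:
            raise ConfigurationError("dose grid must be non-empty")
        doses = [r.dose for r in self.regimens]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ConfigurationError(f"doses must be strictly increasing, got {doses}")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(r.dose for r in self.regimens)


@dataclass(frozen=True)
class EndpointModel:
    """The function f: structural assembly + typical values + BSV + covariates.

    ``fixed`` holds typical values; names appearing in the uncertainty specs
    passed to :func:`compute_pops` are overwritten by each replicate's draw.
    ``covariates`` are optional per-subject draws appended to the parameter
    map before the structural assembly runs (extension point; no bundled
    assembly consumes them).
    """

    structural: StructuralModel
    fixed: Mapping[str, float]
    bsv: BSVSpec = field(default_factory=BSVSpec)
    covariates: Mapping[str, UncertaintyDist] = field(default_factory=dict)

    @property
    def endpoint_names(self) -> tuple[str, ...]:
        return self.structural.endpoint_names

    def validate_against(self, criteria: CriteriaSet) -> None:
        missing = [e for e in criteria.endpoints if e not in self.endpoint_names]
        if missing:
            raise ConfigurationError(
                f"criteria reference endpoint(s) {missing} not produced by model "
                f"{self.structural.name!r} (schema: {list(self.endpoint_names)})"
            )


def simulate_population(
    model: EndpointModel,
    theta: Mapping[str, float],
    omega: RealizedBSV,
    n: int,
    rng: np.random.Generator,
    regimen: Regimen,
) -> pd.DataFrame:
    """Simulate one virtual population of ``n`` subjects at one regimen.

    Subject j's parameters are the replicate's typical values perturbed by
    eta_j (log-normal scale: theta*exp(eta)); covariates, if any, are drawn
    next from their distributions.  Returns an n-row endpoint DataFrame.
    """
    etas = draw_subject_etas(omega.omega, n, rng) if omega.parameters else np.zeros((n, 0))
    params = omega.apply(theta, etas)
    for name, dist in model.covariates.items():
        params[name] = np.asarray(dist.sample(rng, size=n), dtype=float)
    endpoints = model.structural.endpoints(params, regimen)
    return pd.DataFrame(endpoints)


@dataclass(frozen=True)
class PoPSCurve:
    """PoPS and per-criterion diagnostics on a dose grid.

    ``fractions[c]`` holds the replicate-level subject proportions for
    criterion label c as an (M, n_doses) array; ``records`` is the tidy
    per-replicate diagnostic table.
    """

    doses: tuple[float, ...]
    pops: np.ndarray
    m: int
    n: int
    m_prime: np.ndarray
    pass_rate: pd.DataFrame  # doses x criterion labels
    fractions: Mapping[str, np.ndarray]
    records: pd.DataFrame
    metadata: Mapping[str, object]

    @property
    def criterion_labels(self) -> tuple[str, ...]:
        return tuple(self.pass_rate.columns)

    def bands(self, level: float = 90.0) -> pd.DataFrame:
        """Median and predictive band of subject proportions per dose/criterion."""
        rows = []
        for label, frac in self.fractions.items():
            for d, dose in enumerate(self.doses):
                med, lo, hi = proportion_bands(frac[:, d], level)
                rows.append(
                    {"dose": dose, "criterion": label, "median": med, "lo": lo, "hi": hi}
                )
        return pd.DataFrame(rows)

    def to_frame(self, level: float = 90.0) -> pd.DataFrame:
        """Wide per-dose summary: pops, per-criterion pass rates and bands."""
        out = pd.DataFrame({"dose": self.doses, "pops": self.pops})
        for label in self.criterion_labels:
            out[f"pass_rate_{label}"] = self.pass_rate[label].to_numpy()
            frac = self.fractions[label]
            med, lo, hi = zip(*(proportion_bands(frac[:, d], level) for d in range(len(self.doses))))
            out[f"prop_median_{label}"] = med
            out[f"prop_lo_{label}"] = lo
            out[f"prop_hi_{label}"] = hi
        return out


def proportion_bands(fractions: np.ndarray, level: float = 90.0) -> tuple[float, float, float]:
    """Median and central predictive interval of replicate-level proportions.

    Percentiles use linear interpolation between order statistics (the
    numpy default, Hyndman-Fan type 7).
    """
    fractions = np.asarray(fractions, dtype=float)
    half = (100.0 - level) / 2.0
    lo, med, hi = np.percentile(fractions, [half, 50.0, 100.0 - half])
    return float(med), float(lo), float(hi)


def compute_pops(
    plan: SimulationPlan,
    model: EndpointModel,
    criteria: CriteriaSet,
    specs: Mapping[str, UncertaintyDist] | None = None,
    correlation: CorrelationSpec | None = None,
) -> PoPSCurve:
    """Estimate PoPS = M'/M on the plan's dose grid.

    ``specs`` are the outer-loop uncertainty distributions for fixed-effect /
    translation parameters (names must be model parameters); parameters not
    named keep their typical values from the model.
    """
    specs = dict(specs or {})
    model.validate_against(criteria)
    unknown = [p for p in specs if p not in model.structural.param_names]
    if unknown:
        raise ConfigurationError(
            f"uncertainty specs name parameter(s) {unknown} unknown to model "
            f"{model.structural.name!r}"
        )

    labels = [c.label for c in criteria]
    n_doses = len(plan.regimens)
    passed = np.zeros((plan.m, n_doses), dtype=bool)
    fractions = {lab: np.zeros((plan.m, n_doses)) for lab in labels}
    crit_passed = {lab: np.zeros((plan.m, n_doses), dtype=bool) for lab in labels}
    rec_rows: list[dict] = []

    for i in range(plan.m):
        rng_u = uncertainty_rng(plan.seed, i)
        theta = dict(model.fixed)
        if specs:
            draw = draw_fixed_effects(specs, correlation, M=1, rng=rng_u)
            theta.update({k: float(draw[k].iloc[0]) for k in draw.columns})
        omega = model.bsv.realize(rng_u)
        realized = realize_criteria(criteria, rng_u)

        if plan.common_random_numbers:
            rng_s = subject_rng(plan.seed, i)
            etas = draw_subject_etas(omega.omega, plan.n, rng_s) if omega.parameters else np.zeros((plan.n, 0))
            cov = {
                name: np.asarray(dist.sample(rng_s, size=plan.n), dtype=float)
                for name, dist in model.covariates.items()
            }
        for d, regimen in enumerate(plan.regimens):
            if not plan.common_random_numbers:
                rng_s = subject_rng(plan.seed, i, d)
                etas = draw_subject_etas(omega.omega, plan.n, rng_s) if omega.parameters else np.zeros((plan.n, 0))
                cov = {
                    name: np.asarray(dist.sample(rng_s, size=plan.n), dtype=float)
                    for name, dist in model.covariates.items()
                }
            params = omega.apply(theta, etas)
            params.update(cov)
            try:
                endpoints = model.structural.endpoints(params, regimen)
            except Exception as exc:  # noqa: BLE001 - re-raised with context, run aborts
                raise EngineError(
                    f"structural model failed at replicate {i}, dose {regimen.dose}: {exc}"
                ) from exc
            ok, records = criteria_pass(realized, endpoints)
            passed[i, d] = ok
            for rec in records:
                fractions[rec["criterion"]][i, d] = rec["fraction"]
                crit_passed[rec["criterion"]][i, d] = rec["passed"]
                rec_rows.append({"replicate": i, "dose": regimen.dose, **rec})

    m_prime = passed.sum(axis=0)
    pass_rate = pd.DataFrame(
        {lab: crit_passed[lab].mean(axis=0) for lab in labels}, index=list(plan.doses)
    )
    records = pd.DataFrame(rec_rows)
    records["thresholds"] = records["thresholds"].map(lambda t: ";".join(repr(x) for x in t))
    return PoPSCurve(
        doses=plan.doses,
        pops=m_prime / plan.m,
        m=plan.m,
        n=plan.n,
        m_prime=m_prime,
        pass_rate=pass_rate,
        fractions=fractions,
        records=records,
        metadata={
            "seed": plan.seed,
            "m": plan.m,
            "n": plan.n,
            "common_random_numbers": plan.common_random_numbers,
            "model": model.structural.name,
        },
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Full-factorial scenario sweep: one PoPS curve per cell."""

    axes: Mapping[str, tuple[str, ...]]
    cells: Mapping[tuple[str, ...], PoPSCurve]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, curve in self.cells.items():
            base = dict(zip(self.axes, key))
            frame = curve.to_frame()
            for col, val in base.items():
                frame.insert(0, col, val)
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def scenario_analysis(config, axes: Mapping[str, Mapping[str, Mapping[str, object]]]) -> ScenarioResult:
    """Run compute_pops over the full factorial of configuration overrides.

    ``axes`` maps axis name -> level name -> {dotted config path: value}.
    Every cell shares the base config's master seed, so with common random
    numbers differences between cells reflect the assumptions, not noise.
    """
    from itertools import product

    from .assemble import apply_overrides, run_config  # local import: avoids cycle

    if not axes:
        raise ConfigurationError("scenario analysis needs at least one axis")
    names = list(axes)
    levels = [list(axes[a]) for a in names]
    cells: dict[tuple[str, ...], PoPSCurve] = {}
    for combo in product(*levels):
        overrides: dict[str, object] = {}
        for axis, level in zip(names, combo):
            overrides.update(axes[axis][level])
        cells[tuple(combo)] = run_config(apply_overrides(config, overrides))
    return ScenarioResult(axes={a: tuple(axes[a]) for a in names}, cells=cells)


def optimal_dose(curve: PoPSCurve) -> tuple[float, float]:
    """Dose attaining the maximal PoPS; ties broken toward the lowest dose."""
    idx = int(np.argmax(curve.pops))
    return curve.doses[idx], float(curve.pops[idx])
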