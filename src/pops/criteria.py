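"""Success criteria: thresholded subject proportions for benefit and risk.

A criterion asks whether a simulated endpoint satisfies a comparison against
a threshold K in a required proportion n of subjects.  Both K and n may be
uncertain, in which case one realization is drawn per outer replicate (per
virtual trial).  A criterion may combine several per-subject conditions
(a *derived* endpoint): the subject counts toward the proportion only when
every condition holds — e.g. "central target activity normalised AND at
least 10% peripheral activity preserved".

Benefit criteria pass when the achieving proportion reaches n (inclusive by
default); risk criteria count the *violating* proportion and pass when it
stays strictly below the allowance.  Both boundaries are configurable per
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .distributions import UncertaintyDist, point
from .errors import ConfigurationError

__all__ = [
    "Condition",
    "Criterion",
    "CriteriaSet",
    "RealizedCriterion",
    "realize_criteria",
    "proportion_meeting",
    "criterion_pass",
    "criteria_pass",
]

_COMPARATORS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


def _as_dist(x) -> UncertaintyDist:
    return x if isinstance(x, UncertaintyDist) else point(float(x))


@dataclass(frozen=True)
class Condition:
    """One per-subject comparison: endpoint <comparator> threshold.

    ``transform`` maps the realized threshold draw onto the endpoint's scale
    (e.g. a fold-elevation prior mapped to a required inhibition fraction).
    """

    endpoint: str
    comparator: str
    threshold: UncertaintyDist
    transform: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ConfigurationError(
                f"unknown comparator {self.comparator!r}; known: {list(_COMPARATORS)}"
            )
        object.__setattr__(self, "threshold", _as_dist(self.threshold))


@dataclass(frozen=True)
class Criterion:
    """A benefit or risk criterion over one or more per-subject conditions."""

    label: str
    kind: Literal["benefit", "risk"]
    conditions: tuple[Condition, ...]
    required_proportion: UncertaintyDist
    proportion_inclusive: bool | None = None  # default: benefit >=, risk <

    def __post_init__(self) -> None:
        if self.kind not in ("benefit", "risk"):
            raise ConfigurationError(f"criterion kind must be benefit or risk, got {self.kind!r}")
        if not self.conditions:
            raise ConfigurationError(f"criterion {self.label!r} has no conditions")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "required_proportion", _as_dist(self.required_proportion))

    @property
    def inclusive(self) -> bool:
        if self.proportion_inclusive is not None:
            return self.proportion_inclusive
        return self.kind == "benefit"

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(c.endpoint for c in self.conditions)


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered criteria combined by conjunction: every criterion must pass."""

    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if not self.criteria:
            raise ConfigurationError("at least one criterion is required")
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"criterion labels must be unique, got {labels}")

    def __iter__(self):
        return iter(self.criteria)

    @property
    def endpoints(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.criteria:
            for e in c.endpoints:
                if e not in seen:
                    seen.append(e)
        return tuple(seen)


@dataclass(frozen=True)
class RealizedCriterion:
    """One outer replicate's concrete (K_i, n_i) for a criterion."""

    criterion: Criterion
    thresholds: tuple[float, ...]  # per condition, after transform
    raw_thresholds: tuple[float, ...]  # the draws before transform
    n: float

    @property
    def label(self) -> str:
        return self.criterion.label


def realize_criteria(cset: CriteriaSet, rng: np.random.Generator) -> list[RealizedCriterion]:
    """Draw one (K_i, n_i) realization per criterion.

    Draw order is pinned: criteria in set order; within a criterion each
    condition's threshold in order, then the required proportion.
    """
    out: list[RealizedCriterion] = []
    for crit in cset:
        raw, mapped = [], []
        for cond in crit.conditions:
            k = float(cond.threshold.sample(rng))
            raw.append(k)
            mapped.append(float(cond.transform(k)) if cond.transform is not None else k)
        n = float(crit.required_proportion.sample(rng))
        if not 0.0 <= n <= 1.0:
            raise ConfigurationError(
                f"required proportion for {crit.label!r} must be a fraction in [0,1], got {n}"
            )
        out.append(RealizedCriterion(crit, tuple(mapped), tuple(raw), n))
    return out


def proportion_meeting(values: np.ndarray, comparator: str, K: float) -> float:
    """Fraction of subjects whose endpoint satisfies ``value <comparator> K``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty population")
    if comparator not in _COMPARATORS:
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    return float(np.mean(_COMPARATORS[comparator](values, K)))


def criterion_pass(fraction: float, n: float, kind: str, inclusive: bool | None = None) -> bool:
    """Whether a criterion passes given the achieved/violating fraction.

    Benefit: fraction achieving must reach n (``>=`` by default).
    Risk: fraction violating must stay below the allowance (``<`` by default).
    """
    if not 0.0 <= fraction <= 1.0 or not 0.0 <= n <= 1.0:
        raise ValueError("fraction and n must lie in [0, 1]")
    if kind == "benefit":
        inc = True if inclusive is None else inclusive
        return fraction >= n if inc else fraction > n
    if kind == "risk":
        inc = False if inclusive is None else inclusive
        return fraction <= n if inc else fraction < n
    raise ConfigurationError(f"kind must be benefit or risk, got {kind!r}")


def subject_mask(realized: RealizedCriterion, endpoints: Mapping[str, np.ndarray]) -> np.ndarray:
    """Boolean per-subject vector: all of the criterion's conditions hold."""
    mask: np.ndarray | None = None
    for cond, k in zip(realized.criterion.conditions, realized.thresholds):
        if cond.endpoint not in endpoints:
            raise ConfigurationError(
                f"criterion {realized.label!r} references endpoint {cond.endpoint!r} "
                f"not in the model output schema {sorted(endpoints)}"
            )
        hit = _COMPARATORS[cond.comparator](np.asarray(endpoints[cond.endpoint], dtype=float), k)
        mask = hit if mask is None else (mask & hit)
    return mask


def criteria_pass(
    realizations: Sequence[RealizedCriterion], endpoints: Mapping[str, np.ndarray]
) -> tuple[bool, list[dict]]:
    """Evaluate every realized criterion on one simulated population.

    Returns the conjunction and a per-criterion diagnostic record retaining
    the achieved fraction and the realized (K_i, n_i).
    """
    overall = True
    records: list[dict] = []
    for rc in realizations:
        frac = float(np.mean(subject_mask(rc, endpoints)))
        ok = criterion_pass(frac, rc.n, rc.criterion.kind, rc.criterion.proportion_inclusive)
        overall = overall and ok
        records.append(
            {
                "criterion": rc.label,
                "kind": rc.criterion.kind,
                "thresholds": rc.thresholds,
                "n": rc.n,
                "fraction": frac,
                "passed": ok,
            }
        )
    return overall, records
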