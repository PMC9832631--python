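"""Structural PK and PKPD models.

Exposure models (one-compartment oral/IV, two-compartment, target-mediated
drug disposition), exposure-response models (Emax/Imax, turnover a.k.a.
indirect response with an optional transit chain), and the translation
transforms (plasma protein binding, unbound brain partition kp,uu,
plasma-to-tissue distribution, allometric scaling) that carry an animal or
in-vitro model into a human population simulation.

Where a closed form exists (steady-state average concentration, turnover
steady states, Emax inversion) it is used directly; time-course endpoints are
integrated with a stiff-capable solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, NumericError

__all__ = [
    "Regimen",
    "OneCompOralParams",
    "EmaxParams",
    "PartitionParams",
    "TurnoverParams",
    "TMDDParams",
    "AllometricSpec",
    "css_average",
    "conc_profile_onecomp",
    "site_free_concentration",
    "emax_effect",
    "emax_inverse",
    "required_central_inhibition",
    "turnover_profile",
    "turnover_steady_state",
    "tmdd_profile",
    "allometric_scale",
    "auc_interval",
]

RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class Regimen:
    """A repeated-dose regimen: ``dose`` every ``tau`` hours, ``n_doses`` times.

    Oral doses fold relative bioavailability into the apparent parameters
    (CL/F, V/F), the usual convention when F is not separately identifiable.
    """

    dose: float
    tau: float = 24.0
    route: Literal["oral", "iv_bolus"] = "oral"
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ConfigurationError(f"dose must be >= 0, got {self.dose}")
        if self.tau <= 0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")
        if self.n_doses < 1:
            raise ConfigurationError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.route not in ("oral", "iv_bolus"):
            raise ConfigurationError(f"route must be 'oral' or 'iv_bolus', got {self.route!r}")


@dataclass(frozen=True)
class OneCompOralParams:
    """One-compartment model with first-order absorption and elimination."""

    cl_f: float
    v_f: float
    ka: float

    def __post_init__(self) -> None:
        if min(self.cl_f, self.v_f, self.ka) <= 0:
            raise ConfigurationError(f"one-compartment parameters must be > 0: {self}")

    @property
    def ke(self) -> float:
        return self.cl_f / self.v_f


@dataclass(frozen=True)
class EmaxParams:
    """Saturable concentration-response: E = Emax * C^h / (EC50^h + C^h) + E0."""

    emax: float
    ec50: float
    e0: float = 0.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.emax < 0:
            raise ConfigurationError(f"Emax must be >= 0, got {self.emax}")
        if self.ec50 <= 0:
            raise ConfigurationError(f"EC50 must be > 0, got {self.ec50}")
        if self.hill <= 0:
            raise ConfigurationError(f"hill must be > 0, got {self.hill}")


@dataclass(frozen=True)
class PartitionParams:
    """Protein-binding and tissue-partition translation factors."""

    fu: float = 1.0
    kp_uu: float | None = None
    kp_tissue: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fu <= 1.0:
            raise ConfigurationError(f"fu must be in (0, 1], got {self.fu}")
        if self.kp_uu is not None and self.kp_uu <= 0:
            raise ConfigurationError(f"kp_uu must be > 0, got {self.kp_uu}")
        if self.kp_tissue is not None and self.kp_tissue <= 0:
            raise ConfigurationError(f"kp_tissue must be > 0, got {self.kp_tissue}")


TurnoverMode = Literal[
    "inhibit-production", "stimulate-production", "inhibit-loss", "stimulate-loss"
]


@dataclass(frozen=True)
class TurnoverParams:
    """Indirect-response (turnover) model, optionally with a transit chain.

    Baseline response R0 = kin/kout.  The drug modulates production or loss
    through an Emax/Imax term; ``n_transit`` extra compartments (rate kout)
    delay the observed signal, the structure used for transduction models
    that map an ex-vivo concentration-response onto an in-vivo time course.
    """

    kin: float
    kout: float
    mode: TurnoverMode
    drug: EmaxParams
    n_transit: int = 0

    def __post_init__(self) -> None:
        if self.kin <= 0 or self.kout <= 0:
            raise ConfigurationError(f"kin and kout must be > 0: {self}")
        if self.mode not in ("inhibit-production", "stimulate-production", "inhibit-loss", "stimulate-loss"):
            raise ConfigurationError(f"unknown turnover mode {self.mode!r}")
        if self.n_transit < 0:
            raise ConfigurationError("n_transit must be >= 0")

    @property
    def r0(self) -> float:
        return self.kin / self.kout


@dataclass(frozen=True)
class TMDDParams:
    """Target-mediated drug disposition on a two-compartment PK backbone.

    Binding is given either as (kon, koff) for the full model or as the
    quasi-steady-state constant KSS for the reduced model.  Baseline target
    R0 = ksyn/kdeg.
    """

    cl: float
    v1: float
    q: float
    v2: float
    ksyn: float
    kdeg: float
    kint: float
    kon: float | None = None
    koff: float | None = None
    kss: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2", "kdeg", "kint"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"TMDD parameter {name} must be > 0")
        if self.ksyn < 0:
            raise ConfigurationError("ksyn must be >= 0")
        full = self.kon is not None and self.koff is not None
        if not full and self.kss is None:
            raise ConfigurationError("give (kon, koff) for the full model or kss for the QSS model")

    @property
    def r0(self) -> float:
        return self.ksyn / self.kdeg


@dataclass(frozen=True)
class AllometricSpec:
    """Allometric scaling convention: value * (weight ratio)^exponent."""

    reference_weight: float = 70.0
    exponents: Mapping[str, float] = field(
        default_factory=lambda: {"clearance-like": 0.75, "volume-like": 1.0}
    )
    baseline_scaling: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_weight <= 0:
            raise ConfigurationError("reference weight must be > 0")


# ---------------------------------------------------------------------------
# exposure


def css_average(regimen: Regimen, cl_over_f: float) -> float:
    """Average steady-state total concentration: dose / (CL/F * tau)."""
    if cl_over_f <= 0:
        raise ConfigurationError(f"clearance must be > 0, got {cl_over_f}")
    return regimen.dose / (cl_over_f * regimen.tau)


def _onecomp_single_dose(p: OneCompOralParams, dose: float, route: str, t: np.ndarray) -> np.ndarray:
    """Concentration after one dose at t=0 (t may include negatives: zero there)."""
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    pos = t >= 0
    s = t[pos]
    ke = p.ke
    if route == "iv_bolus":
        c[pos] = dose / p.v_f * np.exp(-ke * s)
        return c
    ka = p.ka
    if math.isclose(ka, ke, rel_tol=1e-9):
        # equal-rates limit of the Bateman function
        c[pos] = dose / p.v_f * ka * s * np.exp(-ka * s)
    else:
        c[pos] = dose * ka / (p.v_f * (ka - ke)) * (np.exp(-ke * s) - np.exp(-ka * s))
    return c


def conc_profile_onecomp(p: OneCompOralParams, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Analytic multiple-dose concentration profile by superposition."""
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < 0:
        raise ConfigurationError("times must be non-negative")
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ConfigurationError("times must be non-decreasing")
    c = np.zeros_like(times)
    for k in range(regimen.n_doses):
        c += _onecomp_single_dose(p, regimen.dose, regimen.route, times - k * regimen.tau)
    return c


def site_free_concentration(
    c_plasma_total, partition: PartitionParams, site: Literal["plasma", "brain", "tissue"]
):
    """Translate total plasma concentration to the pharmacologically active site.

    plasma -> total*fu (free); brain -> total*fu*kp_uu (free at target);
    tissue -> total*Kp_tissue (tissue distribution coefficient applied to
    the plasma concentration).
    """
    c = np.asarray(c_plasma_total, dtype=float)
    if np.any(c < 0):
        raise ConfigurationError("concentrations must be >= 0")
    if site == "plasma":
        out = c * partition.fu
    elif site == "brain":
        if partition.kp_uu is None:
            raise ConfigurationError("site 'brain' requires kp_uu in PartitionParams")
        out = c * partition.fu * partition.kp_uu
    elif site == "tissue":
        if partition.kp_tissue is None:
            raise ConfigurationError("site 'tissue' requires kp_tissue in PartitionParams")
        out = c * partition.kp_tissue
    else:
        raise ConfigurationError(f"unknown site {site!r}")
    return float(out) if np.isscalar(c_plasma_total) else out


# ---------------------------------------------------------------------------
# response


def emax_effect(c, p: EmaxParams):
    """Emax model effect (above baseline E0 is *not* added; see EmaxParams doc)."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, p.hill)
    out = p.emax * ch / (p.ec50**p.hill + ch)
    return float(out) if out.ndim == 0 else out


def emax_inverse(effect, p: EmaxParams):
    """Concentration producing the given effect; inverse of :func:`emax_effect`."""
    e = np.asarray(effect, dtype=float)
    if np.any(e < 0) or np.any(e >= p.emax):
        raise ValueError(f"effect must be in [0, Emax={p.emax}), got {effect}")
    out = p.ec50 * np.power(e / (p.emax - e), 1.0 / p.hill)
    return float(out) if out.ndim == 0 else out


def required_central_inhibition(fold_elevation):
    """Inhibition needed to bring a fold-elevated target activity back to normal.

    With disease activity at ``fold`` times normal, inhibition I normalises it
    when fold*(1-I) <= 1, i.e. I >= 1 - 1/fold.
    """
    f = np.asarray(fold_elevation, dtype=float)
    if np.any(f < 1):
        raise ValueError(f"fold elevation must be >= 1, got {fold_elevation}")
    out = 1.0 - 1.0 / f
    return float(out) if out.ndim == 0 else out


def turnover_steady_state(p: TurnoverParams, c: float) -> float:
    """Analytic steady-state response at constant concentration ``c``."""
    e = emax_effect(c, p.drug)
    r0 = p.r0
    if p.mode == "inhibit-production":
        return r0 * (1.0 - e)
    if p.mode == "stimulate-production":
        return r0 * (1.0 + e)
    if p.mode == "inhibit-loss":
        return r0 / (1.0 - e)
    return r0 / (1.0 + e)


def turnover_profile(
    p: TurnoverParams, conc_at: Callable[[float], float], times: np.ndarray
) -> np.ndarray:
    """Response time course of the turnover model driven by ``conc_at(t)``.

    Initial condition is the baseline R0 propagated through every transit
    step, so with zero drug the response stays flat at kin/kout.
    """
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ConfigurationError("times must be strictly increasing")

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        e = emax_effect(max(conc_at(t), 0.0), p.drug)
        kin, kout = p.kin, p.kout
        if p.mode == "inhibit-production":
            kin = kin * (1.0 - e)
        elif p.mode == "stimulate-production":
            kin = kin * (1.0 + e)
        elif p.mode == "inhibit-loss":
            kout = kout * (1.0 - e)
        else:
            kout = kout * (1.0 + e)
        dy = np.empty_like(y)
        dy[0] = kin - kout * y[0]
        # transit chain at the baseline turnover rate
        for i in range(1, y.size):
            dy[i] = p.kout * (y[i - 1] - y[i])
        return dy

    y0 = np.full(1 + p.n_transit, p.r0)
    t0, t1 = float(times[0]), float(times[-1])
    if t0 == t1:
        return np.full(times.shape, p.r0)
    sol = solve_ivp(rhs, (t0, t1), y0, t_eval=times, method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise NumericError(f"turnover ODE solver failed ({sol.message}); params: {p}")
    return sol.y[-1]


# ---------------------------------------------------------------------------
# TMDD


def _tmdd_rhs_full(p: TMDDParams):
    kon, koff = p.kon, p.koff

    def rhs(t, y):
        a1, a2, r, cplx, elim, internal = y
        c = a1 / p.v1
        dist = p.q * (c - a2 / p.v2)
        bind = kon * c * r - koff * cplx
        da1 = -p.cl * c - dist - bind * p.v1
        da2 = dist
        dr = p.ksyn - p.kdeg * r - bind
        dcplx = bind - p.kint * cplx
        return [da1, da2, dr, dcplx, p.cl * c, p.kint * cplx * p.v1]

    return rhs


def _tmdd_rhs_qss(p: TMDDParams):
    kss = p.kss

    def rhs(t, y):
        ctot, a2, rtot = y[0], y[1], y[2]
        # free drug from the QSS quadratic
        b = ctot - rtot - kss
        c_free = 0.5 * (b + math.sqrt(b * b + 4.0 * kss * ctot))
        bound = rtot * c_free / (kss + c_free)
        dist = p.q * (c_free - a2 / p.v2)
        dctot = -(p.cl / p.v1) * c_free - dist / p.v1 - p.kint * bound
        da2 = dist
        drtot = p.ksyn - p.kdeg * rtot - (p.kint - p.kdeg) * bound
        return [dctot, da2, drtot, p.cl * c_free, p.kint * bound * p.v1]

    return rhs


def tmdd_profile(p: TMDDParams, regimen: Regimen, times: np.ndarray) -> dict[str, np.ndarray]:
    """Simulate TMDD states over ``times`` for an IV-bolus regimen.

    Returns free drug, free target, complex (all central concentrations),
    target occupancy = complex/(free target + complex), and bookkeeping
    amounts ``eliminated`` and ``internalized`` for mass-balance audits.
    """
    if regimen.route != "iv_bolus":
        raise ConfigurationError("tmdd_profile supports iv_bolus regimens")
    times = np.asarray(times, dtype=float)
    if times.size < 1 or np.any(np.diff(times) <= 0) or times.min() < 0:
        raise ConfigurationError("times must be non-negative and strictly increasing")

    full = p.kon is not None and p.koff is not None
    rhs = _tmdd_rhs_full(p) if full else _tmdd_rhs_qss(p)
    if full:
        y = np.array([0.0, 0.0, p.r0, 0.0, 0.0, 0.0])
    else:
        y = np.array([0.0, 0.0, p.r0, 0.0, 0.0])

    dose_times = [k * regimen.tau for k in range(regimen.n_doses)]
    out = np.empty((y.size, times.size))
    filled = 0
    segments = dose_times + [max(float(times[-1]), dose_times[-1]) + 1e-9]
    for k, t_start in enumerate(dose_times):
        y[0] += regimen.dose / p.v1 if not full else regimen.dose  # Ctot (conc) vs A1 (amount)
        t_end = segments[k + 1]
        last = k == len(dose_times) - 1
        mask = (times >= t_start) & ((times <= t_end) if last else (times < t_end))
        t_eval = times[mask]
        sol = solve_ivp(
            rhs, (t_start, t_end), y, t_eval=t_eval if t_eval.size else None,
            method="BDF", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise NumericError(
                f"TMDD ODE solver failed ({sol.message}); consider looser tolerances; params: {p}"
            )
        if t_eval.size:
            out[:, filled : filled + t_eval.size] = sol.y
            filled += t_eval.size
        y = sol.y[:, -1] if sol.y.shape[1] else y

    if full:
        a1, a2, r, cplx, elim, internal = out
        c_free = a1 / p.v1
        occupancy = np.divide(cplx, r + cplx, out=np.zeros_like(cplx), where=(r + cplx) > 0)
        return {
            "time": times, "free_drug": c_free, "free_target": r, "complex": cplx,
            "occupancy": occupancy, "peripheral_amount": a2,
            "eliminated": elim, "internalized": internal,
        }
    ctot, a2, rtot, elim, internal = out
    b = ctot - rtot - p.kss
    c_free = 0.5 * (b + np.sqrt(b * b + 4.0 * p.kss * ctot))
    bound = rtot * c_free / (p.kss + c_free)
    r_free = rtot - bound
    occupancy = np.divide(bound, rtot, out=np.zeros_like(bound), where=rtot > 0)
    return {
        "time": times, "free_drug": c_free, "free_target": r_free, "complex": bound,
        "occupancy": occupancy, "peripheral_amount": a2,
        "eliminated": elim, "internalized": internal,
    }


# ---------------------------------------------------------------------------
# translation & summaries


def allometric_scale(
    value: float,
    kind: str,
    from_weight: float,
    to_weight: float,
    spec: AllometricSpec | None = None,
) -> float:
    """Scale a parameter across body weight: value * (to/from)^exponent."""
    spec = spec or AllometricSpec()
    if from_weight <= 0 or to_weight <= 0:
        raise ConfigurationError("body weights must be > 0")
    if kind not in spec.exponents:
        raise ConfigurationError(f"unknown parameter kind {kind!r}; known: {list(spec.exponents)}")
    return value * (to_weight / from_weight) ** spec.exponents[kind]


def auc_interval(times: np.ndarray, conc: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal area under the concentration curve on [t0, t1]."""
    if t1 <= t0:
        raise ValueError(f"t1 must exceed t0, got [{t0}, {t1}]")
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(f"[{t0}, {t1}] outside the grid span [{times[0]}, {times[-1]}]")
    grid = np.unique(np.concatenate([times[(times >= t0) & (times <= t1)], [t0, t1]]))
    vals = np.interp(grid, times, conc)
    return float(np.trapezoid(vals, grid))
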