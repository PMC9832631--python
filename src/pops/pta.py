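"""Probability-of-target-attainment workflow for anti-infectives.

The anti-infective route to a success probability differs from the nested
uncertainty simulation: the efficacy driver is a PKPD index — AUC:MIC,
Cmax:MIC or the fraction of the dosing interval with concentration above the
MIC — whose population distribution is built by randomly pairing simulated
patient PK with minimum-inhibitory-concentration (MIC) draws from a fitted
pathogen distribution.  A candidate drug's index distribution is then
compared with that of an in-class benchmark known to be efficacious: the
overlap of the two distributions, and the probability of reaching the
benchmark's target index level, quantify the candidate's prospects.

MIC population distributions are represented either as a logistic CDF on the
log2 (doubling-dilution) scale — the conventional fit to published cumulative
frequency tables — or as a log-normal on the natural-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from .errors import ConfigurationError

__all__ = [
    "MICDistribution",
    "IndexSample",
    "fit_mic_logistic",
    "sample_mic",
    "index_distribution",
    "attainment_vs_benchmark",
    "overlap_coefficient",
]

OVERLAP_BINS = 64  # shared log-scale histogram grid; pinned for reproducibility


@dataclass(frozen=True)
class MICDistribution:
    """A fitted MIC population distribution.

    ``logistic``: CDF(mic) = expit(slope * (log2(mic) - log2(midpoint)));
    ``lognormal``: ln(MIC) ~ N(mu, sigma^2).
    """

    form: Literal["logistic", "lognormal"]
    params: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        p = dict(self.params)
        if self.form == "logistic":
            if "midpoint" not in p or "slope" not in p:
                raise ConfigurationError("logistic MIC distribution needs midpoint and slope")
            if p["midpoint"] <= 0 or p["slope"] <= 0:
                raise ConfigurationError(f"midpoint and slope must be > 0, got {p}")
        elif self.form == "lognormal":
            if "mu" not in p or "sigma" not in p:
                raise ConfigurationError("lognormal MIC distribution needs mu and sigma")
            if p["sigma"] <= 0:
                raise ConfigurationError(f"sigma must be > 0, got {p}")
        else:
            raise ConfigurationError(f"unknown MIC distribution form {self.form!r}")

    def cdf(self, mic) -> np.ndarray:
        mic = np.asarray(mic, dtype=float)
        if self.form == "logistic":
            x = np.log2(mic) - math.log2(self.params["midpoint"])
            return expit(self.params["slope"] * x)
        z = (np.log(mic) - self.params["mu"]) / self.params["sigma"]
        from scipy.stats import norm

        return norm.cdf(z)

    def ppf(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.form == "logistic":
            return np.exp2(math.log2(self.params["midpoint"]) + logit(u) / self.params["slope"])
        from scipy.stats import norm

        return np.exp(self.params["mu"] + self.params["sigma"] * norm.ppf(u))


@dataclass(frozen=True)
class IndexSample:
    """Draws of a PKPD index with provenance."""

    kind: Literal["auc_mic", "cmax_mic", "t_above_mic"]
    values: np.ndarray
    provenance: Mapping[str, object]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ConfigurationError("IndexSample needs at least one value")
        if self.kind in ("auc_mic", "cmax_mic") and np.any(v <= 0):
            raise ConfigurationError(f"{self.kind} values must be positive")
        if self.kind == "t_above_mic" and (np.any(v < 0) or np.any(v > 1)):
            raise ConfigurationError("t_above_mic values must lie in [0, 1]")


def fit_mic_logistic(mic_levels: np.ndarray, cumulative_fractions: np.ndarray) -> MICDistribution:
    """Least-squares logistic CDF fit on the log2(MIC) scale.

    ``mic_levels`` are the (strictly increasing, typically doubling-dilution)
    concentrations and ``cumulative_fractions`` the observed cumulative
    frequency of isolates with MIC at or below each level.
    """
    mic = np.asarray(mic_levels, dtype=float)
    frac = np.asarray(cumulative_fractions, dtype=float)
    if mic.size != frac.size or mic.size < 3:
        raise ValueError("need >= 3 matched (mic, cumulative fraction) points")
    if np.any(mic <= 0) or np.any(np.diff(mic) <= 0):
        raise ValueError("MIC levels must be positive and strictly increasing")
    if np.any(np.diff(frac) < 0):
        raise ValueError("cumulative fractions must be non-decreasing")
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("cumulative fractions must lie in [0, 1]")
    if frac.max() == 0.0 or frac.min() == 1.0:
        raise ValueError("degenerate cumulative data (all 0 or all 1)")

    x = np.log2(mic)

    def model(x, mid_log2, slope):
        return expit(slope * (x - mid_log2))

    # start at the empirical median dilution with unit slope
    mid0 = float(np.interp(0.5, frac, x)) if frac.min() < 0.5 < frac.max() else float(np.median(x))
    import warnings

    from scipy.optimize import OptimizeWarning

    with warnings.catch_warnings():
        # a perfect fit makes the parameter covariance singular; we only need popt
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, x, frac, p0=[mid0, 1.0], maxfev=10000)
    mid_log2, slope = popt
    if slope <= 0:
        raise ValueError(f"fitted slope must be positive, got {slope}")
    return MICDistribution("logistic", {"midpoint": 2.0**mid_log2, "slope": float(slope)})


def sample_mic(dist: MICDistribution, N: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. MIC draws by inverse-CDF sampling (always strictly positive)."""
    if N < 1:
        raise ConfigurationError(f"N must be >= 1, got {N}")
    u = rng.uniform(0.0, 1.0, size=N)
    # guard the open interval for logit
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return np.asarray(dist.ppf(u), dtype=float)


def round_to_doubling_dilution(mic: np.ndarray) -> np.ndarray:
    """Quantize MICs to the nearest doubling dilution (2^k grid)."""
    return np.exp2(np.round(np.log2(np.asarray(mic, dtype=float))))


def index_distribution(
    pk_samples,
    mic_samples: np.ndarray,
    kind: Literal["auc_mic", "cmax_mic", "t_above_mic"] = "auc_mic",
    rng: np.random.Generator | None = None,
    tau: float | None = None,
    provenance: Mapping[str, object] | None = None,
) -> IndexSample:
    """Pair PK draws with MIC draws at random and form the PKPD index.

    For ``auc_mic``/``cmax_mic``, ``pk_samples`` is the per-subject AUC or
    Cmax vector; for ``t_above_mic`` it must be a ``(times, conc_matrix)``
    pair of a time grid and an (N, len(times)) array of full profiles over
    one dosing interval of length ``tau``.  The random permutation pairing
    preserves both marginals.
    """
    if rng is None:
        raise ConfigurationError("a seeded numpy Generator is required for pairing")
    mic = np.asarray(mic_samples, dtype=float)
    if kind in ("auc_mic", "cmax_mic"):
        pk = np.asarray(pk_samples, dtype=float)
        if pk.ndim != 1:
            raise ConfigurationError(f"{kind} needs a 1-D PK sample vector")
        if pk.size != mic.size:
            raise ConfigurationError(
                f"PK and MIC sample counts differ ({pk.size} vs {mic.size}); resample first"
            )
        values = pk / rng.permutation(mic)
    elif kind == "t_above_mic":
        if not (isinstance(pk_samples, tuple) and len(pk_samples) == 2):
            raise ConfigurationError(
                "t_above_mic requires full profiles: pass (times, conc_matrix)"
            )
        times, conc = np.asarray(pk_samples[0], dtype=float), np.asarray(pk_samples[1], dtype=float)
        if conc.ndim != 2 or conc.shape[0] != mic.size:
            raise ConfigurationError("conc_matrix must be (n_subjects, n_times) matching MIC count")
        span = tau if tau is not None else float(times[-1] - times[0])
        mic_p = rng.permutation(mic)
        above = conc > mic_p[:, None]
        # fraction of the interval above MIC by trapezoid on the indicator
        values = np.trapezoid(above.astype(float), times, axis=1) / span
        values = np.clip(values, 0.0, 1.0)
    else:
        raise ConfigurationError(f"unknown index kind {kind!r}")
    return IndexSample(kind=kind, values=values, provenance=dict(provenance or {}))


def overlap_coefficient(a: np.ndarray, b: np.ndarray, bins: int = OVERLAP_BINS) -> float:
    """Overlap of two positive-valued samples' distributions.

    Estimated as sum over a shared log-spaced histogram grid of the
    bin-wise minimum of the two probability masses; 1 for identical
    distributions, 0 for disjoint supports.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo <= 0:
        raise ConfigurationError("overlap estimator requires positive values (log grid)")
    if lo == hi:
        return 1.0
    edges = np.geomspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / a.size, pb / b.size).sum())


def attainment_vs_benchmark(
    candidate: IndexSample, benchmark: IndexSample, target_quantile: float
) -> dict[str, float]:
    """Compare a candidate's index distribution against a benchmark's.

    ``target_quantile`` positions the benchmark's target efficacy level on
    its own index distribution; attainment is the fraction of candidate
    draws at or above that level.  Also reports the overlap coefficient of
    the two distributions.
    """
    if not 0.0 <= target_quantile <= 1.0:
        raise ValueError(f"target_quantile must lie in [0, 1], got {target_quantile}")
    target = float(np.quantile(benchmark.values, target_quantile))
    attainment = float(np.mean(candidate.values >= target))
    ovl = overlap_coefficient(candidate.values, benchmark.values)
    return {
        "overlap": ovl,
        "attainment": attainment,
        "target_value": target,
        "target_quantile": target_quantile,
        "n_candidate": int(candidate.values.size),
        "n_benchmark": int(benchmark.values.size),
    }
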