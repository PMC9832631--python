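"""Synthetic, fully documented case-study configurations.

The four bundled cases emulate the situations the framework is built for —
compound selection on a central/peripheral inhibition balance, first-in-human
commitment on an induced biomarker with animal-derived safety limits, an
antibody with target-mediated disposition and a tissue-translated protein
endpoint, and an antibiotic benchmarked through AUC:MIC — using invented
placeholder PK/PD parameter values.  Where a published statement fixes a
structural choice (a distribution family, a range, a CV, plan sizes, the
criteria), the fixture uses exactly that; every other number is a synthetic
placeholder chosen once so the qualitative outcome of each case (compound
ranking, rise-then-fall dose-response of success, negligible benchmark
overlap) is reproduced.  Absolute PoPS values from these fixtures are
properties of the synthetic parameters, not of any real compound.

Each ``make_case*_config`` function documents, per value, whether it is a
stated study condition or an invented placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig, dump_config, validate_config

__all__ = [
    "CaseConfig",
    "make_case1_config",
    "make_case2_config",
    "make_case3_config",
    "make_case4_config",
    "make_case_config",
    "benchmark_mic_table",
]


@dataclass(frozen=True)
class CaseConfig:
    """A runnable synthetic case study: one or more configs plus provenance notes."""

    case_id: int
    configs: Mapping[str, RunConfig]
    notes: str
    inputs: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the YAML config(s) and any tabular inputs; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, cfg in self.configs.items():
            p = out / f"case{self.case_id}_{name}.yaml"
            p.write_text(dump_config(cfg))
            paths[name] = p
        for name, frame in self.inputs.items():
            p = out / f"case{self.case_id}_{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = p
        (out / f"case{self.case_id}_notes.md").write_text(self.notes)
        return paths


# ---------------------------------------------------------------------------
# Case 1 — central/peripheral balance, two-compound selection


def make_case1_config(seed: int = 1) -> CaseConfig:
    """Two oral small molecules against a centrally elevated target.

    Study conditions (stated): kp_uu translation uncertainty uniform
    0.45-0.75 (compound A) and 0.35-0.50 (compound B); fold-elevation of the
    target uniform 1.5-3.0 mapped to the required central inhibition
    1 - 1/fold; log-normal BSV with CV 30% on CL/F and on EC50; benefit =
    central activity normalised AND >= 10% peripheral activity preserved, in
    >= 80% of patients; risk = peripheral preservation < 10%, allowed in
    < 5% of patients.

    Invented placeholders: CL/F, V/F-free steady-state formulation, fu,
    EC50 per compound, the dose grid, and reduced plan sizes (M=200, N=500)
    for test-speed; compound A is constructed with a wider margin between
    its central-efficacy window and its peripheral-safety ceiling than
    compound B, so A ranks above B on maximal PoPS.
    """

    def compound(label: str, ec50: float, kp_lo: float, kp_hi: float) -> RunConfig:
        return validate_config(
            {
                "name": f"case1-compound-{label}",
                "description": "synthetic two-compound central/peripheral balance case",
                "units": {"dose": "mg", "time": "h", "concentration": "mg/L"},
                "model": {
                    "kind": "central_peripheral_emax",
                    "params": {
                        "cl_f": 10.0,  # placeholder L/h
                        "fu": 0.02,  # placeholder unbound fraction
                        "emax": 1.0,  # stated: maximal effect = 100% inhibition
                        "ec50": ec50,  # placeholder free-drug potency, mg/L
                        "kp_uu": (kp_lo + kp_hi) / 2.0,
                    },
                },
                "uncertainty": {
                    "kp_uu": {"family": "uniform", "params": {"lower": kp_lo, "upper": kp_hi}}
                },
                "bsv": {"cl_f": {"cv": 30.0}, "ec50": {"cv": 30.0}},
                "criteria": [
                    {
                        "label": "benefit",
                        "kind": "benefit",
                        "required_proportion": 0.80,
                        "conditions": [
                            {
                                "endpoint": "central_inhibition",
                                "comparator": ">=",
                                "threshold": {
                                    "family": "uniform",
                                    "params": {"lower": 1.5, "upper": 3.0},
                                },
                                "transform": "fold_to_inhibition",
                            },
                            {
                                "endpoint": "peripheral_preservation",
                                "comparator": ">=",
                                "threshold": 0.10,
                            },
                        ],
                    },
                    {
                        "label": "risk",
                        "kind": "risk",
                        "required_proportion": 0.05,
                        "conditions": [
                            {
                                "endpoint": "peripheral_preservation",
                                "comparator": "<",
                                "threshold": 0.10,
                            }
                        ],
                    },
                ],
                "plan": {
                    "m": 200,
                    "n": 500,
                    "doses": [7.0, 14.0, 28.0, 56.0, 112.0, 224.0, 448.0, 896.0],
                    "tau": 24.0,
                    "route": "oral",
                    "seed": seed,
                },
            }
        )

    configs = {
        "compound_a": compound("a", ec50=0.0025, kp_lo=0.45, kp_hi=0.75),
        "compound_b": compound("b", ec50=0.0015, kp_lo=0.35, kp_hi=0.50),
    }
    notes = """# Case 1 fixture: synthetic parameter provenance

Stated study conditions:
- kp_uu uncertainty: uniform 0.45-0.75 (A), 0.35-0.50 (B)
- required-inhibition prior: fold-elevation uniform 1.5-3.0, mapped via 1 - 1/fold
- BSV: log-normal, CV 30% on CL/F and EC50; Emax fixed at 100% inhibition
- criteria: benefit (central normalised AND >=10% peripheral preserved) in >=80%;
  risk (peripheral preservation <10%) in <5%

Invented placeholders (synthetic; chosen once for qualitative outcome):
- CL/F 10 L/h, fu 0.02, EC50 0.0025 (A) / 0.0015 (B) mg/L free
- dose grid 7-896 mg QD; plan M=200, N=500 (reduced for test speed)
- compound B is peripherally more potent relative to its central window,
  narrowing its benefit-risk margin, so max PoPS(A) > max PoPS(B)
"""
    return CaseConfig(case_id=1, configs=configs, notes=notes)


# ---------------------------------------------------------------------------
# Case 2 — induced biomarker, species-weighted safety limit, scenario grid

# synthetic NOAEL-equivalent average-concentration limits per species (mg/L):
_CASE2_NOAEL = {"values": [3.0, 6.0, 15.0], "weights": [60.0, 30.0, 10.0]}


def make_case2_config(seed: int = 2) -> CaseConfig:
    """Oral small molecule inducing a protein biomarker (mRNA fold-increase).

    Study conditions (stated): pharmacology-need prior = beta with mode at
    2-fold, decreasing toward the upper support (here rescaled to [1, 16]);
    safety limit = weighted categorical over three animal-species exposure
    limits with weights 60:30:10; criteria >= 90% achieve the needed
    fold-increase, <= 5% above the safety limit; PK BSV CV 30%; estimation
    uncertainty on Emax and EC50 with correlation; scenario grid = required
    fold (2/4/8) x biomarker BSV level (low/mid/high).

    Invented placeholders: CL/F 5 L/h, fu 0.5, Emax 19 (max 20-fold), EC50
    1 mg/L, the three NOAEL-equivalent limits (3, 6, 15 mg/L), BSV level
    CVs (15/30/60), the dose grid, plan sizes M=200, N=500.
    """
    config = validate_config(
        {
            "name": "case2-biomarker-induction",
            "description": "synthetic transduction/induction case with species-weighted safety prior",
            "units": {"dose": "mg", "time": "h", "concentration": "mg/L"},
            "model": {
                "kind": "turnover_induction_ss",
                "params": {"cl_f": 5.0, "fu": 0.5, "emax": 19.0, "ec50": 1.0},
            },
            "uncertainty": {
                "emax": {"family": "lognormal", "params": {"median": 19.0, "cv_percent": 20.0}},
                "ec50": {"family": "lognormal", "params": {"median": 1.0, "cv_percent": 25.0}},
            },
            "uncertainty_correlation": {
                "parameters": ["emax", "ec50"],
                "matrix": [[1.0, 0.6], [0.6, 1.0]],
            },
            "bsv": {"cl_f": {"cv": 30.0}, "emax": {"cv": 30.0}},
            "criteria": [
                {
                    "label": "pharmacology",
                    "kind": "benefit",
                    "required_proportion": 0.90,
                    "conditions": [
                        {
                            "endpoint": "biomarker_fold",
                            "comparator": ">=",
                            "threshold": {
                                "family": "scaled_beta",
                                "params": {
                                    "mode": 2.0,
                                    "lower": 1.0,
                                    "upper": 16.0,
                                    "concentration": 4.0,
                                },
                            },
                        }
                    ],
                },
                {
                    "label": "safety",
                    "kind": "risk",
                    "required_proportion": 0.05,
                    "proportion_inclusive": True,  # "at most 5%" allowance
                    "conditions": [
                        {
                            "endpoint": "cavg",
                            "comparator": ">",
                            "threshold": {
                                "family": "weighted_categorical",
                                "params": dict(_CASE2_NOAEL),
                            },
                        }
                    ],
                },
            ],
            "plan": {
                "m": 200,
                "n": 500,
                "doses": [25.0, 50.0, 100.0, 200.0, 300.0, 450.0, 700.0, 1000.0],
                "tau": 24.0,
                "route": "oral",
                "seed": seed,
            },
            "scenarios": {
                "axes": {
                    "required_fold": {
                        "2-fold": {"criteria.0.conditions.0.threshold": 2.0},
                        "4-fold": {"criteria.0.conditions.0.threshold": 4.0},
                        "8-fold": {"criteria.0.conditions.0.threshold": 8.0},
                    },
                    "biomarker_bsv": {
                        "low": {"bsv.emax.cv": 15.0},
                        "mid": {"bsv.emax.cv": 30.0},
                        "high": {"bsv.emax.cv": 60.0},
                    },
                }
            },
        }
    )
    notes = """# Case 2 fixture: synthetic parameter provenance

Stated study conditions:
- pharmacology-need prior: scaled beta, mode at 2-fold, decreasing density
  toward the upper support (support here [1, 16] fold)
- safety prior: weighted categorical over three species limits, weights 60:30:10
- criteria: >=90% achieve the required fold-increase; <=5% exceed the limit
- PK BSV CV 30% (CL/F); estimation uncertainty on Emax and EC50, correlated
- scenario grid: required fold 2/4/8 x biomarker BSV low/mid/high

Invented placeholders: CL/F 5 L/h, fu 0.5, Emax 19 (20-fold ceiling),
EC50 1 mg/L, species limits 3/6/15 mg/L average concentration, BSV levels
CV 15/30/60, dose grid 25-1000 mg QD, plan M=200, N=500.
The single-most-relevant-species re-estimate is the override
criteria.1.conditions.0.threshold -> weights 0:0:1 (highest limit).
"""
    return CaseConfig(case_id=2, configs={"base": config}, notes=notes)


# ---------------------------------------------------------------------------
# Case 3 — antibody, TMDD exposure, tissue-translated protein endpoint


def make_case3_config(seed: int = 3) -> CaseConfig:
    """Monoclonal antibody dosed Q4W with a tissue-translated protein endpoint.

    Study conditions (stated): required-inhibition prior uniform 0.70-0.95;
    both criteria demand more than half the subjects comply (benefit
    comparisons strict); plan 500 trials x 500 subjects; Q4W IV dosing with
    a dose grid extending beyond the safety limit so the top dose shows the
    safety-driven PoPS decline.

    Invented placeholders: CL 0.012 L/h, plasma-to-tissue coefficient
    log-normal around 0.1, Imax 0.98, tissue IC50 2 mg/L, safety exposure
    limit 900 mg/L average serum concentration, the dose grid.
    """
    config = validate_config(
        {
            "name": "case3-antibody-tissue-protein",
            "description": "synthetic TMDD/indirect-response case with tissue translation",
            "units": {"dose": "mg", "time": "h", "concentration": "mg/L"},
            "model": {
                "kind": "tmdd_indirect_ss",
                "params": {"cl": 0.012, "kp_tissue": 0.1, "imax": 0.98, "ic50": 2.0},
            },
            "uncertainty": {
                "kp_tissue": {
                    "family": "lognormal",
                    "params": {"median": 0.1, "cv_percent": 30.0},
                },
                "ic50": {"family": "lognormal", "params": {"median": 2.0, "cv_percent": 25.0}},
            },
            "bsv": {"cl": {"cv": 30.0}, "ic50": {"cv": 30.0}},
            "criteria": [
                {
                    "label": "pharmacology",
                    "kind": "benefit",
                    "required_proportion": 0.50,
                    "proportion_inclusive": False,  # "> 50% of subjects"
                    "conditions": [
                        {
                            "endpoint": "protein_inhibition",
                            "comparator": ">=",
                            "threshold": {
                                "family": "uniform",
                                "params": {"lower": 0.70, "upper": 0.95},
                            },
                        }
                    ],
                },
                {
                    "label": "safety",
                    "kind": "benefit",  # "> 50% within the exposure limit"
                    "required_proportion": 0.50,
                    "proportion_inclusive": False,
                    "conditions": [
                        {"endpoint": "cavg_serum", "comparator": "<=", "threshold": 900.0}
                    ],
                },
            ],
            "plan": {
                "m": 500,
                "n": 500,
                "doses": [300.0, 600.0, 1200.0, 2400.0, 5000.0, 10000.0],
                "tau": 672.0,  # Q4W
                "route": "iv_bolus",
                "seed": seed,
            },
        }
    )
    notes = """# Case 3 fixture: synthetic parameter provenance

Stated study conditions:
- required tissue protein inhibition: uniform 0.70-0.95
- criteria: >50% of subjects achieve the required inhibition; >50% stay
  within the systemic exposure limit (both strict majorities)
- plan: 500 trials x 500 subjects; Q4W (tau = 672 h) IV dosing
- dose grid extends beyond the safety limit (decline expected at the top)

Invented placeholders: CL 0.012 L/h; plasma-to-tissue distribution
coefficient log-normal, median 0.1, 30% uncertainty CV (family is a
configurable choice; log-normal default); Imax 0.98; tissue IC50 2 mg/L
(25% uncertainty CV); BSV CV 30% on CL and IC50; exposure limit 900 mg/L
average serum concentration; dose grid 300-10000 mg.
"""
    return CaseConfig(case_id=3, configs={"base": config}, notes=notes)


# ---------------------------------------------------------------------------
# Case 4 — antibiotic AUC:MIC benchmark comparison


def benchmark_mic_table() -> pd.DataFrame:
    """Synthetic published-style cumulative MIC frequency table (benchmark drug).

    Generated from a logistic CDF on log2(MIC) with midpoint 0.5 mg/L and
    slope 1.5, evaluated at seven doubling dilutions and rounded to three
    decimals — the shape of a literature cumulative-frequency table.
    """
    mic = np.array([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0])
    frac = 1.0 / (1.0 + np.exp(-1.5 * (np.log2(mic) - np.log2(0.5))))
    return pd.DataFrame({"mic": mic, "cumulative_fraction": np.round(frac, 3)})


def make_case4_config(seed: int = 4) -> CaseConfig:
    """Oral antibiotic candidate benchmarked by AUC:MIC against an in-class drug.

    Study conditions (stated): N = 3000 per simulated population; index =
    AUC:MIC; benchmark MIC distribution fitted by a logistic function to a
    cumulative frequency table; candidate MIC distribution log-normal;
    point-estimate PK (no parameter uncertainty).

    Invented placeholders: candidate CL/F 8 L/h (BSV 30%), dose 1000 mg QD,
    candidate MIC median 64 mg/L (sigma 0.6) — a poorly susceptible
    pathogen population relative to the benchmark's (midpoint 0.5 mg/L) —
    benchmark CL/F 5 L/h (BSV 25%), dose 500 mg QD, target efficacy level
    at the benchmark's 10th index percentile.  The separation is constructed
    so the two index distributions barely overlap.
    """
    table = benchmark_mic_table()
    config = validate_config(
        {
            "name": "case4-antibiotic-auc-mic",
            "description": "synthetic AUC:MIC benchmark comparison (negligible-overlap construction)",
            "units": {"dose": "mg", "time": "h", "concentration": "mg/L", "auc": "mg*h/L"},
            "pta": {
                "n": 3000,
                "index": "auc_mic",
                "target_quantile": 0.10,
                "candidate": {
                    "cl_f": 8.0,
                    "cv": 30.0,
                    "dose": 1000.0,
                    "tau": 24.0,
                    "mic": {
                        "family": "lognormal",
                        "params": {"mu": float(np.log(64.0)), "sigma": 0.6},
                    },
                },
                "benchmark": {
                    "cl_f": 5.0,
                    "cv": 25.0,
                    "dose": 500.0,
                    "tau": 24.0,
                    "mic_table": {
                        "mic": [float(x) for x in table["mic"]],
                        "cumulative_fraction": [float(x) for x in table["cumulative_fraction"]],
                    },
                },
                "seed": seed,
            },
        }
    )
    notes = """# Case 4 fixture: synthetic parameter provenance

Stated study conditions:
- N = 3000 per simulated population; PKPD index = AUC:MIC
- benchmark MIC distribution: logistic CDF fitted (log2 scale) to a
  cumulative frequency table; candidate MIC distribution: log-normal
- point-estimate PK parameters (uncertainty deliberately omitted)

Invented placeholders: candidate CL/F 8 L/h, BSV 30%, 1000 mg QD, MIC
log-normal median 64 mg/L sigma 0.6; benchmark CL/F 5 L/h, BSV 25%,
500 mg QD, MIC logistic midpoint 0.5 mg/L slope 1.5 (table generated from
that curve and rounded to 3 decimals); target efficacy level = benchmark's
10th AUC:MIC percentile.  Construction places the candidate's index
distribution far below the benchmark's (negligible overlap).
"""
    return CaseConfig(case_id=4, configs={"base": config}, inputs={"benchmark_mic": table}, notes=notes)


def make_case_config(case: int, seed: int | None = None) -> CaseConfig:
    makers = {1: make_case1_config, 2: make_case2_config, 3: make_case3_config, 4: make_case4_config}
    if case not in makers:
        raise ValueError(f"case must be 1-4, got {case}")
    return makers[case]() if seed is None else makers[case](seed)
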