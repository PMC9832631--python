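"""Vectorised endpoint assemblies: parameters + regimen -> per-subject endpoints.

Each assembly wires the primitives in :mod:`pops.pkpd` into the function f of
the simulation: it receives per-subject parameter arrays (typical values
already perturbed by between-subject random effects) and a dosing regimen,
and returns named endpoint arrays.  Assemblies are registered by name so a
configuration file can select one and so criteria can be checked against the
declared output schema before any simulation runs.

The bundled assemblies evaluate steady-state endpoints in closed form — the
regime the dose-ranging questions here live in — which keeps the nested
Monte-Carlo loop vectorised over subjects.  Time-course endpoints can be
added by registering a new assembly over :func:`pops.pkpd.turnover_profile`
or :func:`pops.pkpd.tmdd_profile`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigurationError
from .pkpd import Regimen

__all__ = ["StructuralModel", "get_model", "register_model", "known_models"]

_REGISTRY: dict[str, "StructuralModel"] = {}


@dataclass(frozen=True)
class StructuralModel:
    """A named endpoint assembly with a declared parameter/endpoint schema."""

    name: str
    param_names: tuple[str, ...]
    endpoint_names: tuple[str, ...]
    fn: Callable[[Mapping[str, np.ndarray], Regimen], dict[str, np.ndarray]]

    def endpoints(self, params: Mapping[str, np.ndarray], regimen: Regimen) -> dict[str, np.ndarray]:
        missing = [p for p in self.param_names if p not in params]
        if missing:
            raise ConfigurationError(f"model {self.name!r} missing parameter(s): {missing}")
        return self.fn(params, regimen)


def register_model(model: StructuralModel) -> StructuralModel:
    _REGISTRY[model.name] = model
    return model


def get_model(name: str) -> StructuralModel:
    if name not in _REGISTRY:
        raise ConfigurationError(
            f"unknown structural model {name!r}; known models: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def known_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


# ---------------------------------------------------------------------------
# bundled assemblies


def _central_peripheral_emax(params: Mapping[str, np.ndarray], regimen: Regimen) -> dict:
    """Oral steady-state exposure driving Emax inhibition centrally and peripherally.

    The free average concentration (cavg*fu) acts at peripheral tissue; the
    brain sees it scaled by the unbound partition coefficient kp_uu.  Potency
    (ec50) is a free-drug potency.  Peripheral preservation = 1 - inhibition.
    """
    cavg = regimen.dose / (np.asarray(params["cl_f"], dtype=float) * regimen.tau)
    c_free = cavg * params["fu"]
    c_brain = c_free * params["kp_uu"]
    emax, ec50 = params["emax"], params["ec50"]
    central = emax * c_brain / (ec50 + c_brain)
    peripheral = emax * c_free / (ec50 + c_free)
    return {
        "cavg": cavg,
        "central_inhibition": central,
        "peripheral_inhibition": peripheral,
        "peripheral_preservation": 1.0 - peripheral,
    }


register_model(
    StructuralModel(
        name="central_peripheral_emax",
        param_names=("cl_f", "fu", "kp_uu", "emax", "ec50"),
        endpoint_names=(
            "cavg",
            "central_inhibition",
            "peripheral_inhibition",
            "peripheral_preservation",
        ),
        fn=_central_peripheral_emax,
    )
)


def _turnover_induction_ss(params: Mapping[str, np.ndarray], regimen: Regimen) -> dict:
    """Oral exposure driving a stimulate-production turnover model at steady state.

    Biomarker fold-increase over baseline: R_ss/R0 = 1 + Emax*C/(EC50+C),
    with C the free steady-state average concentration.  ``cavg`` (total) is
    also exported as the safety exposure endpoint.
    """
    cavg = regimen.dose / (np.asarray(params["cl_f"], dtype=float) * regimen.tau)
    c_free = cavg * params["fu"]
    fold = 1.0 + params["emax"] * c_free / (params["ec50"] + c_free)
    return {"cavg": cavg, "biomarker_fold": fold}


register_model(
    StructuralModel(
        name="turnover_induction_ss",
        param_names=("cl_f", "fu", "emax", "ec50"),
        endpoint_names=("cavg", "biomarker_fold"),
        fn=_turnover_induction_ss,
    )
)


def _tmdd_indirect_ss(params: Mapping[str, np.ndarray], regimen: Regimen) -> dict:
    """Serum exposure with tissue translation driving Imax protein suppression.

    Average serum concentration over the dosing interval from systemic
    clearance (the linear regime of a target-mediated system at doses that
    saturate the target); tissue concentration via the plasma-to-tissue
    distribution coefficient; protein inhibition by an Imax model at steady
    state of an inhibit-production turnover.
    """
    cavg = regimen.dose / (np.asarray(params["cl"], dtype=float) * regimen.tau)
    c_tissue = cavg * params["kp_tissue"]
    inhibition = params["imax"] * c_tissue / (params["ic50"] + c_tissue)
    return {"cavg_serum": cavg, "c_tissue": c_tissue, "protein_inhibition": inhibition}


register_model(
    StructuralModel(
        name="tmdd_indirect_ss",
        param_names=("cl", "kp_tissue", "imax", "ic50"),
        endpoint_names=("cavg_serum", "c_tissue", "protein_inhibition"),
        fn=_tmdd_indirect_ss,
    )
)


def _onecomp_auc(params: Mapping[str, np.ndarray], regimen: Regimen) -> dict:
    """Steady-state AUC over one dosing interval for a one-compartment model.

    At steady state AUC_tau = dose/(CL/F) regardless of absorption rate."""
    auc = regimen.dose / np.asarray(params["cl_f"], dtype=float)
    return {"auc_tau": auc, "cavg": auc / regimen.tau}


register_model(
    StructuralModel(
        name="onecomp_auc",
        param_names=("cl_f",),
        endpoint_names=("auc_tau", "cavg"),
        fn=_onecomp_auc,
    )
)
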