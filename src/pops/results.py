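"""Result serialization: tidy CSV tables plus a JSON provenance record.

Every run writes, into one output directory:

* ``pops_curve.csv`` — per-dose PoPS, per-criterion pass rates, and the
  median/5th/95th percentiles of the subject proportions (scenario runs add
  one column per scenario axis);
* ``replicates.csv`` — per-replicate diagnostics (realized thresholds,
  required proportions, achieved fractions, pass flags);
* ``run.json`` — the full configuration echo, master seed, sizes and tool
  version, so any result file can be traced back to its inputs.

Numeric CSV formatting is pinned to 10 significant digits so identical runs
produce byte-identical tables.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .engine import PoPSCurve, ScenarioResult

__all__ = ["write_results", "write_pta_results", "read_curve"]

_FLOAT_FMT = "%.10g"


def _run_header(config: RunConfig | None, seed: int | None, extra: dict | None = None) -> dict:
    header = {
        "tool": "pops",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config.model_dump(exclude_none=True) if config is not None else None,
    }
    header.update(extra or {})
    return header


def write_results(
    result: PoPSCurve | ScenarioResult,
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a PoPS curve or scenario sweep to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if isinstance(result, ScenarioResult):
        frame = result.to_frame()
        replicates = pd.concat(
            [
                curve.records.assign(**dict(zip(result.axes, key)))
                for key, curve in result.cells.items()
            ],
            ignore_index=True,
        )
        meta = {"kind": "scenarios", "axes": {a: list(v) for a, v in result.axes.items()}}
        seed = seed if seed is not None else next(iter(result.cells.values())).metadata.get("seed")
        m = next(iter(result.cells.values())).m
        n = next(iter(result.cells.values())).n
    else:
        frame = result.to_frame()
        replicates = result.records
        meta = {"kind": "run"}
        seed = seed if seed is not None else result.metadata.get("seed")
        m, n = result.m, result.n

    paths["curve"] = out / "pops_curve.csv"
    frame.to_csv(paths["curve"], index=False, float_format=_FLOAT_FMT)
    paths["replicates"] = out / "replicates.csv"
    replicates.to_csv(paths["replicates"], index=False, float_format=_FLOAT_FMT)
    paths["run"] = out / "run.json"
    header = _run_header(config, seed, {**meta, "m": m, "n": n})
    paths["run"].write_text(json.dumps(header, indent=2, default=str))
    return paths


def write_pta_results(
    pta_result: dict, out_dir: str | Path, config: RunConfig | None = None, seed: int | None = None
) -> dict[str, Path]:
    """Write PTA index distributions and the overlap/attainment summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = pd.DataFrame(
        {
            "candidate": pta_result["candidate"].values,
            "benchmark": pta_result["benchmark"].values,
        }
    )
    paths["indices"] = out / "index_distribution.csv"
    frame.to_csv(paths["indices"], index=False, float_format=_FLOAT_FMT)

    paths["summary"] = out / "pta_summary.json"
    summary = dict(pta_result["summary"])
    paths["summary"].write_text(json.dumps(_run_header(config, seed, {"kind": "pta", **summary}), indent=2))
    return paths


def read_curve(path: str | Path) -> pd.DataFrame:
    """Read back a ``pops_curve.csv`` table."""
    return pd.read_csv(path)
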