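"""Result serialization: JSON with provenance, flat CSV tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .results import RecoveryResult, SplittingResult

__all__ = ["config_hash", "write_results", "load_result"]


def config_hash(config: ScenarioConfig) -> str:
    """SHA-256 of the canonical (sorted, compact) JSON of the scenario."""
    return hashlib.sha256(config.canonical_json().encode()).hexdigest()


def _payload(result, config: ScenarioConfig | None) -> dict:
    if isinstance(result, SplittingResult):
        body = {"kind": "splitting", **result.to_dict()}
    elif isinstance(result, RecoveryResult):
        body = {"kind": "recovery", **result.to_dict()}
    elif isinstance(result, pd.DataFrame):
        body = {"kind": "table", "columns": list(result.columns),
                "rows": result.to_numpy().tolist()}
    elif isinstance(result, dict):
        body = {"kind": "mapping", **result}
    else:
        raise TypeError(f"don't know how to serialize {type(result)!r}")
    meta = {"gradsense_version": __version__}
    if config is not None:
        meta["config"] = config.model_dump()
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.simulation.seed
    return {"meta": meta, "result": body}


def write_results(result, path, fmt: str = "json",
                  config: ScenarioConfig | None = None) -> list[Path]:
    """Write a result as JSON and/or CSV; returns the files written.

    JSON output is canonical (sorted keys) so a loaded result re-serializes
    byte-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt in ("json", "both"):
        p = path.with_suffix(".json")
        p.write_text(json.dumps(_payload(result, config), sort_keys=True,
                                indent=1) + "\n")
        written.append(p)
    if fmt in ("csv", "both"):
        p = path.with_suffix(".csv")
        if isinstance(result, SplittingResult):
            result.to_frame().to_csv(p, index=False)
        elif isinstance(result, RecoveryResult):
            pd.DataFrame({"x": [result.position[0]], "y": [result.position[1]],
                          "residual_norm": [result.residual_norm]}
                         ).to_csv(p, index=False)
        elif isinstance(result, pd.DataFrame):
            result.to_csv(p, index=False)
        else:
            raise TypeError(f"no CSV writer for {type(result)!r}")
        written.append(p)
    if not written:
        raise ValueError(f"unknown format {fmt!r}; use json, csv or both")
    return written


def load_result(path) -> dict:
    """Load a JSON result written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
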