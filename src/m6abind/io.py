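"""Tabular I/O contracts shared by the CLI and the library.

Traces and peak tables travel as TSV with '#'-prefixed metadata header
lines; configs are flat YAML; every CLI run drops a JSON provenance
record (config echo + package version + seed) next to its outputs.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .bli import SensorTrace
from .csp import PeakTable
from .errors import ValidationError

__all__ = [
    "to_nanomolar",
    "read_trace",
    "write_trace",
    "read_peak_table",
    "write_peak_table",
    "load_config",
    "write_provenance",
]

_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


def to_nanomolar(value: float, unit: str = "nM") -> float:
    """Convert a concentration to the package-internal nanomolar scale."""
    try:
        return float(value) * _UNIT_TO_NM[unit]
    except KeyError:
        raise ValidationError(
            f"unknown concentration unit {unit!r}; use one of {sorted(_UNIT_TO_NM)}") from None


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("#").strip().partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_trace(trace: SensorTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"# phase = {trace.phase}\n")
        if trace.analyte_concentration is not None:
            handle.write(f"# concentration_nM = {trace.analyte_concentration:g}\n")
        handle.write("time_s\tresponse_RU\n")
        for t, r in zip(trace.time, trace.response):
            handle.write(f"{t:.6g}\t{r:.10g}\n")


def read_trace(path: str | Path) -> SensorTrace:
    path = Path(path)
    meta = _read_metadata(path)
    if "phase" not in meta:
        raise ValidationError(f"{path}: missing '# phase =' metadata line")
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"time_s", "response_RU"} <= set(frame.columns):
        raise ValidationError(f"{path}: expected columns time_s, response_RU")
    conc = float(meta["concentration_nM"]) if "concentration_nM" in meta else None
    return SensorTrace(
        time=frame["time_s"].to_numpy(dtype=float),
        response=frame["response_RU"].to_numpy(dtype=float),
        phase=meta["phase"],
        analyte_concentration=conc,
    )


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# condition = {table.condition}\n")
        table.to_frame().to_csv(handle, sep="\t", index=False)


def read_peak_table(path: str | Path) -> PeakTable:
    path = Path(path)
    meta = _read_metadata(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue", "dH_ppm", "dN_ppm"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    excluded = (frame["excluded"].to_numpy(dtype=bool)
                if "excluded" in frame.columns else None)
    return PeakTable(
        condition=meta.get("condition", path.stem),
        residues=frame["residue"].to_numpy(dtype=int),
        delta_h=frame["dH_ppm"].to_numpy(dtype=float),
        delta_n=frame["dN_ppm"].to_numpy(dtype=float),
        excluded=excluded,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if config is None:
        return {}
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: config must be a mapping of keys to values")
    return config


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_provenance(out_path: str | Path, subcommand: str,
                     config: dict[str, Any], seed: int | None = None) -> Path:
    """Write a JSON provenance record next to an output file.

    Timestamps live only here, never in data outputs, so re-runs stay
    byte-identical.
    """
    from . import __version__

    out_path = Path(out_path)
    record = {
        "tool": "m6abind",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": _jsonable(config),
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov_path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return prov_path
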