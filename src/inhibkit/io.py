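"""CSV schemas, configuration, and report serialization.

Tabular I/O is plain RFC-4180 CSV with '.' decimals and UTF-8; column units
are encoded in the headers (``time_s``, ``S_uM``, ``I_nM``) and converted to
the internal molar/second convention on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .models import ProgressCurve, ThermoContext
from .triage import (
    DDG_THRESHOLD,
    LIKENESS_LIMITS,
    CandidateRecord,
    DescriptorSet,
)

_uM = 1e-6
_nM = 1e-9

PROGRESS_COLUMNS = ("time_s", "signal", "S_uM", "I_nM", "curve_id")
RATE_COLUMNS = ("S_uM", "I_nM", "v")
CANDIDATE_COLUMNS = ("compound",)  # remaining candidate columns are optional


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_progress_csv(path) -> list[ProgressCurve]:
    """Read progress curves (columns time_s, signal, S_uM, I_nM, curve_id).

    Rows are grouped by curve_id and sorted by time, so shuffled files load
    identically.  Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROGRESS_COLUMNS, path)
    bad = []
    for col in ("time_s", "signal", "S_uM", "I_nM"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad.extend((df.index[coerced.isna() & df[col].notna()] + 2).tolist())
        df[col] = coerced
    bad.extend((df.index[df[["time_s", "S_uM", "I_nM"]].isna().any(axis=1)] + 2).tolist())
    if bad:
        raise SchemaError(f"{path}: malformed rows at lines {sorted(set(bad))}")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("time_s")
        if grp["time_s"].duplicated().any():
            raise SchemaError(f"{path}: duplicate/non-monotone times in curve {cid!r}")
        S = grp["S_uM"].iloc[0] * _uM
        I = grp["I_nM"].iloc[0] * _nM
        curves.append(ProgressCurve(
            times=grp["time_s"].to_numpy(), signal=grp["signal"].to_numpy(),
            S=float(S), I=float(I), label=str(cid),
        ))
    return curves


def write_progress_csv(curves: Sequence[ProgressCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_s": c.times, "signal": c.signal,
            "S_uM": c.S / _uM, "I_nM": c.I / _nM,
            "curve_id": c.label or f"S{c.S/_uM:.6g}_I{c.I/_nM:.6g}",
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_rate_csv(path) -> pd.DataFrame:
    """Read an initial-rate table into internal units (columns S, I, v, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RATE_COLUMNS, path)
    out = pd.DataFrame({
        "S": pd.to_numeric(df["S_uM"], errors="coerce") * _uM,
        "I": pd.to_numeric(df["I_nM"], errors="coerce") * _nM,
        "v": pd.to_numeric(df["v"], errors="coerce"),
    })
    if out.isna().any().any():
        lines = sorted((out.index[out.isna().any(axis=1)] + 2).tolist())
        raise SchemaError(f"{path}: malformed rows at lines {lines}")
    out["replicate"] = df.get("replicate", 0)
    return out


def write_rate_csv(table: pd.DataFrame, path) -> None:
    """Write an internal-units rate table back to the S_uM/I_nM/v schema."""
    out = pd.DataFrame({
        "S_uM": table["S"] / _uM, "I_nM": table["I"] / _nM, "v": table["v"],
        "replicate": table.get("replicate", 0),
    })
    out.to_csv(path, index=False, float_format="%.17g")


def read_candidates_csv(path) -> list[CandidateRecord]:
    """Read a candidate table (compound, ddG_cal_kcal, ki_nM, descriptors...)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CANDIDATE_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        desc = None
        if all(c in df.columns and pd.notna(row[c])
               for c in ("MW", "ClogP", "HBA", "HBD", "ROB", "ARB")):
            desc = DescriptorSet(
                MW=float(row["MW"]), ClogP=float(row["ClogP"]),
                HBA=int(row["HBA"]), HBD=int(row["HBD"]),
                ROB=int(row["ROB"]), ARB=int(row["ARB"]),
            )
        ddg = row.get("ddG_cal_kcal")
        ki = row.get("ki_nM")
        records.append(CandidateRecord(
            label=str(row["compound"]),
            ddG_cal=float(ddg) if pd.notna(ddg) else None,
            Ki_exp=float(ki) * _nM if pd.notna(ki) else None,
            descriptors=desc,
            synthesizable=bool(row["synthesizable"])
            if "synthesizable" in df.columns and pd.notna(row.get("synthesizable")) else None,
        ))
    return records


@dataclass
class RunConfig:
    """Pipeline configuration; the defaults reproduce the published criteria."""

    thermo: ThermoContext = field(default_factory=ThermoContext)
    triage_threshold: float = DDG_THRESHOLD
    likeness_limits: dict[str, float] = field(default_factory=lambda: dict(LIKENESS_LIMITS))
    fit_alpha: float = 0.05
    weighting: str = "proportional"
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thermo"] = {"R": self.thermo.R, "T": self.thermo.T}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        th = d.pop("thermo", {})
        return cls(thermo=ThermoContext(**th), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _jsonable(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_json_report(report: dict, path) -> None:
    """Write a report dict as JSON (NaN -> null; numpy types unwrapped)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def file_sha256(path) -> str:
    """Short content hash used in run logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
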