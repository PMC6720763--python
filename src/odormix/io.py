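"""Tabular and JSON persistence for panel data, profiles and calibrations.

All tabular formats are UTF-8 CSV with a header row and "." decimal
separator; nested objects (odorant profiles, fuzzy calibrations) use JSON.
Reads validate the declared schema and report missing columns by name;
extra columns are preserved and passed through.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy import LabeledSample
from .psychophysics import OdorantProfile, StevensLaw, WeberFechnerLaw

__all__ = [
    "SchemaError",
    "PANEL_SCHEMA",
    "COEFFICIENT_SCHEMA",
    "read_table",
    "write_table",
    "read_profiles",
    "write_profiles",
    "read_enose_samples",
    "write_enose_samples",
]

#: Panel CSV schema: one rating per row.
PANEL_SCHEMA = ("odorant", "concentration_ppm", "panelist_id", "oi")

#: Tidy interaction-coefficient schema.
COEFFICIENT_SCHEMA = ("odorant_a", "odorant_b", "model", "oi_level", "cos_ab")


class SchemaError(ValueError):
    """A table is missing required columns."""


def read_table(path, schema: Sequence[str]) -> pd.DataFrame:
    """Read a CSV and check it carries at least the schema columns."""
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"expected at least {list(schema)}")
    return df


def write_table(df: pd.DataFrame, path, schema: Sequence[str] | None = None) -> None:
    """Write a CSV at full float precision (lossless round-trip)."""
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {path}: missing column(s) {missing}")
    df.to_csv(path, index=False)


def _profile_to_dict(p: OdorantProfile) -> dict:
    return {"molar_mass": p.molar_mass, "density_liquid": p.density_liquid,
            "vapor_pressure": p.vapor_pressure,
            "odor_threshold_lit": p.odor_threshold_lit,
            "k_wf": p.wf.k_wf, "c_ot": p.wf.c_ot,
            "n": p.stevens.n, "k_s": p.stevens.k_s}


def write_profiles(profiles: Sequence[OdorantProfile], path) -> None:
    Path(path).write_text(json.dumps(
        {p.name: _profile_to_dict(p) for p in profiles}, indent=2, sort_keys=True),
        encoding="utf-8")


def read_profiles(path) -> list[OdorantProfile]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for name, d in data.items():
        try:
            out.append(OdorantProfile(
                name=name, molar_mass=d["molar_mass"],
                density_liquid=d["density_liquid"],
                vapor_pressure=d["vapor_pressure"],
                odor_threshold_lit=d["odor_threshold_lit"],
                wf=WeberFechnerLaw(k_wf=d["k_wf"], c_ot=d["c_ot"]),
                stevens=StevensLaw(k_s=d["k_s"], n=d["n"])))
        except KeyError as e:
            raise SchemaError(f"{path}: profile {name!r} missing field {e}") from None
    return out


def write_enose_samples(samples: Sequence[LabeledSample], path) -> None:
    rows = []
    for i, s in enumerate(samples):
        row = {"sample_id": s.sample_id or f"sample{i + 1}", "oi_label": s.oi_label}
        row.update(s.signals)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_enose_samples(path, labeled: bool = True) -> list[LabeledSample]:
    """Read an e-nose sample CSV: ``sample_id`` + sensor columns [+ ``oi_label``].

    With ``labeled=False`` the label column is optional and unlabeled rows
    get label 0 placeholders stripped by callers that only need signals.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing column(s) ['sample_id']")
    if labeled and "oi_label" not in df.columns:
        raise SchemaError(f"{path}: missing column(s) ['oi_label']")
    sensor_cols = [c for c in df.columns if c not in ("sample_id", "oi_label")]
    if not sensor_cols:
        raise SchemaError(f"{path}: no sensor signal columns found")
    out = []
    for d in df.to_dict("records"):
        out.append(LabeledSample(
            signals={c: float(d[c]) for c in sensor_cols},
            oi_label=int(d["oi_label"]) if "oi_label" in d else 0,
            sample_id=str(d["sample_id"])))
    return out
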