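"""Cohort CSV and spec-config serialisation.

Cohort CSV dialect (wide, one row per trial, UTF-8, comma-separated,
header required): trial_id, patient_id, outcome, age, sex, the seven
comorbidity flags, days_intubated, trial_duration_min, apache_ii, then
pre_/post_-prefixed gas columns (ph, pao2, paco2, sao2, pcvo2, pcvco2,
scvo2, lac, hb).  Missing values are empty cells.  Saturations may be
given as fractions (0-1] or percent (0-100]; values above 1 are treated
as percent and normalised on read — no other unit auto-detection is done.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .bloodgas import COMORBIDITY_FLAGS, BloodGasPanel, TrialRecord
from .cohort import CohortSpec, CohortTable, GroupNormal, IndexCalibration

GAS_FIELDS = ("ph", "pao2", "paco2", "sao2", "pcvo2", "pcvco2", "scvo2", "lac", "hb")

REQUIRED_COLUMNS = (
    ["trial_id", "patient_id", "outcome", "age", "sex"]
    + list(COMORBIDITY_FLAGS)
    + ["days_intubated", "trial_duration_min", "apache_ii"]
    + [f"{p}_{g}" for p in ("pre", "post") for g in GAS_FIELDS if g != "hb"]
)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write the wide cohort CSV; deterministic byte-for-byte given the cohort."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _saturation(value: float, column: str) -> float:
    if value > 1.0:  # percent input, as printed in clinical tables
        value = value / 100.0
    if not 0 < value <= 1:
        raise ValueError(f"column {column}: saturation {value} not interpretable")
    return value


def read_cohort_csv(path) -> CohortTable:
    """Parse a cohort CSV into a :class:`CohortTable`, validating panels.

    Raises ``ValueError`` naming the offending column or row on malformed
    input.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no trial rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    trials = []
    for idx, row in df.iterrows():
        panels = {}
        for prefix in ("pre", "post"):
            hb = row.get(f"{prefix}_hb", np.nan)
            hb = None if pd.isna(hb) else float(hb)
            try:
                panels[prefix] = BloodGasPanel(
                    ph=float(row[f"{prefix}_ph"]),
                    pao2=float(row[f"{prefix}_pao2"]),
                    paco2=float(row[f"{prefix}_paco2"]),
                    sao2=_saturation(float(row[f"{prefix}_sao2"]), f"{prefix}_sao2"),
                    pcvo2=float(row[f"{prefix}_pcvo2"]),
                    pcvco2=float(row[f"{prefix}_pcvco2"]),
                    scvo2=_saturation(float(row[f"{prefix}_scvo2"]), f"{prefix}_scvo2"),
                    lactate=float(row[f"{prefix}_lac"]),
                    hemoglobin=hb,
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"{path}: row {idx} ({row['trial_id']!r}), {prefix} panel: {exc}"
                ) from exc
        trials.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                patient_id=str(row["patient_id"]),
                outcome=str(row["outcome"]).strip().lower(),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                **{f: bool(int(row[f])) for f in COMORBIDITY_FLAGS},
                days_intubated=float(row["days_intubated"]),
                trial_duration=float(row["trial_duration_min"]),
                apache_ii=float(row["apache_ii"]),
                pre=panels["pre"],
                post=panels["post"],
            )
        )
    return CohortTable(trials)


# ---------------------------------------------------------------------------
# CohortSpec config round-trip
# ---------------------------------------------------------------------------

def spec_to_dict(spec: CohortSpec) -> dict[str, Any]:
    def convert(obj):
        if isinstance(obj, (GroupNormal, IndexCalibration)):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None  # +-inf truncation bounds
        return obj

    out = {}
    for f in dataclasses.fields(spec):
        out[f.name] = convert(getattr(spec, f.name))
    return out


def _group_normal(d: dict) -> GroupNormal:
    d = dict(d)
    d["lo"] = -np.inf if d.get("lo") is None else d["lo"]
    d["hi"] = np.inf if d.get("hi") is None else d["hi"]
    return GroupNormal(**d)


def spec_from_dict(data: dict[str, Any]) -> CohortSpec:
    kwargs = dict(data)
    for name in ("age", "days_intubated", "trial_duration", "apache_ii"):
        if name in kwargs:
            kwargs[name] = _group_normal(kwargs[name])
    if "indices" in kwargs:
        kwargs["indices"] = {
            k: IndexCalibration(
                pre=_group_normal(v["pre"]),
                change=_group_normal(v["change"]),
                post_lo=v["post_lo"],
                post_hi=v["post_hi"],
            )
            for k, v in kwargs["indices"].items()
        }
    for name in ("male_prevalence", "pao2", "pcvo2", "hemoglobin"):
        if name in kwargs:
            kwargs[name] = tuple(kwargs[name])
    if "comorbidity_prevalence" in kwargs:
        kwargs["comorbidity_prevalence"] = {
            k: tuple(v) for k, v in kwargs["comorbidity_prevalence"].items()
        }
    return CohortSpec(**kwargs)


def write_spec(spec: CohortSpec, path) -> None:
    """Serialise a spec to YAML or JSON depending on the file suffix."""
    path = Path(path)
    data = spec_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_spec(path) -> CohortSpec:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return spec_from_dict(data)
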