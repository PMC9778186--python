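"""Configuration files and result serialization.

The on-disk configuration is a flat YAML mapping whose keys mirror the model
parameter names, a ``life_table`` list of ``[age, expected_death_age]``
pairs, and an optional ``conventions`` mapping.  Results serialize to CSV
and JSON with two-decimal presentation for currency/QALY columns in CSV and
full-precision floats in JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional, Tuple, Union

import pandas as pd
import yaml

from .model import Conventions, LifeTable, ModelParameters, ParameterError
from .scenarios import PairResult

__all__ = [
    "ConfigError",
    "params_to_dict",
    "params_from_dict",
    "write_config",
    "read_config",
    "pair_to_frame",
    "write_frame",
]

PARAM_KEYS = tuple(f.name for f in dataclasses.fields(ModelParameters))
CONVENTION_KEYS = tuple(f.name for f in dataclasses.fields(Conventions))


class ConfigError(ValueError):
    """Raised for unreadable, incomplete or invalid configuration input."""


def params_to_dict(params: ModelParameters) -> Dict[str, Any]:
    return {k: getattr(params, k) for k in PARAM_KEYS}


def params_from_dict(d: Dict[str, Any]) -> ModelParameters:
    unknown = set(d) - set(PARAM_KEYS)
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    try:
        return ModelParameters(**d)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def write_config(path: Union[str, Path],
                 params: ModelParameters,
                 life_table: LifeTable,
                 conventions: Optional[Conventions] = None) -> None:
    """Serialize a full model input to a YAML config file."""
    doc: Dict[str, Any] = params_to_dict(params)
    doc["life_table"] = [[age, death] for age, death in life_table.anchors]
    if conventions is not None:
        doc["conventions"] = dataclasses.asdict(conventions)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path: Union[str, Path]) -> Tuple[ModelParameters, LifeTable, Conventions]:
    """Parse and validate a YAML config file.

    Raises ``ConfigError`` for malformed YAML, unknown keys or values that
    violate the model invariants.
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a mapping")
    doc = dict(doc)
    anchors = doc.pop("life_table", None)
    if anchors is None:
        raise ConfigError("config is missing the 'life_table' anchor list")
    conv_doc = doc.pop("conventions", {}) or {}
    unknown_conv = set(conv_doc) - set(CONVENTION_KEYS)
    if unknown_conv:
        raise ConfigError(f"unknown convention keys: {sorted(unknown_conv)}")
    try:
        life_table = LifeTable(anchors)
        conventions = Conventions(**conv_doc)
    except (ParameterError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    params = params_from_dict(doc)
    return params, life_table, conventions


_ROW_LABELS = (
    ("npv_treatment", "treatment"),
    ("npv_patient_productivity", "productivity_loss_patient"),
    ("npv_caregiver", "productivity_loss_caregiver"),
    ("npv_surgery", "cost_operation"),
    ("npv_total", "total_cost"),
    ("qalys", "quality_of_life_qaly"),
)


def pair_to_frame(pair: PairResult) -> pd.DataFrame:
    """Component table of a pair: net-value rows x without/with columns,
    plus the cost saving, QALY benefit, ICER and corridor summary rows."""
    rows = []
    for attr, label in _ROW_LABELS:
        rows.append({
            "quantity": label,
            "without_surgery": getattr(pair.arm_without, attr),
            "with_surgery": getattr(pair.arm_with, attr),
        })
    rows.append({"quantity": "cost_saving",
                 "without_surgery": float("nan"),
                 "with_surgery": pair.cost_saving})
    rows.append({"quantity": "benefit_qaly",
                 "without_surgery": float("nan"),
                 "with_surgery": pair.qaly_gain})
    rows.append({"quantity": "icer_usd_per_qaly",
                 "without_surgery": float("nan"),
                 "with_surgery": pair.icer if pair.icer is not None else float("nan")})
    rows.append({"quantity": "corridor",
                 "without_surgery": "",
                 "with_surgery": pair.corridor})
    return pd.DataFrame(rows)


def write_frame(frame: pd.DataFrame, path: Union[str, Path], fmt: str = "csv") -> None:
    """Write a result table as CSV (2-decimal floats) or JSON (full floats)."""
    path = Path(path)
    if fmt == "csv":
        # columns mixing labels and numbers end up object-dtype, which
        # to_csv's float_format ignores; format cell-wise instead
        formatted = frame.map(
            lambda v: ("" if pd.isna(v) else f"{v:.2f}")
            if isinstance(v, float) else v)
        formatted.to_csv(path, index=False)
    elif fmt == "json":
        records = json.loads(frame.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=2))
    else:
        raise ConfigError(f"unknown output format {fmt!r}")
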