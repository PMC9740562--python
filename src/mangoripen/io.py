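"""Tidy CSV observation schema, model JSON documents and run configs.

The observation table is one row per fruit x storage day x replicate
with an exact header; pulp columns may be empty (e.g. for the Kent
reference whose pulp was not assayed), all others are required.  Model
documents are versioned JSON with the spec, coefficients, optional
alpha baselines and the fit metrics.  Run configurations round-trip
through YAML and always carry the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .published import LinearModel
from .simulate import OBSERVATION_COLUMNS

#: Pulp columns in which empty cells are permitted.
PULP_COLUMNS = ["pH", "TA", "SSC", "DM", "Lstar", "astar", "bstar", "hue_deg"]

_NUMERIC_COLUMNS = [
    "day", "replicate", "weight_g", "L_cm", "l_cm", "e_cm", *PULP_COLUMNS
]

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Observation tables
# ---------------------------------------------------------------------------


def read_observations(path, decimal: str = ".") -> pd.DataFrame:
    """Read and validate a tidy observation CSV.

    Raises :class:`SchemaError` naming the offending column/row on a
    header mismatch, a non-numeric value in a numeric field, a negative
    day, an unknown storage condition or a duplicate
    (fruit_id, day, replicate) key.
    """
    df = pd.read_csv(path, dtype=str, decimal=decimal, keep_default_na=False)
    if list(df.columns) != OBSERVATION_COLUMNS:
        raise SchemaError(
            f"{path}: header mismatch; expected {OBSERVATION_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    for col in _NUMERIC_COLUMNS:
        raw = df[col].str.strip()
        if decimal != ".":
            raw = raw.str.replace(decimal, ".", regex=False)
        empty = raw == ""
        if empty.any() and col not in PULP_COLUMNS:
            row = int(df.index[empty][0]) + 2  # header is line 1
            raise SchemaError(f"{path}: empty value in column {col!r} at line {row}")
        values = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = values.isna() & ~empty
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise SchemaError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at line {row}"
            )
        df[col] = values
    df["replicate"] = df["replicate"].astype(int)
    if (df["day"] < 0).any():
        row = int(df.index[df["day"] < 0][0]) + 2
        raise SchemaError(f"{path}: negative day at line {row}")
    bad_cond = ~df["condition"].isin(["CC", "CA"])
    if bad_cond.any():
        row = int(df.index[bad_cond][0]) + 2
        raise SchemaError(
            f"{path}: unknown condition {df['condition'][bad_cond].iloc[0]!r} "
            f"at line {row} (use CC or CA)"
        )
    key = ["fruit_id", "day", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise SchemaError(
            f"{path}: duplicate row key (fruit_id={first.fruit_id!r}, "
            f"day={first.day}, replicate={first.replicate})"
        )
    return df


def write_observations(table: pd.DataFrame, path) -> None:
    """Write a tidy observation table; write-then-read is the identity."""
    if list(table.columns) != OBSERVATION_COLUMNS:
        raise SchemaError(
            f"table columns {list(table.columns)} do not match the schema"
        )
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model documents
# ---------------------------------------------------------------------------


def save_model(results_or_dict, path, seed: int | None = None) -> None:
    """Serialize a fitted model (or its to_dict) to a JSON document."""
    doc = (
        dict(results_or_dict)
        if isinstance(results_or_dict, dict)
        else results_or_dict.to_dict()
    )
    doc["schema_version"] = MODEL_SCHEMA_VERSION
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(json.dumps(doc, indent=2, ensure_ascii=False))


def load_model(path) -> LinearModel:
    """Load a model JSON document; rejects unknown schema versions."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    for key in ("intercept", "coefficients", "form"):
        if key not in doc:
            raise SchemaError(f"{path}: model document missing {key!r}")
    return LinearModel(
        label=doc.get("label", Path(str(path)).stem),
        form=doc["form"],
        intercept=float(doc["intercept"]),
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        scope=doc.get("scope", "multi-variety"),
        baselines=doc.get("baselines"),
        metrics=doc.get("metrics"),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Seeded configuration of a simulate/fit run; YAML round-trippable."""

    seed: int
    varieties: list[str] = field(default_factory=list)  # empty = all local
    n_per_variety: int = 20
    sampling_days: list[float] = field(default_factory=lambda: [0, 4, 8, 12])
    condition: str = "CC"
    campaign: str = "C1"
    replicates: int = 2
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("run config requires a seed")
        self.seed = int(self.seed)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "seed" not in raw:
            raise SchemaError(f"{path}: config must set a seed")
        return cls(**raw)
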