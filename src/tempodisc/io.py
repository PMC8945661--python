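"""CSV schemas, validated readers/writers and configuration loading.

Every table the pipeline consumes or emits has exactly one schema;
validation is total — each offending row is reported with its (1-based,
header-exclusive) row number rather than failing on the first problem.
All files are UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "load_config",
    "get_logger",
]

logger = logging.getLogger("tempodisc")


def get_logger(verbose: bool = False) -> logging.Logger:
    """Structured logging to stderr; idempotent setup."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


class SchemaError(ValueError):
    """Raised when a table fails validation; carries row-level detail."""

    def __init__(self, table: str, problems: list[str]):
        self.table = table
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... {len(problems) - 20} more"
        super().__init__(f"table {table!r} failed validation:\n  {preview}{more}")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # 'float' | 'int' | 'str'
    required: bool = True
    lo: float | None = None
    hi: float | None = None
    choices: tuple | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    key: tuple[str, ...] = ()

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        problems: list[str] = []
        missing = [c.name for c in self.columns
                   if c.required and c.name not in df.columns]
        if missing:
            raise SchemaError(self.name, [f"missing required column(s): "
                                          f"{', '.join(missing)}"])
        out = df.copy()
        for col in self.columns:
            if col.name not in out.columns:
                continue
            series = out[col.name]
            if col.kind in ("float", "int"):
                converted = pd.to_numeric(series, errors="coerce")
                bad = converted.isna() & series.notna()
                for idx in np.flatnonzero(bad.to_numpy())[:50]:
                    problems.append(
                        f"row {idx + 1}: column {col.name!r} not numeric "
                        f"({series.iloc[idx]!r})")
                out[col.name] = converted
                if col.lo is not None:
                    for idx in np.flatnonzero(
                            (converted < col.lo).to_numpy(na_value=False))[:50]:
                        problems.append(
                            f"row {idx + 1}: {col.name}={converted.iloc[idx]} "
                            f"below {col.lo}")
                if col.hi is not None:
                    for idx in np.flatnonzero(
                            (converted > col.hi).to_numpy(na_value=False))[:50]:
                        problems.append(
                            f"row {idx + 1}: {col.name}={converted.iloc[idx]} "
                            f"above {col.hi}")
            if col.choices is not None:
                bad = ~series.isin(col.choices) & series.notna()
                for idx in np.flatnonzero(bad.to_numpy())[:50]:
                    problems.append(
                        f"row {idx + 1}: {col.name}={series.iloc[idx]!r} "
                        f"not in {col.choices}")
        if self.key and len(out):
            dups = out.duplicated(subset=list(self.key))
            for idx in np.flatnonzero(dups.to_numpy())[:50]:
                problems.append(
                    f"row {idx + 1}: duplicate key {tuple(out.loc[out.index[idx], list(self.key)])}")
        if problems:
            raise SchemaError(self.name, problems)
        return out


SCHEMAS: dict[str, TableSchema] = {
    "subjects": TableSchema(
        "subjects",
        (
            ColumnSpec("subject_id", "str"),
            ColumnSpec("sex", "str", choices=("M", "F")),
            ColumnSpec("chronological_age", "float", lo=0),
            ColumnSpec("physical_age", "float", lo=0),
            ColumnSpec("psychological_age", "float", lo=0),
            ColumnSpec("physical_health", "float", lo=1, hi=5),
            ColumnSpec("psychological_health", "float", lo=1, hi=5),
            ColumnSpec("childhood_ses", "float", lo=1, hi=7),
            ColumnSpec("lhs", "float"),
            ColumnSpec("ftp", "float"),
            ColumnSpec("age_bias", "float"),
            ColumnSpec("group_label", "str", required=False),
        ),
        key=("subject_id",),
    ),
    "choices": TableSchema(
        "choices",
        (
            ColumnSpec("subject_id", "str"),
            ColumnSpec("item_id", "str"),
            ColumnSpec("chose_ss", "int", choices=(0, 1)),
        ),
        key=("subject_id", "item_id"),
    ),
    "time_probes": TableSchema(
        "time_probes",
        (
            ColumnSpec("subject_id", "str"),
            ColumnSpec("horizon_months", "float", lo=np.nextafter(0, 1)),
            ColumnSpec("slider_mm", "float", lo=0, hi=150),
        ),
    ),
    "items": TableSchema(
        "items",
        (
            ColumnSpec("item_id", "str"),
            ColumnSpec("ss_amount", "float", lo=np.nextafter(0, 1)),
            ColumnSpec("ll_amount", "float", lo=np.nextafter(0, 1)),
            ColumnSpec("delay_days", "float", lo=np.nextafter(0, 1)),
        ),
        key=("item_id",),
    ),
    "truth": TableSchema(
        "truth",
        (
            ColumnSpec("subject_id", "str"),
            ColumnSpec("k_true", "float", lo=0),
            ColumnSpec("sigma_true", "float", lo=0),
            ColumnSpec("alpha_true", "float", lo=0),
            ColumnSpec("beta_true", "float", lo=0),
        ),
        key=("subject_id",),
    ),
}


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate a CSV against its schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return schema.validate(df)


def write_table(df: pd.DataFrame, path, schema: TableSchema | str | None = None
                ) -> Path:
    """Validate (optionally) and write a CSV."""
    if schema is not None:
        if isinstance(schema, str):
            schema = SCHEMAS[schema]
        schema.validate(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


_CONFIG_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}


def load_config(path=None, overrides: dict | None = None) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML key-value file.

    Absent keys take their defaults; unknown keys are rejected.  An
    empty (or missing) document yields the full default config.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a key-value mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    # YAML lists -> tuples so the frozen dataclass hashes/compares cleanly
    def _tuplify(v):
        if isinstance(v, list):
            return tuple(_tuplify(x) for x in v)
        return v
    data = {k: _tuplify(v) for k, v in data.items()}
    return CohortConfig(**data)


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-JSON echo of the effective configuration."""
    return dataclasses.asdict(config)
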