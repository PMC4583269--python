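"""Table readers/writers and pipeline configuration.

Inputs are comma-separated with a header row; outputs are tab-separated at
full precision (12 significant digits).  Headers are matched
case-insensitively and order-free against a named schema; validation
errors carry file, line and column so a bad cell in a 400k-row table is
findable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table failed schema validation; the message names file/line/column."""


@dataclasses.dataclass(frozen=True)
class TableSchema:
    name: str
    sep: str
    columns: dict[str, str]  # column -> 'str' | 'int' | 'float'
    key: tuple[str, ...]


SCHEMAS: dict[str, TableSchema] = {
    "blot": TableSchema("blot", ",", {
        "strain": "str", "membrane_id": "str", "replicate": "int",
        "raw_intensity": "float"}, ("strain", "membrane_id", "replicate")),
    "growth": TableSchema("growth", ",", {
        "strain": "str", "trial": "int", "time_h": "float",
        "od600": "float"}, ("strain", "trial", "time_h")),
    "fcop": TableSchema("fcop", ",", {
        "strain": "str", "replicate": "int", "fm464": "float",
        "cfu": "float"}, ("strain", "replicate")),
    "annotation": TableSchema("annotation", "\t", {
        "category_id": "str", "category_name": "str", "gene": "str"},
        ("category_id", "gene")),
    "scores": TableSchema("scores", "\t", {
        "strain": "str", "n_replicates": "int", "mean_linear": "float",
        "log10_score": "float", "cv": "float"}, ("strain",)),
    "growth_status": TableSchema("growth_status", "\t", {
        "strain": "str", "mean_rate": "float", "n_usable_trials": "int",
        "passed": "str", "reason": "str"}, ("strain",)),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a table against a named schema.

    Headers are matched case-insensitively in any order; extra columns are
    dropped with a log line.  Numeric columns are parsed strictly — the
    first unparseable or missing cell raises a :class:`SchemaError` naming
    file, line (1-based, header is line 1) and column.  Duplicate key rows
    are rejected the same way.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    raw = pd.read_csv(path, sep=schema.sep, dtype=str,
                      skipinitialspace=True)
    lower_map = {c.lower().strip(): c for c in raw.columns}
    out = {}
    for col, kind in schema.columns.items():
        if col.lower() not in lower_map:
            raise SchemaError(
                f"{path}: missing column {col!r} for schema "
                f"{schema.name!r} (found {list(raw.columns)})")
        series = raw[lower_map[col.lower()]]
        if kind == "str":
            if series.isna().any():
                line = int(series.index[series.isna()][0]) + 2
                raise SchemaError(f"{path}:{line}: empty value in "
                                  f"column {col!r}")
            out[col] = series.str.strip()
        else:
            parsed = pd.to_numeric(series, errors="coerce")
            bad = parsed.isna()
            if bad.any():
                line = int(series.index[bad][0]) + 2
                val = series[bad].iloc[0]
                raise SchemaError(f"{path}:{line}: unparseable value "
                                  f"{val!r} in column {col!r}")
            if kind == "int":
                if not np.allclose(parsed, parsed.round()):
                    line = int(series.index[parsed != parsed.round()][0]) + 2
                    raise SchemaError(f"{path}:{line}: non-integer value "
                                      f"in column {col!r}")
                out[col] = parsed.astype(int)
            else:
                out[col] = parsed.astype(float)
    extra = set(raw.columns) - {lower_map[c.lower()] for c in schema.columns}
    if extra:
        logger.info("%s: ignoring extra columns %s", path, sorted(extra))
    df = pd.DataFrame(out)
    dup = df.duplicated(subset=list(schema.key))
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}:{line}: duplicate key "
                          f"{tuple(df.loc[dup.idxmax(), list(schema.key)])}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list, one identifier per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV at 12 significant digits (lossless round-trip at the
    documented precision)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an input-dialect CSV (what the simulator emits and the
    pipeline reads)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


_CONFIG_FIELDS: dict[str, object] = dict(
    blot=None, growth=None, annotation=None, fcop=None, wt_label="WT",
    out_dir="results", n_sd_growth=1.0, n_sd_call=2.0, r2_min=0.7,
    alpha=0.05, min_replicates=2, log_average=False, pooled_rates=False,
    log_od=False, correlation="pearson", histogram=False, seed=0,
)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end pipeline run.

    ``n_sd_growth`` is the growth-rate outlier band (1 sd), ``n_sd_call``
    the vesiculation call band (2 sd), ``r2_min`` the Gompertz fit-quality
    floor and ``alpha`` the enrichment significance level.
    """

    blot: str | None = None
    growth: str | None = None
    annotation: str | None = None
    fcop: str | None = None
    wt_label: str = "WT"
    out_dir: str = "results"
    n_sd_growth: float = 1.0
    n_sd_call: float = 2.0
    r2_min: float = 0.7
    alpha: float = 0.05
    min_replicates: int = 2
    log_average: bool = False
    pooled_rates: bool = False
    log_od: bool = False
    correlation: str = "pearson"
    histogram: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.blot is None:
            raise ValueError("config: blot table path is required")
        if self.growth is None:
            raise ValueError("config: growth table path is required; "
                             "growth QC is mandatory")
        if self.n_sd_growth < 0 or self.n_sd_call < 0:
            raise ValueError("config: sd multiples must be nonnegative")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("config: r2_min must be in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("config: alpha must be in (0, 1]")
        if self.min_replicates < 2:
            raise ValueError("config: min_replicates must be >= 2")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("config: correlation must be pearson or spearman")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data).validate()
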