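"""Cohort file I/O and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import MixtureCohort

logger = logging.getLogger("ersmix")

__all__ = ["CohortSchema", "RunConfig", "read_cohort", "config_hash"]

VALID_METHODS = ("AENET-M", "AENET-I", "BART", "BKMR", "SL")


@dataclass
class CohortSchema:
    """Column declaration for a delimited cohort table."""

    exposures: list[str]
    covariates: list[str]
    outcome: str
    binary: str | None = None
    entry_age: str | None = None
    exit_age: str | None = None
    event: str | None = None
    categorical: list[str] = field(default_factory=list)
    lod: dict[str, float] = field(default_factory=dict)


@dataclass
class RunConfig:
    """End-to-end run settings: input (file or simulation), methods, split."""

    seed: int
    methods: list[str] = field(default_factory=lambda: list(VALID_METHODS))
    input_path: str | None = None
    schema: CohortSchema | None = None
    simulate: dict = field(default_factory=dict)
    split_ratio: float = 0.5
    outdir: str = "ersmix_run"
    settings: dict = field(default_factory=dict)  # per-method overrides

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        bad = [m for m in self.methods if m not in VALID_METHODS]
        if bad:
            raise ValueError(f"unknown methods: {bad}; valid: {list(VALID_METHODS)}")
        if self.input_path is not None and self.schema is None:
            raise ValueError("schema required when reading a cohort file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        schema = raw.pop("schema", None)
        if schema is not None:
            schema = CohortSchema(**schema)
        return cls(schema=schema, **raw)

    def to_jsonable(self) -> dict:
        d = {
            "seed": self.seed,
            "methods": self.methods,
            "input_path": self.input_path,
            "simulate": self.simulate,
            "split_ratio": self.split_ratio,
            "outdir": self.outdir,
            "settings": self.settings,
        }
        if self.schema is not None:
            d["schema"] = dict(self.schema.__dict__)
        return d


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration; the output path is excluded so
    identical analyses hash identically wherever they are written."""
    d = config.to_jsonable()
    d.pop("outdir", None)
    blob = json.dumps(_stringify_keys(d), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_cohort(path: str | Path, schema: CohortSchema) -> MixtureCohort:
    """Read a delimited cohort; complete cases only.

    Rows missing an exposure, the outcome, or a covariate are dropped with
    a logged count.  Non-numeric entries in numeric columns raise an error
    naming the cell.
    """
    df = pd.read_csv(path, comment="#")
    declared = (
        schema.exposures
        + schema.covariates
        + [schema.outcome]
        + [c for c in (schema.binary, schema.entry_age, schema.exit_age, schema.event) if c]
    )
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing declared columns: {missing_cols}")

    numeric_cols = schema.exposures + [schema.outcome] + [
        c for c in schema.covariates if c not in schema.categorical
    ]
    for c in numeric_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {df.loc[row, c]!r} in column {c!r}, row {row}"
            )
        df[c] = converted

    core = schema.exposures + schema.covariates + [schema.outcome]
    complete = df[core].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing exposure/outcome/covariate", n_dropped)
    df = df[complete].reset_index(drop=True)

    covariates = df[schema.covariates].copy()
    for c in schema.categorical:
        covariates[c] = pd.Categorical(covariates[c])

    survival = None
    if schema.entry_age and schema.exit_age and schema.event:
        survival = pd.DataFrame(
            {
                "entry_age": pd.to_numeric(df[schema.entry_age]),
                "exit_age": pd.to_numeric(df[schema.exit_age]),
                "event": pd.to_numeric(df[schema.event]).astype(int),
            }
        )

    exposures = df[schema.exposures].copy()
    if schema.lod:
        from .synthetic import apply_lod

        for c, lod in schema.lod.items():
            exposures[c] = apply_lod(exposures[c].to_numpy(), lod)

    cohort = MixtureCohort(
        exposures=exposures,
        covariates=covariates,
        outcome=pd.to_numeric(df[schema.outcome]).rename("outcome"),
        binary=None if schema.binary is None else df[schema.binary].astype(int),
        survival=survival,
        lod=pd.Series(schema.lod) if schema.lod else None,
    )
    cohort.validate()
    return cohort


def write_table(df: pd.DataFrame, path: str | Path, header: str) -> None:
    """CSV with a provenance header comment (seed + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
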