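"""Reading and writing the TSV exchange tables and run configuration.

The canonical exchange format is a flat tab-separated peptide table — the
common denominator of quantification reports exported by search-engine
post-processors — with the header::

    protein_id gene_symbol peptide_key is_proteotypic gg_positions
    condition bio_rep tech_rep fraction xic

``gg_positions`` is a semicolon-joined list of 1-based residue positions
(empty for unmodified peptides) and a blank or ``NA`` ``xic`` encodes a
missing intensity. Intensities round-trip bit-exactly: they are serialized
with 17 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    QUANT_COLUMNS,
    ConfigError,
    Design,
    QuantTable,
    RunConfig,
    SchemaError,
    Stage,
)

__all__ = [
    "read_quant_table",
    "write_quant_table",
    "load_config",
    "read_results",
    "write_results",
]

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _parse_gg(cell: object) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(int(tok) for tok in text.split(";"))


def _format_gg(gg: tuple[int, ...]) -> str:
    return ";".join(str(int(p)) for p in gg)


def read_quant_table(
    path: Union[str, Path],
    design: Design,
    stage: Stage = Stage.RAW,
) -> QuantTable:
    """Read a peptide quantification TSV into a validated :class:`QuantTable`.

    Row order is preserved. Raises :class:`SchemaError` if a required
    column is absent and :class:`ValidationError` (with the 1-based data
    row number) for invariant violations.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "protein_id": str,
            "gene_symbol": str,
            "peptide_key": str,
            "gg_positions": str,
            "condition": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        msg = f"{path}: missing required column(s): {', '.join(missing)}"
        logger.error(msg)
        raise SchemaError(msg)

    df = df[QUANT_COLUMNS].copy()
    df["gene_symbol"] = df["gene_symbol"].replace({"NA": ""})
    df["is_proteotypic"] = (
        df["is_proteotypic"].astype(str).str.lower().isin({"true", "1", "yes"})
    )
    df["gg_positions"] = [_parse_gg(v) for v in df["gg_positions"]]
    xic = df["xic"].astype(str).str.strip()
    df["xic"] = pd.to_numeric(xic.where(~xic.isin(_MISSING_TOKENS)), errors="coerce")
    nonnum = xic[(~xic.isin(_MISSING_TOKENS)) & df["xic"].isna()]
    if len(nonnum):
        row = int(nonnum.index[0]) + 1
        msg = f"{path}: non-numeric xic {nonnum.iloc[0]!r} on row {row}"
        logger.error(msg)
        raise SchemaError(msg)
    for col in ("bio_rep", "tech_rep", "fraction"):
        df[col] = df[col].astype(np.int64)

    table = QuantTable(design=design, data=df, stage=stage)
    try:
        table.validate()
    except Exception as exc:
        logger.error("%s: %s", path, exc)
        raise
    return table


def write_quant_table(table: QuantTable, path: Union[str, Path]) -> Path:
    """Write a :class:`QuantTable` as TSV; missing intensities become ``NA``."""
    path = Path(path)
    df = table.data.copy()
    df["gg_positions"] = [_format_gg(gg) for gg in df["gg_positions"]]
    df["is_proteotypic"] = df["is_proteotypic"].map({True: "true", False: "false"})
    df["xic"] = [
        "NA" if (v is None or (isinstance(v, float) and np.isnan(v))) else f"{v:.17g}"
        for v in df["xic"]
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, columns=QUANT_COLUMNS)
    return path


def load_config(path: Union[str, Path, None] = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or YAML mapping.

    All keys are optional; unspecified fields take the default candidate
    criteria (2-fold, alpha 0.05, fence 1.5, detection in 3 replicates).
    """
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            payload = yaml.safe_load(text) or {}
        except yaml.YAMLError:
            payload = json.loads(text)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    payload.update(overrides)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**payload)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


_RESULT_FLOATS = ["log2_fc", "se", "raw_p", "adj_p"]


def write_results(
    results: pd.DataFrame,
    path: Union[str, Path],
    full_precision: bool = False,
) -> Path:
    """Write a differential-result table as TSV.

    Floats use 6 significant digits by default so that golden-file
    comparisons are stable; pass ``full_precision=True`` for 17 digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g" if full_precision else "%.6g"
    results.to_csv(path, sep="\t", index=False, float_format=fmt, na_rep="NA")
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read a differential-result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    for col in _RESULT_FLOATS:
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df
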