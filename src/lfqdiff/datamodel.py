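"""Shared data model for label-free XIC differential-abundance analysis.

The pipeline operates on long-format peptide quantification tables: one row
per extracted-ion-chromatogram (XIC) measurement of one peptide in one
(condition, biological replicate, technical replicate, fraction) cell.
Intensities are arbitrary-unit XIC areas; missing measurements are encoded
as absent values (NaN), never zero, because only observed XICs are
quantified and zeros would corrupt log-scale statistics.

Feature levels:

* ``protein`` — quantification unit is the protein accession (whole
  proteome or pan-ubiquitin enriched proteome).
* ``site`` — quantification unit is a ubiquitylation site, i.e. a lysine
  carrying the Gly-Gly remnant (+114.0429 Da) that trypsin leaves behind
  on a ubiquitylated residue. Residue positions are 1-based in protein
  coordinates (``P00001_K343`` denotes lysine 343 of protein P00001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Design",
    "QuantTable",
    "RunConfig",
    "Stage",
    "UbiSite",
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "QUANT_COLUMNS",
    "FEATURE_LEVELS",
]


class SchemaError(ValueError):
    """A table is missing required columns or has a malformed header."""


class ValidationError(ValueError):
    """A table row or object violates a data-model invariant."""


class ConfigError(ValueError):
    """A run configuration value is out of its legal range."""


#: Canonical column order of the TSV exchange format.
QUANT_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "peptide_key",
    "is_proteotypic",
    "gg_positions",
    "condition",
    "bio_rep",
    "tech_rep",
    "fraction",
    "xic",
]

#: Columns that uniquely identify one observation within a table.
OBSERVATION_KEY = ["peptide_key", "condition", "bio_rep", "tech_rep", "fraction"]

FEATURE_LEVELS = ("protein", "site")


class Stage(str, Enum):
    """Processing stage of a :class:`QuantTable`; transitions are monotone."""

    RAW = "raw"
    FRACTIONS_SUMMED = "fractions_summed"
    TECH_MERGED = "tech_merged"
    FILTERED = "filtered"
    NORMALIZED = "normalized"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {
    Stage.RAW: 0,
    Stage.FRACTIONS_SUMMED: 1,
    Stage.TECH_MERGED: 2,
    Stage.FILTERED: 3,
    Stage.NORMALIZED: 4,
}


@dataclass(frozen=True)
class Design:
    """An experimental comparison of two conditions.

    Parameters
    ----------
    name:
        Short label; ``proteome``, ``digly`` and ``panub`` are the built-in
        designs, anything else is ``custom``.
    condition_a, condition_b:
        Condition labels. ``condition_a`` is the reference (e.g. parental
        cells); fold changes are reported as ``condition_b / condition_a``.
    n_reps_a, n_reps_b:
        Numbers of biological replicates per condition.
    n_fractions:
        Off-line fractions per replicate (1 if unfractionated).
    n_tech_reps:
        Repeat MS injections of each sample.
    feature_level:
        ``protein`` or ``site`` (diGly ubiquitylation-site level).
    """

    name: str
    condition_a: str
    condition_b: str
    n_reps_a: int
    n_reps_b: int
    n_fractions: int = 1
    n_tech_reps: int = 1
    feature_level: str = "protein"

    def __post_init__(self) -> None:
        for attr in ("n_reps_a", "n_reps_b", "n_fractions", "n_tech_reps"):
            if int(getattr(self, attr)) < 1:
                raise ValidationError(f"Design.{attr} must be >= 1")
        if self.feature_level not in FEATURE_LEVELS:
            raise ValidationError(
                f"feature_level must be one of {FEATURE_LEVELS}, "
                f"got {self.feature_level!r}"
            )
        if self.condition_a == self.condition_b:
            raise ValidationError("condition_a and condition_b must differ")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.condition_a, self.condition_b)

    def n_reps(self, condition: str) -> int:
        if condition == self.condition_a:
            return self.n_reps_a
        if condition == self.condition_b:
            return self.n_reps_b
        raise KeyError(condition)

    def swapped(self) -> "Design":
        """The same design with the roles of the two conditions exchanged."""
        return replace(
            self,
            condition_a=self.condition_b,
            condition_b=self.condition_a,
            n_reps_a=self.n_reps_b,
            n_reps_b=self.n_reps_a,
        )


@dataclass(frozen=True)
class UbiSite:
    """A ubiquitylation site: protein accession plus 1-based lysine position."""

    protein_id: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("UbiSite.position must be >= 1")

    @property
    def site_key(self) -> str:
        return f"{self.protein_id}_K{self.position}"

    @classmethod
    def parse(cls, site_key: str) -> "UbiSite":
        protein_id, _, pos = site_key.rpartition("_K")
        if not protein_id or not pos.isdigit():
            raise ValidationError(f"not a site key: {site_key!r}")
        return cls(protein_id=protein_id, position=int(pos))

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.site_key


@dataclass
class RunConfig:
    """Thresholds and knobs of one differential-analysis run.

    Defaults reproduce the candidate criteria used throughout: minimum
    2-fold change, BH-adjusted p <= 0.05, Tukey fence factor 1.5, and
    detection in at least 3 biological replicates of either condition.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.05
    fence_k: float = 1.5
    min_detect_reps: int = 3
    direction: Optional[str] = None  # "increase" | "decrease"
    seed: int = 0
    top_n: Optional[int] = None  # peptide cap per feature; None = unlimited
    scale_estimator: str = "mad"  # "mad" | "iqr"
    normalize: bool = True
    outlier_unit: str = "peptide"  # "peptide" | "observation"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ConfigError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fence_k < 0:
            raise ConfigError("fence_k must be >= 0")
        if int(self.min_detect_reps) < 1:
            raise ConfigError("min_detect_reps must be a positive integer")
        if self.direction is not None and self.direction not in (
            "increase",
            "decrease",
        ):
            raise ConfigError("direction must be 'increase' or 'decrease'")
        if self.top_n is not None and int(self.top_n) < 1:
            raise ConfigError("top_n must be a positive integer or None")
        if self.scale_estimator not in ("mad", "iqr"):
            raise ConfigError("scale_estimator must be 'mad' or 'iqr'")
        if self.outlier_unit not in ("peptide", "observation"):
            raise ConfigError("outlier_unit must be 'peptide' or 'observation'")

    @property
    def log2_fold_threshold(self) -> float:
        return math.log2(self.fold_threshold)


@dataclass
class QuantTable:
    """A validated long-format peptide quantification table.

    ``data`` holds one row per observation with the columns of
    :data:`QUANT_COLUMNS`; ``gg_positions`` cells are tuples of 1-based
    integers (empty tuple when the peptide carries no Gly-Gly remnant) and
    ``xic`` is a float with NaN for missing.
    """

    design: Design
    data: pd.DataFrame
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        if isinstance(self.stage, str):
            self.stage = Stage(self.stage)

    # -- plumbing -----------------------------------------------------------

    def copy(self) -> "QuantTable":
        return QuantTable(self.design, self.data.copy(), self.stage)

    def with_data(self, data: pd.DataFrame, stage: Stage) -> "QuantTable":
        if stage.order < self.stage.order:
            raise ValidationError(
                f"stage transition {self.stage.value} -> {stage.value} "
                "is not monotone"
            )
        return QuantTable(self.design, data.reset_index(drop=True), stage)

    @property
    def n_observations(self) -> int:
        return len(self.data)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "QuantTable":
        """Check all row-level invariants; raise on the first violation."""
        df = self.data
        missing = [c for c in QUANT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        xic = pd.to_numeric(df["xic"], errors="coerce")
        bad = df.index[(~df["xic"].isna()) & xic.isna()]
        if len(bad):
            raise ValidationError(f"non-numeric xic on row {bad[0] + 1}")
        neg = df.index[xic < 0]
        if len(neg):
            raise ValidationError(f"negative xic on row {neg[0] + 1}")

        dup = df.duplicated(subset=OBSERVATION_KEY, keep=False)
        if dup.any():
            row = int(df.index[dup][0]) + 1
            key = df.loc[df.index[dup][0], OBSERVATION_KEY].tolist()
            raise ValidationError(
                f"duplicate observation key {key} (first on row {row})"
            )

        for col in ("bio_rep", "tech_rep", "fraction"):
            if (df[col].astype(int) < 1).any():
                raise ValidationError(f"{col} must be a 1-based positive integer")

        for i, gg in enumerate(df["gg_positions"]):
            if any(int(p) < 1 for p in gg):
                raise ValidationError(f"gg position < 1 on row {i + 1}")

        if self.design.feature_level == "protein":
            pass  # gg annotations allowed but unused at protein level
        else:
            n_gg = sum(1 for gg in df["gg_positions"] if len(gg) > 0)
            if len(df) and n_gg == 0:
                raise ValidationError(
                    "site-level design but no observation carries a GG position"
                )

        known = set(self.design.conditions)
        unknown = set(df["condition"].unique()) - known
        if unknown:
            raise ValidationError(
                f"condition label(s) {sorted(unknown)} not in design "
                f"{self.design.conditions}"
            )

        if self.stage.order >= Stage.FRACTIONS_SUMMED.order:
            if (df["fraction"].astype(int) != 1).any():
                raise ValidationError("fraction != 1 after fraction summation")
        if self.stage.order >= Stage.TECH_MERGED.order:
            if (df["tech_rep"].astype(int) != 1).any():
                raise ValidationError("tech_rep != 1 after technical merge")
        return self


def empty_quant_frame() -> pd.DataFrame:
    """An empty observation frame with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "protein_id": pd.Series(dtype=str),
            "gene_symbol": pd.Series(dtype=str),
            "peptide_key": pd.Series(dtype=str),
            "is_proteotypic": pd.Series(dtype=bool),
            "gg_positions": pd.Series(dtype=object),
            "condition": pd.Series(dtype=str),
            "bio_rep": pd.Series(dtype=np.int64),
            "tech_rep": pd.Series(dtype=np.int64),
            "fraction": pd.Series(dtype=np.int64),
            "xic": pd.Series(dtype=float),
        }
    )
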