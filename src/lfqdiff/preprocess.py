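"""Raw-table preprocessing: fraction summation, technical-replicate
merging, proteotypic/shared-peptide filtering and feature-group building.

All arithmetic here is on the linear intensity scale: XICs are
chromatographic peak areas, so fractions of one peptide add and repeat
injections average as areas. The log2 transform happens afterwards, at the
feature-group stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import QuantTable, Stage, ValidationError

__all__ = [
    "FractionSummer",
    "TechnicalReplicateMerger",
    "FeatureGroup",
    "sum_fractions",
    "merge_technical_replicates",
    "build_feature_groups",
    "log2_transform",
    "preprocess_table",
]

_META_COLS = ["protein_id", "gene_symbol", "is_proteotypic", "gg_positions"]
_GROUP_KEY = ["peptide_key", "condition", "bio_rep"]


def _aggregate(table: QuantTable, key: list[str], how: str, out_stage: Stage,
               reset: dict) -> QuantTable:
    df = table.data
    # peptide metadata is constant within a peptide; keep the first row's
    grouped = df.groupby(key, sort=False, dropna=False)
    if how == "sum":
        # min_count=1 keeps all-missing cells missing instead of 0
        agg = grouped["xic"].sum(min_count=1).reset_index()
    else:
        agg = grouped["xic"].mean().reset_index()
    meta = grouped[_META_COLS].first().reset_index()
    out = meta.merge(agg, on=key)
    for col, val in reset.items():
        out[col] = np.int64(val)
    cols = [
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
    return table.with_data(out[cols], out_stage)


class FractionSummer(BaseEstimator, TransformerMixin):
    """Sum peptide XICs across off-line fractions.

    Stateless transformer: for every (peptide, condition, biological
    replicate, technical replicate) the fraction intensities are summed on
    the linear scale, skipping missing values; the result is missing only
    when every fraction is missing.
    """

    def fit(self, X: QuantTable, y=None) -> "FractionSummer":
        return self

    def transform(self, X: QuantTable) -> QuantTable:
        if X.stage != Stage.RAW:
            raise ValidationError(
                f"sum_fractions expects a raw table, got stage {X.stage.value}"
            )
        key = ["peptide_key", "condition", "bio_rep", "tech_rep"]
        return _aggregate(
            X, key, "sum", Stage.FRACTIONS_SUMMED, {"fraction": 1}
        )


class TechnicalReplicateMerger(BaseEstimator, TransformerMixin):
    """Average repeat MS injections of the same sample.

    The arithmetic mean of the non-missing technical-replicate XICs is
    taken on the linear scale; a value measured once passes through
    unchanged.
    """

    def fit(self, X: QuantTable, y=None) -> "TechnicalReplicateMerger":
        return self

    def transform(self, X: QuantTable) -> QuantTable:
        if X.stage != Stage.FRACTIONS_SUMMED:
            raise ValidationError(
                "merge_technical_replicates expects a fractions_summed table, "
                f"got stage {X.stage.value}"
            )
        return _aggregate(
            X,
            _GROUP_KEY,
            "mean",
            Stage.TECH_MERGED,
            {"tech_rep": 1, "fraction": 1},
        )


def sum_fractions(table: QuantTable) -> QuantTable:
    """Functional wrapper over :class:`FractionSummer`."""
    return FractionSummer().fit_transform(table)


def merge_technical_replicates(table: QuantTable) -> QuantTable:
    """Functional wrapper over :class:`TechnicalReplicateMerger`."""
    return TechnicalReplicateMerger().fit_transform(table)


def preprocess_table(table: QuantTable) -> QuantTable:
    """Run fraction summation and technical merging as needed."""
    if table.stage == Stage.RAW:
        table = sum_fractions(table)
    if table.stage == Stage.FRACTIONS_SUMMED:
        table = merge_technical_replicates(table)
    return table


@dataclass
class FeatureGroup:
    """All quantified evidence for one feature (protein or site).

    ``observations`` holds one row per (peptide, condition, bio_rep) with a
    non-missing intensity, columns ``peptide_key``, ``condition``,
    ``bio_rep`` and ``value`` (log2 intensity once transformed).
    ``shared_peptides`` are those with at least one observation in each
    condition — the peptides eligible for model fitting. Groups whose
    observations all fall in a single condition are ``specific_candidate``
    and skip the model.
    """

    feature_id: str
    protein_id: str
    level: str
    observations: pd.DataFrame
    shared_peptides: frozenset
    specific_candidate: bool
    detect_reps: dict[str, int]
    gene_symbol: str = ""
    is_log2: bool = False

    @property
    def peptide_keys(self) -> frozenset:
        return frozenset(self.observations["peptide_key"].unique())


def build_feature_groups(
    table: QuantTable, top_n: Optional[int] = None
) -> list[FeatureGroup]:
    """Group a tech-merged table into per-feature evidence.

    Non-proteotypic peptides are discarded. At protein level one group is
    made per accession; at site level each peptide row contributes one
    observation per GG position it carries, and one group is made per
    (protein, position). Within a group, only peptides observed in both
    conditions ("shared") are eligible for model fitting; groups observed
    in exactly one condition are retained and tagged as condition-specific
    candidates. Detection counts per condition are taken before the
    shared-peptide filter so condition-specific features keep honest
    counts. ``top_n`` optionally caps the number of shared peptides per
    group, keeping the highest-total-intensity ones (default: unlimited).
    """
    if table.stage.order < Stage.TECH_MERGED.order:
        raise ValidationError(
            f"build_feature_groups expects stage >= tech_merged, got {table.stage.value}"
        )
    design = table.design
    df = table.data
    df = df[df["is_proteotypic"] & df["xic"].notna()].copy()

    if design.feature_level == "site":
        df = df[df["gg_positions"].map(len) > 0]
        df = df.assign(_pos=df["gg_positions"]).explode("_pos")
        df["_pos"] = df["_pos"].astype(int)
        df["feature_id"] = (
            df["protein_id"].astype(str) + "_K" + df["_pos"].astype(str)
        )
    else:
        df["feature_id"] = df["protein_id"]

    # vectorized precomputation of detection counts and shared peptides
    detect_tbl = (
        df.groupby(["feature_id", "condition"])["bio_rep"].nunique().to_dict()
    )
    pep_conds = (
        df[["feature_id", "peptide_key", "condition"]]
        .drop_duplicates()
        .groupby(["feature_id", "peptide_key"])["condition"]
        .size()
    )
    shared_pairs = set(pep_conds.index[pep_conds == 2])

    groups: list[FeatureGroup] = []
    for fid, sub in df.groupby("feature_id", sort=True):
        detect = {
            c: int(detect_tbl.get((fid, c), 0)) for c in design.conditions
        }
        obs = sub[["peptide_key", "condition", "bio_rep", "xic"]].rename(
            columns={"xic": "value"}
        )
        specific = sub["condition"].nunique() == 1
        if specific:
            shared: frozenset = frozenset()
        else:
            shared = frozenset(
                p for p in obs["peptide_key"].unique() if (fid, p) in shared_pairs
            )
            if top_n is not None and len(shared) > top_n:
                totals = (
                    sub[sub["peptide_key"].isin(shared)]
                    .groupby("peptide_key")["xic"]
                    .sum()
                    .sort_values(ascending=False)
                )
                shared = frozenset(totals.index[:top_n])
        groups.append(
            FeatureGroup(
                feature_id=str(fid),
                protein_id=str(sub["protein_id"].iloc[0]),
                level=design.feature_level,
                observations=obs.reset_index(drop=True),
                shared_peptides=shared,
                specific_candidate=specific,
                detect_reps=detect,
                gene_symbol=str(sub["gene_symbol"].iloc[0]),
            )
        )
    return groups


def log2_transform(group: FeatureGroup) -> FeatureGroup:
    """Replace a group's intensities by their log2; missing stays missing."""
    if group.is_log2:
        return group
    values = group.observations["value"]
    if (values == 0).any():
        raise ValidationError(
            "zero intensity encountered: zeros must be encoded as missing "
            "upstream, they are not quantifiable XICs"
        )
    obs = group.observations.copy()
    obs["value"] = np.log2(obs["value"])
    return FeatureGroup(
        feature_id=group.feature_id,
        protein_id=group.protein_id,
        level=group.level,
        observations=obs,
        shared_peptides=group.shared_peptides,
        specific_candidate=group.specific_candidate,
        detect_reps=group.detect_reps,
        gene_symbol=group.gene_symbol,
        is_log2=True,
    )
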