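"""Candidate selection and cross-experiment integration.

A feature is a substrate candidate when its fold change is at least the
threshold in the expected direction (increase of protein abundance in the
proteome; decrease of ubiquitylation in the ubiquitylomes when the ligase
is inactivated), its BH-adjusted p-value is at or under alpha, and at
least one of its peptides was identified in the required number of
biological replicates of either condition. Both thresholds are inclusive:
"minimum 2-fold" admits a fold of exactly 2 and the significance cut
admits p = 0.05 exactly.

Condition-specific features (observed in one condition only) carry no
p-value; they join the candidate set when their absence/presence pattern
matches the direction — present only in condition b counts as an increase
in b, present only in condition a as a decrease — and they meet the
detection filter in the condition where they exist.

Site-level candidate sets are collapsed to their distinct proteins before
any cross-experiment intersection, keeping the site-to-protein mapping for
provenance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import ConfigError, RunConfig, ValidationError

__all__ = [
    "CandidateSet",
    "IntegrationReport",
    "CandidateSelector",
    "select_candidates",
    "collapse_sites_to_proteins",
    "intersect_candidates",
    "format_significance_stars",
    "build_heatmap_table",
]


@dataclass
class CandidateSet:
    """A directional, thresholded selection of differential results."""

    experiment: str
    direction: str
    fold_threshold: float
    alpha: float
    min_detect_reps: int
    members: pd.DataFrame  # DiffResult rows of all members
    level: str = "protein"

    @property
    def member_ids(self) -> list[str]:
        return sorted(self.members["feature_id"].tolist())

    @property
    def specific_member_ids(self) -> list[str]:
        mask = self.members["specific_flag"] != "none"
        return sorted(self.members.loc[mask, "feature_id"].tolist())

    def __len__(self) -> int:
        return len(self.members)


class CandidateSelector(BaseEstimator):
    """Apply the candidate criteria to a differential-result table.

    Parameters mirror the run configuration: ``fold_threshold`` (>= on the
    linear fold), ``alpha`` (<= on the adjusted p), ``min_detect_reps``
    (detection in either condition) and ``direction``.

    ``fit`` stores the resulting :class:`CandidateSet` as
    ``candidate_set_``; ``transform`` returns the member rows.
    """

    def __init__(
        self,
        direction: Optional[str] = None,
        fold_threshold: float = 2.0,
        alpha: float = 0.05,
        min_detect_reps: int = 3,
        experiment: str = "experiment",
    ):
        self.direction = direction
        self.fold_threshold = fold_threshold
        self.alpha = alpha
        self.min_detect_reps = min_detect_reps
        self.experiment = experiment

    def fit(self, X: pd.DataFrame, y=None) -> "CandidateSelector":
        if self.direction not in ("increase", "decrease"):
            raise ConfigError(
                "direction must be set to 'increase' or 'decrease' "
                "before selecting candidates"
            )
        results = X
        lf = math.log2(self.fold_threshold)
        increase = self.direction == "increase"

        tested = results["specific_flag"] == "none"
        has_p = results["adj_p"].notna()
        sig = results["adj_p"] <= self.alpha
        fold_ok = (
            results["log2_fc"] >= lf if increase else results["log2_fc"] <= -lf
        )
        detect_ok = (
            results[["detect_reps_a", "detect_reps_b"]].max(axis=1)
            >= self.min_detect_reps
        )
        tested_members = tested & has_p & sig & fold_ok & detect_ok

        # present-only-in-b is an increase in b; only-in-a a decrease
        spec_flag = "b_only" if increase else "a_only"
        spec_detect = (
            results["detect_reps_b"] if increase else results["detect_reps_a"]
        ) >= self.min_detect_reps
        specific_members = (results["specific_flag"] == spec_flag) & spec_detect

        members = results[tested_members | specific_members].copy()
        members = members.sort_values("feature_id", kind="mergesort").reset_index(
            drop=True
        )
        level = (
            str(results["level"].iloc[0]) if len(results) and "level" in results
            else "protein"
        )
        self.candidate_set_ = CandidateSet(
            experiment=self.experiment,
            direction=self.direction,
            fold_threshold=self.fold_threshold,
            alpha=self.alpha,
            min_detect_reps=self.min_detect_reps,
            members=members,
            level=level,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.candidate_set_.members


def select_candidates(
    results: pd.DataFrame,
    config: RunConfig,
    experiment: str = "experiment",
    direction: Optional[str] = None,
) -> CandidateSet:
    """Functional wrapper over :class:`CandidateSelector`."""
    sel = CandidateSelector(
        direction=direction or config.direction,
        fold_threshold=config.fold_threshold,
        alpha=config.alpha,
        min_detect_reps=config.min_detect_reps,
        experiment=experiment,
    )
    return sel.fit(results).candidate_set_


def collapse_sites_to_proteins(
    candidate_set: CandidateSet,
) -> tuple[set[str], pd.DataFrame]:
    """Project a site-level candidate set onto its distinct proteins.

    Returns the protein-id set and the site-to-protein mapping kept for
    provenance. Protein-level sets pass through (identity mapping).
    """
    members = candidate_set.members
    if candidate_set.level == "site" and "protein_id" in members:
        mapping = members[["feature_id", "protein_id"]].rename(
            columns={"feature_id": "site_key"}
        )
    else:
        mapping = pd.DataFrame(
            {
                "site_key": members["feature_id"],
                "protein_id": members.get("protein_id", members["feature_id"]),
            }
        )
    mapping = mapping.sort_values("site_key").reset_index(drop=True)
    return set(mapping["protein_id"]), mapping


@dataclass
class IntegrationReport:
    """Venn-style overlaps of protein-level candidate sets.

    ``counts`` holds per-experiment candidate counts; ``pairwise`` and
    ``common`` the sorted member lists of every pairwise and the full
    intersection.
    """

    experiments: list[str]
    counts: dict[str, int]
    pairwise: dict[tuple[str, str], list[str]]
    common: list[str]
    site_maps: dict[str, pd.DataFrame] = field(default_factory=dict)

    def overlap(self, a: str, b: str) -> list[str]:
        return self.pairwise.get((a, b), self.pairwise.get((b, a), []))

    def to_json_dict(self) -> dict:
        return {
            "experiments": self.experiments,
            "counts": self.counts,
            "pairwise": {
                " & ".join(k): v for k, v in self.pairwise.items()
            },
            "common": self.common,
        }


def intersect_candidates(
    protein_sets: Mapping[str, Iterable[str]],
    site_maps: Optional[dict[str, pd.DataFrame]] = None,
) -> IntegrationReport:
    """All pairwise and the full intersection of protein-level sets.

    ``protein_sets`` maps experiment label to an iterable of protein ids
    (site sets must be collapsed first). Output member lists are sorted
    lexicographically for deterministic reports.
    """
    labels = list(protein_sets)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate experiment labels")
    sets = {k: set(v) for k, v in protein_sets.items()}
    pairwise = {
        (a, b): sorted(sets[a] & sets[b])
        for a, b in itertools.combinations(labels, 2)
    }
    common = sorted(set.intersection(*sets.values())) if sets else []
    return IntegrationReport(
        experiments=labels,
        counts={k: len(v) for k, v in sets.items()},
        pairwise=pairwise,
        common=common,
        site_maps=site_maps or {},
    )


def format_significance_stars(p: Optional[float]) -> str:
    """Star annotation of a p-value: *** <= 0.001, ** <= 0.01, * <= 0.05."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if not 0 <= p <= 1:
        raise ValidationError("p-value must lie in [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def build_heatmap_table(
    results_by_experiment: Mapping[str, pd.DataFrame],
    report: IntegrationReport,
) -> pd.DataFrame:
    """Fold-change/direction/significance matrix of all candidate features.

    Rows are the union of candidate features across experiments, indexed
    by (protein, feature); site rows repeat their protein once per site.
    Each experiment contributes three columns: the linear fold
    ``2**|log2_fc|``, the direction (``increase``/``decrease``/
    ``specific``) and the significance stars of the adjusted p-value.
    Cells of experiments where the feature was not quantified stay empty.
    """
    # collect candidate features per protein
    row_keys: list[tuple[str, str]] = []
    for exp, df in results_by_experiment.items():
        for _, r in df.iterrows():
            key = (str(r["protein_id"]), str(r["feature_id"]))
            if key not in row_keys:
                row_keys.append(key)
    row_keys.sort()

    rows = []
    for protein_id, feature_id in row_keys:
        row: dict = {"protein_id": protein_id, "feature_id": feature_id}
        for exp, df in results_by_experiment.items():
            sub = df[df["feature_id"] == feature_id]
            if not len(sub):
                # a site row may still be quantified at protein level
                sub = df[
                    (df["protein_id"] == protein_id)
                    & (df["level"] == "protein")
                ]
            if not len(sub):
                row[f"{exp}_fold"] = np.nan
                row[f"{exp}_direction"] = ""
                row[f"{exp}_stars"] = ""
                continue
            r = sub.iloc[0]
            if r["specific_flag"] != "none":
                row[f"{exp}_fold"] = np.nan
                row[f"{exp}_direction"] = "specific"
                row[f"{exp}_stars"] = ""
            else:
                lfc = float(r["log2_fc"])
                row[f"{exp}_fold"] = float(2.0 ** abs(lfc))
                row[f"{exp}_direction"] = "increase" if lfc >= 0 else "decrease"
                row[f"{exp}_stars"] = format_significance_stars(r["adj_p"])
        rows.append(row)
    return pd.DataFrame(rows)
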