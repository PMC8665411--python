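"""Statistical core: Tukey-fences outlier removal, the peptide-adjusted
linear model per feature, Benjamini-Hochberg FDR and condition-specific
feature handling.

Model
-----
For one feature (protein or ubiquitylation site) with peptides ``p``,
conditions ``c`` in {a, b} and biological replicates ``r``, the fixed
effects model::

    log2 x_{p,c,r} = mu + beta_p + delta * 1[c == b] + eps

is fitted by ordinary least squares. The peptide main effects absorb
ionization-efficiency differences between peptides; biological replicates
enter as independent observations (the residual term). ``delta`` is the
log2 fold change of condition b over condition a; its two-sided p-value
comes from the t distribution with the residual degrees of freedom. For a
single-peptide feature this reduces exactly to a two-sample equal-variance
t test.

Outlier peptides are removed per feature and per condition before
fitting: observations are centered on their peptide's mean across all
replicates, and within each (feature, condition) cell Tukey's fences
``[Q1 - k*IQR, Q3 + k*IQR]`` (quartiles by linear interpolation) decide
what is discarded. The default removal unit is the peptide — within a
cell, each peptide is summarized by its mean centered residual and
peptides outside the fences lose all their observations in that cell —
because an aberrant peptide (interference, mis-integration) contaminates
all its measurements at once, and because fencing individual observations
trims the tails of well-behaved noise and systematically understates the
residual variance. Observation-level fencing is available as an option.
Cells with fewer than 4 units pass through unfiltered.

Features observed in only one condition bypass the model: they carry no
fold change or p-value and reach candidate selection on the detection
filter alone. The BH family counts only features that were actually
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    Design,
    QuantTable,
    RunConfig,
    Stage,
    ValidationError,
)
from .normalize import MedianScaleNormalizer, NormalizationReport
from .preprocess import (
    FeatureGroup,
    build_feature_groups,
    log2_transform,
    preprocess_table,
)

__all__ = [
    "tukey_fences_filter",
    "fit_feature_model",
    "flag_condition_specific",
    "adjust_bh",
    "DifferentialAbundance",
    "run_differential",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "feature_id",
    "protein_id",
    "gene_symbol",
    "level",
    "log2_fc",
    "se",
    "raw_p",
    "adj_p",
    "n_peptides_used",
    "n_obs_removed_outlier",
    "detect_reps_a",
    "detect_reps_b",
    "specific_flag",
]


def tukey_fences_filter(values: Sequence[float], fence_k: float = 1.5) -> np.ndarray:
    """Boolean retention mask under Tukey's fences.

    A value is retained iff it lies within ``[Q1 - k*IQR, Q3 + k*IQR]``
    (inclusive), with quartiles by linear interpolation (the convention
    where Q1 of {1, 2, 3, 4} is 1.75). Sets of fewer than 4 values are
    returned unfiltered: quartiles of so few points are meaningless.
    """
    if fence_k < 0:
        raise ValidationError("fence_k must be >= 0")
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return np.ones(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - fence_k * iqr) & (v <= q3 + fence_k * iqr)


@dataclass
class FeatureFit:
    log2_fc: float
    se: float
    raw_p: float
    n_peptides_used: int
    df_resid: int


def _fit_arrays(y: np.ndarray, pep_codes: np.ndarray, n_pep: int,
                is_b: np.ndarray) -> FeatureFit:
    """OLS fit of intercept + peptide dummies + condition indicator."""
    n = y.size
    X = np.zeros((n, n_pep + 1))
    X[:, 0] = 1.0
    mask = pep_codes > 0
    X[np.nonzero(mask)[0], pep_codes[mask]] = 1.0
    X[:, -1] = is_b

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - int(rank)
    delta = float(beta[-1])

    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    unit_var = float(xtx_inv[-1, -1])

    if df > 0:
        sigma2 = rss / df
        se = float(np.sqrt(max(sigma2, 0.0) * unit_var))
        if se == 0.0:
            raw_p = 0.0 if delta != 0.0 else 1.0
        else:
            raw_p = float(2.0 * stats.t.sf(abs(delta) / se, df))
    else:
        se = np.nan
        raw_p = np.nan
    return FeatureFit(
        log2_fc=delta,
        se=se,
        raw_p=raw_p,
        n_peptides_used=n_pep,
        df_resid=df,
    )


def fit_feature_model(
    observations: pd.DataFrame, condition_b: str
) -> FeatureFit:
    """Least-squares fit of the peptide + condition model for one feature.

    ``observations`` must have columns ``peptide_key``, ``condition`` and
    ``value`` (log2 intensity), with both conditions present. Returns the
    condition coefficient (log2 fold change b/a), its standard error, the
    two-sided t-test p-value and bookkeeping counts. With zero residual
    degrees of freedom the p-value is NaN (the estimate is still
    reported); a zero standard error with positive df yields p = 0 for a
    nonzero effect and p = 1 otherwise.
    """
    y = observations["value"].to_numpy(dtype=float)
    peptides = sorted(observations["peptide_key"].unique())
    codes = observations["peptide_key"].map(
        {p: i for i, p in enumerate(peptides)}
    ).to_numpy(dtype=np.intp)
    is_b = (observations["condition"] == condition_b).to_numpy(dtype=float)
    return _fit_arrays(y, codes, len(peptides), is_b)


def flag_condition_specific(group: FeatureGroup, design: Design) -> str:
    """Classify a specific-candidate group as ``a_only`` or ``b_only``."""
    conds = set(group.observations["condition"].unique())
    if conds == {design.condition_a}:
        return "a_only"
    if conds == {design.condition_b}:
        return "b_only"
    raise ValidationError(
        f"group {group.feature_id} has observations in both conditions; "
        "it must not be tagged condition-specific"
    )


def adjust_bh(raw_pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing p-values are excluded from the family (``m`` counts only the
    tested hypotheses) and returned as NaN in place.
    """
    p = np.asarray(pd.Series(raw_pvals, dtype=float))
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _peptide_centered_residuals(obs: pd.DataFrame) -> np.ndarray:
    """Observation minus its peptide's mean across all replicates."""
    means = obs.groupby("peptide_key")["value"].transform("mean")
    return (obs["value"] - means).to_numpy(dtype=float)


class DifferentialAbundance(BaseEstimator):
    """Per-feature differential-abundance analysis of a quantification table.

    ``fit`` takes a :class:`~lfqdiff.datamodel.QuantTable` (raw tables are
    preprocessed automatically) and produces ``results_``, one row per
    feature with the log2 fold change (condition_b over condition_a), its
    standard error, raw and BH-adjusted p-values, peptide/outlier
    bookkeeping, per-condition detection counts and the
    condition-specific flag.

    Parameters
    ----------
    fence_k:
        Tukey fence factor for outlier removal (1.5 by default).
    outlier_unit:
        ``"peptide"`` (default): within each (feature, condition) cell the
        fences are applied to the peptides' mean centered residuals and an
        outlying peptide loses all its observations in that cell.
        ``"observation"``: the fences are applied to the individual
        centered residuals.
    normalize:
        Apply median-and-scale normalization across replicates before
        fitting (on by default; turn off for data already normalized).
    scale_estimator:
        Scale estimator of the normalizer, ``"mad"`` or ``"iqr"``.
    top_n:
        Optional cap on shared peptides per feature (None = all).

    Attributes
    ----------
    results_ : pandas.DataFrame
    normalization_report_ : NormalizationReport or None
    n_features_ : int
    """

    def __init__(
        self,
        fence_k: float = 1.5,
        outlier_unit: str = "peptide",
        normalize: bool = True,
        scale_estimator: str = "mad",
        top_n: Optional[int] = None,
    ):
        self.fence_k = fence_k
        self.outlier_unit = outlier_unit
        self.normalize = normalize
        self.scale_estimator = scale_estimator
        self.top_n = top_n

    # -- internals ----------------------------------------------------------

    def _outlier_keep_mask(
        self, resid: np.ndarray, pep_codes: np.ndarray, n_pep: int,
        cond_masks: list[np.ndarray],
    ) -> np.ndarray:
        """Retention mask under Tukey's fences, per condition cell."""
        keep = np.ones(resid.size, dtype=bool)
        for cell in cond_masks:
            if not cell.any():
                continue
            if self.outlier_unit == "observation":
                keep[cell] = tukey_fences_filter(resid[cell], self.fence_k)
            else:
                counts = np.bincount(pep_codes[cell], minlength=n_pep)
                present = np.nonzero(counts)[0]
                if present.size < 4:
                    continue
                sums = np.bincount(
                    pep_codes[cell], weights=resid[cell], minlength=n_pep
                )
                means = sums[present] / counts[present]
                ok = tukey_fences_filter(means, self.fence_k)
                bad_peps = present[~ok]
                if bad_peps.size:
                    keep[cell & np.isin(pep_codes, bad_peps)] = False
        return keep

    def fit(self, X: QuantTable, y=None) -> "DifferentialAbundance":
        if self.outlier_unit not in ("peptide", "observation"):
            raise ValidationError(
                "outlier_unit must be 'peptide' or 'observation'"
            )
        table = preprocess_table(X)
        design = table.design
        groups = [
            log2_transform(g)
            for g in build_feature_groups(table, top_n=self.top_n)
        ]
        self.n_features_ = len(groups)

        # normalization over the total signal (all observations pooled)
        self.normalization_report_ = None
        if self.normalize and groups:
            sizes = [len(g.observations) for g in groups]
            pooled = pd.concat(
                [g.observations for g in groups], ignore_index=True
            )
            norm = MedianScaleNormalizer(scale_estimator=self.scale_estimator)
            pooled = norm.fit(pooled).transform(pooled)
            self.normalization_report_ = norm.report_
            bounds = np.concatenate([[0], np.cumsum(sizes)])
            for i, g in enumerate(groups):
                g.observations = pooled.iloc[
                    bounds[i] : bounds[i + 1]
                ].reset_index(drop=True)

        rows = []
        raw_ps = []
        for g in groups:
            row = {
                "feature_id": g.feature_id,
                "protein_id": g.protein_id,
                "gene_symbol": g.gene_symbol,
                "level": g.level,
                "log2_fc": np.nan,
                "se": np.nan,
                "raw_p": np.nan,
                "adj_p": np.nan,
                "n_peptides_used": 0,
                "n_obs_removed_outlier": 0,
                "detect_reps_a": g.detect_reps.get(design.condition_a, 0),
                "detect_reps_b": g.detect_reps.get(design.condition_b, 0),
                "specific_flag": "none",
            }
            if g.specific_candidate:
                row["specific_flag"] = flag_condition_specific(g, design)
                rows.append(row)
                raw_ps.append(np.nan)
                continue

            obs = g.observations
            in_shared = obs["peptide_key"].isin(g.shared_peptides).to_numpy()
            if not in_shared.any():
                rows.append(row)
                raw_ps.append(np.nan)
                continue

            vals = obs["value"].to_numpy(dtype=float)[in_shared]
            pep_codes, _ = pd.factorize(
                obs["peptide_key"].to_numpy()[in_shared], sort=True
            )
            n_pep = int(pep_codes.max()) + 1
            is_b = (
                obs["condition"].to_numpy()[in_shared] == design.condition_b
            )

            # peptide-centered residuals across all replicates
            counts = np.bincount(pep_codes, minlength=n_pep)
            sums = np.bincount(pep_codes, weights=vals, minlength=n_pep)
            resid = vals - (sums / counts)[pep_codes]

            keep = self._outlier_keep_mask(
                resid, pep_codes, n_pep, [~is_b, is_b]
            )
            row["n_obs_removed_outlier"] = int((~keep).sum())

            # outlier removal may strip a peptide of one condition entirely
            has_a = np.bincount(pep_codes[keep & ~is_b], minlength=n_pep) > 0
            has_b = np.bincount(pep_codes[keep & is_b], minlength=n_pep) > 0
            still_shared = has_a & has_b
            keep &= still_shared[pep_codes]

            n_a = int((keep & ~is_b).sum())
            n_b = int((keep & is_b).sum())
            if not still_shared.any() or n_a < 2 or n_b < 2:
                logger.info(
                    "feature %s: insufficient data after filtering "
                    "(%d shared peptides, %d/%d observations)",
                    g.feature_id,
                    int(still_shared.sum()),
                    n_a,
                    n_b,
                )
                rows.append(row)
                raw_ps.append(np.nan)
                continue

            sub_codes, _ = pd.factorize(pep_codes[keep], sort=True)
            fit = _fit_arrays(
                vals[keep],
                sub_codes,
                int(sub_codes.max()) + 1,
                is_b[keep].astype(float),
            )
            row["log2_fc"] = fit.log2_fc
            row["se"] = fit.se
            row["raw_p"] = fit.raw_p
            row["n_peptides_used"] = fit.n_peptides_used
            rows.append(row)
            raw_ps.append(fit.raw_p)

        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        results["adj_p"] = adjust_bh(raw_ps) if len(rows) else []
        results = results.sort_values("feature_id", kind="mergesort").reset_index(
            drop=True
        )
        self.results_ = results
        self.design_ = design
        return self


def run_differential(table: QuantTable, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Run the full per-feature differential analysis on a table.

    Raw tables are preprocessed (fractions summed, technical replicates
    merged) first; the stages then run in order: feature-group building,
    log2 transform, median-and-scale normalization over the total signal,
    peptide-centered Tukey-fences outlier removal, the peptide-adjusted
    linear model (or the condition-specific flag) and BH adjustment.
    """
    config = config or RunConfig()
    est = DifferentialAbundance(
        fence_k=config.fence_k,
        outlier_unit=config.outlier_unit,
        normalize=config.normalize,
        scale_estimator=config.scale_estimator,
        top_n=config.top_n,
    )
    return est.fit(table).results_
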