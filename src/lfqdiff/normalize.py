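"""Median-and-scale normalization across biological replicates.

Each biological replicate (one MS sample) carries its own systematic
offset — loading differences, ionization drift — so the log2 intensities
of every replicate are brought to a common location and spread before any
feature is tested. "Total signal" means all quantified peptide
observations of the replicate, not per-feature subsets.

For replicate ``j`` with location ``m_j`` (median of its log2 intensities)
and scale ``s_j`` (MAD scaled by 1.4826 by default, IQR optional)::

    x' = (x - m_j) / s_j * s_bar + m_bar

where ``m_bar`` and ``s_bar`` are the across-replicate means of the
locations and scales, so normalized intensities stay in the familiar
range. After the transform every replicate has the same median and the
same robust scale.

A normality check per replicate (D'Agostino-Pearson omnibus test) is
computed and logged in the report; it is advisory only and never gates the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import ValidationError

__all__ = [
    "MedianScaleNormalizer",
    "NormalizationReport",
    "check_normality",
    "normalize_median_scale",
]

_MIN_NORMALITY_N = 8


def check_normality(values) -> tuple[Optional[float], Optional[float]]:
    """Advisory normality check of one replicate's log2 intensities.

    Returns the D'Agostino-Pearson omnibus statistic and p-value, or
    ``(None, None)`` when fewer than 8 non-missing values are available
    ("insufficient data" — logged, never raised).
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < _MIN_NORMALITY_N:
        return None, None
    stat, p = stats.normaltest(v)
    return float(stat), float(p)


def _scale(values: np.ndarray, estimator: str) -> float:
    if estimator == "mad":
        return float(stats.median_abs_deviation(values, scale="normal"))
    if estimator == "iqr":
        q1, q3 = np.percentile(values, [25, 75])
        return float(q3 - q1)
    raise ValidationError(f"unknown scale estimator {estimator!r}")


@dataclass
class NormalizationReport:
    """Per-replicate diagnostics of one normalization pass.

    One row per replicate: observation count, pre/post median, pre/post
    scale and the advisory normality statistic/p-value (NaN with note
    ``insufficient data`` below 8 observations).
    """

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


class MedianScaleNormalizer(BaseEstimator, TransformerMixin):
    """Location/scale normalization of log2 intensities per replicate.

    Operates on a long frame with columns ``condition``, ``bio_rep`` and
    ``value`` (log2 intensity). ``fit`` learns per-replicate medians and
    robust scales plus the common anchors; ``transform`` applies them.

    Parameters
    ----------
    scale_estimator:
        ``"mad"`` (median absolute deviation x 1.4826, the default) or
        ``"iqr"``.

    Attributes
    ----------
    locations_, scales_ : dict
        Per-replicate ``(condition, bio_rep) ->`` median and scale.
    anchor_location_, anchor_scale_ : float
        Across-replicate means the output is re-anchored to.
    report_ : NormalizationReport
    """

    def __init__(self, scale_estimator: str = "mad"):
        self.scale_estimator = scale_estimator

    def fit(self, X: pd.DataFrame, y=None) -> "MedianScaleNormalizer":
        locations: dict = {}
        scales: dict = {}
        rows = []
        for key, sub in X.groupby(["condition", "bio_rep"], sort=True):
            v = sub["value"].dropna().to_numpy(dtype=float)
            if v.size < 2:
                raise ValidationError(
                    f"replicate {key} has {v.size} observation(s); "
                    "cannot estimate a scale"
                )
            m = float(np.median(v))
            s = _scale(v, self.scale_estimator)
            if s == 0.0:
                if np.unique(v).size > 1:
                    raise ValidationError(
                        f"degenerate scale 0 in replicate {key} despite "
                        "multiple distinct values; normalization undefined"
                    )
                raise ValidationError(
                    f"replicate {key} has a single distinct value; "
                    "scale normalization undefined"
                )
            locations[key] = m
            scales[key] = s
            stat, p = check_normality(v)
            rows.append(
                {
                    "condition": key[0],
                    "bio_rep": key[1],
                    "n": int(v.size),
                    "pre_median": m,
                    "pre_scale": s,
                    "normality_stat": np.nan if stat is None else stat,
                    "normality_p": np.nan if p is None else p,
                    "normality_note": "" if stat is not None else "insufficient data",
                }
            )
        self.locations_ = locations
        self.scales_ = scales
        self.anchor_location_ = float(np.mean(list(locations.values())))
        self.anchor_scale_ = float(np.mean(list(scales.values())))
        self._report_rows = rows
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        keys = list(zip(out["condition"], out["bio_rep"]))
        m = np.array([self.locations_[k] for k in keys])
        s = np.array([self.scales_[k] for k in keys])
        out["value"] = (
            (out["value"].to_numpy(dtype=float) - m) / s * self.anchor_scale_
            + self.anchor_location_
        )
        # complete the report with post statistics
        rows = []
        for row in self._report_rows:
            key = (row["condition"], row["bio_rep"])
            sub = out[(out["condition"] == key[0]) & (out["bio_rep"] == key[1])]
            v = sub["value"].dropna().to_numpy(dtype=float)
            post = dict(row)
            post["post_median"] = float(np.median(v)) if v.size else np.nan
            post["post_scale"] = _scale(v, self.scale_estimator) if v.size else np.nan
            rows.append(post)
        self.report_ = NormalizationReport(pd.DataFrame(rows))
        return out


def normalize_median_scale(
    X: pd.DataFrame, scale_estimator: str = "mad"
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Functional wrapper: fit and apply :class:`MedianScaleNormalizer`."""
    norm = MedianScaleNormalizer(scale_estimator=scale_estimator)
    out = norm.fit(X).transform(X)
    return out, norm.report_
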