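"""Exposure-error statistics: hybrid tier, ND/NAD, CV, quintile contingency.

The six exposure metrics (outdoor/indoor × background, on-road, hybrid) are
compared against a standard — by default the hybrid-based indoor
concentration, the richest tier. Individual-level error is summarized by the
normalized difference ND = (C_x − C_s)/C_s·100% (signed bias) and normalized
absolute difference NAD = |C_x − C_s|/C_s·100% (magnitude of deviation);
population-level agreement by cross-classifying blocks into quintiles of the
annual average under each metric. Spatial and temporal variability are
summarized by the coefficient of variation σ/μ across blocks per hour and
across hours per block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import ConcentrationField

logger = logging.getLogger(__name__)

#: Standard metric all others are compared against.
STANDARD_TIER = "indoor_hybrid"

#: Denominator exclusion threshold (μg/m³): block-hours where the standard is
#: essentially zero (remote blocks of an on-road-only tier) are excluded from
#: ND/NAD and counted.
ND_EPSILON = 1e-9


def combine_hybrid(
    stok_field: ConcentrationField, onroad_field: ConcentrationField
) -> ConcentrationField:
    """Hybrid tier: elementwise sum of background and on-road concentration.

    For a daily-cadence background (EC-like) the daily value has already been
    broadcast to hours, so the hybrid's within-day structure comes from the
    on-road term alone.
    """
    if not stok_field.aligned_with(onroad_field):
        raise ValueError("background and on-road fields are not on the same grid")
    out = stok_field.copy_with(stok_field.values + onroad_field.values,
                               tier="outdoor_hybrid")
    return out


# ----------------------------------------------------------------------
# ND / NAD
# ----------------------------------------------------------------------
def normalized_difference(c_x, c_s, epsilon: float = ND_EPSILON):
    """ND in percent; entries with standard ≤ epsilon (or NaN) come back NaN."""
    c_x = np.asarray(c_x, dtype=float)
    c_s = np.asarray(c_s, dtype=float)
    ok = np.isfinite(c_s) & np.isfinite(c_x) & (c_s > epsilon)
    out = np.full(np.broadcast(c_x, c_s).shape, np.nan)
    out[ok] = (np.broadcast_to(c_x, out.shape)[ok] - np.broadcast_to(c_s, out.shape)[ok]) \
        / np.broadcast_to(c_s, out.shape)[ok] * 100.0
    return float(out) if out.ndim == 0 else out


def normalized_absolute_difference(c_x, c_s, epsilon: float = ND_EPSILON):
    """NAD in percent: |ND| pointwise."""
    return np.abs(normalized_difference(c_x, c_s, epsilon))


# ----------------------------------------------------------------------
# coefficient of variation
# ----------------------------------------------------------------------
def coefficient_of_variation(values, ddof: int = 0) -> float:
    """CV = σ/μ with population σ by default; NaN when μ ≤ 0 or all-missing."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    mu = v.mean()
    if mu <= 0:
        logger.debug("CV undefined for non-positive mean %.3g", mu)
        return float("nan")
    return float(v.std(ddof=ddof) / mu)


@dataclass
class CVSeries:
    axis: str                       # "spatial" | "temporal"
    values: np.ndarray              # one per hour (spatial) or per block (temporal)
    labels: np.ndarray = dc_field(default=None)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def spatial_cv(field: ConcentrationField, ddof: int = 0) -> CVSeries:
    """One CV across blocks for each hour."""
    vals = np.array([
        coefficient_of_variation(field.values[:, j], ddof) for j in range(field.n_hours)
    ])
    return CVSeries(axis="spatial", values=vals, labels=np.asarray(field.hours))


def temporal_cv(field: ConcentrationField, ddof: int = 0) -> CVSeries:
    """One CV across hours for each block."""
    vals = np.array([
        coefficient_of_variation(field.values[i, :], ddof) for i in range(field.n_blocks)
    ])
    return CVSeries(axis="temporal", values=vals, labels=field.block_ids)


# ----------------------------------------------------------------------
# annual averages and quintile contingency
# ----------------------------------------------------------------------
def annual_average(field: ConcentrationField) -> pd.Series:
    """Per-block mean over available (non-missing) hours."""
    with np.errstate(invalid="ignore"):
        means = np.nanmean(field.values, axis=1)
    n_empty = int(np.isnan(means).sum())
    if n_empty:
        logger.warning("%d blocks have no valid hours; excluded from annual average", n_empty)
    return pd.Series(means, index=field.block_ids, name=f"{field.tier}_annual")


def _quintile_labels(x: np.ndarray) -> np.ndarray:
    """Quintile index 0..4 per value, cuts at the 20/40/60/80th percentiles.

    Cut points use linear-interpolation percentiles; a value exactly at a cut
    stays in the lower quintile.
    """
    cuts = np.percentile(x, [20, 40, 60, 80])
    lab = np.searchsorted(cuts, x, side="left")
    if len(np.unique(lab)) < 5:
        raise ValueError("degenerate quintiles: massive ties leave an empty quintile")
    return lab


def quintile_contingency(
    metric_means: pd.Series, standard_means: pd.Series
) -> tuple[np.ndarray, dict]:
    """5×5 table: cell (i, j) = % of blocks in standard-quintile j that land in
    metric-quintile i. Each column sums to 100; a perfect metric puts 100% on
    the diagonal.

    Returns the percentage table and a dict with each vector's cut points.
    """
    m = metric_means.loc[standard_means.index].to_numpy(dtype=float)
    s = standard_means.to_numpy(dtype=float)
    ok = np.isfinite(m) & np.isfinite(s)
    m, s = m[ok], s[ok]
    if len(s) < 5:
        raise ValueError("need at least 5 blocks for quintiles")
    qm = _quintile_labels(m)
    qs = _quintile_labels(s)
    table = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            table[i, j] = np.sum((qm == i) & (qs == j))
    col = table.sum(axis=0)
    pct = 100.0 * table / col[None, :]
    cuts = {
        "metric": np.percentile(m, [20, 40, 60, 80]),
        "standard": np.percentile(s, [20, 40, 60, 80]),
    }
    return pct, cuts


def contingency_diagonal(pct_table: np.ndarray) -> float:
    """Mean of the diagonal agreement percentages (100 = perfect match)."""
    return float(np.mean(np.diag(pct_table)))


# ----------------------------------------------------------------------
# full comparison
# ----------------------------------------------------------------------
@dataclass
class ExposureComparison:
    """All error statistics of one candidate tier against the standard."""

    tier: str
    standard: str
    nd: np.ndarray                 # per block-hour, %; NaN = excluded
    nad: np.ndarray
    nd_block_mean: pd.Series       # per-block mean over hours
    nad_block_mean: pd.Series
    nd_pooled_mean: float
    nad_pooled_mean: float
    excluded_fraction: float
    spatial_cv: CVSeries
    temporal_cv: CVSeries
    contingency: np.ndarray        # 5×5 %
    quintile_cuts: dict

    def summary(self) -> dict:
        return {
            "tier": self.tier,
            "standard": self.standard,
            "nd_pooled_mean_pct": self.nd_pooled_mean,
            "nad_pooled_mean_pct": self.nad_pooled_mean,
            "nd_block_mean_pct": float(np.nanmean(self.nd_block_mean)),
            "nad_block_mean_pct": float(np.nanmean(self.nad_block_mean)),
            "excluded_fraction": self.excluded_fraction,
            "mean_spatial_cv": self.spatial_cv.mean,
            "mean_temporal_cv": self.temporal_cv.mean,
            "contingency_diagonal_pct": contingency_diagonal(self.contingency),
        }


def compare_tiers(
    candidate: ConcentrationField,
    standard: ConcentrationField,
    epsilon: float = ND_EPSILON,
) -> ExposureComparison:
    """Full error profile of one exposure metric against the standard."""
    if not candidate.aligned_with(standard):
        raise ValueError("candidate and standard fields are not on the same grid")
    nd = normalized_difference(candidate.values, standard.values, epsilon)
    nad = np.abs(nd)
    valid = np.isfinite(standard.values) & np.isfinite(candidate.values)
    excluded = float(np.mean(~np.isfinite(nd) & valid)) if valid.any() else 0.0

    with np.errstate(invalid="ignore"):
        nd_block = pd.Series(np.nanmean(nd, axis=1), index=candidate.block_ids)
        nad_block = pd.Series(np.nanmean(nad, axis=1), index=candidate.block_ids)

    table, cuts = quintile_contingency(annual_average(candidate), annual_average(standard))
    return ExposureComparison(
        tier=candidate.tier,
        standard=standard.tier,
        nd=nd,
        nad=nad,
        nd_block_mean=nd_block,
        nad_block_mean=nad_block,
        nd_pooled_mean=float(np.nanmean(nd)),
        nad_pooled_mean=float(np.nanmean(nad)),
        excluded_fraction=excluded,
        spatial_cv=spatial_cv(candidate),
        temporal_cv=temporal_cv(candidate),
        contingency=table,
        quintile_cuts=cuts,
    )
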