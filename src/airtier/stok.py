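"""Space-time ordinary kriging (STOK) of monitor data to block centroids.

Background concentration is treated as a second-order stationary space-time
random field. Monitor observations are the exact conditioning points ("hard
data"); the estimate at each block-hour is the linear combination of nearby
hard data whose weights minimize estimation variance subject to the
unbiasedness constraint Σw = 1 (the ordinary-kriging system).

The covariance model is a separable exponential product
``σ²·exp(−3h/a_s)·exp(−3τ/a_t) + nugget`` with practical ranges a_s (km) and
a_t (h); both the model and the neighborhood size are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .fields import ConcentrationField
from .scene import SpaceTimeCovariance

logger = logging.getLogger(__name__)

MIN_PAIRS_PER_BIN = 30


@dataclass
class KrigingEstimate:
    x_km: float
    y_km: float
    hour: object
    estimate: float
    variance: float
    n_neighbors: int


class KrigingError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# hard data handling
# ----------------------------------------------------------------------
def validate_hard_data(hard_data: pd.DataFrame) -> pd.DataFrame:
    """Check the monitor table: finite values, no duplicate (station, hour)."""
    required = {"station_id", "x_km", "y_km", "hour", "value"}
    missing = required - set(hard_data.columns)
    if missing:
        raise ValueError(f"hard data missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(hard_data["value"])):
        raise ValueError("hard data contains non-finite values")
    dup = hard_data.duplicated(subset=["station_id", "hour"])
    if dup.any():
        raise ValueError(
            f"duplicate (station, hour) pairs in hard data: "
            f"{hard_data.loc[dup, ['station_id', 'hour']].head().to_dict('records')}"
        )
    return hard_data


def _hours_to_float(hours) -> np.ndarray:
    """Timestamps -> float hours since the epoch (any common origin works)."""
    return pd.DatetimeIndex(hours).view("int64").astype(float) / 3.6e12


# ----------------------------------------------------------------------
# empirical covariance
# ----------------------------------------------------------------------
def empirical_covariance(
    hard_data: pd.DataFrame,
    spatial_bin_edges: np.ndarray,
    temporal_lags: np.ndarray,
) -> pd.DataFrame:
    """Method-of-moments space-time covariance on (distance bin, time lag) cells.

    Observations are demeaned by the grand mean; for each integer time lag τ
    the cross-products between all station pairs (including a station with
    itself) are accumulated into spatial-distance bins. The (0-distance, 0-lag)
    cell therefore equals the plain sample variance of all values.

    Returns a frame with ``spatial_lag`` (bin center), ``temporal_lag``,
    ``covariance``, ``n_pairs`` and a ``flagged`` column marking cells with
    fewer than 30 pairs.
    """
    validate_hard_data(hard_data)
    if hard_data["station_id"].nunique() < 2:
        raise KrigingError("need at least 2 stations for spatial covariance bins")
    if hard_data["hour"].nunique() < 2:
        raise KrigingError("need at least 2 hours for temporal covariance bins")

    wide = hard_data.pivot(index="station_id", columns="hour", values="value")
    v = wide.to_numpy()
    mask = np.isfinite(v)
    vd = np.where(mask, v - np.nanmean(v), 0.0)

    coords = hard_data.groupby("station_id")[["x_km", "y_km"]].first().loc[wide.index]
    xy = coords.to_numpy()
    dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)

    edges = np.asarray(spatial_bin_edges, dtype=float)
    sbin = np.digitize(dist, edges) - 1  # -1 = below first edge
    n_sbins = len(edges) - 1
    # distance-0 (same-station) pairs always land in the first bin
    sbin[dist == 0.0] = 0

    n_t = v.shape[1]
    rows = []
    for tau in np.asarray(temporal_lags, dtype=int):
        if tau >= n_t:
            continue
        a, b = vd[:, : n_t - tau], vd[:, tau:]
        ma, mb = mask[:, : n_t - tau], mask[:, tau:]
        prod = a @ b.T
        cnt = ma.astype(float) @ mb.T.astype(float)
        if tau > 0:  # symmetrize: C(h, τ) pools both orderings of each pair
            prod = prod + prod.T
            cnt = cnt + cnt.T
        for k in range(n_sbins):
            sel = sbin == k
            total = cnt[sel].sum()
            if total == 0:
                continue
            rows.append(
                {
                    # pair-weighted mean distance: a better abscissa than the
                    # bin center when stations are irregular
                    "spatial_lag": float((dist[sel] * cnt[sel]).sum() / total),
                    "temporal_lag": float(tau),
                    "covariance": prod[sel].sum() / total,
                    "n_pairs": int(total),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise KrigingError("no covariance bins could be populated")
    out["flagged"] = out["n_pairs"] < MIN_PAIRS_PER_BIN
    return out


def fit_covariance(
    binned: pd.DataFrame,
    form: str = "exponential",
    fit_nugget: bool = False,
) -> tuple[SpaceTimeCovariance, dict]:
    """Weighted least squares fit of the separable exponential model to binned
    covariances, weights proportional to pair counts.

    Returns the fitted model and a diagnostics dict (``converged``, ``cost``,
    ``flags``). A range hitting its upper bound (flat empirical covariance) is
    flagged rather than treated as an error.
    """
    if form != "exponential":
        raise ValueError(f"unsupported covariance form: {form!r}")
    h = binned["spatial_lag"].to_numpy(dtype=float)
    tau = binned["temporal_lag"].to_numpy(dtype=float)
    c = binned["covariance"].to_numpy(dtype=float)
    w = np.sqrt(binned["n_pairs"].to_numpy(dtype=float))

    if len(np.unique(h)) < 3 or len(np.unique(tau)) < 3:
        raise KrigingError("need >= 3 distinct lags per axis to fit the covariance")

    h_hi = max(h.max(), 1e-6) * 10.0
    t_hi = max(tau.max(), 1e-6) * 10.0
    c0 = max(c.max(), 1e-9)

    def model(p):
        sill, a_s, a_t, nug = p
        m = sill * np.exp(-3.0 * h / a_s) * np.exp(-3.0 * tau / a_t)
        return m + nug * ((h == 0) & (tau == 0))

    def resid(p):
        return w * (model(p) - c)

    p0 = [c0, max(h[h > 0].min() if (h > 0).any() else 1.0, h.max() / 3, 1e-3),
          max(t_hi / 30, 1.0), 0.0]
    lo = [1e-12, 1e-6, 1e-6, 0.0]
    hi = [np.inf, h_hi, t_hi, np.inf if fit_nugget else 1e-30]
    p0[3] = 0.0 if not fit_nugget else 0.1 * c0
    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    sill, a_s, a_t, nug = sol.x
    flags = []
    if a_s > 0.99 * h_hi:
        flags.append("spatial_range_at_upper_bound")
    if a_t > 0.99 * t_hi:
        flags.append("temporal_range_at_upper_bound")
    if not sol.success:
        raise KrigingError(f"covariance fit did not converge; last iterate {sol.x}")
    cov = SpaceTimeCovariance(
        sill=float(sill), spatial_range=float(a_s), temporal_range=float(a_t),
        nugget=float(nug) if fit_nugget else 0.0,
    )
    return cov, {"converged": sol.success, "cost": float(sol.cost), "flags": flags}


# ----------------------------------------------------------------------
# kriging solver
# ----------------------------------------------------------------------
class _HardDataIndex:
    """Array view of the hard data plus a KD-tree in range-scaled coordinates.

    The neighbor metric is sqrt((h/a_s)² + (τ/a_t)²); embedding points at
    (x/a_s, y/a_s, t/a_t) makes the Euclidean KD-tree query exactly that
    metric.
    """

    def __init__(self, hard_data: pd.DataFrame, cov: SpaceTimeCovariance):
        validate_hard_data(hard_data)
        self.cov = cov
        stations, s_codes = np.unique(hard_data["station_id"].to_numpy(), return_inverse=True)
        self.station_codes = s_codes
        self.xy = hard_data[["x_km", "y_km"]].to_numpy(dtype=float)
        self.t = _hours_to_float(hard_data["hour"])
        self.z = hard_data["value"].to_numpy(dtype=float)
        self.tree = cKDTree(
            np.column_stack(
                [self.xy / cov.spatial_range, self.t[:, None] / cov.temporal_range]
            )
        )

    def neighbors(self, xy: np.ndarray, t: float, k: int) -> np.ndarray:
        q = np.array([xy[0] / self.cov.spatial_range, xy[1] / self.cov.spatial_range,
                      t / self.cov.temporal_range])
        k = min(k, len(self.z))
        _, idx = self.tree.query(q, k=k)
        return np.atleast_1d(idx)


def _solve_ok_system(
    cov: SpaceTimeCovariance,
    n_xy: np.ndarray,
    n_t: np.ndarray,
    target_xy: np.ndarray,
    target_t: float,
) -> tuple[np.ndarray, float]:
    """Solve [C 1; 1ᵀ 0]·[w; μ] = [c₀; 1]; return weights and kriging variance."""
    m = len(n_t)
    d = np.linalg.norm(n_xy[:, None, :] - n_xy[None, :, :], axis=-1)
    dt = np.abs(n_t[:, None] - n_t[None, :])
    big_c = cov.sill * cov.spatial_corr(d) * cov.temporal_corr(dt)
    big_c[np.diag_indices(m)] += cov.nugget + 1e-10 * max(cov.sill, 1e-30)

    d0 = np.linalg.norm(n_xy - target_xy, axis=1)
    t0 = np.abs(n_t - target_t)
    c0 = cov.sill * cov.spatial_corr(d0) * cov.temporal_corr(t0)

    # a nugget-free target coinciding with a hard datum is interpolated
    # exactly, bypassing the jitter-perturbed solve
    if cov.nugget == 0.0:
        hit = np.flatnonzero((d0 < 1e-12) & (t0 < 1e-12))
        if hit.size:
            w = np.zeros(m)
            w[hit[0]] = 1.0
            return w, 0.0

    lhs = np.empty((m + 1, m + 1))
    lhs[:m, :m] = big_c
    lhs[:m, m] = 1.0
    lhs[m, :m] = 1.0
    lhs[m, m] = 0.0
    rhs = np.append(c0, 1.0)
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise KrigingError(
            "singular kriging system; hard data likely contains (near-)duplicate points"
        ) from exc
    w, mu = sol[:m], sol[m]
    var = float(cov.sill + cov.nugget - w @ c0 - mu)
    return w, var


def krige_point(
    target_xy,
    target_hour,
    hard_data: pd.DataFrame,
    cov: SpaceTimeCovariance,
    n_neighbors: int = 30,
) -> KrigingEstimate:
    """Ordinary-kriging estimate at one space-time point.

    Uses the ``n_neighbors`` nearest hard data under the range-scaled metric.
    Negative kriging variances (numerical) are clamped to zero.
    """
    index = _HardDataIndex(hard_data, cov)
    target_xy = np.asarray(target_xy, dtype=float)
    t = float(_hours_to_float([pd.Timestamp(target_hour)])[0])
    idx = index.neighbors(target_xy, t, n_neighbors)
    w, var = _solve_ok_system(cov, index.xy[idx], index.t[idx], target_xy, t)
    est = float(w @ index.z[idx])
    return KrigingEstimate(
        x_km=float(target_xy[0]),
        y_km=float(target_xy[1]),
        hour=target_hour,
        estimate=est,
        variance=max(var, 0.0),
        n_neighbors=len(idx),
    )


def krige_field(
    blocks: pd.DataFrame,
    hours: pd.DatetimeIndex,
    hard_data: pd.DataFrame,
    cov: SpaceTimeCovariance,
    n_neighbors: int = 30,
    cadence: str = "hourly",
    pollutant: str = "generic",
) -> ConcentrationField:
    """Krige the background tier at every block-hour.

    For ``cadence='daily'`` (EC-like pollutants with only daily observations)
    monitor values are first averaged per station-day, one estimate per
    block-day is computed, and that value is broadcast to the day's 24 hours —
    so the background tier has zero within-day variation.

    Identical neighbor geometries (the common case on a complete monitor grid,
    where every interior hour sees the same station/lag pattern) share one
    linear solve, which keeps full-year runs fast.
    """
    if cadence not in ("hourly", "daily"):
        raise ValueError("cadence must be 'hourly' or 'daily'")

    if cadence == "daily":
        hd = hard_data.copy()
        hd["hour"] = pd.to_datetime(hd["hour"]).dt.floor("D") + pd.Timedelta(hours=12)
        hd = (
            hd.groupby(["station_id", "hour"], as_index=False)
            .agg({"x_km": "first", "y_km": "first", "value": "mean"})
        )
        targets = pd.DatetimeIndex(
            pd.Series(hours.floor("D")).drop_duplicates()
        ) + pd.Timedelta(hours=12)
        hard = hd
    else:
        targets = hours
        hard = hard_data

    index = _HardDataIndex(hard, cov)
    block_xy = blocks[["x_km", "y_km"]].to_numpy(dtype=float)
    t_targets = _hours_to_float(targets)

    est = np.full((len(block_xy), len(targets)), np.nan)
    var = np.full_like(est, np.nan)
    n_clamped = 0
    weight_cache: dict = {}
    k = min(n_neighbors, len(index.z))
    for b, xy in enumerate(block_xy):
        query = np.column_stack(
            [
                np.full(len(t_targets), xy[0] / cov.spatial_range),
                np.full(len(t_targets), xy[1] / cov.spatial_range),
                t_targets / cov.temporal_range,
            ]
        )
        _, idx_all = index.tree.query(query, k=k)
        idx_all = idx_all.reshape(len(t_targets), k)
        for j, t in enumerate(t_targets):
            idx = idx_all[j]
            if len(idx) == 0:
                continue  # recorded as missing
            offsets = np.round((index.t[idx] - t) * 4) / 4  # quarter-hour resolution
            key = (b, index.station_codes[idx].tobytes(), offsets.tobytes())
            cached = weight_cache.get(key)
            if cached is None:
                w, v = _solve_ok_system(cov, index.xy[idx], index.t[idx], xy, t)
                weight_cache[key] = (w, v)
            else:
                w, v = cached
            est[b, j] = w @ index.z[idx]
            if v < 0:
                n_clamped += 1
                v = 0.0
            var[b, j] = v
    if n_clamped:
        logger.warning("clamped %d negative kriging variances to 0", n_clamped)
    n_missing = int(np.isnan(est).sum())
    if n_missing:
        logger.warning("%d block-%s targets had no neighbors (left missing)",
                       n_missing, "days" if cadence == "daily" else "hours")

    if cadence == "daily":
        day_of = hours.floor("D") + pd.Timedelta(hours=12)
        col = pd.Series(np.arange(len(targets)), index=targets).loc[day_of].to_numpy()
        est = est[:, col]
        var = var[:, col]

    out = ConcentrationField(
        values=est,
        block_ids=blocks["block_id"].to_numpy(),
        hours=hours,
        pollutant=pollutant,
        tier="outdoor_stok",
    )
    out.variance = var
    return out


# ----------------------------------------------------------------------
# baselines & diagnostics
# ----------------------------------------------------------------------
def nearest_monitor_field(
    blocks: pd.DataFrame,
    hours: pd.DatetimeIndex,
    hard_data: pd.DataFrame,
    pollutant: str = "generic",
) -> ConcentrationField:
    """Assign each block the series of its spatially nearest monitor.

    The classic central-site assignment; used as the head-to-head baseline the
    kriged field must beat in recovery experiments.
    """
    wide = hard_data.pivot(index="station_id", columns="hour", values="value")
    coords = hard_data.groupby("station_id")[["x_km", "y_km"]].first().loc[wide.index]
    block_xy = blocks[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.linalg.norm(block_xy[:, None, :] - coords.to_numpy()[None, :, :], axis=-1)
    nearest = np.argmin(d, axis=1)
    col = wide.columns.get_indexer(hours)
    if np.any(col < 0):
        raise KrigingError("monitor table does not cover all requested hours")
    vals = wide.to_numpy()[nearest][:, col]
    return ConcentrationField(
        values=vals,
        block_ids=blocks["block_id"].to_numpy(),
        hours=hours,
        pollutant=pollutant,
        tier="nearest_monitor",
    )


def loo_cross_validation(
    hard_data: pd.DataFrame,
    cov: SpaceTimeCovariance,
    n_neighbors: int = 30,
) -> pd.DataFrame:
    """Leave-one-station-out cross validation.

    Each station is removed in turn and kriged back from the rest; returns
    per-observation standardized errors (error / kriging standard deviation).
    On scenes generated from the fitted model these should have mean ≈ 0 and
    variance ≈ 1.
    """
    rows = []
    for station in hard_data["station_id"].unique():
        held = hard_data[hard_data["station_id"] == station]
        rest = hard_data[hard_data["station_id"] != station]
        xy = held[["x_km", "y_km"]].iloc[0].to_numpy(dtype=float)
        hours = pd.DatetimeIndex(held["hour"])
        blocks = pd.DataFrame({"block_id": [station], "x_km": [xy[0]], "y_km": [xy[1]]})
        pred = krige_field(blocks, hours, rest, cov, n_neighbors=n_neighbors)
        err = held["value"].to_numpy() - pred.values[0]
        sd = np.sqrt(np.maximum(pred.variance[0], 1e-300))
        rows.append(pd.DataFrame({"station_id": station, "hour": hours,
                                  "error": err, "std_error": err / sd}))
    return pd.concat(rows, ignore_index=True)
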