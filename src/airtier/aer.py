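"""Residential air exchange rates from the leakage-area / LBL infiltration model.

The chain per house and hour is:

    NL    = exp(β₀ + β₁·Y_built + β₂·A_floor)           normalized leakage
    A_inf = 1e4 · NL · A_floor / (1000 · (H/2.5)^0.3)   effective leakage area, cm²
    Q_inf = A_inf · sqrt(k_s·|T_in − T_out| + k_w·U²)   infiltration flow, L/s
    AER   = 3600 · Q_inf / V                            air changes per hour

with β-coefficients differing between low-income (below 125% of the poverty
guideline) and conventional homes, and the stack/wind coefficients k_s, k_w
taken from the standard handbook table keyed by number of stories and an
ordinal wind-shelter class (1 = fully exposed … 5 = heavily sheltered, assigned
here from neighborhood house density). Block-level AER is the hourly mean over
10 randomly sampled houses per block, each block using its nearest
meteorological station; indoor temperature is fixed at 23.6 °C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .roadsource import assign_met_stations

logger = logging.getLogger(__name__)

T_IN_DEFAULT = 23.6  # °C, regional mean indoor temperature

#: ASHRAE basic-model stack coefficients, (L/s)²/(cm⁴·K), by stories.
STACK_COEFF = {1: 0.000145, 2: 0.000290, 3: 0.000435}

#: ASHRAE basic-model wind coefficients, (L/s)²/(cm⁴·(m/s)²),
#: by (stories, shelter class 1..5).
WIND_COEFF = {
    (1, 1): 0.000319, (1, 2): 0.000246, (1, 3): 0.000174, (1, 4): 0.000104, (1, 5): 0.000032,
    (2, 1): 0.000420, (2, 2): 0.000325, (2, 3): 0.000231, (2, 4): 0.000137, (2, 5): 0.000042,
    (3, 1): 0.000494, (3, 2): 0.000382, (3, 3): 0.000271, (3, 4): 0.000161, (3, 5): 0.000049,
}

#: Default shelter-class cutoffs on block house density, houses/km².
DENSITY_CUTOFFS = (50.0, 200.0, 800.0, 2000.0)

MAX_FLOOR_AREA_M2 = 650.3  # 7000 ft²: larger buildings treated as multi-unit
STORY_AREA_THRESHOLD_M2 = 1000.0  # one story below, two at or above


@dataclass
class LeakageCoefficients:
    """Envelope-leakage regression coefficients by income class."""

    low_income: tuple[float, float, float] = (11.1, -5.37e-3, -4.18e-3)
    conventional: tuple[float, float, float] = (20.7, -1.07e-2, -2.20e-3)
    stack_coeff: dict = dc_field(default_factory=lambda: dict(STACK_COEFF))
    wind_coeff: dict = dc_field(default_factory=lambda: dict(WIND_COEFF))

    def betas(self, income_low: bool) -> tuple[float, float, float]:
        return self.low_income if income_low else self.conventional

    def k_s(self, stories: int) -> float:
        return self.stack_coeff[min(int(stories), max(self.stack_coeff))]

    def k_w(self, stories: int, shelter_class: int) -> float:
        s = min(int(stories), max(k[0] for k in self.wind_coeff))
        c = min(max(int(shelter_class), 1), max(k[1] for k in self.wind_coeff))
        return self.wind_coeff[(s, c)]


# ----------------------------------------------------------------------
# house-level building blocks
# ----------------------------------------------------------------------
def filter_housing_stock(
    houses: pd.DataFrame, max_floor_area: float = MAX_FLOOR_AREA_M2
) -> pd.DataFrame:
    """Drop buildings with floor area strictly above the multi-unit threshold."""
    keep = houses["a_floor_m2"] <= max_floor_area
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d buildings above %.1f m² floor area", n_removed, max_floor_area)
    return houses[keep].reset_index(drop=True)


def assign_stories(a_floor: float, area_threshold: float = STORY_AREA_THRESHOLD_M2) -> int:
    """One story below the area threshold, two at or above it."""
    return 1 if a_floor < area_threshold else 2


def building_height(stories: int) -> float:
    """Height in meters: 2.5 m per story plus 0.5 m of roof space."""
    return 2.5 * stories + 0.5


def house_volume_liters(a_floor: float, stories: int) -> float:
    """Conditioned volume: floor area × 2.5 m ceiling per story, in liters."""
    return a_floor * 2.5 * stories * 1000.0


def normalized_leakage(
    y_built: float | np.ndarray,
    a_floor: float | np.ndarray,
    income_low: bool | np.ndarray,
    coeffs: LeakageCoefficients | None = None,
) -> float | np.ndarray:
    """NL = exp(β₀ + β₁·Y_built + β₂·A_floor), income-matched coefficients."""
    coeffs = coeffs or LeakageCoefficients()
    y = np.asarray(y_built, dtype=float)
    if np.any((y < 1600) | (y > 2030)):
        logger.warning("construction year outside plausible span 1600-2030")
    b_low = np.array(coeffs.low_income)
    b_con = np.array(coeffs.conventional)
    low = np.asarray(income_low, dtype=bool)
    b0 = np.where(low, b_low[0], b_con[0])
    b1 = np.where(low, b_low[1], b_con[1])
    b2 = np.where(low, b_low[2], b_con[2])
    nl = np.exp(b0 + b1 * y + b2 * np.asarray(a_floor, dtype=float))
    return float(nl) if np.ndim(y_built) == 0 and np.ndim(a_floor) == 0 else nl


def leakage_area(
    nl: float | np.ndarray, a_floor: float | np.ndarray, height: float | np.ndarray
) -> float | np.ndarray:
    """Effective leakage area A_inf in cm².

    Inverts the normalization NL = 1000·(A_inf/A_floor)·(H/2.5)^0.3 (areas in
    common units) and converts m² → cm²; at the 2.5 m reference height this is
    exactly 10·NL·A_floor.
    """
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be > 0")
    a = np.asarray(a_floor, dtype=float) * np.asarray(nl, dtype=float)
    out = 1e4 * a / (1000.0 * (h / 2.5) ** 0.3)
    return float(out) if np.ndim(out) == 0 else out


def infiltration_flow(
    a_inf: float | np.ndarray,
    k_s: float | np.ndarray,
    k_w: float | np.ndarray,
    t_in: float,
    t_out: float | np.ndarray,
    wind_speed: float | np.ndarray,
) -> float | np.ndarray:
    """Q_inf = A_inf·sqrt(k_s·|T_in − T_out| + k_w·U²), in L/s."""
    u = np.asarray(wind_speed, dtype=float)
    if np.any(np.asarray(a_inf) < 0) or np.any(u < 0):
        raise ValueError("leakage area and wind speed must be >= 0")
    q = np.asarray(a_inf) * np.sqrt(
        np.asarray(k_s) * np.abs(t_in - np.asarray(t_out, dtype=float))
        + np.asarray(k_w) * u**2
    )
    return float(q) if np.ndim(q) == 0 else q


def air_exchange_rate(q_inf: float | np.ndarray, volume_l: float | np.ndarray):
    """AER (h⁻¹) = 3600·Q_inf / V with Q_inf in L/s and V in liters."""
    v = np.asarray(volume_l, dtype=float)
    if np.any(v <= 0):
        raise ValueError("house volume must be > 0")
    out = 3600.0 * np.asarray(q_inf, dtype=float) / v
    return float(out) if np.ndim(out) == 0 else out


def shelter_class_from_density(
    density: float, cutoffs: tuple[float, ...] = DENSITY_CUTOFFS
) -> int:
    """Ordinal shelter class from block house density (houses/km²).

    Intervals are left-closed: density below the first cutoff is class 1
    (fully exposed); a density exactly at a cutoff joins the higher class.
    """
    cut = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cut) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    return int(np.searchsorted(cut, density, side="right")) + 1


# ----------------------------------------------------------------------
# block-level AER field
# ----------------------------------------------------------------------
def block_aer(
    houses: pd.DataFrame,
    blocks: pd.DataFrame,
    met: pd.DataFrame,
    hours: pd.DatetimeIndex,
    t_in: float = T_IN_DEFAULT,
    coeffs: LeakageCoefficients | None = None,
    n_sample: int = 10,
    seed: int = 0,
    density_cutoffs: tuple[float, ...] = DENSITY_CUTOFFS,
) -> pd.DataFrame:
    """Hourly block AER: mean over up to ``n_sample`` randomly sampled houses.

    Houses are sampled once per block per run (not per hour), so a block's
    hourly series reflects one fixed sub-stock driven by its met station's
    temperature and wind. Returns a long frame (block_id, hour, aer_per_h,
    n_houses).
    """
    coeffs = coeffs or LeakageCoefficients()
    rng = np.random.default_rng(seed)
    assignment = assign_met_stations(blocks, met)
    met_wide = {
        sid: grp.set_index("hour").loc[hours]
        for sid, grp in met.groupby("station_id")
    }

    frames = []
    for _, blk in blocks.iterrows():
        block_id = blk["block_id"]
        stock = houses[houses["block_id"] == block_id]
        if len(stock) == 0:
            logger.warning("block %s has no houses; using one default house", block_id)
            stock = pd.DataFrame(
                [{"a_floor_m2": 150.0, "y_built": 1980, "stories": 1, "income_low": False}]
            )
        if len(stock) > n_sample:
            stock = stock.iloc[rng.choice(len(stock), n_sample, replace=False)]

        shelter = shelter_class_from_density(blk["house_density"], density_cutoffs)
        a_floor = stock["a_floor_m2"].to_numpy(dtype=float)
        stories = stock["stories"].to_numpy(dtype=int)
        nl = normalized_leakage(
            stock["y_built"].to_numpy(dtype=float), a_floor,
            stock["income_low"].to_numpy(dtype=bool), coeffs,
        )
        a_inf = leakage_area(nl, a_floor, building_height(stories))
        k_s = np.array([coeffs.k_s(s) for s in stories])
        k_w = np.array([coeffs.k_w(s, shelter) for s in stories])
        vol = house_volume_liters(a_floor, stories)

        m = met_wide[assignment.loc[block_id]]
        t_out = m["t_out"].to_numpy(dtype=float)
        u = m["wind_speed"].to_numpy(dtype=float)
        # (n_houses, n_hours)
        q = infiltration_flow(
            a_inf[:, None], k_s[:, None], k_w[:, None], t_in, t_out[None, :], u[None, :]
        )
        aer = air_exchange_rate(q, vol[:, None]).mean(axis=0)
        frames.append(pd.DataFrame({
            "block_id": block_id, "hour": hours, "aer_per_h": aer, "n_houses": len(stock),
        }))
    return pd.concat(frames, ignore_index=True)


def aer_matrix(aer_long: pd.DataFrame, block_ids, hours: pd.DatetimeIndex) -> np.ndarray:
    """Pivot the long AER table to a (n_blocks, n_hours) array."""
    wide = aer_long.pivot(index="block_id", columns="hour", values="aer_per_h")
    return wide.loc[block_ids, hours].to_numpy(dtype=float)
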