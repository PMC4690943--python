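"""Block-by-hour concentration fields and their long-CSV interchange format.

Every stage of the pipeline consumes and produces :class:`ConcentrationField`
objects: a dense (n_blocks, n_hours) matrix of concentrations for one
pollutant and one exposure-metric tier, with NaN marking hours that could not
be computed (e.g. calm-wind dispersion hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six exposure-metric tiers, outdoor and indoor.
TIERS = (
    "outdoor_stok",
    "outdoor_onroad",
    "outdoor_hybrid",
    "indoor_stok",
    "indoor_onroad",
    "indoor_hybrid",
)


@dataclass
class ConcentrationField:
    """Concentration (μg/m³) at block centroids over an hourly grid.

    Parameters
    ----------
    values
        Array of shape ``(n_blocks, n_hours)``; NaN = missing.
    block_ids
        Block identifiers, one per row.
    hours
        Hourly timestamps (``pandas.DatetimeIndex``), one per column,
        strictly increasing at 1 h spacing.
    pollutant, tier
        Labels; ``tier`` is one of :data:`TIERS` (or a custom label).
    """

    values: np.ndarray
    block_ids: np.ndarray
    hours: pd.DatetimeIndex
    pollutant: str = "generic"
    tier: str = "outdoor_stok"
    variance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.block_ids = np.asarray(self.block_ids)
        if self.values.shape != (len(self.block_ids), len(self.hours)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.block_ids)} blocks x {len(self.hours)} hours"
            )

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_hours(self) -> int:
        return self.values.shape[1]

    def aligned_with(self, other: "ConcentrationField") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.block_ids, other.block_ids)
            and self.hours.equals(other.hours)
        )

    def copy_with(self, values: np.ndarray, tier: str | None = None) -> "ConcentrationField":
        return ConcentrationField(
            values=np.asarray(values, dtype=float),
            block_ids=self.block_ids,
            hours=self.hours,
            pollutant=self.pollutant,
            tier=tier if tier is not None else self.tier,
        )

    # ------------------------------------------------------------------
    # long-CSV interchange
    # ------------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long table: block_id, hour, pollutant, tier, value_ugm3[, variance]."""
        n_b, n_h = self.values.shape
        out = pd.DataFrame(
            {
                "block_id": np.repeat(self.block_ids, n_h),
                "hour": np.tile(self.hours, n_b),
                "pollutant": self.pollutant,
                "tier": self.tier,
                "value_ugm3": self.values.ravel(),
            }
        )
        if self.variance is not None:
            out["variance"] = np.asarray(self.variance, dtype=float).ravel()
        return out

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ConcentrationField":
        pollutants = df["pollutant"].unique()
        tiers = df["tier"].unique()
        if len(pollutants) != 1 or len(tiers) != 1:
            raise ValueError("long table must contain exactly one pollutant and one tier")
        wide = df.pivot(index="block_id", columns="hour", values="value_ugm3")
        hours = pd.DatetimeIndex(pd.to_datetime(wide.columns))
        return cls(
            values=wide.to_numpy(),
            block_ids=wide.index.to_numpy(),
            hours=hours,
            pollutant=str(pollutants[0]),
            tier=str(tiers[0]),
        )

    @classmethod
    def from_csv(cls, path) -> "ConcentrationField":
        return cls.from_long(pd.read_csv(path, parse_dates=["hour"]))


def check_hourly_grid(hours: pd.DatetimeIndex) -> None:
    """Raise if timestamps are not strictly increasing at uniform 1 h spacing."""
    if len(hours) == 0:
        raise ValueError("empty hour grid")
    if len(hours) > 1:
        deltas = np.diff(hours.view("int64"))
        if not np.all(deltas == 3_600_000_000_000):
            raise ValueError("hours must be strictly increasing with uniform 1 h spacing")
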