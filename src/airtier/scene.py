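"""Seeded synthetic scenes: monitors, background field, roads, meteorology, housing.

The generator emulates the statistical structure the analysis assumes — a
smooth spatiotemporal background concentration observed by a sparse monitor
network, a handful of meteorological stations, road segments carrying traffic,
and a housing stock whose attributes drive residential air exchange — so that
every downstream stage can be exercised end-to-end without external data.
All randomness flows from a single integer seed; a fixed seed reproduces every
scene table exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import ConcentrationField, check_hourly_grid

PASQUILL_CLASSES = ("A", "B", "C", "D", "E", "F")


# ----------------------------------------------------------------------
# configuration types
# ----------------------------------------------------------------------
@dataclass
class SpaceTimeCovariance:
    """Separable space-time covariance C(h, τ) = sill·C_s(h)·C_t(τ) + nugget·1{h=τ=0}.

    ``spatial_range`` (km) and ``temporal_range`` (h) are *practical* ranges:
    for the exponential form the correlation falls to 5% at the range,
    i.e. C_s(h) = exp(−3h/a_s).
    """

    sill: float = 4.0          # (μg/m³)²
    spatial_range: float = 20.0  # km
    temporal_range: float = 12.0  # h
    nugget: float = 0.0        # (μg/m³)²
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.sill < 0:
            raise ValueError("sill must be >= 0")
        if self.spatial_range <= 0 or self.temporal_range <= 0:
            raise ValueError("ranges must be > 0")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.form != "exponential":
            raise ValueError(f"unsupported covariance form: {self.form!r}")

    def spatial_corr(self, h: np.ndarray) -> np.ndarray:
        return np.exp(-3.0 * np.asarray(h, dtype=float) / self.spatial_range)

    def temporal_corr(self, tau: np.ndarray) -> np.ndarray:
        return np.exp(-3.0 * np.abs(np.asarray(tau, dtype=float)) / self.temporal_range)

    def covariance(self, h: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Covariance at spatial lag ``h`` (km) and temporal lag ``tau`` (h)."""
        h = np.asarray(h, dtype=float)
        tau = np.asarray(tau, dtype=float)
        c = self.sill * self.spatial_corr(h) * self.temporal_corr(tau)
        return c + self.nugget * ((h == 0) & (tau == 0))


@dataclass
class RoadSpec:
    """How many road segments to draw and the traffic they carry."""

    n_roads: int = 4
    aadt_range: tuple[float, float] = (5_000.0, 60_000.0)
    truck_fraction_range: tuple[float, float] = (0.02, 0.15)
    speed_bins: tuple[int, ...] = (30, 45, 60)
    road_types: tuple[str, ...] = ("primary", "secondary")


@dataclass
class HousingSpec:
    """Distributions for the synthetic housing stock.

    Floor areas are lognormal (median ``floor_area_median`` m²); construction
    years uniform over ``year_built_span``; the low-income fraction of each
    block group is Beta-distributed; block house density (houses/km², the
    shelter-class covariate) is lognormal.
    """

    houses_per_block: int = 15
    floor_area_median: float = 150.0   # m²
    floor_area_gsd: float = 1.5        # geometric sd
    max_floor_area_m2: float = 650.3   # 7000 ft² apartment filter
    year_built_span: tuple[int, int] = (1700, 2015)
    income_beta: tuple[float, float] = (2.0, 8.0)  # mean fraction 0.2
    density_median: float = 300.0      # houses/km²
    density_gsd: float = 3.0
    story_area_threshold: float = 1000.0  # m², 1 story below / 2 at or above


@dataclass
class SceneConfig:
    n_blocks: int = 20
    domain_extent: tuple[float, float] = (30.0, 30.0)  # km × km
    n_monitors: int = 8
    n_met_stations: int = 4
    hours: pd.DatetimeIndex = dc_field(
        default_factory=lambda: pd.date_range("2012-01-01", periods=168, freq="h")
    )
    seed: int = 0
    background_cov: SpaceTimeCovariance = dc_field(default_factory=SpaceTimeCovariance)
    background_mean: float = 10.0      # μg/m³
    diurnal_amplitude: float = 2.0     # μg/m³, peak of the daily cycle
    road_spec: RoadSpec = dc_field(default_factory=RoadSpec)
    housing_spec: HousingSpec = dc_field(default_factory=HousingSpec)
    mean_wind: float = 3.0             # m/s
    clip_background: bool = True

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_monitors < 1:
            raise ValueError("n_monitors must be >= 1: kriging has no hard data")
        if self.domain_extent[0] <= 0 or self.domain_extent[1] <= 0:
            raise ValueError("domain extent must be positive")
        if len(self.hours) == 0:
            raise ValueError("scene needs at least one hour")
        check_hourly_grid(self.hours)


@dataclass
class RoadSegment:
    segment_id: str
    polyline: np.ndarray               # (k, 2) km
    aadt: float                        # vehicles/day
    vehicle_mix: dict[str, float]      # class -> fraction, sums to 1
    speed_bin: int
    road_type: str

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.length_km() <= 0:
            raise ValueError("polyline length must be > 0")
        if self.aadt < 0:
            raise ValueError("aadt must be >= 0")
        total = sum(self.vehicle_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"vehicle mix fractions sum to {total}, expected 1")

    def length_km(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))


@dataclass
class Scene:
    """Everything downstream stages consume, plus the latent truth."""

    config: SceneConfig
    blocks: pd.DataFrame       # block_id, x_km, y_km, house_density
    monitors: pd.DataFrame     # station_id, x_km, y_km, hour, value
    true_field: ConcentrationField  # latent background at blocks × hours
    met: pd.DataFrame          # station_id, x_km, y_km, hour, wind_speed, wind_dir, t_out, stability
    houses: pd.DataFrame       # house_id, block_id, a_floor_m2, y_built, stories, income_low
    roads: list[RoadSegment]

    @property
    def hours(self) -> pd.DatetimeIndex:
        return self.true_field.hours

    # ------------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write the scene as plain CSV tables plus a GeoJSON road layer."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.monitors.to_csv(outdir / "monitors.csv", index=False)
        self.blocks.to_csv(outdir / "blocks.csv", index=False)
        self.met.to_csv(outdir / "met.csv", index=False)
        self.houses.to_csv(outdir / "houses.csv", index=False)
        self.true_field.to_csv(outdir / "true_background.csv")
        features = []
        for seg in self.roads:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(x), float(y)] for x, y in seg.polyline],
                    },
                    "properties": {
                        "segment_id": seg.segment_id,
                        "aadt": seg.aadt,
                        "speed_bin": seg.speed_bin,
                        "road_type": seg.road_type,
                        "vehicle_mix": seg.vehicle_mix,
                    },
                }
            )
        (outdir / "roads.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )


def read_roads_geojson(path: str | Path) -> list[RoadSegment]:
    data = json.loads(Path(path).read_text())
    segments = []
    for feat in data["features"]:
        props = feat["properties"]
        segments.append(
            RoadSegment(
                segment_id=str(props["segment_id"]),
                polyline=np.asarray(feat["geometry"]["coordinates"], dtype=float),
                aadt=float(props["aadt"]),
                vehicle_mix={k: float(v) for k, v in props["vehicle_mix"].items()},
                speed_bin=int(props["speed_bin"]),
                road_type=str(props["road_type"]),
            )
        )
    return segments


# ----------------------------------------------------------------------
# Gaussian field sampling
# ----------------------------------------------------------------------
def _chol_with_jitter(mat: np.ndarray, scale: float) -> np.ndarray:
    jitter = 1e-10 * max(scale, 1.0)
    for _ in range(8):
        try:
            return np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even after diagonal jitter"
    )


def sample_gaussian_field(
    locations: np.ndarray,
    hours: pd.DatetimeIndex,
    cov: SpaceTimeCovariance,
    mean: float | np.ndarray = 0.0,
    seed: int | np.random.Generator = 0,
    diurnal_amplitude: float = 0.0,
    clip: bool = False,
) -> np.ndarray:
    """Draw one realization of the separable Gaussian background field.

    Exploits the Kronecker structure C = sill·C_s ⊗ C_t: with L_s L_sᵀ = sill·C_s
    and L_t L_tᵀ = C_t, the matrix L_s G L_tᵀ (G iid standard normal) has the
    target covariance, so only an (n_sites) and an (n_hours) Cholesky are needed.

    Returns an ``(n_sites, n_hours)`` array. The mean may include a diurnal
    sinusoid peaking at 07:00 (morning traffic/boundary-layer peak). Values can
    be negative; pass ``clip=True`` to floor at 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n_s, n_t = len(locations), len(hours)

    hour_of_day = hours.hour.to_numpy()
    mean_t = np.asarray(mean, dtype=float) + diurnal_amplitude * np.cos(
        2.0 * np.pi * (hour_of_day - 7) / 24.0
    )

    if cov.sill == 0.0 and cov.nugget == 0.0:
        return np.broadcast_to(mean_t, (n_s, n_t)).copy()

    if cov.sill > 0.0:
        d = np.linalg.norm(locations[:, None, :] - locations[None, :, :], axis=-1)
        ks = cov.sill * cov.spatial_corr(d)
        ls = _chol_with_jitter(ks, cov.sill)
        # The exponential kernel exp(-3|τ|/a_t) is Markov, so the temporal
        # factor is an exact AR(1) recursion: z_t = φ z_{t-1} + √(1-φ²) ε_t,
        # φ = exp(-3/a_t) — O(n_t) instead of an O(n_t³) Cholesky.
        phi = float(np.exp(-3.0 / cov.temporal_range))
        eps = rng.standard_normal((n_s, n_t))
        w = np.empty((n_s, n_t))
        w[:, 0] = eps[:, 0]
        innov = np.sqrt(1.0 - phi * phi)
        for t in range(1, n_t):
            w[:, t] = phi * w[:, t - 1] + innov * eps[:, t]
        z = ls @ w
    else:
        z = np.zeros((n_s, n_t))
    if cov.nugget > 0.0:
        z = z + np.sqrt(cov.nugget) * rng.standard_normal((n_s, n_t))

    out = mean_t + z
    if clip:
        np.clip(out, 0.0, None, out=out)
    return out


# ----------------------------------------------------------------------
# component generators
# ----------------------------------------------------------------------
def generate_housing(
    blocks: pd.DataFrame, spec: HousingSpec, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Sample a housing stock for each block.

    Floor areas above the multi-unit threshold (7000 ft² ≈ 650.3 m²) are
    filtered out, mirroring the removal of apartment buildings for which the
    single-compartment infiltration model does not apply; a block left empty
    falls back to a single default house so the air-exchange stage never
    starves.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    lo_year, hi_year = spec.year_built_span
    for block_id, frac_low in zip(blocks["block_id"], blocks["income_fraction"]):
        n = spec.houses_per_block
        areas = spec.floor_area_median * np.exp(
            np.log(spec.floor_area_gsd) * rng.standard_normal(n)
        )
        keep = areas <= spec.max_floor_area_m2
        areas = areas[keep]
        if len(areas) == 0:  # degenerate block: fall back to one default house
            areas = np.array([spec.floor_area_median])
        m = len(areas)
        years = rng.integers(lo_year, hi_year + 1, size=m)
        stories = np.where(areas < spec.story_area_threshold, 1, 2)
        income_low = rng.random(m) < frac_low
        for i in range(m):
            rows.append(
                {
                    "house_id": f"{block_id}_h{i}",
                    "block_id": block_id,
                    "a_floor_m2": areas[i],
                    "y_built": int(years[i]),
                    "stories": int(stories[i]),
                    "income_low": bool(income_low[i]),
                }
            )
    return pd.DataFrame(rows)


def _generate_met(
    stations: np.ndarray,
    hours: pd.DatetimeIndex,
    mean_wind: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """AR(1) wind speed, slowly drifting direction, diurnal+seasonal temperature.

    Stability class follows a simple insolation/wind scheme: unstable classes in
    light daytime winds, stable classes in light nighttime winds, neutral (D)
    otherwise — enough to exercise the class-dependent plume-spread curves.
    """
    n_t = len(hours)
    hod = hours.hour.to_numpy()
    doy = hours.dayofyear.to_numpy()
    records = []
    for s_idx, (x, y) in enumerate(stations):
        # log-wind AR(1), lag-1 correlation 0.9
        eps = rng.standard_normal(n_t)
        lw = np.empty(n_t)
        lw[0] = eps[0] * 0.4
        for t in range(1, n_t):
            lw[t] = 0.9 * lw[t - 1] + 0.4 * np.sqrt(1 - 0.81) * eps[t]
        u = mean_wind * np.exp(lw - 0.08)  # ~lognormal with mean ≈ mean_wind

        wd = np.cumsum(rng.standard_normal(n_t) * 20.0) + rng.uniform(0, 360)
        wd = np.mod(wd, 360.0)

        t_out = (
            14.0
            - 10.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
            + 5.0 * np.cos(2 * np.pi * (hod - 15) / 24.0)
            + rng.standard_normal(n_t) * 1.0
        )

        daytime = (hod >= 8) & (hod <= 18)
        stab = np.full(n_t, "D", dtype="<U1")
        stab[daytime & (u < 2.0)] = "B"
        stab[daytime & (u >= 2.0) & (u < 5.0)] = "C"
        stab[~daytime & (u < 2.0)] = "F"
        stab[~daytime & (u >= 2.0) & (u < 3.0)] = "E"

        records.append(
            pd.DataFrame(
                {
                    "station_id": f"met{s_idx}",
                    "x_km": x,
                    "y_km": y,
                    "hour": hours,
                    "wind_speed": u,
                    "wind_dir": wd,
                    "t_out": t_out,
                    "stability": stab,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def _generate_roads(
    spec: RoadSpec, extent: tuple[float, float], rng: np.random.Generator
) -> list[RoadSegment]:
    """Straight chords across the domain, each with its own traffic profile."""
    w, h = extent
    segments = []
    for i in range(spec.n_roads):
        if rng.random() < 0.5:  # west-east chord
            p0 = np.array([0.0, rng.uniform(0.1 * h, 0.9 * h)])
            p1 = np.array([w, rng.uniform(0.1 * h, 0.9 * h)])
        else:  # south-north chord
            p0 = np.array([rng.uniform(0.1 * w, 0.9 * w), 0.0])
            p1 = np.array([rng.uniform(0.1 * w, 0.9 * w), h])
        truck = rng.uniform(*spec.truck_fraction_range)
        segments.append(
            RoadSegment(
                segment_id=f"road{i}",
                polyline=np.vstack([p0, p1]),
                aadt=float(rng.uniform(*spec.aadt_range)),
                vehicle_mix={"passenger": 1.0 - truck, "truck": truck},
                speed_bin=int(rng.choice(spec.speed_bins)),
                road_type=str(rng.choice(spec.road_types)),
            )
        )
    return segments


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a complete synthetic scene from one seed.

    The latent background field is drawn *jointly* at block centroids and
    monitor locations from the same Gaussian-process realization, so monitor
    observations are genuinely informative about the truth at the blocks and
    kriging-recovery experiments are meaningful.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_blocks, r_field, r_met, r_roads, r_housing = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    w, h = config.domain_extent
    hours = config.hours

    blocks = pd.DataFrame(
        {
            "block_id": [f"b{i:04d}" for i in range(config.n_blocks)],
            "x_km": r_blocks.uniform(0, w, config.n_blocks),
            "y_km": r_blocks.uniform(0, h, config.n_blocks),
            "house_density": config.housing_spec.density_median
            * np.exp(
                np.log(config.housing_spec.density_gsd)
                * r_blocks.standard_normal(config.n_blocks)
            ),
            "income_fraction": r_blocks.beta(
                *config.housing_spec.income_beta, size=config.n_blocks
            ),
        }
    )

    # monitors live in a 1.5x extended region: the real network includes
    # surrounding-county sites, which widens the spatial-lag coverage
    mon_xy = np.column_stack(
        [
            r_blocks.uniform(-0.25 * w, 1.25 * w, config.n_monitors),
            r_blocks.uniform(-0.25 * h, 1.25 * h, config.n_monitors),
        ]
    )

    block_xy = blocks[["x_km", "y_km"]].to_numpy()
    all_xy = np.vstack([block_xy, mon_xy])
    field = sample_gaussian_field(
        all_xy,
        hours,
        config.background_cov,
        mean=config.background_mean,
        seed=r_field,
        diurnal_amplitude=config.diurnal_amplitude,
        clip=config.clip_background,
    )
    true_field = ConcentrationField(
        values=field[: config.n_blocks],
        block_ids=blocks["block_id"].to_numpy(),
        hours=hours,
        tier="true_background",
    )

    mon_vals = field[config.n_blocks :]
    monitors = pd.DataFrame(
        {
            "station_id": np.repeat([f"aqs{i}" for i in range(config.n_monitors)], len(hours)),
            "x_km": np.repeat(mon_xy[:, 0], len(hours)),
            "y_km": np.repeat(mon_xy[:, 1], len(hours)),
            "hour": np.tile(hours, config.n_monitors),
            "value": mon_vals.ravel(),
        }
    )

    # met stations on an interior grid-ish scatter
    met_xy = np.column_stack(
        [
            r_met.uniform(0.1 * w, 0.9 * w, config.n_met_stations),
            r_met.uniform(0.1 * h, 0.9 * h, config.n_met_stations),
        ]
    )
    met = _generate_met(met_xy, hours, config.mean_wind, r_met)

    roads = _generate_roads(config.road_spec, config.domain_extent, r_roads)
    houses = generate_housing(blocks, config.housing_spec, r_housing)

    return Scene(
        config=config,
        blocks=blocks,
        monitors=monitors,
        true_field=true_field,
        met=met,
        houses=houses,
        roads=roads,
    )
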