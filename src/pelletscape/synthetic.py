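"""Synthetic study fixtures with known ground truth.

The generator emulates the study conditions at desk scale: 123 pellet-mill
procurement landscapes observed over the panel years {2005, 2008, 2011,
2014, 2017}, inventory plots at one per 24.28 km² with ~2428 ha expansion
factors, competing power/pulp facilities, ports, population units and
drought footprints.  Geography is an abstract planar box expressed in
lon/lat through a fixed equirectangular anchor — realism is limited to the
published covariate moments (large-capacity share 0.2, coastal share 0.3,
export access 0.5, mill-operational 0.5, years of operation mean 3.2,
pellet/power/pulp overlap means 0.3/1.4/1.1, population mean 486.5 thousand,
drought flag 0.1) and to the presence of sub-161 km neighbour structure for
the spatial weights.

Panel responses can additionally be simulated directly from the model's own
data-generating process (spatially transformed composite errors) with known
coefficients, which is what the estimator-recovery tests consume.

Everything is deterministic given (seed, config).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape

from . import geoscape
from .design import ECOREGIONS, ECOREGION_BASELINE, PANEL_YEARS, DesignMatrices
from .geoscape import DroughtEvent, Facility, Landscape, local_km_transform
from .weights import WeightMatrix


def _field_dict(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape panel.

    Spatial quantities are in km on a plane anchored at (anchor_lon,
    anchor_lat); the facility box is centred on the anchor.  Calibrated
    constants (minimum mill separation, competitor counts, port count,
    drought rate) put the realized covariate moments on the published
    targets under the default box size.
    """

    seed: int = 0
    n_facilities: int = 123
    panel_years: Tuple[int, ...] = PANEL_YEARS
    anchor_lon: float = -84.0
    anchor_lat: float = 35.5
    box_width_km: float = 1050.0
    box_height_km: float = 950.0
    aux_margin_km: float = 130.0       # ports, population, drought coverage
    competitor_margin_km: float = 210.0
    plot_margin_km: float = 85.0
    min_separation_km: float = 54.0    # hard-core distance between pellet mills
    coastal_share: float = 0.3
    large_capacity_share: float = 0.2
    legacy_share: float = 0.052        # mills already running before 2005
    legacy_start_years: Tuple[int, int] = (1984, 1996)
    recent_start_years: Tuple[int, int] = (2007, 2017)
    n_ports: int = 23
    pellet_port_share: float = 0.6
    n_power: int = 167
    n_pulp: int = 55
    competitor_pre2005_share: float = 0.7
    drought_events_per_year: float = 1.33
    drought_radius_km: Tuple[float, float] = (100.0, 250.0)
    population_units_per_km2: float = 1.0 / 1500.0
    population_mean_count: float = 74377.0
    population_sigma_log: float = 1.0
    population_growth_mean: float = 0.01
    population_growth_sd: float = 0.005
    plot_hexagon_km2: float = 24.28
    timberland_share: float = 0.7
    expansion_factor_ha: float = 2428.0
    expansion_jitter: float = 0.1
    attribute_density_per_ha: Dict[str, float] = _field_dict(
        live_trees=990.0,
        growing_stock_trees=220.0,
        standing_dead_trees=22.0,
        carbon_live=28.0,
        carbon_standing_dead=2.5,
        carbon_soil=83.0,
    )
    attribute_density_sigma_log: float = 0.35
    remeasure_sigma_log: float = 0.10
    # ---- response data-generating process (known truth)
    true_alpha: float = 50.0
    true_rho: float = 0.4
    sigma2_mu: float = 25.0
    sigma2_nu: float = 25.0
    true_beta: Dict[str, float] = _field_dict(
        mill_operational=-5.0,
        years_operation=1.5,
        large_capacity=20.0,
        export_access=3.0,
        coastal_southeast=-4.0,
        eco_beech_maple_basswood=-6.0,
        eco_mesophytic=-2.0,
        eco_mississippi_alluvial_plain=-3.0,
        eco_northern_hardwoods_hemlock=5.0,
        eco_oak_hickory=-4.0,
        eco_southern_mixed=2.0,
        eco_subtropical_evergreen=-5.0,
        pellet_overlap=5.0,
        power_overlap=3.0,
        pulp_overlap=2.0,
        post_2009=4.0,
        population_thousands=-0.02,
        drought_lag=-6.0,
        years_operation_x_coastal_southeast=-1.0,
        years_operation_x_large_capacity=0.8,
        mill_operational_x_large_capacity=5.0,
        mill_operational_x_coastal_southeast=-3.0,
        mill_operational_x_export_access=2.0,
        large_capacity_x_coastal_southeast=6.0,
        large_capacity_x_export_access=4.0,
        large_capacity_x_drought_lag=-2.0,
        coastal_southeast_x_export_access=-5.0,
        coastal_southeast_x_drought_lag=3.0,
        export_access_x_drought_lag=1.0,
    )

    def __post_init__(self) -> None:
        for name, val in (("coastal_share", self.coastal_share),
                          ("large_capacity_share", self.large_capacity_share),
                          ("legacy_share", self.legacy_share)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.true_rho) >= 1.0:
            raise ValueError("|true_rho| must be < 1")
        if self.sigma2_mu < 0 or self.sigma2_nu < 0:
            raise ValueError("variance components must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """Everything needed to score estimator recovery against the truth."""

    Y: np.ndarray            # (T, N)
    mu: np.ndarray           # (N,)
    nu: np.ndarray           # (T, N)
    eps: np.ndarray          # (T, N)
    u: np.ndarray            # (T, N)
    alpha: float
    beta: np.ndarray         # aligned with design columns
    beta_names: List[str]
    rho: float
    sigma2_mu: float
    sigma2_nu: float


# ---------------------------------------------------------------------------
# facilities and auxiliary layers

def _hardcore_points(
    rng: np.random.Generator, n: int, width: float, height: float, min_sep: float
) -> np.ndarray:
    """Sequential random placement with a hard-core minimum separation,
    centred on the origin.  Rejects configurations the box cannot hold."""
    pts: List[Tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"box {width}x{height} km too small for {n} facilities at "
                f"{min_sep} km separation"
            )
        attempts += 1
        x = rng.uniform(-width / 2.0, width / 2.0)
        y = rng.uniform(-height / 2.0, height / 2.0)
        ok = all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts)
        if ok:
            pts.append((x, y))
    return np.asarray(pts)


def generate_facilities(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, dict]:
    """Pellet-mill registry plus auxiliary layers.

    Returns (facilities, aux) where aux holds ports, population units,
    drought events and competing power/pulp facilities.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _, to_lonlat = local_km_transform(config.anchor_lon, config.anchor_lat)
    w, h = config.box_width_km, config.box_height_km

    xy = _hardcore_points(rng, config.n_facilities, w, h, config.min_separation_km)
    lonlat = to_lonlat(xy)

    large = rng.random(config.n_facilities) < config.large_capacity_share
    capacity = np.where(
        large,
        rng.uniform(100_000.0, 600_000.0, config.n_facilities),
        rng.uniform(10_000.0, 95_000.0, config.n_facilities),
    )
    legacy = rng.random(config.n_facilities) < config.legacy_share
    lo_l, hi_l = config.legacy_start_years
    lo_r, hi_r = config.recent_start_years
    start = np.where(
        legacy,
        rng.integers(lo_l, hi_l + 1, config.n_facilities),
        rng.integers(lo_r, hi_r + 1, config.n_facilities),
    )

    # southernmost band of the box is the treated coastal region
    coastal_cut = -h / 2.0 + config.coastal_share * h
    coastal = xy[:, 1] < coastal_cut

    # ecoregions: nearest of 8 anchor points, baseline label pinned north
    eco_xy = np.column_stack(
        [rng.uniform(-w / 2, w / 2, len(ECOREGIONS)),
         rng.uniform(-h / 2, h / 2, len(ECOREGIONS))]
    )
    eco_xy[list(ECOREGIONS).index(ECOREGION_BASELINE), 1] = abs(
        eco_xy[list(ECOREGIONS).index(ECOREGION_BASELINE), 1]
    )
    d2 = ((xy[:, None, :] - eco_xy[None, :, :]) ** 2).sum(axis=2)
    eco = [ECOREGIONS[j] for j in d2.argmin(axis=1)]

    facilities = pd.DataFrame(
        {
            "facility_id": [f"mill_{i:03d}" for i in range(config.n_facilities)],
            "lon": lonlat[:, 0],
            "lat": lonlat[:, 1],
            "capacity_tpy": capacity,
            "start_year": start,
            "end_year": [pd.NA] * config.n_facilities,
            "sector": "pellet",
            "region": np.where(coastal, "coastal_southeast", "rest_east"),
            "ecoregion": eco,
        }
    )

    # ports: uniform over the box plus margin; all trade forest products,
    # a subset ships pellets specifically
    m = config.aux_margin_km
    port_xy = np.column_stack(
        [rng.uniform(-w / 2 - m, w / 2 + m, config.n_ports),
         rng.uniform(-h / 2 - m, h / 2 + m, config.n_ports)]
    )
    port_lonlat = to_lonlat(port_xy)
    ports = pd.DataFrame(
        {
            "port_id": [f"port_{i:02d}" for i in range(config.n_ports)],
            "lon": port_lonlat[:, 0],
            "lat": port_lonlat[:, 1],
            "exports_pellets": (rng.random(config.n_ports) < config.pellet_port_share).astype(int),
            "exports_forest_products": 1,
        }
    )

    # population units: Poisson scatter with lognormal counts, mild growth
    area_aux = (w + 2 * m) * (h + 2 * m)
    n_units = int(rng.poisson(config.population_units_per_km2 * area_aux))
    unit_xy = np.column_stack(
        [rng.uniform(-w / 2 - m, w / 2 + m, n_units),
         rng.uniform(-h / 2 - m, h / 2 + m, n_units)]
    )
    unit_lonlat = to_lonlat(unit_xy)
    mu_log = math.log(config.population_mean_count) - 0.5 * config.population_sigma_log**2
    counts = rng.lognormal(mu_log, config.population_sigma_log, n_units)
    growth = rng.normal(config.population_growth_mean, config.population_growth_sd, n_units)
    population = pd.DataFrame(
        {
            "unit_id": [f"pop_{i:04d}" for i in range(n_units)],
            "lon": unit_lonlat[:, 0],
            "lat": unit_lonlat[:, 1],
            "count_2011": counts,       # anchored at the middle panel year
            "annual_growth": growth,
        }
    )

    # drought footprints for the August preceding each panel year
    events: List[DroughtEvent] = []
    severities = ("severe", "extreme", "exceptional")
    for year in config.panel_years:
        n_ev = int(rng.poisson(config.drought_events_per_year))
        for _ in range(n_ev):
            cx = rng.uniform(-w / 2 - m, w / 2 + m)
            cy = rng.uniform(-h / 2 - m, h / 2 + m)
            r = rng.uniform(*config.drought_radius_km)
            circle_km = Point(cx, cy).buffer(r, quad_segs=16)
            from shapely import transform as shp_transform

            events.append(
                DroughtEvent(
                    august_year=year - 1,
                    severity=severities[rng.integers(0, len(severities))],
                    footprint=shp_transform(circle_km, to_lonlat),
                )
            )

    # competing facilities
    cm = config.competitor_margin_km
    aux_frames = {}
    for sector, count, prefix in (("power", config.n_power, "pw"), ("pulp", config.n_pulp, "pl")):
        cxy = np.column_stack(
            [rng.uniform(-w / 2 - cm, w / 2 + cm, count),
             rng.uniform(-h / 2 - cm, h / 2 + cm, count)]
        )
        clonlat = to_lonlat(cxy)
        pre = rng.random(count) < config.competitor_pre2005_share
        cstart = np.where(pre, rng.integers(1990, 2005, count), rng.integers(2006, 2017, count))
        aux_frames[sector] = pd.DataFrame(
            {
                "facility_id": [f"{prefix}_{i:03d}" for i in range(count)],
                "lon": clonlat[:, 0],
                "lat": clonlat[:, 1],
                "capacity_tpy": rng.uniform(50_000.0, 400_000.0, count),
                "start_year": cstart,
                "end_year": [pd.NA] * count,
                "sector": sector,
            }
        )

    aux = {
        "ports": ports,
        "population": population,
        "drought_events": events,
        "power": aux_frames["power"],
        "pulp": aux_frames["pulp"],
    }
    return facilities, aux


def generate_plots(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Inventory plot records over the facility box plus margin.

    One plot per 24.28 km² hexagon is emulated as uniform random placement
    at that density; each plot is re-measured on a fixed 3-year cycle with a
    random phase, so every 3-year sampling window sees exactly one record
    per plot.  Attribute columns are per-hectare densities; multiplying by
    the ~2428 ha expansion factor recovers represented totals.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    _, to_lonlat = local_km_transform(config.anchor_lon, config.anchor_lat)
    m = config.plot_margin_km
    w = config.box_width_km + 2 * m
    h = config.box_height_km + 2 * m
    n_plots = int(round(w * h / config.plot_hexagon_km2))
    xy = np.column_stack([rng.uniform(-w / 2, w / 2, n_plots), rng.uniform(-h / 2, h / 2, n_plots)])
    lonlat = to_lonlat(xy)
    timberland = (rng.random(n_plots) < config.timberland_share).astype(int)
    ef = config.expansion_factor_ha * rng.uniform(
        1.0 - config.expansion_jitter, 1.0 + config.expansion_jitter, n_plots
    )
    phase = rng.integers(0, 3, n_plots)
    base = {
        a: mean * rng.lognormal(
            -0.5 * config.attribute_density_sigma_log**2,
            config.attribute_density_sigma_log,
            n_plots,
        )
        for a, mean in config.attribute_density_per_ha.items()
    }
    first, last = min(config.panel_years) - 2, max(config.panel_years)
    records = []
    for year in range(first, last + 1):
        sel = (year - first) % 3 == ((phase + 0) % 3)
        # cycle anchored at the first window year: plot measured when
        # (year - first) ≡ phase (mod 3)
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            continue
        noise = rng.lognormal(
            -0.5 * config.remeasure_sigma_log**2, config.remeasure_sigma_log, idx.size
        )
        rec = {
            "plot_id": [f"plot_{i:06d}" for i in idx],
            "lon": lonlat[idx, 0],
            "lat": lonlat[idx, 1],
            "measure_year": year,
            "timberland": timberland[idx],
            "expansion_factor_ha": ef[idx],
        }
        for a in config.attribute_density_per_ha:
            rec[a] = base[a][idx] * noise
        records.append(pd.DataFrame(rec))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# response simulation from the model's data-generating process

def default_beta_vector(config: SimulationConfig, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in config.true_beta]
    if missing:
        raise ValueError(f"no true coefficient configured for: {missing}")
    return np.asarray([config.true_beta[n] for n in names], dtype=float)


def simulate_panel(
    design: DesignMatrices,
    wm: WeightMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticTruth:
    """Draw one response panel from the spatial composite-error process.

    mu_i ~ N(0, sigma2_mu) once per landscape, nu_{i,t} ~ N(0, sigma2_nu),
    eps_t = mu + nu_t, u_t = (I - rho W)^{-1} eps_t and
    Y_t = alpha + Z_t beta + u_t.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    N = len(design.facility_order)
    T = len(design.panel_years)
    B = np.eye(N) - config.true_rho * wm.W
    sign, _ = np.linalg.slogdet(B)
    if sign <= 0:
        raise ValueError("I - rho*W not invertible at true_rho")
    beta = default_beta_vector(config, design.names)
    mu = rng.normal(0.0, math.sqrt(config.sigma2_mu), N)
    nu = rng.normal(0.0, math.sqrt(config.sigma2_nu), (T, N))
    eps = mu[None, :] + nu
    u = np.linalg.solve(B, eps.T).T
    Y = config.true_alpha + np.einsum("tnk,k->tn", design.tensor, beta) + u
    return SyntheticTruth(
        Y=Y,
        mu=mu,
        nu=nu,
        eps=eps,
        u=u,
        alpha=config.true_alpha,
        beta=beta,
        beta_names=list(design.names),
        rho=config.true_rho,
        sigma2_mu=config.sigma2_mu,
        sigma2_nu=config.sigma2_nu,
    )


# ---------------------------------------------------------------------------
# fixture bundle I/O (CSV + GeoJSON, all plain text)

def drought_events_to_geojson(events: Sequence[DroughtEvent]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(ev.footprint),
                "properties": {"august_year": ev.august_year, "severity": ev.severity},
            }
            for ev in events
        ],
    }


def drought_events_from_geojson(doc: dict) -> List[DroughtEvent]:
    return [
        DroughtEvent(
            august_year=int(f["properties"]["august_year"]),
            severity=str(f["properties"]["severity"]),
            footprint=shape(f["geometry"]),
        )
        for f in doc["features"]
    ]


def write_bundle(outdir, config: SimulationConfig) -> dict:
    """Generate and write the full fixture bundle; returns file paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    facilities, aux = generate_facilities(config, rng)
    plots = generate_plots(config, np.random.default_rng(config.seed + 1))
    paths = {}
    fmt = "%.12g"
    facilities.to_csv(outdir / "facilities.csv", index=False, float_format=fmt)
    paths["facilities"] = outdir / "facilities.csv"
    for name in ("power", "pulp"):
        aux[name].to_csv(outdir / f"{name}.csv", index=False, float_format=fmt)
        paths[name] = outdir / f"{name}.csv"
    aux["ports"].to_csv(outdir / "ports.csv", index=False, float_format=fmt)
    paths["ports"] = outdir / "ports.csv"
    aux["population"].to_csv(outdir / "population.csv", index=False, float_format=fmt)
    paths["population"] = outdir / "population.csv"
    with open(outdir / "drought.geojson", "w") as fh:
        json.dump(drought_events_to_geojson(aux["drought_events"]), fh)
    paths["drought"] = outdir / "drought.geojson"
    plots.to_csv(outdir / "plots.csv", index=False, float_format=fmt)
    paths["plots"] = outdir / "plots.csv"
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.as_dict(), fh, indent=2, sort_keys=True)
    paths["config"] = outdir / "sim_config.json"
    return paths
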