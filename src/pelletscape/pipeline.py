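"""End-to-end orchestration: layers -> covariates -> panel -> fits -> report.

Stages are pure functions over DataFrames so the CLI can run them separately
against files, and tests can run them in memory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import geoscape, inventory, reporting
from .design import PANEL_YEARS, DesignMatrices, build_design
from .geoscape import (
    Facility,
    Landscape,
    assign_procurement_radius,
    circle_lens_area,
    haversine_matrix,
    operational_in_window,
)
from .inventory import ATTRIBUTES, build_attribute_panel, panel_to_response
from .model import SpatialREFit, fit_spatial_fe, fit_spatial_re, hausman_test
from .synthetic import SimulationConfig, drought_events_from_geojson
from .weights import WeightMatrix, build_weight_matrix

logger = logging.getLogger(__name__)


def facilities_to_landscapes(facilities: pd.DataFrame) -> list[Landscape]:
    out = []
    for row in facilities.itertuples():
        out.append(
            Landscape(
                facility_id=row.facility_id,
                lon=row.lon,
                lat=row.lat,
                radius_km=assign_procurement_radius(row.capacity_tpy, row.sector),
            )
        )
    return out


def _overlap_series(
    targets: pd.DataFrame,
    others: pd.DataFrame,
    panel_years: Sequence[int],
    exclude_self: bool,
) -> pd.DataFrame:
    """Summed lens/area fractions of ``others`` landscapes over ``targets``
    per panel year, counting only facilities operational in the window."""
    t_r = np.array(
        [assign_procurement_radius(c, s) for c, s in zip(targets["capacity_tpy"], targets["sector"])]
    )
    o_r = np.array(
        [assign_procurement_radius(c, s) for c, s in zip(others["capacity_tpy"], others["sector"])]
    )
    n_t, n_o = len(targets), len(others)
    d = haversine_matrix(
        np.concatenate([targets["lon"], others["lon"]]),
        np.concatenate([targets["lat"], others["lat"]]),
    )[:n_t, n_t:]
    lens = np.zeros((n_t, n_o))
    for i in range(n_t):
        for j in range(n_o):
            if exclude_self and targets["facility_id"].iat[i] == others["facility_id"].iat[j]:
                continue
            lens[i, j] = circle_lens_area(t_r[i], o_r[j], d[i, j])
    area = np.pi * t_r**2
    o_start = others["start_year"].to_numpy()
    o_end = others["end_year"].to_numpy()
    rows = []
    for year in panel_years:
        op = np.array(
            [
                operational_in_window(
                    None if pd.isna(s) else int(s), None if pd.isna(e) else int(e), year
                )
                for s, e in zip(o_start, o_end)
            ]
        )
        frac = (lens[:, op] @ np.ones(op.sum())) / area if op.any() else np.zeros(n_t)
        for fid, f in zip(targets["facility_id"], frac):
            rows.append({"facility_id": fid, "year": year, "overlap": f})
    return pd.DataFrame(rows)


def compute_covariates(
    facilities: pd.DataFrame,
    aux: dict,
    panel_years: Sequence[int] = PANEL_YEARS,
    port_flag: str = "exports_forest_products",
) -> dict:
    """All geometry-derived covariates for the design matrix.

    Returns dict with ``facilities`` (augmented with large_capacity,
    export_access, coastal_southeast), ``overlaps``, ``population`` and
    ``drought`` tables keyed by (facility_id, year).
    """
    fac = facilities.copy()
    fac["large_capacity"] = (fac["capacity_tpy"] >= geoscape.LARGE_CAPACITY_TPY).astype(int)
    fac["coastal_southeast"] = (fac["region"] == "coastal_southeast").astype(int)
    ports = aux["ports"]
    port_pts = ports.loc[ports[port_flag] == 1, ["lon", "lat"]].to_numpy()
    fac["export_access"] = [
        geoscape.proximity_flag((lo, la), port_pts) for lo, la in zip(fac["lon"], fac["lat"])
    ]

    landscapes = facilities_to_landscapes(fac)

    pellet = _overlap_series(fac, fac, panel_years, exclude_self=True).rename(
        columns={"overlap": "pellet_overlap"}
    )
    power = _overlap_series(fac, aux["power"], panel_years, exclude_self=False).rename(
        columns={"overlap": "power_overlap"}
    )
    pulp = _overlap_series(fac, aux["pulp"], panel_years, exclude_self=False).rename(
        columns={"overlap": "pulp_overlap"}
    )
    overlaps = pellet.merge(power, on=["facility_id", "year"]).merge(
        pulp, on=["facility_id", "year"]
    )

    pop = aux["population"]
    unit_lonlat = pop[["lon", "lat"]].to_numpy()
    d = haversine_matrix(
        np.concatenate([fac["lon"], pop["lon"]]),
        np.concatenate([fac["lat"], pop["lat"]]),
    )[: len(fac), len(fac):]
    radii = np.array([ls.radius_km for ls in landscapes])
    inside = d < radii[:, None]
    rows = []
    for year in panel_years:
        counts = pop["count_2011"].to_numpy() * (1.0 + pop["annual_growth"].to_numpy()) ** (
            year - 2011
        )
        totals = inside @ counts / 1000.0
        for fid, v in zip(fac["facility_id"], totals):
            rows.append({"facility_id": fid, "year": year, "population_thousands": v})
    population = pd.DataFrame(rows)

    events = aux["drought_events"]
    rows = []
    for ls in landscapes:
        for year in panel_years:
            rows.append(
                {
                    "facility_id": ls.facility_id,
                    "year": year,
                    "drought_lag": geoscape.drought_flag(ls, events, year),
                }
            )
    drought = pd.DataFrame(rows)

    return {
        "facilities": fac,
        "landscapes": landscapes,
        "overlaps": overlaps,
        "population": population,
        "drought": drought,
    }


def load_bundle(indir) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    indir = Path(indir)
    facilities = pd.read_csv(indir / "facilities.csv")
    aux = {
        "ports": pd.read_csv(indir / "ports.csv"),
        "population": pd.read_csv(indir / "population.csv"),
        "power": pd.read_csv(indir / "power.csv"),
        "pulp": pd.read_csv(indir / "pulp.csv"),
    }
    with open(indir / "drought.geojson") as fh:
        aux["drought_events"] = drought_events_from_geojson(json.load(fh))
    plots = pd.read_csv(indir / "plots.csv")
    return facilities, aux, plots


def run_pipeline(
    facilities: pd.DataFrame,
    aux: dict,
    plots: pd.DataFrame,
    panel_years: Sequence[int] = PANEL_YEARS,
    attributes: Sequence[str] = ATTRIBUTES,
    rho_starts: Sequence[float] = (-0.5, 0.0, 0.5),
    with_hausman: bool = True,
) -> dict:
    """Run covariates -> design -> weights -> inventory panel -> fits.

    Returns a dict with the design, weight matrix, attribute panel, fitted
    models, Hausman results, standardized and area-adjusted effects.
    """
    cov = compute_covariates(facilities, aux, panel_years)
    fac = cov["facilities"]
    design = build_design(fac, cov["overlaps"], cov["population"], cov["drought"], panel_years)
    wm = build_weight_matrix(fac["lon"].to_numpy(), fac["lat"].to_numpy())
    logger.info(
        "design: %d obs x %d covariates (%d dropped), %d isolated units",
        design.matrix.shape[0],
        design.matrix.shape[1],
        len(design.dropped),
        int(wm.isolated.sum()),
    )
    panel = build_attribute_panel(plots, cov["landscapes"], panel_years, attributes)
    if (panel["n_plots"] == 0).any():
        bad = panel.loc[panel["n_plots"] == 0, ["facility_id", "year"]].drop_duplicates()
        raise ValueError(f"empty inventory cells; cannot fit a balanced panel: {bad.values[:5]}")

    area = panel.groupby(["facility_id", "year"])["timberland_area_ha"].first()
    tv = design.time_variant
    fits: Dict[str, SpatialREFit] = {}
    hausman = {}
    standardized = {}
    adjusted = {}
    for attr in attributes:
        Y = panel_to_response(panel, attr, design.facility_order, panel_years)
        fit = fit_spatial_re(Y, design.tensor, wm.W, names=design.names, rho_starts=rho_starts)
        fits[attr] = fit
        logger.info("fit %s: rho=%.3f loglik=%.1f converged=%s", attr, fit.rho, fit.loglik, fit.converged)
        if with_hausman:
            idx = [design.names.index(n) for n in tv]
            fe = fit_spatial_fe(Y, design.tensor[:, :, idx], wm.W, names=tv, rho_starts=rho_starts)
            hausman[attr] = hausman_test(fe, fit)
        standardized[attr] = reporting.standardize_coefficients(fit, design.df, Y)
        adjusted[attr] = reporting.area_adjust(fit, area)
    return {
        "covariates": cov,
        "design": design,
        "weights": wm,
        "panel": panel,
        "timberland_area_ha": area,
        "fits": fits,
        "hausman": hausman,
        "standardized": standardized,
        "adjusted": adjusted,
    }
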