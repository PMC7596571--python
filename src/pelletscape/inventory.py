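"""Plot-to-landscape attribute estimation.

Timberland attributes for a landscape×period cell are estimated from
inventory plots the way national forest-inventory totals are built: each
plot carries an *area expansion factor* (hectares of land it represents) and
a per-hectare attribute density; the landscape total is the sum of density ×
expansion factor over the timberland plots that fall inside the procurement
circle and were measured within the 3-year window ending at the panel year.

Six attributes are tracked: numbers of live, growing-stock and standing-dead
trees, and carbon (tons) in live trees, standing-dead trees and organic soil.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geoscape import Landscape, haversine_to_point

logger = logging.getLogger(__name__)

ATTRIBUTES = (
    "live_trees",
    "growing_stock_trees",
    "standing_dead_trees",
    "carbon_live",
    "carbon_standing_dead",
    "carbon_soil",
)

PANEL_YEARS = (2005, 2008, 2011, 2014, 2017)
WINDOW_YEARS = 3


@dataclass(frozen=True)
class AttributeEstimate:
    facility_id: str
    period: int
    attribute: str
    total: float
    sampling_error_pct: float
    n_plots: int


def select_plots(
    plots: pd.DataFrame,
    landscape: Landscape,
    panel_year: int,
    window_years: int = WINDOW_YEARS,
) -> pd.DataFrame:
    """Timberland plots strictly inside the circle, measured in
    [panel_year - window + 1, panel_year]; latest re-measurement wins per
    plot_id.  May return an empty frame."""
    lo = panel_year - (window_years - 1)
    sub = plots[
        (plots["timberland"] == 1)
        & (plots["measure_year"] >= lo)
        & (plots["measure_year"] <= panel_year)
    ]
    if sub.empty:
        return sub
    d = haversine_to_point(
        sub["lon"].to_numpy(), sub["lat"].to_numpy(), landscape.lon, landscape.lat
    )
    sub = sub[d < landscape.radius_km]
    if sub.empty:
        logger.debug(
            "no plots selected for %s, panel %d", landscape.facility_id, panel_year
        )
        return sub
    # most recent measurement per plot
    sub = sub.sort_values("measure_year").groupby("plot_id", as_index=False).last()
    return sub


def estimate_attribute_total(subset: pd.DataFrame, attribute: str) -> AttributeEstimate:
    """Expansion-factor total with a simple-random-sampling standard error.

    total = Σ_p value_p × expansion_factor_p.  The sampling error treats the
    expanded per-plot values x_p as an SRS draw: SE(total) = sqrt(n · s²(x)),
    reported as a percentage of the total.  Fewer than two plots (or a zero
    total) reports error 0.
    """
    n = len(subset)
    if n == 0:
        return AttributeEstimate("", 0, attribute, 0.0, 0.0, 0)
    x = subset[attribute].to_numpy(dtype=float) * subset["expansion_factor_ha"].to_numpy(
        dtype=float
    )
    total = float(x.sum())
    if n < 2 or total == 0.0:
        err = 0.0
    else:
        se = math.sqrt(n * float(np.var(x, ddof=1)))
        err = 100.0 * se / total
    return AttributeEstimate("", 0, attribute, total, err, n)


def timberland_area_ha(subset: pd.DataFrame) -> float:
    """Estimated timberland hectares: summed expansion factors of the
    selected plots."""
    if subset.empty:
        return 0.0
    return float(subset["expansion_factor_ha"].sum())


def build_attribute_panel(
    plots: pd.DataFrame,
    landscapes: Sequence[Landscape],
    panel_years: Iterable[int] = PANEL_YEARS,
    attributes: Sequence[str] = ATTRIBUTES,
) -> pd.DataFrame:
    """Long panel of attribute estimates for every landscape × period.

    Returns a DataFrame keyed by (facility_id, year, attribute) with columns
    total, sampling_error_pct, n_plots, plus one row per (facility_id, year)
    pair carried implicitly through the ``timberland_area_ha`` column.
    Cells with no selected plots are kept (total 0, n_plots 0) and logged;
    model fitting refuses such panels upstream.
    """
    for a in attributes:
        if a not in plots.columns:
            raise ValueError(f"plots table missing attribute column {a!r}")
    records = []
    for landscape in landscapes:
        for year in panel_years:
            sub = select_plots(plots, landscape, year)
            area = timberland_area_ha(sub)
            if sub.empty:
                logger.warning(
                    "empty plot selection: landscape %s, panel %d",
                    landscape.facility_id,
                    year,
                )
            for a in attributes:
                est = estimate_attribute_total(sub, a)
                records.append(
                    {
                        "facility_id": landscape.facility_id,
                        "year": year,
                        "attribute": a,
                        "total": est.total,
                        "sampling_error_pct": est.sampling_error_pct,
                        "n_plots": est.n_plots,
                        "timberland_area_ha": area,
                    }
                )
    return pd.DataFrame.from_records(records)


def panel_to_response(panel: pd.DataFrame, attribute: str, facility_order, panel_years=PANEL_YEARS):
    """Extract a (T, N) response matrix for one attribute, rows ordered by
    ``panel_years`` and columns by ``facility_order``."""
    sub = panel[panel["attribute"] == attribute].pivot(
        index="year", columns="facility_id", values="total"
    )
    sub = sub.reindex(index=list(panel_years), columns=list(facility_order))
    if sub.isna().any().any():
        missing = sub.stack(dropna=False)
        missing = missing[missing.isna()]
        raise ValueError(f"missing panel cells for {attribute}: {list(missing.index)[:5]}")
    return sub.to_numpy(dtype=float)
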