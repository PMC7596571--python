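"""Model-ready design matrices for the landscape panel regression.

The regression explains each landscape×period timberland attribute with:
time-variant mill descriptors (operational dummy, years of operation),
time-invariant descriptors (large capacity, export-port access, coastal
southeast, seven ecoregion indicators against a Northern Hardwoods-Red Pine
baseline), competing-industry overlap fractions (pellet, power, pulp), a
post-2009 recession/bioenergy-policy indicator, population (thousands), a
one-year-lagged extreme-drought indicator, and eleven pairwise interaction
terms between the mill/region/weather descriptors, plus an intercept.

Observations are stacked period-major: row index t*N + i for period t and
landscape i, with a fixed facility ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geoscape import operational_in_window

PANEL_YEARS = (2005, 2008, 2011, 2014, 2017)
POST_RECESSION_YEARS = frozenset({2011, 2014, 2017})
MAX_YEARS_OF_OPERATION = 28

ECOREGIONS = (
    "Beech-Maple-Basswood",
    "Mesophytic",
    "Mississippi Alluvial Plain",
    "Northern Hardwoods-Hemlock",
    "Northern Hardwoods-Red Pine",  # baseline: no indicator column
    "Oak-Hickory",
    "Southern Mixed",
    "Subtropical Evergreen",
)
ECOREGION_BASELINE = "Northern Hardwoods-Red Pine"

#: the eleven interaction terms, as (column, column) parent pairs
INTERACTIONS = (
    ("years_operation", "coastal_southeast"),
    ("years_operation", "large_capacity"),
    ("mill_operational", "large_capacity"),
    ("mill_operational", "coastal_southeast"),
    ("mill_operational", "export_access"),
    ("large_capacity", "coastal_southeast"),
    ("large_capacity", "export_access"),
    ("large_capacity", "drought_lag"),
    ("coastal_southeast", "export_access"),
    ("coastal_southeast", "drought_lag"),
    ("export_access", "drought_lag"),
)


def mill_operational_dummy(start_year, end_year, panel_year: int) -> int:
    """1 iff the mill's operating span intersects the 3-year sampling window
    [panel_year - 2, panel_year]."""
    return int(operational_in_window(start_year, end_year, panel_year))


def years_of_operation(start_year, end_year, panel_year: int) -> int:
    """Inclusive count of continuous operating years accrued by the panel
    year (0 if operations had not started), capped at the observed support."""
    if start_year is None or start_year > panel_year:
        return 0
    stop = panel_year if end_year is None else min(panel_year, end_year)
    return min(max(0, stop - start_year + 1), MAX_YEARS_OF_OPERATION)


@dataclass
class DesignMatrices:
    """Wide design table plus block bookkeeping.

    ``df`` has a (year, facility_id) MultiIndex sorted period-major and one
    column per covariate (intercept excluded; the estimator adds it).
    """

    df: pd.DataFrame
    groups: Dict[str, List[str]]
    dropped: List[str]
    facility_order: List[str]
    panel_years: List[int]

    @property
    def names(self) -> List[str]:
        return list(self.df.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def tensor(self) -> np.ndarray:
        """(T, N, K) view of the stacked design."""
        T = len(self.panel_years)
        N = len(self.facility_order)
        return self.matrix.reshape(T, N, -1)

    @property
    def time_variant(self) -> List[str]:
        """Columns that vary within at least one landscape over time."""
        out = []
        for c in self.df.columns:
            wide = self.df[c].unstack(level=0)  # facilities × years
            if (wide.nunique(axis=1) > 1).any():
                out.append(c)
        return out


def build_design(
    facilities: pd.DataFrame,
    overlaps: pd.DataFrame,
    population: pd.DataFrame,
    drought: pd.DataFrame,
    panel_years: Sequence[int] = PANEL_YEARS,
    drop_empty: bool = True,
) -> DesignMatrices:
    """Assemble all covariate blocks into one design table.

    Parameters
    ----------
    facilities
        One row per pellet mill: facility_id, start_year, end_year,
        large_capacity, export_access, coastal_southeast, ecoregion.
    overlaps
        (facility_id, year) rows with pellet_overlap, power_overlap,
        pulp_overlap fractions.
    population
        (facility_id, year) rows with population_thousands.
    drought
        (facility_id, year) rows with drought_lag in {0, 1} (the flag for
        the August preceding ``year``).
    drop_empty
        Drop constant-zero columns (e.g. unoccupied ecoregions) so they
        never enter estimation.
    """
    fac = facilities.set_index("facility_id", drop=False)
    order = list(fac.index)
    idx = pd.MultiIndex.from_product(
        [list(panel_years), order], names=["year", "facility_id"]
    )

    def lookup(df: pd.DataFrame, col: str) -> pd.Series:
        s = df.set_index(["year", "facility_id"])[col].reindex(idx)
        if s.isna().any():
            year, fid = s[s.isna()].index[0]
            raise ValueError(f"missing {col} for facility {fid!r}, year {year}")
        return s.astype(float)

    out = pd.DataFrame(index=idx)
    start = fac["start_year"].where(fac["start_year"].notna(), None)
    end = fac["end_year"].where(fac["end_year"].notna(), None)
    out["mill_operational"] = [
        mill_operational_dummy(
            None if pd.isna(start[f]) else int(start[f]),
            None if pd.isna(end[f]) else int(end[f]),
            y,
        )
        for y, f in idx
    ]
    out["years_operation"] = [
        years_of_operation(
            None if pd.isna(start[f]) else int(start[f]),
            None if pd.isna(end[f]) else int(end[f]),
            y,
        )
        for y, f in idx
    ]
    for col in ("large_capacity", "export_access", "coastal_southeast"):
        if col not in fac.columns:
            raise ValueError(f"facilities table missing column {col!r}")
        out[col] = [float(fac.loc[f, col]) for y, f in idx]
    eco_cols = []
    for eco in ECOREGIONS:
        if eco == ECOREGION_BASELINE:
            continue
        name = "eco_" + eco.lower().replace(" ", "_").replace("-", "_")
        out[name] = [float(fac.loc[f, "ecoregion"] == eco) for y, f in idx]
        eco_cols.append(name)
    for col in ("pellet_overlap", "power_overlap", "pulp_overlap"):
        out[col] = lookup(overlaps, col)
    out["post_2009"] = [float(y in POST_RECESSION_YEARS) for y, f in idx]
    out["population_thousands"] = lookup(population, "population_thousands")
    out["drought_lag"] = lookup(drought, "drought_lag")

    inter_cols = []
    for a, b in INTERACTIONS:
        name = f"{a}_x_{b}"
        out[name] = out[a] * out[b]
        inter_cols.append(name)

    groups = {
        "X": ["mill_operational", "years_operation"],
        "F": ["large_capacity", "export_access", "coastal_southeast"] + eco_cols,
        "C": ["pellet_overlap", "power_overlap", "pulp_overlap"],
        "R": ["post_2009"],
        "P": ["population_thousands"],
        "D": ["drought_lag"],
        "INT": inter_cols,
    }

    dropped = []
    if drop_empty:
        for c in list(out.columns):
            if (out[c] == 0.0).all():
                dropped.append(c)
        out = out.drop(columns=dropped)
        groups = {g: [c for c in cols if c not in dropped] for g, cols in groups.items()}

    # indicator sanity
    for c in ["mill_operational", "large_capacity", "export_access",
              "coastal_southeast", "post_2009", "drought_lag"] + eco_cols:
        if c in out.columns and not out[c].isin([0.0, 1.0]).all():
            raise ValueError(f"indicator column {c} has non-binary entries")

    return DesignMatrices(
        df=out,
        groups=groups,
        dropped=dropped,
        facility_order=order,
        panel_years=list(panel_years),
    )


def write_design_csv(design: DesignMatrices, path) -> None:
    """Long-format export: facility_id, year, covariate, value."""
    long = (
        design.df.stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_2": "covariate"})
    )
    long = long[["facility_id", "year", "covariate", "value"]]
    long.to_csv(path, index=False, float_format="%.12g")
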