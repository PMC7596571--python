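"""Standardized coefficients, per-hectare effects, and result export.

Standardization rescales a raw coefficient by the ratio of the covariate's
to the response's pooled sample standard deviation, std_beta = beta * s_x /
s_y, making effect sizes comparable across the six attribute models.  Area
adjustment converts a per-procurement-area coefficient into a per-hectare
rate by dividing by a timberland-hectare divisor; because the appropriate
divisor is a modelling choice, the policy is explicit and configurable
(default: the panel-mean timberland hectares per landscape), and the divisor
used is recorded on every output row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import SpatialREFit


@dataclass(frozen=True)
class StandardizedEffect:
    covariate: str
    beta: float
    s_x: float
    s_y: float
    std_beta: float      # nan when undefined (zero-variance covariate/response)
    p: float
    defined: bool


def standardize_coefficients(
    fit: SpatialREFit, design_df: pd.DataFrame, y: np.ndarray
) -> list[StandardizedEffect]:
    """One standardized effect per non-intercept coefficient; SDs are pooled
    over all N*T observations.  Zero-variance covariates are flagged rather
    than silently zeroed."""
    y = np.asarray(y, dtype=float).reshape(-1)
    s_y = float(np.std(y, ddof=1))
    out = []
    for name, b, p in zip(fit.names[1:], fit.beta, fit.p[1:]):
        s_x = float(design_df[name].std(ddof=1))
        defined = s_x > 0 and s_y > 0
        out.append(
            StandardizedEffect(
                covariate=name,
                beta=float(b),
                s_x=s_x,
                s_y=s_y,
                std_beta=float(b) * s_x / s_y if defined else float("nan"),
                p=float(p),
                defined=defined,
            )
        )
    return out


@dataclass(frozen=True)
class AreaAdjustedEffect:
    covariate: str
    per_area: float
    per_ha: float
    divisor_ha: float


def area_adjust(
    fit: SpatialREFit,
    timberland_area_ha: pd.Series,
    divisor_overrides: Optional[Mapping[str, float]] = None,
    include_intercept: bool = True,
) -> list[AreaAdjustedEffect]:
    """Per-hectare effects.

    ``timberland_area_ha`` holds one value per (facility, period) cell; the
    default divisor is its mean.  ``divisor_overrides`` maps covariate names
    to alternative divisors (e.g. the large-capacity-landscape mean for
    coefficients interacted with large capacity).
    """
    default = float(np.mean(np.asarray(timberland_area_ha, dtype=float)))
    if default <= 0:
        raise ValueError("zero hectare divisor")
    names = fit.names if include_intercept else fit.names[1:]
    params = fit.params if include_intercept else fit.beta
    out = []
    for name, b in zip(names, params):
        div = float(divisor_overrides.get(name, default)) if divisor_overrides else default
        if div <= 0:
            raise ValueError(f"zero hectare divisor for {name}")
        out.append(AreaAdjustedEffect(name, float(b), float(b) / div, div))
    return out


def config_hash(config: Mapping) -> str:
    """Stable hash of a configuration mapping (order-insensitive)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def results_table(
    fit: SpatialREFit,
    standardized: Sequence[StandardizedEffect],
    adjusted: Sequence[AreaAdjustedEffect],
) -> pd.DataFrame:
    """Wide per-attribute table: coefficient, SE, ha-adjusted effect, p."""
    adj = {a.covariate: a for a in adjusted}
    rows = []
    for name, b, se, p in zip(fit.names, fit.params, fit.se, fit.p):
        rows.append(
            {
                "covariate": name,
                "coefficient": b,
                "std_error": se,
                "ha_adjusted": adj[name].per_ha if name in adj else np.nan,
                "divisor_ha": adj[name].divisor_ha if name in adj else np.nan,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def export_results(
    fits: Dict[str, SpatialREFit],
    standardized: Dict[str, Sequence[StandardizedEffect]],
    adjusted: Dict[str, Sequence[AreaAdjustedEffect]],
    outdir,
    config: Mapping,
    seed: Optional[int] = None,
    timestamp: Optional[str] = None,
) -> dict:
    """Write one wide CSV per attribute, a long standardized-coefficient CSV,
    and a JSON manifest.  Floats carry 12 significant digits; re-running with
    the same seed and config reproduces the CSVs byte for byte."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fit in fits.items():
        table = results_table(fit, standardized[attr], adjusted[attr])
        path = outdir / f"{attr}.csv"
        table.to_csv(path, float_format="%.12g")
        written.append(path.name)
    long = []
    for attr, effects in standardized.items():
        for e in effects:
            long.append(
                {
                    "attribute": attr,
                    "covariate": e.covariate,
                    "std_beta": e.std_beta,
                    "p": e.p,
                    "defined": e.defined,
                }
            )
    std_path = outdir / "standardized.csv"
    pd.DataFrame(long).to_csv(std_path, index=False, float_format="%.12g")
    written.append(std_path.name)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": {k: config[k] for k in sorted(config)},
        "attributes": sorted(fits),
        "files": written,
        "rho": {a: fits[a].rho for a in sorted(fits)},
        "loglik": {a: fits[a].loglik for a in sorted(fits)},
        "converged": {a: fits[a].converged for a in sorted(fits)},
    }
    if timestamp is not None:
        manifest["created"] = timestamp
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def plot_standardized(standardized: Dict[str, Sequence[StandardizedEffect]], path) -> None:
    """Dot plot of standardized coefficients by covariate across attributes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    attrs = sorted(standardized)
    covs = [e.covariate for e in standardized[attrs[0]] if e.defined]
    fig, ax = plt.subplots(figsize=(8, max(4, 0.3 * len(covs))))
    for j, attr in enumerate(attrs):
        vals = {e.covariate: e.std_beta for e in standardized[attr]}
        ax.scatter(
            [vals.get(c, np.nan) for c in covs], range(len(covs)), label=attr, s=18
        )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(covs)))
    ax.set_yticklabels(covs, fontsize=7)
    ax.set_xlabel("standardized coefficient")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
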