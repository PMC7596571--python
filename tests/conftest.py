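import numpy as np
import pandas as pd
import pytest

from pelletscape.design import build_design
from pelletscape.pipeline import compute_covariates
from pelletscape.synthetic import SimulationConfig, generate_facilities
from pelletscape.weights import build_weight_matrix


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: 20 landscapes in a smaller box, light aux layers."""
    return SimulationConfig(
        seed=11,
        n_facilities=20,
        box_width_km=420.0,
        box_height_km=380.0,
        min_separation_km=40.0,
        n_ports=8,
        n_power=28,
        n_pulp=10,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Facilities, aux layers, covariates, design and weights for the
    reduced study."""
    fac, aux = generate_facilities(small_config)
    cov = compute_covariates(fac, aux)
    design = build_design(
        cov["facilities"], cov["overlaps"], cov["population"], cov["drought"]
    )
    wm = build_weight_matrix(
        cov["facilities"]["lon"].to_numpy(), cov["facilities"]["lat"].to_numpy()
    )
    return {"facilities": fac, "aux": aux, "cov": cov, "design": design, "wm": wm}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_weights(rng, n, spread=2.0):
    """Helper: a valid row-normalized weight matrix over random points."""
    lon = rng.uniform(-85.0, -85.0 + spread, n)
    lat = rng.uniform(34.0, 34.0 + spread, n)
    return build_weight_matrix(lon, lat)
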