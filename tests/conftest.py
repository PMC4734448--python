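"""Shared fixtures: small grids, flows, and synthetic community scenarios."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from reefplume.diversity import OtuTable
from reefplume.exposure import SiteRecord
from reefplume.synth import ScenarioConfig
from reefplume.transport import FlowField, Grid, TransportParams


@pytest.fixture
def closed_basin():
    grid = Grid.open_water(nx=12, ny=10, dx=1000.0, dy=1000.0)
    flow = FlowField(u=np.zeros((10, 12)), v=np.zeros((10, 12)))
    params = TransportParams(K=40.0, dt=600.0, boundary_mode="closed")
    return grid, flow, params


@pytest.fixture
def channel():
    """Long open channel with uniform along-x flow."""
    grid = Grid.open_water(nx=60, ny=5, dx=1000.0, dy=1000.0)
    u = np.full((5, 60), 0.5)
    flow = FlowField(u=u, v=np.zeros((5, 60)))
    params = TransportParams(K=0.0, dt=500.0, boundary_mode="open-outflow")
    return grid, flow, params


@pytest.fixture
def random_otu_table():
    rng = np.random.default_rng(42)
    n_samples, n_otus = 8, 30
    counts = rng.integers(0, 60, size=(n_samples, n_otus))
    otus = [f"otu{k}" for k in range(n_otus)]
    return OtuTable(
        counts=pd.DataFrame(counts, index=[f"s{k}" for k in range(n_samples)], columns=otus),
        taxonomy=pd.Series([f"k__B; p__; c__; o__O{k % 4}; f__; g__; s__" for k in range(n_otus)], index=otus),
        copy_number=pd.Series(rng.integers(1, 9, n_otus).astype(float), index=otus),
        domain=pd.Series(["prokaryote"] * 25 + ["eukaryote"] * 5, index=otus),
    )


@pytest.fixture
def transect_scenario():
    """Seven-site transect, six dates spanning wet and dry seasons."""
    sites = [
        SiteRecord(id="TR", cell=(2, 5), distance_km=12.0, relation="upstream"),
        SiteRecord(id="TT1", cell=(2, 6), distance_km=4.0, relation="downstream"),
        SiteRecord(id="TT2", cell=(2, 7), distance_km=8.0, relation="downstream"),
        SiteRecord(id="TT3", cell=(2, 9), distance_km=16.0, relation="downstream"),
        SiteRecord(id="TT4", cell=(2, 14), distance_km=36.0, relation="downstream"),
        SiteRecord(id="RI", cell=(2, 16), distance_km=44.0, relation="downstream"),
        SiteRecord(id="FI", cell=(2, 20), distance_km=60.0, relation="downstream"),
    ]
    from reefplume.exposure import classify_site

    for s in sites:
        s.category = classify_site(s)
    dates = [
        date(2011, 10, 10),
        date(2011, 11, 20),
        date(2011, 12, 15),
        date(2012, 1, 20),
        date(2012, 3, 10),
        date(2012, 6, 15),
    ]
    return ScenarioConfig(sites=sites, dates=dates, seed=3)
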