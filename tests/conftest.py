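"""Shared fixtures: small deterministic grids and one large attributed landscape."""

from __future__ import annotations

import numpy as np
import pytest

import riverscape as rs


@pytest.fixture(scope="session")
def east_plane() -> rs.ElevationGrid:
    """A 10x12 plane tilted strictly east (no depressions, unique descent)."""
    cols = np.arange(12, dtype=float)
    z = 500.0 + (11 - cols)[None, :] * np.ones((10, 1))
    return rs.ElevationGrid(values=z, cell_size=10.0, origin=(0.0, 100.0))


def random_grid(seed: int, rows: int = 20, cols: int = 20, cell: float = 10.0) -> rs.ElevationGrid:
    rng = np.random.default_rng(seed)
    return rs.ElevationGrid(values=rng.uniform(0, 100, size=(rows, cols)),
                            cell_size=cell, origin=(0.0, rows * cell))


@pytest.fixture(scope="session")
def valley_landscape():
    """A small dendritic landscape carried through extraction and attribution.

    256x256 cells of 50 m; delineation at 0.2 km^2 and 0.5 km reaches keeps
    the network large enough for modelling tests but cheap to build.
    """
    spec = rs.SyntheticLandscapeSpec(rows=256, cols=256, cell_size=50.0,
                                     kind="dendritic_fractal", seed=3)
    dem = rs.generate_dem(spec)
    filled = rs.fill_depressions(dem)
    flow = rs.d8_flow_direction(filled)
    acc = rs.flow_accumulation(flow)
    mask = rs.delineate_streams(acc, 0.2)
    net = rs.vectorize_and_split(mask, flow, dem, grain_km=0.5)
    env = rs.generate_env_rasters(dem, ["temperature", "precipitation"], seed=1)
    table = rs.build_predictor_table(net, dem, flow, mask, env_rasters=env, filled=filled)
    rs.attach_attributes(net, table)
    return {"dem": dem, "filled": filled, "flow": flow, "acc": acc, "mask": mask,
            "net": net, "env": env, "table": table}


@pytest.fixture(scope="session")
def recovery_landscape():
    """The large landscape used for virtual-species recovery: a 512x512
    dendritic terrain whose network exceeds 10,000 reaches (0.05 km^2
    threshold, 0.25 km grain)."""
    spec = rs.SyntheticLandscapeSpec(rows=512, cols=512, cell_size=50.0,
                                     kind="dendritic_fractal", seed=11)
    dem = rs.generate_dem(spec)
    filled = rs.fill_depressions(dem)
    flow = rs.d8_flow_direction(filled)
    acc = rs.flow_accumulation(flow)
    mask = rs.delineate_streams(acc, 0.05)
    net = rs.vectorize_and_split(mask, flow, dem, grain_km=0.25)
    env = rs.generate_env_rasters(dem, ["temperature", "precipitation"], seed=1)
    table = rs.build_predictor_table(net, dem, flow, mask, env_rasters=env, filled=filled)
    return {"dem": dem, "flow": flow, "mask": mask, "net": net, "table": table}
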