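"""Shared fixtures: small synthetic worlds and one full pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import rangeshift as rs
from rangeshift import bioclim, synth
from rangeshift.grids import GridSpec


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=12, n_cols=15, cell_size_km=5.0)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    """A smooth bioclim stack on a small grid for model-level tests."""
    series = synth.make_monthly_climate(
        small_grid,
        base_temp_c=20.0,
        south_north_temp_gradient=40.0,
        seasonal_amplitude=4.0,
        mean_annual_precip=900.0,
        east_west_precip_gradient=2.0,
        noise_sd=0.0,
        seed=0,
    )
    return bioclim.derive_bioclim(series)


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down pipeline configuration that runs in a few seconds."""
    cfg = rs.default_scenario(seed=5)
    cfg.grid = {"n_rows": 24, "n_cols": 30, "cell_size_km": 5.0}
    cfg.decades = [1990, 2000, 2010]
    cfg.gcms = cfg.gcms[:2]
    cfg.n_regions = 5
    # anchors rescaled into the smaller grid; keep one species per category
    anchors = [(12, 8), (16, 15), (20, 22)]
    cfg.species = cfg.species[:3]
    for sp, (r, c) in zip(cfg.species, anchors):
        sp["anchor_row"], sp["anchor_col"] = r, c
    cfg.species[0]["meta"]["dispersal_category"] = "full"
    cfg.species[1]["meta"].update(
        {"dispersal_category": "rate_limited", "dispersal_rate_km_per_year": 3.0}
    )
    cfg.species[2]["meta"].update(
        {"dispersal_category": "none", "dispersal_rate_km_per_year": None}
    )
    cfg.n_occurrences_per_species = 120
    cfg.max_presence_cells = 80
    return cfg


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One full pipeline run of the bundled default scenario."""
    cfg = rs.default_scenario(seed=1)
    out = tmp_path_factory.mktemp("fixture_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = rs.run(cfg, out)
    return cfg, out, manifest


def flood_fill_patches(presence: np.ndarray, connectivity: int) -> int:
    """Independent patch-count oracle: BFS flood fill."""
    presence = np.asarray(presence, dtype=bool)
    seen = np.zeros_like(presence)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    n = 0
    rows, cols = presence.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not presence[r0, c0] or seen[r0, c0]:
                continue
            n += 1
            queue = [(r0, c0)]
            seen[r0, c0] = True
            while queue:
                r, c = queue.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and presence[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
    return n
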