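"""The bundled synthetic study scenario.

A 60 x 80 grid of 5-km cells carries a north-hot / south-cool temperature
gradient (30 degC per 1000 km, so the grid's 300-km extent spans ~9 degC —
the landscape is a scaled-down continent) and a west-dry / east-wet rainfall
gradient.  Four circulation models with (1, 2, 3, 2) realizations project
ten decades, 1990-2080; their realization-weighted mean warming reaches
about +3.4 degC by 2080, with rainfall factors within a few percent per
decade.  Twelve virtual species with Gaussian niches anchored at cells in
the northern two-thirds of the grid (so their ranges can track the roughly
110-km southward isotherm shift without leaving the landscape) span all
three dispersal categories: eight full, three rate-limited at 3 km/yr, one
no-dispersal.
"""

from __future__ import annotations

from .pipeline import RunConfig

__all__ = ["default_scenario"]

# niche widths per bioclim variable: narrow in mat and ap (the gradient
# axes), effectively unconstraining elsewhere
_WIDTHS = {"mat": 0.6, "ts": 60.0, "twp": 12.0, "ap": 85.0, "ps": 300.0, "pdp": 60.0}

_MOVEMENT = ["M", "N", "P", "S", "SN"]
# biogeographic affiliations interleaved against the movement cycle so the
# two groupings partition the assemblage differently
_BIOGEO = ["tropical", "arid", "temperate", "tropical", "CYP", "ubiquitous",
           "arid", "temperate", "CYP", "tropical", "ubiquitous", "arid"]


def default_scenario(seed: int = 1) -> RunConfig:
    """The default 12-species, 4-GCM, 10-decade synthetic scenario."""
    # anchors stay away from the grid edges so niches are not truncated
    anchors = [(r, c) for r in (32, 40, 48, 56) for c in (16, 40, 64)]
    species = []
    for i, (row, col) in enumerate(anchors):
        sid = f"sp{i + 1:02d}"
        if i < 8:
            category, rate = "full", None
        elif i < 11:
            category, rate = "rate_limited", 3.0
        else:
            category, rate = "none", None
        species.append(
            {
                "species_id": sid,
                "anchor_row": row,
                "anchor_col": col,
                "niche_width": dict(_WIDTHS),
                "prevalence_threshold": "entropy",
                "meta": {
                    "movement_class": _MOVEMENT[i % 5],
                    "biogeo_group": _BIOGEO[i],
                    "dispersal_category": category,
                    "dispersal_rate_km_per_year": rate,
                    "status": {"sp03": "V", "sp07": "E"}.get(sid),
                },
            }
        )
    return RunConfig(
        seed=seed,
        grid={"n_rows": 60, "n_cols": 80, "cell_size_km": 5.0},
        climate={
            "base_temp_c": 18.0,
            "south_north_temp_gradient": 30.0,
            "seasonal_amplitude": 4.0,
            "peak_month": 1,
            "wet_season_months": [12, 1, 2, 3],
            "mean_annual_precip": 800.0,
            "east_west_precip_gradient": 1.5,
            "noise_sd": 0.3,
        },
        gcms=[
            {"gcm_id": "gcmA", "n_realizations": 1, "temp_trend_per_decade": 0.30,
             "precip_factor_per_decade": 0.995, "realization_noise_sd": 0.08},
            {"gcm_id": "gcmB", "n_realizations": 2, "temp_trend_per_decade": 0.36,
             "precip_factor_per_decade": 1.005, "realization_noise_sd": 0.08},
            {"gcm_id": "gcmC", "n_realizations": 3, "temp_trend_per_decade": 0.42,
             "precip_factor_per_decade": 0.99, "realization_noise_sd": 0.08},
            {"gcm_id": "gcmD", "n_realizations": 2, "temp_trend_per_decade": 0.45,
             "precip_factor_per_decade": 1.01, "realization_noise_sd": 0.08},
        ],
        decades=list(range(1990, 2090, 10)),
        n_regions=12,
        species=species,
        n_occurrences_per_species=230,
        max_presence_cells=200,
        n_background=10_000,
        beta_multiplier=0.001,
        auc_threshold=0.7,
        dispersal_rate_km_per_year=3.0,
        connectivity=8,
    )
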