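"""Synthetic climate, landscape and virtual-species generators.

Every downstream stage of the pipeline (bioclim derivation, model fitting,
ensemble projection, dispersal masking, richness summaries) is exercised on
data from this module, so its generators encode the statistical structure the
analysis assumes: a 12-month climate cycle with smooth spatial gradients, a
family of circulation-model-like future trends with per-realization noise, a
mosaic of contiguous biogeographic subregions, and virtual species whose true
suitability is a known Gaussian function of the six bioclimatic covariates,
sampled with presence-only records.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NoHabitatError, SchemaError
from .grids import GridSpec

__all__ = [
    "MonthlyClimateSeries",
    "GcmSpec",
    "RegionMosaic",
    "SpeciesMeta",
    "VirtualSpecies",
    "make_region_mosaic",
    "make_monthly_climate",
    "make_future_series",
    "make_virtual_species",
    "entropy_prevalence_threshold",
    "sample_occurrences",
]

MOVEMENT_CLASSES = ("M", "N", "P", "S", "SN")
BIOGEO_GROUPS = ("arid", "CYP", "temperate", "tropical", "ubiquitous")
DISPERSAL_CATEGORIES = ("full", "rate_limited", "none")


@dataclass
class MonthlyClimateSeries:
    """Twelve monthly temperature (degC) and precipitation (mm) rasters."""

    temperature: np.ndarray  # (12, rows, cols)
    precipitation: np.ndarray  # (12, rows, cols), >= 0
    grid: GridSpec
    year_label: int = 1990

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=np.float64)
        self.precipitation = np.asarray(self.precipitation, dtype=np.float64)
        for name, arr in (("temperature", self.temperature), ("precipitation", self.precipitation)):
            if arr.shape != (12, *self.grid.shape):
                raise SchemaError(f"{name} must have shape (12, rows, cols), got {arr.shape}")
        if np.nanmin(self.precipitation) < 0:
            raise InvalidParameterError("precipitation must be non-negative")


@dataclass(frozen=True)
class GcmSpec:
    """A circulation model's trend and realization structure.

    temp_trend_per_decade is an additive degC shift per decade index;
    precip_factor_per_decade a multiplicative rainfall factor per decade
    index; realization_noise_sd the spread of per-realization offsets
    (degC for temperature, fractional for precipitation).
    """

    gcm_id: str
    n_realizations: int = 1
    temp_trend_per_decade: float = 0.378
    precip_factor_per_decade: float = 1.0
    realization_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise InvalidParameterError("n_realizations must be >= 1")
        if not self.precip_factor_per_decade > 0:
            raise InvalidParameterError("precip_factor_per_decade must be > 0")


@dataclass
class RegionMosaic:
    """Integer raster assigning every cell to one contiguous subregion."""

    labels: np.ndarray  # (rows, cols) int
    grid: GridSpec

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


@dataclass(frozen=True)
class SpeciesMeta:
    """Life-history metadata carried through to the summaries.

    dispersal_rate_km_per_year is meaningful only for the rate-limited
    category (3 km/yr is the assemblage-wide default rate).
    """

    species_id: str
    movement_class: str = "S"
    biogeo_group: str = "tropical"
    dispersal_category: str = "full"
    dispersal_rate_km_per_year: float | None = None
    status: str | None = None

    def __post_init__(self) -> None:
        if self.movement_class not in MOVEMENT_CLASSES:
            raise SchemaError(f"unknown movement class {self.movement_class!r}")
        if self.biogeo_group not in BIOGEO_GROUPS:
            raise SchemaError(f"unknown biogeographic group {self.biogeo_group!r}")
        if self.dispersal_category not in DISPERSAL_CATEGORIES:
            raise SchemaError(f"unknown dispersal category {self.dispersal_category!r}")
        if self.dispersal_category == "rate_limited":
            if self.dispersal_rate_km_per_year is None:
                raise InvalidParameterError("rate_limited species need a dispersal rate")
        elif self.dispersal_rate_km_per_year is not None:
            raise InvalidParameterError(
                "dispersal_rate_km_per_year only applies to rate_limited species"
            )


@dataclass
class VirtualSpecies:
    """A species with a known Gaussian climatic niche.

    True suitability at a cell with bioclim vector x is
    exp(-0.5 * sum_v ((x_v - center_v) / width_v)^2), and the true range is
    the set of cells at or above ``prevalence_threshold``.
    """

    niche_center: dict[str, float]
    niche_width: dict[str, float]
    prevalence_threshold: float = 0.5
    meta: SpeciesMeta = field(default_factory=lambda: SpeciesMeta("sp"))
    true_suitability: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.niche_width.values()):
            raise InvalidParameterError("niche widths must be strictly positive")

    @property
    def true_range(self) -> np.ndarray:
        if self.true_suitability is None:
            raise InvalidParameterError("true suitability has not been evaluated")
        with np.errstate(invalid="ignore"):
            return self.true_suitability >= self.prevalence_threshold


def make_region_mosaic(grid: GridSpec, n_regions: int, seed: int) -> RegionMosaic:
    """Partition the grid into ``n_regions`` contiguous Voronoi subregions.

    Seed points are drawn uniformly (without replacement) among cells; each
    cell takes the label of its nearest seed (Euclidean, ties to the lowest
    label), which yields contiguous regions covering the whole grid.
    """
    if n_regions < 1 or n_regions > grid.n_cells:
        raise InvalidParameterError(
            f"n_regions must be in [1, {grid.n_cells}], got {n_regions}"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n_regions, replace=False)
    seed_rows, seed_cols = np.unravel_index(flat, grid.shape)
    xs, ys = grid.cell_centers()
    sx = grid.origin_x + (seed_cols + 0.5) * grid.cell_size_km
    sy = grid.origin_y + (seed_rows + 0.5) * grid.cell_size_km
    d2 = (xs[None] - sx[:, None, None]) ** 2 + (ys[None] - sy[:, None, None]) ** 2
    labels = np.argmin(d2, axis=0).astype(np.int32) + 1
    return RegionMosaic(labels=labels, grid=grid)


def make_monthly_climate(
    grid: GridSpec,
    *,
    base_temp_c: float = 22.0,
    south_north_temp_gradient: float = 0.0,
    seasonal_amplitude: float = 5.0,
    peak_month: int = 1,
    wet_season_months: tuple[int, ...] = (12, 1, 2, 3),
    mean_annual_precip: float = 800.0,
    east_west_precip_gradient: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    year_label: int = 1990,
) -> MonthlyClimateSeries:
    """Generate a baseline year of monthly climate on the grid.

    Temperature at (month, cell) is
    ``base + gradient * northing/1000 + amplitude * cos(2 pi (month - peak)/12)``
    plus iid Gaussian noise; gradients are per 1000 km so they read as
    continental-scale lapse rates.  Precipitation distributes
    ``mean_annual_precip`` over the wet-season months (scaled by an
    east-west fractional gradient per 1000 km), with multiplicative
    lognormal-style noise, clamped at zero.
    """
    if seasonal_amplitude < 0 or mean_annual_precip < 0 or noise_sd < 0:
        raise InvalidParameterError("amplitudes, precipitation and noise_sd must be >= 0")
    if not wet_season_months:
        raise InvalidParameterError("wet_season_months must be nonempty")
    rng = np.random.default_rng(seed)
    xs, ys = grid.cell_centers()
    northing = ys - grid.origin_y
    easting = xs - grid.origin_x

    months = np.arange(1, 13)
    seasonal = seasonal_amplitude * np.cos(2 * np.pi * (months - peak_month) / 12.0)
    temp = (
        base_temp_c
        + south_north_temp_gradient * northing[None] / 1000.0
        + seasonal[:, None, None]
    )
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=temp.shape)

    wet = np.isin(months, np.asarray(wet_season_months))
    n_wet = int(wet.sum())
    if n_wet == 0:
        raise InvalidParameterError("wet_season_months must name months 1..12")
    # 90% of annual rain falls in the wet season, the rest spread evenly.
    if n_wet == 12:
        monthly_share = np.full(12, 1 / 12.0)
    else:
        monthly_share = np.where(wet, 0.9 / n_wet, 0.1 / (12 - n_wet))
    precip_field = mean_annual_precip * (
        1.0 + east_west_precip_gradient * easting / 1000.0
    )
    precip_field = np.clip(precip_field, 0.0, None)
    precip = monthly_share[:, None, None] * precip_field[None]
    if noise_sd > 0:
        precip = precip * (1.0 + rng.normal(0.0, noise_sd / 10.0, size=precip.shape))
    precip = np.clip(precip, 0.0, None)

    return MonthlyClimateSeries(
        temperature=temp, precipitation=precip, grid=grid, year_label=year_label
    )


def make_future_series(
    baseline: MonthlyClimateSeries,
    gcms: list[GcmSpec],
    decades: list[int],
    seed: int,
) -> dict[tuple[str, int, int], MonthlyClimateSeries]:
    """Project the baseline forward under each GCM realization and decade.

    The decade index is counted in 10-year steps from the first decade, so
    the first decade reproduces the baseline up to realization noise.
    Temperature shifts additively by ``trend * index`` and precipitation
    scales by ``factor ** index``; each (gcm, realization, decade) draws its
    own spatially uniform noise offsets.  Returns a dict keyed by
    (gcm_id, realization, decade) with exactly sum(n_realizations) series
    per decade.
    """
    if not decades:
        raise InvalidParameterError("decades must be nonempty")
    if not gcms:
        raise InvalidParameterError("at least one GcmSpec is required")
    rng = np.random.default_rng(seed)
    start = decades[0]
    out: dict[tuple[str, int, int], MonthlyClimateSeries] = {}
    for gcm in gcms:
        for real in range(1, gcm.n_realizations + 1):
            for decade in decades:
                idx = (decade - start) / 10.0
                t_noise = rng.normal(0.0, gcm.realization_noise_sd) if gcm.realization_noise_sd else 0.0
                p_noise = rng.normal(0.0, gcm.realization_noise_sd) if gcm.realization_noise_sd else 0.0
                temp = baseline.temperature + gcm.temp_trend_per_decade * idx + t_noise
                precip = baseline.precipitation * (gcm.precip_factor_per_decade**idx) * (1.0 + p_noise)
                precip = np.clip(precip, 0.0, None)
                out[(gcm.gcm_id, real, decade)] = MonthlyClimateSeries(
                    temperature=temp, precipitation=precip,
                    grid=baseline.grid, year_label=decade,
                )
    return out


def entropy_prevalence_threshold(suitability: np.ndarray) -> float:
    """Suitability cutoff implied by the entropy-equating rule.

    Normalizing the suitability surface to a probability distribution with
    entropy H, the rule keeps the k = round(exp(H)) highest cells — the
    size of the uniform distribution with the same entropy — and returns
    the k-th largest suitability value.  Defining a virtual species' range
    this way puts the ground truth on the same scale as the thresholded
    model predictions downstream.
    """
    vals = np.asarray(suitability, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    total = vals.sum()
    if total <= 0:
        raise InvalidParameterError("suitability surface has no positive mass")
    p = vals / total
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    k = int(np.clip(np.floor(np.exp(h)), 1, vals.size))
    if k + 1 <= vals.size and abs(np.log(k + 1) - h) < abs(np.log(k) - h):
        k += 1
    return float(np.sort(vals)[::-1][k - 1])


def make_virtual_species(
    niche_center: dict[str, float],
    niche_width: dict[str, float],
    prevalence_threshold,
    meta: SpeciesMeta,
    climate,
) -> VirtualSpecies:
    """Evaluate a Gaussian-niche virtual species on a bioclim stack.

    ``climate`` is a ClimateStack carrying the six bioclim layers; the
    returned species stores the true suitability raster (NaN propagates
    from nodata cells).  ``prevalence_threshold`` is either a suitability
    cutoff in (0, 1] or the string ``"entropy"``, which resolves to the
    entropy-equating cutoff of the true suitability surface (see
    :func:`entropy_prevalence_threshold`).
    """
    missing = [v for v in niche_center if getattr(climate, v, None) is None]
    if missing or set(niche_center) != set(niche_width):
        raise SchemaError("niche center/width must name layers of the climate stack")
    if any(w <= 0 for w in niche_width.values()):
        raise InvalidParameterError("niche widths must be strictly positive")
    z2 = np.zeros(climate.grid.shape, dtype=np.float64)
    for var, c in niche_center.items():
        layer = getattr(climate, var)
        z2 = z2 + ((layer - c) / niche_width[var]) ** 2
    suitability = np.exp(-0.5 * z2)
    if isinstance(prevalence_threshold, str):
        if prevalence_threshold != "entropy":
            raise InvalidParameterError(
                f"prevalence_threshold must be a number or 'entropy', got {prevalence_threshold!r}"
            )
        prevalence_threshold = entropy_prevalence_threshold(suitability)
    sp = VirtualSpecies(
        niche_center=dict(niche_center),
        niche_width=dict(niche_width),
        prevalence_threshold=float(prevalence_threshold),
        meta=meta,
        true_suitability=suitability,
    )
    return sp


def sample_occurrences(
    true_suitability: np.ndarray,
    grid: GridSpec,
    n_points: int,
    seed: int,
    bias_raster: np.ndarray | None = None,
    species_id: str = "sp",
) -> pd.DataFrame:
    """Draw presence-only records proportional to suitability (times bias).

    Records are drawn with replacement, so a cell may be recorded many times
    (atlas-like); coordinates are cell centers.  Returns a DataFrame with
    columns ``species_id, x, y``.
    """
    if n_points < 1:
        raise InvalidParameterError("n_points must be >= 1")
    weights = np.nan_to_num(np.asarray(true_suitability, dtype=np.float64), nan=0.0)
    if bias_raster is not None:
        weights = weights * np.nan_to_num(np.asarray(bias_raster, dtype=np.float64), nan=0.0)
    weights = np.clip(weights, 0.0, None).ravel()
    total = weights.sum()
    if total <= 0:
        raise NoHabitatError(f"species {species_id!r} has no suitable habitat to sample")
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n_points, replace=True, p=weights / total)
    rows, cols = np.unravel_index(flat, grid.shape)
    x = grid.origin_x + (cols + 0.5) * grid.cell_size_km
    y = grid.origin_y + (rows + 0.5) * grid.cell_size_km
    return pd.DataFrame({"species_id": species_id, "x": x, "y": y})
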