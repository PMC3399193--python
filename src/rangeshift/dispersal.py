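"""Dispersal-constrained range forecasting.

A continuous suitability map becomes a binary range by thresholding; the
current potential range is clipped to subregions with at least one
occurrence record to give the realized range; and future ranges are limited
by one of three dispersal scenarios:

* ``full`` — every climatically suitable cell is reachable;
* ``rate_limited`` — suitable cells within a buffer of the current realized
  range that grows by rate x 10 km each decade (3 km/yr, i.e. 30 km per
  decade, is the assemblage default);
* ``none`` — no movement beyond the current realized range.

A per-species "realistic" scenario simply selects, for each species, the
output of the scenario named in its metadata.  Buffers are anchored on the
current realized range (not grown iteratively) and use exact Euclidean
center-to-center distances in km.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .errors import InvalidParameterError, MissingDataError, SchemaError
from .grids import GridSpec
from .maxent import SuitabilityMap
from .synth import RegionMosaic, SpeciesMeta

__all__ = [
    "BinaryRange",
    "DispersalMaskSet",
    "binarize",
    "realized_from_potential",
    "build_masks",
    "apply_scenario",
    "realistic_scenario",
    "SCENARIOS",
]

SCENARIOS = ("full", "rate_limited", "none")


@dataclass
class BinaryRange:
    """Thresholded presence/absence raster for one species and decade."""

    presence: np.ndarray  # bool
    valid: np.ndarray  # bool, the non-nodata landscape
    grid: GridSpec
    species_id: str = "sp"
    decade: int | None = None
    scenario: str | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool) & np.asarray(self.valid, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area_km2


@dataclass
class DispersalMaskSet:
    """Nested per-decade reachability masks around a base range."""

    masks: list[np.ndarray]  # bool, index d-1 = d-th decade step
    radii_km: list[float]
    rate_km_per_year: float
    base: BinaryRange


def binarize(smap: SuitabilityMap, threshold: float, decade=None, scenario=None) -> BinaryRange:
    """Binary range: presence where suitability >= threshold (nodata stays out)."""
    if not 0 < threshold < 1:
        raise InvalidParameterError("threshold must lie in (0, 1)")
    valid = np.isfinite(smap.values)
    with np.errstate(invalid="ignore"):
        presence = valid & (smap.values >= threshold)
    return BinaryRange(
        presence=presence, valid=valid, grid=smap.grid,
        species_id=smap.species_id, decade=decade, scenario=scenario,
        threshold=threshold,
    )


def realized_from_potential(
    potential: BinaryRange, mosaic: RegionMosaic, occurrences: pd.DataFrame
) -> BinaryRange:
    """Clip the potential range to subregions holding at least one record."""
    if len(occurrences) == 0:
        raise InvalidParameterError("occurrences must be nonempty")
    occupied: set[int] = set()
    n_off = 0
    for x, y in zip(occurrences["x"].to_numpy(), occurrences["y"].to_numpy()):
        cell = potential.grid.point_to_cell(float(x), float(y))
        if cell is None or not potential.valid[cell]:
            n_off += 1
            continue
        occupied.add(int(mosaic.labels[cell]))
    if n_off:
        warnings.warn(f"{n_off} occurrence points fall outside the landscape; ignored", stacklevel=2)
    keep = np.isin(mosaic.labels, sorted(occupied))
    return BinaryRange(
        presence=potential.presence & keep, valid=potential.valid,
        grid=potential.grid, species_id=potential.species_id,
        decade=potential.decade, scenario="realized", threshold=potential.threshold,
    )


def build_masks(
    current: BinaryRange, rate_km_per_year: float, n_decades: int,
) -> DispersalMaskSet:
    """Buffer the current range by rate x 10 km per decade step.

    mask_d contains every cell whose center lies within ``rate * 10 * d`` km
    of the nearest presence-cell center of the current range (computed with
    an exact Euclidean distance transform), so the masks are nested and all
    contain the current range.
    """
    if rate_km_per_year < 0:
        raise InvalidParameterError("dispersal rate must be >= 0")
    if n_decades < 1:
        raise InvalidParameterError("need at least one decade")
    radii = [rate_km_per_year * 10.0 * d for d in range(1, n_decades + 1)]
    if current.n_cells == 0:
        warnings.warn("current range is empty; dispersal masks are empty", stacklevel=2)
        empty = np.zeros(current.grid.shape, dtype=bool)
        return DispersalMaskSet(
            masks=[empty.copy() for _ in radii], radii_km=radii,
            rate_km_per_year=rate_km_per_year, base=current,
        )
    dist = distance_transform_edt(
        ~current.presence, sampling=current.grid.cell_size_km
    )
    masks = [(dist <= r) & current.valid for r in radii]
    return DispersalMaskSet(
        masks=masks, radii_km=radii, rate_km_per_year=rate_km_per_year, base=current
    )


def apply_scenario(
    future_potential: BinaryRange,
    scenario: str,
    current_realized: BinaryRange,
    masks: DispersalMaskSet | None = None,
    decade_index: int | None = None,
    none_level: str = "cell",
    occupied_region_mask: np.ndarray | None = None,
) -> BinaryRange:
    """Constrain a future potential range by a dispersal scenario.

    ``decade_index`` counts 10-year steps from the baseline (1-based) and is
    required for the rate-limited scenario to pick the right mask.  The
    no-dispersal constraint intersects with the current realized range at
    cell level by default; ``none_level="region"`` relaxes it to the
    occupied subregions (pass their boolean footprint as
    ``occupied_region_mask``).
    """
    if scenario not in SCENARIOS:
        raise SchemaError(f"unknown scenario {scenario!r}")
    if scenario == "full":
        presence = future_potential.presence
    elif scenario == "none":
        if none_level == "cell":
            presence = future_potential.presence & current_realized.presence
        elif none_level == "region":
            if occupied_region_mask is None:
                raise MissingDataError("none_level='region' needs occupied_region_mask")
            presence = future_potential.presence & occupied_region_mask
        else:
            raise SchemaError(f"unknown none_level {none_level!r}")
    else:
        if masks is None:
            raise MissingDataError("rate_limited scenario requires dispersal masks")
        if decade_index is None or not 1 <= decade_index <= len(masks.masks):
            raise InvalidParameterError(
                f"decade_index must be in [1, {len(masks.masks)}], got {decade_index}"
            )
        presence = future_potential.presence & masks.masks[decade_index - 1]
    return BinaryRange(
        presence=presence, valid=future_potential.valid, grid=future_potential.grid,
        species_id=future_potential.species_id, decade=future_potential.decade,
        scenario=scenario, threshold=future_potential.threshold,
    )


def realistic_scenario(
    meta: SpeciesMeta, outputs_by_scenario: dict[str, BinaryRange]
) -> BinaryRange:
    """Select the scenario output matching the species' dispersal category."""
    if meta.dispersal_category not in outputs_by_scenario:
        raise SchemaError(
            f"no output for category {meta.dispersal_category!r} of {meta.species_id}"
        )
    chosen = outputs_by_scenario[meta.dispersal_category]
    return BinaryRange(
        presence=chosen.presence, valid=chosen.valid, grid=chosen.grid,
        species_id=chosen.species_id, decade=chosen.decade,
        scenario="realistic", threshold=chosen.threshold,
    )
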