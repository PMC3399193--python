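"""Range statistics, proportional change, richness stacks and group tests.

Per-species outputs are landscape-class statistics of a binary range (area,
patch count, proportion of landscape, mean patch area, edge length), the
ratio of projected end-century to current range area with its
increase/decrease classification, and assemblage summaries of those ratios.
Richness maps stack the binary ranges of every species — including species
whose models were screened out on AUC, since per-species accuracy matters
less for a coarse assemblage count.  Group comparisons run a one-way
fixed-effects ANOVA of proportional change across movement or biogeographic
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dispersal import BinaryRange
from .errors import InvalidParameterError, SchemaError
from .grids import GridSpec

__all__ = [
    "RangeStats",
    "ChangeRecord",
    "RichnessGrid",
    "class_stats",
    "proportional_change",
    "assemblage_summary",
    "richness_stack",
    "richness_change",
    "group_comparison",
]


@dataclass
class RangeStats:
    """ClassStat-style landscape metrics for one binary range."""

    total_area_km2: float
    n_patches: int
    proportion_landscape: float
    mean_patch_area_km2: float
    edge_length_km: float


@dataclass
class ChangeRecord:
    """Projected change in a species' range area between two decades."""

    species_id: str
    scenario: str
    area_start_km2: float
    area_end_km2: float
    proportion_of_current: float
    direction: str


@dataclass
class RichnessGrid:
    """Cellwise count of species whose binary range covers the cell."""

    counts: np.ndarray
    grid: GridSpec
    species_ids: list[str]
    decade: int | None = None
    scenario: str | None = None


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def class_stats(brange: BinaryRange, connectivity: int = 8) -> RangeStats:
    """Patch and fragmentation statistics of a binary range.

    Patches are connected components under rook (4) or queen (8, default)
    connectivity; edge length counts presence cell edges adjacent to
    absence, nodata or the grid border, times the cell size.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidParameterError("connectivity must be 4 or 8")
    pres = brange.presence
    cell = brange.grid.cell_size_km
    n_cells = int(pres.sum())
    if n_cells == 0:
        return RangeStats(0.0, 0, 0.0, 0.0, 0.0)
    _labels, n_patches = ndimage.label(pres, structure=_STRUCTURES[connectivity])
    total_area = n_cells * brange.grid.cell_area_km2

    padded = np.pad(pres, 1, constant_values=False)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=axis)
        edges += int(np.sum(padded & ~neighbor))
    n_landscape = int(brange.valid.sum())
    return RangeStats(
        total_area_km2=total_area,
        n_patches=int(n_patches),
        proportion_landscape=n_cells / n_landscape if n_landscape else 0.0,
        mean_patch_area_km2=total_area / n_patches,
        edge_length_km=edges * cell,
    )


def proportional_change(
    area_end: float, area_start: float, species_id: str = "sp", scenario: str = "realistic"
) -> ChangeRecord:
    """Ratio of projected to current range area, classified after rounding.

    Ratios are rounded to two decimals before classification so a species
    printed as 1.00 reads "No change".
    """
    if area_start <= 0:
        raise InvalidParameterError(
            f"species {species_id!r} has zero current range; ratio undefined"
        )
    ratio = area_end / area_start
    rounded = round(ratio, 2)
    if rounded > 1:
        direction = "Increase"
    elif rounded < 1:
        direction = "Decrease"
    else:
        direction = "No change"
    return ChangeRecord(
        species_id=species_id, scenario=scenario,
        area_start_km2=float(area_start), area_end_km2=float(area_end),
        proportion_of_current=rounded, direction=direction,
    )


def assemblage_summary(records: list[ChangeRecord]) -> dict:
    """Assemblage-level counts and mean shifts of proportional change.

    Reports counts and percentages of increasing / decreasing / unchanged
    species, mean percent increase among increasers and decrease among
    decreasers, the overall mean percent shift, how many species change by
    less than 10%, and how many increase by at least 50%.
    """
    if not records:
        raise InvalidParameterError("need at least one change record")
    ratios = np.array([r.proportion_of_current for r in records])
    directions = np.array([r.direction for r in records])
    n = len(records)
    n_inc = int(np.sum(directions == "Increase"))
    n_dec = int(np.sum(directions == "Decrease"))
    n_flat = n - n_inc - n_dec
    pct = lambda k: 100.0 * k / n
    inc_shifts = 100.0 * (ratios[directions == "Increase"] - 1.0)
    dec_shifts = 100.0 * (1.0 - ratios[directions == "Decrease"])
    return {
        "n_species": n,
        "n_increase": n_inc,
        "n_decrease": n_dec,
        "n_no_change": n_flat,
        "pct_increase": pct(n_inc),
        "pct_decrease": pct(n_dec),
        "pct_no_change": pct(n_flat),
        "mean_pct_increase": float(inc_shifts.mean()) if n_inc else 0.0,
        "mean_pct_decrease": float(dec_shifts.mean()) if n_dec else 0.0,
        "mean_pct_shift": float((100.0 * (ratios - 1.0)).mean()),
        "n_small_change": int(np.sum(np.abs(ratios - 1.0) < 0.1)),
        "n_increase_ge_50pct": int(np.sum(ratios >= 1.5)),
    }


def richness_stack(ranges: list[BinaryRange], decade=None, scenario=None) -> RichnessGrid:
    """Cellwise sum of presences across every species' binary range."""
    if not ranges:
        raise InvalidParameterError("need at least one binary range")
    grid = ranges[0].grid
    for r in ranges[1:]:
        if r.grid != grid:
            raise SchemaError("all binary ranges must share one grid")
    counts = np.sum([r.presence for r in ranges], axis=0).astype(np.int32)
    return RichnessGrid(
        counts=counts, grid=grid, species_ids=[r.species_id for r in ranges],
        decade=decade, scenario=scenario,
    )


def richness_change(start: RichnessGrid, end: RichnessGrid) -> np.ndarray:
    """Signed cellwise richness difference (end minus start)."""
    if start.grid != end.grid or set(start.species_ids) != set(end.species_ids):
        raise SchemaError("richness grids must share grid and species list")
    return end.counts.astype(np.int64) - start.counts.astype(np.int64)


def group_comparison(
    records: list[ChangeRecord], groups: dict[str, str]
) -> tuple[pd.DataFrame, float, float]:
    """One-way ANOVA of proportional change across species groups.

    ``groups`` maps species_id to a group label (movement class or
    biogeographic affiliation).  Groups with fewer than two species are
    dropped with a warning.  Returns a per-group quartile table (for
    boxplot-style output) plus the F statistic and p-value.
    """
    by_group: dict[str, list[float]] = {}
    for r in records:
        if r.species_id in groups:
            by_group.setdefault(groups[r.species_id], []).append(r.proportion_of_current)
    dropped = [g for g, v in by_group.items() if len(v) < 2]
    for g in dropped:
        warnings.warn(f"group {g!r} has fewer than 2 records; dropped", stacklevel=2)
        del by_group[g]
    if len(by_group) < 2:
        raise InvalidParameterError("need at least two groups with >= 2 records")
    labels = sorted(by_group)
    samples = [np.asarray(by_group[g]) for g in labels]
    if np.ptp(np.concatenate(samples)) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*samples)
        f_stat, p_val = float(f_stat), float(p_val)
    table = pd.DataFrame(
        {
            "group": labels,
            "n": [len(s) for s in samples],
            "q1": [float(np.percentile(s, 25)) for s in samples],
            "median": [float(np.median(s)) for s in samples],
            "q3": [float(np.percentile(s, 75)) for s in samples],
            "mean": [float(s.mean()) for s in samples],
        }
    )
    return table, f_stat, p_val
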