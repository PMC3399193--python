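"""Ensemble projection across circulation models and realizations.

A fitted model is projected onto every (gcm, realization, decade) climate
surface.  Per decade the ensemble is summarized by a realization-weighted
mean — the cellwise mean is taken within each GCM first and then across GCM
means, so a GCM with many realizations carries no extra weight — and by
unweighted cellwise extremes.  Climate-change maps difference (temperature)
or ratio (rainfall) the two-stage ensemble mean of each bioclim variable
against the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bioclim import BIOCLIM_VARS, ClimateStack
from .errors import InvalidParameterError, MissingDataError, SchemaError
from .maxent import MaxentSDM, SuitabilityMap, predict_logistic

__all__ = [
    "ProjectionSet",
    "EnsembleSummary",
    "project_all",
    "ensemble_mean",
    "ensemble_extremes",
    "ensemble_summary",
    "climate_change_map",
    "two_stage_mean",
]

TEMPERATURE_VARS = ("mat", "ts", "twp")
RAINFALL_VARS = ("ap", "ps", "pdp")


@dataclass
class ProjectionSet:
    """Suitability maps keyed by (gcm_id, realization, decade)."""

    maps: dict[tuple[str, int, int], SuitabilityMap]
    species_id: str = "sp"

    def decades(self) -> list[int]:
        return sorted({k[2] for k in self.maps})

    def gcms(self) -> list[str]:
        return sorted({k[0] for k in self.maps})

    def for_decade(self, decade: int) -> dict[tuple[str, int], SuitabilityMap]:
        return {(g, r): m for (g, r, d), m in self.maps.items() if d == decade}


@dataclass
class EnsembleSummary:
    """Per-decade weighted mean and extreme suitability maps."""

    mean: dict[int, SuitabilityMap] = field(default_factory=dict)
    minimum: dict[int, SuitabilityMap] = field(default_factory=dict)
    maximum: dict[int, SuitabilityMap] = field(default_factory=dict)


def _check_complete(keys) -> None:
    """Every (gcm, realization) pair must appear in every decade."""
    keys = set(keys)
    decades = {k[2] for k in keys}
    pairs = {(k[0], k[1]) for k in keys}
    gaps = [
        (g, r, d) for d in sorted(decades) for (g, r) in sorted(pairs)
        if (g, r, d) not in keys
    ]
    if gaps:
        raise MissingDataError(f"missing (gcm, realization, decade) combinations: {gaps}")


def project_all(
    model: MaxentSDM, future_stacks: dict[tuple[str, int, int], ClimateStack]
) -> ProjectionSet:
    """Project a fitted model onto every future climate surface."""
    if not future_stacks:
        raise InvalidParameterError("no future climate stacks supplied")
    _check_complete(future_stacks.keys())
    maps = {
        key: predict_logistic(model, stack, provenance=f"{key[0]}/r{key[1]}/{key[2]}")
        for key, stack in sorted(future_stacks.items())
    }
    return ProjectionSet(maps=maps, species_id=getattr(model, "species_id_", "sp"))


def two_stage_mean(arrays_by_gcm: dict[str, list[np.ndarray]]) -> np.ndarray:
    """Cellwise mean within each GCM, then unweighted mean across GCMs."""
    if not arrays_by_gcm:
        raise InvalidParameterError("no arrays to average")
    gcm_means = [np.mean(arrs, axis=0) for arrs in arrays_by_gcm.values()]
    return np.mean(gcm_means, axis=0)


def _grouped(pset: ProjectionSet, decade: int) -> dict[str, list[np.ndarray]]:
    sel = pset.for_decade(decade)
    if not sel:
        raise MissingDataError(f"no projections for decade {decade}")
    grouped: dict[str, list[np.ndarray]] = {}
    for (g, _r), m in sorted(sel.items()):
        grouped.setdefault(g, []).append(m.values)
    return grouped


def ensemble_mean(pset: ProjectionSet, decade: int) -> SuitabilityMap:
    """Realization-weighted (two-stage) ensemble mean for one decade."""
    grouped = _grouped(pset, decade)
    mean = two_stage_mean(grouped)
    any_map = next(iter(pset.for_decade(decade).values()))
    return SuitabilityMap(
        values=mean, grid=any_map.grid, species_id=pset.species_id,
        provenance=f"ensemble-mean/{decade}",
    )


def ensemble_extremes(pset: ProjectionSet, decade: int) -> tuple[SuitabilityMap, SuitabilityMap]:
    """Unweighted cellwise minimum and maximum over all realizations."""
    sel = pset.for_decade(decade)
    if not sel:
        raise MissingDataError(f"no projections for decade {decade}")
    stack = np.stack([m.values for _k, m in sorted(sel.items())])
    any_map = next(iter(sel.values()))
    mk = lambda v, s: SuitabilityMap(
        values=v, grid=any_map.grid, species_id=pset.species_id,
        provenance=f"ensemble-{s}/{decade}",
    )
    return mk(stack.min(axis=0), "min"), mk(stack.max(axis=0), "max")


def ensemble_summary(pset: ProjectionSet) -> EnsembleSummary:
    """Mean and extremes for every decade in the projection set."""
    out = EnsembleSummary()
    for d in pset.decades():
        out.mean[d] = ensemble_mean(pset, d)
        lo, hi = ensemble_extremes(pset, d)
        out.minimum[d], out.maximum[d] = lo, hi
    return out


def climate_change_map(
    variable: str,
    baseline: ClimateStack,
    future_stacks: dict[tuple[str, int], ClimateStack],
) -> np.ndarray:
    """Change in one bioclim variable between baseline and a future ensemble.

    Temperature variables report the absolute change (future mean minus
    baseline); rainfall variables the proportional change (future mean over
    baseline, nodata where the baseline is zero).  The future mean uses the
    same two-stage realization weighting as the suitability ensembles;
    ``future_stacks`` is keyed by (gcm_id, realization).
    """
    if variable not in BIOCLIM_VARS:
        raise SchemaError(f"unknown bioclim variable {variable!r}")
    if not future_stacks:
        raise InvalidParameterError("no future stacks supplied")
    grouped: dict[str, list[np.ndarray]] = {}
    for (g, _r), stack in sorted(future_stacks.items()):
        grouped.setdefault(g, []).append(getattr(stack, variable))
    future_mean = two_stage_mean(grouped)
    base = getattr(baseline, variable)
    if variable in TEMPERATURE_VARS:
        return future_mean - base
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(base != 0, future_mean / base, np.nan)
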