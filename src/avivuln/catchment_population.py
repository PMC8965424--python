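"""Step 2 — catchment areas and subpopulation sizes (Np).

The local catchment is the part of the individuals' aggregate plausible-
origin surface inside the BCR containing the facility; the non-local
catchment is the part inside the other flyway BCRs.  Excluded regions
(BCRs without population estimates) never contribute.  Regional population
estimates are converted to catchment subpopulation sizes by weighting each
intersecting BCR's estimate by the stressor-affected proportion of the
catchment there and by the fraction of the BCR lying inside the flyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .isotope_assignment import AssignmentSurface, OriginCall
from .regions import RegionMap

__all__ = [
    "CatchmentArea",
    "SubpopulationSize",
    "MissingEstimateError",
    "aggregate_surface",
    "delineate_catchment",
    "subpopulation_size",
    "continental_fallback",
    "range_only_catchment",
]


class MissingEstimateError(KeyError):
    """A BCR intersecting the catchment has no population-estimate row."""

    def __init__(self, bcr_id):
        super().__init__(bcr_id)
        self.bcr_id = bcr_id

    def __str__(self):
        return f"no population estimate for BCR {self.bcr_id}"


@dataclass(frozen=True)
class CatchmentArea:
    """Cell set + aggregate inclusion surface for one species × origin class.

    ``aggregate`` holds, per cell, the proportion of individuals of this
    origin class whose plausible-origin mask covered the cell; ``weight``
    is its mean over the member cells (the stressor-affected proportion).
    """

    species: str
    origin_class: str
    cells: np.ndarray  # boolean mask
    aggregate: np.ndarray
    weight: float

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("catchment weight must be in (0, 1]")


@dataclass(frozen=True)
class SubpopulationSize:
    species: str
    origin_class: str
    np_mean: float
    np_lci: float
    np_uci: float
    source: str  # "bcr" | "continental_fallback" | "range_only"

    def __post_init__(self):
        if not self.np_lci <= self.np_mean <= self.np_uci:
            raise ValueError("require np_lci <= np_mean <= np_uci")
        if self.np_mean <= 0:
            raise ValueError("np_mean must be > 0")
        if self.source not in ("bcr", "continental_fallback", "range_only"):
            raise ValueError(f"unknown Np source {self.source!r}")


def aggregate_surface(
    surfaces: Sequence[AssignmentSurface],
    origin_calls: Sequence[OriginCall],
    origin_class: str,
) -> Optional[np.ndarray]:
    """Mean of the binary plausible-origin masks of one origin class.

    Returns None when no individual carries that class (the empty-catchment
    signal), otherwise a per-cell proportion surface in [0, 1].
    """
    calls = {c.sample_id: c.origin_class for c in origin_calls}
    masks = [s.mask5 for s in surfaces if calls.get(s.sample_id) == origin_class]
    if not masks:
        return None
    return np.mean([m.astype(float) for m in masks], axis=0)


def delineate_catchment(
    aggregate: Optional[np.ndarray],
    region_map: RegionMap,
    origin_class: str,
    species: str = "",
    min_aggregate: float = 0.0,
) -> Optional[CatchmentArea]:
    """Intersect the aggregate surface with the allowed BCRs for the class.

    Local catchments live inside the local BCR; non-local catchments inside
    the remaining flyway BCRs.  Cells of excluded regions are never kept.
    Returns None when nothing remains (empty-catchment signal).
    """
    if aggregate is None:
        return None
    aggregate = np.asarray(aggregate, dtype=float)
    if origin_class == "local":
        allowed = region_map.local_cells()
    elif origin_class == "non-local":
        allowed = region_map.nonlocal_flyway_cells()
    else:
        raise ValueError(f"unknown origin class {origin_class!r}")
    cells = (aggregate > min_aggregate) & allowed
    if not cells.any():
        return None
    weight = float(aggregate[cells].mean())
    return CatchmentArea(
        species=species,
        origin_class=origin_class,
        cells=cells,
        aggregate=aggregate,
        weight=weight,
    )


def subpopulation_size(
    catchment: CatchmentArea,
    estimates: pd.DataFrame,
    region_map: RegionMap,
) -> SubpopulationSize:
    """Weighted sum of regional estimates over the catchment's BCRs.

    Each intersecting BCR b contributes w_b · estimate_b · frac_b where w_b
    is the mean aggregate value over the catchment cells in b and frac_b is
    the (cell-count) fraction of b inside the flyway.  The same weights
    applied to the LCI/UCI columns propagate the estimate uncertainty.
    """
    est = estimates.set_index("bcr_id")
    bcr_ids = sorted(int(b) for b in np.unique(region_map.bcr[catchment.cells]))
    mean = lci = uci = 0.0
    for b in bcr_ids:
        if b not in est.index:
            raise MissingEstimateError(b)
        cells_b = catchment.cells & region_map.cells_of(b)
        w_b = float(catchment.aggregate[cells_b].mean())
        frac_b = region_map.flyway_fraction(b)
        row = est.loc[b]
        mean += w_b * float(row["mean"]) * frac_b
        lci += w_b * float(row["lci"]) * frac_b
        uci += w_b * float(row["uci"]) * frac_b
    return SubpopulationSize(
        species=catchment.species,
        origin_class=catchment.origin_class,
        np_mean=mean,
        np_lci=lci,
        np_uci=uci,
        source="bcr",
    )


def continental_fallback(
    cp: float,
    range_fraction_in_catchment: float,
    species: str = "",
    origin_class: str = "non-local",
    source: str = "continental_fallback",
) -> SubpopulationSize:
    """Np from a continental estimate, assuming uniform density over range.

    np_mean = Cp · range fraction, with hypothetical 95% bounds at one half
    and double that value.
    """
    if cp <= 0:
        raise ValueError("continental estimate must be > 0")
    if not 0.0 < range_fraction_in_catchment <= 1.0:
        raise ValueError("range fraction must be in (0, 1]")
    np_mean = cp * range_fraction_in_catchment
    return SubpopulationSize(
        species=species,
        origin_class=origin_class,
        np_mean=np_mean,
        np_lci=0.5 * np_mean,
        np_uci=2.0 * np_mean,
        source=source,
    )


def range_only_catchment(
    region_map: RegionMap,
    cp: float,
    species: str = "",
) -> tuple:
    """Fallback for species with no isotope data at all.

    The non-local catchment is the species range inside the flyway minus
    the local BCR, with weight 1; Np comes from the continental estimate
    scaled by the catchment's share of the range.
    """
    cells = region_map.range_mask & region_map.nonlocal_flyway_cells()
    if not cells.any():
        return None, None
    catchment = CatchmentArea(
        species=species,
        origin_class="non-local",
        cells=cells,
        aggregate=cells.astype(float),
        weight=1.0,
    )
    range_fraction = float(cells.sum()) / float(region_map.range_mask.sum())
    size = continental_fallback(
        cp, range_fraction, species=species, origin_class="non-local", source="range_only"
    )
    return catchment, size
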