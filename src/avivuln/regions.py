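"""Abstract geography shared by the pipeline stages.

The analysis only ever needs a cell -> region label mapping plus a handful
of masks (species range, flyway, facility location), never real shapes or
projections, so regions live on a plain rectangular grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionMap"]


@dataclass(frozen=True)
class RegionMap:
    """Cell-to-region labelling for one study area.

    Parameters
    ----------
    bcr
        Integer Bird-Conservation-Region label per cell.
    local_bcr_id
        Label of the BCR containing the energy facility.
    flyway_members
        BCR labels inside the migration flyways under study.  Labels not in
        this set are excluded regions (the "no population estimates
        available" case) and never contribute to catchments.
    facility_cell
        (row, col) of the pooled collection site.
    range_mask
        Boolean species-range mask; cells outside are never plausible
        origins.
    flyway_mask
        Boolean mask of cells geographically inside the flyways.  Defaults
        to the union of the member BCRs; a narrower mask models BCRs that
        extend beyond the flyway boundary ("partial" BCRs).
    """

    bcr: np.ndarray
    local_bcr_id: int
    flyway_members: frozenset
    facility_cell: tuple
    range_mask: np.ndarray = None
    flyway_mask: np.ndarray = None

    def __post_init__(self):
        bcr = np.asarray(self.bcr, dtype=int)
        object.__setattr__(self, "bcr", bcr)
        if self.local_bcr_id not in self.flyway_members:
            raise ValueError("local BCR must belong to the flyway")
        r, c = self.facility_cell
        if not (0 <= r < bcr.shape[0] and 0 <= c < bcr.shape[1]):
            raise ValueError("facility cell outside grid")
        if bcr[r, c] != self.local_bcr_id:
            raise ValueError("facility cell is not inside the local BCR")
        if self.range_mask is None:
            object.__setattr__(self, "range_mask", np.ones(bcr.shape, dtype=bool))
        else:
            object.__setattr__(self, "range_mask", np.asarray(self.range_mask, dtype=bool))
        if self.flyway_mask is None:
            fm = np.isin(bcr, sorted(self.flyway_members))
            object.__setattr__(self, "flyway_mask", fm)
        else:
            object.__setattr__(self, "flyway_mask", np.asarray(self.flyway_mask, dtype=bool))

    @property
    def shape(self):
        return self.bcr.shape

    @property
    def bcr_ids(self):
        return sorted(int(b) for b in np.unique(self.bcr))

    @property
    def excluded_ids(self):
        return sorted(b for b in self.bcr_ids if b not in self.flyway_members)

    def cells_of(self, bcr_id: int) -> np.ndarray:
        """Boolean mask of the cells carrying one BCR label."""
        return self.bcr == bcr_id

    def local_cells(self) -> np.ndarray:
        return self.cells_of(self.local_bcr_id)

    def nonlocal_flyway_cells(self) -> np.ndarray:
        """Flyway cells outside the local BCR (candidate non-local origins)."""
        members = sorted(self.flyway_members - {self.local_bcr_id})
        return np.isin(self.bcr, members)

    def excluded_cells(self) -> np.ndarray:
        return np.isin(self.bcr, self.excluded_ids)

    def flyway_fraction(self, bcr_id: int) -> float:
        """Fraction of a BCR's cells lying inside the flyway (cell counts)."""
        cells = self.cells_of(bcr_id)
        n = int(cells.sum())
        if n == 0:
            return 0.0
        return float((cells & self.flyway_mask).sum()) / n
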