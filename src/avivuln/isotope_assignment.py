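"""Step 1 — geographic origin assignment from feather δ²H values.

A feather's stable-hydrogen isotope ratio (δ²H, ‰ VSMOW) reflects the
precipitation isoscape where the feather grew.  Comparing a measured value
against a calibrated feather isoscape yields a normalized origin-probability
surface for each individual; cells whose origin odds beat a uniform null by
at least 5:1 form the plausible-origin region, and the bird is called
"local" when the collection facility falls inside that region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "IsoscapeGrid",
    "CalibrationParams",
    "AssignmentSurface",
    "OriginCall",
    "calibrate_isoscape",
    "assignment_surface",
    "classify_origin",
]

DEFAULT_ODDS_THRESHOLD = 5.0


@dataclass(frozen=True)
class IsoscapeGrid:
    """Per-cell expected feather δ²H (mu, ‰) and its SD (sd, ‰)."""

    mu: np.ndarray
    sd: np.ndarray
    cellsize: float = 1.0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mu.shape != sd.shape:
            raise ValueError("mu and sd grids must have the same shape")
        if mu.ndim != 2:
            raise ValueError("isoscape grids must be 2-D")
        if not np.all(np.isfinite(mu)):
            raise ValueError("isoscape mu must be finite")
        if not np.all(sd > 0):
            raise ValueError("isoscape sd must be positive everywhere")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sd", sd)

    @property
    def shape(self):
        return self.mu.shape


@dataclass(frozen=True)
class CalibrationParams:
    """Affine rescaling from precipitation δ²H to feather δ²H.

    ``mu_feather = intercept + slope * mu_precip``; the calibration's
    residual SD adds in quadrature to the isoscape SD.
    """

    slope: float
    intercept: float
    residual_sd: float = 0.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class AssignmentSurface:
    """Normalized origin probabilities and odds ratios for one individual.

    ``p`` sums to one over the species-range cells; ``or_value`` is the
    per-cell odds ratio against a uniform-origin null; ``mask5`` marks the
    cells meeting the odds threshold.
    """

    sample_id: str
    p: np.ndarray
    or_value: np.ndarray
    mask5: np.ndarray
    threshold: float = DEFAULT_ODDS_THRESHOLD


@dataclass(frozen=True)
class OriginCall:
    sample_id: str
    origin_class: str  # "local" | "non-local"
    or_at_facility: float = float("nan")

    def __post_init__(self):
        if self.origin_class not in ("local", "non-local"):
            raise ValueError("origin_class must be 'local' or 'non-local'")


def calibrate_isoscape(precip_grid: IsoscapeGrid, calib: CalibrationParams) -> IsoscapeGrid:
    """Rescale a precipitation isoscape into feather-δ²H space.

    mu' = intercept + slope·mu and sd' = sqrt(sd² + residual_sd²).
    """
    mu = calib.intercept + calib.slope * precip_grid.mu
    sd = np.sqrt(precip_grid.sd**2 + calib.residual_sd**2)
    return IsoscapeGrid(mu=mu, sd=sd, cellsize=precip_grid.cellsize)


def assignment_surface(
    d2h: float,
    iso: IsoscapeGrid,
    range_mask: np.ndarray,
    sample_id: str = "",
    threshold: float = DEFAULT_ODDS_THRESHOLD,
    rule: str = "uniform_null",
) -> AssignmentSurface:
    """Build the per-cell origin surface for one measured δ²H value.

    The likelihood of cell c is Normal(d2h; mu_c, sd_c), evaluated in log
    space so observations tens of SDs from every cell still normalize.
    Under the default ``uniform_null`` rule the per-cell odds ratio is
    [p_c/(1-p_c)] / [p0/(1-p0)] with p0 = 1/K for K range cells, and a cell
    enters the plausible-origin mask when that ratio meets ``threshold``.
    The ``cumulative`` rule instead takes the smallest set of top-probability
    cells holding threshold/(threshold+1) of the probability mass.
    """
    range_mask = np.asarray(range_mask, dtype=bool)
    if range_mask.shape != iso.shape:
        raise ValueError("range mask and isoscape shapes differ")
    k = int(range_mask.sum())
    if k == 0:
        raise ValueError("species range mask has no valid cells")

    loglik = np.full(iso.shape, -np.inf)
    mu = iso.mu[range_mask]
    sd = iso.sd[range_mask]
    loglik[range_mask] = -0.5 * ((d2h - mu) / sd) ** 2 - np.log(sd)
    logz = logsumexp(loglik[range_mask])
    p = np.zeros(iso.shape)
    p[range_mask] = np.exp(loglik[range_mask] - logz)

    or_value = np.zeros(iso.shape)
    if k == 1:
        or_value[range_mask] = np.inf
    else:
        null_odds = (1.0 / k) / (1.0 - 1.0 / k)
        pr = p[range_mask]
        with np.errstate(divide="ignore"):
            odds = np.where(pr < 1.0, pr / (1.0 - pr), np.inf)
        or_value[range_mask] = odds / null_odds

    if rule == "uniform_null":
        mask5 = (or_value >= threshold) & range_mask
    elif rule == "cumulative":
        target = threshold / (threshold + 1.0)
        flat = p[range_mask]
        order = np.argsort(flat)[::-1]
        csum = np.cumsum(flat[order])
        n_keep = int(np.searchsorted(csum, target - 1e-12) + 1)
        keep = np.zeros(k, dtype=bool)
        keep[order[:n_keep]] = True
        mask5 = np.zeros(iso.shape, dtype=bool)
        mask5[range_mask] = keep
    else:
        raise ValueError(f"unknown odds rule: {rule!r}")

    return AssignmentSurface(
        sample_id=sample_id, p=p, or_value=or_value, mask5=mask5, threshold=threshold
    )


def classify_origin(
    surface: AssignmentSurface,
    facility_cell: tuple,
    range_mask: np.ndarray,
) -> OriginCall:
    """Call an individual local iff the facility sits in its origin region.

    The plausible-origin region is mask5 ∩ range; a bird whose region does
    not cover the collection facility must have grown its feather elsewhere
    and is called non-local.
    """
    r, c = facility_cell
    rows, cols = surface.mask5.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError("facility cell outside grid")
    range_mask = np.asarray(range_mask, dtype=bool)
    is_local = bool(surface.mask5[r, c] and range_mask[r, c])
    return OriginCall(
        sample_id=surface.sample_id,
        origin_class="local" if is_local else "non-local",
        or_at_facility=float(surface.or_value[r, c]),
    )
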