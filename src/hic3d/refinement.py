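"""Post-inference model refinement.

Three steps, applied per chromosome:

* ``filter_outliers`` removes beads placed aberrantly far from both of
  their sequence neighbours (Euclidean distance above a user threshold,
  default 10x the chromosome's median adjacent-bead distance);
* ``interpolate_missing`` fills interior runs of unplaced beads with
  shape-preserving monotone piecewise-cubic Hermite (PCHIP) interpolants,
  one per axis, over the bead index; runs touching a chromosome end are
  never extrapolated and are discarded instead;
* ``annotate_chromosomes`` assigns each bead its chromosome number,
  chain letter (A, B, C, ...) and residue name (C01, C02, ...).

Refinement never moves a bead whose coordinates were inferred.
"""

from __future__ import annotations

import logging
import string

import numpy as np
from scipy.interpolate import PchipInterpolator

from .inference import (
    STATUS_DISCARDED,
    STATUS_FILTERED,
    STATUS_INFERRED,
    STATUS_INTERPOLATED,
    STATUS_MISSING,
    StructureModel,
)

__all__ = ["interpolate_missing", "filter_outliers", "annotate_chromosomes", "refine"]

logger = logging.getLogger(__name__)

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits  # 62 chains


def _adjacent_distances(coords: np.ndarray) -> np.ndarray:
    """Distances between consecutive beads of one chromosome (NaN where unplaced)."""
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def interpolate_missing(model: StructureModel) -> StructureModel:
    """Fill interior coordinate gaps by per-axis monotone cubic interpolation.

    Knots are the coordinate-bearing beads, the abscissa is the bead
    local index.  Interior gaps get status "interpolated"; gap runs that
    touch either chromosome end are discarded (no extrapolation).
    Idempotent: a model without missing beads is returned unchanged.
    """
    out = model.copy()
    for ci in range(model.layout.n_chromosomes):
        sl = out.chromosome_slice(ci)
        coords = out.coords[sl]
        status = out.status[sl]
        placed = ~np.isnan(coords[:, 0])
        n = len(status)
        fillable = np.array([s == STATUS_MISSING for s in status]) & ~placed
        if placed.sum() < 2:
            logger.warning(
                "chromosome %s has <2 placed beads; all its beads discarded",
                model.layout.names[ci],
            )
            coords[:] = np.nan
            status[:] = STATUS_DISCARDED
            continue
        if not fillable.any():
            continue
        knots = np.flatnonzero(placed)
        first, last = knots[0], knots[-1]
        x = knots.astype(float)
        interps = [PchipInterpolator(x, coords[knots, axis]) for axis in range(3)]
        for k in np.flatnonzero(fillable):
            if k < first or k > last:
                status[k] = STATUS_DISCARDED  # terminal run: never extrapolate
                continue
            coords[k] = [f(float(k)) for f in interps]
            status[k] = STATUS_INTERPOLATED
    return out


def filter_outliers(
    model: StructureModel,
    threshold: float | None = None,
    threshold_factor: float = 10.0,
) -> StructureModel:
    """Remove beads aberrantly far from both sequence neighbours.

    A bead is marked "filtered" (coordinates dropped) when its distance
    to *every* coordinate-bearing sequence neighbour exceeds the
    threshold.  ``threshold`` is absolute; when None it defaults to
    ``threshold_factor`` times the chromosome's median adjacent-bead
    distance.  Created interior gaps are re-interpolated.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be positive")
    if threshold is None and threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    out = model.copy()
    any_filtered = False
    for ci in range(model.layout.n_chromosomes):
        sl = out.chromosome_slice(ci)
        coords = out.coords[sl]
        status = out.status[sl]
        placed = np.flatnonzero(~np.isnan(coords[:, 0]))
        if placed.size < 2:
            continue
        dists = np.linalg.norm(np.diff(coords[placed], axis=0), axis=1)
        cutoff = threshold
        if cutoff is None:
            cutoff = threshold_factor * float(np.median(dists))
        # neighbour distances among placed beads, in placed order
        for pos, bead in enumerate(placed):
            far = []
            if pos > 0:
                far.append(dists[pos - 1] > cutoff)
            if pos < placed.size - 1:
                far.append(dists[pos] > cutoff)
            if far and all(far):
                coords[bead] = np.nan
                status[bead] = STATUS_FILTERED
                any_filtered = True
    if any_filtered:
        out = _reinterpolate_filtered(out)
    return out


def _reinterpolate_filtered(model: StructureModel) -> StructureModel:
    """Give interior filtered beads interpolated replacement coordinates."""
    out = model.copy()
    for ci in range(model.layout.n_chromosomes):
        sl = out.chromosome_slice(ci)
        coords = out.coords[sl]
        status = out.status[sl]
        placed = ~np.isnan(coords[:, 0])
        if placed.sum() < 2:
            continue
        knots = np.flatnonzero(placed)
        first, last = knots[0], knots[-1]
        holes = [
            k for k in np.flatnonzero(~placed)
            if status[k] == STATUS_FILTERED and first < k < last
        ]
        if not holes:
            continue
        x = knots.astype(float)
        interps = [PchipInterpolator(x, coords[knots, axis]) for axis in range(3)]
        for k in holes:
            coords[k] = [f(float(k)) for f in interps]
            status[k] = STATUS_INTERPOLATED
    return out


def annotate_chromosomes(model: StructureModel) -> StructureModel:
    """Assign chromosome number, chain letter and residue name to every bead."""
    if model.layout.n_chromosomes > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"cannot annotate more than {len(_CHAIN_ALPHABET)} chromosomes "
            "(chain alphabet exhausted)"
        )
    out = model.copy()
    chains = np.empty(model.n_beads, dtype=object)
    resnames = np.empty(model.n_beads, dtype=object)
    for ci in range(model.layout.n_chromosomes):
        sl = out.chromosome_slice(ci)
        chains[sl] = _CHAIN_ALPHABET[ci]
        resnames[sl] = f"C{ci + 1:02d}"
    out.chains = chains
    out.resnames = resnames
    return out


def refine(
    model: StructureModel,
    outlier_threshold: float | None = None,
    outlier_factor: float = 10.0,
) -> StructureModel:
    """Full refinement: filter outliers, interpolate gaps, annotate."""
    out = filter_outliers(model, threshold=outlier_threshold, threshold_factor=outlier_factor)
    out = interpolate_missing(out)
    return annotate_chromosomes(out)
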