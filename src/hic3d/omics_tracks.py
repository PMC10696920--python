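"""Per-bin quantitative tracks (e.g. ChIP-seq coverage) painted onto beads.

A track carries one value per bead position, read from a bedGraph whose
bin size equals the model resolution (bin ``[k*res, (k+1)*res)`` maps to
bead ``k+1``).  Thresholding supports the two visualization modes used
for chromatin signal: ``binarize`` (>= cutoff -> 1, else 0, e.g. cutoff
80 for high-residency cohesin anchors) and ``floor`` (values below the
cutoff zeroed, signal kept otherwise, e.g. cutoff 20 for histone marks).
Painting writes values into the model's B-value field and never touches
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_layout import GenomeLayout
from .inference import StructureModel

__all__ = ["Track", "read_bedgraph", "write_bedgraph", "threshold_track", "paint_model"]


@dataclass(frozen=True)
class Track:
    """Per-bead quantitative values at the model resolution (NaN = missing)."""

    layout: GenomeLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != self.layout.n_beads:
            raise ValueError(
                f"track has {len(self.values)} values for "
                f"{self.layout.n_beads} beads"
            )

    @property
    def resolution(self) -> int:
        return self.layout.resolution


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> Track:
    """Read a 4-column bedGraph (0-based half-open) into a bead-order Track.

    Every interval must be one layout bin; bins absent from the file
    become missing values (NaN).
    """
    res = layout.resolution
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    values = np.full(layout.n_beads, np.nan)
    seen: set[int] = set()
    for row in df.itertuples(index=False):
        if row.chrom not in layout.names:
            raise ValueError(f"bedGraph chromosome {row.chrom!r} absent from layout")
        ci = layout.names.index(row.chrom)
        if row.start % res != 0:
            raise ValueError(
                f"bedGraph interval start {row.start} is not on the "
                f"{res} bp bin grid"
            )
        local = row.start // res + 1
        expect = layout.bead_interval(ci, local)
        if (row.start, row.end) != expect:
            raise ValueError(
                f"bin width mismatch: interval ({row.chrom}, {row.start}, "
                f"{row.end}) is not the {res} bp layout bin {expect}"
            )
        g = layout.global_index(ci, int(local))
        if g in seen:
            raise ValueError(
                f"overlapping intervals: bin ({row.chrom}, {row.start}) "
                "appears more than once"
            )
        seen.add(g)
        values[g - 1] = row.value
    return Track(layout=layout, values=values)


def write_bedgraph(track: Track, path: str | Path) -> None:
    """Write a Track as a bedGraph (missing values omitted)."""
    layout = track.layout
    with open(path, "w") as fh:
        for g, ci, local in layout.iter_beads():
            v = track.values[g - 1]
            if np.isnan(v):
                continue
            start, end = layout.bead_interval(ci, local)
            val = int(v) if float(v).is_integer() else v
            fh.write(f"{layout.names[ci]}\t{start}\t{end}\t{val}\n")


def threshold_track(track: Track, mode: str, cutoff: float) -> Track:
    """Apply a visualization threshold; missing values stay missing.

    ``binarize``: value >= cutoff -> 1, else 0 (continuous signal to a
    binary high/low call).  ``floor``: value < cutoff -> 0, signal kept
    otherwise (low values discarded for display; geometry and bead set
    are unaffected).
    """
    v = track.values.copy()
    present = ~np.isnan(v)
    if mode == "binarize":
        v[present] = (v[present] >= cutoff).astype(float)
    elif mode == "floor":
        low = present & (v < cutoff)
        v[low] = 0.0
    else:
        raise ValueError(f"unknown threshold mode {mode!r} (binarize|floor)")
    return Track(layout=track.layout, values=v)


def paint_model(model: StructureModel, track: Track) -> StructureModel:
    """Set bead B-values from a track (missing -> 0.0); geometry untouched."""
    if track.layout.n_beads != model.layout.n_beads:
        raise ValueError("track and model layouts differ in bead count")
    if track.layout.resolution != model.layout.resolution:
        raise ValueError(
            f"track resolution {track.layout.resolution} != model "
            f"resolution {model.layout.resolution}"
        )
    out = model.copy()
    v = track.values.copy()
    v[np.isnan(v)] = 0.0
    out.bvalues = v
    return out
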