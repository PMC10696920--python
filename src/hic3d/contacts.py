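"""Contact matrices: data model, sparse-triplet I/O and shot-noise injection.

Counts are stored in upper-triangle canonical form (global bead indices
``i <= j``, 1-based).  The on-disk dialect is the HiC-Pro sparse triplet
pair: a BED file defining bins (0-based half-open coordinates, 4th column
a 1-based bin id) and a whitespace-separated ``binA binB count`` matrix
file listing the non-zero upper triangle.

Shot noise follows the additive model ``y_ij = x_ij + e_ij`` with
``e_ij ~ Poisson(lambda)`` drawn once per unordered bead pair and
mirrored, so noisy matrices stay symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_layout import GenomeLayout

__all__ = [
    "ContactMatrix",
    "NoisyMatrix",
    "read_triplet",
    "write_triplet",
    "inject_shot_noise",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric non-negative contact counts x_ij on a bead layout.

    ``counts`` holds the upper triangle (i <= j) as a CSR matrix of shape
    (n, n) with 0-based row/col corresponding to 1-based bead index - 1.
    """

    layout: GenomeLayout
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        n = self.layout.n_beads
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} != layout bead count {n}"
            )
        coo = self.counts.tocoo()
        if np.any(coo.row > coo.col):
            raise ValueError("counts must be stored as upper triangle (i <= j)")
        if np.any(coo.data < 0):
            raise ValueError("negative contact count")

    @classmethod
    def from_pairs(
        cls,
        layout: GenomeLayout,
        i: np.ndarray,
        j: np.ndarray,
        c: np.ndarray,
    ) -> "ContactMatrix":
        """Build from 1-based bead index arrays; pairs are canonicalized."""
        i = np.asarray(i, dtype=np.int64) - 1
        j = np.asarray(j, dtype=np.int64) - 1
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        n = layout.n_beads
        m = sp.coo_matrix((np.asarray(c, dtype=float), (lo, hi)), shape=(n, n))
        m.sum_duplicates()
        return cls(layout=layout, counts=m.tocsr())

    @classmethod
    def from_dense(cls, layout: GenomeLayout, dense: np.ndarray) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=float)
        if not np.allclose(dense, dense.T):
            raise ValueError("dense matrix is not symmetric")
        upper = sp.csr_matrix(np.triu(dense))
        return cls(layout=layout, counts=upper)

    @property
    def n(self) -> int:
        return self.layout.n_beads

    @property
    def nnz(self) -> int:
        return self.counts.nnz

    def pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Non-zero upper-triangle entries as (i, j, count), 1-based, i <= j."""
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order] + 1, coo.col[order] + 1, coo.data[order]

    def get(self, i: int, j: int) -> float:
        lo, hi = min(i, j) - 1, max(i, j) - 1
        return float(self.counts[lo, hi])

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (diagonal counted once)."""
        upper = self.counts.toarray()
        return upper + upper.T - np.diag(np.diag(upper))

    def marginal(self) -> np.ndarray:
        """Per-bead total count (row sums of the symmetric matrix)."""
        return self.to_dense().sum(axis=1)

    def is_integer(self) -> bool:
        return bool(np.allclose(self.counts.data, np.round(self.counts.data)))


@dataclass(frozen=True)
class NoisyMatrix:
    """A shot-noise-perturbed contact matrix y = x + e with its provenance."""

    base: ContactMatrix
    lam: float
    seed: int
    counts: ContactMatrix  # y_ij
    noise: ContactMatrix   # e_ij


def read_triplet(
    matrix_path: str | Path,
    bed_path: str | Path,
    layout: GenomeLayout,
) -> ContactMatrix:
    """Read a HiC-Pro-style sparse triplet matrix + bin BED into a ContactMatrix.

    The BED maps 1-based bin ids to (chrom, start, end) which must agree with
    the layout's bead intervals; matrix rows are ``binA binB count``.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "bin_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "bin_id": np.int64},
    )
    bin_to_bead: dict[int, int] = {}
    for row in bed.itertuples(index=False):
        if row.chrom not in layout.names:
            raise ValueError(f"BED chromosome {row.chrom!r} absent from layout")
        ci = layout.names.index(row.chrom)
        res = layout.resolution
        if row.start % res != 0:
            raise ValueError(
                f"BED bin start {row.start} not a multiple of resolution {res}"
            )
        local = row.start // res + 1  # file bin [k*res,(k+1)*res) is bead k+1
        expect = layout.bead_interval(ci, local)
        if (row.start, row.end) != expect:
            raise ValueError(
                f"BED bin ({row.chrom}, {row.start}, {row.end}) inconsistent with "
                f"layout interval {expect} at resolution {res}"
            )
        bin_to_bead[int(row.bin_id)] = layout.global_index(ci, int(local))

    try:
        mat = pd.read_csv(
            matrix_path, sep=r"\s+", header=None, names=["a", "b", "c"],
            dtype={"a": np.int64, "b": np.int64, "c": float},
        )
    except pd.errors.EmptyDataError:
        mat = pd.DataFrame(columns=["a", "b", "c"])
    if len(mat) == 0:
        n = layout.n_beads
        return ContactMatrix(layout, sp.csr_matrix((n, n)))
    unknown = set(mat["a"]).union(mat["b"]) - set(bin_to_bead)
    if unknown:
        raise ValueError(f"matrix references bin ids absent from BED: {sorted(unknown)[:5]}")
    if (mat["c"] < 0).any():
        raise ValueError("negative count in matrix file")
    i = mat["a"].map(bin_to_bead).to_numpy()
    j = mat["b"].map(bin_to_bead).to_numpy()
    return ContactMatrix.from_pairs(layout, i, j, mat["c"].to_numpy())


def write_triplet(
    matrix: ContactMatrix,
    matrix_path: str | Path,
    bed_path: str | Path,
) -> None:
    """Write the upper triangle as triplets plus a full bin-definition BED."""
    layout = matrix.layout
    with open(bed_path, "w") as bed:
        for g, ci, local in layout.iter_beads():
            start, end = layout.bead_interval(ci, local)
            bed.write(f"{layout.names[ci]}\t{start}\t{end}\t{g}\n")
    i, j, c = matrix.pairs()
    with open(matrix_path, "w") as mat:
        for a, b, v in zip(i, j, c):
            val = int(v) if float(v).is_integer() else v
            mat.write(f"{a}\t{b}\t{val}\n")


def write_dense_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    """Dense symmetric TSV export (bead-labelled) for external heatmapping."""
    labels = [str(g) for g, _, _ in matrix.layout.iter_beads()]
    pd.DataFrame(matrix.to_dense(), index=labels, columns=labels).to_csv(path, sep="\t")


def inject_shot_noise(
    matrix: ContactMatrix,
    lam: float,
    seed: int,
    include_diagonal: bool = True,
) -> NoisyMatrix:
    """Add symmetric Poisson(lambda) shot noise to a contact matrix.

    One draw per unordered pair (i, j), including the diagonal by default,
    mirrored to keep the matrix symmetric.  Reproducible for a given seed.
    """
    if lam < 0:
        raise ValueError("Poisson parameter lambda must be >= 0")
    if not matrix.is_integer():
        logger.warning(
            "contact matrix has non-integer counts; shot noise is intended "
            "for raw (pre-normalization) count matrices"
        )
    n = matrix.n
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=0 if include_diagonal else 1)
    e = rng.poisson(lam, size=iu.size).astype(float)
    noise_upper = sp.coo_matrix((e, (iu, ju)), shape=(n, n)).tocsr()
    noise_upper.eliminate_zeros()
    noise = ContactMatrix(matrix.layout, noise_upper)
    y = (matrix.counts + noise_upper).tocsr()
    return NoisyMatrix(
        base=matrix, lam=lam, seed=seed,
        counts=ContactMatrix(matrix.layout, y), noise=noise,
    )
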