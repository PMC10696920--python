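"""Genome sequences and the bin/bead coordinate system.

A genome is modelled as an ordered list of chromosomes; at a fixed
resolution (bp per bead) each chromosome is covered by beads numbered
1-based, where bead ``k`` represents the left-open genomic interval
``](k-1)*res, k*res]`` clipped to the chromosome length.  The trailing
partial interval is kept as an undersized bead rather than dropped.
All file interfaces that are 0-based half-open (BED, bedGraph) are
converted at this boundary: file bin ``[k*res, (k+1)*res)`` is bead
``k+1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ChromosomeRecord",
    "GenomeLayout",
    "load_genome",
    "make_layout",
    "reverse_complement",
    "write_genome",
]

_VALID_BASES = frozenset("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string; case preserved, N maps to N."""
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ChromosomeRecord:
    """One chromosome: a name, its length in bp and (optionally) its sequence."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be positive")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"chromosome {self.name!r}: length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad = set(self.sequence) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {self.name!r}: invalid characters {sorted(bad)!r}"
                )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes plus, once a resolution is set, the bead mapping.

    Bead indices are 1-based.  ``global_index`` concatenates chromosomes in
    FASTA order; per-chromosome ("local") indices restart at 1.
    """

    chromosomes: tuple[ChromosomeRecord, ...]
    resolution: int | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name: {dup}")
        if self.resolution is not None and self.resolution < 1:
            raise ValueError("resolution must be >= 1 bp")

    # -- basic queries -------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def _require_resolution(self) -> int:
        if self.resolution is None:
            raise ValueError("layout has no resolution; call make_layout() first")
        return self.resolution

    @property
    def beads_per_chromosome(self) -> tuple[int, ...]:
        res = self._require_resolution()
        return tuple(math.ceil(c.length / res) for c in self.chromosomes)

    @property
    def n_beads(self) -> int:
        return sum(self.beads_per_chromosome)

    @property
    def chromosome_offsets(self) -> tuple[int, ...]:
        """0-based global offset of each chromosome's first bead."""
        offsets, acc = [], 0
        for n in self.beads_per_chromosome:
            offsets.append(acc)
            acc += n
        return tuple(offsets)

    # -- index arithmetic ----------------------------------------------

    def global_index(self, chrom: int | str, local: int) -> int:
        """1-based global bead index from chromosome and 1-based local index."""
        ci = chrom if isinstance(chrom, int) else self.names.index(chrom)
        n_local = self.beads_per_chromosome[ci]
        if not 1 <= local <= n_local:
            raise IndexError(
                f"local bead {local} out of range 1..{n_local} "
                f"for chromosome {self.names[ci]!r}"
            )
        return self.chromosome_offsets[ci] + local

    def local_index(self, global_index: int) -> tuple[int, int]:
        """(chromosome index, 1-based local bead index) from a global index."""
        if not 1 <= global_index <= self.n_beads:
            raise IndexError(f"global bead {global_index} out of range 1..{self.n_beads}")
        for ci, (off, n) in enumerate(zip(self.chromosome_offsets, self.beads_per_chromosome)):
            if global_index <= off + n:
                return ci, global_index - off
        raise AssertionError("unreachable")

    def bead_interval(self, chrom: int | str, local: int) -> tuple[int, int]:
        """Genomic interval of a bead as 0-based half-open (start, end) in bp."""
        ci = chrom if isinstance(chrom, int) else self.names.index(chrom)
        res = self._require_resolution()
        n_local = self.beads_per_chromosome[ci]
        if not 1 <= local <= n_local:
            raise IndexError(f"local bead {local} out of range for chromosome {ci}")
        start = (local - 1) * res
        end = min(local * res, self.chromosomes[ci].length)
        return start, end

    def iter_beads(self) -> Iterator[tuple[int, int, int]]:
        """Yield (global index, chromosome index, local index) for every bead."""
        g = 0
        for ci, n in enumerate(self.beads_per_chromosome):
            for k in range(1, n + 1):
                g += 1
                yield g, ci, k

    def with_sequences(self, sequences: dict[str, str]) -> "GenomeLayout":
        chroms = tuple(
            replace(c, sequence=sequences[c.name]) if c.name in sequences else c
            for c in self.chromosomes
        )
        return replace(self, chromosomes=chroms)


def load_genome(fasta_path: str | Path) -> GenomeLayout:
    """Read a genome FASTA into a GenomeLayout (no resolution set).

    Chromosomes appear in file order; sequences are retained for later
    reverse-complement correction and re-export.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    chroms = tuple(
        ChromosomeRecord(name=r.id, length=len(r.seq), sequence=str(r.seq))
        for r in records
    )
    return GenomeLayout(chromosomes=chroms)


def make_layout(genome: GenomeLayout, resolution: int) -> GenomeLayout:
    """Fix the bead resolution (bp per bead) of a genome."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1 bp")
    if all(c.length < resolution for c in genome.chromosomes):
        raise ValueError(
            f"resolution {resolution} exceeds every chromosome length; "
            "no chromosome would have more than a single partial bead"
        )
    return replace(genome, resolution=resolution)


def write_genome(genome: GenomeLayout, fasta_path: str | Path, width: int = 60) -> None:
    """Write chromosome sequences as 60-column wrapped FASTA."""
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise ValueError(f"chromosome {c.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
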