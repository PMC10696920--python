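"""Detection and correction of assembly inversions from bead geometry.

Beads are placed in 3D from contact information only, independently of
the reference assembly, so a reverse-complemented (inverted) contig
shows up as a disagreement between the spatial chaining of beads and
their sequence numbering: the Euclidean distance between
sequence-adjacent beads jumps at the two junctions of the inverted
segment.  The detector flags adjacent pairs whose distance exceeds
``tau`` times the chromosome's median adjacent distance, pairs flagged
junctions left to right, tentatively reverses the enclosed bead segment
and accepts the inversion iff both junction distances drop back below
the threshold.  An accepted report can then be applied to produce a
corrected genome sequence (segment reverse-complemented) and a
corrected model (bead labels reversed; coordinates untouched).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .genome_layout import GenomeLayout, reverse_complement
from .inference import StructureModel

__all__ = [
    "AdjacencyProfile",
    "InversionReport",
    "adjacency_profile",
    "detect_inversions",
    "apply_correction",
    "detect_and_correct",
    "write_reports",
]


@dataclass(frozen=True)
class AdjacencyProfile:
    """Per-chromosome distances between beads with consecutive numbers.

    ``entries[chrom_name]`` is a list of (lower local bead index k,
    distance between beads k and k+1), restricted to pairs where both
    beads carry coordinates.
    """

    entries: dict[str, list[tuple[int, float]]]

    def median(self, chrom: str) -> float:
        d = [v for _, v in self.entries[chrom]]
        return float(np.median(d))


@dataclass(frozen=True)
class InversionReport:
    """One candidate inversion on a chromosome (bead indices are 1-based local)."""

    chromosome: str
    junctions: tuple[tuple[int, int], tuple[int, int]]  # ((i, i+1), (j, j+1))
    segment: tuple[int, int]                            # [i+1, j]
    genomic_interval: tuple[int, int]                   # 0-based half-open bp
    pre_distances: tuple[float, float]
    post_distances: tuple[float, float]
    threshold: float
    accepted: bool
    note: str = ""

    @property
    def segment_length(self) -> int:
        return self.segment[1] - self.segment[0] + 1


def adjacency_profile(model: StructureModel) -> AdjacencyProfile:
    """Distances between consecutive coordinate-bearing beads, per chromosome."""
    entries: dict[str, list[tuple[int, float]]] = {}
    for ci in range(model.layout.n_chromosomes):
        sl = model.chromosome_slice(ci)
        coords = model.coords[sl]
        placed = ~np.isnan(coords[:, 0])
        if placed.sum() < 2:
            raise ValueError(
                f"chromosome {model.layout.names[ci]!r} has fewer than 2 "
                "placed beads"
            )
        out: list[tuple[int, float]] = []
        for k in range(len(coords) - 1):
            if placed[k] and placed[k + 1]:
                d = float(np.linalg.norm(coords[k + 1] - coords[k]))
                out.append((k + 1, d))  # 1-based lower index
        entries[model.layout.names[ci]] = out
    return AdjacencyProfile(entries=entries)


def _junction_distances_after_reversal(
    coords: np.ndarray, placed: np.ndarray, i: int, j: int
) -> tuple[float, float]:
    """Junction distances (i, i+1) and (j, j+1) if segment [i+1, j] is reversed.

    Indices are 1-based local; coords is the chromosome block.  After
    reversal the bead labelled i+1 sits at the old position of bead j,
    so junction (i, i+1) spans coords[i-1] -> coords[j-1] and junction
    (j, j+1) spans coords[i] -> coords[j].
    """
    left = float(np.linalg.norm(coords[j - 1] - coords[i - 1]))
    right = float(np.linalg.norm(coords[j] - coords[i]))
    return left, right


def detect_inversions(model: StructureModel, tau: float = 5.0) -> list[InversionReport]:
    """Flag and pair anomalous adjacent-bead distances as candidate inversions.

    Junction pairs (i, i+1), (j, j+1) with distance > tau x chromosome
    median are paired greedily left to right; the enclosed segment
    [i+1, j] is tentatively reversed and accepted iff both junction
    distances fall to <= tau x median.  Unpaired flagged junctions are
    reported unaccepted (translocation-like anomalies are not corrected).
    """
    if tau <= 1:
        raise ValueError("tau must be > 1")
    profile = adjacency_profile(model)
    reports: list[InversionReport] = []
    res = model.layout.resolution
    for ci, name in enumerate(model.layout.names):
        entries = profile.entries[name]
        med = profile.median(name)
        cutoff = tau * med
        flagged = [(k, d) for k, d in entries if d > cutoff]
        sl = model.chromosome_slice(ci)
        coords = model.coords[sl]
        placed = ~np.isnan(coords[:, 0])
        idx = 0
        while idx < len(flagged):
            if idx + 1 < len(flagged):
                (i, d_i), (j, d_j) = flagged[idx], flagged[idx + 1]
                left, right = _junction_distances_after_reversal(coords, placed, i, j)
                accepted = left <= cutoff and right <= cutoff
                start_bp, _ = model.layout.bead_interval(ci, i + 1)
                _, end_bp = model.layout.bead_interval(ci, j)
                reports.append(
                    InversionReport(
                        chromosome=name,
                        junctions=((i, i + 1), (j, j + 1)),
                        segment=(i + 1, j),
                        genomic_interval=(start_bp, end_bp),
                        pre_distances=(d_i, d_j),
                        post_distances=(left, right),
                        threshold=cutoff,
                        accepted=accepted,
                        note="" if accepted else "reversal does not restore chaining",
                    )
                )
                idx += 2
            else:
                i, d_i = flagged[idx]
                start_bp, _ = model.layout.bead_interval(ci, i)
                _, end_bp = model.layout.bead_interval(ci, i + 1)
                reports.append(
                    InversionReport(
                        chromosome=name,
                        junctions=((i, i + 1), (i, i + 1)),
                        segment=(i, i + 1),
                        genomic_interval=(start_bp, end_bp),
                        pre_distances=(d_i, d_i),
                        post_distances=(d_i, d_i),
                        threshold=cutoff,
                        accepted=False,
                        note="unpaired anomalous junction (translocation-like)",
                    )
                )
                idx += 1
    return reports


def apply_correction(
    genome: GenomeLayout,
    model: StructureModel,
    report: InversionReport,
) -> tuple[GenomeLayout, StructureModel]:
    """Apply an accepted inversion: fix the sequence and the bead labels.

    The genomic interval spanned by the inverted bead segment is
    reverse-complemented in the genome; on the model, bead labels inside
    the segment are reversed (equivalently, the per-bead coordinate,
    status and B-value rows are reversed) so sequence numbering and
    spatial chaining agree again.  Applying the same correction twice
    restores the original genome and model exactly.
    """
    if not report.accepted:
        raise ValueError("refusing to apply a non-accepted inversion report")
    ci = genome.names.index(report.chromosome)
    chrom = genome.chromosomes[ci]
    if chrom.sequence is None:
        raise ValueError(f"chromosome {chrom.name!r} has no sequence loaded")
    start_bp, end_bp = report.genomic_interval
    seq = chrom.sequence
    corrected_seq = (
        seq[:start_bp] + reverse_complement(seq[start_bp:end_bp]) + seq[end_bp:]
    )
    new_chrom = replace(chrom, sequence=corrected_seq)
    chroms = list(genome.chromosomes)
    chroms[ci] = new_chrom
    corrected_genome = replace(genome, chromosomes=tuple(chroms))

    out = model.copy()
    s, e = report.segment
    off = model.layout.chromosome_offsets[ci]
    gsl = slice(off + s - 1, off + e)
    out.coords[gsl] = out.coords[gsl][::-1]
    out.status[gsl] = out.status[gsl][::-1]
    out.bvalues[gsl] = out.bvalues[gsl][::-1]
    return corrected_genome, out


def detect_and_correct(
    genome: GenomeLayout,
    model: StructureModel,
    tau: float = 5.0,
    max_rounds: int = 5,
) -> tuple[GenomeLayout, StructureModel, list[InversionReport]]:
    """Iterate detect -> correct until no accepted inversion remains."""
    all_reports: list[InversionReport] = []
    for _ in range(max_rounds):
        reports = detect_inversions(model, tau=tau)
        all_reports.extend(reports)
        accepted = [r for r in reports if r.accepted]
        if not accepted:
            break
        for rep in accepted:
            genome, model = apply_correction(genome, model, rep)
    return genome, model, all_reports


def write_reports(reports: list[InversionReport], path: str | Path) -> None:
    """Serialize inversion reports as JSON."""
    Path(path).write_text(json.dumps([asdict(r) for r in reports], indent=2) + "\n")
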