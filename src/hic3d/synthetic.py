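"""Synthetic fixtures: Rabl-like genomes, model-consistent counts,
two-level omics tracks and planted mis-assemblies.

The generators emit the exact dialects the rest of the package consumes
(FASTA, sparse triplet + BED, bedGraph), so every pipeline stage can be
exercised without external data.  The Rabl generator emulates the
hallmark fungal nuclear arrangement: centromeres clustered at one pole,
telomeres toward the opposite pole, chromosome arms coiled into helices
and chromosomes separated angularly into territories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMatrix
from .genome_layout import ChromosomeRecord, GenomeLayout, reverse_complement
from .inference import NBParams, STATUS_INFERRED, StructureModel
from .omics_tracks import Track

__all__ = [
    "RablSpec",
    "make_rabl_structure",
    "make_helix_structure",
    "random_genome",
    "counts_from_structure",
    "plant_inversion",
    "make_track",
]


def random_genome(
    lengths: dict[str, int],
    resolution: int,
    seed: int = 0,
) -> GenomeLayout:
    """A layout with random A/C/G/T sequences of the given lengths."""
    rng = np.random.default_rng(seed)
    chroms = []
    for name, length in lengths.items():
        seq = "".join(rng.choice(list("ACGT"), size=length))
        chroms.append(ChromosomeRecord(name=name, length=length, sequence=seq))
    return GenomeLayout(chromosomes=tuple(chroms), resolution=resolution)


@dataclass(frozen=True)
class RablSpec:
    """Geometry of a synthetic Rabl-conformation genome.

    Defaults give a 3-chromosome genome of 1.0 / 0.8 / 0.6 Mb at 10 kb
    resolution (100 / 80 / 60 beads): large enough to exhibit Rabl
    features, small enough for seconds-scale fits.
    """

    lengths: tuple[int, ...] = (1_000_000, 800_000, 600_000)
    resolution: int = 10_000
    centromere_positions: tuple[int, ...] = (400_000, 300_000, 250_000)
    centromere_radius: float = 1.5
    pole_distance: float = 12.0
    coil_radius: float = 2.0
    beads_per_turn: float = 10.0
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centromere_positions) != len(self.lengths):
            raise ValueError("one centromere position per chromosome required")
        for pos, length in zip(self.centromere_positions, self.lengths):
            if not 0 < pos < length:
                raise ValueError("centromere position must lie within the chromosome")
        if min(self.centromere_radius, self.pole_distance, self.coil_radius) <= 0:
            raise ValueError("geometric parameters must be positive")

    def layout(self, with_sequences: bool = False) -> GenomeLayout:
        names = {f"chr{i + 1}": L for i, L in enumerate(self.lengths)}
        if with_sequences:
            return random_genome(names, self.resolution, seed=self.seed)
        chroms = tuple(
            ChromosomeRecord(name=n, length=L) for n, L in names.items()
        )
        return GenomeLayout(chromosomes=chroms, resolution=self.resolution)


def _arm_curve(
    n: int,
    origin: np.ndarray,
    phi_c: float,
    phase: float,
    spec: "RablSpec",
) -> np.ndarray:
    """A helical arm of n beads leaving `origin` toward the telomere pole.

    The arm drifts axially to z = pole_distance, migrates radially into
    the chromosome's territory (direction phi_c) and coils with the
    spec's radius and pitch; the coil radius ramps up from zero so the
    curve leaves the centromere smoothly.
    """
    u = np.array([math.cos(phi_c), math.sin(phi_c), 0.0])
    v = np.array([-math.sin(phi_c), math.cos(phi_c), 0.0])
    # dense parametric sampling, then arc-length reparametrization so the
    # n beads end up (near-)uniformly spaced along the curve
    dense = 25 * (n + 1)
    t = np.linspace(0.0, float(n + 1), dense)
    frac = t / (n + 1.0)
    ramp = np.minimum(1.0, 4.0 * frac)  # reach full territory/coil by 25% arm length
    z = spec.pole_distance * frac
    rho = 2.0 * spec.coil_radius * ramp
    r_coil = spec.coil_radius * ramp
    theta = phase + 2.0 * math.pi * t / spec.beads_per_turn
    pts = (
        origin[None, :]
        + rho[:, None] * u[None, :]
        + np.column_stack([np.zeros(dense), np.zeros(dense), z])
        + (r_coil * np.cos(theta))[:, None] * u[None, :]
        + (r_coil * np.sin(theta))[:, None] * v[None, :]
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n + 1)[1:]  # skip the origin itself
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, arc, pts[:, axis])
    return out


def make_rabl_structure(spec: RablSpec) -> StructureModel:
    """Deterministic Rabl-like bead structure for the spec's genome.

    Centromere beads of all chromosomes cluster within
    ``centromere_radius`` of the centromere pole (the origin); both arms
    run as helices toward the telomere pole at z = pole_distance;
    chromosomes are offset angularly into separate territories.
    Adjacent-bead spacing is near-uniform (coefficient of variation well
    below 0.2 at the default jitter).
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed)
    model = StructureModel.empty(layout)
    n_chrom = layout.n_chromosomes
    for ci in range(n_chrom):
        n_beads = layout.beads_per_chromosome[ci]
        cen_local = spec.centromere_positions[ci] // spec.resolution + 1
        cen_local = min(max(cen_local, 2), n_beads - 1)
        phi_c = 2.0 * math.pi * ci / n_chrom
        cen_point = (spec.centromere_radius * 0.5) * np.array(
            [math.cos(phi_c), math.sin(phi_c), 0.0]
        )
        # left arm runs cen-1 ... 1 away from the centromere; right arm cen+1 ... n
        n_left = cen_local - 1
        n_right = n_beads - cen_local
        coords = np.empty((n_beads, 3))
        coords[cen_local - 1] = cen_point
        if n_left:
            left = _arm_curve(n_left, cen_point, phi_c + 0.35, 0.0, spec)
            coords[:cen_local - 1] = left[::-1]
        if n_right:
            right = _arm_curve(n_right, cen_point, phi_c - 0.35, math.pi, spec)
            coords[cen_local:] = right
        coords += spec.jitter * rng.standard_normal(coords.shape)
        sl = model.chromosome_slice(ci)
        model.coords[sl] = coords
        model.status[sl] = STATUS_INFERRED
    return model


def make_helix_structure(
    n_beads: int,
    resolution: int = 10_000,
    chrom_name: str = "chr1",
    radius: float = 3.0,
    rise_per_bead: float = 0.12,
    beads_per_turn: float = 12.0,
    jitter: float = 0.0,
    seed: int = 0,
    chrom_length: int | None = None,
) -> tuple[GenomeLayout, StructureModel]:
    """A single smooth helical bead chain (one chromosome).

    Useful both as a planted ground truth for structure recovery and as
    the smooth chain on which mis-assembly fixtures are built.  Adjacent
    bead spacing is uniform by construction.
    """
    if chrom_length is None:
        chrom_length = n_beads * resolution
    layout = GenomeLayout(
        chromosomes=(ChromosomeRecord(name=chrom_name, length=chrom_length),),
        resolution=resolution,
    )
    if layout.n_beads != n_beads:
        raise ValueError("chrom_length inconsistent with n_beads at this resolution")
    t = np.arange(n_beads, dtype=float)
    theta = 2.0 * math.pi * t / beads_per_turn
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise_per_bead * t]
    )
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords += jitter * rng.standard_normal(coords.shape)
    model = StructureModel.empty(layout)
    model.coords[:] = coords
    model.status[:] = STATUS_INFERRED
    return layout, model


def counts_from_structure(
    model: StructureModel,
    params: NBParams,
    noise: str = "none",
    seed: int = 0,
) -> ContactMatrix:
    """Contacts consistent with the count-distance model: mu = beta * d**alpha.

    noise = "none" rounds the mean; "exact" keeps the real-valued mean
    (no rounding; useful for noise-free method checks); "poisson" draws
    Poisson(mu); "nb" draws NB(mu, r).  Output is symmetric and
    non-negative (integer except in "exact" mode).
    """
    coords = model.coords
    if np.isnan(coords).any():
        raise ValueError("all beads must carry coordinates")
    n = model.n_beads
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    if np.any(d <= 0):
        raise ValueError("coincident beads: zero pairwise distance")
    mu = params.beta * d**params.alpha
    if noise == "none":
        c = np.round(mu)
    elif noise == "exact":
        c = mu
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        c = rng.poisson(mu).astype(float)
    elif noise == "nb":
        rng = np.random.default_rng(seed)
        # NB(mean mu, dispersion r) as a Gamma-Poisson mixture
        lam = rng.gamma(shape=params.r, scale=mu / params.r)
        c = rng.poisson(lam).astype(float)
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    keep = c > 0
    return ContactMatrix.from_pairs(
        model.layout, iu[keep] + 1, ju[keep] + 1, c[keep]
    )


def plant_inversion(
    genome: GenomeLayout,
    model: StructureModel,
    chromosome: str,
    segment: tuple[int, int],
) -> tuple[GenomeLayout, StructureModel]:
    """Plant an assembly inversion: mis-assembled genome + mislabeled model.

    ``segment`` = (first, last) 1-based local bead indices, strictly
    interior to the chromosome, length >= 2.  The genomic interval is
    reverse-complemented in the returned genome and the model's bead
    labels on the segment are reversed (geometry untouched): the
    configuration where sequence numbering disagrees with spatial
    chaining.  Planting then correcting round-trips exactly.
    """
    from dataclasses import replace

    s, e = segment
    ci = genome.names.index(chromosome)
    n_local = genome.beads_per_chromosome[ci]
    if e - s + 1 < 2:
        raise ValueError("segment must span at least 2 beads")
    if s <= 1 or e >= n_local:
        raise ValueError("segment must not touch the chromosome ends")
    chrom = genome.chromosomes[ci]
    if chrom.sequence is None:
        raise ValueError("genome sequences required to plant an inversion")
    start_bp, _ = genome.bead_interval(ci, s)
    _, end_bp = genome.bead_interval(ci, e)
    seq = chrom.sequence
    new_seq = seq[:start_bp] + reverse_complement(seq[start_bp:end_bp]) + seq[end_bp:]
    chroms = list(genome.chromosomes)
    chroms[ci] = replace(chrom, sequence=new_seq)
    bad_genome = replace(genome, chromosomes=tuple(chroms))

    out = model.copy()
    off = model.layout.chromosome_offsets[ci]
    gsl = slice(off + s - 1, off + e)
    out.coords[gsl] = out.coords[gsl][::-1]
    out.status[gsl] = out.status[gsl][::-1]
    out.bvalues[gsl] = out.bvalues[gsl][::-1]
    return bad_genome, out


def make_track(
    layout: GenomeLayout,
    enriched_regions: list[tuple[str, int, int]],
    high: float = 100.0,
    low: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Track:
    """A two-level signal track: `high` inside the given genomic intervals
    (0-based half-open bp), `low` elsewhere, plus Gaussian noise truncated
    at zero.  Emulates e.g. a centromeric/subtelomeric histone-mark
    enrichment pattern at the model resolution.
    """
    if high < 0 or low < 0:
        raise ValueError("signal levels must be non-negative")
    values = np.full(layout.n_beads, float(low))
    for chrom, start_bp, end_bp in enriched_regions:
        ci = layout.names.index(chrom)
        for g, ci2, local in layout.iter_beads():
            if ci2 != ci:
                continue
            b_start, b_end = layout.bead_interval(ci, local)
            # a bead is enriched when its interval overlaps the region
            if b_start < end_bp and start_bp < b_end:
                values[g - 1] = float(high)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.maximum(values + noise_sd * rng.standard_normal(values.shape), 0.0)
    return Track(layout=layout, values=values)
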