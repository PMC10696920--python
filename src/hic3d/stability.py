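"""Structure superposition RMSD and the shot-noise stability experiment.

Inferred structures are defined only up to a similarity transform, so
before computing an RMSD the two models are superposed by least squares:
centering, optimal rotation (Kabsch), optionally the reflection branch
(taking whichever mirror gives the smaller RMSD) and optionally a
uniform scale.  Both options default to on because inferred models have
arbitrary orientation, chirality and scale.

The noise experiment perturbs a reference contact matrix with additive
symmetric Poisson(lambda) shot noise over a grid of lambda values (the
default grid is 0.1 then 5, 10, ... up to 110: 23 levels), refits a
structure per noisy replicate (50 by default, 1150 cells in total) with
the same inference seed throughout, and records the global RMSD to the
reference structure plus per-chromosome RMSDs (each chromosome
superposed independently).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, inject_shot_noise
from .inference import InferenceConfig, StructureModel, fit_structure
from .refinement import refine

__all__ = [
    "NoiseExperimentConfig",
    "RMSDRecord",
    "superpose_rmsd",
    "default_lambda_grid",
    "enumerate_cells",
    "run_noise_experiment",
    "summarize_rmsd",
]

logger = logging.getLogger(__name__)


def default_lambda_grid() -> tuple[float, ...]:
    """The default noise grid: 0.1 plus 5, 10, 15, ... , 110 (23 levels)."""
    return (0.1,) + tuple(float(x) for x in range(5, 111, 5))


@dataclass(frozen=True)
class NoiseExperimentConfig:
    lambda_grid: tuple[float, ...] = field(default_factory=default_lambda_grid)
    replicates: int = 50
    base_seed: int = 0
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    outlier_factor: float = 10.0

    def __post_init__(self) -> None:
        if any(lam < 0 for lam in self.lambda_grid):
            raise ValueError("lambda values must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class RMSDRecord:
    lam: float
    replicate: int
    global_rmsd: float | None
    per_chromosome_rmsd: dict[str, float]
    seed: int
    error: str | None = None


def _kabsch_rmsd(
    ref: np.ndarray,
    other: np.ndarray,
    allow_scaling: bool,
    allow_reflection: bool,
) -> tuple[float, dict]:
    """Least-squares superposition of `other` onto `ref` (both centered)."""
    ref_c = ref - ref.mean(axis=0)
    oth_c = other - other.mean(axis=0)
    H = oth_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(Vt.T @ U.T)

    def branch(flip_last: bool) -> tuple[float, np.ndarray, float]:
        D = np.diag([1.0, 1.0, -1.0 if flip_last else 1.0])
        R = Vt.T @ D @ U.T
        trace = np.sum(S * np.diag(D))
        if allow_scaling:
            denom = np.sum(oth_c**2)
            s = trace / denom if denom > 0 else 1.0
        else:
            s = 1.0
        aligned = s * (oth_c @ R.T)
        rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref_c) ** 2, axis=1))))
        return rmsd, R, s

    # proper rotation branch: flip the last singular direction if det < 0
    rmsd_rot, R_rot, s_rot = branch(flip_last=det < 0)
    best = (rmsd_rot, R_rot, s_rot, False)
    if allow_reflection:
        # improper branch: allow det(R) = -1
        rmsd_ref, R_ref, s_ref = branch(flip_last=det >= 0)
        if rmsd_ref < best[0]:
            best = (rmsd_ref, R_ref, s_ref, True)
    rmsd, R, s, reflected = best
    transform = {"rotation": R, "scale": s, "reflected": reflected}
    return rmsd, transform


def superpose_rmsd(
    reference: StructureModel,
    other: StructureModel,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
) -> tuple[float, dict]:
    """RMSD after optimal superposition over beads placed in both models.

    With scaling on the fit is asymmetric: `other` is scaled onto
    `reference`.  Requires at least 3 common coordinate-bearing beads.
    """
    if reference.layout.n_beads != other.layout.n_beads:
        raise ValueError("models do not share a layout")
    common = reference.placed & other.placed
    if common.sum() < 3:
        raise ValueError("fewer than 3 beads placed in both models")
    return _kabsch_rmsd(
        reference.coords[common],
        other.coords[common],
        allow_scaling=allow_scaling,
        allow_reflection=allow_reflection,
    )


def _cell_seed(base_seed: int, lam_index: int, replicate: int) -> int:
    """Deterministic, scheduling-independent per-cell noise seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(lam_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_cells(config: NoiseExperimentConfig) -> list[tuple[float, int, int]]:
    """The (lambda, replicate, seed) design grid, in execution order."""
    return [
        (lam, rep, _cell_seed(config.base_seed, li, rep))
        for li, lam in enumerate(config.lambda_grid)
        for rep in range(config.replicates)
    ]


def _fit_and_refine(
    matrix: ContactMatrix, config: NoiseExperimentConfig
) -> StructureModel:
    model = fit_structure(matrix, config.inference)
    return refine(model, outlier_factor=config.outlier_factor)


def _per_chromosome_rmsd(
    reference: StructureModel, other: StructureModel
) -> dict[str, float]:
    out: dict[str, float] = {}
    for ci, name in enumerate(reference.layout.names):
        sl = reference.chromosome_slice(ci)
        common = reference.placed[sl] & other.placed[sl]
        if common.sum() < 3:
            continue
        rmsd, _ = _kabsch_rmsd(
            reference.coords[sl][common],
            other.coords[sl][common],
            allow_scaling=True,
            allow_reflection=True,
        )
        out[name] = rmsd
    return out


def run_noise_experiment(
    matrix: ContactMatrix,
    config: NoiseExperimentConfig,
) -> list[RMSDRecord]:
    """Reference fit, then one fit per (lambda, replicate) noisy matrix.

    All fits share the inference seed so RMSD differences reflect the
    injected noise, not initialization.  Per-cell failures are recorded
    (error field) rather than aborting the experiment.
    """
    reference = _fit_and_refine(matrix, config)
    records: list[RMSDRecord] = []
    for lam, rep, seed in enumerate_cells(config):
        try:
            noisy = inject_shot_noise(matrix, lam, seed=seed)
            model = _fit_and_refine(noisy.counts, config)
            global_rmsd, _ = superpose_rmsd(reference, model)
            per_chrom = _per_chromosome_rmsd(reference, model)
            records.append(RMSDRecord(lam, rep, global_rmsd, per_chrom, seed))
        except Exception as exc:  # noqa: BLE001 - per-cell failures are data
            logger.warning("cell (lambda=%s, rep=%d) failed: %s", lam, rep, exc)
            records.append(RMSDRecord(lam, rep, None, {}, seed, error=str(exc)))
    return records


def summarize_rmsd(records: list[RMSDRecord]) -> pd.DataFrame:
    """Per-lambda median/quartile summary for the global and per-chromosome series.

    Returns a tidy frame with columns (series, lambda, n, q25, median, q75),
    where series is "global" or a chromosome name.
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    for rec in records:
        if rec.error is not None:
            continue
        rows.append({"series": "global", "lambda": rec.lam, "rmsd": rec.global_rmsd})
        for name, v in rec.per_chromosome_rmsd.items():
            rows.append({"series": name, "lambda": rec.lam, "rmsd": v})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("all cells failed; nothing to summarize")
    grouped = (
        df.groupby(["series", "lambda"])["rmsd"]
        .agg(
            n="count",
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return grouped.sort_values(["series", "lambda"]).reset_index(drop=True)
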