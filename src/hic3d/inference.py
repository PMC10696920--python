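"""Consensus 3D structure inference from contact counts.

The model: the count between beads i and j is a negative-binomial random
variable whose mean decays as a power law of their Euclidean distance,

    c_ij ~ NB(mean mu_ij = beta * d_ij**alpha, dispersion r),

parameterized so that Var = mu + mu**2 / r (r -> infinity recovers the
Poisson model).  alpha < 0 is the contact-distance decay exponent
(default -3, the standard choice for Hi-C at this scale), beta a global
scale and r the over-dispersion of sequencing counts.

Fitting alternates quasi-Newton updates of the bead coordinates
(analytic gradient, L-BFGS-B) with closed-form / method-of-moments
updates of (beta, r), starting from a distance-based multidimensional
scaling embedding of the "wish" distances d_ij = c_ij**(1/alpha).
Only observed (non-zero, off-diagonal) pairs enter the likelihood;
beads whose bin has zero marginal count receive no coordinates and are
resolved later by refinement.  The output is defined up to a similarity
transform (rotation, reflection, translation, and a scale trade-off
with beta); comparisons must superpose first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.special import gammaln

from .contacts import ContactMatrix
from .genome_layout import GenomeLayout

__all__ = [
    "NBParams",
    "InferenceConfig",
    "StructureModel",
    "counts_to_wish_distances",
    "mds_init",
    "nb_loglik",
    "estimate_nb_params",
    "fit_structure",
]

logger = logging.getLogger(__name__)

# bead status values used across the package
STATUS_INFERRED = "inferred"
STATUS_INTERPOLATED = "interpolated"
STATUS_DISCARDED = "discarded"
STATUS_FILTERED = "filtered"
STATUS_MISSING = "missing"  # transient: no coordinates yet, pre-refinement


@dataclass(frozen=True)
class NBParams:
    """Negative-binomial count-distance model parameters."""

    alpha: float = -3.0
    beta: float = 1.0
    r: float = 1e12

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("alpha must be negative (counts decay with distance)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.r <= 0:
            raise ValueError("dispersion r must be positive")


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for fit_structure."""

    alpha: float = -3.0
    dispersion_mode: str = "estimate"  # "estimate" | "fixed"
    dispersion: float = 1e12          # used when dispersion_mode == "fixed"
    beta_mode: str = "estimate"       # "estimate" | "fixed"
    beta: float = 1.0                 # used when beta_mode == "fixed"
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 42
    zeros_informative: bool = False

    def __post_init__(self) -> None:
        if self.dispersion_mode not in ("estimate", "fixed"):
            raise ValueError("dispersion_mode must be 'estimate' or 'fixed'")
        if self.beta_mode not in ("estimate", "fixed"):
            raise ValueError("beta_mode must be 'estimate' or 'fixed'")


@dataclass
class StructureModel:
    """A bead model: one 3D point per genomic bin, plus status and B-value.

    ``coords`` is (n, 3) with NaN rows for beads without coordinates;
    ``status`` holds one of the bead status strings; ``bvalues`` carries
    optional per-bead quantitative signal (written to the PDB B-factor
    field).  Optional annotation arrays (chain letters, residue names)
    are attached by refinement.annotate_chromosomes.
    """

    layout: GenomeLayout
    coords: np.ndarray
    status: np.ndarray
    bvalues: np.ndarray
    chains: np.ndarray | None = None
    resnames: np.ndarray | None = None
    loglik_trace: tuple[float, ...] = ()
    n_iter: int = 0

    @classmethod
    def empty(cls, layout: GenomeLayout) -> "StructureModel":
        n = layout.n_beads
        return cls(
            layout=layout,
            coords=np.full((n, 3), np.nan),
            status=np.array([STATUS_MISSING] * n, dtype=object),
            bvalues=np.zeros(n),
        )

    @property
    def n_beads(self) -> int:
        return self.layout.n_beads

    @property
    def placed(self) -> np.ndarray:
        """Boolean mask of beads carrying coordinates."""
        return ~np.isnan(self.coords[:, 0])

    def copy(self) -> "StructureModel":
        return StructureModel(
            layout=self.layout,
            coords=self.coords.copy(),
            status=self.status.copy(),
            bvalues=self.bvalues.copy(),
            chains=None if self.chains is None else self.chains.copy(),
            resnames=None if self.resnames is None else self.resnames.copy(),
            loglik_trace=self.loglik_trace,
            n_iter=self.n_iter,
        )

    def chromosome_slice(self, ci: int) -> slice:
        off = self.layout.chromosome_offsets[ci]
        return slice(off, off + self.layout.beads_per_chromosome[ci])


# ---------------------------------------------------------------------------
# count -> wish distance conversion


def counts_to_wish_distances(
    matrix: ContactMatrix, alpha: float = -3.0
) -> dict[tuple[int, int], float]:
    """Convert counts to target ("wish") distances d_ij = c_ij**(1/alpha).

    Pairs with zero counts are absent (distance unknown, not infinite).
    Distances are rescaled so the median wish distance between
    sequence-adjacent beads is 1; this fixes the arbitrary model scale.
    """
    if alpha >= 0:
        raise ValueError("alpha must be negative")
    i, j, c = matrix.pairs()
    off = i != j
    i, j, c = i[off], j[off], c[off]
    d = np.power(c, 1.0 / alpha)
    adjacent = d[j == i + 1]
    scale = float(np.median(adjacent)) if adjacent.size else 1.0
    if scale <= 0:
        scale = 1.0
    return {(int(a), int(b)): float(v / scale) for a, b, v in zip(i, j, d)}


# ---------------------------------------------------------------------------
# MDS initialization


def _stress_and_grad(
    x: np.ndarray, ii: np.ndarray, jj: np.ndarray, d0: np.ndarray, n: int
) -> tuple[float, np.ndarray]:
    X = x.reshape(n, 3)
    diff = X[ii] - X[jj]
    d = np.linalg.norm(diff, axis=1)
    d = np.maximum(d, 1e-12)
    resid = d - d0
    stress = float(np.sum(resid**2))
    coef = (2.0 * resid / d)[:, None] * diff
    grad = np.zeros_like(X)
    np.add.at(grad, ii, coef)
    np.add.at(grad, jj, -coef)
    return stress, grad.ravel()


def mds_init(
    wish: dict[tuple[int, int], float], n: int, seed: int = 42
) -> np.ndarray:
    """Stress-minimizing 3D embedding of the observed wish distances.

    Missing distances get zero weight.  Each connected component of the
    observed-pair graph is embedded via shortest-path completion followed
    by classical scaling, then polished by minimizing raw stress over the
    observed pairs only; components are placed apart along the x axis.
    Deterministic for a given seed.
    """
    if n < 2:
        raise ValueError("need at least 2 beads")
    if not wish:
        raise ValueError("no observed pairs to embed")
    ii = np.array([p[0] - 1 for p in wish], dtype=np.int64)
    jj = np.array([p[1] - 1 for p in wish], dtype=np.int64)
    d0 = np.array(list(wish.values()), dtype=float)

    graph = sp.coo_matrix((d0, (ii, jj)), shape=(n, n))
    n_comp, labels = csgraph.connected_components(graph, directed=False)
    rng = np.random.default_rng(seed)
    coords = np.full((n, 3), np.nan)

    x_cursor = 0.0
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size == 1:
            # isolated bead: no information, leave unplaced
            continue
        sub = np.searchsorted(members, np.arange(n))
        mask = np.isin(ii, members)
        si, sj = sub[ii[mask]], sub[jj[mask]]
        sd = d0[mask]
        m = members.size
        g = sp.coo_matrix((sd, (si, sj)), shape=(m, m)).tocsr()
        D = csgraph.shortest_path(g, directed=False)
        # classical scaling on the completed distance matrix
        D2 = D**2
        J = np.eye(m) - np.full((m, m), 1.0 / m)
        B = -0.5 * J @ D2 @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:3]
        lam = np.clip(w[order], 0.0, None)
        X = V[:, order] * np.sqrt(lam)
        if X.shape[1] < 3:
            X = np.hstack([X, np.zeros((m, 3 - X.shape[1]))])
        # tiny seeded jitter breaks exact degeneracies without moving the start
        X = X + 1e-9 * rng.standard_normal(X.shape)
        res = scipy.optimize.minimize(
            _stress_and_grad, X.ravel(), args=(si, sj, sd, m),
            jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-14, "gtol": 1e-12},
        )
        X = res.x.reshape(m, 3)
        X -= X.mean(axis=0)
        span = X[:, 0].max() - X[:, 0].min()
        X[:, 0] += x_cursor - X[:, 0].min()
        x_cursor += span + 2.0 * max(1.0, float(np.median(sd)))
        coords[members] = X
    return coords


# ---------------------------------------------------------------------------
# negative-binomial likelihood


def _nb_terms(c: np.ndarray, mu: np.ndarray, r: float) -> np.ndarray:
    """Elementwise log NB(c; mean mu, dispersion r), Var = mu + mu^2/r.

    For very large r the direct formula loses precision (cancellation in
    gammaln(c + r) - gammaln(r)), so the Poisson limit with its O(1/r)
    correction is used instead.
    """
    if r >= 1e9:
        poisson = c * np.log(mu) - mu - gammaln(c + 1.0)
        return poisson + ((c - mu) ** 2 - c) / (2.0 * r)
    return (
        gammaln(c + r) - gammaln(r) - gammaln(c + 1.0)
        + r * np.log(r / (r + mu))
        + c * np.log(mu / (r + mu))
    )


def nb_loglik(
    matrix: ContactMatrix,
    coords: np.ndarray,
    params: NBParams,
    dist_floor: float = 1e-12,
) -> float:
    """Log-likelihood of observed (non-zero, i<j) counts under the NB model.

    Invariant under rigid motions of the coordinates; pairs involving a
    bead without coordinates are excluded.  A distance floor keeps the
    value finite for (near-)coincident beads.
    """
    i, j, c = matrix.pairs()
    off = i != j
    i, j, c = i[off] - 1, j[off] - 1, c[off]
    placed = ~np.isnan(coords[:, 0])
    keep = placed[i] & placed[j]
    i, j, c = i[keep], j[keep], c[keep]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    d = np.maximum(d, dist_floor)
    mu = params.beta * d**params.alpha
    return float(np.sum(_nb_terms(c, mu, params.r)))


def _negll_and_grad(
    x: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    c: np.ndarray,
    alpha: float,
    beta: float,
    r: float,
    n: int,
    floor: float,
) -> tuple[float, np.ndarray]:
    X = x.reshape(n, 3)
    diff = X[ii] - X[jj]
    d = np.linalg.norm(diff, axis=1)
    d = np.maximum(d, floor)
    mu = beta * d**alpha
    ll = np.sum(_nb_terms(c, mu, r))
    # d ll / d mu, chain through mu = beta d^alpha
    dll_dmu = c / mu - (c + r) / (r + mu)
    dll_dd = dll_dmu * alpha * beta * d ** (alpha - 1.0)
    coef = (dll_dd / d)[:, None] * diff
    grad = np.zeros_like(X)
    np.add.at(grad, ii, coef)
    np.add.at(grad, jj, -coef)
    return -float(ll), -grad.ravel()


def estimate_nb_params(
    matrix: ContactMatrix,
    coords: np.ndarray,
    alpha: float = -3.0,
) -> NBParams:
    """Closed-form beta and method-of-moments r given fixed coordinates.

    beta is the Poisson MLE sum(c) / sum(d**alpha) over observed pairs;
    r solves the moment identity E[(c - mu)^2] = mu + mu^2/r, clamped to
    [1e-2, 1e12] (the upper clamp is effectively Poisson).
    """
    i, j, c = matrix.pairs()
    off = i != j
    i, j, c = i[off] - 1, j[off] - 1, c[off]
    placed = ~np.isnan(coords[:, 0])
    keep = placed[i] & placed[j]
    i, j, c = i[keep], j[keep], c[keep]
    if c.size < 2:
        raise ValueError("need at least 2 observed pairs")
    if np.all(c == 0):
        raise ValueError("all observed counts are zero")
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    d = np.maximum(d, 1e-12)
    da = d**alpha
    beta = float(np.sum(c) / np.sum(da))
    mu = beta * da
    denom = float(np.sum((c - mu) ** 2 - mu))
    if denom <= 0:
        r = 1e12
    else:
        r = float(np.sum(mu**2) / denom)
    r = float(np.clip(r, 1e-2, 1e12))
    return NBParams(alpha=alpha, beta=beta, r=r)


# ---------------------------------------------------------------------------
# full structure fit


def fit_structure(
    matrix: ContactMatrix,
    config: InferenceConfig | None = None,
) -> StructureModel:
    """Infer a consensus bead structure maximizing the NB likelihood.

    Alternates L-BFGS coordinate blocks with (beta, r) re-estimation;
    a parameter update is only accepted when it does not decrease the
    likelihood, so the recorded trace is monotone non-decreasing.
    Beads with zero marginal count stay unplaced (status "missing").
    """
    if config is None:
        config = InferenceConfig()
    if matrix.nnz == 0:
        raise ValueError("contact matrix is empty")
    n = matrix.n
    if n < 2:
        raise ValueError("need at least 2 beads")

    wish = counts_to_wish_distances(matrix, config.alpha)
    if not wish:
        raise ValueError("no off-diagonal contacts to fit")
    floor = 1e-6 * float(np.median(list(wish.values())))

    X = mds_init(wish, n, seed=config.seed)
    active = ~np.isnan(X[:, 0])
    n_comp_unplaced = int(np.sum(~active))
    if n_comp_unplaced:
        logger.warning("%d beads have no contacts and stay unplaced", n_comp_unplaced)

    i, j, c = matrix.pairs()
    off = (i != j)
    i, j, c = i[off] - 1, j[off] - 1, c[off]
    keep = active[i] & active[j]
    ii, jj, cc = i[keep], j[keep], c[keep]

    # map active beads to a compact coordinate block
    idx_map = -np.ones(n, dtype=np.int64)
    act = np.flatnonzero(active)
    idx_map[act] = np.arange(act.size)
    si, sj = idx_map[ii], idx_map[jj]
    Xa = X[act].copy()
    m = act.size

    def params_for(coords: np.ndarray) -> NBParams:
        if config.beta_mode == "fixed" and config.dispersion_mode == "fixed":
            return NBParams(alpha=config.alpha, beta=config.beta, r=config.dispersion)
        full = np.full((n, 3), np.nan)
        full[act] = coords
        est = estimate_nb_params(matrix, full, alpha=config.alpha)
        beta = config.beta if config.beta_mode == "fixed" else est.beta
        r = config.dispersion if config.dispersion_mode == "fixed" else est.r
        return NBParams(alpha=config.alpha, beta=beta, r=r)

    params = params_for(Xa)

    def ll_of(coords: np.ndarray, p: NBParams) -> float:
        d = np.linalg.norm(coords[si] - coords[sj], axis=1)
        d = np.maximum(d, floor)
        mu = p.beta * d**p.alpha
        return float(np.sum(_nb_terms(cc, mu, p.r)))

    trace = [ll_of(Xa, params)]
    n_outer = 0
    max_outer = 50
    inner_iter = max(10, config.max_iter // max_outer)
    for n_outer in range(1, max_outer + 1):
        res = scipy.optimize.minimize(
            _negll_and_grad, Xa.ravel(),
            args=(si, sj, cc, params.alpha, params.beta, params.r, m, floor),
            jac=True, method="L-BFGS-B",
            options={"maxiter": inner_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        X_new = res.x.reshape(m, 3)
        ll_new = ll_of(X_new, params)
        if ll_new >= trace[-1]:
            Xa = X_new
            trace.append(ll_new)
        # parameter update, accepted only if the likelihood does not drop
        cand = params_for(Xa)
        ll_cand = ll_of(Xa, cand)
        if ll_cand >= trace[-1]:
            params = cand
            trace.append(ll_cand)
        rel = abs(trace[-1] - trace[-3]) / (abs(trace[-3]) + 1e-30) if len(trace) > 2 else np.inf
        if rel < config.tol:
            break

    model = StructureModel.empty(matrix.layout)
    model.coords[act] = Xa
    model.status[act] = STATUS_INFERRED
    model.loglik_trace = tuple(trace)
    model.n_iter = n_outer
    return model
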