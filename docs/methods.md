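# Methods

Model assumptions, parameter defaults and numerical choices of `hic3d`.
Nothing here is an empirical claim about real genomes; all quantitative
statements refer to behaviors checked in the test suite on synthetic data.

## Count–distance model

Each off-diagonal bin pair (i, j) with Euclidean bead distance `d_ij`
contributes an independent negative-binomial observation:

    c_ij ~ NB(mu_ij, r),   mu_ij = beta * d_ij^alpha,   Var(c) = mu + mu^2 / r

Assumptions this encodes:

- **Power-law decay.** Contact frequency falls off as a single power of
  spatial distance, the standard coarse-grained assumption for binned Hi-C.
  `alpha = -3` by default; any negative exponent is accepted.
- **Conditional independence.** Counts are independent given the structure;
  correlations induced by polymer connectivity are captured only through the
  shared coordinates.
- **Overdispersion, optionally.** `dispersion_mode="estimate"` fits `r` by
  method of moments (`r = sum(mu^2) / sum((c-mu)^2 - mu)`, clamped to
  [1e-2, 1e12]); `dispersion_mode="fixed"` with the default `r = 1e12`
  is numerically the Poisson model.
- **Zeros are ambiguous.** By default an absent pair is treated as
  unobserved (excluded from the likelihood), because in sparse maps a zero
  conflates "far apart" with "not sequenced". `zeros_informative=True`
  includes them as genuine zero counts.

Beads with an all-zero matrix marginal carry no information and are left
unplaced ("missing"); refinement decides their fate.

## Inference

1. **Wish distances.** `d = c^(1/alpha)` per observed pair, rescaled so the
   median *adjacent* wish distance is 1. This fixes the arbitrary overall
   scale; downstream comparisons use similarity superposition anyway.
2. **Initialization.** The wish-distance graph is completed by shortest
   paths, embedded by classical scaling (top-3 eigenvectors of the
   double-centered squared-distance matrix), and polished by L-BFGS on raw
   stress, independently per connected component.
3. **Alternating maximization.** Outer loop (up to 50 rounds): L-BFGS over
   coordinates at fixed (beta, r), then closed-form `beta = sum c / sum
   d^alpha` (the Poisson MLE, also the NB quasi-likelihood solution) and
   moment-matched `r`. Parameter updates are accepted only if they do not
   decrease the log-likelihood, making the trace non-decreasing by
   construction; convergence is declared on relative change below `tol`
   (default 1e-6).
4. **Identifiability.** The likelihood is invariant to rotations,
   translations and reflections (and rescaling trades off against `beta`),
   so a fitted model is a similarity-class representative. All RMSDs are
   therefore computed after Kabsch superposition with optional reflection
   and uniform-scale branches, both enabled by default.

### Numerical choices

- **Large-dispersion stability.** For `r >= 1e9` the NB log-pmf is evaluated
  as the Poisson log-pmf plus the O(1/r) correction `((c-mu)^2 - c) / (2r)`,
  avoiding catastrophic cancellation in `gammaln(c+r) - gammaln(r)`.
- **Distance floor.** Pairwise distances are floored at 1e-6 inside the
  likelihood so coincident initial beads cannot produce infinities.
- **Determinism.** All randomness flows through seeded numpy Generators; a
  fixed config reproduces outputs byte-identically.

## Refinement

- **Interpolation.** Interior runs of missing beads are filled per axis with
  PCHIP (monotone piecewise-cubic Hermite) over the bead index: shape
  preserving, no overshoot, exact on affine chains. Runs touching a
  chromosome end are discarded — extrapolation of a polymer end is pure
  invention. Chromosomes with fewer than two placed beads are discarded
  entirely.
- **Outlier filtering.** A bead is removed only when it is farther than the
  threshold from *both* sequence neighbours; a single long adjacent distance
  is legitimate (e.g. a real structural jump), two is a placement artifact.
  Default threshold: 10x the chromosome median adjacent distance — an
  order of magnitude above typical spacing, so only gross artifacts trigger,
  and scale-free because it is relative to the chromosome itself. Removed
  interior beads are re-interpolated.

## Mis-assembly detection

Adjacent-bead distances are compared to `tau` times the chromosome median
(default `tau = 5`: far enough above normal variation to avoid false
positives on jittered chains, well below the jumps created by reversed
segments of meaningful length). Flagged junctions are paired greedily left
to right; the enclosed segment is tentatively reversed and the candidate is
accepted only if both junction distances fall back under the threshold.
Unpaired junctions are reported but never corrected (translocation-like
anomalies are out of scope). Correction reverse-complements the genomic
interval and reverses the bead labels; it is an exact involution.

Detection limits: segments shorter than the distance scale of the threshold
produce sub-threshold jumps and are invisible; so are inversions whose
junction geometry happens to be compact. The detector sees label/space
disagreement only — it cannot distinguish an assembly error from a genuine
biological rearrangement relative to the reference.

## Shot-noise stability experiment

Each matrix entry (upper triangle plus diagonal, mirrored) receives additive
Poisson(lambda) noise; lambda sweeps a grid (default 0.1, then 5..110 in
steps of 5: 23 levels) with 50 replicates each (1150 cells). Per-cell noise
seeds derive from `SeedSequence(entropy=base_seed, spawn_key=(level,
replicate))`, so any cell is reproducible in isolation and independent of
execution order. All fits share one inference seed so RMSD differences
reflect the injected noise, not initialization. Summaries are per-lambda
quartiles of the superposed RMSD, globally and per chromosome (each
chromosome superposed independently).

## Synthetic data: what it does and does not emulate

The Rabl generator reproduces the gross nuclear anatomy of many fungi:
centromeres clustered near one pole, telomeres toward the other, helical
arms, angularly separated chromosome territories, near-uniform bead spacing
(arc-length reparametrized curves). Counts drawn from the fitted model
family (`none`/`exact`/`poisson`/`nb` modes) make the generative process
match the inference model exactly — deliberately, so recovery tests isolate
the optimizer from model misspecification. It does **not** emulate polymer
physics, loops/TADs/compartments, mappability or copy-number biases,
restriction-site geometry, or the rDNA/nucleolus. Track fixtures are
two-level signals with truncated-Gaussian noise (the consumed quantity is
normalized coverage, not raw counts).

## File formats

- **Matrix**: HiC-Pro-style sparse triplet (`binA binB count`, 1-based bin
  ids, upper triangle) plus a BED file of 0-based half-open bins whose
  4th column is the bin id.
- **PDB**: one ATOM per placed bead; chromosome number in the residue
  sequence field (authoritative on read), chain id A–Z a–z 0–9 (62 max),
  residue name C01, C02, ...; per-bead signal in the B-factor column;
  coordinates uniformly scaled so the maximum absolute value is 100.0;
  TER per chromosome. The writer is canonical: write -> read -> write is
  byte-identical.
- **G3D**: header `##g3d resolution=N`, then tab-separated
  (chromosome, 0-based bp start, x, y, z) per placed bead.
- **bedGraph**: layout-resolution bins; gaps read as missing values.

## Limitations

- Single-structure point estimate: no ensemble or uncertainty
  quantification beyond the noise-perturbation experiment.
- The power-law/NB family is assumed, not checked; real maps with strong
  normalization artifacts violate it.
- Inter-chromosomal placement is only as good as inter-chromosomal counts;
  in shallow maps chromosome positioning relative to each other is weakly
  constrained.
- Assembly QC handles inversions only, at bead (bin) resolution: junction
  placement is no finer than the resolution, and the reported genomic
  interval inherits that granularity.
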