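# Methods

This note records the models, numerical choices, and design decisions
behind `anglescape`, in the spirit of the methods documentation shipped by
statsmodels or msprime: enough detail that a careful user can predict what
the code computes before running it.

## Coordinates and metric

A trajectory is an N × M matrix of backbone dihedral angles in radians,
each entry confined to the half-open domain **[−π, π)**.  The half-open
convention makes validation unambiguous; the minimal-image difference is
returned in (−π, π], with the tie at |δ| = π broken to +π so that the
operation is deterministic and testable.  The dissimilarity between frames
is the flat torus metric — the Euclidean norm of per-coordinate
minimal-image differences — and is bounded by π√M.  Dissimilarity matrices
are stored dense; the driver caps N at 30 000 frames (configurable) to
bound the O(N²) memory, the same order as the subsampled trajectories this
kind of analysis is usually run on.  An O(N²M) compiled (numba) kernel
computes the matrix; a pure-numpy path produces identical values and is
used automatically for small inputs or when no JIT is available.

Dihedral extraction from multi-MODEL PDB files (one MODEL = one frame) uses
the standard atan2 formulation with the IUPAC right-handed sign convention
(cis = 0, trans = ±π); its sign is cross-checked in the tests against
Biopython's independent `calc_dihedral`.  Which torsions to compute is an
explicit argument — a 16-residue peptide has 30 φ/ψ angles plus ω and
side-chain options, and guessing silently would be worse than asking.

## Landmark selection

Farthest point sampling (FPS) greedily maximizes the minimal distance to
the already-chosen set; it is deterministic given the start frame
(default 0).  Well-tempered FPS interpolates between FPS and
density-weighted random sampling: at each step the next landmark is drawn
with probability ∝ d_i^(2/γ).  The draw is implemented by the Gumbel-max
trick on the logits (2/γ)·log d_i, which is numerically exact for
arbitrarily small γ, so the γ → 0⁺ limit reproduces FPS *identically*
(this limit is property-tested).  The original well-tempered scheme is
published in an external appendix; this one-parameter rule is this
package's own concretization with the documented limiting behaviors.
Voronoi weights count the frames nearest to each landmark (ties to the
lowest frame index) and therefore always sum to N.

## Projections

- **dPCA** diagonalizes the covariance of the column-centered sin/cos
  matrix.  Chord distances satisfy 2|sin(δ/2)| ≤ |δ| per angle, and an
  orthogonal projection can only shrink distances further, so dPCA
  distances never exceed the torus dissimilarities — the contraction
  property the joint-density diagnostic makes visible.
- **Stress minimization** ("dist. match") minimizes
  χ = Σ_{i≠j}(R_ij − r_ij)² with conjugate gradients and the analytic
  gradient.  Initialization is the classical-scaling solution
  (deterministic; exact whenever R is Euclidean and embeddable in d
  dimensions) unless a seeded random start is requested.  Convergence:
  relative loss change < 1e−9 or 5000 iterations.
- **Isomap** builds a k-NN graph symmetrized **by union** (an edge survives
  if either endpoint lists the other — the choice that keeps graphs
  connected longest), runs Dijkstra for all-pairs geodesics, and applies
  classical scaling.  A disconnected graph raises an error that names the
  component sizes; silently embedding the largest component would corrupt
  downstream frame indexing.
- **Laplacian eigenmaps** weights graph edges by exp(−γ R²) and solves the
  generalized problem L v = λ Deg v, discarding the zero eigenvalue's
  constant eigenvector.
- **Exact t-SNE**: per-point precisions are bisected until every
  conditional perplexity 2^H(P_i) is within 1e−3 of the target;
  affinities are symmetrized and the KL divergence is minimized by gradient
  descent (1000 iterations, learning rate 200, early exaggeration ×12 for
  250 iterations, momentum 0.5 → 0.8, seeded 1e−4-scale Gaussian
  initialization).  These optimizer constants are package defaults — the
  usual choices in reference implementations — not quantities with any
  external authority.  The Barnes–Hut approximation is deliberately not
  implemented: at the N this package targets the exact gradient is
  affordable and far easier to test.
- Deterministic spectral methods fix each eigenvector's sign by making its
  largest-magnitude entry positive, so repeated runs are bit-identical.

## Sketch-map

The switching function F_{σ,p,q}(r) = 1 − (1 + (2^{p/q} − 1)(r/σ)^p)^{−q/p}
satisfies F(0) = 0 and F(σ) = 1/2 for every exponent pair (an algebraic
identity the tests exercise for random parameters).  The landmark stress is
normalized by Σ_{i<j} w_i w_j so its magnitude is comparable across
landmark counts, making convergence thresholds scale-free.  Optimization:
classical MDS of the σ-scaled F-transformed dissimilarities as the start,
then L-BFGS with the analytic gradient (the optimizer schedule is a package
decision; the reference parameter set σ = 6, A = 8, B = 8, a = 2, b = 8,
1000 landmarks, γ = 0.1 is the default configuration).  The single-frame
out-of-sample stress is multimodal, so each frame is first scanned on a
regular grid over the landmark bounding box expanded by 20% (≈2500 points,
resolution adapted to the output dimension) and then polished with
Nelder–Mead; a brute-force fine-grid oracle in the tests confirms the
minimizer is not trapped.

## Projection fidelity

All N(N−1)/2 unordered pairs are binned into a 100 × 100 histogram over
[0, max R] × [0, max(r, R)] (so the D = d diagonal is always inside the
axes) and normalized to unit integral.  Pairs with r exactly equal to R
are counted in neither the contracted nor the stretched fraction; all
three fractions are reported and sum to 1.

## Basin identification

The grid is FPS-selected (uniform spatial coverage; the start frame is
drawn from the seed).  The KDE kernel is the per-coordinate wrapped
Gaussian truncated at ±1 periodic image — for bandwidths below ~1 rad the
truncation error is below 1e−8 of the kernel mass.  Bandwidth default:
half the median nearest-neighbor distance among grid points; Quick-Shift
links each grid point to its *nearest* strictly-denser grid point within a
cutoff λ, and unlinked points are the density modes.

The cutoff default is **λ = 5h**.  A cutoff of 3h was tried first and
produced spurious single-point modes in roughly a fifth of seeded runs on
the reference scenarios: an FPS grid intentionally covers basin tails,
where inter-grid spacing exceeds 3h, so an isolated low-density tail point
can fail to find any denser neighbor within range.  A sweep over
multipliers {3, 4, 5, 6, 8}×h on sixteen seeded runs of two scenarios
showed every multiplier ≥ 4 recovering the planted mode count in all runs;
5h sits in the middle of that plateau while remaining an order of
magnitude below the inter-basin separations of any scenario considered.
Users clustering data with much closer basins should set `lambda_cut`
explicitly.

Per-cluster covariance: per-coordinate circular mean as the center,
minimal-image residuals, ordinary covariance of the residuals.  This
tangent-space estimator is accurate for concentrated clusters; a cluster is
flagged when any residual exceeds π/2 (covariance no longer trustworthy) or
when it has fewer than M+1 frames (rank-deficient).  Determinant scaling
uses log-determinants so 32-dimensional covariances with eigenvalues of
order 1e−2 (log-det ≈ −150) cannot underflow; the largest-determinant
cluster reads exactly 1.  The effective dimension
exp(−Σ η_k log η_k) is 1 for a rank-one spectrum and equals the rank for a
flat one; 0·log 0 is taken as 0.

Bootstrap significance: each of n_boot (default 41) replicates resamples N
frames with replacement and reclusters with identical settings.  For a
reference cluster, its *majority mode* is the bootstrap mode that most of
its resampled frames land in; two reference clusters merge in a replicate
when their majority modes coincide.  The merge criterion is this package's
concretization of "clusters get merged in some of the bootstrap samples";
a replicate in which a reference cluster receives no resampled frames is
excluded from that pair's denominator.  Merge distance = 1 − merge
frequency; macro-clusters are connected components of the average-linkage
dendrogram cut at a distance threshold.

## Synthetic data

The generator plants mixtures of wrapped normals on the M-torus: draw in
the tangent space at the component mean with a covariance of planted
spectrum (rotated by a seeded Haar-random orthogonal matrix), then wrap.
Wrapped-normal rather than von Mises sampling is deliberate: the
minimal-image covariance estimator used downstream is exactly consistent
for this process in the concentrated regime, which makes
parameter-recovery tests sharp rather than approximate.  Every scenario
keeps 3σ < π per coordinate so wrap-around mass is negligible and planted
labels remain meaningful.

Fixed scenarios (M = 32 throughout):

- `well_separated` — five components with geometric spectra
  (λ_k = 0.0625·0.6^k, planted effective dimension ≈ 5.4, max σ = 0.25),
  weights 0.30/0.25/0.20/0.15/0.10, means rejection-sampled until all
  pairwise torus separations exceed 6× the largest component σ.  The
  baseline for mode-recovery tests.
- `two_funnels` — two broad components with flat 10-eigenvalue spectra
  (0.04 ×10 plus a 2e−4 floor; planted effective dimension ≈ 10.7) and
  three narrow ones (0.03/0.015/0.0075 plus a 1e−6 floor; ≈ 2.6),
  weights 0.3/0.3 and 0.4/3 each.  Mimics a landscape with two folded
  states at the bottom of wide catchments plus small high-energy basins,
  and drives the funnel-diagnostics tests (broad > 7 effective dimensions,
  narrow < 4, largest determinant on a broad funnel).
- `eleven_modes` — eleven components (2 broad + 9 narrow), for workflows
  that want a mode count of the order reported for real peptide data.

What the generator does **not** emulate: Ramachandran-plot statistics,
force-field energetics, kinetic ordering of frames (the analyses here are
order-agnostic), or heavy-tailed intra-basin fluctuations.  Passing the
recovery tests therefore demonstrates correctness of the machinery on
well-specified planted structure, not performance guarantees on real
trajectories, where basins overlap and are not Gaussian.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is sharply testable: N = 200–300 for
projection diagnostics, N = 5000 with a 500-point grid for mode recovery,
N = 4000 with a 400-point grid for funnel diagnostics, 41 bootstrap
replicates at N = 800, and N = 150 for the end-to-end determinism check.
Every stochastic step takes an explicit seed; the driver writes SHA-256
checksums of all artifacts, and identical configurations reproduce
identical checksums (serialization uses %.17g, which round-trips doubles
exactly).

## Known limitations

- All-pairs methods are O(N²) memory; there is no out-of-core path.
- Quick-Shift operates on the sparse grid, so basins thinner than the grid
  covering radius can be missed; increase `grid_size` for fine structure.
- The circular covariance (and hence all spectrum diagnostics) degrades
  for clusters wider than ~π/2 per coordinate; such clusters are flagged
  rather than repaired.
- The out-of-sample sketch-map projection optimizes each frame
  independently; for very large N it is the slowest stage.
- t-SNE and stress minimization converge to local optima; different seeds
  give different (valid) embeddings.
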