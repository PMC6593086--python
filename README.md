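# anglescape

Dimensionality reduction and density-based basin analysis for
dihedral-angle trajectories of biomolecules.

Molecular-dynamics trajectories of peptides and proteins are most naturally
summarized by their backbone torsion angles, which live on an M-dimensional
torus.  This package takes an N × M matrix of dihedral angles (radians) and
answers two questions a simulator typically asks:

1. **What does the sampled conformational ensemble look like?**  Six
   low-dimensional projection strategies, all periodicity-aware, plus a
   quantitative diagnostic of how faithfully each projection reproduces the
   true inter-frame distances.
2. **Which free-energy basins were visited, and what shape are they?**  A
   density-mode clustering (sparse grid → KDE → Quick-Shift) with
   covariance-spectrum diagnostics per basin and a bootstrap test of which
   modes are statistically distinguishable.

It is aimed at structural-bioinformatics and molecular-simulation users who
want a reproducible, scriptable alternative to ad-hoc projection notebooks.

## The methods

All methods except dPCA operate on the periodic (minimal-image) Euclidean
dissimilarity between frames,

    R_ij = sqrt( Σ_k wrap(θ_k^(i) − θ_k^(j))² ),  wrap(δ) ∈ (−π, π].

**Projections** (`DihedralPCA`, `StressEmbedding`, `GeodesicIsomap`,
`LaplacianEigenmaps`, `ExactTSNE`, `SketchMap` — all scikit-learn style
estimators with `fit` / `transform` / `fit_transform`):

- *dPCA*: PCA of the sin/cos transform of each angle — the standard
  periodicity-respecting PCA variant.  Its projected distances never exceed
  R_ij (a linear projection can only contract).
- *dist. match*: metric MDS, minimizing χ = Σ_{i≠j} (R_ij − r_ij)² by
  conjugate gradients from the classical-scaling solution.
- *isomap*: geodesics on a symmetrized k-NN graph (Dijkstra) followed by
  classical scaling; k = 15 by default.
- *Laplacian eigenmaps*: Gaussian edge weights exp(−γ R²) (γ = 1), smallest
  non-trivial generalized eigenvectors of the graph Laplacian.
- *exact t-SNE*: per-point bandwidths calibrated by bisection to a target
  perplexity (default 110), exact O(N²) KL gradient descent with early
  exaggeration.
- *sketch-map*: landmarks chosen by well-tempered farthest point sampling
  (γ = 0.1) and weighted by Voronoi populations; the stress matches
  sigmoid-transformed distances F_{σ,A,B}(R_ij) vs F_{σ,a,b}(r_ij) with
  σ = 6, A = B = 8, a = 2, b = 8, so only separations near σ are
  reproduced; remaining frames are placed by an out-of-sample optimizer.

**Projection quality** (`projeval`): the joint density
P(D, d) ∝ Σ_{i<j} δ(R_ij − D) δ(r_ij − d) as a normalized 2-D histogram,
plus the fractions of pairs contracted (r < R) and stretched (r > R).  An
ideal projection puts all mass on D = d.

**Basin identification** (`ModeClustering`): farthest-point grid over the
frames, wrapped-Gaussian KDE at the grid points, Quick-Shift linking of each
grid point to its nearest strictly-denser neighbor within a cutoff, and
nearest-grid-point assignment of every frame.  Per-basin diagnostics from
the circular-mean-centered covariance spectrum {λ_k}: the scaled
determinant, the top-2 eigenvalue fraction, and the effective dimension

    D_i = exp(−Σ_k η_k log η_k),   η_k = λ_k / Σ_j λ_j,

the participation ratio of the spectrum.  `bootstrap_hierarchy` resamples
the trajectory (41 replicates by default), reclusters, and measures how
often each pair of reference modes becomes indistinguishable — giving a
dendrogram whose cut yields macro-basins.

A synthetic generator (`anglescape.synth`) plants wrapped-normal mixtures
on the torus with known means, covariance spectra, and weights — including
scenarios with two broad high-dimensional "funnels" and several narrow
basins — so every stage can be tested against ground truth.

## Worked example

```python
import numpy as np
from anglescape import (reference_scenario, sample_torus_mixture,
                        pairwise_dissimilarity, dpca_project, stress_minimize,
                        pair_fractions, ModeClustering, cluster_stats)

spec = reference_scenario("two_funnels", seed=0)     # 2 broad + 3 narrow basins
traj, planted = sample_torus_mixture(spec, 2000, seed=1)
D = pairwise_dissimilarity(traj)

pca = dpca_project(traj, d=2)
mds = stress_minimize(D, d=2, seed=1, max_iter=200)
print("dPCA   pair fractions:", pair_fractions(D, pca))
print("dist-match fractions :", pair_fractions(D, mds))

est = ModeClustering(grid_size=250, random_state=0).fit(traj.angles)
stats = cluster_stats(traj, est.labels_)
print(f"modes found: {est.n_modes_} (bandwidth {est.bandwidth_:.3f} rad)")
for i, c in enumerate(stats.labels):
    print(f"  cluster {c}: n={stats.counts[i]:4d}  "
          f"scaled det {stats.scaled_determinant[i]:.3g}  "
          f"top-2 frac {stats.top2_fraction[i]:.2f}  "
          f"eff dim {stats.eff_dimension[i]:.1f}")
```

Output:

```
dPCA   pair fractions: {'contracted': 1.0, 'stretched': 0.0, 'tied': 0.0}
dist-match fractions : {'contracted': 0.586, 'stretched': 0.414, 'tied': 0.0}
modes found: 5 (bandwidth 0.329 rad)
  cluster 0: n= 271  scaled det 1.07e-85  top-2 frac 0.87  eff dim 2.5
  cluster 1: n= 262  scaled det 1.42e-85  top-2 frac 0.84  eff dim 2.7
  cluster 2: n= 265  scaled det 1.48e-85  top-2 frac 0.85  eff dim 2.7
  cluster 3: n= 613  scaled det 1  top-2 frac 0.23  eff dim 10.6
  cluster 4: n= 589  scaled det 0.64  top-2 frac 0.24  eff dim 10.6
```

Reading this: dPCA contracts every pair (all joint-density mass below the
D = d diagonal), while direct stress minimization scatters pairs on both
sides of it.  The clustering recovers all five planted basins; the two
broad funnels (clusters 3 and 4) carry ~10 effective dimensions and the
largest covariance volumes, so only ~23% of their variance fits in a plane
— exactly why they are hard to project faithfully — while the three narrow
basins are essentially 3-dimensional.

A YAML-driven CLI covers the same pipeline end to end
(`anglescape simulate | featurize | project | evaluate | cluster | run-all`),
writing plain-text artifacts and a checksummed manifest, so identical
configurations and seeds reproduce bit-identical outputs.

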