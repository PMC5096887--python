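# Methods

## The model

`covnet` analyses *structural covariance networks*: graphs whose nodes are
cortical regions and whose edges are strong inter-subject correlations of a
morphometric measure (here regional mean cortical thickness, mm). The
working assumption of the field is that coordinated thickness variation
between two regions reflects shared trophic, genetic and connectional
influences, so the group-level correlation matrix can be read as a
connectivity proxy. The pipeline is group-level by construction — one
network per group, not per subject — so all inference is by permutation of
group labels.

The stages, each exposed as a library function and a CLI subcommand:

1. **Residualization** (`residualize`). For each region, thickness is
   regressed (OLS with intercept) on nuisance covariates — age (years),
   gender (0/1 coding declared in the schema), illness burden, mean cortical
   thickness, optionally white-matter-hyperintensity (WMH) volume (mL) — and
   replaced by the residual. Fits are per group by default (`per_group`),
   so each group's covariance reflects only its own covariate-adjusted
   variation; a pooled variant is available. Residualization is idempotent
   and invariant to affine rescaling of covariates.
2. **Association** (`build_association`). Pearson correlation of the
   residuals across the subjects of one group; diagonal set to 0. R × R,
   symmetric, entries in [−1, 1].
3. **Thresholding** (`threshold_at_density`). The binary undirected network
   at density d keeps the E = round(d·R(R−1)/2) largest *signed*
   correlations (strong negative correlations are never edges; ranking by
   |R| is available behind `absolute=True`). Rounding is half-away-from-zero
   and ties are broken by ascending (row, column) pair, so thresholding is
   deterministic and edge sets are nested across densities.
4. **Minimum density** (`find_min_density`). The smallest density on the
   analysis grid (default 0.10:0.01:0.20) at which every group's network
   forms a single connected component. Resilience, nodal and hub analyses
   run at D_min; curve analyses span the grid.
5. **Graph measures** (`covnet.metrics`). Integration: characteristic path
   length Lp (mean shortest-path length) and global efficiency (mean inverse
   shortest-path length, with 1/∞ = 0). Segregation: mean nodal clustering
   Cp, local efficiency, transitivity (3·triangles / connected triples),
   and Newman modularity Q of a deterministic greedy agglomerative
   (Clauset–Newman–Moore) partition. Nodal: degree, clustering,
   unnormalized betweenness. Small-worldness: gamma = Cp/⟨Cp_rand⟩,
   lambda = Lp/⟨Lp_rand⟩, sigma = gamma/lambda, normalized by
   ratio-of-means over degree-preserving double-edge-swap (Maslov–Sneppen)
   reference networks (default 20 references, 100 × E attempted swaps each).
6. **Group comparison** (`covnet.compare`). Nonparametric permutation tests:
   group labels are shuffled across subjects preserving group sizes and the
   whole pipeline — residualization included — is recomputed per
   permutation. Differences are assessed per density and via the
   trapezoidal area under the metric-versus-density curve (AUC), which is a
   single summary insensitive to any one threshold. All p-values are
   two-tailed with the add-one correction p = (1 + #{|null| ≥ |obs|}) /
   (n_perm + 1), so p ∈ [1/(n_perm+1), 1]. Nodal comparisons at a fixed
   density are corrected across regions by Benjamini–Hochberg FDR within
   each nodal metric.
7. **Resilience** (`covnet.resilience`). Nodes are deleted cumulatively —
   uniformly at random (curve averaged over 50 removal orders by default) or
   in descending order of betweenness computed once on the intact network
   (static targeted attack; a recompute-after-removal variant exists behind
   a flag) — and damage is the largest remaining component divided by the
   original node count R. Group curves are compared at D_min by the same
   permutation scheme; supplying `extra_covariates=["wmh_total"]` adds WMH
   to the residualization throughout (the covariate-adjusted secondary
   analysis); a missing WMH column is an error, never imputed.
8. **Hubs** (`covnet.hubs`). A region is a hub when its betweenness is at
   least 2 population SDs above the network mean (z ≥ 2, inclusive, with a
   1e-9 roundoff guard; threshold configurable). Zero-variance betweenness
   (e.g. complete graphs) yields an empty hub set with a warning.

## Numerical and design choices

- **Disconnected graphs.** Lp is averaged over reachable pairs with a
  warning; efficiency, clustering, transitivity and modularity are well
  defined on any graph. In curve comparisons, densities where an observed
  group network fragments are dropped *only* for the path-length family
  (Lp, gamma, lambda, sigma); count-based metrics keep the full grid. For
  permuted cohorts no densities are dropped (the null sample size stays
  fixed); fragmented permuted networks use the reachable-pairs conventions.
- **Small-world references for fragmented networks.** When the input
  network is connected, disconnected rewires are discarded and redrawn (up
  to 20 redraws); when it is fragmented, any degree-preserving rewire is
  accepted, since demanding connected references of a disconnected graph
  would bias lambda.
- **Determinism.** Thresholding and the modularity partition are fully
  deterministic; every stochastic component (permutations, rewirings,
  random failure orders, simulation) consumes a named substream of one
  master seed, making each output bit-reproducible in isolation.
- **Modularity optimizer.** Greedy agglomeration trades optimality for
  determinism; on random graphs with ≤ 8 nodes its Q is within 0.15
  (typically within 0.03) of the exhaustive-partition optimum, a gap the
  test suite bounds explicitly.
- **Betweenness normalization.** Raw path counts are used; the 2-SD hub
  rule and the attack ranking are invariant to any common rescaling.
- **Tie-breaks.** Attack order and hub listing break betweenness ties by
  higher degree, then lexicographic region label.
- **Implementation note.** Shortest paths use dense level-synchronous BFS
  (one uint8 matrix product per level), and betweenness/greedy modularity
  run through igraph's C implementations; both are validated against
  hand-rolled enumeration oracles on randomized small-graph batteries.

## The synthetic cohort generator

`covnet.simulate` draws cohorts from exactly the model the pipeline assumes:

    thickness_ij = base + Σ_c slope_c · (covariate_ci − center_c)
                   + struct_sd · z_ij + noise_ij

with z rows multivariate normal under a block-structured correlation matrix
(compound symmetry: within-module correlation per module, a global
between-module floor, optional "hub" regions with elevated cross-module
correlation). Validity (within < 1, 0 ≤ between ≤ within, positive
semi-definiteness) is checked at construction and never repaired.

Defaults describe a realistic elderly two-group study: 68 regions with
two-hemisphere Desikan–Killiany-style labels, 25 + 33 subjects, 4 modules
with within-module rho 0.6–0.8 over a between floor of 0.1, base thickness
2.3 mm, age ~ U(60, 84) years, ~26 % male (fixed shuffled fraction, so the
gender column is never constant within a group), right-skewed illness
burden (gamma) and WMH volume (lognormal, capped at a physiological 80 mL).
Covariate slopes may be scalar or per-region; a per-region loading is how a
covariate can *carry* a network difference, since rank-based thresholding is
invariant to the uniform correlation shift a scalar loading induces.

`struct_sd = noise_sd = 0.12 mm` splits regional variance evenly between the
correlated deviation and region-idiosyncratic variation. This puts the
observable correlations near what empirical thickness-covariance studies
report (≈ 0.3–0.4 within-module after covariate adjustment; total regional
SD ≈ 0.17 mm) and, as in real data, lets sampling variability create the
between-module bridges that connect the network on the standard density
grid (D_min ≈ 0.10–0.14 across seeds). `GroundTruth.correlation` stores the
observable (noise-attenuated) correlation matrix the association step
converges to; `latent_correlation` stores the un-attenuated block matrix.

What the generator does *not* emulate: spatial autocorrelation and
distance-dependent covariance, hemispheric asymmetry, non-Gaussian thickness
distributions, scanner/site effects, and subject-level network variability.
Passing tests therefore demonstrate correctness of the estimator and the
inference machinery under the assumed model, not robustness to those
real-data features.

`plant_segregation_difference(spec, delta)` raises the second group's
within-module correlations by delta, producing the canonical segregation
signature (higher transitivity and modularity in that group). At delta =
0.2 with 25/33 subjects the signature direction is recovered in ~98 % of
replicates, while the two-tailed AUC test at alpha = 0.05 detects the
effect in roughly 40 % — group sizes this small leave the realized effect
highly variable between draws.

## Problem sizes used in validation

The full-scale checks run the default 68-region cohort: small-worldness
across the 11-density grid with 20 references per network; null calibration
of the AUC test over 500 simulated cohorts at n_perm = 200 (type-I error
within [0.03, 0.07] at alpha = 0.05); planted-effect recovery over 100
cohorts at n_perm = 200. Unit tests use reduced cohorts (20–32 regions) and
enumeration oracles on graphs with ≤ 10 nodes. The default `run-all`
configuration (n_perm = 1000, 50 random-failure repeats) completes in a few
minutes on one CPU.

## Known limitations

- Group-level networks preclude subject-level correlates; no confidence
  intervals on the network measures themselves, only permutation bands on
  group differences.
- The greedy modularity partition can split or merge planted modules near
  the resolution limit; the recovery tests use clearly separated blocks.
- The permutation comparison of gamma/lambda/sigma requires rewired
  references inside every permutation and is correspondingly expensive; the
  orchestrated `run-all` reports observed sigma-family curves and restricts
  permutation inference to the six non-normalized measures (explicit
  `compare --metric sigma` runs remain available).
- Static targeted attack uses the intact-network betweenness ranking;
  recomputation after each removal is more aggressive but quadratic in R.
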