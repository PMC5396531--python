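# Methods

This document describes the statistical model, the synthetic-cohort
generator, and the numerical choices made in `connectolapse`.

## 1. Data model

A dataset consists of

- a **parcellation** of `n_cortical` cortical regions (left/right
  hemisphere) and `n_striatal` striatal regions (default 70 + 4);
- per subject and visit, a symmetric non-negative **connectome matrix** `W`
  with zero diagonal (weights are streamline-count-like connection
  strengths); asymmetries above a 1e-9 relative tolerance are rejected,
  smaller ones symmetrized;
- a **cohort table** with group (`control` / `preHD`), age, sex, site,
  education, and for the disease group a CAG repeat length and baseline
  cognitive composite.

The analysed connection-level units are all cortico-cortical and
striatal-cortical region pairs: `C(n_cortical, 2) + n_striatal * n_cortical`
(2,695 at the default parcellation). Striatal-striatal pairs are excluded.

## 2. Network partition

Community structure is estimated on the cortical submatrix of the baseline
average network by **consensus Louvain**:

1. run Louvain modularity maximization `n_runs` times at resolution γ with
   independent seeds;
2. build the agreement matrix `A_ij` = fraction of runs assigning regions
   `i` and `j` to the same module;
3. zero entries below the threshold τ (default 0.5), re-run Louvain on the
   thresholded matrix, and iterate until all runs return the identical
   partition (agreement-matrix consensus). A "modal" alternative (most
   frequent partition across runs) is also available.

The resolution sweep γ ∈ {0.6, 1.0, 1.7} probes robustness; γ = 1 is the
primary analysis. Louvain is stochastic, so consensus over many runs plus a
fixed master seed makes the partition deterministic and stable.

## 3. Connection subtypes

Relative to the consensus partition, each analysed region pair is labelled

- **cortico-striatal** — one striatal, one cortical region (the striatum is
  pooled across hemispheres);
- **interhemispheric** — cortical regions in modules of opposite
  hemispheres;
- **intrahemispheric** — cortical regions in different modules of the same
  hemisphere;
- **intramodular** — cortical regions in the same module.

Subtype-level connections aggregate the member-pair weights; for `m` modules
per hemisphere and pooled striatum this yields `2m` cortico-striatal, `m²`
interhemispheric, `m(m-1)` intrahemispheric and `2m` intramodular
connections (6/9/6/6 at m = 3). Modules are required to be hemisphere-pure;
planted and consensus partitions satisfy this by construction.

## 4. Longitudinal group model

Per connection, strength is modelled as

```
Y_ij = α + β t_ij + γ group_i + δ group_i t_ij + θ'X_i + a_i + b_i t_ij + e_ij
```

with time in years since baseline (`t = visit − 1`), covariates X = age,
sex, site, education, joint-normal random intercept/slope `(a_i, b_i)` and
normal errors. Fitting is maximum likelihood (not REML) via
`statsmodels.MixedLM`; contrasts are tested two-sided with `z = estimate/SE`.
γ is the baseline group difference, δ the group difference in rate of
change. A cognition variant replaces the group dummy by a continuous
standardized baseline composite within the disease group, with CAG and
CAG-by-time covariates.

**Optimizer fallback.** Each fit tries L-BFGS, then statsmodels' default
optimizer chain; a fit is accepted only if it converged with finite standard
errors. If the random-slope model fails, the model falls back to a random
intercept only, and as a last resort reports the non-converged
intercept-only fit flagged `converged=False`. Two-sided p-values are floored
at the smallest positive float so the invariant p ∈ (0, 1] holds under
underflow.

**Multiplicity.** Benjamini–Hochberg FDR is applied within each subtype
family, separately for the γ and δ contrasts.

## 5. Topology–atrophy analysis

- **Path lengths.** On the baseline control-average network, weights map to
  lengths `L_ij = 1/W_ij` (infinite where `W_ij = 0`) and all-pairs shortest
  paths are computed with `scipy.sparse.csgraph.dijkstra`. Pairs with
  infinite shortest-path length are excluded from the correlation with a
  logged count.
- **Atrophy scores.** For each connection, the disease-group baseline
  strength and the per-subject least-squares slope over visits (subjects
  with all visits only) are Z-scored against the control sample mean and
  sample (n−1) SD, after residualizing both groups' values on age and sex
  (residualize-then-Z). Z maps to a score in (0, 1) via the **logistic**
  transform `1/(1+e^Z)` (default; monotone, higher score = greater atrophy).
  A **literal** variant `1/(e^{−Z}+e^{Z}) = sech(Z)/2` is exposed as
  `--transform=literal`; it is symmetric about Z = 0 and therefore
  non-monotone, which is why it is not the default. Both give 0.5 at Z = 0.
- **Correlation.** Spearman rank correlation (average-rank ties) between
  path length and the mean transformed score across disease subjects, with
  df = n − 2; computed separately for the cross-sectional and longitudinal
  scores.
- **Subtype contrast.** One-way ANOVA of path length across the four
  subtypes (df = (3, 2691) at the default parcellation) with Tukey–Kramer
  post-hoc pairwise comparisons (unequal group sizes supported).

## 6. Synthetic-cohort generator

The generator plants the structure the pipeline is supposed to recover.

**Base network.** Cortical regions are split into `modules_per_hemisphere`
modules per hemisphere. Each analysed pair gets an edge with probability
`edge_density[subtype]` (default 1.0 for every subtype — a dense,
SIFT2-style unthresholded connectome) and base weight
`base_weights[subtype] · exp(N(0, noise_sd²))`, defaults
intramodular 20 > intrahemispheric 6 > interhemispheric 3 >
cortico-striatal 1. This weight hierarchy induces the intended topological
length ordering (cortico-striatal longest). If sparse densities disconnect
the graph, a minimal backbone reconnects the components.

**Degeneration.** With `L*` the true path length on the base network, the
log-scale longitudinal model for subject `i`, pair `(j,k)`, time `t` is

```
W_ijk(t) = B_jk · exp(−λ L*_jk · disease_i − (κ0 + κ1 L*_jk) t · disease_i
                      + θ'X_i + u_i + v_i t + ε_ijkt)
```

with baseline deficit λ (default 0.15), rate intercept κ0 (0.02), rate-length
slope κ1 (0.08), small covariate effects on age/sex/site, subject random
intercept `u_i` and slope `v_i`, and symmetric noise ε. κ1 > 0 makes the
rate of atrophy increase with topological length — the effect the pipeline
measures. Visit 1 is always observed; later visits can be dropped with
`missing_visit_prob`. The disease group receives a baseline cognitive
composite coupled (default ρ = 0.5) to its interhemispheric baseline
strength, plus a CAG repeat length.

**Default cohort size** is 85 controls and 82 disease participants over 3
annual visits, a realistic multi-site observational design. These defaults
are the package's own study conditions; the worked-example and test
configurations shrink the cohort for runtime, not the effects.

**What the generator does not emulate:** tractography and its biases
(distance-dependent false positives, gyral bias), scanner/site batch
structure beyond a mean site offset, head motion, non-linear trajectories,
dropout that is informative with respect to disease severity, and millimetre
(biological) tract length.

## 7. Determinism and numerics

- A single master seed; each random stage derives a child seed as
  `(seed XOR crc32(stage_name)) mod (2³¹ − 1)`, so reproducibility survives
  stage re-ordering. Re-running a pipeline config reproduces all outputs
  bit-identically.
- Connectome CSV round-trips are bit-exact (`repr` on write, round-trip
  float parsing on read).
- Dijkstra and Floyd–Warshall agree only up to float summation order, so
  cross-algorithm checks use a relative tolerance of 1e-12 with zero
  absolute tolerance.
- Sample (n−1) standard deviations are used for all Z-scores; connections
  with zero control variance are reported as missing rather than silently
  dropped or infinite.

## 8. Limitations

- The mixed-model z-test relies on asymptotic normality; at very small
  cohort sizes its type-I error is only approximately nominal (the
  acceptance suite calibrates it at 50 subjects per group).
- The correlation between path length and atrophy score is an observational
  association on edges that share nodes and a common partition; edges are
  not independent, so the Spearman p-value (df = n − 2) is anti-conservative
  in the usual way for network data.
- The literal transform variant is provided for completeness but is
  non-monotone; results under it are not interpretable as "higher = more
  atrophy".
- Consensus Louvain depends on γ; the sensitivity loop reports module counts
  per γ but the downstream analysis uses a single primary partition.
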