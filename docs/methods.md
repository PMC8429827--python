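# Methods

This note records the statistical model behind `scnet`, the conventions
chosen where weighted-graph definitions are not unique, what the
synthetic generator does and does not emulate, and the numerical
choices that affect results.

## Structural covariance networks

A structural covariance network is a *group-level* object: one graph
per (structure, hemisphere, outcome group), with one node per atlas
subregion. Subject-level volumes enter only through the across-subject
correlation of normalized volumes. Concretely, for subjects `s` in one
group, let `x_is` be region i's volume in percent of intracranial
volume (`100·raw/eTIV`, so head size cancels) after relabeling
hemispheres to ipsi/contralateral with respect to each subject's side
of hippocampal sclerosis. Each region is OLS-residualized on an
intercept, age and sex (coded 0 = female, 1 = male), and the edge
weight between i and j is the Pearson correlation of those residuals.
Residualize-then-correlate is algebraically the partial correlation of
the pair given the covariates, and is numerically simpler than the
inverse-correlation route.

Assumptions: volume-covariate relations are linear; subjects within a
group are exchangeable draws; the covariance structure, not the mean,
carries the group signal of interest. Estimating a 25-node covariance
from ~30 subjects is intrinsically noisy — groups below 10 subjects
trigger an explicit wide-variance warning and network construction
needs at least covariates + 2 subjects.

Partial correlations in [−1, 0) have no standard treatment in
path-based weighted analysis. Two policies are implemented: `zero`
(default; negatives clipped to 0, which can disconnect nodes) and `abs`
(absolute value, which treats anti-correlation as coupling). Neither is
asserted to be what any particular toolbox does; the default is the
more conservative one for path measures and is recorded in each
matrix's provenance sidecar.

## The twelve measures

Weights lie in [0, 1]; edge length is `1/w`; distances are weighted
shortest paths (Dijkstra; validated against a Floyd-Warshall oracle in
the tests).

* **average strength** — mean row sum of weights.
* **characteristic path length** — mean over nodes of the mean *finite*
  distance to other nodes. Infinite distances (possible under the
  `zero` policy) are excluded from means rather than propagated, so the
  scalar stays finite; isolated nodes are skipped.
* **eccentricity / radius / diameter** — per-node eccentricity is the
  maximum finite distance; the graph-level eccentricity scalar is the
  *mean* of node eccentricities (its min and max are already reported
  as radius and diameter).
* **global efficiency** — mean of `1/d` over ordered pairs, `1/∞ = 0`.
* **local efficiency** — mean over nodes of the global efficiency of
  the subgraph induced by each node's neighbors (original weights).
* **clustering / transitivity** — Onnela geometric-mean triangle
  intensity with weights rescaled by the global maximum; per-node
  clustering is `Σ(ŵ_ij ŵ_ih ŵ_jh)^(1/3) / k(k−1)`, nodes with binary
  degree < 2 contribute 0 to the mean; transitivity is the matching
  global ratio Σ triangle intensity / Σ k(k−1).
* **modularity** — weighted Newman Q of the best of 10 Louvain restarts
  at resolution 1, each restart seeded deterministically from the stage
  seed; restarts reduce local-optimum noise while keeping runs
  reproducible.
* **assortativity** — Pearson correlation of the *binary* degrees at
  the endpoints of each edge, edge weights acting as frequencies. On
  zero-variance endpoint degrees (regular graphs, < 2 edges) it is
  undefined and reported as NaN — never silently 0; permutation runs
  count such draws as ensemble dropout.
* **small-worldness** — `σ = (C/C_rand)/(L/L_rand)`, where the null
  ensemble (default 100 references) applies Maslov-Sneppen double-edge
  swaps to the binary topology (default 10 accepted swaps per edge,
  with a try cap so saturated topologies terminate; a complete graph is
  returned unchanged since no swap exists) and then randomly reassigns
  the original weight multiset to the rewired edges. σ is scale
  invariant: C uses max-rescaled weights and the L ratio cancels a
  global weight factor.

## Group inference

Network measures exist only at group level, so they are compared by
label permutation: group labels are shuffled preserving group sizes,
*both* networks are rebuilt from scratch (residualization included, to
keep the full statistic exchangeable), the measure is recomputed, and
the two-sided p is `(1 + #{|Δ*| ≥ |Δ_obs|}) / (n_valid + 1)`. The
add-one convention keeps p > 0; at 1,000 permutations the attainable
floor is 1/1001 ≈ 0.001. Permutations where a measure is undefined are
dropped for that measure and the valid count is reported. Calibration
is verified empirically: over 1,500 independent null cohorts the
rejection rate at α = 0.05 was 0.048 with uniform p-values.

Per-region volume comparisons use a per-group Shapiro-Wilk gate at
0.05: both groups normal → pooled-variance t-test; otherwise
Mann-Whitney U — exact when both groups have ≤ 8 untied observations
(where it equals full enumeration over label assignments), asymptotic
with tie correction otherwise. The 2×2 categorical test is Pearson
chi-squared without continuity correction. Bonferroni families follow
the test batteries: 18 amygdala, 42 hippocampal and 50 thalamic volume
tests (regions × 2 hemispheres) and 12 network measures; corrected
thresholds are exact divisions (0.05/50 = 0.001).

## Synthetic cohorts

The generator emulates what the analysis assumes: two outcome groups
(default 29 poor / 40 good), age ~ N(37, 10²) truncated to [18, 70]
years, 38% male, ~46% right-sided sclerosis, eTIV ~ N(1.5×10⁶,
(1.5×10⁵)²) mm³, and per-region percent-ICV volumes drawn multivariate
normal with means log-spaced over 0.0004–0.05 (the realistic subregion
range), SD 20% of the mean, and a block correlation template (default
ρ = 0.5 within one of 3 contiguous modules, 0.2 between; templates are
rejected unless positive definite). Volumes are generated on the
percent-ICV scale and multiplied out through each subject's eTIV, so
downstream normalization recovers the generated values exactly.
Confounding is injected linearly: −0.4% volume per year of age and a
+5% male offset by default, which the pipeline's age/sex adjustment
must remove — template recovery at n = 2000 per group is a test.
Negative draws are truncated at 0 (rate recorded in `cohort.meta`;
< 0.1% under defaults).

Group effects are expressed as a correlation inflation for the poor
group (a pure network effect, mirroring the scenario of interest:
network differences without mean volume differences) and/or a
per-region mean shift in SD units. Defaults are zero, making the
default cohort an exchangeable null — the basis of the calibration
tests.

What the generator does **not** emulate: segmentation error and its
spatial structure, non-Gaussian volume distributions, hemispheric
asymmetry (hemispheres are independent draws of the same template),
age-by-group interactions, and any true patient covariance topology —
the template is a stated assumption, not an estimate. Passing tests
therefore demonstrate internal statistical correctness of the chain,
not clinical reproducibility.

## Numerical choices and scales

* Stage seeds derive from a single master seed via SHA-256 of
  `"{seed}:{label}"`, truncated to 31 bits — deterministic,
  order-independent and collision-checked (10,000 labels in the tests).
  Two runs with the same master seed produce byte-identical report
  bundles (floats are written with `repr` round-trip precision; tables
  are re-read with the round-trip float parser).
* Degenerate inputs fail loudly: zero residual variance names the
  offending region; missing regions are a hard error (no imputation);
  re-normalizing an already normalized matrix, or re-lateralizing, is
  rejected rather than silently applied twice.
* Symmetry tolerance for connectivity input is 1e−10; residual means
  are zero to 1e−10 by construction.
* Test and acceptance problem sizes are chosen to exercise the exact
  code paths at desk scale: calibration uses 500 null cohorts × 200
  permutations on the 9-node amygdala atlas with the average-strength
  measure (the cheapest measure, since calibration is a property of the
  permutation machinery, not of any one measure); template recovery
  uses 2000 subjects per group; pipeline determinism runs use 5
  permutations and 2 null references. Full-scale runs (1,000
  permutations, 100 references, all structures) are the CLI defaults.

## Known limitations

* With ~30 subjects per group the sampling noise of a 25-node partial
  correlation matrix is large; measure differences between groups are
  dominated by estimation variance, which is exactly why inference is
  by whole-pipeline permutation rather than analytic approximations.
* The `zero` policy can disconnect networks; finite-pair averaging
  keeps the path measures defined but makes them non-comparable across
  graphs with very different disconnection patterns.
* Louvain is a heuristic; the reported Q is the best of 10 seeded
  restarts and can sit marginally below the global optimum (bounded at
  0.02 against exhaustive search on 12-node two-block graphs in the
  tests).
* Weighted-measure conventions (Onnela clustering, mean-of-eccentricity
  scalar, 1/w lengths, rewire-and-reassign null) are common choices,
  documented here precisely because other toolboxes make different
  ones; absolute measure values are only comparable within a fixed
  convention set.
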