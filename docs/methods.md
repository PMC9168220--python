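# Methods

`scnet` implements a group-level structural covariance network (SCN)
analysis of regional brain morphometry, together with a synthetic cohort
generator that reproduces the statistical structure such an analysis
assumes, so that every stage can be exercised and validated without
access to patient data.

## The analysis

### Structural covariance graphs

Structural covariance is an across-*subject* statistic: for one group and
one morphometric property (cortical thickness CT, surface area SA, mean
curvature MC — each over the 68 Desikan–Killiany cortical parcels,
complemented by the volumes of 19 non-cortical parcels for a total of
P = 87 regions), the edge weight between regions i and j is the Pearson
correlation of the property's residualized values in the two regions
across the group's subjects. One graph is obtained per group, not per
subject, which is why group contrasts require permutation inference rather
than subject-level statistics.

Before any correlation is computed, each region is residualized by
ordinary least squares on [intercept, age, gender, total gray-matter
volume], separately within each group. Residuals are exactly orthogonal to
the design and zero-mean; residualizing twice is a no-op.

Negative correlations are excluded (set to zero) so that the weighted
graph machinery applies; the diagonal is zero. The *retained fraction*
(share of positive off-diagonal entries) is reported per graph because it
bounds the feasible density range.

Cross-property graphs correlate property m1 in region i with property m2
in region j over the same subjects, giving an asymmetric matrix — a
directed graph over the 68 cortical regions, with self-loops removed
before the negative-edge exclusion. It satisfies
cross(m1, m2) = cross(m2, m1)ᵀ before the zeroing steps.

### Density sweep and metrics

Graphs are analyzed at a sweep of edge densities ρ: the round(ρ·E_max)
strongest positive edges are kept with their weights (E_max = P(P−1)/2
undirected, P(P−1) directed — direction matters for in/out-degree, so the
edge budget counts ordered pairs). Ties at the cut break by descending
weight then ascending (row, column) index, making the sweep deterministic
and its edge sets nested across densities. `round` (half-up) fixes the
edge count; floor/ceil would change counts by at most one edge and is a
flagged sensitivity, not a default.

The default grid is 20% to 60% in 1% steps (41 points). The two bounds are
data-dependent in principle — the lower bound is the smallest density at
which all observed graphs are fully connected, the upper bound the largest
with enough positive edges — so the pipeline *tightens* (never widens) the
configured bounds to what the observed graphs support, logs the
adjustment, and records the effective grid in the run manifest. All groups
and subcases of one run share one grid, keeping AUC values comparable.

Per-region metrics at each density:

- **degree** — sum of incident edge weights (weighted, not binarized:
  thresholding selects edges, weights are preserved);
- **clustering coefficient** — Onnela's weighted form, the geometric mean
  of triangle weights, on weights rescaled by the graph maximum; nodes
  with fewer than two neighbors score 0;
- **eigenvector centrality** — the leading eigenvector of the adjacency,
  nonnegative with unit Euclidean norm (Perron–Frobenius guarantees
  uniqueness on connected graphs);
- **in-degree / out-degree** (directed graphs) — column and row sums; the
  in-degree at region j measures how strongly property m2 there depends on
  property m1 elsewhere, the out-degree the converse.

Each metric-versus-density curve is reduced to its **AUC**, defined as the
plain sum over grid points. The sum (rather than a trapezoid) makes the
reduction linear, so the AUC of a between-group difference curve equals
the difference of the group AUCs identically — the two natural readings of
"difference of AUC over the sweep" coincide.

The full analysis comprises 15 subcases: 3 properties × {degree,
clustering, eigenvector centrality} on the 87-region same-property graphs,
plus 3 ordered property pairs × {in-degree, out-degree} on the 68-region
directed graphs.

### Group inference

Two contrasts are computed: controls minus pre-intervention patients, and
post- minus pre-intervention patients. The observed statistic per region
and subcase is ΔAUC. Its null distribution comes from randomly reassigning
the pooled subjects to two pseudo-groups of the original sizes
(`unrestricted` scheme; 8,000 permutations in the full configuration) and
re-running the whole chain from the covariance computation onward. A
`paired_swap` scheme (flip pre/post labels independently per patient) is
available for the paired contrast.

Permutations shuffle residualized rows by default; the confound regression
is treated as preprocessing and not re-fitted per permutation. Because the
per-group OLS fits give each group's residuals slightly different geometry,
this default is marginally anticonservative on exchangeable data (we
measured a Kolmogorov–Smirnov rejection of p-value uniformity at n = 2,000
pooled p-values). A strict mode (`design_residualizer`) re-fits the
regression inside every pseudo-group, restoring exact exchangeability; the
calibration test runs in strict mode, and the pipeline default mirrors the
analysis-as-preprocessing convention.

p-values are two-sided add-one estimates,
p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1), which avoids exact zeros.
The Benjamini–Hochberg step-up procedure controls FDR, by default pooled
over all regions × subcases of one contrast (9·87 + 6·68 = 1,191 tests);
per-subcase scope is available. Findings are tiered at α₁ = 0.01 and
α₂ = 0.001.

Degenerate permutation draws are handled rather than discarded (discarding
would bias the null): a pseudo-group graph that disconnects at low density
still gets eigenvector centrality per connected component (unit norm per
component, isolated nodes 0, occurrences logged); a draw without enough
positive edges for the top of the grid is redrawn with a fresh assignment,
up to ten attempts, so exactly n_perm null rows are produced.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes: groups of
29 / 34 / 34 subjects (pre and post rows belong to the same patients),
per-property cross-regional correlation, cross-property coupling, linear
confound effects, and plantable group differences in covariance structure.

### Model

Values follow a latent-factor Gaussian model. For subject s, region r,
property m:

    x[s, r] = mean_m + scale_m · ( L_m[r] · z_m[s] + B_m[:, r] · c[s]
                                   + τ · a[s, r] + ε · e_m[s, r] )

- `L_m` is the property's loading matrix over K = 8 factors plus
  *structural* columns: one factor per left/right homologous region pair
  (weight `homotopic_strength` = 1.3) and one per lobe sub-community of 4–6
  regions (weight `cluster_strength` = 0.7). Ordinary loading rows have a
  common positive direction (`loading_disp` = 0.6 dispersion around it) and
  controlled magnitudes (±20% around the nominal norm set by
  `loading_scale` = 0.42): magnitudes bounded away from zero keep every
  region correlated with the rest of the brain, as in real data.
- The factor vector `z_m` is a unit-variance mixture of a global component
  (weight √g, `global_coupling` g = 0.75 — a brain-size/atrophy-like factor
  shared by all properties; the non-cortical volumes ride it harder,
  `vol_global_coupling` = 0.95, which ties the non-cortical block into the
  87-region graphs), one shared component per property pair
  (`cross_property_coupling` γ = 0.1 each) and an own component. The
  population cross-property correlation of a region pair is exactly
  (g + γ) times its same-property correlation, so cross-property graph
  density is controlled independently of within-property topology.
- `c[s]` are standardized confounds: age ~ Normal(70, 8) truncated to
  [45, 90] years, gender ~ Bernoulli(1/2), total gray-matter volume ~
  Normal(600, 50) cm³. Effects default to (−0.3, +0.2, +0.4) residual
  units per SD with a ±30% per-region jitter profile.
- `τ·a` (τ = 0.8) is stable subject anatomy: a subject × region deviation
  from the group factor structure that a patient's pre and post scans
  share verbatim. `ε·e` (ε = 0.3) is scan noise, independent across
  sessions. Together with a factor-level pre/post correlation of 0.9 this
  gives pre/post value reliabilities around 0.95, in line with test-retest
  reliability of surface-based morphometry.

One global seed expands into named substreams (loadings, factors per
group/property, confounds, noise), so enlarging one group or adding
regions never perturbs draws in unrelated streams.

Clinical scores are drawn per patient as bivariate Gaussians with
configurable pre/post moments and within-pair correlation; the default
summaries emulate a drug-resistant essential-tremor cohort before and one
year after thalamotomy (daily-living, head-tremor, quality-of-life, and
treated-hand tremor scores).

### Planted effects

A planted effect multiplies the **common-mode component** of the loadings
of a chosen region set, in one group only: the region's projection on the
direction all regions share is scaled by the multiplier, while its local
structural loadings and noise are untouched. This raises the region's
long-range coupling with the rest of the network — the kind of covariance
reorganization the graph contrasts are designed to detect. A pair target
applies the boost only within that pair's shared component, raising the
regions' out-degree in the directed graph.

A plain row-scale multiplier is deliberately *not* used: Pearson
correlation normalizes per-region scale, so scaling a region's entire
loading row moves its correlations only through the (small) noise share of
variance. We verified empirically that no parameterization of the model
makes a row-scale effect of modest size detectable at these sample sizes,
whereas common-mode boosts are (see limitations below for the implied
detectability floor).

### What the generator does and does not emulate

Emulated: predominantly positive covariance, strong homotopic and lobar
community structure, a dominant global factor coupling all properties
including non-cortical volumes, paired pre/post subjects with realistic
reliability, linear confound contamination, group differences expressed as
coupling changes.

Not emulated: spatial smoothness beyond the community structure,
measurement artifacts of surface reconstruction, non-Gaussian tails,
scanner/site effects, or the real cohort's actual covariance values.
Retained-edge fractions under the defaults (~0.9 same-property, ~0.7–0.9
cross-property) are somewhat higher than is typical of real morphometric
covariance; they were chosen so that the full density sweep is feasible at
the study's sample sizes. Passing tests therefore demonstrate correctness
and calibration of the *machinery*, not effect sizes transferable to real
cohorts.

## Numerical and design choices

- Correlations use the unbiased (n−1) normalization; the choice cancels in
  the correlation.
- Thresholding sorts edges once per graph; each density is a prefix of the
  sorted edge list (this is also what guarantees nestedness).
- Eigenvector centrality uses a dense symmetric eigensolver restricted to
  the top eigenpair; deterministic orientation (nonnegative, unit norm).
- Degenerate inputs raise typed errors naming the offender: zero-variance
  regions, rank-deficient confound designs (e.g. a single-gender group),
  misaligned subject ids, infeasible densities (with the maximum feasible
  density), disconnected graphs where uniqueness is required.
- Full inference is bit-reproducible from the configured seed; the run
  manifest records the configuration, effective grid, library versions and
  SHA-256 of every output table.

## Problem sizes used in the validation suite

The test suite scales the Monte-Carlo studies to single-CPU runtimes while
keeping the study's group sizes: calibration uses 100 exchangeable cohorts
of 20 regions (29/34 subjects) × 200 permutations; recovery uses 20
replicate cohorts of 30 regions (34/34 subjects) × 1,000 permutations with
a multiplier-4 common-mode boost on 4 regions; the determinism check runs
the complete 87-region, 15-subcase, 2-contrast pipeline twice at 500
permutations. The 8,000-permutation configuration of the full analysis is
supported but not exercised in tests.

## Known limitations

- Permutation nulls of density-thresholded degree are wide at n ≈ 34
  (rank competition near the cut amplifies sampling noise), which sets a
  noticeable floor on detectable coupling changes; the recovery study's
  multiplier reflects that floor.
- The default no-refit permutation mode is marginally anticonservative
  (see above); strict mode exists where exact calibration matters.
- The lobe-community and homotopic structure uses the atlas's lobe labels;
  for synthetic atlases without anatomical labels, blocks of eight regions
  stand in.
- FDR pooling is per contrast; pooling across both contrasts jointly is a
  one-line change but not the default.
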