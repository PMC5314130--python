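# Methods

This note documents the models, conventions and numerical choices behind
`covnet`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real morphometry data.

## The structural covariance model

Structural covariance networks treat across-subject correlation of
regional gray-matter volumes as a connectivity measure: regions whose
volumes rise and fall together across a cohort are taken to develop in a
coordinated way.  The unit of analysis is therefore the *group*, not the
subject — each group of `n` subjects yields a single `N × N` association
matrix `R` of Pearson correlations, and all statistics are functionals of
the two groups' matrices.  Inference about group differences has to come
from permutation of subject labels, because no subject-level network
exists.

Input volumes are assumed to be positive, already normalized for total
brain volume, and free of nuisance structure the user wants removed:
`covnet` correlates the columns as given.  Whether to residualize age,
sex or site effects before correlating is a preprocessing decision left
outside the package (the table reader accepts any numeric matrix, so
residualized volumes can be supplied directly).

## Thresholding conventions

Binary graphs are obtained by keeping the `E = round(D · N(N−1)/2)`
largest **signed** off-diagonal correlations at each density `D`.  Three
details are pinned so results are bit-reproducible across platforms:

- `round` is half-away-from-zero, fixed by `E = floor(D·M + 0.5)`; at
  `N = 92` this gives 1507 edges at `D = 0.36` and 2093 at `D = 0.50`.
- Ties in `r` are broken by lexicographic `(i, j)` node order.  Exact-`E`
  selection keeps the two groups' edge counts identical even under ties,
  which is what makes density-matched comparison fair.
- Negative correlations are eligible only if they reach the top `E`; with
  the dense positive covariance typical of volume data they effectively
  never do below `D = 0.50`.  No absolute-value mode is provided.

Edge sets are nested across the density grid by construction (a single
ranking drives all densities), and thresholding is invariant under any
strictly monotone transform of the off-diagonal values — both properties
are asserted in tests.

The analysis grid runs from `D_min`, the smallest grid density at which
*both* groups' graphs are connected, to 0.50 in steps of 0.02 (all three
numbers configurable).  Above 0.50 binary covariance graphs become
increasingly random and the comparison carries little signal.  Inside the
permutation test the grid is **fixed** at the observed-data `D_min` rather
than recomputed per permutation: recomputing would change the statistic's
support from permutation to permutation and make the AUC distributions
incomparable.  Permutation graphs that fragment at low densities fall
back to reachable-pair path length (see below).

## Graph metrics

- **Clustering coefficient.** `C_i = 2 t_i / (k_i (k_i − 1))` with `t_i`
  the triangle count through node `i`; `C_i = 0` where `k_i < 2`, and the
  network value is the unweighted mean over *all* nodes (the binary-network
  toolbox convention).  Implemented as batched matrix products across the
  density stack, because the permutation framework recomputes it millions
  of times.
- **Characteristic path length.** Mean hop count over reachable ordered
  pairs, via breadth-first search (scipy's csgraph).  Unreachable pairs
  are excluded from the mean and surfaced as a count instead of producing
  infinities; on the analysis grid (which starts at full connectivity)
  the count is zero by construction, so this matters only inside
  permutations.
- **Betweenness centrality.** Unnormalized Brandes betweenness
  (`igraph`'s C implementation), i.e. `b_i = Σ_{s<t} σ_st(i)/σ_st`.  It is
  reported raw because the group comparison divides by the network mean,
  which cancels any constant normalization factor.
- **Small-worldness.** `γ = C/C_null`, `λ = L/L_null`, `σ = γ/λ` against
  the HQS null ensemble mean at the same density.

All four metrics are verified against independent brute-force oracles
(triangle enumeration, Floyd–Warshall, exhaustive shortest-path
enumeration) on random graphs, and betweenness additionally against
networkx.

## The HQS null ensemble

Null networks must control for the distributional properties of the
observed correlations, not just for density.  The Hirschberger–Qi–Steuer
construction draws an `N × m` matrix `X` with i.i.d. `N(μ, σ²)` entries
and uses the Gram matrix `C = X Xᵀ`, with

    m  = max(2, round((d̄² − ē²) / v̄)),
    μ  = sqrt(ē / m),
    σ² = −μ² + sqrt(μ⁴ + v̄ / m),

where `ē` and `v̄` are the mean and (population) variance of the observed
off-diagonal entries and `d̄` the mean diagonal (1 for correlation
matrices).  `C` is positive semi-definite by construction and matches the
observed off-diagonal mean and variance in expectation; both properties
are verified empirically (200-draw ensembles land within 5% / 15%
relative error).  Null matrices are thresholded directly, without
rescaling to unit diagonal, since top-`E` selection depends only on the
ordering of off-diagonal entries.

Two calibration facts are worth knowing.  First, normalizing a metric
curve against an ensemble built from the *observed matrix itself* returns
exactly `γ = λ = σ = 1` — an identity the tests assert.  Second, HQS Gram
matrices are *not* order-equivalent to flat "all correlations equal plus
noise" matrices: the row norms of `X` vary, which induces degree
heterogeneity and hence more clustering in thresholded HQS graphs than in
an Erdős–Rényi graph of equal density.  A flat-correlation observed
matrix therefore normalizes to `γ < 1` (measured ≈ 0.67–0.84 across the
grid).  The unbiasedness statement that does hold, and that the tests
check, is self-consistency: an observed matrix that is itself a random
Gram covariance matrix gives `σ` within [0.9, 1.1] against its own HQS
ensemble at densities ≥ 0.2.

Defaults: 20 nulls for observed curves; 5 per permutation (see below).

## Permutation framework

Group labels are shuffled with group sizes preserved; each permutation
rebuilds both association matrices, re-thresholds across the fixed grid,
and recomputes every requested metric, including fresh HQS normalization
when normalized measures are compared.  Differences (group A − group B,
labels in sorted order) are recorded per density and as the trapezoidal
area under the metric-vs-density curve (functional density analysis),
which integrates evidence across thresholds instead of privileging any
single one.  On a single-point grid the AUC statistic degenerates to the
value at that density, so the functional and density-wise comparisons
coincide.

Two-tailed p-values are positional with the add-one convention,
`p = (#{|perm| ≥ |obs|} + 1)/(n_perm + 1)`, which is standard, slightly
conservative, and never returns zero.  FDR correction (Benjamini–
Hochberg) is applied within two families: the global measures compared
together, and all nodes per nodal metric.  Per-density p-values are
computed but treated as diagnostics; nodal inference is based on the AUC
statistic to avoid the densities × nodes multiplicity explosion.

Nodal degree and betweenness are divided by their network-wide mean
within each group before comparison.  For degree this is a formality
(equal `E` forces equal mean degree), for betweenness it removes overall-
scale differences between the groups' networks.  A permutation that
produces a constant region within a group is redrawn and logged; more
than 5% redraws aborts the run, since that signals near-degenerate input
rather than bad luck.

`n_null` inside permutations defaults to 5 rather than 20: the null mean
enters the normalized statistic only through an ensemble average whose
noise is absorbed into the permutation distribution, and the 4× saving is
what makes 1000 normalized-metric permutations tractable.  Setting
`n_null_perm = 20` restores the fully matched scheme.

Default `n_perm` is 1000; with the add-one rule the smallest attainable
p-value is then 1/1001 and the effective test size at α = 0.05 is
50/1001 ≈ 0.04995.

## Hub classification

A node is a hub if its degree is at least one sample standard deviation
(`N−1` denominator) above the mean network degree, evaluated by default at
`D_min` (the density at which the regional analysis is best defined, since
both networks are just fully connected).  A flat degree distribution has
no upper tail, so zero variance yields no hubs (with a warning) rather
than flagging every node.  Hub sets are compared as common /
unique-to-A / unique-to-B partitions in stable region order.

Note a structural property of the 1-s.d. rule: in any group, roughly the
upper ~16–20% of nodes qualify by chance, so even a perfectly planted hub
module in group A appears in the *unique*-to-A list at most ~80% of the
time per node — the other ~20% of the time the same regions are chance
hubs in group B as well.  Recovery of a planted module is therefore
evaluated as a per-dataset event (a majority of the module's regions
classified unique-to-A), not as a per-node frequency.

## Synthetic data generator

`SyntheticConfig` draws two groups of multivariate-normal "volumes" around
a block correlation matrix: regions are split as evenly as possible into
modules (remainder to the first modules); within-module correlation is
`rho_within_a` / `rho_within_b` per group and between-module correlation a
shared `rho_between`.  Defaults emulate the kind of pediatric morphometry
study the pipeline targets: 92 regions, groups of 34 and 28 subjects,
8 modules, `rho_within_a = 0.65`, `rho_within_b = 0.55`,
`rho_between = 0.35`, volumes `5.0 ± 0.5` (arbitrary units).  The strong
background correlation is deliberate: volume data typically shows the
large majority of regional covariances individually significant even at
`n ≈ 30`, which requires typical `r` well above ~0.35.

Optionally one module is planted as a hub set in group A (`hub_module`)
by raising its correlation with all other regions to `hub_rho`
(default 0.55).  Feasibility is constrained: if the background is
`rho_between`, no correlation matrix can give a sub-group cross-correlation
much above `sqrt(rho_between)`, and a single-factor argument requires the
planted module's internal correlation to be at least
`hub_rho²/rho_between`; the generator raises the planted block to that
floor and verifies the smallest eigenvalue (≥ −1e−10) of every implied
matrix, rejecting infeasible configurations with the offending parameters
named.  Sampling uses an eigendecomposition factor with tiny negative
eigenvalues clipped at zero, and each group has an independent RNG
substream spawned from the master seed, so resizing one group never
perturbs the other's draws.

What the generator does **not** emulate: measurement noise with spatial
structure, age/sex covariate effects, site/scanner effects, non-Gaussian
volume distributions, or hemispheric symmetry.  Passing tests on this
substrate establish that the statistics are calibrated and sensitive under
a clean modular covariance model — not that any particular empirical
cohort will show effects.

## Problem sizes used in the checks

The package's own verification runs use deliberately chosen sizes: the
type-I-error calibration uses 200 replicates of a null configuration at
40 regions and `n = 30/30` with 500 permutations (measured rejection rate
at α = 0.05: within [0.02, 0.08]); the power check uses 50 replicates of a
strong planted effect (`rho_within` 0.6 vs 0.3, `n = 40/40`, 92 regions),
where detection is essentially certain; planted-hub recovery uses 20
datasets at the default study shape.  Brute-force oracle comparisons run
on graphs of up to 12 nodes, where exhaustive shortest-path enumeration
is exact and fast.

## Known limitations

- Weighted-network analysis is out of scope; only binary graphs are
  analyzed.
- Partial-correlation or covariate-residualized association matrices are
  not computed internally (supply residualized volumes instead).
- The permutation scheme assumes exchangeability of subjects under the
  null; covariate-stratified permutation (e.g. Freedman–Lane) is not
  implemented.
- Group-level networks mean no subject-level network estimates or
  brain–behavior correlations are available from this design.
- Betweenness inside permutations is the slowest path; nodal betweenness
  comparisons at 1000 permutations on ~100 regions take a few minutes on
  one core.
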