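# Methods

## Scientific problem

Structural covariance networks treat brain regions as nodes and the
across-subject Pearson correlation of a regional morphometric measure
(cortical thickness in mm, or cortical volume in mm³) as edges.  Because the
correlation matrix is estimated from a *group* of subjects, every graph
measure inherits sampling variability from the particular subjects included.
`covstab` quantifies that variability: how graph measures move as the group
grows, how many subjects a group needs before a measure stabilizes (the
minimum number of subjects, MNS), and how often two groups — elderly controls
and Alzheimer's disease (AD) patients — are declared different by a
permutation test under repeated random re-composition of the groups.

## Pipeline

1. **Covariate removal** (`covariates`).  Each region's measure is regressed
   on age and sex (plus intracranial volume for volumetric measures) by
   ordinary least squares fitted **on controls only**, and the fitted model is
   subtracted from every subject.  Fitting on controls detrends healthy
   ageing without absorbing disease effects; the AD group's departure from
   the healthy trend therefore survives into the residuals.  Covariate
   centering is irrelevant to the residuals, so none is imposed.  Residuals
   are computed once, before any subsampling or permutation (the analysis
   permutes groups downstream of residualization, never refitting).

2. **Network construction** (`connectome`).  For a subject subset of one
   group, the connectivity matrix is the region × region Pearson correlation
   of the residuals (diagonal stored as zero; at least 3 subjects required).
   *Binary* graphs keep the m = round(d·n(n−1)/2) strongest edges by signed
   correlation at each target density d (0.05–0.35 in steps of 0.01 by
   default), so groups are compared at matched density.  Rounding is half-up;
   ties in correlation are broken by lexicographic region index, which makes
   binarization deterministic and edge sets nested across densities (ties
   have measure zero on real data).  A warning is raised if a retained edge
   has non-positive correlation — at these densities the retained
   correlations are expected to be positive.  *Weighted* graphs use
   w_ij = |r_ij|, keeping all edges non-negative.  Disconnected binary graphs
   are allowed; no largest-component extraction is performed, because
   comparing subgraphs of different node sets would confound the group
   comparison.

3. **Graph measures** (`metrics`).  With d_ij the shortest-path distance
   (hops for binary graphs; minimal summed 1/w for weighted, with 1/0 = ∞),
   t_i the triangle count (binary) or geometric-mean triangle intensity
   t_i = ½ Σ_{j,h}(w_ij w_ih w_jh)^{1/3} (weighted), and k_i the count of
   non-zero connections (in both modes):

   - characteristic path length  L = (1/n) Σ_i Σ_{j≠i} d_ij /(n−1)
   - global efficiency           E = (1/n) Σ_i Σ_{j≠i} d_ij⁻¹/(n−1), ∞⁻¹ = 0
   - clustering coefficient      C = (1/n) Σ_i 2t_i/(k_i(k_i−1)), 0 when k_i<2
   - transitivity                T = Σ_i 2t_i / Σ_i k_i(k_i−1)
   - average strength            mean off-diagonal w_ij (weighted only)

   L is exposed for both modes but the pipeline only evaluates it on weighted
   graphs, which are fully connected in practice; binary graphs are generally
   disconnected at these densities, where L is undefined and E is the
   appropriate integration measure.  Small-worldness is deliberately not
   implemented (only meaningful on connected graphs).  When every weighted
   edge is non-zero, k_i = n−1 for all i and C ≡ T; this special case is
   asserted in the tests.  The k_i < 2 convention (contribute 0) keeps C
   defined on disconnected graphs and within [0, 1].

   Numerics: binary distances use breadth-first search by repeated matrix
   products (these graphs have small diameter); weighted distances use
   all-pairs Floyd–Warshall on the dense inverse-weight matrix via
   scipy.sparse.csgraph.  Both give distances identical to Dijkstra's
   algorithm on the same costs and are checked against exhaustive simple-path
   enumeration on all graphs with ≤ 6 nodes.

4. **Stability experiment** (`stability`).  For each of R group compositions
   (default 100), a random permutation of each group's subjects is truncated
   at sizes 50, 55, …, 290 (binary; steps of 10 for weighted), so subsets are
   nested within a composition and drawn without replacement.  At every size,
   networks are rebuilt for both groups, all applicable measures computed,
   and a two-tailed subject-level permutation test compares the groups.
   Derived summaries:

   - **MNS**: the smallest schedule size from which the across-composition
     mean of a measure stays within ±5 % of its full-group reference value
     *at that size and all larger sizes* (permanence rule — a later excursion
     disqualifies earlier band entries).  The reference uses all available
     subjects per group (293 in the default design, while the schedule stops
     at 290: drawing 293 from 293 would leave no composition variability).
   - **Significance ratio**: the fraction of compositions whose permutation
     test rejects at p < 0.05, per size, density and measure.
   - **Average adjacency**: the entrywise mean of binary adjacency matrices
     over many independent subsamples at a fixed size and density; entry
     (i, j) estimates the probability that regions i and j are connected.
     Its mean off-diagonal value equals the realized density by construction.

   Randomness: one master seed; composition r draws its subsamples from
   substream (seed, r) and its permutation tests from substream (seed, r, 1),
   so every stage is independently reproducible.

5. **Inference** (`inference`).  The group network is a statistic of the
   subject set, so exchangeability holds at the subject level: each of the
   n_perm permutations (default 1000) re-splits the pooled residual rows into
   two groups of the original (equal) sizes, rebuilds both networks and
   recomputes every metric difference, sharing one set of permutations across
   metrics and densities.  p = (1 + #{|perm| ≥ |observed|})/(n_perm + 1)
   (plus-one estimator; never zero, valid at finite n_perm).  A permuted
   split that leaves a region with zero variance is redrawn (capped).

   One subtlety worth stating: Pearson correlation removes per-region means
   *within each evaluated subset*, so the metric values are invariant to a
   location shift of a whole group — but the permutation *null distribution*
   is not, because a between-group mean offset creates shared variance inside
   mixed permuted splits, inflating their correlations.  The subject-level
   permutation test is therefore a test of full exchangeability, not of
   correlation structure alone.  Calibration checks must use groups that are
   statistically identical, including the mean level.

   **Average-strength correction**: for each group size, every weighted
   metric is regressed (one pooled least-squares line over both groups'
   composition-level values) on average strength; the residuals replace the
   values, and the group difference of residual means is re-assessed by
   permuting group labels over the composition-level points.  Pooling
   preserves a group contrast in the residuals unless strength explains it.
   The regression design (pooled across groups, separate per size) is a
   package decision; the correction has several defensible designs and this
   one is the most conservative about removing group structure.

## Synthetic cohorts

`cohort.generate_cohort` draws two equal groups (293 per group by default,
68 regions) from a single-factor model: for subject i in group g and region r,

    y_ir = μ_r − 1{g=ad}·δ + β_age(age_i − 75) + β_sex·sex_i
           [+ β_icv(icv_i − icv_mean) for volumes] + λ_g f_i + ε_ir,

with f_i ~ N(0,1) shared across regions and ε_ir ~ N(0, σ²) independent.
Within a group, every region pair then has correlation
ρ_g = λ_g²/(λ_g² + σ²) after covariate removal — a closed form used as the
test oracle (`analytic_strength`).  Defaults describe a thickness study:
μ = 2.5 mm, σ = 0.15 mm, δ = 0.15 mm, β_age = −0.008 mm/yr, age ≈ 75 ± 6 yr,
sex balanced, and loadings λ_control = 0.09, λ_AD = 0.12 giving
ρ_control ≈ 0.26 and ρ_AD ≈ 0.39.  The larger AD loading encodes the
empirical phenomenon that inter-regional atrophy correlations are stronger in
AD, which is what drives every weighted group difference in this model.
Unequal cohorts are balanced by `equalize_groups`, which randomly discards
subjects from the larger group.

What the generator does **not** emulate — and hence what passing tests do and
do not show:

- Regions are exchangeable (one factor, homoscedastic noise, uniform
  correlation).  Real cortices have spatially structured, heterogeneous
  covariance.  Consequently the *binary* edge ranking is driven by estimation
  noise at small-to-moderate sizes: binary topology, and especially the
  clustering coefficient, stabilizes only when subsample overlap with the
  finite pool forces it to, and the across-composition SD of binary measures
  is flat below ~150 subjects per group (it shrinks on average, dominated by
  efficiency and transitivity).  On real data, where true edge strengths are
  well separated, binary topology stabilizes faster.  Weighted measures are
  smooth functions of the correlations and show the clean finite-pool SD
  decrease cell by cell.
- All weighted group differences are mediated by average strength, by
  construction.  This makes the cohort ideal for demonstrating the
  average-strength correction (adjusted differences vanish) but silent on
  metrics that could carry strength-independent signal in real data.
- No site effects, no longitudinal structure, no missing data.

## Scaled problem sizes

The full design (100 compositions × 49 sizes × 31 densities × 1000
permutations) is the library default.  The test suite and the acceptance
script run the same code at reduced sizes chosen as the smallest designs that
still exhibit each phenomenon: 20 (tests) or 10 (script) compositions, sizes
50–150, densities {0.15, 0.25} (the two headline densities), and 200
permutations per test (p-resolution ~0.005 at the 0.05 threshold).  Type-I
calibration uses 200 replicate null cohorts at 60 subjects per group and a
±3 binomial-SE acceptance band around 0.05.

## Known limitations

- MNS is reported per schedule; a trajectory that never re-enters the ±5 %
  band within the schedule yields NA rather than an extrapolated value.
- The permutation test assumes equal group sizes (the design guarantees this
  after `equalize_groups`); unequal sizes are rejected rather than handled.
- The average-strength correction returns one adjusted p-value per
  (size, metric); it does not produce per-composition adjusted significance.
- Volumetric defaults reuse the thickness-scale parameters; volume studies
  should set region_mean, noise_sd, loadings and β_icv to volume-scale
  values.
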