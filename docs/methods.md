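# Methods

## Model

A gene expression matrix (GEM) holds *m* genes by *n* cells of
non-negative values (counts, FPKM or TPM — every downstream quantity is
rank/count-based, so units do not matter).  For each unordered gene pair
(x, y) and each focal cell *k* we test

* H0: x and y are independent in cell k,
* H1: x and y are associated in cell k,

by comparing the local joint density of (x_k, y_k) with the product of
the local marginal densities, all estimated by box-counting frequencies:
f_X(x_k) ≈ n_x/n, f_Y(y_k) ≈ n_y/n, f(x_k, y_k) ≈ n_xy/n, giving

    rho = n_xy/n − (n_x/n)(n_y/n) ∈ [−1, 1].

Rejection is one-sided at level alpha (default 0.01): an edge is drawn
only for local *over*-representation (positive dependence around the
focal cell).  Cells lying off the joint support of a dependent pair
(outliers) get small n_xy and therefore no edge.

## Neighborhood boxes

The box of gene x around cell k is defined in rank space: sort the
gene's values (stable sort), take the contiguous window of target size
h = round(box_size · n) positioned with ceil((h−1)/2) ranks below the
focal cell's rank and the rest above, shifted inward at the
distribution's extremes so the size is preserved, then expand the window
to include every cell tied with either boundary value.  Tie expansion
makes the box well-defined and permutation-invariant in the presence of
the heavy ties (especially zeros) typical of scRNA-seq.  The occupancy
that enters the statistic is the actual post-expansion count, not the
target.  The intersection box is the intersection of the two expanded
marginal boxes.  Box construction is deterministic; nothing in network
construction consumes randomness.

## Exact null via focal-cell exclusion

The focal cell lies in all three of its own boxes by construction.
Conditional on that, the expected overlap under independence is
1 + (n_x−1)(n_y−1)/(n−1), not n_x n_y/n: counting the focal cell biases
the normalized statistic upward by roughly 9/sqrt(n) at box size 0.1
(≈ +0.41 at n = 500, with a type-I rate near 0.04 at nominal 0.01 —
measured by simulation).  The statistic is therefore computed on the
n − 1 *non-focal* cells: with N = n−1 and the focal cell removed from
all three counts, the marginal boxes of two independent genes are
uniform random N_x- and N_y-subsets of the non-focal cells, so the null
law of the overlap is exactly Hypergeometric(N, N_x, N_y), whose mean
and variance are exactly the stated mu = 0 and sigma.  The normalized
statistic

    rho_hat = sqrt(N−1) · (N·n_xy − N_x N_y) / sqrt(N_x N_y (N−N_x)(N−N_y))

is then exactly centered and scaled, and approximately standard normal.
`NeighborhoodSpec(include_focal=True)` restores the literal
count-everything convention for comparison.

## Edge rule, zeros, degeneracy

* Edge iff rho_hat > z*(alpha), the upper-alpha standard-normal
  quantile.  Because n_xy is an integer, the achievable levels are
  discrete: at n = 500 and box 0.1 the rule fires iff n_xy ≥ 10, whose
  exact null probability is P(Hyp(499,49,49) ≥ 10) = 0.0140.  The
  empirical type-I rate converges to this exact level, slightly above
  the nominal 0.01; the adjacent achievable level (n_xy ≥ 11) would be
  0.0046.  No count-based rule attains 0.01 exactly.
* Zeros: default `drop_zero_edges` forces edge = 0 whenever either gene
  reads zero in the focal cell, regardless of the statistic (scRNA-seq
  zeros are mostly technical dropouts).  `trust_zeros` lets the
  statistic decide, for data whose zeros are believed biological.
* Degenerate boxes (a constant or near-constant gene whose expanded box
  spans no or all non-focal cells) have sigma = 0; such pairs get
  rho_hat = 0 and no edge, with one warning per gene.  A constant gene
  carries no association evidence.
* Multiple testing across the m(m−1)/2 pairs is deliberately *not*
  corrected: the per-edge level is a fixed local significance, matching
  the method's design.  Group-level analyses (below) do correct.

## Network degree matrix

NDM_xk = sum over y ≠ x of edge_xy^(k); same shape and orderings as the
GEM.  Normalization rescales each column so its total degree equals the
mean raw column total — scale-preserving, parameter-free, and it leaves
within-cell degree ratios unchanged.  Cells with empty networks stay
zero (warned).  The target of the common total was an open choice (a
fixed constant, the mean, or the median would all equalize columns); the
mean keeps the matrix on the scale of the raw degrees.

## Group analyses

All contrasts are one-vs-rest per group.  The test is the two-sided
Wilcoxon rank-sum (distribution-free; degrees and per-cell statistics
are heavy-tailed and zero-inflated), with Benjamini–Hochberg adjustment
across the family of tests actually performed.  An all-constant input
yields p = 1.  Dark genes for a contrast: q_degree < 0.05 and
q_expression ≥ 0.05 (both families tested on the same cells; both
results returned for audit).  Hub genes: ranked by mean normalized
degree within the group, ties broken by gene id.  Rewiring summaries
aggregate per-stage mean statistics per pair and per-stage mean
within-panel degree per gene, reporting each gene's peak stage.

## Evaluation metrics

ARI (scikit-learn), pairwise F1 (precision/recall over co-clustered cell
pairs — the multi-class F1 variant is not standardized, so the pairwise
form is fixed here), purity (weighted majority fraction), and
conditional entropy H(truth | predicted) in bits (0 for pure clusters).
Trajectory accuracy T/(T+F): over every ordered cell pair whose known
stages differ, T counts pairs where the later-stage cell received the
strictly larger ordering score.  Ties count as F (the literal "not
larger" rule), so the measure penalizes tied scores; it is invariant
under strictly monotone transforms of the scores.  Clustering algorithms
are pluggable seeded scikit-learn methods (k-means, agglomerative,
spectral); the comparison harness applies identical method and
parameters to GEM and NDM so that representation, not tuning, drives
score differences.

## Synthetic generators

`generate_pair` emulates the five reference dependence archetypes
(independent; half-dependent linear/nonlinear; fully dependent
linear/nonlinear) at n = 500 with continuous right-skewed (log-normal)
or uniform marginals; dependent cells follow y = g(x) + noise with g
linear, quadratic, or a circular arc, with noise at 0.1 of the x spread.

`generate_population` plants association structure without expression
structure: within a type, module genes share a latent N(0,1) factor with
per-gene noise (default noise_sd = 0.1, within-module rank correlation
≈ 0.99).  The effect size is deliberately strong: the box test is local,
so power requires the conditional rank spread of a dependent pair,
sqrt(1−r²) of the rank range, to be comparable to the box width (0.1);
at r ≈ 0.92 the test has little power and at r ≈ 0.99 dependent cells
are detected at high rate.  With `marginal_matched=True` every gene is
rank-remapped onto a common zero-inflated log-normal reference through a
jittered probability-integral transform q = (rank + U)/n_t, which
preserves within-type rank structure exactly while making the remapped
values exactly reference-distributed — so per-gene marginals are
identically distributed across types and expression-level tests are
null by construction.  (A deterministic quantile grid would duplicate
every value across equally sized types; the resulting systematic
cross-type ties expand the rank windows asymmetrically and fabricate
degree differences — measured as a ~3x false-edge imbalance — hence the
jitter.)  `dropout_rate` adds independent zero-masking on top of the
reference's zero spike (default spike 0.1, extra masking 0).

What the generators do not emulate: library-size variation, gene-length
or capture biases, count discreteness, doublets, batch effects, and
realistic module topology (overlapping, hierarchical, signed).  Passing
tests therefore demonstrate the statistic's calibration and the
degree-vs-expression separation mechanism, not performance on real
tissue atlases.

## Problem sizes and tolerances

Simulation studies use 120–200 replicate pairs at n = 500 for null
calibration (clustered standard errors: cells within a pair share boxes,
so the pair is the unit of replication), populations of 2–3 types with
60–100 cells per type and 16–30 genes for the dark-gene and separability
studies, and 1,000 random instances at n ≤ 50 for the box-counting
oracle check.  Exhaustive enumerations (|rho| ≤ 1, ARI pair-counting)
run at n ≤ 30 and n ≤ 12 respectively.

## Known limitations

* The per-edge test's achievable levels are discrete (see above); the
  realized type-I rate at default settings is 0.0140, not 0.0100.
* Under partial dependence, cells in the *independent* subpopulation
  show edge rates somewhat above alpha (~0.15 at 50% dependence) because
  the dependent mass distorts the pooled marginal windows; the contrast
  with dependent cells (rate > 0.5) remains large.
* With `drop_zero_edges`, dropout erases degree signal for the affected
  cells: at a 10% zero spike the NDM clustering ARI on the synthetic
  separability scenario drops from ~0.92 to ~0.72.  Imputation is *not*
  recommended inside CSN construction; the zero rule is the supported
  mitigation.
* Networks capture association, not causation or sign: the one-sided
  rule detects local over-representation only.
* The all-pairs construction is O(m² n) per cell in the worst case;
  the `stat_tensor` sink refuses materializations above a configurable
  cap and the `degree_only` sink never stores per-pair statistics.
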