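# Methods

This note documents the model behind each pipeline stage, the defaults and
why they were chosen, what the synthetic benchmark does and does not emulate,
and the numerical conventions that make runs reproducible.

## The differential-network model

The analysis treats a perturbation experiment as a pair of gene × timepoint
matrices from the same system, one treated and one untreated. Co-expression
in either condition is summarized by the Pearson correlation of gene pairs'
time series. The object of interest is the set of gene pairs strongly
co-expressed **only under treatment**: the differential network (DN). The
implicit assumptions are

- expression is on a common non-negative scale across the two series (the
  pipeline does no between-sample normalization; inputs should already be
  TPM-like),
- the perturbation adds coordinated temporal structure rather than merely
  shifting means — which is why the edge statistic is correlation over time,
  not differential expression per timepoint, and
- co-expression shared by both conditions (housekeeping co-regulation,
  circadian structure) is uninformative about the perturbation and should be
  subtracted away.

Subtraction is by edge identity, not weight: an edge present in both
networks is removed however different its two weights are. This makes the DN
a set-difference object, robust to the exact weight values but sensitive to
the thresholding that defines "present".

## Stage-by-stage choices

**QC.** Rules run in a fixed order: duplicate-row removal, the sparsity rule
(drop genes missing at strictly more than 1/8 of timepoints, judged on the
original blanks — judging after imputation would make the rule vacuous),
zero-imputation, floor-at-1, zero-variance removal. The floor bounds the
denominator of the selection statistic away from zero; flooring before the
variance check means constant-after-flooring genes are also dropped. The
filter is idempotent.

**Gene selection.** The per-gene score
Δ_TU = (1/N) Σ_i (T_i − U_i)/(T_i + U_i) is a bounded, symmetric measure of
sustained relative difference; each summand lies in [−1, 1] because both
series are positive after QC. Genes at or beyond the empirical 25th/75th
percentiles are kept. Quantiles use linear interpolation between order
statistics (the numpy default); the cutoffs are applied inclusively, so a
degenerate all-tied distribution selects every gene rather than none. With
duplicated experiments the score is computed per replicate pair and averaged
before taking quartiles, keeping the statistic's definition exact within
each replicate. No expression-abundance cutoff is applied beyond the
floor-at-1; the log notes this.

**Network threshold.** The edge cutoff is the 99.5% empirical quantile of
the off-diagonal upper-triangle correlation values — each gene pair counted
once — applied inclusively (r ≥ q), so exact ties at the threshold are
retained and the retained fraction is at most 0.5% plus ties. The one-sided
rule selects strong positive co-expression, which is also what keeps the
weighted modularity objective well-behaved downstream. A matrix whose pair
correlations are all identical has no usable quantile and is rejected as
degenerate. Replicate networks are intersected by edge identity with the
arithmetic mean of the two weights (symmetric, stays in [−1, 1]).

**Communities.** Louvain modularity maximization at resolution 1 runs by
default on the weighted DN (edges carry treated correlations; an unweighted
flag exists because weighting is a genuine open choice). Louvain is
order-dependent, so the node-visit order is fixed by an explicit seed;
identical seed and input give identical partitions. Communities below five
genes are pruned — tiny fragments are uninformative for enrichment — and
survivors are labeled C0, C1, … by descending size, ties broken by the
lexicographically smallest member gene so labels are deterministic.

**Temporal signatures.** Each gene's series is made relative to the start of
the experiment: d_i = x_i − x_0 (up-regulation positive), scaled to unit
Euclidean norm; the community heatmap rows are the treated-minus-untreated
difference of these unit profiles, renormalized to unit norm so entries lie
in [−1, 1] with column t0 identically zero. Rows are displayed in the leaf
order of complete-linkage (farthest-point) hierarchical clustering with
Euclidean distance — the linkage is part of the method, the metric is the
expression-heatmap convention. A community's peak is the argmax over t > 0
of the absolute column mean (median available as an option); the mean is the
simplest aggregate that matches the "one prominent column" signature the
heatmaps show, and argmax ties resolve to the earliest timepoint. A heatmap
whose aggregate signal is identically zero (e.g. balanced up- and
down-regulated halves) is flagged "no response" and excluded from the
ordering. All timepoint indices are 0-based: t0 is the first sample.

**Hubs.** Degree centrality deg(v)/(n_c − 1) is computed on each community's
induced subgraph in isolation — a gene's connections to other communities do
not count. The top five values are reported with competition ranking; equal
centralities are tied and all reported, so a near-clique community can
legitimately list more than five hubs.

**Enrichment.** One-sided hypergeometric (Fisher's exact enrichment) per
(community, pathway): universe M = genes annotated in the GMT collection
(an experiment-wide universe can be passed instead), K pathway members,
n community genes in the universe, overlap k, p = P(X ≥ k). Communities
under eight genes are skipped — small sets essentially never reach
significance and inflate the correction burden. Benjamini–Hochberg FDR is
applied across the pathways of each community independently, matching the
per-community reporting convention of enrichment services.

## The synthetic benchmark

`generate_dataset` emulates the paired single-subject regime: thousands of
genes, 24 (or 6) timepoints, treated and untreated series, optionally
duplicated. Planted modules share a latent pulse — baseline plus an
activation amplitude at the module's activation time with half-height
shoulders one timepoint either side — **in the treated condition only**,
with per-gene amplitude jitter (uniform 0.8–1.2) and independent additive
Gaussian noise truncated at zero. Untreated module genes are pure
baseline-plus-noise. A configurable fraction of background genes shares one
smooth latent profile (a standardized random walk) in **both** conditions;
these genes are co-expressed everywhere and must cancel in the DN. Missing
entries are blanked uniformly at random; a fraction of background genes is
made constant to exercise the variance filter.

Default study conditions: 2,000 genes, 24 timepoints, five modules of 30
genes at activation times 2, 7, 12, 17, 22, baseline 10, amplitude 10, noise
s.d. 0.5, 5% shared background, 0.2% missingness, 1% constant genes. The
defaults are calibration choices, set once: noise well below the pulse
(within-module r ≈ 0.95), missingness sparse — each missing entry becomes a
baseline-sized spike after zero-imputation and flooring, so even sub-percent
rates measurably degrade a gene's correlations — and the shared-background
latent at 0.15× the activation amplitude (pairwise r ≈ 0.9), strong but
subordinate to the treatment response so background co-regulation does not
dominate the fixed 0.5% edge budget. Default activation times start at t2
because a pulse shoulder touching t0 contaminates the time-0 reference every
relative series is measured against, leaving that module's peak ill-defined.

What the generator does **not** emulate: count noise (no negative-binomial
machinery, no library-size effects), gene-specific baselines and variances,
autocorrelated or heavy-tailed noise, partially-overlapping or nested
modules, and activation shapes other than a single short pulse. Passing the
recovery benchmarks therefore demonstrates that the pipeline's stages
compose correctly and recover punctuated treated-only structure under
realistic sparsity/missingness — not that real perturbation data, with its
messier noise and weaker modules, will be recovered at the same rates.

**Recovery scoring.** `score_recovery` computes the adjusted Rand index
between recovered communities and planted modules over the genes that carry
a true module label. Background genes are excluded by default for a
structural reason: the quantile rule always admits ≈0.5% of all pairs, so a
few hundred spurious background edges always enter the treated network and
survive subtraction; Louvain then attaches dangling background genes to
module communities and keeps some background-only communities above the
pruning size. Those contaminants say nothing about whether the planted
modules were found — module-restricted ARI is ≈1.0 in runs where
background-inclusive ARI is 0.1–0.4. `include_background=True` exposes the
stricter score. Temporal recovery maps each module to the community holding
the majority of its genes and asks whether those communities' peaks
reproduce the planted times and order.

## Numerical conventions and degenerate inputs

- Fixed seed ⇒ bit-identical outputs everywhere: the generator uses one
  `numpy` Generator, Louvain's visit order is seeded, and every writer sorts
  its rows, so rerunning a pipeline config is byte-identical.
- Constant series: relative_series returns the zero vector rather than
  dividing by a zero norm; zero heatmap rows stay zero.
- Peak ties: earliest timepoint wins (`argmax` convention); community-size
  ties: smallest member gene id; ordering ties on peak time: label order.
- Correlation needs ≥ 3 timepoints; zero-variance rows are an error at the
  network stage because QC should have removed them.
- Hypergeometric p-values are clipped into (0, 1]; k = 0 overlaps report
  p = 1 rather than being dropped, so the BH family is the full pathway set.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default 2,000-gene scale (ten seeds, a few seconds per run); oracle checks
(exhaustive modularity maximization, brute-force hypergeometric tails,
naive complete-linkage) run at the small sizes where exhaustive computation
is exact — 8-node graphs, universes up to 60, ≤ 10 heatmap rows.

## Known limitations

- Negative correlations are invisible by construction (one-sided threshold);
  anti-correlated regulation never forms edges.
- The DN is unsigned about direction of rewiring: edges *lost* under
  treatment are discarded, matching the method's definition, so the analysis
  only sees gained co-expression.
- Edge presence is a hard threshold; pairs just below the quantile in the
  untreated network but just above it in the treated one count as rewired,
  with no significance test on the correlation difference.
- Louvain maximizes modularity greedily; the seed makes it reproducible, not
  optimal. The resolution is fixed at 1.
- Per-community BH correction does not control FDR across communities.
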