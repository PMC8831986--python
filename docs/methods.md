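# Methods

`cofitnet` infers a co-functional gene network from CRISPR gene-fitness
profiles. Two genes are called co-functional when their fitness profiles
across a panel of cell lines co-vary — linearly or not — suggesting shared
membership in a pathway or complex. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Pipeline model

The unit of analysis is the unordered gene pair. The pipeline proceeds:

1. **Candidate-gene filters.** Genes must be (a) expressed — TPM > 0 in at
   least one cell line; (b) depended upon — minimum fitness score strictly
   below −0.5 in at least one line; (c) variable — per-gene MAD strictly
   above `median(MADs) + 1·MAD(MADs)` over the surviving population. All
   cutoffs are strict and configurable. The MAD rule is population-relative:
   re-running it on its own survivors raises the threshold and drops more
   genes, so the chain is deliberately not re-entrant (the expression and
   dependency filters are per-gene predicates and are idempotent).
2. **Featurization.** Ten similarity/distance features per pair: Pearson,
   Spearman, Euclidean, Manhattan, Chebyshev, Minkowski (order 3 by default,
   chosen to differ from the p = 1, 2, ∞ distances already present), Dice and
   Jaccard on binarized profiles (depleted = score < −0.5), a harmonic-mean
   similarity on min-max-shifted, sum-normalized profiles (0/0 terms
   contribute 0), and plug-in mutual information in bits over a 5×5
   equal-frequency contingency table (ties broken by value order). Distances
   stay raw; per-feature z-scoring happens at training time with statistics
   stored for reuse at scoring time. Constant profiles get correlation 0 by
   imputation policy; both-empty binary profiles get Dice/Jaccard 0.
3. **Reference labels.** Positives: pairs supported by ≥ 2 curated studies.
   Negatives: non-positive pairs whose annotation term sets are disjoint
   (the ontology root never counts — it would annotate everything).
   Everything else is unlabeled and excluded. Negatives are down-sampled to
   5× the positives (seeded, configurable up to "all") for desk-scale
   training stability.
4. **Edge scoring.** Four scorer backends — an additive MARS model (authored
   here, see below), random forest, RBF-SVM and distance-weighted kNN — are
   benchmarked by stratified 5-fold cross-validation repeated 10 times; the
   winner by mean out-of-fold AUROC is refit on all labelled rows and scores
   every pair. The edge threshold maximizes Youden's J on the pooled
   out-of-fold ROC curve (ties to the larger threshold, i.e. the sparser
   network); a fixed threshold (e.g. 0.02) is available as a config policy.
   AUROC is computed by the trapezoid rule and cross-checked against the
   concordance (Mann-Whitney) form internally.
5. **Network analysis.** Edges are pairs scoring strictly above the
   threshold, weighted by score. Hubs are ranked by Kleinberg's HITS
   centrality; on an undirected graph hub = authority = the dominant
   adjacency eigenvector, computed by power iteration from a uniform start
   with a +1 diagonal shift (same eigenvectors; prevents the ±λ sign
   oscillation on bipartite graphs). Edge weights are used by default; on
   disconnected graphs the dominant component absorbs the score mass, which
   is documented behavior (run per component if per-component scores are
   needed). Module-restricted partners of a query gene are its direct
   network neighbors inside any module containing it.
6. **Module detection.** Greedy cohesiveness clustering: a cluster V is
   scored f(V) = w_in / (w_in + w_bound + p·|V|) with p = 2; clusters grow
   from seed vertices by best-improvement single moves (add an adjacent
   external vertex or remove an internal one, never the seed), ties
   preferring additions and then the lexicographically smallest gene. Seeds
   are visited in descending weighted-degree order — a deterministic stand-in
   for the original randomized seeding (a seeded random order is available).
   Cluster pairs with overlap ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8 are merged to a
   fixpoint; clusters smaller than 3 or with internal edge density < 0.5 are
   dropped; survivors are numbered CID-01… by descending size.
7. **Validation.** Hypergeometric upper-tail enrichment of modules against
   gene-set collections, BH-adjusted within each collection (raw p also
   reported); Lin semantic similarity over an annotation DAG with
   information content IC(t) = −ln(n_t/n_root) after ancestor propagation,
   aggregated gene-to-gene by best-match average (unannotated genes and
   root-only common ancestors score 0); edge-set comparison by two-sided
   Wilcoxon rank-sum (normal approximation, tie-corrected, no continuity
   correction so identical sets give p = 1); and edge-overlap counts against
   reference networks. Lin/BMA is the single implemented similarity; the
   universe for enrichment defaults to the network's genes.

## MARS

The additive (degree-1) MARS model is a sum of mirrored hinges
max(0, x−t) / max(0, t−x) at knots on observed feature values. The forward
pass greedily adds the mirrored pair with the largest RSS reduction,
evaluated exhaustively over up to `max_knots = 128` observed values per
feature (beyond that, evenly spaced order statistics) and vectorized against
a QR-orthonormalized current design. Growth stops at `max_terms = 21` basis
functions or when the best pair improves training R² by less than
`thresh = 1e-3` — the customary forward stopping rule for this model family;
without it the GCV backward pass can legitimately retain several
near-duplicate hinges around a single true knot. The backward pass prunes
one term at a time (never the intercept) by

    GCV(M) = (RSS/N) / (1 − eff(M)/N)²,  eff(M) = M + penalty·(M−1)/2,

with penalty 3, returning the GCV minimum over the pruning sequence. For
edge classification the model is least-squares fit to 0/1 labels and its
output clipped to [0, 1] — the standard regression-as-classification
shortcut, chosen for simplicity and testability; the raw prediction remains
available for regression use. Degenerate constant responses yield an
intercept-only model with a warning.

## Synthetic benchmark

The generator plants ground truth so recovery is measurable. Genes are
grouped into `n_modules = 10` modules of 8–12 genes; module m has a latent
profile z_m i.i.d. standard normal over `n_cell_lines = 40` lines, and a
member's fitness row is `essential_depth_mean + g(z_m) + ε` with
`essential_depth_mean = −1`, ε ~ N(0, 0.3). For a `nonlinear_fraction = 0.2`
of members g is `|z| − E|z|`, which has exactly zero linear correlation with
z under symmetry while remaining strongly dependent — the kind of
association Pearson ranking misses but mutual information carries. A pair is
recorded as *nonlinear* when exactly one member uses the transform (two
transformed members correlate linearly with each other). Background genes
are N(0, 0.5) i.i.d.; the smaller background spread is what makes the MAD
variability filter informative. Expression is log-normal TPM, independent of
fitness, except that an `unexpressed_fraction = 0.1` of genes is all-zero;
unexpressed genes are chosen before module assignment so module members are
always expressed and unexpressed rows carry background fitness only.
Curated studies report each planted edge with coverage 0.8 plus false pairs
at rate 0.001 (three studies; ≥ 2-of-3 support then recovers ≈ 0.896 of
planted edges in expectation); annotations give one leaf term per module
plus 20 random noise terms under a single root. A single global seed drives
per-stage substreams at fixed offsets, so every artifact is a deterministic
function of the seed.

What this emulates: modular co-essentiality structure, essential-gene
depletion, non-expressed genes, noisy multi-study curation, module-aligned
annotations, and PCC-blind nonlinear dependence. What it does not: guide-
level count noise, copy-number artifacts, lineage-specific dependency
structure, correlated measurement error across cell lines, or realistic GO
DAG depth. The Gaussian latent-profile noise model is an assumption — the
real noise process of fitness screens is not specified by any of our
sources of truth about the data regime. Passing recovery tests therefore
demonstrates internal correctness of the pipeline, not performance on real
screens.

Problem sizes used by the test suite and the acceptance script — 300 genes ×
40 lines end-to-end, 120 genes for the repeated-run determinism check,
100k-draw Monte-Carlo for the hypergeometric tail, 20 random graphs ≤ 50
nodes for the HITS oracle — were chosen to exercise every stage at
desk scale; all thresholds asserted by tests (AUROC ≥ 0.85, ≥ 80% module
recovery at Jaccard ≥ 0.5, ≥ 50% nonlinear-pair detection) are met with wide
margins under these conditions.

## Numerical choices and edge cases

- Strict inequalities at every cutoff (filters, binarization, edge
  threshold), applied uniformly.
- Correlations of constant vectors are imputed (default 0); features are
  finite by construction and the table builder asserts it.
- Equal-frequency MI binning breaks ties by value order, making the
  estimator deterministic; the plug-in estimate is biased upward at small
  samples, which is harmless here because MI enters as a relative feature.
- ROC thresholds are the unique scores plus ±∞ sentinels under the rule
  "positive iff score > t"; the +∞ sentinel is excluded from operating-point
  selection.
- Cross-validation folds come from scikit-learn's stratified splitter with
  per-repeat seeds; every row is scored exactly once out-of-fold per repeat
  and the code asserts it.
- Cluster growth uses best-improvement (not first-improvement) search with
  total tie-ordering, so results are independent of adjacency iteration
  order; grown clusters are 1-move-optimal and the tests re-verify this
  post hoc.
- Matrices are written at 17 significant digits so a stage reading its
  predecessor's TSV reproduces in-memory results bit-for-bit.

## Known limitations

- The paper-scale regime (tens of thousands of genes, ~460k pairs,
  3M negatives) is supported by the algorithms but not exercised by the
  default tests; the MI featurization chunks pairs to bound memory.
- Semantic similarity implements Lin/BMA only; Resnik/Wang/Jiang variants
  and OBO parsing are out of scope (annotation inputs are GMT + child-parent
  TSV).
- The cohesiveness clustering is a faithful reimplementation of the
  published greedy scheme with deterministic seeding, not a clone of any
  particular tool's output; boundary p-values for individual clusters are
  not computed.
- MARS is additive (degree 1); no interaction terms.
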