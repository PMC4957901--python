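# Methods

## Overview of the inference chain

The pipeline turns tumor/control count matrices into regulatory
programs in five stages:

1. **Quantification.** Raw counts (or read alignments, via the
   more-than-50%-overlap counting rule) are quantile-normalized so every
   sample shares one empirical distribution. Per time point, tumor vs.
   control differential expression is summarized as
   logFC = log2((mean tumor + c) / (mean control + c)) with pseudocount
   c = 1, a p-value from a two-sample test on log2(normalized + 1), and
   BH-FDR across features; a feature is called "up"/"down" at FDR < 0.05
   (configurable), otherwise "ns".
2. **Dynamics.** φFC = 2^logFC for logFC ≥ 0, −2^(−logFC) otherwise.
   The transform is symmetric around ±1 (a 2-fold induction is +2, a
   2-fold repression −2) and jumps from −1 to +1 at logFC = 0; values in
   (−1, 1) never occur. Transitions T = φFC(t+1) − φFC(t) are
   discretized against a band μ ± kσ with k = 0.4: '+' strictly above,
   '−' strictly below, '0' otherwise — boundary values and a degenerate
   σ = 0 give '0'. Four time points give 3³ = 27 patterns; patterns
   using only {0,+} are the non-decrease trend, only {0,−} non-increase,
   "000" is flat (excluded from both trends — a flat profile would
   otherwise match everything), the rest mixed.
3. **Networks.** Candidate pairs keep a strictly negative Spearman ρ
   computed once across all samples (non-negative or non-computable
   correlations are dropped). Stage networks additionally require both
   ends significant with opposite directions at that time point; trend
   networks require the gene's pattern to equal the character-wise
   mirror of a trending miRNA's pattern, exactly (a Hamming-tolerance
   relaxation exists but is off by default). Edges carry an
   `admitted_by` tag so the two admission modes never mix.
4. **Enrichment.** Per-term upper-tail hypergeometric test of a query
   gene set against a caller-supplied background universe (never
   defaulted to the annotated query), all counts taken after
   intersecting with the background; BH-FDR across tested terms.
   Hallmark roll-ups count unions (not sums) of network genes over the
   enriched terms mapped to each hallmark.
5. **FRPs.** The network's annotated genes form a boolean gene × term
   incidence. All closed term itemsets with support ≥ the per-network
   minimum (defaults 8, 7, 7, 6 for the four stages and 4 for trend
   networks) are mined by depth-first prefix-preserving closure
   extension (LCM-style, searching term space since terms are far fewer
   than genes). Each biclique is tested with k = support, n = network
   genes in the background, K = background genes co-annotated with all
   its terms, N = background size; BH-FDR < 0.05 keeps it. Silhouettes
   use the distance d(x, y) = 1 − Jaccard(term profile x, term profile
   y) over the incidence rows, each biclique acting as a cluster; a
   member's own-cluster distance is its mean distance to the other
   members (0 for singletons), its neighbor distance the smallest mean
   distance to another biclique (the gene itself excluded when shared);
   the biclique score is the member mean. Only positive silhouettes
   survive; a single biclique has an undefined score and is retained.
   FRPs attach every miRNA with at least one network edge into the
   biclique's genes; programs without regulators are kept but flagged.

## The differential-expression test

The pipeline deliberately does not re-implement a full count-model DE
framework: downstream stages consume only (logFC, direction,
significance), and externally computed DE tables in the same schema can
be substituted at any point. The built-in test is a **moderated t-test**
on log2(normalized + 1): per-feature pooled two-group variances are
shrunk toward a scaled-F prior fitted across all features by the
digamma/trigamma moment equations, and the t statistic gains the prior
degrees of freedom. With three replicates per arm a plain Welch t-test
is dominated by the sampling noise of the per-feature variance estimate
(2 residual df per arm) and its power saturates well below full recall
regardless of how small the true biological variance is; variance
sharing across features is the standard remedy in small-n expression
analysis and is what count-model DE tools do internally. A plain Welch
test remains available via `method="welch"`.

Note that quantile normalization compresses log fold-change *magnitudes*
when a large fraction of features is perturbed (ranks saturate);
direction and significance calls are unaffected. Fold-change-faithful
estimates need a scale-preserving normalization (e.g. median-of-ratios),
which the DE function accepts through its `normalized` argument.

## Discretization and trend conventions

- μ and σ are pooled over all features × all three transitions by
  default ("one global band"); a per-transition-index scope is available.
- σ is the population standard deviation (n denominator); the sample
  convention is available via `ddof=1`. Differences are absorbed by k.
- The '+'/'−' inequalities are strict, so T exactly on the band edge is
  '0'.
- The trend labels are bound to the math: *non-decrease* means only
  {0, +} transitions, *non-increase* only {0, −}. The module logs a
  one-time warning to make the binding visible, because the two labels
  are easy to swap in prose.
- mRNA profiles use the same φFC machinery, discretized against the
  mRNA population's own μ, σ (not the miRNAs').

## The synthetic study

The generator emulates the target study design — 4 time points, tumor
and control arms with 3 replicates each (24 samples) — with:

- **Counts**: negative binomial, var = m + φm², shared dispersion
  φ = 0.02 by default; per-sample library-size factors log-normal
  (σ = 0.2) so normalization is non-trivial.
- **Regulators**: 10 promoter miRNAs with a tumor/control log2 effect
  ramping linearly to +2 at the last time point (monotone
  non-decreasing), 10 suppressors with the mirrored ramp.
- **Coupling**: each regulator owns 10 target genes (disjoint across
  regulators; every target has exactly one planted regulator), whose
  tumor-arm mean is multiplied by 2^(−regulator effect). This directly
  induces the opposite-sign differential expression and the negative
  cross-sample correlation the pipeline filters on.
- **Decoys**: 100 miRNA–gene pairs whose gene is not a target of any
  regulator, hence statistically independent of the miRNA; their sample
  correlations are symmetric around zero.
- **Modules**: 3 planted gene–term bicliques (8–12 genes × 2–4 terms,
  driven by 4–8 regulators each, every chosen regulator contributing at
  least one module gene), plus 40 background terms; extra annotations
  are sprinkled at rate 0.02 per free gene × term cell.
- **Baselines**: null features draw log2 baselines uniformly over
  (3, 11); planted features draw from the middle of that range. The
  restriction matters: rank-based normalization erases a fold-change
  whose whole excursion stays beyond the extremes of the null
  distribution (the rank saturates), so planted features need headroom
  on both sides to remain observable at realistic depth.

Sizes (80 miRNAs, 600 genes) keep every stage exercised — including
non-trivial BH corrections and biclique mining — while the full test
suite runs in seconds.

**What passing tests do and do not show.** The generator plants exactly
the structure the pipeline searches for: monotone effects, one regulator
per target, clean bicliques. Real data have correlated genes, shared
targets, batch effects, non-monotone regulation and annotation bias;
recovery on the synthetic study demonstrates the machinery is correct,
not that real-data recovery will be complete. One subtlety worth knowing:
because network genes are overwhelmingly planted targets, a background
term that randomly annotates several targets is *genuinely*
over-represented in the network, so occasional significant FRPs built on
background terms are correct behavior, not false positives of the test.

## Numerical and design choices

- Spearman ρ is Pearson on mid-ranks; constant vectors are not
  computable and the pair is dropped downstream.
- The hypergeometric upper tail is summed from log-factorials
  (`gammaln`), vectorized over a tail grid; exact to ~1e-14 against
  integer enumeration on small arguments.
- Quantile normalization resolves ties by averaging the reference values
  over the tied rank block, which intentionally departs from exact
  column-distribution equality on tied data.
- The counting rule checks strand only when both records carry one;
  a read clearing the >50% threshold for several loci increments each
  (no fractional assignment).
- Closed-itemset output is deterministically ordered by (−support,
  lexicographic term tuple); reruns are diffable. Itemsets of a single
  term are allowed (minimum itemset size is configurable).
- `select_min_support` scores each candidate support by the mean
  biclique silhouette and breaks ties toward the smaller support.
- Pipeline artifacts are stamped with a config digest and seed; a rerun
  with identical config and inputs is bit-identical.

## Known limitations

- The DE stand-in tests log-transformed normalized counts, not a count
  likelihood; very low counts are handled by the pseudocount, not by a
  proper NB model.
- The silhouette construction (Jaccard-on-term-profile distance,
  overlapping cluster memberships scored per membership) is this
  package's explicit choice; other biclustering-validation conventions
  exist and would rank borderline bicliques differently.
- Trend matching is exact per character and therefore conservative at
  low replication, where pattern estimates are noisy.
- The generator does not simulate raw reads, adapter artifacts,
  alignment ambiguity, or inter-gene correlation beyond the planted
  couplings.
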