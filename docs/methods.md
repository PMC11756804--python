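# Methods

## Scope and model of the data

`cernapipe` operates downstream of read alignment, transcript assembly and
target prediction: its inputs are summary tables (counts, an annotation
summary with coding-potential scores, prediction scores, localization
scores, PPI confidences, gene sets), not reads.  Coding-potential tools
(CPC/CNCI/CPAT/PFAM), the localization predictor and the target-prediction
algorithms are consumed as scores, never re-implemented — the package's
contribution is the inference chain that combines them.

Counts for feature *f* in sample *s* are modelled as negative binomial
with mean `sf_s · μ_{f,g(s)}` and variance `μ + αμ²`, where `sf_s` is a
sample size factor, `g(s)` the sample's group, and `α` a per-feature
dispersion shared between the two groups.

## Differential expression

* **Normalization.** Median-of-ratios size factors: each sample's factor
  is the median over features with all-positive counts of the ratio of
  the count to the feature's geometric mean.  If no feature is positive
  everywhere the default is a hard error; a configurable fallback builds a
  pseudo-reference from the nonzero cells of features expressed anywhere.
* **Dispersion.** Per-feature method-of-moments estimate
  `α̂ = (s²_pooled − μ̄)/μ̄²` (clipped to [1e−8, 10]), shrunk with fixed
  weight 0.8 toward a least-squares mean–dispersion trend `a0 + a1/μ̄`.
  At n = 5 per group the raw moment estimate is far too noisy to use
  alone; the trend-dominant shrinkage was chosen by null simulation
  before the test was frozen.
* **Test.** Delta-method Wald statistic on the difference of log group
  means of normalized counts, `SE² = (1/μ̂₁ + α̂)/n₁ + (1/μ̂₂ + α̂)/n₂`,
  referred to the standard normal.  A t reference with n₁+n₂−2 degrees of
  freedom was evaluated and rejected: it is markedly over-conservative
  here (null rejection ~0.02 at nominal 0.05, with a large power cost).
  This is a documented re-implementation of the classical NB testing
  recipe, not a bit-for-bit reproduction of any specific released tool.
* **Calibration.** On simulated nulls (2000 features, n = 5 vs 5,
  dispersions 0.02–0.1 — the regime the generator models) the empirical
  type-I error at α = 0.05 lies within the 99% binomial confidence
  interval [0.0374, 0.0626]; the test suite pins this.  *Limitation:* at
  dispersions ≳ 0.2 the Wald test grows mildly anticonservative
  (≈ 0.06–0.07); with very small groups and high biological variability
  its p-values should be read accordingly.
* **Fold change.** `log2fc = log2((μ̂_test + 0.5)/(μ̂_ctrl + 0.5))` — the
  0.5 pseudo-count is display-only and never enters the test statistic.
  All-zero features are kept with p = FDR = 1 and flagged.
* **Multiple testing.** Benjamini–Hochberg step-up, implemented directly
  (`fdr_i = min_{p_j ≥ p_i} m·p_j/rank_j`, capped at 1) and cross-checked
  against `statsmodels.multipletests` in the tests.
* **Direction thresholds** (defaults, per layer): lncRNA |log2FC| ≥ 1
  (fold change ≥ 2, inclusive), FDR < 0.01, p < 0.05; miRNA |log2FC| > 1
  (strict), adjusted p < 0.05, no raw-p gate; mRNA |log2FC| > 2 (strict),
  FDR < 0.01, p < 0.05.  Inclusive-vs-strict semantics follow the
  fold-change vs log-fold-change phrasing of each rule and are
  configurable per layer.

## Screening, prioritization, gating

* Screening applies its rules in a fixed order (class code → length →
  exons → FPKM → missing score → CPC → CNCI → CPAT → PFAM) so the
  per-rule rejection tally is mutually exclusive and sums, with the
  retained count, to the input size.  The FPKM floor uses the **maximum**
  across samples by default (a transcript expressed in one condition only
  is still expressed); a mean mode is configurable.
* Class-code mapping: u → intergenic, i → intronic, x → antisense,
  o/e → sense.
* cis association: same chromosome and edge-to-edge gap ≤ 100 kb between
  1-based inclusive intervals, overlap counting as gap 0, strand ignored.
  trans association: Pearson |r| > 0.9 (strict) with two-sided P < 0.01
  from the exact t transform across ≥ 3 shared samples; constant vectors
  are skipped and flagged rather than tested.
* Core-DEL selection ranks by **mean FPKM over all samples** (descending;
  max is configurable) and by significance (FDR, then raw p, then |log2FC|
  descending, then id).  All ranks break ties by ascending id, making both
  stages invariant to row order.  K values larger than the list clamp
  with a warning.
* Localization calls are the argmax of the five compartment scores; exact
  ties break by a fixed compartment order (nucleus first) and are
  flagged.  Cytosol is kept distinct from cytoplasm by default (the
  upstream predictor emits both); a config flag merges them.

## Pair filters and network assembly

Boundary semantics follow each rule's phrasing literally: target score
≥ 60 (a stated *minimum* is inclusive) and conservation > 0.5 (strict);
context++ ≤ −0.4 (inclusive); miRanda score > 140 and energy < −20
kcal/mol (both strict).  Duplicate prediction rows for one pair collapse
to the best score per tool (max target/miRanda score, min context/energy)
before filtering, since prediction tables commonly list one row per
binding site.  Every dropped row is tallied under its first failing rule,
so retained + tally = input.

The same-trend (sponge direction) rule acts **per pair** by default: a
miRNA sharing its direction with one lncRNA can still pair with an
opposite-direction lncRNA.  A per-miRNA scope — removing such miRNAs
globally — is configurable; the narrative phrasing of such removals in
study reports is ambiguous between the two, and the choice is exposed
rather than hidden.

Triplets are materialized (not just a bipartite edge union) so
per-triplet provenance scores survive to reports; the network export
collapses them to unique typed edges.  The direction invariant (lncRNA
opposite miRNA, miRNA opposite mRNA) is asserted at construction.  If the
two pair tables disagree about a miRNA's direction the join is refused,
naming the miRNA — that indicates inconsistent upstream DE tables.

## Hubs and over-representation

The PPI combined score (auto-rescaled from a 0–1000 export if detected)
is a filter at ≥ 0.4, never an edge weight: betweenness and closeness are
computed on the unweighted confidence-filtered subgraph induced on the
query genes, with isolated query genes kept (ranking last).  Degree is
the default hub measure — the specific centrality behind published
"top-20" hub lists is rarely stated — and all three measures are reported
so the choice is auditable.  Ties rank by ascending id.

Over-representation: for a query of size n in a universe of size N, a
term with K members in the universe and k hits has
`p = Σ_{i=k}^{min(K,n)} C(K,i)·C(N−K,n−i)/C(N,n)` (hypergeometric upper
tail), BH-corrected across the tested terms; K = 0 terms are skipped.
Term membership comes from user-supplied GMT files — database-versioned
term counts from web services are deliberately out of scope.

## The synthetic generator

The generator emulates the study design the pipeline targets: two groups
of 5 sequenced samples; three count layers (defaults 3000 lncRNAs, 800
miRNAs, 4000 mRNAs); NB counts with baseline means log-normal
(ln-mean 4.0, ln-sd 1.0 → typical means ~7–400), dispersion 0.1, library
factors log-uniform in [0.7, 1.4]; 10% of each layer differentially
expressed at planted |log2FC| = 2.  Those unstated magnitudes were chosen
once as realistic for bulk tissue RNA-seq and are not revisited.

Planted ceRNA triplets are the full per-miRNA bipartite product (default
6 miRNAs × 2 lncRNAs × 3 mRNAs = 36 triplets over 12 lncRNAs), which is
exactly the closure a natural join recovers, so planted and recoverable
sets coincide.  Triplet members are emitted as the strongest signals of
their layers — baseline three ln-units above typical and planted effect
two log2 units above the layer default: the design being emulated is
precisely that the sponge axis sits among the most abundant, most
significant features (published core lncRNAs validate at >10-fold while
the DE floor is 2-fold), which is what the expression × significance
prioritization selects for.  Keeping the planted lncRNA count (12) below
the top-20 rank cutoffs leaves slack for rank noise.  Retained lncRNA
class codes follow the positional mix reported for rat cortex
(63.7% sense, 8.5% antisense, 20.6% intronic, 7.2% intergenic), so the
classification stage reflects that mix by construction — a label
distribution, not a claim the pipeline can test.

Side tables support every planted triplet with rows passing all score
thresholds, plus decoys in three labelled classes (score-fail,
direction-fail, non-DE-partner) so each filter's rejections are
attributable in tests.  FPKM is derived from counts with lengths
log-uniform in [200, 10000] nt, so the length ≥ 200 nt screen and the
FPKM ranks are exercised on count-consistent values.

**What passing tests show — and don't.** Planted-triplet
precision = recall = 1 demonstrates that the thresholds, direction rules
and join are implemented correctly and that the chain is lossless for
strong, well-supported signals.  It does not show that real sponge
interactions are recoverable: real prediction tables have far higher
false-positive rates, real effects are weaker and correlated, counts have
outliers and batch structure the generator omits (no sequence-level
simulation, no GC/length bias, no multi-factor designs, no batch
correction).

## Numerical and degenerate-input choices

Ranked lists everywhere break ties by ascending id for cross-platform
determinism.  Feature identifiers are opaque case-sensitive strings;
only whitespace is stripped (silent id munging is the dominant failure
mode of network joins).  Empty networks export as valid empty files;
empty PPI graphs warn and return empty rankings; an empty gene-set
universe is an error.  Dispersions clip to [1e−8, 10]; group means enter
log ratios guarded at 1e−8 (features with a zero group mean get large but
finite statistics; all-zero features are assigned the null result
directly).

Every run emits a JSON manifest recording the full configuration and
seed, so any output is reproducible from (input files + config + seed).
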