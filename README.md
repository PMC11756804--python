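# cernapipe

**lncRNA–miRNA–mRNA ceRNA network inference for two-group RNA-seq designs.**

`cernapipe` implements the post-sequencing analysis chain used to nominate
long non-coding RNAs that act as competing endogenous RNAs (ceRNAs, miRNA
"sponges") in a two-condition bulk transcriptome experiment — e.g. a rodent
ischaemic-stroke model (middle cerebral artery occlusion, MCAO) against
sham-operated controls with n = 5 sequenced animals per group.  It is a
library first: every stage is an importable function over pandas tables,
with a thin CLI (`cernapipe`) for shell-driven runs and an `examples/`
directory of narrative scripts.

The chain:

1. **lncRNA screening** — keep assembled transcripts with class code in
   {i, x, u, o, e}, length ≥ 200 nt, ≥ 2 exons, FPKM ≥ 0.1, and no coding
   evidence (CPC < 0.5, CNCI < 0, CPAT < 0.5, PFAM < 0); classify retained
   lncRNAs as sense / antisense / intronic / intergenic by class code.
2. **Differential expression** — per layer (lncRNA, miRNA, mRNA):
   median-of-ratios size factors, NB Wald test
   (var = μ + αμ², trend-shrunk moment dispersion α̂), BH correction, and
   layer thresholds (lncRNA FC ≥ 2 & FDR < 0.01; miRNA |log2FC| > 1 &
   adj. p < 0.05; mRNA |log2FC| > 2 & FDR < 0.01).
3. **Core-DEL prioritization** — intersect the top-200 DELs by mean FPKM
   with the top-200 by significance, then union the top-20 of each rank
   within that intersection; gate on predicted subcellular localization
   (argmax of five lncLocator-style compartment scores = cytoplasm).
4. **Pair filtering** — lncRNA→miRNA predictions pass on miRDB-style
   target score ≥ 60 and conservation > 0.5; miRNA→mRNA predictions need
   *both* tools: TargetScan-style context++ ≤ −0.4 **and** miRanda-style
   score > 140 with duplex energy < −20 kcal/mol.  Both stages enforce the
   sponge direction rule: partners must be differentially expressed in
   *opposite* directions.
5. **ceRNA assembly** — natural join of the two pair sets on the shared
   miRNA yields direction-consistent triplets (lncRNA and mRNA
   co-directional); exported as SIF/GraphML with typed, direction-annotated
   nodes.
6. **Hubs + enrichment** — PPI edges at combined confidence ≥ 0.4 induce a
   subgraph on the network mRNAs; the top-20 by centrality (degree by
   default; betweenness/closeness also reported) are hub genes and induce
   the core ceRNA subnetwork.  Over-representation of the network mRNAs in
   GMT gene sets is the hypergeometric upper tail
   P(X ≥ k), X ~ Hypergeom(N, K, n), BH-corrected.
7. **qPCR utility** — relative expression by 2^−ΔΔCt.

Because raw reads for such studies are often unavailable, the package
ships a first-class **synthetic-data generator** that emulates the whole
input bundle — NB counts with planted DE, planted direction-consistent
triplets, prediction tables with labelled decoys, localization scores, PPI
edges and gene sets — so the entire chain is testable against known ground
truth.

## Worked example

```python
from cernapipe import run_pipeline, simulate_dataset

ds = simulate_dataset(seed=1)          # full synthetic study, n=5 vs n=5
res = run_pipeline(
    counts=ds.counts, annotation=ds.annotation, mirdb=ds.mirdb,
    targetscan=ds.targetscan, miranda=ds.miranda,
    localization=ds.localization, ppi=ds.ppi,
    gene_sets=ds.gene_sets, groups=ds.groups,
)
print(res.composition)
```

Running the example scripts prints, for seed 1:

```
lncrna   3000 features -> 289 DE (134 up, 155 down)
mirna     800 features -> 80 DE (41 up, 39 down)
mrna     4000 features -> 201 DE (95 up, 106 down)
DELs: 289; top-200 x top-200 intersection: 153; top-20 union within it: 31
cytoplasmic core lncRNAs: 18
lncRNA-miRNA pairs: 12
miRNA-mRNA pairs:  18
triplets: 36; network composition: {'lncrnas': 12, 'mirnas': 6, 'mrnas': 18, ...}
planted-triplet recall: 36/36, precision: 36/36
```

i.e. ~10% of each layer is called differentially expressed (the planted
fraction), the two-stage rank intersection narrows 289 DELs to 31 core
candidates of which 18 are cytoplasmic, and the assembled network recovers
every planted triplet with no false positives — the decoy prediction rows
(score failures, same-direction pairs, non-DE partners) are all rejected
by the threshold and direction filters.

See `examples/` for one narrative script per capability, and `cernapipe
--help` for the CLI subcommands (`simulate`, `screen`, `de`, `prioritize`,
`pairs`, `assemble`, `hubs`, `enrich`, `run-all`).

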