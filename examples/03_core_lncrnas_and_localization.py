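"""Prioritize core differentially expressed lncRNAs and gate on localization.

Stage 1 intersects the top-200 DELs by mean FPKM with the top-200 by
significance; stage 2 unions the top-20 of each rank within stage 1.
Candidates then pass only if their argmax lncLocator-style compartment is
the cytoplasm — ceRNA sponging is a cytoplasmic mechanism.
"""

import pandas as pd

from cernapipe import PipelineConfig, gate_cytoplasmic, nb_test, select_core_dels, simulate_dataset

ds = simulate_dataset(seed=1)
mat = ds.counts["lncrna"]
de = nb_test(mat, [ds.groups[s] for s in mat.columns], "mcao", "sham", layer="lncrna",
             thresholds=PipelineConfig().lncrna)

dels = de[de["direction"] != "ns"].reset_index(drop=True)
ann = ds.annotation.set_index("transcript_id")
fpkm_cols = [c for c in ds.annotation.columns if c.startswith("fpkm")]
dels = pd.concat([dels, ann.loc[dels["feature_id"], fpkm_cols].reset_index(drop=True)], axis=1)

stage1, stage2 = select_core_dels(dels, k_big=200, k_small=20)
print(f"DELs: {len(dels)}; top-200 x top-200 intersection: {len(stage1)}; "
      f"top-20 union within it: {len(stage2)}")

cytoplasmic, tally = gate_cytoplasmic(stage2, ds.localization)
print("localization of the core candidates:", {k: v for k, v in tally.items() if v})
print(f"cytoplasmic core lncRNAs: {len(cytoplasmic)}")
# Only the cytoplasmic set feeds the lncRNA->miRNA sponge-target stage.
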