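"""End-to-end orchestration: screen -> DE -> prioritize -> pairs -> network -> hubs -> ORA.

`run_pipeline` takes in-memory tables (a :class:`~cernapipe.synthetic.SyntheticDataset`
has exactly this shape; real tables read via :mod:`cernapipe.data_io` work the
same) and applies every stage in study order, returning a result bundle with
per-stage outputs and the stage-count summary that the run manifest records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cerna import assemble_cerna, core_subnetwork
from .config import PipelineConfig
from .data_io import NetworkExport, export_network, write_manifest, write_table
from .diffexpr import nb_test
from .netstats import enrich, hub_genes, top_enriched
from .prioritize import gate_cytoplasmic, select_core_dels
from .screen import classify_lncrnas, screen_lncrnas
from .synthetic import fpkm_from_counts
from .target_filters import lnc_mir_pairs, merge_mrna_predictions, mir_mrna_pairs


@dataclass
class PipelineResult:
    screened: pd.DataFrame
    screen_tally: dict
    class_counts: dict
    de: dict[str, pd.DataFrame]  # layer -> DE table
    de_counts: dict[str, tuple[int, int]]  # layer -> (n_up, n_down)
    core_stage1: set[str]
    core_stage2: set[str]
    cytoplasmic: set[str]
    localization_tally: dict
    lnc_mir: pd.DataFrame
    lnc_mir_tally: dict
    mir_mrna: pd.DataFrame
    mir_mrna_tally: dict
    triplets: pd.DataFrame
    network: NetworkExport
    composition: dict
    hubs: pd.DataFrame
    ppi_tally: dict
    core_triplets: pd.DataFrame
    core_composition: dict
    enrichment: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(
    counts: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    mirdb: pd.DataFrame,
    targetscan: pd.DataFrame,
    miranda: pd.DataFrame,
    localization: pd.DataFrame,
    ppi: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    groups: dict[str, str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    group_series = [groups[s] for s in counts["lncrna"].columns]

    # 1. lncRNA screening + classification
    screened, screen_tally = screen_lncrnas(annotation, cfg)
    class_counts = classify_lncrnas(screened)
    kept_ids = set(screened["transcript_id"])
    lnc_counts = counts["lncrna"].loc[counts["lncrna"].index.isin(kept_ids)]

    # 2. three-layer differential expression
    de = {}
    de_counts = {}
    for layer, mat in (("lncrna", lnc_counts), ("mirna", counts["mirna"]), ("mrna", counts["mrna"])):
        g = [groups[s] for s in mat.columns]
        table = nb_test(
            mat,
            g,
            test_group=cfg.test_group,
            control_group=cfg.control_group,
            layer=layer,
            thresholds=cfg.layer(layer),
            size_factor_fallback=cfg.size_factor_fallback,
        )
        de[layer] = table
        de_counts[layer] = (
            int((table["direction"] == "up").sum()),
            int((table["direction"] == "down").sum()),
        )

    # 3. core-DEL prioritization (expression x significance) + localization gate
    dels = de["lncrna"][de["lncrna"]["direction"] != "ns"].reset_index(drop=True)
    ann_idx = annotation.set_index("transcript_id")
    fpkm_cols = [c for c in annotation.columns if c.startswith("fpkm")]
    fpkm_block = ann_idx.loc[dels["feature_id"], fpkm_cols].reset_index(drop=True)
    dels = pd.concat([dels, fpkm_block], axis=1)
    stage1, stage2 = select_core_dels(
        dels, k_big=cfg.k_big, k_small=cfg.k_small, expression_summary=cfg.expression_summary
    )
    cytoplasmic, loc_tally = gate_cytoplasmic(stage2, localization, merge_cytosol=cfg.merge_cytosol)

    # 4. prediction-score + direction filters
    lm_pairs, lm_tally = lnc_mir_pairs(cytoplasmic, mirdb, de["mirna"], de["lncrna"], cfg)
    merged = merge_mrna_predictions(targetscan, miranda)
    mm_pairs, mm_tally = mir_mrna_pairs(
        set(lm_pairs["mirna_id"]), merged, de["mrna"], de["mirna"], cfg
    )

    # 5. ceRNA assembly; drop lncRNA-miRNA pairs whose miRNA lost all mRNAs
    triplets, network, composition = assemble_cerna(lm_pairs, mm_pairs)

    # 6. PPI hubs over the network mRNAs + core subnetwork
    net_mrnas = set(triplets["mrna_id"])
    hubs, ppi_tally = hub_genes(
        ppi, net_mrnas, top_n=cfg.n_hubs, measure=cfg.hub_measure, score_min=cfg.ppi_score_min
    )
    hub_ids = set(hubs[hubs["is_hub"]]["id"]) if len(hubs) else set()
    if hub_ids:
        core_triplets, core_comp = core_subnetwork(triplets, hub_ids)
    else:
        core_triplets, core_comp = triplets.iloc[0:0], {"lncrnas": 0, "mirnas": 0, "mrnas": 0}

    # 7. over-representation of the network mRNAs in the gene sets
    universe = set(counts["mrna"].index.astype(str))
    enrichment = enrich(net_mrnas, gene_sets, universe) if net_mrnas else pd.DataFrame(
        columns=["term", "k", "K", "n", "N", "pvalue", "fdr"]
    )

    stage_counts = {
        "transcripts_in": len(annotation),
        "lncrnas_retained": screen_tally["retained"],
        "class_counts": class_counts,
        "n_del": sum(de_counts["lncrna"]),
        "n_del_up": de_counts["lncrna"][0],
        "n_del_down": de_counts["lncrna"][1],
        "n_demirna": sum(de_counts["mirna"]),
        "n_demrna": sum(de_counts["mrna"]),
        "core_stage1": len(stage1),
        "core_stage2": len(stage2),
        "cytoplasmic": len(cytoplasmic),
        "localization_tally": {k: v for k, v in loc_tally.items()},
        "lnc_mir_pairs": len(lm_pairs),
        "mir_mrna_pairs": len(mm_pairs),
        "composition": composition,
        "ppi": {k: ppi_tally.get(k) for k in ("nodes", "edges")},
        "hubs": len(hub_ids),
        "core_composition": core_comp,
        "enriched_terms_p05": int((enrichment["pvalue"] < 0.05).sum()) if len(enrichment) else 0,
    }
    return PipelineResult(
        screened=screened,
        screen_tally=screen_tally,
        class_counts=class_counts,
        de=de,
        de_counts=de_counts,
        core_stage1=stage1,
        core_stage2=stage2,
        cytoplasmic=cytoplasmic,
        localization_tally=loc_tally,
        lnc_mir=lm_pairs,
        lnc_mir_tally=lm_tally,
        mir_mrna=mm_pairs,
        mir_mrna_tally=mm_tally,
        triplets=triplets,
        network=network,
        composition=composition,
        hubs=hubs,
        ppi_tally=ppi_tally,
        core_triplets=core_triplets,
        core_composition=core_comp,
        enrichment=enrichment,
        stage_counts=stage_counts,
    )


def write_results(result: PipelineResult, config: PipelineConfig, outdir: str | Path) -> Path:
    """Write per-stage tables, network exports and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, table in result.de.items():
        write_table(table, outdir / f"de_{layer}.tsv")
    write_table(result.lnc_mir, outdir / "lnc_mir_pairs.tsv")
    write_table(result.mir_mrna, outdir / "mir_mrna_pairs.tsv")
    write_table(result.triplets, outdir / "cerna_triplets.tsv")
    write_table(result.hubs, outdir / "hub_genes.tsv")
    write_table(result.enrichment, outdir / "enrichment.tsv")
    if len(result.network.nodes):
        export_network(result.network, outdir / "cerna_network.sif", "sif")
        export_network(result.network, outdir / "cerna_network.graphml", "graphml")
    return write_manifest(config, outdir, stage_counts=_jsonable(result.stage_counts))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(v, dict)] if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
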