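"""ceRNA triplet assembly and the core subnetwork.

A ceRNA triplet (lncRNA, miRNA, mRNA) is the natural join of the two
directed pair sets on the shared miRNA.  By construction every triplet is
direction-consistent: lncRNA opposite to miRNA, miRNA opposite to mRNA,
hence lncRNA and mRNA co-directional — the expression signature of a
sponge relieving repression of the miRNA's targets.  Triplets are
materialized (not just the bipartite edge union) so per-triplet provenance
scores survive to reports; the network export collapses them back to
unique typed edges.
"""

from __future__ import annotations

import pandas as pd

from .data_io import NetworkExport

TRIPLET_COLUMNS = [
    "lncrna_id", "mirna_id", "mrna_id",
    "lnc_direction", "mir_direction", "mrna_direction",
    "target_score", "conservation",
    "context_score", "miranda_score", "miranda_energy",
]


def _composition(triplets: pd.DataFrame) -> dict[str, int]:
    return {
        "lncrnas": int(triplets["lncrna_id"].nunique()),
        "mirnas": int(triplets["mirna_id"].nunique()),
        "mrnas": int(triplets["mrna_id"].nunique()),
    }


def _check_directions(triplets: pd.DataFrame) -> None:
    bad = triplets[
        (triplets["lnc_direction"] == triplets["mir_direction"])
        | (triplets["mir_direction"] == triplets["mrna_direction"])
    ]
    if len(bad):
        raise AssertionError(
            "direction-inconsistent triplet(s): "
            + ", ".join(
                f"{r.lncrna_id}-{r.mirna_id}-{r.mrna_id}"
                for r in bad.head(5).itertuples(index=False)
            )
        )


def assemble_cerna(
    lnc_mir: pd.DataFrame, mir_mrna: pd.DataFrame
) -> tuple[pd.DataFrame, NetworkExport, dict[str, int]]:
    """Join the pair sets into triplets and build the typed network.

    Returns ``(triplets, network, composition)`` where composition counts
    the unique lncRNAs / miRNAs / mRNAs appearing in at least one triplet.
    miRNAs present in only one pair table are dropped (they cannot bridge)
    and reported under ``composition["mirnas_dropped_one_sided"]``.  If the
    two tables disagree on a shared miRNA's direction the join is refused
    with an error naming the miRNA.
    """
    mir_dirs = pd.concat(
        [
            lnc_mir[["mirna_id", "mir_direction"]],
            mir_mrna[["mirna_id", "mir_direction"]],
        ]
    ).drop_duplicates()
    conflicted = mir_dirs["mirna_id"][mir_dirs["mirna_id"].duplicated()].unique()
    if len(conflicted):
        raise ValueError(
            "conflicting miRNA direction between pair tables: "
            + ", ".join(map(str, conflicted[:5]))
        )

    triplets = lnc_mir.merge(
        mir_mrna.drop(columns=["mir_direction"]), on="mirna_id", how="inner"
    )[TRIPLET_COLUMNS].sort_values(
        ["lncrna_id", "mirna_id", "mrna_id"], kind="mergesort"
    ).reset_index(drop=True)
    _check_directions(triplets)

    composition = _composition(triplets)
    one_sided = (set(lnc_mir["mirna_id"]) ^ set(mir_mrna["mirna_id"]))
    composition["mirnas_dropped_one_sided"] = len(one_sided)

    nodes_rows = []
    for col, dcol, role in (
        ("lncrna_id", "lnc_direction", "lncRNA"),
        ("mirna_id", "mir_direction", "miRNA"),
        ("mrna_id", "mrna_direction", "mRNA"),
    ):
        sub = triplets[[col, dcol]].drop_duplicates()
        for row in sub.itertuples(index=False):
            nodes_rows.append({"id": row[0], "role": role, "direction": row[1]})
    nodes = pd.DataFrame(nodes_rows, columns=["id", "role", "direction"])

    e1 = triplets[["lncrna_id", "mirna_id", "target_score", "conservation"]].drop_duplicates(
        ["lncrna_id", "mirna_id"]
    )
    e1 = e1.rename(columns={"lncrna_id": "source", "mirna_id": "target"})
    e1["kind"] = "lncRNA-miRNA"
    e2 = triplets[
        ["mirna_id", "mrna_id", "context_score", "miranda_score", "miranda_energy"]
    ].drop_duplicates(["mirna_id", "mrna_id"])
    e2 = e2.rename(columns={"mirna_id": "source", "mrna_id": "target"})
    e2["kind"] = "miRNA-mRNA"
    edges = pd.concat([e1, e2], ignore_index=True)
    edges = edges[
        ["source", "target", "kind", "target_score", "conservation",
         "context_score", "miranda_score", "miranda_energy"]
    ]

    network = NetworkExport(nodes=nodes, edges=edges)
    network.validate()
    return triplets, network, composition


def core_subnetwork(
    triplets: pd.DataFrame, hub_mrnas: set[str] | list[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict the triplet set to hub mRNAs and recompute the composition."""
    hubs = {str(h) for h in hub_mrnas}
    if not hubs:
        raise ValueError("hub mRNA set is empty")
    sub = triplets[triplets["mrna_id"].isin(hubs)].reset_index(drop=True)
    return sub, _composition(sub)
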