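"""Prediction-score thresholds and sponge direction-consistency filters.

Two pair sets feed the ceRNA join:

* lncRNA-miRNA: miRDB-style rows kept when target score >= 60 (the stated
  "minimum target score" is inclusive), conservation > 0.5 (strict), the
  lncRNA is a core candidate, the miRNA is differentially expressed, and
  the lncRNA and miRNA change in *opposite* directions (a sponge and its
  sponged miRNA anti-correlate).

* miRNA-mRNA: kept only when predicted by BOTH tools — TargetScan-style
  context++ score <= -0.4 (inclusive) AND miRanda-style score > 140 with
  duplex energy < -20 kcal/mol (both strict) — the mRNA is differentially
  expressed, and the miRNA and mRNA directions are opposite.

Each dropped row is tallied under its first failing rule, so
retained + tally = input rows.  Duplicate predictions for one pair are
collapsed to the best score per tool before filtering (prediction tables
commonly list multiple sites per pair).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PipelineConfig

LNC_MIR_REASONS = (
    "unknown_id",
    "low_target_score",
    "low_conservation",
    "not_core_lncrna",
    "mirna_not_de",
    "same_direction",
)
MIR_MRNA_REASONS = (
    "unknown_id",
    "single_tool",
    "context_score",
    "miranda_score",
    "miranda_energy",
    "not_in_mirna_set",
    "mrna_not_de",
    "same_direction",
)


def _direction_map(de: pd.DataFrame) -> dict[str, str]:
    return dict(zip(de["feature_id"].astype(str), de["direction"]))


def _dedupe(df: pd.DataFrame, keys: list[str], best: dict[str, str]) -> pd.DataFrame:
    """Collapse duplicate pair rows keeping the best score per column.

    ``best`` maps score column -> 'max' | 'min'.
    """
    if df.duplicated(keys).any():
        warnings.warn("duplicate prediction rows collapsed to best score per pair",
                      stacklevel=3)
        df = df.groupby(keys, as_index=False).agg(best)
    return df


def lnc_mir_pairs(
    core_lncs: set[str] | list[str],
    predictions: pd.DataFrame,
    mir_de: pd.DataFrame,
    lnc_de: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter miRDB-style lncRNA->miRNA predictions into directed pairs.

    Returns ``(pairs, tally)``.  ``pairs`` columns: lncrna_id, mirna_id,
    lnc_direction, mir_direction, target_score, conservation.  The tally
    has one count per reason in :data:`LNC_MIR_REASONS`, plus ``retained``
    and ``duplicates_collapsed``; it also lists ``lncrnas_without_mirna``
    (core lncRNAs left with zero surviving miRNAs).

    With ``same_trend_scope="mirna"`` a miRNA sharing its trend with *any*
    predicted core lncRNA is removed globally rather than per pair.
    """
    cfg = config or PipelineConfig()
    core = {str(c) for c in core_lncs}
    lnc_dir = _direction_map(lnc_de)
    mir_dir = _direction_map(mir_de)
    missing_core = core - set(lnc_dir)
    if missing_core:
        raise ValueError(f"core lncRNAs missing from lncRNA DE table: {sorted(missing_core)[:5]}")
    not_de = sorted(c for c in core if lnc_dir[c] not in ("up", "down"))
    if not_de:
        raise ValueError(f"core lncRNAs are not differentially expressed: {not_de[:5]}")

    pred = predictions.copy()
    n_in = len(pred)
    pred = _dedupe(pred, ["lncrna_id", "mirna_id"],
                   {"target_score": "max", "conservation": "max"})
    tally = {k: 0 for k in LNC_MIR_REASONS}
    tally["duplicates_collapsed"] = n_in - len(pred)

    same_trend_mirnas: set[str] = set()
    if cfg.same_trend_scope == "mirna":
        for row in pred.itertuples(index=False):
            ld = lnc_dir.get(str(row.lncrna_id))
            md = mir_dir.get(str(row.mirna_id))
            if (str(row.lncrna_id) in core and ld in ("up", "down")
                    and md in ("up", "down") and ld == md):
                same_trend_mirnas.add(str(row.mirna_id))

    kept_rows = []
    for row in pred.itertuples(index=False):
        lnc, mir = str(row.lncrna_id), str(row.mirna_id)
        if lnc not in lnc_dir or mir not in mir_dir:
            tally["unknown_id"] += 1
            continue
        if not row.target_score >= cfg.mirdb_score_min:
            tally["low_target_score"] += 1
            continue
        if not row.conservation > cfg.mirdb_conservation_min:
            tally["low_conservation"] += 1
            continue
        if lnc not in core:
            tally["not_core_lncrna"] += 1
            continue
        md = mir_dir[mir]
        if md not in ("up", "down"):
            tally["mirna_not_de"] += 1
            continue
        ld = lnc_dir[lnc]
        if ld == md or mir in same_trend_mirnas:
            tally["same_direction"] += 1
            continue
        kept_rows.append(
            {
                "lncrna_id": lnc,
                "mirna_id": mir,
                "lnc_direction": ld,
                "mir_direction": md,
                "target_score": float(row.target_score),
                "conservation": float(row.conservation),
            }
        )
    pairs = pd.DataFrame(
        kept_rows,
        columns=["lncrna_id", "mirna_id", "lnc_direction", "mir_direction",
                 "target_score", "conservation"],
    )
    tally["retained"] = len(pairs)
    tally["lncrnas_without_mirna"] = sorted(core - set(pairs["lncrna_id"]))
    return pairs, tally


def merge_mrna_predictions(
    targetscan: pd.DataFrame, miranda: pd.DataFrame
) -> pd.DataFrame:
    """Outer-join the two tool tables on (mirna_id, mrna_id).

    Keeps the best score per tool for duplicated pairs; pairs seen by only
    one tool carry NaN in the other tool's columns (and a present-flag).
    """
    ts = _dedupe(targetscan.copy(), ["mirna_id", "mrna_id"], {"context_score": "min"})
    mr = _dedupe(
        miranda.copy(),
        ["mirna_id", "mrna_id"],
        {"miranda_score": "max", "miranda_energy": "min"},
    )
    merged = ts.merge(mr, on=["mirna_id", "mrna_id"], how="outer")
    merged["has_targetscan"] = merged["context_score"].notna()
    merged["has_miranda"] = merged["miranda_score"].notna()
    return merged


def mir_mrna_pairs(
    mirnas: set[str] | list[str],
    predictions: pd.DataFrame,
    mrna_de: pd.DataFrame,
    mir_de: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter merged two-tool miRNA->mRNA predictions into directed pairs.

    ``predictions`` is the output of :func:`merge_mrna_predictions` (or any
    table with the same columns).  ``mirnas`` restricts to the miRNAs that
    survived the lncRNA-miRNA stage.  Returns ``(pairs, tally)``.
    """
    cfg = config or PipelineConfig()
    mirnas = {str(m) for m in mirnas}
    mir_dir = _direction_map(mir_de)
    mrna_dir = _direction_map(mrna_de)
    missing = mirnas - set(mir_dir)
    if missing:
        raise ValueError(f"miRNAs missing from miRNA DE table: {sorted(missing)[:5]}")

    tally = {k: 0 for k in MIR_MRNA_REASONS}
    kept_rows = []
    for row in predictions.itertuples(index=False):
        mir, mrna = str(row.mirna_id), str(row.mrna_id)
        if mir not in mir_dir or mrna not in mrna_dir:
            tally["unknown_id"] += 1
            continue
        if not (row.has_targetscan and row.has_miranda):
            tally["single_tool"] += 1
            continue
        if not row.context_score <= cfg.context_score_max:
            tally["context_score"] += 1
            continue
        if not row.miranda_score > cfg.miranda_score_min:
            tally["miranda_score"] += 1
            continue
        if not row.miranda_energy < cfg.miranda_energy_max:
            tally["miranda_energy"] += 1
            continue
        if mir not in mirnas:
            tally["not_in_mirna_set"] += 1
            continue
        gd = mrna_dir[mrna]
        if gd not in ("up", "down"):
            tally["mrna_not_de"] += 1
            continue
        md = mir_dir[mir]
        if md == gd:
            tally["same_direction"] += 1
            continue
        kept_rows.append(
            {
                "mirna_id": mir,
                "mrna_id": mrna,
                "mir_direction": md,
                "mrna_direction": gd,
                "context_score": float(row.context_score),
                "miranda_score": float(row.miranda_score),
                "miranda_energy": float(row.miranda_energy),
            }
        )
    pairs = pd.DataFrame(
        kept_rows,
        columns=["mirna_id", "mrna_id", "mir_direction", "mrna_direction",
                 "context_score", "miranda_score", "miranda_energy"],
    )
    tally["retained"] = len(pairs)
    return pairs, tally
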