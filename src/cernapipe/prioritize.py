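"""Core-DEL prioritization and cytoplasmic gating.

Among differentially expressed lncRNAs (DELs), the pipeline first
intersects the top-K_big by expression (summary FPKM across all samples,
descending) with the top-K_big by significance (FDR ascending, then raw P,
then |log2FC| descending, then id), then takes the union of the top-K_small
by each rank *within* that intersection.  The surviving candidates are
gated on predicted subcellular localization: only lncRNAs whose argmax
compartment is the cytoplasm proceed to sponge-target prediction, since
ceRNA activity is a cytoplasmic mechanism.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import COMPARTMENT_TIE_ORDER, PipelineConfig


def _expression_rank(dels: pd.DataFrame, summary: str) -> pd.Index:
    """Ids ordered by descending summary FPKM, ties by ascending id."""
    fpkm_cols = [c for c in dels.columns if c.startswith("fpkm")]
    if not fpkm_cols:
        raise ValueError("DEL table needs per-sample FPKM columns (prefix 'fpkm')")
    x = dels[fpkm_cols].to_numpy(dtype=float)
    expr = x.mean(axis=1) if summary == "mean" else x.max(axis=1)
    order = (
        pd.DataFrame({"id": dels["feature_id"].to_numpy(), "expr": expr})
        .sort_values(["expr", "id"], ascending=[False, True], kind="mergesort")
    )
    return pd.Index(order["id"])


def _significance_rank(dels: pd.DataFrame) -> pd.Index:
    """Ids ordered by ascending FDR, then P, then descending |log2FC|, then id."""
    order = (
        dels.assign(_abs=dels["log2fc"].abs())
        .sort_values(
            ["fdr", "pvalue", "_abs", "feature_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
    )
    return pd.Index(order["feature_id"])


def select_core_dels(
    dels: pd.DataFrame,
    k_big: int = 200,
    k_small: int = 20,
    expression_summary: str = "mean",
) -> tuple[set[str], set[str]]:
    """Two-stage expression x significance prioritization of DELs.

    ``dels`` must carry feature_id, log2fc, pvalue, fdr and per-sample
    ``fpkm*`` columns, and contain only threshold-passing DELs.  Returns
    ``(stage1, stage2)``: the top-K_big intersection and the union of
    top-K_small (by each rank, within stage 1).  K values exceeding the
    list size are clamped with a warning.  Both stages are deterministic
    under row permutation (all ranks break ties by id).
    """
    if k_small > k_big:
        raise ValueError("k_small must be <= k_big")
    n = len(dels)
    if k_big > n:
        warnings.warn(f"k_big={k_big} exceeds DEL count {n}; clamped", stacklevel=2)
        k_big = n
    if k_small > n:
        warnings.warn(f"k_small={k_small} exceeds DEL count {n}; clamped", stacklevel=2)
        k_small = n

    expr_rank = _expression_rank(dels, expression_summary)
    sig_rank = _significance_rank(dels)
    stage1 = set(expr_rank[:k_big]) & set(sig_rank[:k_big])

    expr_in = [i for i in expr_rank if i in stage1]
    sig_in = [i for i in sig_rank if i in stage1]
    stage2 = set(expr_in[:k_small]) | set(sig_in[:k_small])
    return stage1, stage2


def localize(records: pd.DataFrame, merge_cytosol: bool = False) -> pd.DataFrame:
    """Assign the argmax compartment per lncRNA.

    Scores need not sum to 1; only the argmax matters.  Exact ties are
    broken by the fixed compartment order (nucleus first) and flagged in
    the ``tie`` column.  With ``merge_cytosol`` the cytosol score is folded
    into cytoplasm before the argmax.
    """
    out = records.copy()
    comps = list(COMPARTMENT_TIE_ORDER)
    scores = out[comps].to_numpy(dtype=float).copy()
    if merge_cytosol:
        i_cyt, i_sol = comps.index("cytoplasm"), comps.index("cytosol")
        scores[:, i_cyt] += scores[:, i_sol]
        scores[:, i_sol] = -np.inf
    best = scores.max(axis=1)
    is_best = scores == best[:, None]
    out["predicted"] = [comps[int(np.argmax(row))] for row in is_best]
    out["tie"] = is_best.sum(axis=1) > 1
    return out


def gate_cytoplasmic(
    candidates: set[str] | list[str],
    localization: pd.DataFrame,
    merge_cytosol: bool = False,
) -> tuple[set[str], dict[str, int]]:
    """Keep candidates whose predicted compartment is the cytoplasm.

    Returns ``(cytoplasmic ids, tally)`` where the tally counts candidates
    per predicted compartment plus ``missing`` for candidates without a
    localization record; it sums to ``len(candidates)``.
    """
    candidates = set(candidates)
    loc = localize(localization, merge_cytosol=merge_cytosol).set_index("lncrna_id")
    tally = {c: 0 for c in COMPARTMENT_TIE_ORDER}
    tally["missing"] = 0
    kept = set()
    for cid in candidates:
        if cid not in loc.index:
            tally["missing"] += 1
            continue
        comp = loc.at[cid, "predicted"]
        tally[comp] += 1
        if comp == "cytoplasm":
            kept.add(cid)
    return kept, tally
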