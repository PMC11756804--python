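"""lncRNA candidate screening, classification and mRNA association.

Screening takes an assembler-derived transcript summary (class code,
length, exon count, per-sample FPKM, four coding-potential scores) and
retains putative lncRNAs: novel-relative-to-annotation class codes
(i/x/u/o/e), length >= 200 nt, >= 2 exons, expressed (FPKM floor), and no
coding evidence from any of CPC, CNCI, CPAT or PFAM.  Rejections are
tallied per rule, in a fixed filter order, so the tally is mutually
exclusive and sums with the retained count to the input size.

Retained lncRNAs are classified by class code: u -> intergenic,
i -> intronic, x -> antisense, o/e -> sense.

lncRNA-mRNA association supports the two standard neighbour definitions:
*cis* (same chromosome, edge-to-edge gap <= 100 kb; overlap counts as
gap 0; strand-agnostic) and *trans* (expression Pearson |r| > 0.9 with
two-sided P < 0.01 across shared samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, ScreenThresholds

CLASS_CODE_MAP = {"u": "intergenic", "i": "intronic", "x": "antisense", "o": "sense", "e": "sense"}

#: tally keys in filter order; "missing_score" catches absent coding scores
FILTER_ORDER = (
    "class_code",
    "length",
    "exons",
    "fpkm",
    "missing_score",
    "cpc",
    "cnci",
    "cpat",
    "pfam",
)


def _fpkm_columns(transcripts: pd.DataFrame) -> list[str]:
    cols = [c for c in transcripts.columns if c.startswith("fpkm")]
    if not cols:
        raise ValueError("no per-sample FPKM columns (expected prefix 'fpkm')")
    return cols


def screen_lncrnas(
    transcripts: pd.DataFrame, config: PipelineConfig | ScreenThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply basic screening + coding-potential filters.

    Returns ``(retained rows, tally)`` where the tally has one count per
    rule in :data:`FILTER_ORDER` plus ``retained``; each transcript is
    counted exactly once, at the first rule it fails.
    """
    thr = config.screen if isinstance(config, PipelineConfig) else (config or ScreenThresholds())
    fpkm_cols = _fpkm_columns(transcripts)
    fpkm = transcripts[fpkm_cols].to_numpy(dtype=float)
    fpkm_summary = fpkm.max(axis=1) if thr.fpkm_mode == "max" else fpkm.mean(axis=1)

    score_cols = ["cpc_score", "cnci_score", "cpat_score", "pfam_score"]
    scores = transcripts[score_cols].to_numpy(dtype=float)

    checks = [
        ("class_code", transcripts["class_code"].isin(thr.class_codes).to_numpy()),
        ("length", transcripts["length_nt"].to_numpy(dtype=float) >= thr.length_min),
        ("exons", transcripts["exon_count"].to_numpy(dtype=float) >= thr.exons_min),
        ("fpkm", fpkm_summary >= thr.fpkm_min),
        ("missing_score", ~np.isnan(scores).any(axis=1)),
        ("cpc", scores[:, 0] < thr.cpc_max),
        ("cnci", scores[:, 1] < thr.cnci_max),
        ("cpat", scores[:, 2] < thr.cpat_max),
        ("pfam", scores[:, 3] < thr.pfam_max),
    ]
    tally = {k: 0 for k in FILTER_ORDER}
    alive = np.ones(len(transcripts), dtype=bool)
    for name, passed in checks:
        failed_here = alive & ~np.nan_to_num(passed, nan=False).astype(bool)
        tally[name] = int(failed_here.sum())
        alive &= ~failed_here
    retained = transcripts[alive].reset_index(drop=True)
    tally["retained"] = int(alive.sum())
    return retained, tally


def classify_lncrnas(retained: pd.DataFrame) -> dict[str, int]:
    """Count retained lncRNAs per positional class.

    The partition is exhaustive and disjoint over the screened class codes;
    an unexpected code raises (it cannot occur for screened input).
    """
    counts = {"sense": 0, "antisense": 0, "intronic": 0, "intergenic": 0}
    for code in retained["class_code"] if len(retained) else []:
        try:
            counts[CLASS_CODE_MAP[code]] += 1
        except KeyError:
            raise ValueError(f"unexpected class code {code!r} after screening") from None
    return counts


def _cis_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Edge-to-edge gap between two 1-based inclusive intervals (0 on overlap)."""
    return max(0, max(s1, s2) - min(e1, e2))


def associate_mrnas(
    lncrnas: pd.DataFrame,
    mrnas: pd.DataFrame,
    lnc_expr: pd.DataFrame | None = None,
    mrna_expr: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Label every lncRNA-mRNA pair passing the cis and/or trans rule.

    ``lncrnas`` / ``mrnas`` carry coordinate columns (chrom, start, end);
    ``lnc_expr`` / ``mrna_expr`` are feature x sample expression tables for
    the trans rule (>= 3 shared samples required).  Strand never enters the
    cis rule.  Pairs where either expression vector is constant get
    ``trans_skipped=True`` rather than a correlation call.

    Returns a table with columns lncrna_id, mrna_id, cis, trans, gap_bp,
    r, pvalue, trans_skipped — one row per pair passing at least one rule
    or flagged as skipped.
    """
    cfg = config or PipelineConfig()
    rows = []

    lnc_ids = lncrnas["transcript_id"].tolist()
    mrna_ids = mrnas["transcript_id"].tolist()

    r_mat = p_mat = None
    const_l = const_m = None
    if lnc_expr is not None and mrna_expr is not None:
        shared = [s for s in lnc_expr.columns if s in set(mrna_expr.columns)]
        if len(shared) < 3:
            raise ValueError("trans rule needs >= 3 shared samples")
        xl = lnc_expr.loc[lnc_ids, shared].to_numpy(dtype=float)
        xm = mrna_expr.loc[mrna_ids, shared].to_numpy(dtype=float)
        n = len(shared)
        const_l = xl.std(axis=1) == 0
        const_m = xm.std(axis=1) == 0
        zl = xl - xl.mean(axis=1, keepdims=True)
        zm = xm - xm.mean(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_mat = (zl @ zm.T) / np.sqrt(
                (zl**2).sum(axis=1)[:, None] * (zm**2).sum(axis=1)[None, :]
            )
        r_mat = np.clip(r_mat, -1.0, 1.0)
        # exact t transform: t = r * sqrt((n-2)/(1-r^2)), two-sided
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r_mat * np.sqrt((n - 2) / np.maximum(1.0 - r_mat**2, 0.0))
        p_mat = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        p_mat[np.isnan(tstat)] = np.nan
        p_mat[np.abs(r_mat) == 1.0] = 0.0

    for i, lrow in enumerate(lncrnas.itertuples(index=False)):
        for j, mrow in enumerate(mrnas.itertuples(index=False)):
            cis = False
            gap = None
            if lrow.chrom == mrow.chrom:
                gap = _cis_gap(lrow.start, lrow.end, mrow.start, mrow.end)
                cis = gap <= cfg.cis_window_bp
            trans = False
            skipped = False
            r = p = np.nan
            if r_mat is not None:
                if const_l[i] or const_m[j]:
                    skipped = True
                else:
                    r = float(r_mat[i, j])
                    p = float(p_mat[i, j])
                    trans = abs(r) > cfg.trans_r_min and p < cfg.trans_p_max
            if cis or trans or skipped:
                rows.append(
                    {
                        "lncrna_id": lrow.transcript_id,
                        "mrna_id": mrow.transcript_id,
                        "cis": cis,
                        "trans": trans,
                        "gap_bp": gap,
                        "r": r,
                        "pvalue": p,
                        "trans_skipped": skipped,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "mrna_id", "cis", "trans", "gap_bp", "r", "pvalue", "trans_skipped"],
    )
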