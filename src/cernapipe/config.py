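"""Run configuration: every threshold the pipeline applies, in one serializable object.

The defaults reproduce the screening criteria of the study design this
pipeline implements: a two-group (ischaemia vs sham) bulk RNA-seq comparison
in which lncRNAs are screened by class code, length, exon count, expression
and four coding-potential scores; differential expression is called per
layer (lncRNA / miRNA / mRNA) with layer-specific fold-change and FDR
cutoffs; lncRNA-miRNA predictions are gated on miRDB-style target score and
conservation; miRNA-mRNA predictions on TargetScan-style context++ score
plus miRanda-style score and duplex energy; and the protein-protein network
on a combined-confidence floor.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

Compartment = Literal["cytoplasm", "nucleus", "ribosome", "cytosol", "exosome"]

#: Tie-break order for subcellular localization argmax (first wins on ties).
COMPARTMENT_TIE_ORDER: tuple[str, ...] = (
    "nucleus",
    "cytoplasm",
    "ribosome",
    "cytosol",
    "exosome",
)


class LayerThresholds(BaseModel):
    """Differential-expression call thresholds for one RNA layer.

    ``log2fc_min`` is the magnitude cutoff on log2 fold change;
    ``inclusive`` selects ``|log2FC| >= t`` (fold-change phrasing "FC >= 2")
    versus the strict ``|log2FC| > t``.  ``p_max`` of ``None`` disables the
    raw-p gate (the miRNA layer is called on adjusted p alone).
    """

    log2fc_min: float = 1.0
    inclusive: bool = True
    fdr_max: float = 0.01
    p_max: Optional[float] = 0.05

    @field_validator("log2fc_min", "fdr_max", "p_max")
    @classmethod
    def _finite(cls, v):
        if v is not None and not math.isfinite(v):
            raise ValueError("threshold must be finite")
        return v


class ScreenThresholds(BaseModel):
    """Basic screening plus coding-potential cutoffs for lncRNA candidates."""

    class_codes: tuple[str, ...] = ("i", "x", "u", "o", "e")
    length_min: int = 200
    exons_min: int = 2
    fpkm_min: float = 0.1
    fpkm_mode: Literal["max", "mean"] = "max"
    cpc_max: float = 0.5
    cnci_max: float = 0.0
    cpat_max: float = 0.5
    pfam_max: float = 0.0


class PipelineConfig(BaseModel):
    """All tunables for one pipeline run.

    Serializes losslessly to/from JSON so that a run is reproducible from
    (input files + config + seed) alone.
    """

    screen: ScreenThresholds = Field(default_factory=ScreenThresholds)

    # per-layer DE thresholds (defaults as realized in the study's results)
    lncrna: LayerThresholds = Field(
        default_factory=lambda: LayerThresholds(
            log2fc_min=1.0, inclusive=True, fdr_max=0.01, p_max=0.05
        )
    )
    mirna: LayerThresholds = Field(
        default_factory=lambda: LayerThresholds(
            log2fc_min=1.0, inclusive=False, fdr_max=0.05, p_max=None
        )
    )
    mrna: LayerThresholds = Field(
        default_factory=lambda: LayerThresholds(
            log2fc_min=2.0, inclusive=False, fdr_max=0.01, p_max=0.05
        )
    )

    # cis / trans lncRNA-mRNA association
    cis_window_bp: int = 100_000
    trans_r_min: float = 0.9  # strict: |r| > trans_r_min
    trans_p_max: float = 0.01  # strict: P < trans_p_max

    # lncRNA -> miRNA prediction gates (miRDB-style)
    mirdb_score_min: float = 60.0  # inclusive ("minimum target score")
    mirdb_conservation_min: float = 0.5  # strict

    # miRNA -> mRNA prediction gates
    context_score_max: float = -0.4  # inclusive (<=)
    miranda_score_min: float = 140.0  # strict (>)
    miranda_energy_max: float = -20.0  # strict (<), kcal/mol

    # PPI + hubs
    ppi_score_min: float = 0.4  # inclusive (>=), combined confidence 0-1
    n_hubs: int = 20
    hub_measure: Literal["degree", "betweenness", "closeness"] = "degree"

    # core-DEL prioritization
    k_big: int = 200
    k_small: int = 20
    expression_summary: Literal["mean", "max"] = "mean"

    # localization gating
    merge_cytosol: bool = False  # fold "cytosol" calls into "cytoplasm"

    # same-trend (direction) removal scope for lncRNA-miRNA pairs
    same_trend_scope: Literal["pair", "mirna"] = "pair"

    # size-factor fallback when no feature is positive in every sample
    size_factor_fallback: Literal["error", "pseudo_reference"] = "error"

    seed: int = 0
    groups: Optional[dict[str, str]] = None  # sample id -> group label
    test_group: str = "mcao"
    control_group: str = "sham"
    outdir: Optional[str] = None

    @field_validator(
        "cis_window_bp",
        "trans_r_min",
        "trans_p_max",
        "mirdb_score_min",
        "mirdb_conservation_min",
        "context_score_max",
        "miranda_score_min",
        "miranda_energy_max",
        "ppi_score_min",
    )
    @classmethod
    def _finite(cls, v):
        if not math.isfinite(v):
            raise ValueError("cutoff must be finite")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.k_small > self.k_big:
            raise ValueError(f"k_small ({self.k_small}) must be <= k_big ({self.k_big})")
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")
        return self

    def layer(self, name: str) -> LayerThresholds:
        """Thresholds for layer ``name`` in {'lncrna', 'mirna', 'mrna'}."""
        try:
            return {"lncrna": self.lncrna, "mirna": self.mirna, "mrna": self.mrna}[name]
        except KeyError:
            raise KeyError(f"unknown layer {name!r}") from None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))
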