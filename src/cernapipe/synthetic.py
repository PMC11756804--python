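"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at the level of summary tables, what a two-group
(ischaemia vs sham, n = 5 sequenced per group) whole-transcriptome study
produces after upstream processing: negative-binomial count matrices for
the lncRNA / miRNA / mRNA layers with planted differential expression,
a transcript annotation summary with class codes, coordinates, coding
scores and count-derived FPKM, and the side tables the downstream stages
consume — miRDB-style lncRNA->miRNA predictions, TargetScan-style and
miRanda-style miRNA->mRNA predictions, a five-compartment localization
table, a PPI edge list and GMT gene sets.

Ground truth is carried in :class:`SyntheticTruth`: which features are DE
and by how much, which (lncRNA, miRNA, mRNA) triplets were planted with
sponge-consistent directions (lncRNA opposite the miRNA, miRNA opposite
the mRNA), where each lncRNA was planted, which gene sets are enriched,
and which prediction rows are decoys of which class.  Decoys come in three
labelled classes so each filter's rejections can be attributed: rows that
fail a score threshold, rows whose directions are the same (sponge rule
violation), and rows whose partner is not differentially expressed.

Counts are NB with ``var = mu + dispersion * mu**2``; per-sample library
factors are log-uniform in [0.7, 1.4].  Planted triplet members are
emitted as the strongest signals of their layers (high baseline, effect
two log2 units above the layer default) — the study condition being
emulated is precisely that the sponge axis sits among the most abundant
and most significant features, which is what the two-stage core-DEL
prioritization selects for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COMPARTMENT_TIE_ORDER

LAYERS = ("lncrna", "mirna", "mrna")

#: study-matched class-code mix for retained lncRNAs (sense split over o/e)
CLASS_CODE_PROPORTIONS = {"o": 0.3185, "e": 0.3185, "x": 0.085, "i": 0.206, "u": 0.072}

_DEFAULT_N_FEATURES = {"lncrna": 3000, "mirna": 800, "mrna": 4000}


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset."""

    lfc: dict[str, dict[str, float]]  # layer -> feature id -> signed log2FC
    triplets: list[tuple[str, str, str]]
    localization: dict[str, str]  # lncRNA id -> planted compartment
    enriched_sets: list[str]
    decoys: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def validate(self, counts: dict[str, pd.DataFrame]) -> None:
        for l, m, g in self.triplets:
            for layer, feat in (("lncrna", l), ("mirna", m), ("mrna", g)):
                if feat not in counts[layer].index:
                    raise AssertionError(f"triplet member {feat} missing from {layer} counts")
            sl, sm, sg = (
                self.lfc["lncrna"][l],
                self.lfc["mirna"][m],
                self.lfc["mrna"][g],
            )
            if sl * sm >= 0 or sm * sg >= 0:
                raise AssertionError(f"triplet ({l},{m},{g}) is not direction-consistent")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["triplets"] = [list(t) for t in self.triplets]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _sample_names(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    names = [f"T{i + 1:02d}" for i in range(2 * n_per_group)]
    groups = {s: ("mcao" if i < n_per_group else "sham") for i, s in enumerate(names)}
    return names, groups


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB parameterized by mean and dispersion alpha: var = mu + alpha mu^2
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_counts(
    n_features: dict[str, int] | None = None,
    n_per_group: int = 5,
    baseline: tuple[float, float] = (4.0, 1.0),
    dispersion: float = 0.1,
    de_fraction: float = 0.1,
    effect: float = 2.0,
    n_triplet_mirnas: int = 6,
    lnc_per_mirna: int = 2,
    mrna_per_mirna: int = 3,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate the three count matrices and the planted truth.

    ``baseline`` gives (mean, sd) of the natural-log baseline mean.
    ``effect`` is the planted |log2FC| for ordinary DE features; triplet
    members get ``effect + 2`` on a high baseline so the sponge axis is the
    study's strongest signal (the emulated study validated its core lncRNAs
    at more than tenfold, well clear of the twofold DE threshold).  Planted triplets are the full bipartite
    product per miRNA (its lncRNA partners x its mRNA partners), which is
    exactly the closure a natural join recovers.  Same seed, same output.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if de_fraction > 0 and effect == 0:
        raise ValueError("effect must be nonzero when de_fraction > 0")

    nf = dict(_DEFAULT_N_FEATURES)
    if n_features:
        nf.update(n_features)
    rng = np.random.default_rng(seed)
    samples, groups = _sample_names(n_per_group)

    ids = {
        "lncrna": [f"MSTRG.{1000 + i}.1" for i in range(nf["lncrna"])],
        "mirna": [f"rno-miR-{3000 + i}-5p" for i in range(nf["mirna"])],
        "mrna": [f"Gene{i:05d}" for i in range(nf["mrna"])],
    }

    n_de = {layer: int(round(de_fraction * nf[layer])) for layer in LAYERS}

    # triplet budget: clamp so planted members fit inside each layer's DE set
    n_mir_t = n_triplet_mirnas if de_fraction > 0 else 0
    n_mir_t = min(n_mir_t, n_de["mirna"],
                  n_de["lncrna"] // max(lnc_per_mirna, 1),
                  n_de["mrna"] // max(mrna_per_mirna, 1))

    lfc: dict[str, dict[str, float]] = {layer: {} for layer in LAYERS}
    triplets: list[tuple[str, str, str]] = []
    t_lnc = ids["lncrna"][: n_mir_t * lnc_per_mirna]
    t_mir = ids["mirna"][:n_mir_t]
    t_mrna = ids["mrna"][: n_mir_t * mrna_per_mirna]
    t_effect = abs(effect) + 2.0
    for j, m in enumerate(t_mir):
        sign = 1.0 if j % 2 == 0 else -1.0  # miRNA direction alternates
        lfc["mirna"][m] = sign * t_effect
        lncs = t_lnc[j * lnc_per_mirna : (j + 1) * lnc_per_mirna]
        mrnas = t_mrna[j * mrna_per_mirna : (j + 1) * mrna_per_mirna]
        for l in lncs:
            lfc["lncrna"][l] = -sign * t_effect
        for g in mrnas:
            lfc["mrna"][g] = -sign * t_effect
        triplets.extend((l, m, g) for l in lncs for g in mrnas)

    # ordinary (non-triplet) DE features fill the remaining DE budget
    for layer in LAYERS:
        pool = [f for f in ids[layer] if f not in lfc[layer]]
        n_fill = n_de[layer] - len(lfc[layer])
        chosen = rng.choice(len(pool), size=n_fill, replace=False) if n_fill > 0 else []
        for i in chosen:
            lfc[layer][pool[i]] = float(rng.choice([-1.0, 1.0])) * abs(effect)

    counts: dict[str, pd.DataFrame] = {}
    triplet_members = {
        "lncrna": set(t_lnc),
        "mirna": set(t_mir),
        "mrna": set(t_mrna),
    }
    for layer in LAYERS:
        mu = np.exp(rng.normal(baseline[0], baseline[1], nf[layer]))
        # triplet members: high, tight baseline (the layer's most abundant DE)
        is_t = np.array([f in triplet_members[layer] for f in ids[layer]])
        mu[is_t] = np.exp(rng.normal(baseline[0] + 3.0, 0.3, int(is_t.sum())))
        delta = np.array([2.0 ** lfc[layer].get(f, 0.0) for f in ids[layer]])
        libs = np.exp(rng.uniform(np.log(0.7), np.log(1.4), 2 * n_per_group))
        cols = []
        for s_idx, s in enumerate(samples):
            m_s = mu * (delta if groups[s] == "mcao" else 1.0) * libs[s_idx]
            cols.append(_nb_draw(rng, m_s, dispersion))
        counts[layer] = pd.DataFrame(
            np.column_stack(cols), index=pd.Index(ids[layer], name="feature_id"),
            columns=samples,
        )

    # planted localization: triplet lncRNAs cytoplasmic, the rest mixed
    localization: dict[str, str] = {}
    other_comps = list(COMPARTMENT_TIE_ORDER)
    for f in ids["lncrna"]:
        if f in triplet_members["lncrna"]:
            localization[f] = "cytoplasm"
        else:
            localization[f] = other_comps[int(rng.integers(0, len(other_comps)))]

    truth = SyntheticTruth(
        lfc=lfc,
        triplets=triplets,
        localization=localization,
        enriched_sets=[],
        seed=seed,
    )
    truth.validate(counts)
    return counts, truth


def fpkm_from_counts(
    counts: pd.DataFrame, lengths_nt: pd.Series
) -> pd.DataFrame:
    """FPKM = count / (length in kb x library size in millions), per sample."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    kb = (lengths_nt.loc[counts.index].to_numpy(dtype=float)) / 1000.0
    return counts / (kb[:, None] * (lib[None, :] / 1e6))


def simulate_annotation(
    lnc_counts: pd.DataFrame,
    truth: SyntheticTruth,
    n_reject: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transcript summary table: every count-matrix lncRNA passes the screen;
    ``n_reject`` extra transcripts each fail exactly one screening rule.

    Lengths are log-uniform in [200, 10000] nt; FPKM columns are derived
    from the counts, so expression ranks downstream reflect the planted
    count structure.  Class codes follow the study-matched positional mix.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    ids = list(lnc_counts.index)
    n = len(ids)
    codes, probs = zip(*CLASS_CODE_PROPORTIONS.items())
    class_code = rng.choice(codes, size=n, p=np.array(probs) / sum(probs))
    lengths = np.exp(rng.uniform(np.log(200), np.log(10000), n)).round().astype(int)
    fpkm = fpkm_from_counts(lnc_counts, pd.Series(lengths, index=ids))

    def passing_scores(k):
        return {
            "cpc_score": rng.uniform(-2.0, 0.45, k),
            "cnci_score": rng.uniform(-5.0, -0.05, k),
            "cpat_score": rng.uniform(0.0, 0.45, k),
            "pfam_score": rng.uniform(-10.0, -0.5, k),
        }

    base = pd.DataFrame(
        {
            "transcript_id": ids,
            "class_code": class_code,
            "length_nt": lengths,
            "exon_count": rng.integers(2, 12, n),
            **passing_scores(n),
            "chrom": [f"chr{c}" for c in rng.integers(1, 21, n)],
            "start": rng.integers(1, 10_000_000, n),
            "strand": rng.choice(["+", "-"], n),
        }
    )
    base["end"] = base["start"] + base["length_nt"] - 1
    for j, s in enumerate(lnc_counts.columns):
        base[f"fpkm_{s}"] = fpkm.iloc[:, j].to_numpy()

    # rejects: cycle through the screening rules, one violation each
    fail_rules = ["class_code", "length", "exons", "fpkm", "cpc", "cnci", "cpat", "pfam"]
    rej_rows = []
    for i in range(n_reject):
        rule = fail_rules[i % len(fail_rules)]
        k = 1
        row = {
            "transcript_id": f"MSTRG.REJ{i:04d}.1",
            "class_code": "=" if rule == "class_code" else str(rng.choice(codes)),
            "length_nt": int(rng.integers(200, 10000)) if rule != "length" else int(rng.integers(50, 199)),
            "exon_count": int(rng.integers(2, 12)) if rule != "exons" else 1,
            **{k2: float(v[0]) for k2, v in passing_scores(k).items()},
            "chrom": f"chr{rng.integers(1, 21)}",
            "start": int(rng.integers(1, 10_000_000)),
            "strand": str(rng.choice(["+", "-"])),
        }
        if rule == "cpc":
            row["cpc_score"] = float(rng.uniform(0.5, 2.0))
        elif rule == "cnci":
            row["cnci_score"] = float(rng.uniform(0.0, 3.0))
        elif rule == "cpat":
            row["cpat_score"] = float(rng.uniform(0.5, 1.0))
        elif rule == "pfam":
            row["pfam_score"] = float(rng.uniform(0.0, 5.0))
        row["end"] = row["start"] + row["length_nt"] - 1
        fpkm_val = 0.01 if rule == "fpkm" else float(rng.uniform(0.5, 50.0))
        for s in lnc_counts.columns:
            row[f"fpkm_{s}"] = fpkm_val
        rej_rows.append(row)
    out = pd.concat([base, pd.DataFrame(rej_rows)], ignore_index=True)
    return out[base.columns]


def simulate_side_tables(
    truth: SyntheticTruth,
    decoy_fraction: float = 0.3,
    seed: int | None = None,
    n_background_sets: int = 10,
    n_enriched_sets: int = 3,
    mrna_universe: list[str] | None = None,
    mirna_universe: list[str] | None = None,
) -> dict[str, object]:
    """Prediction, localization, PPI and gene-set tables matching ``truth``.

    Every planted triplet is supported by rows that pass all thresholds
    (target score >= 60, conservation > 0.5, context++ <= -0.4, miRanda
    score > 140, energy < -20) and the direction rules.  Decoy rows —
    ``decoy_fraction`` of the planted row count per table, spread over the
    three classes — each fail at least one gate, and are labelled in
    ``truth.decoys`` by class so each filter's rejections are attributable.
    """
    if not 0 <= decoy_fraction:
        raise ValueError("decoy_fraction must be >= 0")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)

    lnc_mir = sorted({(l, m) for l, m, _ in truth.triplets})
    mir_mrna = sorted({(m, g) for _, m, g in truth.triplets})
    mir_sign = truth.lfc["mirna"]
    lnc_sign = truth.lfc["lncrna"]
    mrna_sign = truth.lfc["mrna"]

    mirdb_rows = [
        {
            "lncrna_id": l,
            "mirna_id": m,
            "target_score": float(rng.uniform(62, 98)),
            "conservation": float(rng.uniform(0.55, 0.95)),
        }
        for l, m in lnc_mir
    ]
    ts_rows = [
        {"mirna_id": m, "mrna_id": g, "context_score": float(rng.uniform(-0.9, -0.45))}
        for m, g in mir_mrna
    ]
    mir_rows = [
        {
            "mirna_id": m,
            "mrna_id": g,
            "miranda_score": float(rng.uniform(145, 190)),
            "miranda_energy": float(rng.uniform(-35, -21)),
        }
        for m, g in mir_mrna
    ]

    decoys: dict[str, list] = {"score_fail": [], "direction_fail": [], "non_de_member": []}
    triplet_lncs = sorted({l for l, _, _ in truth.triplets})
    de_mirnas = sorted(mir_sign)
    non_de_mirnas = sorted(set(mirna_universe or []) - set(de_mirnas))
    de_mrnas = sorted(mrna_sign)
    non_de_mrnas = sorted(set(mrna_universe or []) - set(de_mrnas))

    def pick(seq):
        return seq[int(rng.integers(0, len(seq)))] if seq else None

    n_decoy = int(round(decoy_fraction * max(len(lnc_mir), 1)))
    for i in range(n_decoy):
        cls = ("score_fail", "direction_fail", "non_de_member")[i % 3]
        l = pick(triplet_lncs)
        if l is None:
            break
        if cls == "score_fail":
            opp = [m for m in de_mirnas if mir_sign[m] * lnc_sign[l] < 0]
            m = pick(opp)
            if m is None:
                continue
            row = {
                "lncrna_id": l,
                "mirna_id": m,
                "target_score": float(rng.uniform(10, 59)),
                "conservation": float(rng.uniform(0.55, 0.95)),
            }
        elif cls == "direction_fail":
            same = [m for m in de_mirnas if mir_sign[m] * lnc_sign[l] > 0]
            m = pick(same)
            if m is None:
                continue
            row = {
                "lncrna_id": l,
                "mirna_id": m,
                "target_score": float(rng.uniform(62, 98)),
                "conservation": float(rng.uniform(0.55, 0.95)),
            }
        else:
            m = pick(non_de_mirnas)
            if m is None:
                continue
            row = {
                "lncrna_id": l,
                "mirna_id": m,
                "target_score": float(rng.uniform(62, 98)),
                "conservation": float(rng.uniform(0.55, 0.95)),
            }
        if (row["lncrna_id"], row["mirna_id"]) in set(lnc_mir):
            continue
        mirdb_rows.append(row)
        decoys[cls].append({"table": "mirdb", **row})

    planted_mm = set(mir_mrna)
    triplet_mirs = sorted({m for _, m, _ in truth.triplets})
    n_decoy = int(round(decoy_fraction * max(len(mir_mrna), 1)))
    for i in range(n_decoy):
        cls = ("score_fail", "direction_fail", "non_de_member")[i % 3]
        m = pick(triplet_mirs)
        if m is None:
            break
        if cls == "score_fail":
            opp = [g for g in de_mrnas if mrna_sign[g] * mir_sign[m] < 0]
            g = pick(opp)
            mode = int(rng.integers(0, 4))
        elif cls == "direction_fail":
            same = [g for g in de_mrnas if mrna_sign[g] * mir_sign[m] > 0]
            g = pick(same)
            mode = -1
        else:
            g = pick(non_de_mrnas)
            mode = -1
        if g is None or (m, g) in planted_mm:
            continue
        ts = {"mirna_id": m, "mrna_id": g, "context_score": float(rng.uniform(-0.9, -0.45))}
        mr = {
            "mirna_id": m,
            "mrna_id": g,
            "miranda_score": float(rng.uniform(145, 190)),
            "miranda_energy": float(rng.uniform(-35, -21)),
        }
        if mode == 0:  # weak context score
            ts["context_score"] = float(rng.uniform(-0.39, -0.05))
        elif mode == 1:  # weak miRanda score
            mr["miranda_score"] = float(rng.uniform(80, 140))
        elif mode == 2:  # weak duplex energy
            mr["miranda_energy"] = float(rng.uniform(-19.9, -5.0))
        elif mode == 3:  # single tool only
            mr = None
        ts_rows.append(ts)
        if mr is not None:
            mir_rows.append(mr)
        decoys[cls].append({"table": "mirna_mrna", "mirna_id": m, "mrna_id": g, "mode": mode})

    # localization scores realizing truth.localization as the argmax
    loc_rows = []
    comps = list(COMPARTMENT_TIE_ORDER)
    for lnc, comp in sorted(truth.localization.items()):
        top = float(rng.uniform(0.45, 0.9))
        rest = rng.uniform(0.0, top * 0.8, len(comps) - 1)
        scores = {}
        k = 0
        for c in comps:
            if c == comp:
                scores[c] = top
            else:
                scores[c] = float(rest[k])
                k += 1
        loc_rows.append({"lncrna_id": lnc, **scores})
    localization = pd.DataFrame(loc_rows)

    # PPI: a connected backbone over the planted network mRNAs plus noise
    net_mrnas = sorted({g for _, _, g in truth.triplets})
    ppi_rows = []
    for i, g in enumerate(net_mrnas):
        if len(net_mrnas) > 1:
            h = net_mrnas[(i + 1) % len(net_mrnas)]
            ppi_rows.append(
                {"protein_a": g, "protein_b": h, "combined_score": float(rng.uniform(0.45, 0.99))}
            )
    for _ in range(len(net_mrnas)):
        if len(net_mrnas) < 3:
            break
        g, h = rng.choice(net_mrnas, 2, replace=False)
        if g != h:
            ppi_rows.append(
                {"protein_a": str(g), "protein_b": str(h), "combined_score": float(rng.uniform(0.45, 0.99))}
            )
    # low-confidence decoy edges
    for _ in range(max(1, int(decoy_fraction * len(net_mrnas)))):
        if len(net_mrnas) < 2:
            break
        g, h = rng.choice(net_mrnas, 2, replace=False)
        if g != h:
            ppi_rows.append(
                {"protein_a": str(g), "protein_b": str(h), "combined_score": float(rng.uniform(0.05, 0.39))}
            )
    ppi = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "combined_score"])

    # gene sets over the mRNA universe; planted enriched sets are loaded
    # with network mRNAs, background sets are uniform draws
    universe = sorted(mrna_universe or de_mrnas)
    gene_sets: dict[str, list[str]] = {}
    enriched = []
    for i in range(n_enriched_sets):
        name = f"SET_ENRICHED_{i:02d}"
        core = [g for j, g in enumerate(net_mrnas) if j % n_enriched_sets == i]
        filler = [str(x) for x in rng.choice(universe, size=max(5, len(core)), replace=False)]
        gene_sets[name] = sorted(set(core + filler))
        enriched.append(name)
    for i in range(n_background_sets):
        size = int(rng.integers(10, 60))
        gene_sets[f"SET_BG_{i:02d}"] = sorted(
            str(x) for x in rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    truth.enriched_sets = enriched
    truth.decoys = decoys

    return {
        "mirdb": pd.DataFrame(mirdb_rows),
        "targetscan": pd.DataFrame(ts_rows),
        "miranda": pd.DataFrame(mir_rows),
        "localization": localization,
        "ppi": ppi,
        "gene_sets": gene_sets,
    }


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the ground truth."""

    counts: dict[str, pd.DataFrame]
    annotation: pd.DataFrame
    mirdb: pd.DataFrame
    targetscan: pd.DataFrame
    miranda: pd.DataFrame
    localization: pd.DataFrame
    ppi: pd.DataFrame
    gene_sets: dict[str, list[str]]
    groups: dict[str, str]
    truth: SyntheticTruth


def simulate_dataset(
    n_features: dict[str, int] | None = None,
    n_per_group: int = 5,
    baseline: tuple[float, float] = (4.0, 1.0),
    dispersion: float = 0.1,
    de_fraction: float = 0.1,
    effect: float = 2.0,
    decoy_fraction: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> SyntheticDataset:
    """One-call generator for a complete synthetic study."""
    counts, truth = simulate_counts(
        n_features=n_features,
        n_per_group=n_per_group,
        baseline=baseline,
        dispersion=dispersion,
        de_fraction=de_fraction,
        effect=effect,
        seed=seed,
        **kwargs,
    )
    annotation = simulate_annotation(counts["lncrna"], truth)
    side = simulate_side_tables(
        truth,
        decoy_fraction=decoy_fraction,
        mrna_universe=list(counts["mrna"].index),
        mirna_universe=list(counts["mirna"].index),
    )
    _, groups = _sample_names(n_per_group)
    return SyntheticDataset(
        counts=counts,
        annotation=annotation,
        mirdb=side["mirdb"],
        targetscan=side["targetscan"],
        miranda=side["miranda"],
        localization=side["localization"],
        ppi=side["ppi"],
        gene_sets=side["gene_sets"],
        groups=groups,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the seven input files plus the truth JSON into ``outdir``."""
    from .data_io import write_gmt, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer in LAYERS:
        p = outdir / f"counts_{layer}.tsv"
        ds.counts[layer].to_csv(p, sep="\t")
        paths[f"counts_{layer}"] = p
    for name in ("annotation", "mirdb", "targetscan", "miranda", "localization", "ppi"):
        paths[name] = write_table(getattr(ds, name), outdir / f"{name}.tsv")
    paths["gene_sets"] = write_gmt(ds.gene_sets, outdir / "gene_sets.gmt")
    groups = pd.DataFrame(sorted(ds.groups.items()), columns=["sample", "group"])
    paths["groups"] = write_table(groups, outdir / "groups.tsv")
    paths["truth"] = ds.truth.to_json(outdir / "truth.json")
    return paths
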