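"""Table, gene-set and network I/O.

Every table the pipeline touches is one header line plus data rows in a
tab- or comma-separated file (delimiter sniffed); comment lines start with
``#``.  Feature identifiers are opaque, case-sensitive strings — the only
normalization applied is whitespace stripping, because silent id munging is
the dominant failure mode of network joins.  Schemas tolerate extra columns
(supplementary exports rarely document their full layout).

Networks are exported as SIF, GraphML or an edge TSV; all three round-trip
to an isomorphic graph with identical node attributes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import pandas as pd

from .config import PipelineConfig

NODE_ROLES = ("lncRNA", "miRNA", "mRNA", "protein")
#: role pairs an edge may connect (order-insensitive)
ALLOWED_EDGE_ROLES = frozenset(
    {
        frozenset({"lncRNA", "miRNA"}),
        frozenset({"miRNA", "mRNA"}),
        frozenset({"protein"}),  # protein-protein
    }
)


class SchemaError(ValueError):
    """A table does not match its declared schema."""


class DuplicateIdWarning(UserWarning):
    """Duplicate feature identifiers found in an id column."""


@dataclass(frozen=True)
class TableSchema:
    """Declared layout for one input table.

    ``columns`` maps required column names to a dtype kind: ``"str"``,
    ``"float"`` or ``"int"``.  ``id_column`` (if set) is checked for
    duplicates, which are reported with a :class:`DuplicateIdWarning`.
    Extra columns are kept untouched.
    """

    name: str
    columns: Mapping[str, str]
    id_column: str | None = None


# Schemas for the pipeline's standard tables.  Per-sample columns (FPKM,
# counts) are matched by prefix at the call site, not listed here.
DE_SCHEMA = TableSchema(
    "de", {"id": "str", "log2fc": "float", "pvalue": "float", "fdr": "float"}, "id"
)
TRANSCRIPT_SCHEMA = TableSchema(
    "transcripts",
    {
        "transcript_id": "str",
        "class_code": "str",
        "length_nt": "int",
        "exon_count": "int",
        "cpc_score": "float",
        "cnci_score": "float",
        "cpat_score": "float",
        "pfam_score": "float",
        "chrom": "str",
        "start": "int",
        "end": "int",
        "strand": "str",
    },
    "transcript_id",
)
LOCALIZATION_SCHEMA = TableSchema(
    "localization",
    {
        "lncrna_id": "str",
        "cytoplasm": "float",
        "nucleus": "float",
        "ribosome": "float",
        "cytosol": "float",
        "exosome": "float",
    },
    "lncrna_id",
)
MIRDB_SCHEMA = TableSchema(
    "mirdb",
    {
        "lncrna_id": "str",
        "mirna_id": "str",
        "target_score": "float",
        "conservation": "float",
    },
)
TARGETSCAN_SCHEMA = TableSchema(
    "targetscan", {"mirna_id": "str", "mrna_id": "str", "context_score": "float"}
)
MIRANDA_SCHEMA = TableSchema(
    "miranda",
    {
        "mirna_id": "str",
        "mrna_id": "str",
        "miranda_score": "float",
        "miranda_energy": "float",
    },
)
PPI_SCHEMA = TableSchema(
    "ppi", {"protein_a": "str", "protein_b": "str", "combined_score": "float"}
)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one table against ``schema``.

    Returns the rows coerced to the schema's dtypes, row order preserved,
    string cells whitespace-stripped.  Missing required columns raise a
    :class:`SchemaError` naming the column; an unparseable numeric cell
    raises a :class:`SchemaError` carrying its 1-based data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]

    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table {schema.name!r} ({path.name}): missing required column(s) "
            + ", ".join(repr(c) for c in missing)
        )
    for col, kind in schema.columns.items():
        if kind == "str":
            df[col] = df[col].astype(str).str.strip()
            continue
        coerced = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1  # 1-based data-row number
            raise SchemaError(
                f"table {schema.name!r} ({path.name}): unparseable numeric value "
                f"{df[col][bad.idxmax()]!r} in column {col!r}, data row {row}"
            )
        df[col] = coerced.astype(int) if kind == "int" else coerced
    # extra columns: try numeric coercion, keep as-is on failure
    for col in df.columns:
        if col not in schema.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if not (coerced.isna() & df[col].notna()).any():
                df[col] = coerced

    if schema.id_column is not None:
        dups = df[schema.id_column][df[schema.id_column].duplicated()].unique()
        if len(dups):
            warnings.warn(
                f"table {schema.name!r}: duplicate identifier(s) "
                + ", ".join(map(repr, dups[:5]))
                + ("..." if len(dups) > 5 else ""),
                DuplicateIdWarning,
                stacklevel=2,
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a count matrix (first column = feature id, rest = samples)."""
    df = pd.read_csv(Path(path), sep=_sniff_sep(Path(path)), comment="#", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return df


# --------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{term: [member, ...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        if len(parts) < 3:
            raise SchemaError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term, members in sets.items():
            fh.write("\t".join([term, term, *members]) + "\n")
    return path


# --------------------------------------------------------------------------
# typed network export

Dialect = Literal["sif", "graphml", "tsv"]


@dataclass
class NetworkExport:
    """A typed node list plus typed edge list, ready for a graph viewer.

    ``nodes``: columns (id, role, direction); ``edges``: columns
    (source, target, kind) plus optional provenance score columns.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def validate(self) -> None:
        known = set(self.nodes["id"])
        if len(known) != len(self.nodes):
            raise ValueError("duplicate node ids in network export")
        bad_role = set(self.nodes["role"]) - set(NODE_ROLES)
        if bad_role:
            raise ValueError(f"unknown node role(s): {sorted(bad_role)}")
        unknown = [
            (s, t)
            for s, t in zip(self.edges["source"], self.edges["target"])
            if s not in known or t not in known
        ]
        if unknown:
            raise ValueError(f"edge endpoints not in node list: {unknown[:5]}")
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("self-loop in network export")
        role_of = dict(zip(self.nodes["id"], self.nodes["role"]))
        for s, t in zip(self.edges["source"], self.edges["target"]):
            pair = frozenset({role_of[s], role_of[t]})
            if pair not in ALLOWED_EDGE_ROLES:
                raise ValueError(
                    f"edge {s!r}-{t!r} connects disallowed roles {sorted(pair)}"
                )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.id, role=row.role, direction=row.direction)
        score_cols = [c for c in self.edges.columns if c not in ("source", "target", "kind")]
        for row in self.edges.itertuples(index=False):
            attrs = {"kind": row.kind}
            for c in score_cols:
                v = getattr(row, c)
                if pd.notna(v):
                    attrs[c] = float(v)
            g.add_edge(row.source, row.target, **attrs)
        return g


def export_network(net: NetworkExport, path: str | Path, dialect: Dialect = "sif") -> Path:
    """Write ``net`` to ``path`` in the requested dialect.

    SIF lines are ``source<TAB>kind<TAB>target`` (node attributes go to a
    sidecar ``.nodes.tsv`` so the export stays loadable by generic viewers);
    GraphML carries node/edge attributes inline; the TSV dialect writes a
    ``.nodes.tsv`` / ``.edges.tsv`` pair.
    """
    net.validate()
    path = Path(path)
    if dialect == "sif":
        with open(path, "w") as fh:
            for row in net.edges.itertuples(index=False):
                fh.write(f"{row.source}\t{row.kind}\t{row.target}\n")
        write_table(net.nodes, path.with_suffix(path.suffix + ".nodes.tsv"))
    elif dialect == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif dialect == "tsv":
        write_table(net.nodes, path.with_suffix(".nodes.tsv"))
        write_table(net.edges, path.with_suffix(".edges.tsv"))
        return path
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")
    return path


def read_network(path: str | Path, dialect: Dialect = "sif") -> nx.Graph:
    """Read a network written by :func:`export_network` back into a graph."""
    path = Path(path)
    if dialect == "graphml":
        return nx.read_graphml(path)
    if dialect == "sif":
        g = nx.Graph()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            s, kind, t = line.split("\t")
            g.add_edge(s, t, kind=kind)
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        if nodes_path.exists():
            for row in pd.read_csv(nodes_path, sep="\t", dtype=str).itertuples(index=False):
                g.add_node(row.id, role=row.role, direction=row.direction)
        return g
    if dialect == "tsv":
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t", dtype=str)
        edges = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t")
        for c in ("source", "target", "kind"):
            edges[c] = edges[c].astype(str)
        return NetworkExport(nodes, edges).to_graph()
    raise ValueError(f"unknown network dialect {dialect!r}")


# --------------------------------------------------------------------------
# run manifest


def write_manifest(
    config: PipelineConfig,
    outdir: str | Path,
    inputs: Mapping[str, str] | None = None,
    stage_counts: Mapping[str, object] | None = None,
) -> Path:
    """Write a JSON manifest logging every threshold, the seed and inputs.

    A run is fully reproducible from (input files + config + seed); the
    manifest makes the applied configuration auditable after the fact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "inputs": dict(inputs or {}),
        "stage_counts": dict(stage_counts or {}),
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
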