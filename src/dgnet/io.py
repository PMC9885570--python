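"""Readers and writers for the on-disk formats the pipeline touches.

Formats: GMT gene-set libraries (term \\t description \\t member...), two-column
drug-target TSV, per-drug signature TSV (drug, gene, fc, p[, p_adj]),
gene-score TSV and GraphML network export.  All tabular output is
tab-separated UTF-8 with Unix newlines and a header row.

Identifier policy: drug and gene ids are opaque strings, normalized by
trimming whitespace and uppercasing, so matching is deterministic and needs
no external id-resolution service.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .network import LayeredNetwork, GeneScores, GeneSetPartition, LAYERS

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or column."""


def normalize_id(raw: str) -> str:
    """Trim whitespace and uppercase; ids are otherwise opaque."""
    return raw.strip().upper()


@dataclass(frozen=True)
class GeneSetLibrary:
    """A named collection of gene sets: term-id -> (description, members)."""

    name: str
    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"term {term!r} has an empty member set")

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    @property
    def terms(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class DrugTargetTable:
    """Binary drug -> target-gene membership (the t_ij incidence)."""

    pairs: frozenset[tuple[str, str]]

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SignatureTable:
    """Per-drug per-gene differential-expression records before thresholding.

    ``records`` is a DataFrame with columns ``drug, gene, fc, p, p_adj``
    (p / p_adj nullable).  Fold change is on the linear scale and positive;
    each (drug, gene) appears at most once and carries at least one p column.
    """

    records: pd.DataFrame = field(repr=False)

    _COLS = ("drug", "gene", "fc", "p", "p_adj")

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != list(self._COLS):
            raise ValueError(f"expected columns {self._COLS}, got {list(df.columns)}")
        if len(df):
            if (df["fc"] <= 0).any():
                bad = df.loc[df["fc"] <= 0].iloc[0]
                raise ValueError(
                    f"fold change must be positive on the linear scale; "
                    f"got fc={bad['fc']} for ({bad['drug']}, {bad['gene']})"
                )
            both_missing = df["p"].isna() & df["p_adj"].isna()
            if both_missing.any():
                bad = df.loc[both_missing].iloc[0]
                raise ValueError(
                    f"record ({bad['drug']}, {bad['gene']}) carries neither p nor p_adj"
                )
            for col in ("p", "p_adj"):
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"column {col} outside [0, 1]")
            dup = df.duplicated(subset=["drug", "gene"])
            if dup.any():
                pairs = df.loc[dup, ["drug", "gene"]].itertuples(index=False)
                raise ValueError(
                    "duplicate (drug, gene) records: "
                    + ", ".join(f"({d}, {g})" for d, g in list(pairs)[:5])
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self.records["drug"])


def _empty_signature_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug": pd.Series(dtype=str),
            "gene": pd.Series(dtype=str),
            "fc": pd.Series(dtype=float),
            "p": pd.Series(dtype=float),
            "p_adj": pd.Series(dtype=float),
        }
    )


def make_signature_table(
    rows: Iterable[tuple[str, str, float, float | None, float | None]],
) -> SignatureTable:
    """Construct a SignatureTable from (drug, gene, fc, p, p_adj) tuples."""
    rows = list(rows)
    if not rows:
        return SignatureTable(_empty_signature_frame())
    df = pd.DataFrame(rows, columns=["drug", "gene", "fc", "p", "p_adj"])
    df["drug"] = df["drug"].map(normalize_id)
    df["gene"] = df["gene"].map(normalize_id)
    for col in ("fc", "p", "p_adj"):
        df[col] = pd.to_numeric(df[col])
    return SignatureTable(df)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: one gene set per line, ``term \\t description \\t member...``.

    Duplicate members within a line are collapsed; a duplicate term-id or a
    line with fewer than 3 fields is a :class:`ParseError` naming the line.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            term = fields[0].strip()
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = frozenset(
                normalize_id(m) for m in fields[2:] if m.strip()
            )
            if not members:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = (fields[1], members)
    return GeneSetLibrary(name=name or path.stem, sets=sets)


def write_gmt(library: GeneSetLibrary | Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write a GMT library (or a bare mapping term -> members, description '.')."""
    path = Path(path)
    if isinstance(library, GeneSetLibrary):
        items = [(t, d, sorted(m)) for t, (d, m) in library.sets.items()]
    else:
        items = [(t, ".", sorted(m)) for t, m in library.items()]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for term, desc, members in items:
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Drug-target tables

def read_drug_target_table(path: str | Path, dialect: str = "two-column-tsv") -> DrugTargetTable:
    """Read a binary drug->target table in GMT or two-column TSV dialect.

    Repeated (drug, gene) rows are deduplicated (the model is binary); rows
    with a blank gene id are rejected with a logged warning count.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    n_rejected = 0
    if dialect == "gmt":
        lib = read_gmt(path)
        for drug, (_, members) in lib.sets.items():
            for gene in members:
                pairs.add((normalize_id(drug), gene))
                n_rows += 1
    elif dialect == "two-column-tsv":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if lineno == 1 and [f.strip().lower() for f in line.split("\t")[:2]] == ["drug", "gene"]:
                    continue  # optional header row
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                    )
                n_rows += 1
                drug, gene = normalize_id(fields[0]), normalize_id(fields[1])
                if not drug or not gene:
                    n_rejected += 1
                    continue
                pairs.add((drug, gene))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'gmt' or 'two-column-tsv'")
    if n_rows == 0:
        raise ParseError(f"{path}: empty drug-target table")
    table = DrugTargetTable(frozenset(pairs))
    logger.info(
        "read %s: %d rows -> %d pairs (%d drugs, %d genes, %d rejected)",
        path, n_rows, len(table), len(table.drugs), len(table.genes), n_rejected,
    )
    return table


def write_drug_target_table(table: DrugTargetTable, path: str | Path) -> None:
    """Write the two-column TSV dialect (drug \\t gene), sorted, with header."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug\tgene\n")
        for drug, gene in sorted(table.pairs):
            fh.write(f"{drug}\t{gene}\n")


# ---------------------------------------------------------------------------
# Signature tables

_SIG_ALIASES = {
    "drug": {"drug", "drug_id", "compound"},
    "gene": {"gene", "gene_id", "symbol"},
    "fc": {"fc", "fold_change", "foldchange"},
    "p": {"p", "pvalue", "p_value"},
    "p_adj": {"p_adj", "padj", "adj_p", "adjusted_p", "fdr", "qvalue"},
}


def read_signature_table(path: str | Path) -> SignatureTable:
    """Read a signature TSV with header columns drug, gene, fc and >=1 p column.

    Rows with non-numeric fc/p are rejected and counted; duplicated
    (drug, gene) rows are a hard error (ambiguous statistics).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    colmap: dict[str, str] = {}
    for canonical, aliases in _SIG_ALIASES.items():
        hits = [c for c in raw.columns if c.strip().lower() in aliases]
        if hits:
            colmap[canonical] = hits[0]
    for required in ("drug", "gene", "fc"):
        if required not in colmap:
            raise ParseError(f"{path}: missing mandatory column {required!r}")
    if "p" not in colmap and "p_adj" not in colmap:
        raise ParseError(f"{path}: need at least one of a p / adjusted-p column")

    df = pd.DataFrame(
        {
            "drug": raw[colmap["drug"]].map(normalize_id),
            "gene": raw[colmap["gene"]].map(normalize_id),
            "fc": pd.to_numeric(raw[colmap["fc"]], errors="coerce"),
            "p": pd.to_numeric(raw[colmap["p"]], errors="coerce")
            if "p" in colmap
            else float("nan"),
            "p_adj": pd.to_numeric(raw[colmap["p_adj"]], errors="coerce")
            if "p_adj" in colmap
            else float("nan"),
        }
    )
    ok = df["fc"].notna() & (df["p"].notna() | df["p_adj"].notna()) & (df["fc"] > 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d rows with non-numeric/invalid fc or p", path, n_rejected)
    if (df.loc[df["fc"].notna(), "fc"] <= 0).any():
        logger.warning("%s: non-positive fold changes found; fc must be linear-scale", path)
    df = df.loc[ok].reset_index(drop=True)
    table = SignatureTable(df)
    logger.info("read %s: %d records (%d rejected)", path, len(table), n_rejected)
    return table


def write_signature_table(table: SignatureTable, path: str | Path) -> None:
    df = table.records.sort_values(["drug", "gene"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(
    network: LayeredNetwork,
    path: str | Path,
    partition: GeneSetPartition | None = None,
) -> None:
    """GraphML export with node attrs kind/set and edge attr layer."""
    nx.write_graphml(network.to_networkx(partition), str(path))


def read_graphml(path: str | Path) -> LayeredNetwork:
    """Read back a GraphML file written by :func:`write_graphml`."""
    graph = nx.read_graphml(str(path), force_multigraph=True)
    drugs, genes = set(), set()
    for node, attrs in graph.nodes(data=True):
        kind = attrs.get("kind")
        if kind == "drug":
            drugs.add(node)
        elif kind == "gene":
            genes.add(node)
        else:
            raise ParseError(f"{path}: node {node!r} has kind {kind!r}, expected drug/gene")
    edges = set()
    for u, v, attrs in graph.edges(data=True):
        layer = attrs.get("layer")
        if layer not in LAYERS:
            raise ParseError(f"{path}: edge ({u}, {v}) has layer {layer!r}")
        drug, gene = (u, v) if u in drugs else (v, u)
        edges.add((drug, gene, layer))
    return LayeredNetwork(frozenset(edges), frozenset(drugs), frozenset(genes))


# ---------------------------------------------------------------------------
# Gene scores

def write_gene_scores(
    scores: GeneScores,
    path: str | Path,
    partition: GeneSetPartition | None = None,
) -> None:
    """TSV with columns gene, KDTN, KDSN, set; one row per gene, sorted by gene id."""
    labels = partition.labels() if partition is not None else {}
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tKDTN\tKDSN\tset\n")
        for g in sorted(scores.genes):
            fh.write(f"{g}\t{scores.kdtn[g]}\t{scores.kdsn[g]}\t{labels.get(g, 'none')}\n")


def read_gene_scores(path: str | Path) -> tuple[GeneScores, GeneSetPartition | None]:
    """Read back a gene-score TSV; returns scores and the partition if labelled."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "KDTN", "KDSN", "set"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    scores = GeneScores(
        kdtn=dict(zip(df["gene"], df["KDTN"].astype(int))),
        kdsn=dict(zip(df["gene"], df["KDSN"].astype(int))),
    )
    if (df["set"] == "none").all():
        return scores, None
    part = GeneSetPartition(
        dtg=frozenset(df.loc[df["set"] == "DTG", "gene"]),
        dsg=frozenset(df.loc[df["set"] == "DSG", "gene"]),
        dtsg=frozenset(df.loc[df["set"] == "DTSG", "gene"]),
    )
    return scores, part
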