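"""Readers and writers for the external formats the pipeline touches.

GTF (exon features only), FASTA (via Biopython), tab-separated expression
and verdict tables (via pandas), and SIF / GraphML network exports (GraphML
via networkx). All genomic coordinates are 1-based closed.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionMatrix, NetworkEdge, SequenceSet, Transcript

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

VERDICT_COLUMNS = ("cpc", "pfam", "phylocsf", "cnci")


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path) -> list[Transcript]:
    """Parse exon features of a GTF file into :class:`Transcript` models.

    Non-exon features and comment lines are ignored. The ``class_code``
    attribute defaults to "=" (annotated match) when absent; ``biotype``
    defaults to "unclassified". Exons are sorted and overlapping intervals
    merged. Returns transcripts sorted by id.
    """
    path = Path(path)
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: exon start {start} > end {end}")
            attrs = dict(_ATTR_RE.findall(attrs_s))
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing transcript_id/gene_id attribute")
            tid = attrs["transcript_id"]
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "class_code": attrs.get("class_code", "="),
                    "biotype": attrs.get("biotype", "unclassified"),
                    "exons": [],
                },
            )
            rec["exons"].append((start, end))
    out = []
    for tid in sorted(per_tx):
        rec = per_tx[tid]
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=_merge_exons(rec["exons"]),
                class_code=rec["class_code"],
                biotype=rec["biotype"],
            )
        )
    return out


def _merge_exons(exons: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(exons):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def write_gtf(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write one GTF exon line per exon, carrying class_code and biotype."""
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: t.transcript_id):
            for start, end in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'class_code "{tx.class_code}"; biotype "{tx.biotype}";'
                )
                fh.write(
                    f"{tx.chrom}\tlncnet\texon\t{start}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> SequenceSet:
    """Load FASTA into a :class:`SequenceSet` (upper-cased, U normalized to T)."""
    return SequenceSet.from_pairs(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    )


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression tables

def read_expression_table(
    path: str | Path,
    design: Mapping[str, tuple[str, int]],
    counts_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column = feature ids).

    The columns must match the design's sample ids exactly; negative values
    and duplicate feature ids are rejected.
    """
    fpkm = _read_feature_table(path)
    counts = _read_feature_table(counts_path) if counts_path is not None else None
    return ExpressionMatrix(fpkm=fpkm, design=dict(design), counts=counts)


def _read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    if df.size and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", index_label="feature_id", float_format=float_format)


def write_design(design: Mapping[str, tuple[str, int]], path: str | Path) -> None:
    rows = [
        {"sample_id": s, "stage": st, "replicate": rep} for s, (st, rep) in design.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> dict[str, tuple[str, int]]:
    df = pd.read_csv(path, sep="\t")
    return {r.sample_id: (r.stage, int(r.replicate)) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Coding-potential verdicts

def read_verdicts(path: str | Path) -> pd.DataFrame:
    """Read the four-predictor verdict table (transcript_id + one column per tool).

    Values must be 'coding' or 'noncoding' in every predictor column.
    """
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    missing = [c for c in VERDICT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing verdict columns {missing}")
    bad = df[list(VERDICT_COLUMNS)].stack().loc[
        lambda s: ~s.isin(["coding", "noncoding"])
    ]
    if len(bad):
        raise ValueError(f"{path}: invalid verdict values {sorted(set(bad))}")
    return df[list(VERDICT_COLUMNS)]


def write_verdicts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Networks

def write_network(edges: Sequence[NetworkEdge], path: str | Path, format: str = "SIF") -> None:
    """Export edges as SIF ('source<TAB>type<TAB>target') or GraphML.

    GraphML uses a directed multigraph so parallel edges of different types
    survive a round trip.
    """
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.source}\t{e.edge_type}\t{e.target}\n")
    elif fmt == "GRAPHML":
        g = nx.MultiDiGraph()
        for e in edges:
            attrs = {"edge_type": e.edge_type}
            if e.weight is not None:
                attrs["weight"] = float(e.weight)
            g.add_edge(e.source, e.target, **attrs)
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r} (use SIF or GraphML)")


def read_network(path: str | Path, format: str = "SIF") -> list[NetworkEdge]:
    fmt = format.upper()
    edges: list[NetworkEdge] = []
    if fmt == "SIF":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                source, edge_type, target = line.split("\t")
                edges.append(NetworkEdge(source, target, edge_type))
    elif fmt == "GRAPHML":
        g = nx.read_graphml(str(path), force_multigraph=True)
        for source, target, data in g.edges(data=True):
            weight = data.get("weight")
            edges.append(
                NetworkEdge(
                    str(source),
                    str(target),
                    data["edge_type"],
                    float(weight) if weight is not None else None,
                )
            )
    else:
        raise ValueError(f"unknown network format {format!r} (use SIF or GraphML)")
    return edges
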