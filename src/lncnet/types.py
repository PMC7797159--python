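"""Shared domain types for the lncRNA analysis pipeline.

Coordinates are 1-based closed intervals throughout (GTF convention).
Expression is carried as FPKM (fragments per kilobase of exon per million
mapped fragments), optionally alongside raw counts for count-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Developmental stages of the 12-sample design (weeks post-hatch).
STAGES = ("W6", "W14", "W22", "W30")

#: Replicates per stage.
N_REPLICATES = 3

#: The six ordered stage comparisons, numerator vs denominator.
COMPARISONS = (
    ("W14", "W6"),
    ("W22", "W14"),
    ("W22", "W6"),
    ("W30", "W6"),
    ("W30", "W14"),
    ("W30", "W22"),
)


def comparison_label(numerator: str, denominator: str) -> str:
    return f"{numerator}v{denominator}"


#: Labels of the six comparison groups, in canonical order.
COMPARISON_LABELS = tuple(comparison_label(a, b) for a, b in COMPARISONS)

BIOTYPES = ("mRNA", "lncRNA_annotated", "lncRNA_novel", "TUCP", "unclassified")

EDGE_TYPES = ("cis", "trans", "mirna_lncrna", "mirna_mrna", "ppi")


@dataclass(frozen=True)
class Transcript:
    """A stranded, exon-structured transcript model.

    ``exons`` is an ordered tuple of 1-based closed ``(start, end)`` intervals,
    sorted by start and non-overlapping. ``class_code`` is the single-character
    cuffcompare-style relation to the reference annotation ("=" exact match,
    "u" intergenic, "x" antisense exonic overlap, ...).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    class_code: str = "="
    biotype: str = "unclassified"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start < 1:
                raise ValueError(f"{self.transcript_id}: exon start {start} < 1")
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ExpressionMatrix:
    """Features x samples expression with the stage/replicate design.

    ``design`` maps each sample id to ``(stage, replicate)``. Every stage must
    carry exactly :data:`N_REPLICATES` samples. ``fpkm`` holds non-negative
    expression; ``counts`` optionally holds non-negative integer counts on the
    same index and columns.
    """

    fpkm: pd.DataFrame
    design: dict[str, tuple[str, int]]
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.fpkm.index.duplicated().any():
            dups = self.fpkm.index[self.fpkm.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        missing = [s for s in self.fpkm.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples not in design: {missing}")
        absent = [s for s in self.design if s not in self.fpkm.columns]
        if absent:
            raise ValueError(f"design samples missing from table: {absent}")
        per_stage: dict[str, int] = {}
        for stage, _rep in self.design.values():
            per_stage[stage] = per_stage.get(stage, 0) + 1
        bad = {s: n for s, n in per_stage.items() if n != N_REPLICATES}
        if bad:
            raise ValueError(f"every stage needs exactly {N_REPLICATES} samples, got {bad}")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        if self.counts is not None:
            arr = self.counts.to_numpy()
            if (arr < 0).any():
                raise ValueError("negative counts")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def samples_for_stage(self, stage: str) -> list[str]:
        return [s for s, (st, _r) in self.design.items() if st == stage]

    def stage_means(self) -> pd.DataFrame:
        """Mean FPKM per stage (features x stages)."""
        stages = sorted({st for st, _ in self.design.values()},
                        key=lambda s: STAGES.index(s) if s in STAGES else 99)
        return pd.DataFrame(
            {st: self.fpkm[self.samples_for_stage(st)].mean(axis=1) for st in stages}
        )

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        counts = self.counts.loc[ids] if self.counts is not None else None
        return ExpressionMatrix(self.fpkm.loc[ids], dict(self.design), counts)


class SequenceSet(dict):
    """Mapping of sequence id -> nucleotide string over {A,C,G,T,N}.

    U is normalized to T on insertion so RNA (miRNA) and DNA (transcript)
    alphabets compare directly; sequences are upper-cased.
    """

    _ALLOWED = frozenset("ACGTN")

    def __setitem__(self, key: str, seq: str) -> None:
        norm = seq.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"{key}: empty sequence")
        bad = set(norm) - self._ALLOWED
        if bad:
            raise ValueError(f"{key}: invalid characters {sorted(bad)}")
        super().__setitem__(key, norm)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        out = cls()
        for key, seq in pairs:
            if key in out:
                raise ValueError(f"duplicate sequence id {key!r}")
            out[key] = seq
        return out


@dataclass(frozen=True, order=True)
class NetworkEdge:
    """A typed edge in an exported interaction network."""

    source: str
    target: str
    edge_type: str
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.edge_type == "ppi" and self.source == self.target:
            raise ValueError(f"ppi self-edge on {self.source!r}")


@dataclass(frozen=True, order=True)
class TargetPair:
    """A lncRNA -> gene regulatory link, by proximity (cis) or correlation (trans)."""

    lncrna_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    distance_bp: Optional[int] = None
    r: Optional[float] = None
    group: str = "global"

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.lncrna_id == self.gene_id:
            raise ValueError(f"self-target {self.lncrna_id!r}")


@dataclass(frozen=True, order=True)
class CeRNATriad:
    """A lncRNA-miRNA-mRNA competing-endogenous-RNA triple within one comparison."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    group: str


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, optionally with its hairpin precursor sequence."""

    mirna_id: str
    mature_seq: str
    precursor_id: Optional[str] = None
    precursor_seq: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", self.mature_seq.upper().replace("U", "T"))
        if self.precursor_seq is not None:
            object.__setattr__(
                self, "precursor_seq", self.precursor_seq.upper().replace("U", "T")
            )


@dataclass(frozen=True, order=True)
class HomologyHit:
    """An exact occurrence of a pre-miRNA inside a host lncRNA (1-based closed)."""

    lncrna_id: str
    precursor_id: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneSet:
    """A named annotation term (GO/pathway) with its member genes."""

    term_id: str
    term_name: str
    namespace: str  # GO_BP | GO_MF | GO_CC | pathway
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term_id}: empty gene set")
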