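"""The five-step lncRNA screening cascade and transcript characterization.

Candidates from a merged assembly are screened in order: (1) exon number
>= 2; (2) spliced length > 200 bp; (3) removal of transcripts whose
cuffcompare class code marks exonic overlap with annotated protein-coding
exons, with transcripts matching annotated lncRNAs routed straight to the
output; (4) maximum FPKM across samples >= 0.5; (5) coding-potential
consensus over four predictors - all four noncoding gives a novel lncRNA,
any coding verdict gives a transcript of uncertain coding potential (TUCP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SequenceSet, Transcript

logger = logging.getLogger(__name__)

#: cuffcompare codes denoting exonic overlap with reference annotation.
OVERLAP_CLASS_CODES = frozenset({"=", "c", "j", "e", "o"})

STEP_LABELS = ("exon", "length", "overlap", "expression", "coding_potential")

OUTCOME_REMOVED = "removed"
OUTCOME_LNCRNA = "retained as lncRNA"
OUTCOME_TUCP = "retained as TUCP"
OUTCOME_ANNOTATED = "annotated lncRNA"


@dataclass
class FilterReport:
    """Per-transcript record of the cascade outcome.

    ``records`` maps transcript_id -> (outcome, step) where step is the
    removing step label for removed transcripts and None otherwise.
    """

    records: dict[str, tuple[str, Optional[str]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "outcome": o, "step": s or ""}
            for t, (o, s) in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "outcome", "step"])

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for outcome, step in self.records.values():
            key = f"removed:{step}" if outcome == OUTCOME_REMOVED else outcome
            out[key] = out.get(key, 0) + 1
        return out


def filter_cascade(
    transcripts: Iterable[Transcript],
    expression: ExpressionMatrix,
    verdicts: pd.DataFrame,
    annotated_lncrna_ids: Iterable[str] = (),
    min_exons: int = 2,
    min_length: int = 200,
    min_fpkm: float = 0.5,
    overlap_codes: frozenset[str] = OVERLAP_CLASS_CODES,
) -> tuple[list[Transcript], list[Transcript], FilterReport]:
    """Run the screening cascade.

    Returns ``(lncrnas, tucps, report)`` where ``lncrnas`` contains both the
    novel lncRNAs (all four predictors noncoding) and the transcripts routed
    as annotated lncRNAs at the overlap step; biotypes on the returned
    transcripts are set accordingly. The three outputs partition the input.

    Length is strict (> ``min_length``); the FPKM rule is inclusive
    (max across samples >= ``min_fpkm``). A transcript surviving steps 1-4
    without a verdicts row raises ``KeyError`` naming it.
    """
    annotated = set(annotated_lncrna_ids)
    report = FilterReport()
    lncrnas: list[Transcript] = []
    tucps: list[Transcript] = []
    max_fpkm = expression.fpkm.max(axis=1)

    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        tid = tx.transcript_id
        if tx.n_exons < min_exons:
            report.records[tid] = (OUTCOME_REMOVED, "exon")
            continue
        if tx.length <= min_length:
            report.records[tid] = (OUTCOME_REMOVED, "length")
            continue
        if tx.class_code in overlap_codes:
            if tid in annotated:
                report.records[tid] = (OUTCOME_ANNOTATED, None)
                lncrnas.append(_with_biotype(tx, "lncRNA_annotated"))
            else:
                report.records[tid] = (OUTCOME_REMOVED, "overlap")
            continue
        if tid not in max_fpkm.index or max_fpkm[tid] < min_fpkm:
            report.records[tid] = (OUTCOME_REMOVED, "expression")
            continue
        if tid not in verdicts.index:
            raise KeyError(f"transcript {tid!r} survived filtering but has no coding-potential verdicts")
        row = verdicts.loc[tid]
        if (row == "noncoding").all():
            report.records[tid] = (OUTCOME_LNCRNA, None)
            lncrnas.append(_with_biotype(tx, "lncRNA_novel"))
        else:
            report.records[tid] = (OUTCOME_TUCP, None)
            tucps.append(_with_biotype(tx, "TUCP"))
    return lncrnas, tucps, report


def _with_biotype(tx: Transcript, biotype: str) -> Transcript:
    if tx.biotype == biotype:
        return tx
    return Transcript(
        tx.transcript_id, tx.gene_id, tx.chrom, tx.strand, tx.exons, tx.class_code, biotype
    )


def classify_lncrna(lncrnas: Iterable[Transcript]) -> dict[str, str]:
    """Classify surviving lncRNAs: class code "u" -> lincRNA, "x" -> antisense.

    Any other class code raises ``ValueError`` listing the offending ids;
    surviving transcripts are expected to carry only these two codes.
    """
    out: dict[str, str] = {}
    bad: list[str] = []
    for tx in lncrnas:
        if tx.class_code == "u":
            out[tx.transcript_id] = "lincRNA"
        elif tx.class_code == "x":
            out[tx.transcript_id] = "antisense"
        else:
            bad.append(tx.transcript_id)
    if bad:
        raise ValueError(f"unexpected class codes on lncRNAs: {sorted(bad)}")
    return out


def count_orfs(seq: str, min_codons: int = 30) -> int:
    """Count ATG-initiated, stop-terminated open reading frames.

    An ORF is an ATG whose nearest in-frame stop codon lies at least
    ``min_codons`` codons downstream (stop excluded), scanned over the three
    forward frames of the spliced sequence. Every qualifying ATG counts,
    including nested starts.
    """
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    n = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        next_stop: list[Optional[int]] = [None] * len(codons)
        last = None
        for i in range(len(codons) - 1, -1, -1):
            if codons[i] in stops:
                last = i
            next_stop[i] = last
        for i, codon in enumerate(codons):
            if codon == "ATG" and next_stop[i] is not None and next_stop[i] - i >= min_codons:
                n += 1
    return n


_LENGTH_BINS = np.array([200, 400, 600, 800, 1000, 1500, 2000, 3000, 5000, 10_000, np.inf])
_EXON_BINS = np.array([1, 2, 3, 4, 5, 6, 8, 10, 15, 20, np.inf])
_ORF_BINS = np.array([0, 1, 2, 3, 4, 5, 7, 10, np.inf])


def characterize(
    transcripts_by_biotype: Mapping[str, Sequence[Transcript]],
    sequences: SequenceSet,
    expression: ExpressionMatrix,
    min_codons: int = 30,
) -> dict[str, pd.DataFrame]:
    """Per-biotype distributions of length, exon count, ORF count and expression.

    Returns a mapping with a ``values`` table (one row per transcript) and
    histogram tables with stated bin edges for each statistic. Transcripts
    without a sequence get a missing ORF count and a logged warning.
    """
    rows = []
    for biotype, txs in transcripts_by_biotype.items():
        for tx in txs:
            tid = tx.transcript_id
            seq = sequences.get(tid)
            if seq is None:
                logger.warning("no sequence for %s; ORF count recorded as missing", tid)
                orfs = np.nan
            else:
                orfs = count_orfs(seq, min_codons=min_codons)
            fpkm = (
                float(expression.fpkm.loc[tid].mean())
                if tid in expression.fpkm.index
                else np.nan
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "biotype": biotype,
                    "length": tx.length,
                    "n_exons": tx.n_exons,
                    "n_orfs": orfs,
                    "mean_fpkm": fpkm,
                }
            )
    values = pd.DataFrame(
        rows, columns=["transcript_id", "biotype", "length", "n_exons", "n_orfs", "mean_fpkm"]
    )
    out: dict[str, pd.DataFrame] = {"values": values}
    for col, bins in (("length", _LENGTH_BINS), ("n_exons", _EXON_BINS), ("n_orfs", _ORF_BINS)):
        hists = {}
        for biotype, sub in values.groupby("biotype"):
            counts, _ = np.histogram(sub[col].dropna(), bins=bins)
            hists[biotype] = counts
        edges = [f"[{bins[i]:g},{bins[i+1]:g})" for i in range(len(bins) - 1)]
        out[f"{col}_hist"] = pd.DataFrame(hists, index=pd.Index(edges, name="bin"))
    return out
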