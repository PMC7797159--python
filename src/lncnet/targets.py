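"""Cis and trans target-gene prediction for lncRNAs.

Cis: a gene is a cis target of a lncRNA when both lie on the same
chromosome and the gap between their genomic spans (first exon start to
last exon end, strand ignored) is at most a fixed window, 100 kb by
default; overlapping spans count as distance 0. Trans: a gene is a trans
target when the Pearson correlation of the two expression profiles across
the samples strictly exceeds a threshold (0.95 by default, signed - only
positive co-expression qualifies; an absolute-value mode is available).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, TargetPair, Transcript

logger = logging.getLogger(__name__)


def span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two 1-based closed spans; 0 if they overlap or touch."""
    if a[0] > b[0]:
        a, b = b, a
    return max(0, b[0] - a[1] - 1)


def cis_targets(
    lncrnas: Iterable[Transcript],
    genes: Iterable[Transcript],
    window_bp: int = 100_000,
    group: str = "global",
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs within ``window_bp`` of each other (inclusive)."""
    by_chrom: dict[str, list[Transcript]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[TargetPair] = []
    for lnc in sorted(lncrnas, key=lambda t: t.transcript_id):
        lspan = lnc.span
        for g in by_chrom.get(lnc.chrom, ()):
            if g.transcript_id == lnc.transcript_id:
                continue
            gap = span_gap(lspan, g.span)
            if gap <= window_bp:
                pairs.append(
                    TargetPair(
                        lncrna_id=lnc.transcript_id,
                        gene_id=g.transcript_id,
                        mode="cis",
                        distance_bp=gap,
                        group=group,
                    )
                )
    pairs.sort()
    return pairs


def trans_targets(
    expr: ExpressionMatrix,
    lncrna_ids: Iterable[str],
    gene_ids: Iterable[str],
    r_threshold: float = 0.95,
    absolute: bool = False,
    group: str = "global",
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs with Pearson r strictly above ``r_threshold``.

    Correlation is computed across all samples of ``expr``. Features with
    zero variance are skipped with a logged warning; ids absent from the
    matrix raise ``KeyError``.
    """
    lnc_ids = sorted(set(lncrna_ids))
    gen_ids = sorted(set(gene_ids))
    missing = [i for i in lnc_ids + gen_ids if i not in expr.fpkm.index]
    if missing:
        raise KeyError(f"ids missing from expression matrix: {missing}")

    lmat = expr.fpkm.loc[lnc_ids].to_numpy(dtype=float)
    gmat = expr.fpkm.loc[gen_ids].to_numpy(dtype=float)

    def _standardize(mat: np.ndarray, ids: Sequence[str]) -> tuple[np.ndarray, list[int]]:
        centered = mat - mat.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        keep = []
        for i, s in enumerate(sd):
            if s == 0:
                logger.warning("zero variance for %s; skipped in trans prediction", ids[i])
            else:
                keep.append(i)
        out = centered[keep] / sd[keep, None]
        return out, keep

    lz, lkeep = _standardize(lmat, lnc_ids)
    gz, gkeep = _standardize(gmat, gen_ids)
    if not len(lkeep) or not len(gkeep):
        return []
    rmat = lz @ gz.T / lz.shape[1]

    pairs: list[TargetPair] = []
    for i, li in enumerate(lkeep):
        for j, gj in enumerate(gkeep):
            if lnc_ids[li] == gen_ids[gj]:
                continue
            r = float(rmat[i, j])
            val = abs(r) if absolute else r
            if val > r_threshold:
                pairs.append(
                    TargetPair(
                        lncrna_id=lnc_ids[li],
                        gene_id=gen_ids[gj],
                        mode="trans",
                        r=r,
                        group=group,
                    )
                )
    pairs.sort()
    return pairs


def pairs_to_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "mode": p.mode,
                "distance_bp": p.distance_bp if p.distance_bp is not None else "",
                "r": p.r if p.r is not None else "",
                "group": p.group,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "gene_id", "mode", "distance_bp", "r", "group"],
    )
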