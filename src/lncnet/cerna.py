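"""Competing-endogenous-RNA (ceRNA) triad assembly.

A triad (lncRNA, miRNA, mRNA) exists in a comparison group when the miRNA
is differentially expressed in that group, both the lncRNA and the mRNA
are ceRNA-grade DE (q < 0.05, |log2FC| >= 1) in it, and the miRNA targets
both. The triad set is exactly the relational join of the three membership
sets with the two target-pair tables. The per-gene "network count" used in
reporting is the number of distinct (lncRNA, miRNA) pairs among a gene's
triads.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .types import CeRNATriad, NetworkEdge

logger = logging.getLogger(__name__)


def build_triads(
    de_lncrnas: Iterable[str],
    de_mrnas: Iterable[str],
    de_mirnas: Iterable[str],
    mirna_lncrna_pairs: Iterable[tuple[str, str]],
    mirna_mrna_pairs: Iterable[tuple[str, str]],
    group: str,
    require_anticorrelation: bool = False,
    de_direction: dict[str, float] | None = None,
) -> list[CeRNATriad]:
    """Assemble deduplicated triads in deterministic lexicographic order.

    ``mirna_*_pairs`` are (mirna_id, target_id) tuples. Pairs referencing
    features outside the DE sets are silently excluded (logged in summary).
    With ``require_anticorrelation`` the miRNA's DE direction (from
    ``de_direction``: feature_id -> log2FC) must oppose both partners; the
    default leaves this filter off.
    """
    lnc = set(de_lncrnas)
    mrna = set(de_mrnas)
    mir = set(de_mirnas)

    ml = {(m, t) for m, t in mirna_lncrna_pairs}
    mg = {(m, t) for m, t in mirna_mrna_pairs}
    n_dropped = sum(1 for m, t in ml if m not in mir or t not in lnc) + sum(
        1 for m, t in mg if m not in mir or t not in mrna
    )
    if n_dropped:
        logger.info("%s: %d target pairs referenced features outside the DE sets", group, n_dropped)

    lnc_of: dict[str, set[str]] = {}
    for m, t in ml:
        if m in mir and t in lnc:
            lnc_of.setdefault(m, set()).add(t)
    mrna_of: dict[str, set[str]] = {}
    for m, t in mg:
        if m in mir and t in mrna:
            mrna_of.setdefault(m, set()).add(t)

    triads: set[CeRNATriad] = set()
    for m in mir:
        for l in lnc_of.get(m, ()):
            for g in mrna_of.get(m, ()):
                if require_anticorrelation and de_direction is not None:
                    dm = de_direction.get(m, 0.0)
                    if not (dm * de_direction.get(l, 0.0) < 0 and dm * de_direction.get(g, 0.0) < 0):
                        continue
                triads.add(CeRNATriad(l, m, g, group))
    return sorted(triads)


def per_gene_network_count(triads: Iterable[CeRNATriad]) -> dict[str, int]:
    """Distinct (lncRNA, miRNA) pair count per mRNA across its triads."""
    pairs: dict[str, set[tuple[str, str]]] = {}
    for t in triads:
        pairs.setdefault(t.mrna_id, set()).add((t.lncrna_id, t.mirna_id))
    return {g: len(s) for g, s in sorted(pairs.items())}


def triads_to_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lncrna_id": t.lncrna_id, "mirna_id": t.mirna_id, "mrna_id": t.mrna_id, "group": t.group}
            for t in triads
        ],
        columns=["lncrna_id", "mirna_id", "mrna_id", "group"],
    )


def triads_to_edges(triads: Iterable[CeRNATriad]) -> list[NetworkEdge]:
    """Network export: miRNA->lncRNA and miRNA->mRNA edges, deduplicated."""
    edges: set[NetworkEdge] = set()
    for t in triads:
        edges.add(NetworkEdge(t.mirna_id, t.lncrna_id, "mirna_lncrna"))
        edges.add(NetworkEdge(t.mirna_id, t.mrna_id, "mirna_mrna"))
    return sorted(edges)
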