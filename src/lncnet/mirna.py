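"""miRNA interactions: seed-match target prediction and precursor homology.

Target prediction uses the canonical 7-mer seed: a miRNA targets a
transcript when the reverse complement of mature positions 2-8 occurs at
least once in the transcript sequence; every site start is reported
(1-based). Precursor homology reports every exact forward-strand occurrence
of a pre-miRNA sequence inside a lncRNA, with 1-based inclusive
coordinates; a reverse-complement search mode exists but is off by default
because the biological signal of interest is a lncRNA literally containing
the hairpin.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .types import HomologyHit, MiRNA, SequenceSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


def seed_site(mature_seq: str, seed_start: int = 2, seed_end: int = 8) -> str:
    """Target-site motif: reverse complement of mature positions 2-8 (1-based)."""
    seq = mature_seq.upper().replace("U", "T")
    if len(seq) < seed_end:
        raise ValueError(f"mature sequence shorter than {seed_end} nt")
    return reverse_complement(seq[seed_start - 1 : seed_end])


def find_occurrences(haystack: str, needle: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence."""
    positions = []
    start = haystack.find(needle)
    while start != -1:
        positions.append(start + 1)
        start = haystack.find(needle, start + 1)
    return positions


def predict_targets(
    mirnas: Iterable[MiRNA],
    sequences: Mapping[str, str],
    target_kind: str,
    seed_start: int = 2,
    seed_end: int = 8,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Seed-match target pairs: one row per (miRNA, target) with site starts.

    Columns: mirna_id, target_id, target_kind, site_positions (list of
    1-based starts). A pair is emitted when the target carries at least
    ``min_sites`` seed-complement sites.
    """
    if target_kind not in ("lncRNA", "mRNA"):
        raise ValueError(f"target_kind must be 'lncRNA' or 'mRNA', got {target_kind!r}")
    rows = []
    for m in sorted(mirnas, key=lambda m: m.mirna_id):
        site = seed_site(m.mature_seq, seed_start, seed_end)
        for tid in sorted(sequences):
            seq = sequences[tid].upper().replace("U", "T")
            positions = find_occurrences(seq, site)
            if len(positions) >= min_sites:
                rows.append(
                    {
                        "mirna_id": m.mirna_id,
                        "target_id": tid,
                        "target_kind": target_kind,
                        "site_positions": positions,
                    }
                )
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_kind", "site_positions"])


def precursor_homology(
    lncrna_seqs: Mapping[str, str],
    precursors: Iterable[MiRNA],
    search_reverse_complement: bool = False,
) -> list[HomologyHit]:
    """Exact substring matches of pre-miRNA sequences inside lncRNAs.

    Every occurrence is reported as a 1-based closed interval; a precursor
    may hit multiple hosts and a host may carry multiple copies.
    """
    hits: list[HomologyHit] = []
    for m in sorted(precursors, key=lambda m: m.mirna_id):
        if m.precursor_seq is None:
            continue
        pre_id = m.precursor_id or m.mirna_id
        queries = [m.precursor_seq]
        if search_reverse_complement:
            queries.append(reverse_complement(m.precursor_seq))
        for tid in sorted(lncrna_seqs):
            seq = lncrna_seqs[tid].upper().replace("U", "T")
            seen: set[int] = set()
            for query in queries:
                for start in find_occurrences(seq, query):
                    if start not in seen:
                        seen.add(start)
                        hits.append(
                            HomologyHit(
                                lncrna_id=tid,
                                precursor_id=pre_id,
                                start=start,
                                end=start + len(m.precursor_seq) - 1,
                            )
                        )
    hits.sort()
    return hits


def read_mirna_fasta(path, precursor_suffix: str = "-pre") -> list[MiRNA]:
    """Load a miRNA FASTA where precursor records share the mature id + suffix."""
    from . import io as fio

    seqs = fio.read_fasta(path)
    mature = {k: v for k, v in seqs.items() if not k.endswith(precursor_suffix)}
    out = []
    for mid in sorted(mature):
        pre_key = mid + precursor_suffix
        pre = seqs.get(pre_key)
        out.append(
            MiRNA(
                mirna_id=mid,
                mature_seq=mature[mid],
                precursor_id=mid if pre is not None else None,
                precursor_seq=pre,
            )
        )
    return out


def hits_to_frame(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lncrna_id": h.lncrna_id, "precursor_id": h.precursor_id, "start": h.start, "end": h.end}
            for h in hits
        ],
        columns=["lncrna_id", "precursor_id", "start", "end"],
    )
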