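"""Annotation over-representation testing and PPI edge filtering.

Enrichment is the hypergeometric upper tail P(X >= k) for an overlap of k
query genes with a K-member term inside an N-gene universe, corrected per
namespace by Benjamini-Hochberg (significant at q < 0.05). An optional
EASE-style conservative variant tests k-1 successes. PPI edges come from a
STRING-format table (protein1, protein2, combined_score in 0..1000); edges
with combined score strictly above 700 are kept, deduplicated as unordered
pairs, with weight = score / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .types import GeneSet, NetworkEdge


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # overlap
    K: int  # term size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float = float("nan")
    significant: bool = False


def hypergeom_upper_tail(k: int, N: int, K: int, n: int, ease: bool = False) -> float:
    """P(X >= k) with X ~ Hypergeometric(N population, K successes, n draws).

    With ``ease`` the EASE score is returned: the same tail probability for
    k-1 successes (p = 1 when k <= 0 after the subtraction).
    """
    if ease:
        k = k - 1
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    terms: Sequence[GeneSet],
    q_threshold: float = 0.05,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query in the universe.

    The query must be a subset of the universe; terms are intersected with
    the universe before testing and skipped when the intersection is empty.
    BH correction is applied across the tested terms within each namespace.
    """
    uni = set(universe)
    qset = set(query)
    offenders = sorted(qset - uni)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    N, n = len(uni), len(qset)

    tested: list[EnrichmentResult] = []
    for term in terms:
        members = term.members & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & qset)
        p = hypergeom_upper_tail(k, N, K, n, ease=ease)
        tested.append(
            EnrichmentResult(term.term_id, term.term_name, term.namespace, k, K, n, N, p)
        )

    out: list[EnrichmentResult] = []
    by_ns: dict[str, list[EnrichmentResult]] = {}
    for r in tested:
        by_ns.setdefault(r.namespace, []).append(r)
    for ns_results in by_ns.values():
        qvals = bh_adjust([r.p for r in ns_results])
        for r, qv in zip(ns_results, qvals):
            out.append(
                EnrichmentResult(
                    r.term_id, r.term_name, r.namespace, r.k, r.K, r.n, r.N, r.p,
                    q=float(qv), significant=bool(qv < q_threshold),
                )
            )
    out.sort(key=lambda r: (r.namespace, r.p, r.term_id))
    return out


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name, "namespace": r.namespace,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p, "q": r.q, "significant": r.significant,
                "test": "hypergeometric upper tail, BH corrected",
            }
            for r in results
        ]
    )


def read_gmt(path) -> list[GeneSet]:
    """GMT-style TSV: term_id, term_name, namespace, then member gene ids."""
    terms = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            terms.append(
                GeneSet(fields[0], fields[1], fields[2], frozenset(f for f in fields[3:] if f))
            )
    return terms


def write_gmt(terms: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, t.namespace, *sorted(t.members)]) + "\n")


def ppi_filter(edges: pd.DataFrame, score_threshold: int = 700) -> list[NetworkEdge]:
    """Keep STRING edges with combined_score strictly above the threshold.

    Duplicate orientations (A-B / B-A) collapse to one undirected edge with
    the endpoints in sorted order; weight is score / 1000. Scores outside
    [0, 1000] raise ``ValueError``.
    """
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"PPI table missing columns {sorted(missing)}")
    scores = edges["combined_score"]
    if ((scores < 0) | (scores > 1000)).any():
        bad = scores[(scores < 0) | (scores > 1000)].tolist()
        raise ValueError(f"combined_score outside [0, 1000]: {bad}")

    best: dict[tuple[str, str], float] = {}
    for row in edges.itertuples():
        score = float(row.combined_score)
        if score <= score_threshold:
            continue
        a, b = sorted((str(row.protein1), str(row.protein2)))
        key = (a, b)
        best[key] = max(best.get(key, 0.0), score)
    return sorted(
        NetworkEdge(a, b, "ppi", weight=score / 1000.0) for (a, b), score in best.items()
    )
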