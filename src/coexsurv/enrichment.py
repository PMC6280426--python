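"""Over-representation analysis of a gene list against GMT gene sets.

The screened co-expression list is tested for enrichment in each gene set
by the hypergeometric upper tail: given a universe of U genes of which K
belong to the set, and a query of N genes, the p-value is P(X >= overlap)
for X ~ Hypergeometric(U, K, N). The universe is the set of genes that
could have been screened (post expression filter), not the whole genome —
genes that could not have entered the query cannot be drawn. One-sided
over-representation only; term hierarchies must be pre-flattened into the
GMT (no GO-DAG propagation is performed).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import scipy.stats

from .io import GeneSetCollection
from .screen import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "hypergeometric_tail", "enrich"]


@dataclasses.dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float
    overlap_genes: str  # comma-joined sorted gene ids, table-friendly


def hypergeometric_tail(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set, query draws)."""
    if min(overlap, set_size, query_size, universe_size) < 0:
        raise ValueError("counts must be non-negative")
    if set_size > universe_size or query_size > universe_size:
        raise ValueError("set and query cannot exceed the universe")
    if overlap > min(set_size, query_size):
        raise ValueError("overlap cannot exceed min(set_size, query_size)")
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    p = float(scipy.stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))
    return min(max(p, 5e-324), 1.0)  # mathematically p > 0; guard float underflow


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped (count logged); set members
    are intersected with the universe before counting. BH adjustment runs
    across all tested terms (those with at least one member in the
    universe). Output is sorted by ascending p, then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("enrich: dropping %d query genes outside the universe", len(outside))
    query &= universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")

    U, N = len(universe), len(query)
    rows = []
    for term_id, (term_name, members) in sorted(collection.items()):
        in_univ = members & universe
        if not in_univ:
            continue
        hits = sorted(query & in_univ)
        p = hypergeometric_tail(len(hits), len(in_univ), N, U)
        rows.append((term_id, term_name, hits, len(in_univ), p))
    if not rows:
        return []

    qvals = bh_adjust([r[4] for r in rows])
    records = [
        EnrichmentRecord(
            term_id=term_id,
            term_name=term_name,
            overlap=len(hits),
            set_size=set_size,
            query_size=N,
            universe_size=U,
            p=p,
            q=float(q),
            overlap_genes=",".join(hits),
        )
        for (term_id, term_name, hits, set_size, p), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.p, r.term_id))
    return records
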