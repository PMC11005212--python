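"""Over-representation analysis against GMT-style annotation sets.

A gene list is tested term by term with the upper-tail hypergeometric
probability P(X >= k) for drawing ``k`` term members in a list of size ``n``
from a universe of ``N`` genes of which ``K`` belong to the term; q-values
are Benjamini-Hochberg within the tested terms, and terms with q <= 0.05 are
flagged enriched.  Over-representation only — depletion is not tested.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .expression import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["AnnotationMap", "hypergeom_test", "enrich", "read_gmt", "write_gmt"]


class AnnotationMap:
    """Term -> (description, member gene set) plus a background universe.

    The universe defaults to the union of all term members (annotated-only
    background); a custom universe restricts every term to its intersection
    with it, dropping emptied terms with a log entry.
    """

    def __init__(self, terms: dict, universe=None):
        if universe is None:
            universe = set()
            for _, members in terms.values():
                universe |= set(members)
        self.universe = frozenset(universe)
        self.terms = {}
        for term, (desc, members) in terms.items():
            kept = set(members) & self.universe
            if not kept:
                log.warning("term %s empty after universe restriction; dropped", term)
                continue
            self.terms[term] = (desc, frozenset(kept))

    def __len__(self) -> int:
        return len(self.terms)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` overlap, ``n`` list size, ``K`` term size, ``N`` universe size.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list, annotation: AnnotationMap, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` per term.

    List members outside the universe are dropped with a warning.  Returns
    one row per term (k, n, K, N, p, q, enriched), sorted by q then p then
    term ID for determinism.
    """
    genes = set(gene_list)
    outside = genes - set(annotation.universe)
    if outside:
        log.warning("%d genes outside the universe dropped from the list", len(outside))
        genes -= outside
    if not genes:
        log.warning("empty gene list after universe restriction")
        return pd.DataFrame(
            columns=["term", "description", "k", "n", "K", "N", "p", "q", "enriched"]
        ).set_index("term")

    N = len(annotation.universe)
    n = len(genes)
    rows = []
    for term in sorted(annotation.terms):
        desc, members = annotation.terms[term]
        K = len(members)
        k = len(genes & members)
        rows.append((term, desc, k, n, K, N, hypergeom_test(k, n, K, N)))
    table = pd.DataFrame(
        rows, columns=["term", "description", "k", "n", "K", "N", "p"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["enriched"] = table["q"] <= q_threshold
    table = table.sort_values(["q", "p", "term"], kind="mergesort").set_index("term")
    return table


def read_gmt(path) -> dict:
    """Read a GMT file into ``{term: (description, set of genes)}``."""
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, members = parts[0], parts[1], parts[2:]
            terms[term] = (desc, {g for g in members if g})
    return terms


def write_gmt(terms: dict, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, members = terms[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
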