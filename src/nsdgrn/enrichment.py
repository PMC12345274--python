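"""Hypergeometric GO-term over-representation.

For a query set of n genes drawn from a universe of N genes, a term
annotating K universe genes, and k query genes carrying the term, the
enrichment p-value is the upper tail of the hypergeometric distribution,
P(X >= k). One-sided over-representation only; no term-hierarchy
propagation (annotations are taken as flat gene -> term sets); no
multiple-testing correction by default (raw P < alpha). Significant
terms are ranked by ascending p-value, then descending k, then term id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set

import pandas as pd
from scipy import stats

from .models import NsdgrnError

logger = logging.getLogger("nsdgrn.enrichment")


@dataclass
class GoAnnotation:
    """Flat gene -> GO-term annotation with human-readable term names."""

    gene_to_terms: Dict[str, FrozenSet[str]]
    term_names: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GoAnnotation":
        """Build from a (gene, term[, name]) table as read by io.read_go_annotation."""
        gene_to_terms: Dict[str, Set[str]] = {}
        term_names: Dict[str, str] = {}
        for row in table.itertuples(index=False):
            gene_to_terms.setdefault(row.gene, set()).add(row.term)
            name = getattr(row, "name", row.term)
            term_names.setdefault(row.term, name)
        return cls(
            gene_to_terms={g: frozenset(t) for g, t in gene_to_terms.items()},
            term_names=term_names,
        )

    def term_to_genes(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out


def enrich(
    query: Iterable[str],
    annotation: GoAnnotation,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every annotated term in a query set.

    Returns the significant terms (p < alpha, strict) as a DataFrame with
    columns term, name, k, K, n, N, p, sorted by (p asc, k desc, term asc).
    """
    query_set = set(query)
    universe_set = set(universe)
    outside = query_set - universe_set
    if outside:
        raise NsdgrnError(
            f"enrich: query contains {len(outside)} genes outside the universe: "
            f"{sorted(outside)[:10]}"
        )
    n = len(query_set)
    N = len(universe_set)
    rows = []
    for term, genes in annotation.term_to_genes().items():
        term_in_universe = genes & universe_set
        K = len(term_in_universe)
        if K == 0:
            continue
        k = len(term_in_universe & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    table = table[table["p"] < alpha]
    table = table.sort_values(
        by=["p", "k", "term"], ascending=[True, False, True], kind="stable",
        ignore_index=True,
    )
    logger.info("enrich: %d terms significant at p < %g (query %d / universe %d)",
                len(table), alpha, n, N)
    return table


def summarize_categories(term_table: pd.DataFrame, max_terms: int) -> pd.DataFrame:
    """The most representative terms: top rows of the ranked table.

    The table is assumed already sorted by (p asc, k desc, term asc), so
    statistical significance and gene-set size jointly drive selection.
    """
    if max_terms < 0:
        raise NsdgrnError("summarize_categories: max_terms must be >= 0")
    return term_table.head(max_terms).reset_index(drop=True)
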