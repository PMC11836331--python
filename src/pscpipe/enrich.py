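"""Over-representation analysis (ORA) of gene sets against annotation terms.

Plain upper-tail hypergeometric testing with BH correction — the generic
statistic behind GO/KEGG-style enrichment tools.  The background universe is
an explicit, required argument (typically all genes on the expression
platform), never an implicit genome-wide default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .expression import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["AnnotationDB", "ora_test", "read_gmt", "write_gmt"]


@dataclass
class AnnotationDB:
    """Mapping of annotation term -> gene set, with optional display names."""

    terms: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for term, genes in self.terms.items():
            gs = frozenset(str(g).strip().upper() for g in genes)
            if not gs:
                raise ValueError(f"term {term!r} has an empty gene set")
            cleaned[term] = gs
        self.terms = cleaned

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> AnnotationDB:
    """Read a GMT file (term, description, genes...; tab-separated)."""
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, desc, genes = fields[0], fields[1], fields[2:]
            terms[term] = frozenset(g for g in genes if g)
            names[term] = desc
    return AnnotationDB(terms=terms, names=names)


def write_gmt(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(db.terms):
            desc = db.names.get(term, "")
            genes = "\t".join(sorted(db.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def ora_test(
    query: Iterable[str],
    db: AnnotationDB | Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set per annotation term.

    For each term the p value is P(X >= overlap) for X hypergeometric with
    population |universe|, successes |term ∩ universe|, and draws |query|.
    Query genes outside the universe are dropped with a logged count.
    Returns a table sorted by (adjusted p, p, term).
    """
    if not isinstance(db, AnnotationDB):
        db = AnnotationDB(terms={t: frozenset(g) for t, g in db.items()})
    uni = {str(g).strip().upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q = {str(g).strip().upper() for g in query}
    dropped = q - uni
    if dropped:
        logger.warning("%d query gene(s) outside the universe were dropped", len(dropped))
    q &= uni
    if not q:
        raise ValueError("empty query after restricting to the universe")
    M, N = len(uni), len(q)
    rows = []
    for term in sorted(db.terms):
        term_in_uni = db.terms[term] & uni
        n = len(term_in_uni)
        if n == 0:
            continue
        overlap = len(q & term_in_uni)
        p = float(hypergeom.sf(overlap - 1, M, n, N))
        rows.append({
            "term": term,
            "name": db.names.get(term, term),
            "overlap": overlap,
            "query_size": N,
            "term_size": n,
            "universe_size": M,
            "p": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["adj_p", "p", "term"], kind="stable").reset_index(drop=True)
    return out
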