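"""Multi-category protein-interaction networks and the PIE score.

A reference network is assembled as the union of per-category edge lists
(physical interactions, predicted interactions, shared protein domains,
co-localization, pathways).  The physical-interaction-enrichment (PIE)
score of a query gene set is the ratio of its observed internal edge count
to the mean internal edge count of number-matched random node sets drawn
from the background network, with an add-one empirical bootstrap p value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "InteractionNetwork",
    "ModuleDecomposition",
    "PIEResult",
    "assemble_network",
    "decompose_modules",
    "internal_edge_count",
    "pie_score",
    "pie_report",
]

CATEGORIES = ("physical", "predicted", "shared_domain", "colocalization", "pathway")


@dataclass
class InteractionNetwork:
    """Undirected gene-symbol network; each edge carries a set of categories."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Combined (category-agnostic) edge count: each pair counts once."""
        return self.graph.number_of_edges()

    def edges_in_category(self, category: str) -> set[frozenset]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown interaction category {category!r}")
        return {
            frozenset((u, v))
            for u, v, cats in self.graph.edges(data="categories")
            if category in cats
        }

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for _, _, cats in self.graph.edges(data="categories"):
            for c in cats:
                counts[c] += 1
        return counts


@dataclass
class ModuleDecomposition:
    """Connected components of the combined network, largest first.

    ``modules`` holds components of size >= min_size, ordered by descending
    size with ties broken by the lexicographically smallest member;
    ``singletons`` are nodes in no module.
    """

    modules: list[list[str]]
    singletons: list[str]

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]


@dataclass
class PIEResult:
    """PIE score of one query set against a background network."""

    observed_internal_edges: int
    null_mean: float
    pie_score: float
    empirical_p: float
    B: int
    category_filter: str | None
    seed: int | None
    query_size: int
    degenerate_null: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        lo = 1.0 / (self.B + 1)
        if not (lo - 1e-12 <= self.empirical_p <= 1.0 + 1e-12):
            raise ValueError("empirical p outside attainable range")


def _normalize(symbol: str) -> str:
    return str(symbol).strip().upper()


def assemble_network(
    edges: pd.DataFrame | Mapping[str, Iterable[tuple[str, str]]],
) -> InteractionNetwork:
    """Combine per-category edge lists into one reference network.

    Accepts either a DataFrame with columns (node_a, node_b, category) or a
    mapping category -> iterable of node pairs.  Duplicate edges within a
    category are removed; self-loops are dropped with a logged count; the
    same pair appearing in several categories yields a single combined edge
    tagged with every category.
    """
    if isinstance(edges, pd.DataFrame):
        required = {"node_a", "node_b", "category"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        records = [
            (str(r.category), str(r.node_a), str(r.node_b))
            for r in edges.itertuples(index=False)
        ]
    else:
        records = [
            (str(cat), str(a), str(b))
            for cat, pairs in edges.items()
            for a, b in pairs
        ]
    g = nx.Graph()
    n_self = 0
    for category, a, b in records:
        if category not in CATEGORIES:
            raise ValueError(f"unknown interaction category {category!r}")
        a, b = _normalize(a), _normalize(b)
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["categories"].add(category)
        else:
            g.add_edge(a, b, categories={category})
    if n_self:
        logger.warning("dropped %d self-loop edge(s) during assembly", n_self)
    return InteractionNetwork(graph=g)


def decompose_modules(
    network: InteractionNetwork, min_size: int = 2
) -> ModuleDecomposition:
    """Connected components of the combined edge set, sorted deterministically."""
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    modules = [c for c in comps if len(c) >= min_size]
    singles = sorted(n for c in comps if len(c) < min_size for n in c)
    modules.sort(key=lambda c: (-len(c), c[0]))
    return ModuleDecomposition(modules=modules, singletons=singles)


def _query_indices(
    network: InteractionNetwork, query: Iterable[str]
) -> tuple[list[str], list[str]]:
    nodes = set(network.graph.nodes)
    q = {_normalize(s) for s in query}
    inside = sorted(q & nodes)
    outside = sorted(q - nodes)
    if outside:
        logger.warning(
            "%d query gene(s) absent from the background network were dropped",
            len(outside),
        )
    return inside, outside


def internal_edge_count(
    network: InteractionNetwork,
    node_set: Iterable[str],
    category_filter: str | None = None,
) -> int:
    """Edges with both endpoints inside ``node_set`` (per category if given)."""
    inside, _ = _query_indices(network, node_set)
    if not inside:
        logger.warning("empty node set: internal edge count is 0")
        return 0
    members = set(inside)
    count = 0
    for u, v, cats in network.graph.edges(data="categories"):
        if u in members and v in members:
            if category_filter is None or category_filter in cats:
                count += 1
    if category_filter is not None and category_filter not in CATEGORIES:
        raise ValueError(f"unknown interaction category {category_filter!r}")
    return count


def _edge_index_arrays(
    network: InteractionNetwork, category_filter: str | None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Node list plus endpoint index arrays of the (filtered) edge set."""
    nodes = network.nodes
    pos = {n: i for i, n in enumerate(nodes)}
    eu, ev = [], []
    for u, v, cats in network.graph.edges(data="categories"):
        if category_filter is None or category_filter in cats:
            eu.append(pos[u])
            ev.append(pos[v])
    return nodes, np.asarray(eu, dtype=np.intp), np.asarray(ev, dtype=np.intp)


def pie_score(
    background: InteractionNetwork,
    query: Iterable[str],
    B: int = 10_000,
    seed: int | None = None,
    category_filter: str | None = None,
    degree_matched: bool = False,
) -> PIEResult:
    """PIE score of a query set under a number-matched resampling null.

    For each of ``B`` bootstrap draws a uniform node sample of the query's
    size is taken without replacement from the background node universe and
    its internal edge count recorded.  The score is the observed internal
    edge count divided by the null mean; the empirical p value is
    ``(1 + #{E_b >= E_obs}) / (B + 1)``.

    ``degree_matched=True`` switches to a stratified null that samples
    within degree-decile bins matching the query's bin profile (an optional
    stricter null; the default matches only the set size).
    """
    if category_filter is not None and category_filter not in CATEGORIES:
        raise ValueError(f"unknown interaction category {category_filter!r}")
    inside, _ = _query_indices(background, query)
    k = len(inside)
    if k < 2:
        raise ValueError("query must contain at least two background genes")
    nodes, eu, ev = _edge_index_arrays(background, category_filter)
    n = len(nodes)
    if k > n:
        raise ValueError("query larger than the background node universe")
    pos = {node: i for i, node in enumerate(nodes)}
    q_idx = np.asarray([pos[g] for g in inside], dtype=np.intp)
    mask = np.zeros(n, dtype=bool)
    mask[q_idx] = True
    e_obs = int((mask[eu] & mask[ev]).sum())

    rng = np.random.default_rng(seed)
    null_counts = np.empty(B, dtype=np.int64)
    if degree_matched:
        degrees = np.zeros(n, dtype=np.int64)
        for u, v in zip(eu, ev):
            degrees[u] += 1
            degrees[v] += 1
        edges_q = np.quantile(degrees, np.linspace(0, 1, 11)[1:-1])
        bins = np.searchsorted(edges_q, degrees, side="left")
        bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
        q_bins, q_counts = np.unique(bins[q_idx], return_counts=True)
        for b_i in range(B):
            draw = np.concatenate([
                rng.choice(bin_members[b], size=c, replace=False)
                for b, c in zip(q_bins, q_counts)
            ])
            m = np.zeros(n, dtype=bool)
            m[draw] = True
            null_counts[b_i] = (m[eu] & m[ev]).sum()
    else:
        chunk = max(1, min(B, 2_000_000 // max(1, len(eu))))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            masks = np.zeros((b, n), dtype=bool)
            for i in range(b):
                masks[i, rng.choice(n, size=k, replace=False)] = True
            null_counts[done : done + b] = (masks[:, eu] & masks[:, ev]).sum(axis=1)
            done += b

    null_mean = float(null_counts.mean())
    degenerate = False
    if null_mean == 0.0:
        degenerate = True
        score = float("inf") if e_obs > 0 else 1.0
    else:
        score = e_obs / null_mean
    emp_p = (1 + int((null_counts >= e_obs).sum())) / (B + 1)
    return PIEResult(
        observed_internal_edges=e_obs,
        null_mean=null_mean,
        pie_score=score,
        empirical_p=emp_p,
        B=B,
        category_filter=category_filter,
        seed=seed,
        query_size=k,
        degenerate_null=degenerate,
    )


def pie_report(
    background: InteractionNetwork,
    deg_sets: Mapping[str, Iterable[str]],
    categories: Sequence[str] = (),
    B: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """PIE scores for each DEG set (all/up/down) × (combined + categories).

    Sub-seeds are derived deterministically from the set *content* and the
    category, so identical gene sets get identical rows regardless of their
    label or position in the table.
    """
    import zlib

    rows = []
    for cat in categories:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown interaction category {cat!r}")
    set_names = list(deg_sets)
    cat_list: list[str | None] = [None, *categories]
    for name in set_names:
        genes = list(deg_sets[name])
        if not genes:
            raise ValueError(f"DEG set {name!r} is empty")
        content_key = zlib.crc32("\n".join(sorted(map(str, genes))).encode())
        for ci, cat in enumerate(cat_list):
            sub_seed = None
            if seed is not None:
                sub_seed = int(
                    np.random.SeedSequence(
                        seed, spawn_key=(content_key, ci)
                    ).generate_state(1)[0] % (2**31)
                )
            res = pie_score(background, genes, B=B, seed=sub_seed, category_filter=cat)
            rows.append({
                "set": name,
                "category": cat if cat is not None else "combined",
                "observed_internal_edges": res.observed_internal_edges,
                "null_mean": res.null_mean,
                "pie_score": res.pie_score,
                "empirical_p": res.empirical_p,
                "B": res.B,
                "seed": sub_seed,
            })
    return pd.DataFrame(rows)
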