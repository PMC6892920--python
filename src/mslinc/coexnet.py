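"""Coexpression network construction and module detection.

Transcript pairs are classified as cis (same chromosome, span gap <= 100 kb)
or trans (different chromosomes, or > 1 Mb apart).  Pairs become edges when
their Pearson correlation exceeds 0.6 at p < 1e-5; coding-coding pairs must
additionally be supported by a protein-protein interaction.  Modules are
found by greedy cohesiveness maximisation, where the cohesiveness of a
vertex set V is w_in(V) / (w_in(V) + w_bound(V)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel

__all__ = [
    "classify_pair_locality",
    "build_edges",
    "NetworkModule",
    "detect_modules",
    "hypergeometric_enrichment",
    "read_gmt",
]

CIS_WINDOW = 100_000
TRANS_MIN = 1_000_000


def classify_pair_locality(
    t1: TranscriptModel,
    t2: TranscriptModel,
    cis_window: int = CIS_WINDOW,
    trans_min: int = TRANS_MIN,
) -> str:
    """cis / trans / neither for a transcript pair (symmetric, gap-based)."""
    if t1.chrom != t2.chrom:
        return "trans"
    gap = max(t1.start - t2.end, t2.start - t1.end, 0)
    if gap <= cis_window:
        return "cis"
    if gap > trans_min:
        return "trans"
    return "neither"


def build_edges(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    ppi: Iterable[frozenset] | None = None,
    catalog=None,
    r_min: float = 0.6,
    p_max: float = 1e-5,
) -> pd.DataFrame:
    """Correlation edges over candidate pairs.

    ``pairs`` are ``(id1, id2, pair_type)`` with pair_type in
    {lincRNA-coding, coding-coding, lincRNA-lincRNA}.  An edge is kept iff
    r > ``r_min`` (strict) and p < ``p_max``; coding-coding edges
    additionally require membership in ``ppi`` (a set of frozenset id
    pairs).  When ``catalog`` is given, cis/trans locality is annotated.
    Returns all tested pairs with a ``kept`` flag.
    """
    ppi_set = set(ppi) if ppi is not None else set()
    rows = []
    for id1, id2, pair_type in pairs:
        x = matrix.loc[id1].to_numpy(dtype=float)
        y = matrix.loc[id2].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(x, y)
        supported = frozenset((id1, id2)) in ppi_set
        kept = r > r_min and p < p_max
        if pair_type == "coding-coding":
            kept = kept and supported
        locality = ""
        if catalog is not None and id1 in catalog and id2 in catalog:
            locality = classify_pair_locality(catalog[id1], catalog[id2])
        rows.append(
            {
                "id1": id1,
                "id2": id2,
                "pair_type": pair_type,
                "r": float(r),
                "p": float(p),
                "locality": locality,
                "ppi_supported": supported,
                "kept": kept,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id1", "id2", "pair_type", "r", "p", "locality", "ppi_supported", "kept"],
    )


@dataclass
class NetworkModule:
    module_id: int
    members: list[str]
    cohesiveness: float


def _cohesiveness(graph: nx.Graph, members: set) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2.0
            else:
                w_bound += w
    total = w_in + w_bound
    return w_in / total if total > 0 else 0.0


def detect_modules(
    edges: pd.DataFrame | nx.Graph,
    min_size: int = 3,
    overlap_max: float = 0.8,
) -> list[NetworkModule]:
    """Greedy-cohesiveness module detection.

    Seeds at the highest weighted-degree unassigned vertex and repeatedly
    applies the single vertex addition or removal that most increases
    cohesiveness, stopping at a local maximum.  Modules smaller than
    ``min_size`` are discarded and module pairs with Jaccard overlap
    > ``overlap_max`` are merged.  Fully deterministic: ties break by higher
    degree then lexicographic id.
    """
    if isinstance(edges, nx.Graph):
        graph = edges
    else:
        kept = edges[edges["kept"]] if "kept" in edges.columns else edges
        graph = nx.Graph()
        for row in kept.itertuples(index=False):
            graph.add_edge(row.id1, row.id2, weight=abs(row.r))
    if graph.number_of_edges() == 0:
        return []

    def seed_key(node):
        return (-graph.degree(node, weight="weight"), node)

    unassigned = set(graph.nodes)
    raw_modules: list[set] = []
    while unassigned:
        seed = min(unassigned, key=seed_key)
        members = {seed}
        current = _cohesiveness(graph, members)
        while True:
            candidates = []
            frontier = {v for u in members for v in graph[u] if v not in members}
            for v in sorted(frontier, key=seed_key):
                candidates.append((members | {v}, v))
            if len(members) > 1:
                for v in sorted(members, key=seed_key):
                    candidates.append((members - {v}, v))
            best_set, best_f = None, current
            for cand, _ in candidates:
                f = _cohesiveness(graph, cand)
                if f > best_f + 1e-12:
                    best_set, best_f = cand, f
            if best_set is None:
                break
            members, current = best_set, best_f
        raw_modules.append(members)
        unassigned -= members

    modules = [m for m in raw_modules if len(m) >= min_size]
    # merge heavily overlapping modules (Jaccard > overlap_max)
    merged = True
    while merged:
        merged = False
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                inter = len(modules[i] & modules[j])
                union = len(modules[i] | modules[j])
                if union and inter / union > overlap_max:
                    modules[i] = modules[i] | modules[j]
                    del modules[j]
                    merged = True
                    break
            if merged:
                break
    modules.sort(key=lambda m: (-len(m), sorted(m)))
    return [
        NetworkModule(i + 1, sorted(m), _cohesiveness(graph, m))
        for i, m in enumerate(modules)
    ]


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeometric_enrichment(
    genes: Iterable[str],
    gene_sets: Mapping[str, set],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``genes`` in each term.

    Term members outside the universe are dropped before testing; BH
    adjustment is applied across terms.
    """
    universe = set(universe)
    genes = set(genes) & universe
    if not genes:
        raise ValueError("empty query after restriction to the universe")
    rows = []
    for term, members in gene_sets.items():
        members = members & universe
        if not members:
            continue
        k = len(genes & members)
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(genes))
        rows.append({"term": term, "overlap": k, "term_size": len(members), "p": float(p)})
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(table):
        table["q"] = stats.false_discovery_control(table["p"], method="bh")
    else:
        table["q"] = []
    return table.sort_values(["p", "term"]).reset_index(drop=True)
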