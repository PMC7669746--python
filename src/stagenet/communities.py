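"""Community detection and per-community over-representation analysis.

Networks are partitioned with Infomap (the random-walk map-equation
method, via python-igraph; two-level, 10 trials, seeded) or a
deterministic seeded label-propagation fallback.  Each community of at
least ``min_community`` genes is then tested for over-representation
of every supplied gene set by the upper-tail hypergeometric test

    P(X >= k) = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n)

with universe N (all genes that survived the expression filter), set
size K, community size n and overlap k, followed by Benjamini–Hochberg
correction across all community x set tests.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .core import AnnotatedNetwork, StagenetError
from .diffexpr import bh_adjust

__all__ = [
    "CommunityPartition",
    "EnrichmentResult",
    "detect_communities",
    "enrich",
]

INFOMAP_TRIALS = 10


@dataclass
class CommunityPartition:
    """Node -> community id; ids are contiguous integers from 0.

    Communities are numbered by their lexicographically smallest
    member, making the labelling independent of detection order.
    """

    assignment: dict[str, int]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, community: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == community}

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return out


@dataclass
class EnrichmentResult:
    """One community x gene-set over-representation test."""

    community: int
    gene_set: str
    k: int  # overlap
    K: int  # set size in universe
    n: int  # community size in universe
    N: int  # universe size
    p_value: float
    fdr: float


def _renumber(groups: list[set[str]]) -> CommunityPartition:
    ordered = sorted(groups, key=lambda g: min(g))
    assignment = {node: i for i, grp in enumerate(ordered) for node in grp}
    return CommunityPartition(assignment)


def detect_communities(
    network: AnnotatedNetwork, method: str = "infomap", seed: int = 0
) -> CommunityPartition:
    """Partition the network's nodes into communities.

    Deterministic given ``(method, seed)``; nodes of disconnected
    components are never merged into one community by either method.
    """
    if not network.edges:
        raise StagenetError("cannot detect communities in an empty network")
    nodes = sorted(network.nodes)
    if method == "infomap":
        g = ig.Graph()
        g.add_vertices(nodes)
        g.add_edges([(a, b) for a, b in network.edges])
        g.es["weight"] = [float(w) for w in network.mi]
        ig.set_random_number_generator(random.Random(seed))
        try:
            clustering = g.community_infomap(
                edge_weights="weight", trials=INFOMAP_TRIALS
            )
        finally:
            ig.set_random_number_generator(random)
        groups = [
            {g.vs[v]["name"] for v in cluster} for cluster in clustering
        ]
    elif method == "label_propagation":
        nxg = nx.Graph()
        nxg.add_nodes_from(nodes)
        for (a, b), w in zip(network.edges, network.mi):
            nxg.add_edge(a, b, weight=float(w))
        comms = nx.algorithms.community.asyn_lpa_communities(
            nxg, weight="weight", seed=seed
        )
        groups = [set(c) for c in comms]
    else:
        raise StagenetError(f"unknown community method {method!r}")
    return _renumber(groups)


def enrich(
    partition: CommunityPartition,
    gene_sets: dict[str, set[str]],
    universe: list[str],
    alpha: float = 0.05,
    min_community: int = 5,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every gene set in every
    community of size >= ``min_community`` (after restriction to the
    universe), BH-corrected across all tested pairs and sorted by FDR.

    Community genes absent from the universe are dropped with a
    warning; gene sets are intersected with the universe.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise StagenetError("empty universe")
    uni_set = set(uni)
    N = len(uni_set)

    rows: list[EnrichmentResult] = []
    raw_p: list[float] = []
    dropped: set[str] = set()
    for community, members in sorted(partition.communities().items()):
        outside = members - uni_set
        if outside:
            dropped |= outside
        comm = members & uni_set
        n = len(comm)
        if n < min_community:
            continue
        for name in sorted(gene_sets):
            in_universe = gene_sets[name] & uni_set
            K = len(in_universe)
            if K == 0:
                continue
            k = len(comm & in_universe)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append(EnrichmentResult(community, name, k, K, n, N, p, fdr=1.0))
            raw_p.append(p)
    if dropped:
        warnings.warn(
            f"{len(dropped)} community genes absent from universe were dropped",
            stacklevel=2,
        )
    if rows:
        adj = bh_adjust(pd.Series(raw_p).to_numpy())
        for row, q in zip(rows, adj):
            row.fdr = float(q)
        rows.sort(key=lambda r: (r.fdr, r.p_value, r.community, r.gene_set))
    return rows


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "community": r.community,
                "set": r.gene_set,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=["community", "set", "k", "K", "n", "N", "p", "fdr"],
    )
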