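"""Synteny-network assembly, family-subnetwork extraction, and k-clique
percolation communities.

The network's nodes are genes and its edges connect anchor pairs inside
collinear blocks. The family subnetwork is extracted by querying domain-
positive candidate genes against the full network with an ordinal context
window (default 25 genes): a candidate pair is connected iff some shared
block has an anchor within the window of both candidates on their
respective chromosomes. Communities follow clique-percolation semantics:
two k-cliques are adjacent iff they share k-1 nodes, and a community is a
union of percolating k-cliques (membership may overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import pandas as pd

from .collinearity import CollinearBlock
from .seqio import AnnotatedGenome


@dataclass
class CliqueCommunity:
    community_id: str
    members: frozenset
    k: int


def build_network(blocks: Sequence[CollinearBlock],
                  genomes: Sequence[AnnotatedGenome] | None = None,
                  architectures: dict[str, str] | None = None) -> nx.Graph:
    """One edge per anchored gene pair; an anchor pair present in several
    blocks yields a single edge annotated with every supporting block id.

    When ``genomes`` are given, anchors referencing unknown genes raise,
    and node/gene position attributes are attached (required later by
    :func:`extract_family_subnetwork`).
    """
    graph = nx.Graph()
    gene_pos: dict[str, tuple[str, str, int]] = {}
    if genomes is not None:
        for genome in genomes:
            for g in genome.genes():
                gene_pos[g.gene_id] = (g.genome_id, g.chrom, g.ordinal)
    for block in blocks:
        for a in block.anchors:
            if gene_pos and (a.gene_a not in gene_pos or a.gene_b not in gene_pos):
                missing = a.gene_a if a.gene_a not in gene_pos else a.gene_b
                raise ValueError(
                    f"block {block.block_id} anchors unknown gene {missing!r}")
            if a.gene_a == a.gene_b:
                continue
            if graph.has_edge(a.gene_a, a.gene_b):
                ids = graph.edges[a.gene_a, a.gene_b]["block_ids"]
                if block.block_id not in ids:
                    ids.append(block.block_id)
            else:
                graph.add_edge(a.gene_a, a.gene_b, block_ids=[block.block_id])
    for node in graph.nodes:
        if node in gene_pos:
            genome, chrom, ordinal = gene_pos[node]
            graph.nodes[node].update(genome=genome, chrom=chrom,
                                     ordinal=ordinal)
        if architectures and node in architectures:
            graph.nodes[node]["architecture"] = architectures[node]
    graph.graph["blocks"] = list(blocks)
    graph.graph["gene_pos"] = gene_pos
    return graph


def extract_family_subnetwork(network: nx.Graph, candidates: Iterable[str],
                              window: int = 25) -> nx.Graph:
    """Family subnetwork over candidate genes only.

    An edge between candidates c1, c2 is kept iff a block on their
    chromosome pair has an anchor within ``window`` ordinal positions of
    both; all non-candidate nodes are pruned. Candidates with no edge stay
    in the graph as isolated nodes so downstream membership statistics can
    count them.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    if window < 1:
        raise ValueError("window must be >= 1")
    gene_pos = network.graph.get("gene_pos") or {}
    blocks: list[CollinearBlock] = network.graph.get("blocks") or []
    if not gene_pos:
        raise ValueError("network lacks gene positions; build it with genomes")

    by_chrom: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for c in candidates:
        if c not in gene_pos:
            continue
        genome, chrom, ordinal = gene_pos[c]
        by_chrom.setdefault((genome, chrom), []).append((ordinal, c))

    sub = nx.Graph()
    for c in candidates:
        if c in gene_pos:
            genome, chrom, ordinal = gene_pos[c]
            sub.add_node(c, genome=genome, chrom=chrom, ordinal=ordinal,
                         **{k: v for k, v in network.nodes[c].items()
                            if k == "architecture"} if c in network else {})
        else:
            sub.add_node(c)

    for block in blocks:
        side_a, side_b = block.chrom_pair
        cands_a = by_chrom.get(side_a, ())
        cands_b = by_chrom.get(side_b, ())
        if not cands_a or not cands_b:
            continue
        for ord1, c1 in cands_a:
            for ord2, c2 in cands_b:
                if c1 == c2:
                    continue
                hit = any(abs(a.pos_a - ord1) <= window
                          and abs(a.pos_b - ord2) <= window
                          for a in block.anchors)
                if not hit:
                    continue
                if sub.has_edge(c1, c2):
                    ids = sub.edges[c1, c2]["block_ids"]
                    if block.block_id not in ids:
                        ids.append(block.block_id)
                else:
                    sub.add_edge(c1, c2, block_ids=[block.block_id])
    sub.graph["gene_pos"] = gene_pos
    sub.graph["blocks"] = blocks
    return sub


# ---------------------------------------------------------------------------
# Clique percolation


def bron_kerbosch_cliques(graph: nx.Graph) -> list[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting)."""
    adj = {v: set(graph[v]) for v in graph}
    cliques: list[frozenset] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: (len(adj[v] & p), str(v)))
        for v in sorted(p - adj[pivot], key=str):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(graph.nodes), set())
    return cliques


def clique_communities(graph: nx.Graph, k: int = 3) -> list[CliqueCommunity]:
    """Clique-percolation communities.

    Maximal cliques of size >= k percolate when they overlap in at least
    k-1 nodes; each community is the union of one connected component of
    percolating cliques. Nodes in no k-clique are unassigned. Returns an
    empty list (not an error) when the graph has no clique of size k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cliques = [c for c in bron_kerbosch_cliques(graph) if len(c) >= k]
    if not cliques:
        return []
    cliques.sort(key=lambda c: tuple(sorted(map(str, c))))
    # percolation graph over maximal cliques
    membership: dict[Hashable, set[int]] = {}
    for i, c in enumerate(cliques):
        for v in c:
            membership.setdefault(v, set()).add(i)
    perc = nx.Graph()
    perc.add_nodes_from(range(len(cliques)))
    for i, c in enumerate(cliques):
        neighbours = set()
        for v in c:
            neighbours |= membership[v]
        for j in neighbours:
            if j > i and len(cliques[i] & cliques[j]) >= k - 1:
                perc.add_edge(i, j)
    communities = []
    for comp in nx.connected_components(perc):
        members = frozenset().union(*(cliques[i] for i in comp))
        communities.append(members)
    communities.sort(key=lambda m: tuple(sorted(map(str, m))))
    return [
        CliqueCommunity(community_id=f"C{i + 1}", members=m, k=k)
        for i, m in enumerate(communities)
    ]


# ---------------------------------------------------------------------------
# Membership statistics


def membership_stats(communities: Sequence[CliqueCommunity],
                     clade_labels: dict[str, str],
                     universe: Iterable[str] | None = None) -> pd.DataFrame:
    """Percent of each clade's genes found in each community.

    Genes in no community are counted in a ``none`` row; genes without a
    clade label form the ``unlabeled`` clade. ``universe`` defaults to the
    labelled genes plus all community members.
    """
    genes = set(clade_labels)
    for com in communities:
        genes |= set(com.members)
    if universe is not None:
        genes |= set(universe)
    clade_of = {g: clade_labels.get(g, "unlabeled") for g in genes}
    clade_sizes: dict[str, int] = {}
    for g, clade in clade_of.items():
        clade_sizes[clade] = clade_sizes.get(clade, 0) + 1

    assigned: dict[str, set[str]] = {}
    rows = []
    for com in communities:
        counts: dict[str, int] = {}
        for g in com.members:
            if g in clade_of:
                counts[clade_of[g]] = counts.get(clade_of[g], 0) + 1
                assigned.setdefault(clade_of[g], set()).add(g)
        for clade, n in sorted(counts.items()):
            rows.append({
                "clade": clade, "community": com.community_id, "n_genes": n,
                "percent": 100.0 * n / clade_sizes[clade],
            })
    for clade in sorted(clade_sizes):
        n_none = clade_sizes[clade] - len(assigned.get(clade, ()))
        if n_none:
            rows.append({
                "clade": clade, "community": "none", "n_genes": n_none,
                "percent": 100.0 * n_none / clade_sizes[clade],
            })
    return pd.DataFrame(rows, columns=["clade", "community", "n_genes",
                                       "percent"])


def communities_to_rows(communities: Sequence[CliqueCommunity]) -> list[dict]:
    rows = []
    for com in communities:
        for g in sorted(map(str, com.members)):
            rows.append({"gene_id": g, "community_id": com.community_id})
    return rows


def graph_to_edge_rows(graph: nx.Graph) -> list[dict]:
    rows = []
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        a, b = sorted((str(u), str(v)))
        rows.append({"gene_a": a, "gene_b": b,
                     "block_id": ",".join(data.get("block_ids", []))})
    return rows
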