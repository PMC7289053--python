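"""Independent oracles used to check pipeline algorithms.

Each oracle is written from the problem definition, without reference to
the implementation it checks: brute-force enumeration, naive DP, or
event-log replay.
"""

from __future__ import annotations

import itertools
from collections import defaultdict


# ---------------------------------------------------------------------------
# Naive affine-gap local alignment (score only)


def sw_score_naive(a: str, b: str, submat: dict, gap_open: float,
                   gap_extend: float) -> float:
    """Plain dict-based 3-state DP; gap of length L costs
    open + extend*(L-1)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            s = submat[(a[i - 1], b[j - 1])]
            M[i][j] = max(0.0,
                          s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                  Y[i - 1][j - 1]))
            best = max(best, M[i][j])
    return best


# ---------------------------------------------------------------------------
# Exhaustive monotone-chain enumeration


def _chain_valid(chain, orientation, max_gap):
    for prev, cur in zip(chain, chain[1:]):
        if cur.pos_a <= prev.pos_a:
            return False
        gap_a = cur.pos_a - prev.pos_a - 1
        if orientation == "same":
            if cur.pos_b <= prev.pos_b:
                return False
            gap_b = cur.pos_b - prev.pos_b - 1
        else:
            if cur.pos_b >= prev.pos_b:
                return False
            gap_b = prev.pos_b - cur.pos_b - 1
        if gap_a > max_gap or gap_b > max_gap:
            return False
    return True


def _chain_score(chain, gap_penalty):
    score = sum(a.score for a in chain)
    for prev, cur in zip(chain, chain[1:]):
        score += gap_penalty * ((cur.pos_a - prev.pos_a - 1)
                                + (abs(cur.pos_b - prev.pos_b) - 1))
    return score


def best_chain_exhaustive(anchors, max_gap, gap_penalty):
    """Best-scoring monotone chain over all subsets and both orientations.

    Orientation preference mirrors the implementation: 'same' is tried
    first and 'inverted' replaces it only on a strictly higher score.
    """
    best = ([], "same", float("-inf"))
    for orientation in ("same", "inverted"):
        for r in range(1, len(anchors) + 1):
            for subset in itertools.combinations(anchors, r):
                chain = sorted(subset, key=lambda x: x.pos_a)
                if not _chain_valid(chain, orientation, max_gap):
                    continue
                s = _chain_score(chain, gap_penalty)
                if s > best[2]:
                    best = (chain, orientation, s)
    return best


def chain_blocks_exhaustive(anchors, max_gap, gap_penalty, min_block_size):
    """Mirror of the extraction loop: repeatedly take the best chain,
    consume its anchors, and report chains reaching min_block_size."""
    remaining = list(anchors)
    blocks = []
    while remaining:
        chain, orientation, score = best_chain_exhaustive(
            remaining, max_gap, gap_penalty)
        if not chain:
            break
        used = {(a.gene_a, a.gene_b) for a in chain}
        remaining = [a for a in remaining if (a.gene_a, a.gene_b) not in used]
        if len(chain) >= min_block_size:
            blocks.append((tuple(chain), orientation, score))
    return blocks


# ---------------------------------------------------------------------------
# Clique-percolation by literal k-subset enumeration


def cpm_communities_exhaustive(nodes, edges, k):
    """Communities from first principles: enumerate every k-subset that is
    a clique, connect k-cliques sharing k-1 nodes, union components."""
    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    kcliques = []
    for subset in itertools.combinations(sorted(nodes), k):
        if all(v in adj[u] for u, v in itertools.combinations(subset, 2)):
            kcliques.append(frozenset(subset))
    if not kcliques:
        return set()
    parent = list(range(len(kcliques)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i, j in itertools.combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) == k - 1:
            union(i, j)
    comps = defaultdict(set)
    for i, c in enumerate(kcliques):
        comps[find(i)] |= c
    return {frozenset(members) for members in comps.values()}


# ---------------------------------------------------------------------------
# Random additive trees for NJ consistency


def random_tree_distances(n_taxa, rng):
    """Random binary tree via recursive splitting; returns (labels,
    distance matrix (numpy), bipartitions as frozensets of labels)."""
    import numpy as np

    labels = [f"t{i:02d}" for i in range(n_taxa)]

    class Node:
        def __init__(self, leaves=None, children=None):
            self.leaves = leaves or []
            self.children = children or []   # (child, branch_length)

    def build(leafset):
        if len(leafset) == 1:
            return Node(leaves=list(leafset))
        k = int(rng.integers(1, len(leafset)))
        left, right = leafset[:k], leafset[k:]
        return Node(children=[(build(left), float(rng.uniform(0.1, 1.0))),
                              (build(right), float(rng.uniform(0.1, 1.0)))])

    shuffled = list(labels)
    rng.shuffle(shuffled)
    root = build(shuffled)

    # leaf depths per node -> pairwise distances through the root path
    dist = {l: {} for l in labels}

    def leaf_depths(node):
        if node.leaves:
            return {node.leaves[0]: 0.0}
        out = {}
        sides = []
        for child, length in node.children:
            depths = {l: d + length for l, d in leaf_depths(child).items()}
            sides.append(depths)
            out.update(depths)
        for l1, d1 in sides[0].items():
            for l2, d2 in sides[1].items():
                dist[l1][l2] = dist[l2][l1] = d1 + d2
        return out

    leaf_depths(root)
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = dist[a][b]

    # bipartitions: leafset under every internal edge
    full = frozenset(labels)
    anchor = min(labels)
    splits = set()

    def collect(node):
        if node.leaves:
            return frozenset(node.leaves)
        sets = []
        for child, _ in node.children:
            s = collect(child)
            sets.append(s)
        for s in sets:
            side = s if anchor not in s else full - s
            if 1 < len(side) < n - 1:
                splits.add(side)
        return frozenset().union(*sets)

    collect(root)
    return labels, D, splits


# ---------------------------------------------------------------------------
# Event-log replay (structural)


def replay_gene_orders(ancestor_orders, tree, events):
    """Reconstruct per-leaf gene orders (chrom -> gene id list) from the
    ancestral order and the event log alone.

    ``ancestor_orders``: dict chrom -> list of gene ids.
    """
    parent_of = {}

    def index(node, parent_label):
        if parent_label is not None:
            parent_of[node.label] = parent_label
        for child in node.children:
            index(child, node.label)

    index(tree.root, None)
    states = {tree.root.label: {c: list(g) for c, g in ancestor_orders.items()}}

    for ev in events:
        if ev.kind == "speciation":
            mapping = dict(zip(ev.parent_genes, ev.child_genes))
            src = states[parent_of[ev.branch]]
            states[ev.branch] = {
                chrom: [mapping[g] for g in genes]
                for chrom, genes in src.items()
            }
            continue
        genome = states[ev.branch]
        if ev.kind == "wgd":
            child_of = dict(zip(ev.parent_genes, ev.child_genes))
            placement = dict(ev.meta["placements"])
            for src_chrom, new_names in ev.meta["chrom_map"].items():
                for new_name in new_names:
                    genome[new_name] = [
                        child_of[g] for g in genome[src_chrom]
                        if g in child_of and placement[child_of[g]] == new_name
                    ]
        elif ev.kind in ("tandem_dup", "transposed_dup"):
            chrom, idx = ev.meta["chrom"], ev.meta["index"]
            genome[chrom].insert(idx, ev.child_genes[0])
        elif ev.kind == "loss":
            chrom, idx = ev.meta["chrom"], ev.meta["index"]
            assert genome[chrom][idx] == ev.parent_genes[0]
            del genome[chrom][idx]
        elif ev.kind == "fusion":
            chrom, idx = ev.meta["chrom"], ev.meta["index"]
            assert genome[chrom][idx] == ev.meta["replaced"]
            genome[chrom][idx] = ev.child_genes[0]
        elif ev.kind == "domain_loss":
            pass
        else:
            raise AssertionError(f"unknown event kind {ev.kind}")

    leaves = {}
    for node_label in [n.label for n in tree.walk() if n.is_leaf]:
        leaves[node_label] = states[node_label]
    return leaves
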