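"""Alignment, column filtering, distance-based tree inference with
bootstrap, and exemplar-anchored clade extraction.

Tree inference is neighbour joining on corrected protein distances
rather than maximum likelihood: downstream analyses need clades and
support values, and distance NJ is deterministic and exactly testable at
desk scale. This is the one deliberate methodological substitution in
the pipeline and is flagged here and in the README.

Domain trees and full-sequence trees share every code path; the only
difference is which residue range of each protein is fed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

#: Kimura correction saturates; p at or above this bound gets the cap.
SATURATION_P = 0.85
SATURATION_DISTANCE = 5.0

GAP = "-"


@dataclass
class MultipleAlignment:
    """Gapped rows keyed by gene id; all rows equal length."""

    rows: dict[str, str]
    flags: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace(GAP, "")

    def matrix(self) -> np.ndarray:
        """Rows as a 2-D uint8 character matrix (gap = ord('-'))."""
        return np.array([np.frombuffer(s.encode(), dtype=np.uint8)
                         for s in self.rows.values()])


# ---------------------------------------------------------------------------
# Pairwise alignment and progressive MSA


def _pairwise_aligner() -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _submat.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _align_pair(a: str, b: str,
                aligner: _BioAlign.PairwiseAligner) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    sa, sb = aln[0], aln[1]
    return str(sa), str(sb)


def pairwise_identity(a: str, b: str,
                      aligner: _BioAlign.PairwiseAligner | None = None) -> float:
    """Percent identity over global alignment columns; gap columns count
    as mismatches."""
    if not a and not b:
        return 100.0
    if not a or not b:
        return 0.0
    aligner = aligner or _pairwise_aligner()
    sa, sb = _align_pair(a, b, aligner)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
    return 100.0 * matches / len(sa)


def progressive_msa(sequences: dict[str, str]) -> MultipleAlignment:
    """Center-star multiple alignment.

    The center is the sequence minimizing the summed pairwise alignment
    distance; every other sequence is aligned to the center and merged
    under the once-a-gap-always-a-gap rule.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    for name, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence {name!r}")
    names = list(sequences)
    aligner = _pairwise_aligner()

    # choose center (cache pairwise alignments center-candidate x others)
    dist_sum = {n: 0.0 for n in names}
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            sa, sb = _align_pair(sequences[ni], sequences[nj], aligner)
            matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
            d = 1.0 - matches / len(sa)
            dist_sum[ni] += d
            dist_sum[nj] += d
    center = min(names, key=lambda n: (dist_sum[n], n))

    master = sequences[center]          # center row with accumulated gaps
    others: dict[str, str] = {}         # merged non-center rows
    for name in names:
        if name == center:
            continue
        ca, sa = _align_pair(sequences[center], sequences[name], aligner)
        master, others, row = _merge_into_master(master, others, ca, sa)
        others[name] = row
    rows = {n: (master if n == center else others[n]) for n in names}
    aln = MultipleAlignment(rows=rows)
    for name in names:
        assert aln.ungapped(name) == sequences[name]
    return aln


def _merge_into_master(master: str, others: dict[str, str], center_new: str,
                       other_new: str) -> tuple[str, dict[str, str], str]:
    """Merge one pairwise (center, other) alignment into the running MSA.

    ``master`` is the center with all gaps accumulated so far;
    ``center_new`` is the center as aligned in the new pairwise
    alignment. Gap columns are reconciled under once-a-gap-always-a-gap:
    a column present in one view but not the other becomes a gap column
    on the opposite side.
    """
    i = j = 0
    out_master: list[str] = []
    out_other: list[str] = []
    insert_old: list[bool] = []  # True where previously merged rows need a gap
    while i < len(master) or j < len(center_new):
        mc = master[i] if i < len(master) else None
        nc = center_new[j] if j < len(center_new) else None
        if mc == GAP:
            # gap accumulated from an earlier merge; absent from this
            # pairwise alignment
            out_master.append(GAP)
            out_other.append(GAP)
            insert_old.append(False)
            i += 1
        elif nc == GAP or mc is None:
            # this pairwise alignment opened a new gap in the center
            out_master.append(GAP)
            out_other.append(other_new[j])
            insert_old.append(True)
            j += 1
        else:
            # both views hold the same center residue
            out_master.append(mc)
            out_other.append(other_new[j])
            insert_old.append(False)
            i += 1
            j += 1
    new_master = "".join(out_master)
    if any(insert_old):
        rebuilt = {}
        for name, row in others.items():
            chars = []
            k = 0
            for is_new in insert_old:
                if is_new:
                    chars.append(GAP)
                else:
                    chars.append(row[k])
                    k += 1
            rebuilt[name] = "".join(chars)
        others = rebuilt
    return new_master, others, "".join(out_other)


def clean_alignment(aln: MultipleAlignment,
                    occupancy: float = 0.5) -> MultipleAlignment:
    """Drop columns whose non-gap fraction is below ``occupancy``
    (boundary inclusive: a column at exactly the threshold is kept)."""
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    n = len(aln.rows)
    keep = []
    cols = list(zip(*aln.rows.values()))
    for c, col in enumerate(cols):
        frac = sum(1 for ch in col if ch != GAP) / n
        if frac >= occupancy and frac > 0:
            keep.append(c)
    if not keep:
        raise ValueError(
            "no columns left after occupancy filtering; lower the occupancy"
        )
    rows = {name: "".join(s[c] for c in keep) for name, s in aln.rows.items()}
    return MultipleAlignment(rows=rows)


# ---------------------------------------------------------------------------
# Distances


def kimura_correction(p: float) -> float:
    """Kimura's protein distance: ``-ln(1 - p - 0.2 p^2)``, capped at the
    saturation bound."""
    if p >= SATURATION_P:
        return SATURATION_DISTANCE
    return -math.log(1.0 - p - 0.2 * p * p)


def distance_matrix(aln: MultipleAlignment,
                    correction: str = "kimura") -> tuple[list[str], np.ndarray]:
    """Pairwise distances from shared non-gap columns.

    p = mismatches / shared columns; ``correction`` is ``kimura`` or
    ``p`` (uncorrected). A pair with zero shared columns is an error.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    if correction not in ("kimura", "p"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = aln.ids
    mat = aln.matrix()
    gap = ord(GAP)
    nongap = mat != gap
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {ids[i]!r} and {ids[j]!r}")
            p = float((mat[i][shared] != mat[j][shared]).sum()) / n_shared
            d = kimura_correction(p) if correction == "kimura" else p
            dist[i, j] = dist[j, i] = d
    return ids, dist


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> dendropy.Tree:
    """Canonical neighbour joining (Q criterion, Studier-Keppler updates).

    Deterministic: ties in Q choose the smallest (label, label) pair;
    negative branch lengths are clamped to zero.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in ids:
        taxon = taxa.new_taxon(str(name))
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    labels = [str(x) for x in ids]
    active = list(range(n))
    D = dist.copy()

    while len(active) > 2:
        m = len(active)
        row_sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - row_sums[i] - row_sums[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        m2 = m - 2
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2 * m2)
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # Studier-Keppler distance update; reuse slot i for the new node
        for k in active:
            if k == i or k == j:
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    # final join: graft the remaining node onto the other with the full
    # residual distance (yields the unrooted star for 3 taxa)
    i, j = active
    if not nodes[i].is_leaf():
        root, other = nodes[i], nodes[j]
    else:
        root, other = nodes[j], nodes[i]
    root.add_child(other)
    other.edge.length = max(D[i, j], 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as the leaf-label side not containing the
    lexicographically smallest taxon."""
    all_taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = all_taxa[0]
    full = frozenset(all_taxa)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            splits.add(side)
    return splits


def _resample(aln: MultipleAlignment,
              rng: np.random.Generator) -> MultipleAlignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    rows = {name: "".join(s[c] for c in cols) for name, s in aln.rows.items()}
    return MultipleAlignment(rows=rows)


def bootstrap_support(aln: MultipleAlignment, n_reps: int = 100,
                      seed: int = 0,
                      correction: str = "kimura") -> dendropy.Tree:
    """NJ tree from the full alignment, with internal-node labels set to
    the percentage of column-resampled replicates containing each
    bipartition."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, dist = distance_matrix(aln, correction)
    tree = nj_tree(ids, dist)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = _resample(aln, rng)
        try:
            rep_ids, rep_dist = distance_matrix(rep, correction)
        except ValueError:  # a pair lost all shared columns in this replicate
            continue
        rep_tree = nj_tree(rep_ids, rep_dist)
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = all_taxa[0]
    full = frozenset(all_taxa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            support = 100.0 * counts.get(side, 0) / n_reps
            node.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# Clade assignment


@dataclass
class CladeAssignment:
    labels: dict[str, str]            # gene -> clade label (or "unresolved")
    support: dict[str, float]         # clade label -> support at defining node
    non_monophyletic: set[str]


def _node_support(node: dendropy.Node) -> float:
    """Missing support labels are treated as 100 (not contradicted)."""
    if node.label is None:
        return 100.0
    try:
        return float(node.label)
    except ValueError:
        return 100.0


def assign_clades(tree: dendropy.Tree, reference_labels: dict[str, str],
                  min_support: float = 70.0) -> CladeAssignment:
    """Exemplar-anchored clade extraction.

    Each clade is the maximal monophyletic group containing every
    exemplar of one label, no exemplar of another, and support at least
    ``min_support`` at its defining node. Genes in no such group are
    ``unresolved``; labels whose exemplars cannot be covered by any clean
    node are reported non-monophyletic.
    """
    # monophyly is only defined on a rooted view; the seed node is the root
    tree.is_rooted = True
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    exemplars: dict[str, set[str]] = {}
    for gene, label in reference_labels.items():
        if gene not in leaf_labels:
            raise ValueError(f"exemplar {gene!r} not in tree")
        exemplars.setdefault(label, set()).add(gene)

    assignment: dict[str, str] = {}
    support: dict[str, float] = {}
    non_mono: set[str] = set()
    foreign_by_label = {
        label: set().union(*(g for l, g in exemplars.items() if l != label))
        if len(exemplars) > 1 else set()
        for label in exemplars
    }
    for label in sorted(exemplars):
        genes = exemplars[label]
        mrca = tree.mrca(taxa=[l.taxon for l in tree.leaf_node_iter()
                               if l.taxon.label in genes])
        clade_leaves = {l.taxon.label for l in mrca.leaf_iter()}
        if clade_leaves & foreign_by_label[label]:
            non_mono.add(label)
            continue
        # climb while the clade stays clean of foreign exemplars, then
        # settle on the largest clean node meeting the support bound
        path = [mrca]
        node = mrca
        while node.parent_node is not None:
            parent = node.parent_node
            parent_leaves = {l.taxon.label for l in parent.leaf_iter()}
            if parent_leaves & foreign_by_label[label]:
                break
            path.append(parent)
            node = parent
        defining = next((n for n in reversed(path)
                         if _node_support(n) >= min_support), None)
        if defining is None:
            continue
        support[label] = _node_support(defining)
        for leaf in defining.leaf_iter():
            assignment[leaf.taxon.label] = label
    for leaf in leaf_labels:
        assignment.setdefault(leaf, "unresolved")
    return CladeAssignment(labels=assignment, support=support,
                           non_monophyletic=non_mono)


def slice_to_domain(sequences: dict[str, str],
                    spans: dict[str, tuple[int, int]]) -> dict[str, str]:
    """Restrict each protein to its domain residue span; genes without a
    span are dropped. Feeding the result to the same MSA/tree code yields
    the domain tree."""
    out = {}
    for name, seq in sequences.items():
        if name in spans:
            s, e = spans[name]
            out[name] = seq[s:e]
    return out
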