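"""Forward simulator of genome and protein evolution.

Evolves an ancestral genome down a species tree, planting whole-genome
duplications/triplications, tandem and transposed gene duplications, gene
losses, loss of the second protein domain, and chimeric fusions of
paralogs. Emits per-leaf FASTA+BED datasets together with a ground-truth
:class:`EventLog` so every downstream stage of the pipeline can be scored
against what actually happened.

Family genes carry a two-domain architecture: an N-flank, a first
catalytic-like domain block, a linker, a second allosteric-like domain
block, and a C-flank. Duplicates may lose the second block, which is how
single-domain family members arise in the simulation.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from . import seqio
from .seqio import AnnotatedGenome, GeneRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Domain names used across the pipeline.
DOMAIN_FIRST = "HMGL-like"
DOMAIN_SECOND = "LeuA"

GENE_SPACING = 100  # bp between consecutive gene models when laying out BED


# ---------------------------------------------------------------------------
# Species tree


@dataclass
class TreeNode:
    label: str
    length: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree; every edge is identified by its child node label.

    Branch lengths are expected substitutions per site. The root carries its
    own (possibly zero-length) branch so that events such as a WGD shared by
    all leaves can be placed on it.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.validate()

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = seqio.read_newick(newick)
        counter = itertools.count(1)

        auto_labelled: set[int] = set()

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = str(dnode.label)
            else:
                label = f"n{next(counter)}"
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = TreeNode(label=label, length=float(length))
            if dnode.taxon is None and not dnode.label:
                auto_labelled.add(id(node))
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        if id(root) in auto_labelled:
            root.label = "root"
        return cls(root)

    def validate(self) -> None:
        labels = [n.label for n in self.walk()]
        if len(labels) != len(set(labels)):
            raise ValueError("species tree node labels are not unique")
        leaf_labels = self.leaf_labels()
        if len(leaf_labels) != len(set(leaf_labels)):
            raise ValueError("duplicate leaf labels")
        for node in self.walk():
            if node is not self.root and node.length <= 0:
                raise ValueError(f"branch {node.label!r} has non-positive length")

    def walk(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.walk() if n.is_leaf]

    def branch_ids(self) -> list[str]:
        return [n.label for n in self.walk()]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class EvolutionConfig:
    """Rates and sizes governing a simulation run.

    Duplication/loss/fusion rates are per family gene per unit branch
    length (fusion: per genome per branch length unit); the background
    genome evolves only by substitution and polyploidy.
    """

    rate_tandem: float = 0.0
    rate_transposed: float = 0.0
    rate_loss: float = 0.0
    rate_fusion: float = 0.0
    p_domain_loss: float = 0.0
    wgd_events: list[tuple[str, int]] = field(default_factory=list)
    wgd_retention: float = 0.6
    subst_model: str = "uniform"
    n_background_genes: int = 50
    n_chromosomes: int = 2
    n_family_genes: int = 1
    background_len: tuple[int, int] = (80, 140)
    len_flank_n: int = 30
    len_domain1: int = 80
    len_linker: int = 10
    len_domain2: int = 50
    len_flank_c: int = 20
    seed: int = 0

    @property
    def family_protein_length(self) -> int:
        return (self.len_flank_n + self.len_domain1 + self.len_linker
                + self.len_domain2 + self.len_flank_c)

    def validate(self) -> None:
        for name in ("rate_tandem", "rate_transposed", "rate_loss", "rate_fusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_domain_loss <= 1:
            raise ValueError("p_domain_loss must be in [0, 1]")
        if not 0 <= self.wgd_retention <= 1:
            raise ValueError("wgd_retention must be in [0, 1]")
        for branch, mult in self.wgd_events:
            if mult not in (2, 3):
                raise ValueError(f"wgd multiplier must be 2 or 3, got {mult}")
        if self.n_background_genes < 1:
            raise ValueError("n_background_genes must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.n_family_genes < 1:
            raise ValueError("n_family_genes must be >= 1")
        if self.subst_model not in ("uniform", "blosum"):
            raise ValueError(f"unknown subst_model {self.subst_model!r}")


# ---------------------------------------------------------------------------
# Events / ground truth


@dataclass
class SimEvent:
    kind: str  # speciation | wgd | tandem_dup | transposed_dup | loss | domain_loss | fusion
    branch: str
    parent_genes: list[str]
    child_genes: list[str]
    breakpoints: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class GeneTruth:
    """Per-leaf-gene ground truth used by acceptance tests."""

    gene_id: str
    genome_id: str
    is_family: bool
    has_domain1: bool
    has_domain2: bool
    origin: str  # ancestral | tandem | transposed | wgd | fusion
    wgd_groups: frozenset
    fused: bool

    @property
    def architecture(self) -> str:
        if self.has_domain1 and self.has_domain2:
            return "IPMS-like"
        if self.has_domain1:
            return "MAM-like"
        return "none"


@dataclass
class EventLog:
    """Ordered record of every simulated event plus the generating tree."""

    events: list[SimEvent]
    tree: SpeciesTree
    leaf_truth: dict[str, GeneTruth] = field(default_factory=dict)

    def events_of_kind(self, kind: str) -> list[SimEvent]:
        return [e for e in self.events if e.kind == kind]

    def expected_duplication_calls(self, genomes: list[AnnotatedGenome],
                                   tandem_gap: int = 5) -> dict[str, str]:
        """Ground-truth duplication type per leaf family gene.

        Mirrors the vocabulary of the downstream classifier cascade:
        tandem > syntenic_wgd > transposed > dispersed > singleton.
        """
        calls: dict[str, str] = {}
        for genome in genomes:
            fam = [g for g in genome.genes()
                   if self.leaf_truth[g.gene_id].is_family]
            fam_ids = {g.gene_id for g in fam}
            group_members: dict[object, set[str]] = {}
            for g in fam:
                for grp in self.leaf_truth[g.gene_id].wgd_groups:
                    group_members.setdefault(grp, set()).add(g.gene_id)
            by_chrom: dict[str, list[GeneRecord]] = {}
            for g in fam:
                by_chrom.setdefault(g.chrom, []).append(g)
            for g in fam:
                truth = self.leaf_truth[g.gene_id]
                tandem = any(
                    o.gene_id != g.gene_id
                    and abs(o.ordinal - g.ordinal) <= tandem_gap
                    for o in by_chrom[g.chrom]
                )
                if tandem:
                    calls[g.gene_id] = "tandem"
                    continue
                wgd_pair = any(
                    len(group_members.get(grp, ())) >= 2
                    for grp in truth.wgd_groups
                )
                if wgd_pair:
                    calls[g.gene_id] = "syntenic_wgd"
                    continue
                if truth.origin == "transposed":
                    calls[g.gene_id] = "transposed"
                    continue
                calls[g.gene_id] = "dispersed" if len(fam_ids) > 1 else "singleton"
        return calls


# ---------------------------------------------------------------------------
# Internal genome state


@dataclass
class _SimGene:
    gene_id: str
    protein: str
    is_family: bool = False
    domain1: Optional[tuple[int, int]] = None
    domain2: Optional[tuple[int, int]] = None
    origin: str = "ancestral"
    wgd_groups: frozenset = frozenset()
    fused: bool = False
    strand: str = "+"


@dataclass
class _SimGenome:
    chromosomes: dict[str, list[_SimGene]]

    def genes(self):
        for chrom in self.chromosomes.values():
            yield from chrom

    def family_positions(self) -> list[tuple[str, int]]:
        out = []
        for cname, chrom in self.chromosomes.items():
            for i, g in enumerate(chrom):
                if g.is_family:
                    out.append((cname, i))
        return out


def _branch_rng(seed: int, branch: str, salt: str = "") -> np.random.Generator:
    digest = hashlib.blake2b(f"{seed}:{branch}:{salt}".encode(),
                             digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


_BLOSUM_WEIGHTS = None


def _blosum_weights() -> np.ndarray:
    """Row-normalized exp(BLOSUM62/2) with zeroed diagonal, for the optional
    similarity-biased replacement scheme."""
    global _BLOSUM_WEIGHTS
    if _BLOSUM_WEIGHTS is None:
        from .homology import load_matrix
        mat = load_matrix("BLOSUM62")
        w = np.exp(mat / 2.0)
        np.fill_diagonal(w, 0.0)
        _BLOSUM_WEIGHTS = w / w.sum(axis=1, keepdims=True)
    return _BLOSUM_WEIGHTS


def mutate_protein(protein: str, p: float, rng: np.random.Generator,
                   scheme: str = "uniform") -> str:
    """Replace each site independently with probability ``p``.

    ``uniform`` draws the replacement uniformly from the 19 other residues;
    ``blosum`` draws proportionally to exponentiated substitution scores.
    """
    if p <= 0:
        return protein
    codes = np.frombuffer(protein.encode(), dtype=np.uint8)
    idx = np.searchsorted(_AA_ARRAY, codes)
    hit = rng.random(len(idx)) < p
    n_hit = int(hit.sum())
    if n_hit == 0:
        return protein
    if scheme == "uniform":
        shift = rng.integers(1, 20, size=n_hit)
        new = (idx[hit] + shift) % 20
    elif scheme == "blosum":
        weights = _blosum_weights()
        new = np.array([rng.choice(20, p=weights[i]) for i in idx[hit]])
    else:
        raise ValueError(f"unknown substitution scheme {scheme!r}")
    idx = idx.copy()
    idx[hit] = new
    return _AA_ARRAY[idx].tobytes().decode()


# ---------------------------------------------------------------------------
# Ancestor construction


def _build_ancestor(cfg: EvolutionConfig, rng: np.random.Generator,
                    counter: itertools.count) -> _SimGenome:
    cfg.validate()
    chromosomes: dict[str, list[_SimGene]] = {}
    for c in range(cfg.n_chromosomes):
        genes = []
        for _ in range(cfg.n_background_genes):
            length = int(rng.integers(cfg.background_len[0],
                                      cfg.background_len[1] + 1))
            genes.append(_SimGene(
                gene_id=f"g{next(counter):05d}",
                protein=random_protein(length, rng),
                strand="+" if rng.random() < 0.5 else "-",
            ))
        chromosomes[f"chr{c + 1}"] = genes
    # family genes in the middle of chromosomes, round-robin
    d1_start = cfg.len_flank_n
    d1_end = d1_start + cfg.len_domain1
    d2_start = d1_end + cfg.len_linker
    d2_end = d2_start + cfg.len_domain2
    chrom_names = list(chromosomes)
    for f in range(cfg.n_family_genes):
        cname = chrom_names[f % len(chrom_names)]
        protein = random_protein(cfg.family_protein_length, rng)
        gene = _SimGene(
            gene_id=f"g{next(counter):05d}",
            protein=protein,
            is_family=True,
            domain1=(d1_start, d1_end),
            domain2=(d2_start, d2_end),
        )
        mid = len(chromosomes[cname]) // 2
        chromosomes[cname].insert(mid, gene)
    return _SimGenome(chromosomes=chromosomes)


def build_ancestral_genome(cfg: EvolutionConfig) -> AnnotatedGenome:
    """Construct the pre-speciation genome: background genes plus one or
    more two-domain family genes at chromosome-central positions."""
    counter = itertools.count()
    rng = _branch_rng(cfg.seed, "ancestor")
    sim = _build_ancestor(cfg, rng, counter)
    return _to_annotated(sim, "ancestor")


def _to_annotated(sim: _SimGenome, genome_id: str) -> AnnotatedGenome:
    records = []
    for cname in sorted(sim.chromosomes):
        pos = 0
        for gene in sim.chromosomes[cname]:
            start = pos
            end = start + 3 * len(gene.protein)
            pos = end + GENE_SPACING
            records.append(GeneRecord(
                gene_id=gene.gene_id, genome_id=genome_id, chrom=cname,
                start=start, end=end, strand=gene.strand,
                protein=gene.protein,
            ))
    return AnnotatedGenome.from_records(genome_id, records)


# ---------------------------------------------------------------------------
# Chimeras


def make_chimera(a: str, b: str, breakpoints: list[int]) -> str:
    """Splice two proteins at the given residue indices, alternating
    segments and starting with ``a``."""
    if list(breakpoints) != sorted(set(breakpoints)):
        raise ValueError("breakpoints must be strictly increasing")
    limit = min(len(a), len(b))
    for bp in breakpoints:
        if bp < 0 or bp > limit:
            raise ValueError(
                f"breakpoint {bp} outside aligned range [0, {limit}]")
    bounds = [0, *breakpoints]
    parts = []
    for i, start in enumerate(bounds):
        src = a if i % 2 == 0 else b
        end = breakpoints[i] if i < len(breakpoints) else len(src)
        parts.append(src[start:end])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Evolution along the tree


class _Evolver:
    def __init__(self, tree: SpeciesTree, cfg: EvolutionConfig):
        cfg.validate()
        self.tree = tree
        self.cfg = cfg
        self.counter = itertools.count()
        self.events: list[SimEvent] = []
        self.wgd_by_branch: dict[str, int] = dict(cfg.wgd_events)
        unknown = set(self.wgd_by_branch) - set(tree.branch_ids())
        if unknown:
            raise ValueError(f"wgd placed on unknown branch(es): {sorted(unknown)}")
        self.group_counter = itertools.count()

    def run(self) -> tuple[list[AnnotatedGenome], EventLog]:
        cfg = self.cfg
        ancestor = _build_ancestor(cfg, _branch_rng(cfg.seed, "ancestor"),
                                   self.counter)
        leaves: dict[str, _SimGenome] = {}

        def descend(node: TreeNode, genome: _SimGenome) -> None:
            self._evolve_branch(genome, node)
            if node.is_leaf:
                leaves[node.label] = genome
                return
            for child in node.children:
                descend(child, self._speciate(genome, child.label))

        descend(self.tree.root, ancestor)

        log = EventLog(events=self.events, tree=self.tree)
        genomes = []
        for label in self.tree.leaf_labels():
            sim = leaves[label]
            genomes.append(_to_annotated(sim, label))
            for gene in sim.genes():
                log.leaf_truth[gene.gene_id] = GeneTruth(
                    gene_id=gene.gene_id, genome_id=label,
                    is_family=gene.is_family,
                    has_domain1=gene.domain1 is not None,
                    has_domain2=gene.domain2 is not None,
                    origin=gene.origin, wgd_groups=gene.wgd_groups,
                    fused=gene.fused,
                )
        return genomes, log

    # -- helpers

    def _new_id(self) -> str:
        return f"g{next(self.counter):05d}"

    def _speciate(self, genome: _SimGenome, branch: str) -> _SimGenome:
        parents, children = [], []
        chroms: dict[str, list[_SimGene]] = {}
        for cname, genes in genome.chromosomes.items():
            copies = []
            for g in genes:
                child = replace(g, gene_id=self._new_id())
                parents.append(g.gene_id)
                children.append(child.gene_id)
                copies.append(child)
            chroms[cname] = copies
        self.events.append(SimEvent(
            kind="speciation", branch=branch,
            parent_genes=parents, child_genes=children,
        ))
        return _SimGenome(chromosomes=chroms)

    def _evolve_branch(self, genome: _SimGenome, node: TreeNode) -> None:
        cfg = self.cfg
        branch = node.label
        t = node.length
        rng = _branch_rng(cfg.seed, branch, "events")

        if t > 0:
            p = 1.0 - float(np.exp(-t))
            srng = _branch_rng(cfg.seed, branch, "subst")
            for gene in genome.genes():
                gene.protein = mutate_protein(gene.protein, p, srng,
                                              cfg.subst_model)

        if branch in self.wgd_by_branch:
            self._apply_wgd(genome, branch, self.wgd_by_branch[branch], rng)

        n_family = len(genome.family_positions())
        n_tandem = rng.poisson(cfg.rate_tandem * t * n_family)
        n_transposed = rng.poisson(cfg.rate_transposed * t * n_family)
        n_loss = rng.poisson(cfg.rate_loss * t * n_family)
        n_fusion = rng.poisson(cfg.rate_fusion * t)

        for _ in range(n_tandem):
            self._tandem_dup(genome, branch, rng)
        for _ in range(n_transposed):
            self._transposed_dup(genome, branch, rng)
        for _ in range(n_loss):
            self._loss(genome, branch, rng)
        for _ in range(n_fusion):
            self._fusion(genome, branch, rng)

    def _apply_wgd(self, genome: _SimGenome, branch: str, mult: int,
                   rng: np.random.Generator) -> None:
        cfg = self.cfg
        parents, children, placements = [], [], []
        chrom_map: dict[str, list[str]] = {}
        new_chroms: dict[str, list[_SimGene]] = {}
        for cname in list(genome.chromosomes):
            chrom_map[cname] = []
            for k in range(1, mult):
                new_name = f"{cname}.{k}" if mult > 2 else f"{cname}.d"
                chrom_map[cname].append(new_name)
                copies = []
                for g in genome.chromosomes[cname]:
                    if rng.random() >= cfg.wgd_retention:
                        continue
                    grp = next(self.group_counter)
                    child = replace(
                        g, gene_id=self._new_id(), origin="wgd",
                        wgd_groups=g.wgd_groups | {grp},
                    )
                    g.wgd_groups = g.wgd_groups | {grp}
                    parents.append(g.gene_id)
                    children.append(child.gene_id)
                    placements.append((child.gene_id, new_name))
                    copies.append(child)
                new_chroms[new_name] = copies
        genome.chromosomes.update(new_chroms)
        self.events.append(SimEvent(
            kind="wgd", branch=branch, parent_genes=parents,
            child_genes=children,
            meta={"multiplier": mult, "chrom_map": chrom_map,
                  "placements": placements},
        ))

    def _pick_family(self, genome: _SimGenome,
                     rng: np.random.Generator) -> Optional[tuple[str, int]]:
        pos = genome.family_positions()
        if not pos:
            return None
        return pos[int(rng.integers(len(pos)))]

    def _maybe_domain_loss(self, genome: _SimGenome, child: _SimGene,
                           branch: str, rng: np.random.Generator) -> None:
        if child.domain2 is None or rng.random() >= self.cfg.p_domain_loss:
            return
        d2s, d2e = child.domain2
        child.protein = child.protein[:d2s] + child.protein[d2e:]
        child.domain2 = None
        self.events.append(SimEvent(
            kind="domain_loss", branch=branch,
            parent_genes=[child.gene_id], child_genes=[child.gene_id],
            meta={"removed": [d2s, d2e]},
        ))

    def _tandem_dup(self, genome: _SimGenome, branch: str,
                    rng: np.random.Generator) -> None:
        loc = self._pick_family(genome, rng)
        if loc is None:
            return
        cname, i = loc
        parent = genome.chromosomes[cname][i]
        child = replace(parent, gene_id=self._new_id(), origin="tandem",
                        wgd_groups=frozenset(), fused=False)
        genome.chromosomes[cname].insert(i + 1, child)
        self.events.append(SimEvent(
            kind="tandem_dup", branch=branch,
            parent_genes=[parent.gene_id], child_genes=[child.gene_id],
            meta={"chrom": cname, "index": i + 1},
        ))
        self._maybe_domain_loss(genome, child, branch, rng)

    def _transposed_dup(self, genome: _SimGenome, branch: str,
                        rng: np.random.Generator) -> None:
        loc = self._pick_family(genome, rng)
        if loc is None:
            return
        cname, i = loc
        parent = genome.chromosomes[cname][i]
        child = replace(parent, gene_id=self._new_id(), origin="transposed",
                        wgd_groups=frozenset(), fused=False)
        chrom_names = sorted(genome.chromosomes)
        target = chrom_names[int(rng.integers(len(chrom_names)))]
        index = int(rng.integers(len(genome.chromosomes[target]) + 1))
        if target == cname and index == i + 1:  # would be a tandem placement
            index = 0
        genome.chromosomes[target].insert(index, child)
        self.events.append(SimEvent(
            kind="transposed_dup", branch=branch,
            parent_genes=[parent.gene_id], child_genes=[child.gene_id],
            meta={"chrom": target, "index": index},
        ))
        self._maybe_domain_loss(genome, child, branch, rng)

    def _loss(self, genome: _SimGenome, branch: str,
              rng: np.random.Generator) -> None:
        pos = genome.family_positions()
        if len(pos) <= 1:  # keep the family alive in every lineage
            return
        cname, i = pos[int(rng.integers(len(pos)))]
        gone = genome.chromosomes[cname].pop(i)
        self.events.append(SimEvent(
            kind="loss", branch=branch,
            parent_genes=[gone.gene_id], child_genes=[],
            meta={"chrom": cname, "index": i},
        ))

    def _fusion(self, genome: _SimGenome, branch: str,
                rng: np.random.Generator) -> None:
        pos = genome.family_positions()
        candidates = [
            (c, i) for c, i in pos
            if genome.chromosomes[c][i].domain1 is not None
        ]
        # partners must share domain coordinates so breakpoints line up
        pairs = [
            ((c1, i1), (c2, i2))
            for (c1, i1), (c2, i2) in itertools.combinations(candidates, 2)
            if genome.chromosomes[c1][i1].domain1 == genome.chromosomes[c2][i2].domain1
            and len(genome.chromosomes[c1][i1].protein)
            == len(genome.chromosomes[c2][i2].protein)
        ]
        if not pairs:
            return
        (c1, i1), (c2, i2) = pairs[int(rng.integers(len(pairs)))]
        a = genome.chromosomes[c1][i1]
        b = genome.chromosomes[c2][i2]
        breakpoints = list(b.domain1)
        chimera_seq = make_chimera(a.protein, b.protein, breakpoints)
        child = replace(
            b, gene_id=self._new_id(), protein=chimera_seq, fused=True,
        )
        genome.chromosomes[c2][i2] = child
        self.events.append(SimEvent(
            kind="fusion", branch=branch,
            parent_genes=[a.gene_id, b.gene_id], child_genes=[child.gene_id],
            breakpoints=breakpoints,
            meta={"chrom": c2, "index": i2, "replaced": b.gene_id},
        ))


def evolve(tree: SpeciesTree,
           cfg: EvolutionConfig) -> tuple[list[AnnotatedGenome], EventLog]:
    """Evolve the ancestral genome down ``tree``; returns one annotated
    genome per leaf plus the complete event log."""
    return _Evolver(tree, cfg).run()


# ---------------------------------------------------------------------------
# Profile seed material and references


def domain_seed_alignments(cfg: EvolutionConfig, n_rows: int = 10,
                           divergence: float = 0.1) -> dict[str, list[str]]:
    """Seed alignments for building domain profiles: mutated replicates of
    the ancestral domain blocks (gap-free, so already aligned)."""
    counter = itertools.count()
    sim = _build_ancestor(cfg, _branch_rng(cfg.seed, "ancestor"), counter)
    fam = next(g for g in sim.genes() if g.is_family)
    rng = _branch_rng(cfg.seed, "profile-seeds")
    out: dict[str, list[str]] = {}
    for name, span in ((DOMAIN_FIRST, fam.domain1), (DOMAIN_SECOND, fam.domain2)):
        block = fam.protein[span[0]:span[1]]
        out[name] = [mutate_protein(block, divergence, rng)
                     for _ in range(n_rows)]
    return out


def reference_sequences(cfg: EvolutionConfig,
                        divergence: float = 0.08) -> dict[str, str]:
    """Labelled exemplar proteins for the divergence pre-filter: a
    two-domain reference and a single-domain (second block removed)
    reference derived from the ancestral family gene."""
    counter = itertools.count()
    sim = _build_ancestor(cfg, _branch_rng(cfg.seed, "ancestor"), counter)
    fam = next(g for g in sim.genes() if g.is_family)
    rng = _branch_rng(cfg.seed, "references")
    full = mutate_protein(fam.protein, divergence, rng)
    d2s, d2e = fam.domain2
    single = mutate_protein(fam.protein[:d2s] + fam.protein[d2e:],
                            divergence, rng)
    return {"ref_IPMS": full, "ref_MAM": single}


# ---------------------------------------------------------------------------
# Dataset writer

EVENT_SCHEMA = {
    "event_kind": str, "branch": str, "parent_ids": str,
    "child_ids": str, "breakpoints": str,
}


def write_dataset(genomes: list[AnnotatedGenome], log: EventLog,
                  outdir: str | Path) -> list[Path]:
    """Write one FASTA + one BED per genome plus the event truth TSV.

    Everything round-trips through the seqio readers losslessly.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    written = []
    for genome in genomes:
        fasta = outdir / f"{genome.genome_id}.faa"
        bed = outdir / f"{genome.genome_id}.bed"
        seqio.write_fasta({g.gene_id: g.protein for g in genome.genes()}, fasta)
        seqio.write_bed6(genome, bed)
        written += [fasta, bed]
    rows = [
        {
            "event_kind": e.kind, "branch": e.branch,
            "parent_ids": ",".join(e.parent_genes),
            "child_ids": ",".join(e.child_genes),
            "breakpoints": ",".join(map(str, e.breakpoints)),
        }
        for e in log.events
    ]
    truth = outdir / "events.tsv"
    seqio.write_table(rows, EVENT_SCHEMA, truth)
    written.append(truth)
    return written
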