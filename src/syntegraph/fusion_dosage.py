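"""Segment-wise fusion testing, domain conservation summaries,
duplication-type classification, and locus dosage profiling.

The fusion test splits each protein into before-domain / domain /
after-domain segments at its first-domain hit envelope, compares each
focal segment against the corresponding segments of two candidate donor
groups by pairwise global percent identity, and decides the donor per
segment with a two-sided rank-sum test. Segments won by different donors
flag a chimeric origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .domains import DomainHit
from .network import CliqueCommunity
from .phylo import MultipleAlignment, GAP, _pairwise_aligner, pairwise_identity
from .seqio import AnnotatedGenome, GeneRecord

logger = logging.getLogger(__name__)

SEGMENTS = ("before", "domain", "after")
DUPLICATION_TYPES = ("tandem", "syntenic_wgd", "transposed", "dispersed",
                     "singleton")


@dataclass
class SegmentTriplet:
    gene_id: str
    before: str
    domain: str
    after: str

    def segment(self, name: str) -> str:
        return getattr(self, name)


@dataclass
class FusionVerdict:
    segment: str
    mean_identity: dict[str, float]     # donor label -> mean % identity
    statistic: float
    pvalue: float
    verdict: str                        # donor label or "indistinguishable"


@dataclass
class FusionResult:
    verdicts: dict[str, FusionVerdict]  # segment -> verdict
    fusion_flagged: bool


@dataclass
class DuplicationCall:
    gene_id: str
    type: str
    evidence: str


@dataclass
class LocusProfile:
    genome_id: str
    community_id: str
    gene_count: int
    architecture_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Segments and the fusion test


def split_segments(gene: GeneRecord, hits: Sequence[DomainHit]) -> SegmentTriplet:
    """Partition a protein at its single first-domain hit envelope.

    Genes with multiple hits for the domain are excluded with a warning
    (the caller sees a ``None`` via :func:`split_all`); no hit is an
    error.
    """
    if not hits:
        raise ValueError(f"gene {gene.gene_id}: no domain hit to split at")
    if len(hits) > 1:
        raise ValueError(f"gene {gene.gene_id}: multiple domain hits")
    hit = hits[0]
    p = gene.protein
    return SegmentTriplet(gene_id=gene.gene_id, before=p[:hit.start],
                          domain=p[hit.start:hit.end], after=p[hit.end:])


def split_all(genes: Sequence[GeneRecord],
              hits_by_gene: dict[str, list[DomainHit]],
              domain_name: str = "HMGL-like") -> list[SegmentTriplet]:
    out = []
    for gene in genes:
        hits = [h for h in hits_by_gene.get(gene.gene_id, [])
                if h.domain_name == domain_name]
        if len(hits) > 1:
            logger.warning("gene %s: %d %s hits; excluded from segment "
                           "analysis", gene.gene_id, len(hits), domain_name)
            continue
        if not hits:
            continue
        out.append(split_segments(gene, hits))
    return out


def _segment_identities(focal: Sequence[SegmentTriplet],
                        donors: Sequence[SegmentTriplet],
                        segment: str, aligner) -> list[float]:
    vals = []
    for f in focal:
        fs = f.segment(segment)
        for d in donors:
            ds = d.segment(segment)
            if not fs and not ds:
                continue  # both empty: undefined, skip the pair
            vals.append(pairwise_identity(fs, ds, aligner))
    return vals


def fusion_test(focal: Sequence[SegmentTriplet],
                donor_a: Sequence[SegmentTriplet],
                donor_b: Sequence[SegmentTriplet],
                alpha: float = 0.05,
                labels: tuple[str, str] = ("donorA", "donorB")) -> FusionResult:
    """Per-segment donor assignment for a focal gene group.

    For each segment type, all pairwise focal x donor global percent
    identities are computed for both donor groups and compared with a
    two-sided Mann-Whitney rank-sum test; the higher-mean donor wins when
    p < alpha, otherwise the segment is indistinguishable. A fusion is
    flagged when different segments are won by different donors.
    """
    for group, name in ((focal, "focal"), (donor_a, labels[0]),
                        (donor_b, labels[1])):
        if not group:
            raise ValueError(f"group {name!r} is empty")
    aligner = _pairwise_aligner()
    verdicts: dict[str, FusionVerdict] = {}
    winners = set()
    for segment in SEGMENTS:
        ia = _segment_identities(focal, donor_a, segment, aligner)
        ib = _segment_identities(focal, donor_b, segment, aligner)
        if min(len(ia), len(ib)) < 4:
            warnings.warn(
                f"segment {segment!r}: fewer than 4 identity pairs; the "
                f"rank-sum test is underpowered", stacklevel=2)
        if not ia or not ib:
            verdicts[segment] = FusionVerdict(
                segment=segment,
                mean_identity={labels[0]: float(np.mean(ia)) if ia else 0.0,
                               labels[1]: float(np.mean(ib)) if ib else 0.0},
                statistic=float("nan"), pvalue=1.0,
                verdict="indistinguishable")
            continue
        if np.ptp(ia + ib) == 0:
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.mannwhitneyu(ia, ib, alternative="two-sided")
            stat, p = float(stat), float(p)
        mean_a, mean_b = float(np.mean(ia)), float(np.mean(ib))
        if p < alpha:
            verdict = labels[0] if mean_a > mean_b else labels[1]
            winners.add(verdict)
        else:
            verdict = "indistinguishable"
        verdicts[segment] = FusionVerdict(
            segment=segment,
            mean_identity={labels[0]: mean_a, labels[1]: mean_b},
            statistic=stat, pvalue=p, verdict=verdict)
    return FusionResult(verdicts=verdicts, fusion_flagged=len(winners) > 1)


# ---------------------------------------------------------------------------
# Conservation summary


def conservation_score(rows: dict[str, str],
                       threshold: float = 0.8) -> tuple[float, list[str], bool]:
    """Fraction of alignment columns whose modal residue reaches
    ``threshold`` frequency among non-gap rows (boundary inclusive).

    Returns (score, per-column classes 'conserved'/'variable'/'gap',
    degenerate flag for single-row input).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not rows:
        raise ValueError("no rows")
    seqs = list(rows.values())
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("rows have unequal lengths")
    if len(seqs) == 1:
        return 1.0, ["conserved"] * len(seqs[0]), True
    classes = []
    n_scored = 0
    n_conserved = 0
    for col in zip(*seqs):
        residues = [ch for ch in col if ch != GAP]
        if not residues:
            classes.append("gap")
            continue
        n_scored += 1
        top = max(residues.count(ch) for ch in set(residues))
        if top / len(residues) >= threshold:
            classes.append("conserved")
            n_conserved += 1
        else:
            classes.append("variable")
    score = n_conserved / n_scored if n_scored else 0.0
    return score, classes, False


def conservation_summary(aln: MultipleAlignment, clade_labels: dict[str, str],
                         threshold: float = 0.8) -> list[dict]:
    """Per-clade conservation scores over a shared domain alignment,
    ranked most-conserved first."""
    clades: dict[str, dict[str, str]] = {}
    for gene, row in aln.rows.items():
        label = clade_labels.get(gene)
        if label is not None:
            clades.setdefault(label, {})[gene] = row
    results = []
    for label in sorted(clades):
        score, classes, degenerate = conservation_score(clades[label], threshold)
        results.append({"clade": label, "score": score,
                        "n_genes": len(clades[label]),
                        "degenerate": degenerate,
                        "column_classes": classes})
    results.sort(key=lambda r: (-r["score"], r["clade"]))
    for rank, r in enumerate(results, 1):
        r["rank"] = rank
    return results


# ---------------------------------------------------------------------------
# Duplication classification


def classify_duplications(family_genes: Sequence[GeneRecord],
                          network: nx.Graph,
                          communities: Sequence[CliqueCommunity],
                          genomes: Sequence[AnnotatedGenome],
                          tandem_gap: int = 5) -> list[DuplicationCall]:
    """Decision cascade per family gene: tandem > syntenic_wgd >
    transposed > dispersed > singleton.

    - tandem: another family gene within ``tandem_gap`` ordinals on the
      same chromosome;
    - syntenic_wgd: anchored in an intra-genome block whose partner
      region contains a family gene, or sharing a cross-genome community
      with a same-genome paralog that sits in a different community;
    - transposed: has family homologs but no community membership;
    - dispersed: remaining multi-copy cases; singleton otherwise.
    """
    fam_ids = {g.gene_id for g in family_genes}
    by_genome_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in family_genes:
        by_genome_chrom.setdefault((g.genome_id, g.chrom), []).append(g)
        by_genome.setdefault(g.genome_id, []).append(g)

    communities_of: dict[str, set[str]] = {}
    genomes_of_community: dict[str, set[str]] = {}
    com_sizes: dict[str, frozenset] = {}
    gene_genome = {g.gene_id: g.genome_id for g in family_genes}
    for com in communities:
        com_sizes[com.community_id] = com.members
        for gid in com.members:
            communities_of.setdefault(gid, set()).add(com.community_id)
            if gid in gene_genome:
                genomes_of_community.setdefault(
                    com.community_id, set()).add(gene_genome[gid])

    # intra-genome block evidence: some anchor of a block pairing two
    # chromosomes of one genome has family genes close to BOTH of its
    # endpoints - the homoeologous-locus signature of a retained WGD pair
    blocks = network.graph.get("blocks") or []
    wgd_block_genes: dict[str, str] = {}
    homoeologous: set[tuple[str, str, str]] = set()  # (genome, chromA, chromB)
    for block in blocks:
        (ga, ca), (gb, cb) = block.chrom_pair
        if ga != gb or (ca == cb):
            continue
        homoeologous.add((ga, ca, cb))
        homoeologous.add((ga, cb, ca))
        fam_a = by_genome_chrom.get((ga, ca), ())
        fam_b = by_genome_chrom.get((gb, cb), ())
        if not fam_a or not fam_b:
            continue
        for anchor in block.anchors:
            near_a = [g for g in fam_a
                      if abs(g.ordinal - anchor.pos_a) <= tandem_gap]
            near_b = [g for g in fam_b
                      if abs(g.ordinal - anchor.pos_b) <= tandem_gap]
            if near_a and near_b:
                for g in near_a + near_b:
                    wgd_block_genes.setdefault(g.gene_id, block.block_id)

    calls = []
    for g in sorted(family_genes, key=lambda r: r.gene_id):
        neighbours = [
            o for o in by_genome_chrom[(g.genome_id, g.chrom)]
            if o.gene_id != g.gene_id and abs(o.ordinal - g.ordinal) <= tandem_gap
        ]
        if neighbours:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="tandem",
                evidence=f"adjacent:{neighbours[0].gene_id}"))
            continue
        if g.gene_id in wgd_block_genes:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="syntenic_wgd",
                evidence=f"block:{wgd_block_genes[g.gene_id]}"))
            continue
        my_coms = communities_of.get(g.gene_id, set())
        cross = {c for c in my_coms
                 if len(genomes_of_community.get(c, ())) > 1}
        # paralog at a distinct locus community only counts as WGD
        # evidence when the two loci sit on homoeologous chromosomes
        # (chromosomes paired by an intra-genome block)
        wgd_com = None
        if cross:
            for other in by_genome[g.genome_id]:
                if other.gene_id == g.gene_id:
                    continue
                other_coms = communities_of.get(other.gene_id, set())
                if (other_coms and not (other_coms & my_coms)
                        and (g.genome_id, g.chrom, other.chrom) in homoeologous):
                    wgd_com = other.gene_id
                    break
        if wgd_com is not None:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="syntenic_wgd",
                evidence=f"paralog-community:{wgd_com}"))
            continue
        has_homologs = len(fam_ids) > 1
        if has_homologs and not my_coms:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="transposed", evidence="no-community"))
            continue
        # conserved transposed locus: the gene's community is a smaller,
        # non-homoeologous satellite of a paralog's (ancestral) community
        relocated = None
        if my_coms:
            my_size = max(len(com_sizes.get(c, ())) for c in my_coms)
            for other in by_genome[g.genome_id]:
                if other.gene_id == g.gene_id:
                    continue
                other_coms = communities_of.get(other.gene_id, set())
                if not other_coms or (other_coms & my_coms):
                    continue
                if (g.genome_id, g.chrom, other.chrom) in homoeologous:
                    continue
                other_size = max(len(com_sizes.get(c, ()))
                                 for c in other_coms)
                if other_size > my_size:
                    relocated = other.gene_id
                    break
        if relocated is not None:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="transposed",
                evidence=f"relocated-locus:{relocated}"))
            continue
        if len(by_genome[g.genome_id]) > 1:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="dispersed", evidence="multi-copy"))
        else:
            calls.append(DuplicationCall(
                gene_id=g.gene_id, type="singleton", evidence=""))
    return calls


# ---------------------------------------------------------------------------
# Dosage profiling


def dosage_profile(genomes: Sequence[AnnotatedGenome],
                   family_genes: Sequence[GeneRecord],
                   communities: Sequence[CliqueCommunity],
                   architectures: dict[str, str]) -> list[LocusProfile]:
    """Per genome x community (locus) gene and architecture counts, plus
    an ``unassigned`` pseudo-locus so counts always sum to family size."""
    genome_ids = {g.genome_id for g in genomes}
    for g in family_genes:
        if g.genome_id not in genome_ids:
            raise ValueError(f"gene {g.gene_id} from unknown genome "
                             f"{g.genome_id!r}")
    com_of: dict[str, set[str]] = {}
    for com in communities:
        for gid in com.members:
            com_of.setdefault(gid, set()).add(com.community_id)
    profiles: dict[tuple[str, str], LocusProfile] = {}

    def bump(genome_id: str, community_id: str, arch: str) -> None:
        key = (genome_id, community_id)
        if key not in profiles:
            profiles[key] = LocusProfile(genome_id=genome_id,
                                         community_id=community_id,
                                         gene_count=0)
        prof = profiles[key]
        prof.gene_count += 1
        prof.architecture_counts[arch] = prof.architecture_counts.get(arch, 0) + 1

    for g in family_genes:
        arch = architectures.get(g.gene_id, "none")
        coms = com_of.get(g.gene_id)
        if not coms:
            bump(g.genome_id, "unassigned", arch)
        else:
            for c in sorted(coms):
                bump(g.genome_id, c, arch)
    return [profiles[k] for k in sorted(profiles)]


def dosage_deltas(profiles: Sequence[LocusProfile], genome_x: str,
                  genome_y: str) -> dict[str, int]:
    """Per-locus gene count difference (y minus x) between two genomes."""
    counts: dict[tuple[str, str], int] = {
        (p.genome_id, p.community_id): p.gene_count for p in profiles
    }
    loci = sorted({p.community_id for p in profiles})
    return {
        locus: counts.get((genome_y, locus), 0) - counts.get((genome_x, locus), 0)
        for locus in loci
    }


def dosage_report(profiles: Sequence[LocusProfile],
                  locus_pairs: Sequence[tuple[str, str]] = (),
                  genome_pairs: Sequence[tuple[str, str]] = (),
                  wgd_multiplier: dict[str, int] | None = None) -> dict:
    """Descriptive dosage flags (reported, never asserted as biology).

    - ``non_power_of_two``: genome/locus counts that are not 2^k (or the
      planted multiplier) multiples given a WGD history;
    - ``compensatory``: designated locus pairs whose count deltas across
      designated genome pairs have opposite signs.
    """
    report: dict = {"non_power_of_two": [], "compensatory": []}
    if wgd_multiplier:
        for p in profiles:
            mult = wgd_multiplier.get(p.genome_id)
            if not mult or p.community_id == "unassigned":
                continue
            n = p.gene_count
            ok = False
            m = 1
            while m <= n:
                if m == n:
                    ok = True
                    break
                m *= mult
            if not ok:
                report["non_power_of_two"].append(
                    {"genome": p.genome_id, "locus": p.community_id,
                     "count": n, "multiplier": mult})
    for gx, gy in genome_pairs:
        deltas = dosage_deltas(profiles, gx, gy)
        for la, lb in locus_pairs:
            da, db = deltas.get(la, 0), deltas.get(lb, 0)
            if da * db < 0:
                report["compensatory"].append(
                    {"genomes": (gx, gy), "loci": (la, lb),
                     "deltas": (da, db)})
    return report


LOCUS_SCHEMA = {
    "genome_id": str, "community_id": str, "gene_count": int,
    "n_ipms_like": int, "n_mam_like": int,
}


def profiles_to_rows(profiles: Sequence[LocusProfile]) -> list[dict]:
    return [{
        "genome_id": p.genome_id, "community_id": p.community_id,
        "gene_count": p.gene_count,
        "n_ipms_like": p.architecture_counts.get("IPMS-like", 0),
        "n_mam_like": p.architecture_counts.get("MAM-like", 0),
    } for p in profiles]


DUPLICATION_SCHEMA = {"gene_id": str, "type": str, "evidence": str}


def calls_to_rows(calls: Sequence[DuplicationCall]) -> list[dict]:
    return [{"gene_id": c.gene_id, "type": c.type, "evidence": c.evidence}
            for c in calls]
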