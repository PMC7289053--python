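"""Collinear-block detection by dynamic-programming anchor chaining.

Anchors are homologous gene pairs placed at ordinal (gene-rank)
coordinates on a chromosome pair. Chains must be strictly monotone on
both chromosomes, with per-step ordinal gaps bounded by ``max_gap``;
overlapping chains are resolved best-score-first with used anchors
removed. Defaults mirror the shipped values of the standard collinearity
tool this replaces: ``min_block_size=5``, ``max_gap=25``,
``gap_penalty=-1``, anchor scores capped at 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .homology import DEFAULT_K, DEFAULT_LAMBDA, HomologyHit
from .seqio import AnnotatedGenome

ANCHOR_SCORE_CAP = 50.0


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    pos_a: int
    pos_b: int
    score: float


@dataclass
class CollinearBlock:
    block_id: str
    anchors: list[Anchor]
    chrom_pair: tuple[tuple[str, str], tuple[str, str]]  # (genome, chrom) x 2
    orientation: str  # same | inverted
    block_score: float


@dataclass
class ChainParams:
    max_gap: int = 25
    gap_penalty: float = -1.0
    min_block_size: int = 5


def _chain_score(chain: Sequence[Anchor], gap_penalty: float) -> float:
    score = sum(a.score for a in chain)
    for prev, cur in zip(chain, chain[1:]):
        gap_a = cur.pos_a - prev.pos_a - 1
        gap_b = abs(cur.pos_b - prev.pos_b) - 1
        score += gap_penalty * (gap_a + gap_b)
    return score


def _best_chain_oriented(anchors: list[Anchor], orientation: str,
                         max_gap: int, gap_penalty: float) -> list[Anchor]:
    """Best chain under one orientation by DP over anchors sorted by
    pos_a. Ties prefer the lowest predecessor index."""
    flip = -1 if orientation == "inverted" else 1
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].pos_a, flip * anchors[i].pos_b,
                                  anchors[i].gene_a, anchors[i].gene_b))
    pos_a = [anchors[i].pos_a for i in order]
    pos_b = [flip * anchors[i].pos_b for i in order]
    score = [anchors[i].score for i in order]
    n = len(order)
    chain = list(score)
    pred = [-1] * n
    for i in range(n):
        for j in range(i):
            if pos_a[j] >= pos_a[i] or pos_b[j] >= pos_b[i]:
                continue
            gap_a = pos_a[i] - pos_a[j] - 1
            gap_b = pos_b[i] - pos_b[j] - 1
            if gap_a > max_gap or gap_b > max_gap:
                continue
            cand = chain[j] + score[i] + gap_penalty * (gap_a + gap_b)
            if cand > chain[i]:
                chain[i] = cand
                pred[i] = j
    if not n:
        return []
    best = max(range(n), key=lambda i: (chain[i], -i))
    out = []
    i = best
    while i != -1:
        out.append(anchors[order[i]])
        i = pred[i]
    out.reverse()
    return out


def _best_chain(anchors: list[Anchor], max_gap: int,
                gap_penalty: float) -> tuple[list[Anchor], str, float]:
    best_chain: list[Anchor] = []
    best_orient = "same"
    best_score = -math.inf
    for orientation in ("same", "inverted"):
        chain = _best_chain_oriented(anchors, orientation, max_gap, gap_penalty)
        if not chain:
            continue
        s = _chain_score(chain, gap_penalty)
        if s > best_score:
            best_chain, best_orient, best_score = chain, orientation, s
    return best_chain, best_orient, best_score


_NULL_PAIR = (("", ""), ("", ""))


def chain_anchors(anchors: Sequence[Anchor], max_gap: int = 25,
                  gap_penalty: float = -1.0, min_block_size: int = 5,
                  chrom_pair=_NULL_PAIR) -> list[CollinearBlock]:
    """Extract collinear blocks from one chromosome pair's anchors,
    best-score-first, consuming used anchors. Anchors are deduplicated
    per gene pair (best score kept) before chaining; chains shorter than
    ``min_block_size`` are discarded.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    dedup: dict[tuple[str, str], Anchor] = {}
    for a in anchors:
        key = (a.gene_a, a.gene_b)
        if key not in dedup or a.score > dedup[key].score:
            dedup[key] = a
    remaining = sorted(dedup.values(),
                       key=lambda a: (a.pos_a, a.pos_b, a.gene_a, a.gene_b))
    blocks = []
    while remaining:
        chain, orientation, s = _best_chain(remaining, max_gap, gap_penalty)
        if not chain:
            break
        used = set((a.gene_a, a.gene_b) for a in chain)
        remaining = [a for a in remaining if (a.gene_a, a.gene_b) not in used]
        if len(chain) >= min_block_size:
            blocks.append(CollinearBlock(
                block_id=f"c{len(blocks) + 1:04d}", anchors=chain,
                chrom_pair=chrom_pair, orientation=orientation,
                block_score=s,
            ))
    return blocks


def bit_like_score(raw_score: float, K: float = DEFAULT_K,
                   lam: float = DEFAULT_LAMBDA) -> float:
    """Bit-style rescaling of a raw alignment score, capped for chaining."""
    bits = (lam * raw_score - math.log(K)) / math.log(2.0)
    return min(max(bits, 0.0), ANCHOR_SCORE_CAP)


def collinearity_scan(genomes: Sequence[AnnotatedGenome],
                      hits: Sequence[HomologyHit],
                      params: ChainParams | None = None) -> list[CollinearBlock]:
    """Chain anchors for every genome pair, including each genome against
    itself (self-diagonal gene pairs excluded), per chromosome pair.

    Output order is deterministic: genome pairs, then chromosome pairs,
    then blocks best-score-first as extracted.
    """
    params = params or ChainParams()
    gene_pos: dict[str, tuple[str, str, int]] = {}
    for genome in genomes:
        for g in genome.genes():
            gene_pos[g.gene_id] = (g.genome_id, g.chrom, g.ordinal)

    # canonical anchor per unordered gene pair, grouped by chromosome pair
    groups: dict[tuple, dict[tuple[str, str], Anchor]] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        if h.query not in gene_pos or h.subject not in gene_pos:
            continue
        qa, qb = gene_pos[h.query], gene_pos[h.subject]
        if (qa, h.query) <= (qb, h.subject):
            ga, gb = h.query, h.subject
            pa, pb = qa, qb
        else:
            ga, gb = h.subject, h.query
            pa, pb = qb, qa
        key = ((pa[0], pa[1]), (pb[0], pb[1]))
        anchor = Anchor(gene_a=ga, gene_b=gb, pos_a=pa[2], pos_b=pb[2],
                        score=bit_like_score(h.score))
        bucket = groups.setdefault(key, {})
        prev = bucket.get((ga, gb))
        if prev is None or anchor.score > prev.score:
            bucket[(ga, gb)] = anchor

    blocks: list[CollinearBlock] = []
    counter = 1
    for key in sorted(groups):
        chains = chain_anchors(list(groups[key].values()),
                               max_gap=params.max_gap,
                               gap_penalty=params.gap_penalty,
                               min_block_size=params.min_block_size,
                               chrom_pair=key)
        for blk in chains:
            blk.block_id = f"b{counter:04d}"
            blocks.append(blk)
            counter += 1
    return blocks


# ---------------------------------------------------------------------------
# Writers

BLOCK_SCHEMA = {
    "block_id": str, "genome_a": str, "chrom_a": str, "genome_b": str,
    "chrom_b": str, "orientation": str, "block_score": float,
    "gene_a": str, "gene_b": str, "pos_a": int, "pos_b": int,
    "anchor_score": float,
}


def blocks_to_rows(blocks: Sequence[CollinearBlock]) -> list[dict]:
    rows = []
    for b in blocks:
        (ga, ca), (gb, cb) = b.chrom_pair
        for a in b.anchors:
            rows.append({
                "block_id": b.block_id, "genome_a": ga, "chrom_a": ca,
                "genome_b": gb, "chrom_b": cb, "orientation": b.orientation,
                "block_score": b.block_score, "gene_a": a.gene_a,
                "gene_b": a.gene_b, "pos_a": a.pos_a, "pos_b": a.pos_b,
                "anchor_score": a.score,
            })
    return rows


def rows_to_blocks(rows: Sequence[dict]) -> list[CollinearBlock]:
    by_id: dict[str, CollinearBlock] = {}
    for r in rows:
        blk = by_id.get(r["block_id"])
        if blk is None:
            blk = CollinearBlock(
                block_id=r["block_id"], anchors=[],
                chrom_pair=((r["genome_a"], r["chrom_a"]),
                            (r["genome_b"], r["chrom_b"])),
                orientation=r["orientation"], block_score=r["block_score"],
            )
            by_id[r["block_id"]] = blk
        blk.anchors.append(Anchor(
            gene_a=r["gene_a"], gene_b=r["gene_b"],
            pos_a=r["pos_a"], pos_b=r["pos_b"], score=r["anchor_score"],
        ))
    return list(by_id.values())


def write_collinearity_text(blocks: Sequence[CollinearBlock], path) -> None:
    """MCScanX-like ``.collinearity`` flat text for interoperability."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for b in blocks:
            (ga, ca), (gb, cb) = b.chrom_pair
            plus = "plus" if b.orientation == "same" else "minus"
            fh.write(f"## Alignment {b.block_id}: score={b.block_score:.1f} "
                     f"{ga}&{ca} vs {gb}&{cb} {plus}\n")
            for i, a in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{a.gene_a}\t{a.gene_b}\t"
                         f"{a.score:.1f}\n")
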