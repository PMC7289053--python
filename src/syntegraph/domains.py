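"""Profile-based domain detection and the divergence pre-filter.

Domains are detected with an ungapped position-specific scoring model
built from a seed alignment: the best window sum of per-column log-odds
over all offsets is compared with an empirical shuffle null (200 seeded
shuffles of the query), giving an assumption-free e-value. Hits pass at
an inclusive threshold (default 0.007).

The divergence filter removes candidate genes whose corrected distance
to every labelled reference exceeds a multiple of the references' own
median pairwise distance — the guard against highly diverged single-
domain clades that merely share the domain signature.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .phylo import (GAP, MultipleAlignment, _align_pair, _pairwise_aligner,
                    kimura_correction)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Inclusive e-value threshold for reporting a domain hit.
DEFAULT_EVALUE = 0.007
N_SHUFFLES = 200


@dataclass
class ProfileModel:
    """Per-column 20-residue log-odds scores (nats) plus background."""

    name: str
    log_odds: np.ndarray          # (length, 20)
    background: np.ndarray        # (20,)

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def validate(self) -> None:
        if not np.isfinite(self.log_odds).all():
            raise ValueError("profile log-odds contain non-finite values")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


@dataclass
class DomainHit:
    gene_id: str
    domain_name: str
    start: int
    end: int
    score: float
    evalue: float


def build_profile(seed_alignment: Sequence[str] | MultipleAlignment,
                  pseudocount: float = 1.0,
                  name: str = "profile",
                  background: np.ndarray | None = None) -> ProfileModel:
    """Build a log-odds profile from an aligned set of sequences.

    Columns with less than 50% occupancy are dropped before counting.
    ``log_odds[c][r] = ln((count + pc * bg_r) / (n_eff + pc) / bg_r)``
    where ``n_eff`` is the number of non-gap residues in the column.
    """
    if isinstance(seed_alignment, MultipleAlignment):
        rows = list(seed_alignment.rows.values())
    else:
        rows = list(seed_alignment)
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("seed alignment rows have unequal lengths")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)

    n_rows = len(rows)
    cols = []
    for c in range(len(rows[0])):
        col = [r[c] for r in rows]
        occupancy = sum(1 for ch in col if ch != GAP) / n_rows
        if occupancy >= 0.5:
            cols.append(col)
    if not cols:
        raise ValueError("no columns with >= 50% occupancy")

    log_odds = np.empty((len(cols), 20))
    for c, col in enumerate(cols):
        counts = np.zeros(20)
        n_eff = 0
        for ch in col:
            if ch == GAP:
                continue
            idx = _AA_INDEX.get(ch)
            if idx is None:
                raise ValueError(f"non-amino-acid character {ch!r} in column {c}")
            counts[idx] += 1
            n_eff += 1
        freqs = (counts + pseudocount * background) / (n_eff + pseudocount)
        log_odds[c] = np.log(freqs / background)
    model = ProfileModel(name=name, log_odds=log_odds, background=background)
    model.validate()
    return model


def _encode(protein: str) -> np.ndarray:
    out = np.empty(len(protein), dtype=np.int64)
    for i, ch in enumerate(protein):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"non-amino-acid character {ch!r} at position {i}")
        out[i] = idx
    return out


def window_scores(codes: np.ndarray, profile: ProfileModel) -> np.ndarray:
    """Ungapped window score at every offset (window = profile length)."""
    w = profile.length
    n_offsets = len(codes) - w + 1
    if n_offsets <= 0:
        return np.empty(0)
    # per-position emission scores, then moving-window sums
    idx = np.arange(w)
    per_pos = profile.log_odds[idx[None, :], codes[np.arange(n_offsets)[:, None] + idx]]
    return per_pos.sum(axis=1)


def passes_threshold(evalue: float, threshold: float = DEFAULT_EVALUE) -> bool:
    """Inclusion threshold: boundary value itself is included."""
    return evalue <= threshold


def scan(protein: str, profile: ProfileModel,
         evalue_threshold: float = DEFAULT_EVALUE,
         db_factor: float = 1.0, n_shuffles: int = N_SHUFFLES,
         seed: int = 0) -> list[DomainHit]:
    """Scan a protein with one profile.

    The e-value of a window score is the fraction of ``n_shuffles``
    shuffled versions of the protein whose best window scores at least as
    high, times ``db_factor``. Hits at or below the threshold are
    returned best-first with overlaps suppressed greedily. Proteins
    shorter than half the profile are rejected; a profile longer than
    twice the protein yields no hit (not an error).
    """
    if len(protein) < profile.length * 0.5:
        return []  # profile longer than 2x the protein: no hit, not an error
    codes = _encode(protein)
    scores = window_scores(codes, profile)
    if scores.size == 0:
        return []

    # empirical null from seeded shuffles of this protein (vectorized:
    # one big fancy-index over all shuffles x offsets x window columns)
    rng = np.random.default_rng(
        (zlib.crc32(protein.encode()) + seed * 1000003) & 0xFFFFFFFF)
    w = profile.length
    shuffled = np.tile(codes, (n_shuffles, 1))
    perm = rng.permuted(shuffled, axis=1)
    idx = np.arange(w)
    offsets = np.arange(len(codes) - w + 1)
    windows = perm[:, offsets[:, None] + idx]            # (S, n_off, w)
    per = profile.log_odds[idx[None, None, :], windows]  # (S, n_off, w)
    null_best = per.sum(axis=2).max(axis=1)

    hits: list[DomainHit] = []
    order = sorted(range(len(scores)), key=lambda o: (-scores[o], o))
    covered = np.zeros(len(protein), dtype=bool)
    for o in order:
        if covered[o:o + w].any():
            continue
        score = float(scores[o])
        evalue = db_factor * float((null_best >= score).sum()) / n_shuffles
        if not passes_threshold(evalue, evalue_threshold):
            continue
        covered[o:o + w] = True
        hits.append(DomainHit(gene_id="", domain_name=profile.name,
                              start=o, end=o + w, score=score,
                              evalue=evalue))
    hits.sort(key=lambda h: -h.score)
    return hits


def scan_genes(proteins: dict[str, str], profiles: Sequence[ProfileModel],
               evalue_threshold: float = DEFAULT_EVALUE,
               seed: int = 0) -> dict[str, list[DomainHit]]:
    """Scan every protein with every profile; hits carry gene ids."""
    out: dict[str, list[DomainHit]] = {}
    for gene_id in sorted(proteins):
        gene_hits = []
        for profile in profiles:
            try:
                found = scan(proteins[gene_id], profile,
                             evalue_threshold=evalue_threshold, seed=seed)
            except ValueError:
                continue
            for h in found:
                h.gene_id = gene_id
                gene_hits.append(h)
        out[gene_id] = gene_hits
    return out


ARCHITECTURES = ("IPMS-like", "MAM-like", "HMGL-other", "none")


def classify_architecture(hits: Sequence[DomainHit],
                          first_domain: str = "HMGL-like",
                          second_domain: str = "LeuA") -> str:
    """Two-domain architecture call from a gene's domain hits.

    Both domains present -> IPMS-like; first only -> MAM-like (the
    divergence filter downstream separates true family members from
    distant single-domain relatives); neither -> none.
    """
    names = {h.domain_name for h in hits}
    if first_domain in names and second_domain in names:
        return "IPMS-like"
    if first_domain in names:
        return "MAM-like"
    return "none"


def filter_by_divergence(candidates: dict[str, str],
                         references: dict[str, str],
                         max_ratio: float = 2.0) -> tuple[list[str], list[str]]:
    """Keep candidates within ``max_ratio`` x (median reference pairwise
    distance) of at least one labelled reference; distances are
    Kimura-corrected p-distances over pairwise global alignments.

    Returns (kept, removed) gene id lists.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 reference sequences")
    aligner = _pairwise_aligner()

    def pair_distance(a: str, b: str) -> float:
        if a == b:
            return 0.0
        sa, sb = _align_pair(a, b, aligner)
        shared = [(x, y) for x, y in zip(sa, sb) if x != GAP and y != GAP]
        if not shared:
            return float("inf")
        p = sum(1 for x, y in shared if x != y) / len(shared)
        return kimura_correction(p)

    ref_items = sorted(references.items())
    ref_dists = []
    for i in range(len(ref_items)):
        for j in range(i + 1, len(ref_items)):
            ref_dists.append(pair_distance(ref_items[i][1], ref_items[j][1]))
    median = float(np.median(ref_dists))
    cutoff = max_ratio * median

    kept, removed = [], []
    for gene_id in sorted(candidates):
        dmin = min(pair_distance(candidates[gene_id], seq)
                   for _, seq in ref_items)
        (kept if dmin <= cutoff else removed).append(gene_id)
    return kept, removed


DOMAIN_HIT_SCHEMA = {
    "gene_id": str, "domain_name": str, "start": int, "end": int,
    "score": float, "evalue": float,
}


def hits_to_rows(hits_by_gene: dict[str, list[DomainHit]]) -> list[dict]:
    rows = []
    for gene_id in sorted(hits_by_gene):
        for h in hits_by_gene[gene_id]:
            rows.append({"gene_id": gene_id, "domain_name": h.domain_name,
                         "start": h.start, "end": h.end, "score": h.score,
                         "evalue": h.evalue})
    return rows
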