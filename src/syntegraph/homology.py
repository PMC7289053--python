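"""All-vs-all protein similarity search.

Exact Smith-Waterman local alignment with affine gaps (Gotoh), run over
every gene pair within and between genomes. Desk-scale datasets permit
exact dynamic programming, so no heuristic seeding is used; the inner DP
is JIT-compiled when numba is importable and falls back to pure Python
otherwise. A gap of length L costs ``gap_open + gap_extend * (L - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AnnotatedGenome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1
#: under this aligner's gap cost convention (open + extend*(L-1)), fitted
#: once with :func:`shuffle_calibration` on length-200 shuffled pairs.
#: E-values only rank and filter hits, so high precision is not
#: load-bearing; rerun the calibration to refit.
DEFAULT_LAMBDA = 0.219
DEFAULT_K = 0.025

_NEG = -1e30


def encode(seq: str) -> np.ndarray:
    """Map a protein string to residue indices; reject non-amino-acid
    characters, naming the offending position."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"non-amino-acid character {ch!r} at position {i}")
        out[i] = idx
    return out


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 20x20 float substitution matrix in AMINO_ACIDS order."""
    if name not in _MATRIX_CACHE:
        raw = substitution_matrices.load(name)
        mat = np.empty((20, 20), dtype=np.float64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                mat[i, j] = raw[a, b]
        _MATRIX_CACHE[name] = mat
    return _MATRIX_CACHE[name]


def _gotoh_score(a, b, mat, gap_open, gap_extend):
    n, m = len(a), len(b)
    M = np.zeros(m + 1)
    Ix = np.full(m + 1, _NEG)
    Iy = np.full(m + 1, _NEG)
    best = 0.0
    for i in range(1, n + 1):
        prev_diag_M = M[0]
        prev_diag_Ix = Ix[0]
        prev_diag_Iy = Iy[0]
        M[0] = 0.0
        Ix[0] = _NEG
        Iy[0] = _NEG
        for j in range(1, m + 1):
            up_M, up_Ix = M[j], Ix[j]
            ix = max(up_M - gap_open, up_Ix - gap_extend)
            iy = max(M[j - 1] - gap_open, Iy[j - 1] - gap_extend)
            s = mat[a[i - 1], b[j - 1]]
            diag = max(prev_diag_M, prev_diag_Ix, prev_diag_Iy)
            mm = s + diag
            if mm < 0.0:
                mm = 0.0
            prev_diag_M = M[j]
            prev_diag_Ix = Ix[j]
            prev_diag_Iy = Iy[j]
            M[j] = mm
            Ix[j] = ix
            Iy[j] = iy
            if mm > best:
                best = mm
    return best


def _gotoh_full(a, b, mat, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (score, a_start, a_end, b_start, b_end, matches, mismatches,
    gap_opens, aln_len). Traceback ties prefer diagonal, then up (gap in
    b), then left (gap in a).
    """
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    # predecessor state of each cell: 0=M,1=Ix,2=Iy,3=local start
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Ix = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Iy = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            o_M = M[i - 1, j] - gap_open
            e_Ix = Ix[i - 1, j] - gap_extend
            if o_M >= e_Ix:
                Ix[i, j] = o_M
                ptr_Ix[i, j] = 0
            else:
                Ix[i, j] = e_Ix
                ptr_Ix[i, j] = 1
            o_M2 = M[i, j - 1] - gap_open
            e_Iy = Iy[i, j - 1] - gap_extend
            if o_M2 >= e_Iy:
                Iy[i, j] = o_M2
                ptr_Iy[i, j] = 0
            else:
                Iy[i, j] = e_Iy
                ptr_Iy[i, j] = 2
            s = mat[a[i - 1], b[j - 1]]
            dM = M[i - 1, j - 1]
            dIx = Ix[i - 1, j - 1]
            dIy = Iy[i - 1, j - 1]
            # preference: diagonal(M) > up(Ix) > left(Iy); dM >= 0 always,
            # so the chosen predecessor value is never negative
            src = 0
            dbest = dM
            if dIx > dbest:
                dbest = dIx
                src = 1
            if dIy > dbest:
                dbest = dIy
                src = 2
            val = s + dbest
            if val < 0.0:
                val = 0.0
            M[i, j] = val
            ptr_M[i, j] = src
            if val > best:
                best = val
                bi, bj = i, j
    if best <= 0.0:
        return (0.0, 0, 0, 0, 0, 0, 0, 0, 0)
    # traceback from the best-scoring cell, state M
    i, j = bi, bj
    state = 0
    matches = 0
    mismatches = 0
    gap_opens = 0
    aln_len = 0
    while True:
        if state == 0:
            aln_len += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            nxt = ptr_M[i, j]
            i -= 1
            j -= 1
            state = nxt
            if state == 0 and M[i, j] == 0.0:
                break  # local start reached
        elif state == 1:
            aln_len += 1
            nxt = ptr_Ix[i, j]
            if nxt == 0:
                gap_opens += 1
            i -= 1
            state = nxt
        else:
            aln_len += 1
            nxt = ptr_Iy[i, j]
            if nxt == 0:
                gap_opens += 1
            j -= 1
            state = nxt
    return (best, i, bi, j, bj, matches, mismatches, gap_opens, aln_len)


try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _gotoh_score = _njit(cache=False)(_gotoh_score)
    _gotoh_full = _njit(cache=False)(_gotoh_full)
except ImportError:  # pragma: no cover
    pass


@dataclass
class HomologyHit:
    """One row of the blast-tabular-style all-vs-all output.

    Coordinates are 0-based half-open on the unaligned sequences.
    """

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    score: float


def local_align(a: str, b: str, matrix="BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0) -> HomologyHit:
    """Optimal local alignment of two proteins.

    Returns a hit with empty query/subject ids; ``pct_identity`` is over
    the aligned region only.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    mat = load_matrix(matrix) if isinstance(matrix, str) else matrix
    res = _gotoh_full(encode(a), encode(b), mat,
                      float(gap_open), float(gap_extend))
    score, qs, qe, ss, se, matches, mismatch, gapopen, aln_len = res
    pid = 100.0 * matches / aln_len if aln_len else 0.0
    return HomologyHit(
        query="", subject="", pct_identity=pid, aln_len=int(aln_len),
        mismatch=int(mismatch), gapopen=int(gapopen),
        qstart=int(qs), qend=int(qe), sstart=int(ss), send=int(se),
        evalue=float("nan"), score=float(score),
    )


def estimate_evalue(score: float, m: int, n: int,
                    K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA) -> float:
    """Karlin-Altschul expectation: ``K * m * n * exp(-lambda * score)``."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if K <= 0:
        raise ValueError("K must be > 0")
    return K * m * n * math.exp(-lam * score)


def shuffle_calibration(length: int = 200, n_pairs: int = 200, seed: int = 0,
                        matrix="BLOSUM62", gap_open: float = 11.0,
                        gap_extend: float = 1.0) -> tuple[float, float]:
    """Empirical (K, lambda) from a Gumbel fit to shuffled-pair scores.

    Optional alternative to the literature constants; uses a moment fit
    (scale -> lambda, location -> K).
    """
    rng = np.random.default_rng(seed)
    mat = load_matrix(matrix) if isinstance(matrix, str) else matrix
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        a = rng.integers(0, 20, size=length)
        b = rng.integers(0, 20, size=length)
        scores[i] = _gotoh_score(a, b, mat, float(gap_open), float(gap_extend))
    scale = np.sqrt(6.0) * scores.std() / np.pi
    loc = scores.mean() - 0.5772156649 * scale
    lam = 1.0 / scale
    K = math.exp(loc * lam) / (length * length)
    return K, lam


def all_vs_all(genomes: Sequence[AnnotatedGenome], matrix="BLOSUM62",
               gap_open: float = 11.0, gap_extend: float = 1.0,
               evalue_max: float = 1e-5, top_n: int = 5,
               K: float = DEFAULT_K,
               lam: float = DEFAULT_LAMBDA) -> list[HomologyHit]:
    """Reciprocal all-against-all comparison of every gene pair.

    Hits are filtered at ``evalue_max``, capped at ``top_n`` subjects per
    query, and symmetrized afterwards: if (q, s) is kept, (s, q) is
    reported too.
    """
    mat = load_matrix(matrix) if isinstance(matrix, str) else matrix
    genes: list[tuple[str, str]] = []
    for genome in genomes:
        for g in genome.genes():
            genes.append((g.gene_id, g.protein))
    if not genes:
        raise ValueError("no genes to compare")
    ids = [g[0] for g in genes]
    codes = [encode(g[1]) for g in genes]
    lengths = [len(g[1]) for g in genes]
    n = len(genes)

    # score-only pass over unordered pairs
    passing: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            score = _gotoh_score(codes[i], codes[j], mat,
                                 float(gap_open), float(gap_extend))
            ev = estimate_evalue(score, lengths[i], lengths[j], K, lam)
            if ev <= evalue_max:
                passing[(i, j)] = ev

    # per-query top_n, then reciprocal closure
    per_query: dict[int, list[tuple[float, int]]] = {}
    for (i, j), ev in passing.items():
        per_query.setdefault(i, []).append((ev, j))
        per_query.setdefault(j, []).append((ev, i))
    kept_pairs: set[tuple[int, int]] = set()
    for q, cands in per_query.items():
        cands.sort(key=lambda t: (t[0], ids[t[1]]))
        for ev, s in cands[:top_n]:
            kept_pairs.add((min(q, s), max(q, s)))

    hits: list[HomologyHit] = []
    for i, j in sorted(kept_pairs):
        res = _gotoh_full(codes[i], codes[j], mat,
                          float(gap_open), float(gap_extend))
        score, qs, qe, ss, se, matches, mismatch, gapopen, aln_len = res
        pid = 100.0 * matches / aln_len if aln_len else 0.0
        ev = passing[(i, j)]
        common = dict(pct_identity=pid, aln_len=int(aln_len),
                      mismatch=int(mismatch), gapopen=int(gapopen),
                      evalue=ev, score=float(score))
        hits.append(HomologyHit(query=ids[i], subject=ids[j],
                                qstart=int(qs), qend=int(qe),
                                sstart=int(ss), send=int(se), **common))
        hits.append(HomologyHit(query=ids[j], subject=ids[i],
                                qstart=int(ss), qend=int(se),
                                sstart=int(qs), send=int(qe), **common))
    hits.sort(key=lambda h: (h.query, h.evalue, h.subject))
    return hits


def hits_to_rows(hits: Sequence[HomologyHit]) -> list[dict]:
    return [vars(h).copy() for h in hits]


def rows_to_hits(rows: Sequence[dict]) -> list[HomologyHit]:
    return [HomologyHit(**row) for row in rows]
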