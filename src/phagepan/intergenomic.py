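"""VIRIDIC-style pairwise intergenomic nucleotide similarity.

The statistic for a genome pair (A, B) is

    sim = 100 * (I_A / len(A) + I_B / len(B)) / 2

where I_A (resp. I_B) is the number of positions of A (resp. B) credited as
identical after merging local alignment blocks so that each genome position is
counted at most once.  Identical genomes score exactly 100; the statistic is
symmetric and bounded in [0, 100].  ``distance = 100 - similarity``.

Blocks come from an exact k-mer seed-and-extend aligner: seeds are shared
k-mers on both strands, each seeded diagonal is scanned with an ungapped
x-drop criterion (match +1, mismatch -2), and nearby blocks within a small
diagonal band are chained across short indels (bridged positions count as
non-matching).  N mismatches everything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, SimilarityMatrix

__all__ = [
    "AlignParams",
    "AlignmentBlock",
    "seed_extend_align",
    "merge_blocks",
    "intergenomic_similarity",
    "similarity_matrix",
]

_ENC = np.full(256, 4, dtype=np.int64)  # everything unknown -> 4 (N-like)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class AlignParams:
    """Aligner tuning, chosen to be sensitive in the 95-99% identity range."""

    k: int = 15                 # exact seed length
    min_block: int = 100        # minimum reported block length (bp)
    xdrop: float = 20.0         # ungapped extension x-drop threshold
    band: int = 32              # max diagonal offset / gap bridged when chaining
    mismatch_penalty: float = 2.0
    max_seed_occ: int = 50      # k-mers more frequent than this in B are masked


@dataclass(frozen=True)
class AlignmentBlock:
    """An ungapped-or-chained local alignment block.

    Coordinates are 1-based inclusive; ``b_start``/``b_end`` are on the chosen
    strand of B (for strand '-', on the reverse complement of B).
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    matches: int
    aln_len: int

    def __post_init__(self):
        if not (0 < self.matches <= self.aln_len):
            raise ValueError("require 0 < matches <= aln_len")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _encode(s: str) -> np.ndarray:
    return _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes and a validity mask (windows without N)."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for t in range(k):
        codes = (codes << 2) | (enc[t : t + n] & 3)
    isn = (enc == 4).astype(np.int64)
    window_n = np.cumsum(np.concatenate(([0], isn)))
    valid = (window_n[k:] - window_n[:-k]) == 0
    return codes, valid


def _seed_diagonals(a_enc: np.ndarray, b_enc: np.ndarray, params: AlignParams) -> np.ndarray:
    """Distinct diagonals (i - j) carrying at least one exact k-mer seed."""
    k = params.k
    ca, va = _kmer_codes(a_enc, k)
    cb, vb = _kmer_codes(b_enc, k)
    if ca.size == 0 or cb.size == 0:
        return np.empty(0, dtype=np.int64)
    a_pos = np.flatnonzero(va)
    b_pos = np.flatnonzero(vb)
    if a_pos.size == 0 or b_pos.size == 0:
        return np.empty(0, dtype=np.int64)
    ca, cb = ca[a_pos], cb[b_pos]
    order = np.argsort(cb, kind="stable")
    cb_sorted = cb[order]
    lo = np.searchsorted(cb_sorted, ca, side="left")
    hi = np.searchsorted(cb_sorted, ca, side="right")
    occ = hi - lo
    keep = (occ > 0) & (occ <= params.max_seed_occ)
    diags: list[np.ndarray] = []
    for ai, l, h in zip(a_pos[keep], lo[keep], hi[keep]):
        diags.append(ai - b_pos[order[l:h]])
    if not diags:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(diags))


def _xdrop_blocks(match: np.ndarray, params: AlignParams) -> list[tuple[int, int, int]]:
    """Segment a 0/1 match profile into maximal x-drop blocks.

    Returns (start, end, matches) with 0-based inclusive offsets into
    ``match``.  Scoring: match +1, mismatch -penalty; a block is closed when
    the running score falls more than ``xdrop`` below its running maximum,
    at which point the block ends at the position of that maximum.
    """
    n = len(match)
    if n == 0:
        return []
    csum = np.concatenate(([0], np.cumsum(match, dtype=np.int64)))
    mism = np.flatnonzero(~match)
    pen = params.mismatch_penalty
    blocks: list[tuple[int, int, int]] = []

    def close(start: int, best_end: int) -> None:
        # trim leading mismatches; best_end is a match position by construction
        while start <= best_end and not match[start]:
            start += 1
        if start <= best_end:
            nm = int(csum[best_end + 1] - csum[start])
            blocks.append((start, best_end, nm))

    start = 0
    mi = np.searchsorted(mism, start)
    while start < n:
        score = 0.0
        best = 0.0
        best_end = start - 1
        pos = start
        reset = False
        while mi < len(mism):
            q = mism[mi]
            score += q - pos          # matches in [pos, q)
            if score > best:
                best, best_end = score, q - 1
            score -= pen
            pos = q + 1
            mi += 1
            if best - score > params.xdrop:
                close(start, best_end)
                start = pos
                reset = True
                break
        if not reset:
            score += n - pos
            if score > best:
                best, best_end = score, n - 1
            close(start, best_end)
            break
    return blocks


def _chain_blocks(raw: list[tuple[int, int, int, int]], params: AlignParams) -> list[tuple[int, int, int, int, int, int]]:
    """Chain blocks across small gaps/diagonal offsets (banded gapped step).

    Input: (a_start, a_end, b_start, matches) 0-based; output adds b_end and
    aln_len.  Bridged gap positions are counted in aln_len but not as matches.
    """
    if not raw:
        return []
    raw = sorted(raw, key=lambda t: (t[0], t[2]))
    out: list[list[int]] = []
    for a0, a1, b0, nm in raw:
        b1 = b0 + (a1 - a0)
        if out:
            pa0, pa1, pb0, pb1, pnm = out[-1]
            gap_a = a0 - pa1 - 1
            gap_b = b0 - pb1 - 1
            if (
                0 <= gap_a <= params.band
                and 0 <= gap_b <= params.band
                and abs(gap_a - gap_b) <= params.band
            ):
                out[-1] = [pa0, a1, pb0, b1, pnm + nm]
                continue
        out.append([a0, a1, b0, b1, nm])
    result = []
    for a0, a1, b0, b1, nm in out:
        aln_len = max(a1 - a0 + 1, b1 - b0 + 1)
        result.append((a0, a1, b0, b1, nm, aln_len))
    return result


def seed_extend_align(a: str, b: str, k: int = 15, min_block: int = 100,
                      params: AlignParams | None = None) -> list[AlignmentBlock]:
    """Find local alignment blocks between two DNA strings on both strands.

    Deterministic for fixed inputs and parameters.  Returns blocks of aligned
    length >= ``min_block`` with match counts; empty list when no shared
    k-mers exist (k longer than either sequence included).
    """
    if params is None:
        params = AlignParams(k=k, min_block=min_block)
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    a = a.upper()
    a_enc = _encode(a)
    blocks: list[AlignmentBlock] = []
    for strand in "+-":
        b_oriented = b.upper() if strand == "+" else revcomp(b.upper())
        b_enc = _encode(b_oriented)
        raw: list[tuple[int, int, int, int]] = []
        for d in _seed_diagonals(a_enc, b_enc, params):
            i0 = max(0, d)
            i1 = min(len(a), len(b_oriented) + d)  # exclusive on A
            if i1 - i0 < params.k:
                continue
            seg_a = a_enc[i0:i1]
            seg_b = b_enc[i0 - d : i1 - d]
            match = (seg_a == seg_b) & (seg_a != 4) & (seg_b != 4)
            for s, e, nm in _xdrop_blocks(match, params):
                raw.append((i0 + s, i0 + e, i0 + s - d, nm))
        for a0, a1, b0, b1, nm, aln_len in _chain_blocks(raw, params):
            if aln_len >= params.min_block:
                blocks.append(
                    AlignmentBlock(
                        a_start=a0 + 1, a_end=a1 + 1,
                        b_start=b0 + 1, b_end=b1 + 1,
                        strand=strand, matches=nm, aln_len=aln_len,
                    )
                )
    blocks.sort(key=lambda bl: (-bl.matches, bl.a_start, bl.b_start))
    return blocks


def merge_blocks(blocks: list[AlignmentBlock], genome: str, genome_length: int) -> tuple[list[tuple[int, int]], float]:
    """Resolve overlapping blocks on one genome and total identical positions.

    Blocks are taken in descending match order (ties by (a_start, b_start));
    each position of the chosen genome is counted at most once.  A block whose
    interval is partly covered already is credited pro-rata:
    ``matches * uncovered / interval_length``.  For genome B, strand '-'
    coordinates are mapped back to the forward strand.

    Returns the disjoint covered intervals (1-based inclusive) and the total
    identical positions credited to that genome.
    """
    if genome not in ("A", "B"):
        raise ValueError("genome must be 'A' or 'B'")
    covered = np.zeros(genome_length, dtype=bool)
    total = 0.0
    order = sorted(blocks, key=lambda bl: (-bl.matches, bl.a_start, bl.b_start))
    for bl in order:
        if genome == "A":
            s, e = bl.a_start, bl.a_end
        else:
            s, e = bl.b_start, bl.b_end
            if bl.strand == "-":
                s, e = genome_length - e + 1, genome_length - s + 1
        s = max(1, s)
        e = min(genome_length, e)
        if e < s:
            continue
        span = covered[s - 1 : e]
        uncov = int((~span).sum())
        if uncov == 0:
            continue
        total += bl.matches * uncov / (e - s + 1)
        span[:] = True
    # extract disjoint intervals
    idx = np.flatnonzero(covered)
    intervals: list[tuple[int, int]] = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        intervals = [(int(idx[s]) + 1, int(idx[e]) + 1) for s, e in zip(starts, ends)]
    return intervals, min(total, float(genome_length))


def intergenomic_similarity(a: GenomeRecord, b: GenomeRecord,
                            params: AlignParams | None = None) -> float:
    """Percent intergenomic similarity of two genomes (the VIRIDIC statistic)."""
    if params is None:
        params = AlignParams()
    if a.length_bp == 0 or b.length_bp == 0:
        raise ValueError("zero-length genome")
    if a.sequence == b.sequence:
        return 100.0
    blocks = seed_extend_align(a.sequence, b.sequence, params.k, params.min_block, params)
    if not blocks:
        return 0.0
    _, i_a = merge_blocks(blocks, "A", a.length_bp)
    _, i_b = merge_blocks(blocks, "B", b.length_bp)
    sim = 100.0 * (i_a / a.length_bp + i_b / b.length_bp) / 2.0
    return float(min(100.0, max(0.0, sim)))


def similarity_matrix(genomes: list[GenomeRecord],
                      params: AlignParams | None = None) -> SimilarityMatrix:
    """All-pairs intergenomic similarity; each pair computed exactly once."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(genomes)
    m = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        s = intergenomic_similarity(genomes[i], genomes[j], params)
        m[i, j] = m[j, i] = s
    return SimilarityMatrix(pd.DataFrame(m, index=ids, columns=ids))
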