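"""Seed verification by full Smith-Waterman local alignment.

Each seed (an exact k-base match) is verified by aligning the whole read
against a genome window centred on the seed's implied placement, using the
Gotoh affine-gap formulation of Smith-Waterman.  The alignment carries an
explicit edit script so its score is recomputable and variants fall out
directly.  A gap of length g costs gap_open + (g-1) * gap_extend.

The DP kernel is JIT-compiled with numba; the module-level functions wrap
it with coordinate bookkeeping (window -> genome translation, strand
handling is the caller's job: reverse-strand reads are reverse-complemented
before alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .kmers import seq_to_vals

# edit-script opcodes
OP_MATCH = "M"
OP_SUB = "X"
OP_INS = "I"   # base present in the read, absent from the genome
OP_DEL = "D"   # base present in the genome, absent from the read


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring; penalties are stored as positive numbers."""

    match: int = 2
    mismatch: int = 2
    gap_open: int = 3
    gap_extend: int = 1

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class Alignment:
    """One verified local alignment of a read against a genome.

    ``read_start``/``read_end`` are coordinates in the *oriented* read
    (i.e. in the reverse complement for reverse-strand alignments); genome
    coordinates are always forward-strand, 0-based half-open.  ``score``
    is the raw Smith-Waterman score; ``effective_score`` is overwritten by
    pseudo-assembly with the chain score.
    """

    read_id: int
    genome_id: int
    strand: str                 # "+" or "-"
    genome_start: int
    genome_end: int
    read_start: int
    read_end: int
    score: int
    edits: tuple                # ((op, length), ...)
    read_len: int
    fragment_id: str = ""
    mate: int = 0               # 0 single-end, else 1/2
    effective_score: float = 0.0

    def __post_init__(self):
        if self.effective_score == 0.0:
            self.effective_score = float(self.score)


@dataclass(frozen=True)
class Variant:
    genome_pos: int
    ref_allele: str
    alt_allele: str
    kind: str                   # "SNV" | "insertion" | "deletion"


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in read (consumes b)
    F = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in genome (consumes a)
    tbH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    tbE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 open (from H), 0 extend
    tbF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                tbE[i, j] = 1
            else:
                E[i, j] = e_ext
                tbE[i, j] = 0
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                tbF[i, j] = 1
            else:
                F[i, j] = f_ext
                tbF[i, j] = 0
            if ai == b[j - 1] and ai < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            # priority on ties: diagonal, then E, then F (fewer gaps first)
            h = diag
            src = 1
            if E[i, j] > h:
                h = E[i, j]
                src = 2
            if F[i, j] > h:
                h = F[i, j]
                src = 3
            if h <= 0:
                h = 0
                src = 0
            H[i, j] = h
            tbH[i, j] = src
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback (ops reversed): 0=M 1=X 2=D(consume b) 3=I(consume a)
    ops = np.empty(m + n, dtype=np.int8)
    nops = 0
    i = bi
    j = bj
    state = 0  # 0=H 1=E 2=F
    while best > 0 and (i > 0 or j > 0):
        if state == 0:
            src = tbH[i, j]
            if src == 0 or H[i, j] == 0:
                break
            if src == 1:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    ops[nops] = 0
                else:
                    ops[nops] = 1
                nops += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = 2
            nops += 1
            opened = tbE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            ops[nops] = 3
            nops += 1
            opened = tbF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj, ops[:nops]


_OP_NAMES = (OP_MATCH, OP_SUB, OP_DEL, OP_INS)


def _runs(ops_rev: np.ndarray) -> tuple:
    """Collapse the reversed opcode array into ((op, length), ...)."""
    runs = []
    for code in ops_rev[::-1]:
        name = _OP_NAMES[code]
        if runs and runs[-1][0] == name:
            runs[-1][1] += 1
        else:
            runs.append([name, 1])
    return tuple((op, length) for op, length in runs)


def smith_waterman(
    read_seq: str,
    window_seq: str,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    read_id: int = 0,
    genome_id: int = 0,
    strand: str = "+",
    window_start: int = 0,
) -> Alignment:
    """Best local alignment of ``read_seq`` against ``window_seq``.

    ``window_start`` translates window coordinates back to the genome.
    Ambiguous bases never match.  Ties are broken deterministically: the
    first best cell in row-major order ends the alignment and the
    traceback prefers diagonal moves over gaps (fewest gaps).
    A score of 0 yields a degenerate empty alignment which downstream
    screening removes.
    """
    a = seq_to_vals(read_seq)
    b = seq_to_vals(window_seq)
    score, rs, re_, ws, we, ops_rev = _sw_kernel(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    return Alignment(
        read_id=read_id,
        genome_id=genome_id,
        strand=strand,
        genome_start=window_start + int(ws),
        genome_end=window_start + int(we),
        read_start=int(rs),
        read_end=int(re_),
        score=int(score),
        edits=_runs(ops_rev),
        read_len=len(read_seq),
    )


def score_from_edits(edits: tuple, scheme: ScoringScheme) -> int:
    """Recompute the alignment score from its edit script."""
    s = 0
    for op, length in edits:
        if op == OP_MATCH:
            s += scheme.match * length
        elif op == OP_SUB:
            s -= scheme.mismatch * length
        else:
            s -= scheme.gap_open + (length - 1) * scheme.gap_extend
    return s


def window_for_seed(
    genome_offset: int,
    read_offset: int,
    read_len: int,
    genome_len: int,
    margin: int = 32,
) -> tuple[int, int]:
    """Genome interval to align the read against, centred on the seed's
    implied read placement, width read_len + 2*margin, clamped to the
    genome.  ``read_offset`` must be given in the oriented read."""
    start = genome_offset - read_offset - margin
    end = genome_offset - read_offset + read_len + margin
    return max(0, start), min(genome_len, end)


def call_variants(alignment: Alignment, genome_seq: str, read_seq: str) -> list[Variant]:
    """One variant per non-match edit, in genome coordinates.

    ``read_seq`` must be the oriented read (as aligned); ``genome_seq`` the
    full forward-strand genome.
    """
    out = []
    g = alignment.genome_start
    r = alignment.read_start
    for op, length in alignment.edits:
        if op == OP_MATCH:
            g += length
            r += length
        elif op == OP_SUB:
            for t in range(length):
                out.append(
                    Variant(g + t, genome_seq[g + t], read_seq[r + t], "SNV")
                )
            g += length
            r += length
        elif op == OP_INS:
            out.append(Variant(g, "", read_seq[r : r + length], "insertion"))
            r += length
        else:  # OP_DEL
            out.append(Variant(g, genome_seq[g : g + length], "", "deletion"))
            g += length
    return out


def screen_alignments(alignments: list, min_score: int) -> list:
    """Keep alignments with score >= min_score (and drop degenerate
    zero-score alignments regardless)."""
    floor = max(min_score, 1)
    return [a for a in alignments if a.score >= floor]
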