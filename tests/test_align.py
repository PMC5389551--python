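"""Smith-Waterman verification against independent oracles.

Scores are checked against a plain-Python quadratic Gotoh DP and,
separately, against Biopython's PairwiseAligner configured with the same
scheme (two independent routes).
"""

import numpy as np
import pytest

from seedtax.align import (
    Alignment,
    ScoringScheme,
    call_variants,
    score_from_edits,
    screen_alignments,
    smith_waterman,
    window_for_seed,
)
from seedtax.kmers import revcomp
from tests_support import sw_score_oracle

SCHEME = ScoringScheme()


def random_pair(rng, max_len=60):
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, max_len))))
    if rng.random() < 0.5:
        # mutated copy so alignments are non-trivial
        b = list(a)
        for _ in range(int(rng.integers(0, 6))):
            if not b:
                break
            p = int(rng.integers(0, len(b)))
            r = rng.random()
            if r < 0.5:
                b[p] = "ACGT"[int(rng.integers(0, 4))]
            elif r < 0.75:
                b.insert(p, "ACGT"[int(rng.integers(0, 4))])
            else:
                del b[p]
        b = "".join(b) or "A"
    else:
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, max_len))))
    return a, b


def test_identity_alignment_scores_all_matches():
    a = smith_waterman("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
    assert a.score == 40 and a.edits == (("M", 20),)


def test_single_substitution_case():
    a = smith_waterman("ACGTACGT", "ACGAACGT")
    assert a.score == sw_score_oracle("ACGTACGT", "ACGAACGT")
    assert sum(1 for op, _ in a.edits if op == "X") == 1


def test_disjoint_alphabets_degenerate():
    a = smith_waterman("AAAAAAA", "CCCCCCC")
    assert a.score == 0 and a.edits == ()


def test_scores_match_quadratic_dp_oracle(rng):
    for _ in range(120):
        a, b = random_pair(rng)
        got = smith_waterman(a, b, SCHEME)
        assert got.score == sw_score_oracle(a, b)
        assert score_from_edits(got.edits, SCHEME) == got.score


def test_scores_match_biopython_local_aligner(rng):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = SCHEME.match
    aligner.mismatch_score = -SCHEME.mismatch
    aligner.open_gap_score = -SCHEME.gap_open
    aligner.extend_gap_score = -SCHEME.gap_extend
    for _ in range(60):
        a, b = random_pair(rng, max_len=40)
        got = smith_waterman(a, b, SCHEME)
        assert got.score == max(0, int(aligner.score(a, b)))


def test_reverse_strand_invariance(rng):
    """Aligning revcomp(read) against the genome scores the same at the
    mirrored locus."""
    for _ in range(30):
        g = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
        read = g[20:50]
        fwd = smith_waterman(read, g, SCHEME)
        rev = smith_waterman(revcomp(read), revcomp(g), SCHEME)
        assert fwd.score == rev.score
        assert fwd.genome_start == len(g) - rev.genome_end


def test_alignment_edit_script_recomputes_score(rng):
    for _ in range(50):
        a, b = random_pair(rng)
        got = smith_waterman(a, b, SCHEME)
        assert score_from_edits(got.edits, SCHEME) == got.score


def test_window_for_seed_geometry():
    assert window_for_seed(500, 10, 100, 10_000, 32) == (458, 622)
    assert window_for_seed(5, 40, 100, 10_000, 32) == (0, 5 - 40 + 100 + 32)
    assert window_for_seed(10, 0, 100, 50, 32) == (0, 50)


def test_variants_from_edit_script():
    perfect = smith_waterman("ACGTACGT", "ACGTACGT")
    assert call_variants(perfect, "ACGTACGT", "ACGTACGT") == []
    sub = smith_waterman("ACGTACGT", "ACGAACGT")
    (v,) = call_variants(sub, "ACGAACGT", "ACGTACGT")
    assert v.kind == "SNV" and v.genome_pos == 3 and (v.ref_allele, v.alt_allele) == ("A", "T")
    # a two-base deletion in the read
    g = "ACGTACGTTTACGTACGTAC"
    r = g[:8] + g[10:]
    aln = smith_waterman(r, g)
    dels = [v for v in call_variants(aln, g, r) if v.kind == "deletion"]
    assert len(dels) == 1 and len(dels[0].ref_allele) == 2


def _aln(score):
    return Alignment(0, 0, "+", 0, 10, 0, 10, score, (("M", 5),), 10)


def test_screening_keeps_at_or_above_cutoff():
    kept = screen_alignments([_aln(40), _aln(10)], 20)
    assert [a.score for a in kept] == [40]
    assert len(screen_alignments([_aln(40), _aln(10)], 0)) == 2
    assert screen_alignments([], 5) == []


def test_screening_is_monotone(rng):
    alns = [_aln(int(s)) for s in rng.integers(1, 100, size=50)]
    prev = None
    for cutoff in (0, 10, 20, 50, 90):
        kept = {id(a) for a in screen_alignments(alns, cutoff)}
        if prev is not None:
            assert kept <= prev
        prev = kept
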