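"""k-mer encoding, canonicalization, extraction and seed finding.

The seed-completeness oracle compares the sorted-list pipeline against a
brute-force scan of every read k-mer vs every grid-aligned genome k-mer
on both strands.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seedtax import kmers
from seedtax.kmers import (
    AmbiguousBaseError,
    SeedStats,
    canonicalize,
    encode_kmer,
    decode_kmer,
    extract_genome_kmers,
    extract_read_kmers,
    find_seed_matches,
    revcomp,
    revcomp_code,
    sort_entries,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", 0b00011011), ("AAAA", 0), ("TTTT", 255), ("GGGG", 0b10101010)],
)
def test_encode_packs_two_bits_per_base(seq, expected):
    assert encode_kmer(seq) == expected


def test_encode_order_is_lexicographic(rng):
    ks = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=6)) for _ in range(50)]
    codes = [encode_kmer(k) for k in ks]
    assert sorted(ks) == [k for _, k in sorted(zip(codes, ks))]


def test_encode_rejects_ambiguous_base():
    with pytest.raises(AmbiguousBaseError):
        encode_kmer("ACNT")


@pytest.mark.parametrize(
    "seq,canon,flag",
    [("TTTT", "AAAA", True), ("AAAA", "AAAA", False), ("GGGG", "CCCC", True)],
)
def test_canonicalize_examples(seq, canon, flag):
    code, rc = canonicalize(encode_kmer(seq), 4)
    assert decode_kmer(code, 4) == canon and rc is flag


@given(dna.filter(lambda s: 1 <= len(s) <= 12))
def test_canonicalize_strand_symmetric(seq):
    """canonicalize(x) == canonicalize(revcomp(x)) for every k-mer."""
    k = len(seq)
    c1, _ = canonicalize(encode_kmer(seq), k)
    c2, _ = canonicalize(encode_kmer(revcomp(seq)), k)
    assert c1 == c2


@given(dna.filter(lambda s: len(s) <= 20))
def test_revcomp_code_matches_string_revcomp(seq):
    k = len(seq)
    assert decode_kmer(revcomp_code(encode_kmer(seq), k), k) == revcomp(seq)


def test_read_kmer_extraction_counts():
    seq = "ACGT" * 40  # L=160
    assert len(extract_read_kmers(seq, 0, 32)) == 160 - 32 + 1
    assert len(extract_read_kmers("A" * 32, 0, 32)) == 1


def test_read_kmers_skip_windows_containing_n():
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACG"  # 35 bases
    seq = seq[:35] + "N" + "ACGT"  # L=40, N at position 35
    entries = extract_read_kmers(seq, 0, 32)
    assert sorted(entries["offset"]) == [0, 1, 2, 3]


def test_genome_kmers_on_grid():
    entries = extract_genome_kmers("A" * 1000, 0, 32)
    assert len(entries) == 1000 // 32
    assert list(entries["offset"][:3]) == [0, 32, 64]
    assert len(extract_genome_kmers("C" * 63, 0, 32)) == 1


def test_genome_kmers_skip_grid_window_with_n(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=64))
    seq = seq[:40] + "N" + seq[41:]
    entries = extract_genome_kmers(seq, 0, 32)
    assert list(entries["offset"]) == [0]


def test_read_shorter_than_k_is_an_error():
    with pytest.raises(ValueError):
        extract_read_kmers("ACGT", 0, 32)


def test_sort_orders_by_code_then_genome_before_read():
    e = np.zeros(3, dtype=kmers.KMER_DTYPE)
    e["code"] = [5, 2, 5]
    e["source"] = [kmers.SOURCE_READ, kmers.SOURCE_READ, kmers.SOURCE_GENOME]
    s = sort_entries(e)
    assert list(s["code"]) == [2, 5, 5]
    assert s["source"][1] == kmers.SOURCE_GENOME  # genome first within equal codes
    assert len(sort_entries(np.empty(0, dtype=kmers.KMER_DTYPE))) == 0


def test_sort_is_a_permutation(rng):
    e = np.zeros(200, dtype=kmers.KMER_DTYPE)
    e["code"] = rng.integers(0, 50, size=200)
    e["seq_id"] = rng.integers(0, 5, size=200)
    e["offset"] = rng.integers(0, 100, size=200)
    e["source"] = rng.integers(0, 2, size=200)
    s = sort_entries(e)
    assert sorted(map(tuple, e.tolist())) == sorted(map(tuple, s.tolist()))


def _seeds_from(genomes, reads, k, repeat_cap=1000):
    arrays = [extract_genome_kmers(g, i, k) for i, g in enumerate(genomes)]
    arrays += [extract_read_kmers(r, i, k) for i, r in enumerate(reads)]
    entries = sort_entries(np.concatenate(arrays))
    return find_seed_matches(entries, repeat_cap=repeat_cap)


def brute_force_seeds(genomes, reads, k):
    """Compare every read k-mer against every grid genome k-mer on both
    strands, then apply the per-diagonal de-duplication rule (lowest read
    offset survives).  Palindromic matches count as forward only, as a
    canonical store cannot distinguish the strands of a palindrome."""
    raw = set()
    for gid, g in enumerate(genomes):
        for goff in range(0, len(g) - k + 1, k):
            gk = g[goff : goff + k]
            if set(gk) - set("ACGT"):
                continue
            for rid, r in enumerate(reads):
                for roff in range(len(r) - k + 1):
                    rk = r[roff : roff + k]
                    if set(rk) - set("ACGT"):
                        continue
                    if rk == gk:
                        raw.add((rid, gid, roff, goff, False))
                    if revcomp(rk) == gk and rk != revcomp(rk):
                        raw.add((rid, gid, roff, goff, True))
    best = {}
    for rid, gid, roff, goff, rev in sorted(raw):
        diag = goff + roff if rev else goff - roff
        key = (rid, gid, rev, diag)
        if key not in best or roff < best[key][2]:
            best[key] = (rid, gid, roff, goff, rev)
    return set(best.values())


def test_seed_example_forward_and_reverse():
    """Toy case worked by hand: CCCC matches forward, GGGG matches the
    read's CCCC via the shared canonical code with opposite rc flags."""
    seeds = _seeds_from(["AAAACCCCGGGGTTTT"], ["ACCCCG"], 4)
    got = {(int(s["genome_offset"]), int(s["read_offset"]), bool(s["reverse"])) for s in seeds}
    assert got == {(4, 1, False), (8, 1, True)}


def test_no_shared_kmer_no_seed():
    assert len(_seeds_from(["A" * 20], ["CCCCGG"], 4)) == 0


def test_same_diagonal_seeds_are_deduplicated():
    # the read matches three consecutive grid k-mers, all on one diagonal;
    # the genome is built so no other k-mer collides on either strand
    g = "AAACGGATCTGA" + "AAAA"
    seeds = _seeds_from([g], ["AAACGGATCTGA"], 4)
    assert len(seeds) == 1
    assert seeds[0]["read_offset"] == 0  # lowest read offset survives
    assert seeds[0]["genome_offset"] == 0 and not seeds[0]["reverse"]


def test_repeat_cap_skips_low_complexity_blocks():
    stats = SeedStats()
    arrays = [extract_genome_kmers("A" * 40, 0, 4)]
    arrays += [extract_read_kmers("AAAAAA", 0, 4)]
    entries = sort_entries(np.concatenate(arrays))
    seeds = find_seed_matches(entries, repeat_cap=5, stats=stats)
    assert len(seeds) == 0 and stats.blocks_skipped == 1


def test_seed_set_equals_brute_force_on_random_instances(rng):
    """Oracle equivalence on random small instances (k <= 8)."""
    from tests_support import random_instance

    for _ in range(60):
        genomes, reads, k = random_instance(rng)
        seeds = _seeds_from(genomes, reads, k)
        got = {
            (int(s["read_id"]), int(s["genome_id"]), int(s["read_offset"]),
             int(s["genome_offset"]), bool(s["reverse"]))
            for s in seeds
        }
        assert got == brute_force_seeds(genomes, reads, k)


def test_error_free_grid_kmer_always_seeds(rng):
    """A read containing an exact copy of a grid k-mer yields a seed."""
    k = 8
    for _ in range(20):
        g = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        goff = int(rng.integers(0, len(g) // k)) * k
        read = "XX".replace("X", "") + g[goff : goff + k] + "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=10)
        )
        seeds = _seeds_from([g], [read], k)
        assert any(s["genome_offset"] == goff for s in seeds)
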