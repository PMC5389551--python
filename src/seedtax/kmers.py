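"""Canonical k-mer extraction, sorting and exact-match seed finding.

The central data structure is a single flat list of k-mer entries drawn
from both the reads and the reference genomes.  Reads contribute every
overlapping k-mer (k-1 base overlap); genomes contribute only the
non-overlapping "grid" k-mers starting at multiples of k, which keeps the
reference side of the list small.  Each k-mer is stored canonically -- the
lexicographic minimum of the k-mer and its reverse complement -- together
with a flag recording whether the reverse complement was stored, so a
single sorted list covers both strands.  Sorting places identical k-mers
next to one another; one pass over the sorted list then emits every exact
k-base match between a read and a genome (a *seed*), which downstream code
verifies with a full local alignment.

k is a runtime parameter, 1 <= k <= 32, so a k-mer packs into one 64-bit
word at two bits per base (A=0, C=1, G=2, T=3, most significant first;
integer order therefore equals lexicographic order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SOURCE_GENOME = 0
SOURCE_READ = 1

KMER_DTYPE = np.dtype(
    [
        ("code", "u8"),
        ("source", "u1"),   # SOURCE_GENOME sorts before SOURCE_READ
        ("seq_id", "u4"),
        ("offset", "u4"),   # in the ORIGINAL (pre-canonicalization) sequence
        ("rc", "u1"),       # stored code is the reverse complement of the source k-mer
    ]
)

SEED_DTYPE = np.dtype(
    [
        ("read_id", "u4"),
        ("genome_id", "u4"),
        ("read_offset", "u4"),
        ("genome_offset", "u4"),
        ("reverse", "u1"),
    ]
)

# base -> 2-bit value; 4 marks an ambiguous base (N etc.)
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a base outside {A,C,G,T}."""


def seq_to_vals(seq: str) -> np.ndarray:
    """Map a nucleotide string to 2-bit values (4 = ambiguous)."""
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmer(seq: str) -> int:
    """Pack a k-base string into its 2-bit integer code.

    Raises :class:`AmbiguousBaseError` on any base outside {A,C,G,T};
    callers skip such k-mers.
    """
    vals = seq_to_vals(seq)
    if (vals > 3).any():
        raise AmbiguousBaseError(f"ambiguous base in k-mer {seq!r}")
    code = 0
    for v in vals:
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(codes, k: int):
    """Reverse complement of packed k-mer code(s); vectorized on uint64."""
    x = np.asarray(codes, dtype=np.uint64)
    x = ~x  # complement: each 2-bit base value -> 3 - value
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    x = ((x >> np.uint64(2)) & m2) | ((x & m2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & m4) | ((x & m4) << np.uint64(4))
    x = x.byteswap()
    x = x >> np.uint64(64 - 2 * k)
    if np.isscalar(codes) or x.ndim == 0:
        return int(x)
    return x


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan", "")
    return seq.translate(comp)[::-1]


def canonicalize(code: int, k: int) -> tuple[int, bool]:
    """Return (canonical code, rc_flag).

    The canonical code is min(code, revcomp(code)); rc_flag is True iff
    the reverse complement was the smaller, i.e. the stored k-mer is the
    reverse complement of the one read from the source sequence.
    """
    rc = revcomp_code(code, k)
    if rc < code:
        return rc, True
    return code, False


def _window_codes(vals: np.ndarray, offsets: np.ndarray, k: int):
    """Codes + validity mask for k-windows of ``vals`` starting at ``offsets``."""
    win = np.lib.stride_tricks.sliding_window_view(vals, k)[offsets]
    valid = (win <= 3).all(axis=1)
    powers = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    codes = (win.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    return codes, valid


def _entries_at(seq: str, seq_id: int, k: int, offsets: np.ndarray, source: int) -> np.ndarray:
    vals = seq_to_vals(seq)
    codes, valid = _window_codes(vals, offsets, k)
    codes, offsets = codes[valid], offsets[valid]
    rc = revcomp_code(codes, k)
    flag = rc < codes
    canon = np.where(flag, rc, codes)
    out = np.empty(len(canon), dtype=KMER_DTYPE)
    out["code"] = canon
    out["source"] = source
    out["seq_id"] = seq_id
    out["offset"] = offsets
    out["rc"] = flag
    return out


def extract_read_kmers(seq: str, seq_id: int, k: int) -> np.ndarray:
    """All overlapping canonical k-mers of a read (windows with ambiguous
    bases skipped).  Requires len(seq) >= k."""
    if len(seq) < k:
        raise ValueError(f"read {seq_id} shorter than k={k}")
    offsets = np.arange(len(seq) - k + 1, dtype=np.intp)
    return _entries_at(seq, seq_id, k, offsets, SOURCE_READ)


def extract_genome_kmers(seq: str, seq_id: int, k: int) -> np.ndarray:
    """Non-overlapping grid k-mers of a genome at offsets 0, k, 2k, ...;
    the trailing remainder shorter than k is ignored."""
    if len(seq) < k:
        raise ValueError(f"genome {seq_id} shorter than k={k}")
    offsets = np.arange(0, len(seq) - k + 1, k, dtype=np.intp)
    return _entries_at(seq, seq_id, k, offsets, SOURCE_GENOME)


def sort_entries(entries: np.ndarray) -> np.ndarray:
    """Sort by (code, source with genome first, seq_id, offset).

    Stable and deterministic; identical k-mers end up adjacent, and within
    a block of equal codes every genome entry precedes every read entry so
    a single forward pass can pair them.
    """
    if len(entries) == 0:
        return entries
    order = np.lexsort(
        (entries["offset"], entries["seq_id"], entries["source"], entries["code"])
    )
    return entries[order]


@dataclass
class SeedStats:
    """Counters from one seed-finding pass."""

    blocks_skipped: int = 0
    raw_seeds: int = 0
    seeds: int = 0


def find_seed_matches(
    sorted_entries: np.ndarray, repeat_cap: int = 1000, stats: SeedStats | None = None
) -> np.ndarray:
    """Emit exact k-base read-vs-genome matches from the sorted entry list.

    Within each block of equal codes the cross product of genome entries and
    read entries is emitted.  The match is on the reverse strand iff the two
    entries' rc flags differ.  Seeds are de-duplicated per
    (read, genome, strand, diagonal) -- the diagonal is
    genome_offset - read_offset on the forward strand and
    genome_offset + read_offset on the reverse strand -- keeping the seed
    with the lowest read offset, so one locus triggers one verification.

    Blocks whose genome side exceeds ``repeat_cap`` entries are skipped and
    counted (low-complexity guard).
    """
    if stats is None:
        stats = SeedStats()
    empty = np.empty(0, dtype=SEED_DTYPE)
    if len(sorted_entries) == 0:
        return empty
    gmask = sorted_entries["source"] == SOURCE_GENOME
    gen = sorted_entries[gmask]
    red = sorted_entries[~gmask]
    if len(gen) == 0 or len(red) == 0:
        return empty
    gcodes = gen["code"]
    # genome-side run lengths per distinct code
    lo = np.searchsorted(gcodes, red["code"], side="left")
    hi = np.searchsorted(gcodes, red["code"], side="right")
    counts = hi - lo
    capped = counts > repeat_cap
    if capped.any():
        stats.blocks_skipped += len(np.unique(red["code"][capped]))
        counts = np.where(capped, 0, counts)
    keep = counts > 0
    if not keep.any():
        return empty
    r_idx = np.repeat(np.flatnonzero(keep), counts[keep])
    total = int(counts.sum())
    step = np.arange(total) - np.repeat(np.cumsum(counts[keep]) - counts[keep], counts[keep])
    g_idx = np.repeat(lo[keep], counts[keep]) + step

    seeds = np.empty(total, dtype=SEED_DTYPE)
    seeds["read_id"] = red["seq_id"][r_idx]
    seeds["genome_id"] = gen["seq_id"][g_idx]
    seeds["read_offset"] = red["offset"][r_idx]
    seeds["genome_offset"] = gen["offset"][g_idx]
    seeds["reverse"] = red["rc"][r_idx] != gen["rc"][g_idx]
    stats.raw_seeds += total

    g_off = seeds["genome_offset"].astype(np.int64)
    r_off = seeds["read_offset"].astype(np.int64)
    diag = np.where(seeds["reverse"] == 1, g_off + r_off, g_off - r_off)
    order = np.lexsort(
        (seeds["read_offset"], diag, seeds["reverse"], seeds["genome_id"], seeds["read_id"])
    )
    seeds = seeds[order]
    diag = diag[order]
    first = np.ones(total, dtype=bool)
    first[1:] = (
        (np.diff(seeds["read_id"].astype(np.int64)) != 0)
        | (np.diff(seeds["genome_id"].astype(np.int64)) != 0)
        | (np.diff(seeds["reverse"].astype(np.int64)) != 0)
        | (np.diff(diag) != 0)
    )
    seeds = seeds[first]
    stats.seeds += len(seeds)
    return seeds
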