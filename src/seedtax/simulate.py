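"""Synthetic metagenome generator with per-read ground truth.

Classification accuracy can only be measured on data whose true origin is
known, so communities are generated in silico: reference genomes are drawn
i.i.d.-uniform over {A,C,G,T}, grouped into genera whose members share a
long identical "conserved block" copied from a genus ancestor (the
situation that makes species-level classification hard and that
pseudo-assembly addresses), annotated with tiled gene features, and
organized under a root -> genus -> species taxonomy.  Read pairs are then
sampled genome-proportional to configured abundances with a normal
insert-size distribution and a homogeneous substitution/indel error
profile.  Everything is reproducible from the RNG seed.

Defaults reflect a paired-end 150 bp short-read library with an error
rate several-fold above a typical Illumina run (substitutions dominate),
insert 300 +/- 30 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneFeature
from .io import ReferenceRecord, SequenceRecord
from .kmers import revcomp
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GenusGroup:
    """``size`` species sharing a conserved block of
    ``conserved_fraction`` * genome_length bases."""

    size: int
    conserved_fraction: float = 0.0

    def __post_init__(self):
        if not (0 <= self.conserved_fraction < 1):
            raise ValueError("conserved_fraction must be in [0, 1)")
        if not (1 <= self.size <= 9):
            raise ValueError("genus size must be 1..9")


@dataclass
class SimConfig:
    rng_seed: int = 0
    genome_length: int = 50_000
    genus_groups: list[GenusGroup] = field(default_factory=lambda: [GenusGroup(1)] * 6)
    abundances: list[float] | None = None   # per genome, genus order; None = equal
    n_fragments: int = 5000
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    sub_rate: float = 0.005
    indel_rate: float = 0.0005
    gene_length: tuple[int, int] = (300, 1500)
    gene_gap: tuple[int, int] = (50, 200)
    chimera_rate: float = 0.0               # fraction of fragments with a far-away mate
    chimera_min_insert: int = 5000

    @property
    def n_genomes(self) -> int:
        return sum(g.size for g in self.genus_groups)

    def genome_abundances(self) -> np.ndarray:
        n = self.n_genomes
        if self.abundances is None:
            return np.full(n, 1.0 / n)
        a = np.asarray(self.abundances, dtype=float)
        if len(a) != n or not np.isclose(a.sum(), 1.0):
            raise ValueError("abundances must cover every genome and sum to 1")
        return a


@dataclass
class ReadTruth:
    fragment_id: str
    true_taxid: int
    genome_id: str
    genome_position: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _tile_features(rng: np.random.Generator, genome_len: int, taxid: int,
                   cfg: SimConfig) -> list[GeneFeature]:
    features = []
    pos = int(rng.integers(cfg.gene_gap[0], cfg.gene_gap[1] + 1))
    n = 0
    while True:
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        if pos + length > genome_len:
            break
        n += 1
        features.append(
            GeneFeature(
                start=pos,
                end=pos + length,
                strand="+" if rng.random() < 0.5 else "-",
                name=f"t{taxid}_g{n:03d}",
                protein_id=f"P{taxid}.{n}",
                product=f"hypothetical protein {n} [taxon {taxid}]",
            )
        )
        pos += length + int(rng.integers(cfg.gene_gap[0], cfg.gene_gap[1] + 1))
    return features


def simulate_genomes(cfg: SimConfig) -> tuple[list[ReferenceRecord], TaxonomyTree]:
    """Generate the reference side: genomes, annotations and taxonomy.

    Taxids: root 1; genus g (1-based) -> 10*g; species j of genus g ->
    10*g + j.  Within a genus every member carries an identical conserved
    block at a shared offset, copied from an unobserved genus ancestor;
    the remainder of each genome is independent.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    parent, rank, name = {1: 1}, {1: "no rank"}, {1: "root"}
    refs = []
    L = cfg.genome_length
    for gi, group in enumerate(cfg.genus_groups, start=1):
        genus_taxid = 10 * gi
        parent[genus_taxid] = 1
        rank[genus_taxid] = "genus"
        name[genus_taxid] = f"Simulugenus g{gi}"
        block_len = int(round(group.conserved_fraction * L))
        block = _random_seq(rng, block_len) if block_len else ""
        block_at = int(rng.integers(0, L - block_len + 1)) if block_len else 0
        for sj in range(1, group.size + 1):
            taxid = genus_taxid + sj
            parent[taxid] = genus_taxid
            rank[taxid] = "species"
            name[taxid] = f"Simulugenus g{gi} species s{sj}"
            seq = _random_seq(rng, L)
            if block_len:
                seq = seq[:block_at] + block + seq[block_at + block_len :]
            refs.append(
                ReferenceRecord(
                    id=f"g{gi}s{sj}",
                    sequence=seq,
                    taxid=taxid,
                    features=_tile_features(rng, L, taxid, cfg),
                )
            )
    tree = TaxonomyTree(parent=parent, rank=rank, name=name, root=1)
    return refs, tree


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue                                   # deletion
        if r < indel_rate:
            out.append(_random_seq(rng, 1))            # insertion before the base
        if rng.random() < sub_rate:
            cur = "ACGT".index(ch) if ch in "ACGT" else 0
            ch = "ACGT"[(cur + int(rng.integers(1, 4))) % 4]
        out.append(ch)
    return "".join(out) if out else seq[:1]


def simulate_reads(
    references: list[ReferenceRecord], cfg: SimConfig
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], pd.DataFrame]:
    """Sample read pairs with ground truth.

    Fragments are drawn genome-proportional to the configured abundances;
    the fragment start is uniform; the insert is Normal(insert_mean,
    insert_sd) truncated to [2*read_length, genome length].  R1 is the
    forward strand at the fragment start, R2 the reverse complement of the
    insert's far end.  A ``chimera_rate`` fraction of fragments instead
    place R2 at least ``chimera_min_insert`` bases downstream (aberrant
    joins that the insert-size screen should catch).  Errors are applied
    per base.  Returns (pairs, truth table).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    ab = cfg.genome_abundances()
    rl = cfg.read_length
    pairs = []
    truth_rows = []
    n_digits = len(str(max(cfg.n_fragments - 1, 1)))
    for i in range(cfg.n_fragments):
        gidx = int(rng.choice(len(references), p=ab))
        ref = references[gidx]
        glen = len(ref.sequence)
        frag_id = f"frag{i:0{n_digits}d}"
        is_chimera = cfg.chimera_rate > 0 and rng.random() < cfg.chimera_rate
        for _attempt in range(100):
            insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            insert = max(insert, 2 * rl)
            if is_chimera:
                insert = int(rng.integers(cfg.chimera_min_insert, glen))
            if insert <= glen:
                break
        else:
            raise ValueError(f"genome {ref.id} shorter than the insert distribution")
        pos = int(rng.integers(0, glen - insert + 1))
        r1 = ref.sequence[pos : pos + rl]
        r2 = revcomp(ref.sequence[pos + insert - rl : pos + insert])
        r1 = _mutate(rng, r1, cfg.sub_rate, cfg.indel_rate)
        r2 = _mutate(rng, r2, cfg.sub_rate, cfg.indel_rate)
        pairs.append(
            (
                SequenceRecord(frag_id, r1, "I" * len(r1), mate=1),
                SequenceRecord(frag_id, r2, "I" * len(r2), mate=2),
            )
        )
        truth_rows.append(
            {
                "fragment_id": frag_id,
                "true_taxid": ref.taxid,
                "genome_id": ref.id,
                "genome_position": pos,
                "chimeric": bool(is_chimera),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return pairs, truth
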