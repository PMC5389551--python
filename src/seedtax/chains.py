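"""Pseudo-assembly: chaining of overlapping alignments along a genome.

Reads that fall in regions conserved across a genus align equally well to
every genus member and alone can only be classified at the genus level.
Chaining groups alignments that overlap on the same genome into a
"pseudo-assembly"; chains often extend beyond the conserved region into
sequence unique to one genome, and the chain's composite score -- shared
by every member alignment -- then separates the true genome from its
relatives.  No consensus sequence is ever built.

For a chain with members spanning [b_s, b_e):

    L    = b_e - b_s                  chain length in nucleotides
    N_b  = sum of member read lengths
    C    = N_b / L                    coverage
    mu_s = (sum of member scores) / N_b   mean score per nucleotide
    S    = C * mu_s * L               chain score

Algebraically S equals the plain sum of member scores; the intermediate
quantities are still computed and reported as defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import Alignment


@dataclass
class Chain:
    genome_id: int
    members: list[Alignment]
    b_s: int = 0
    b_e: int = 0
    L: int = 0
    N_b: int = 0
    C: float = 0.0
    mu_s: float = 0.0
    S: float = 0.0


def chain_alignments(alignments: list[Alignment], min_overlap: int = 20) -> list[Chain]:
    """Partition one genome's alignments into chains.

    Alignments are sorted by genome start; a left-to-right sweep adds an
    alignment to the current chain iff it overlaps the chain's running
    interval [b_s, max b_e) by MORE than ``min_overlap`` bases, otherwise
    a new chain starts.  Chaining is strand-agnostic and independent of
    input order; singleton chains are allowed.
    """
    if not alignments:
        return []
    ordered = sorted(alignments, key=lambda a: (a.genome_start, a.genome_end, a.read_id))
    chains: list[Chain] = []
    cur = [ordered[0]]
    cur_end = ordered[0].genome_end
    for a in ordered[1:]:
        if cur_end - a.genome_start > min_overlap:
            cur.append(a)
            cur_end = max(cur_end, a.genome_end)
        else:
            chains.append(Chain(genome_id=cur[0].genome_id, members=cur))

            cur = [a]
            cur_end = a.genome_end
    chains.append(Chain(genome_id=cur[0].genome_id, members=cur))
    for c in chains:
        score_chain(c)
    return chains


def score_chain(chain: Chain) -> Chain:
    """Fill in b_s, b_e, L, N_b, C, mu_s and S for a non-empty chain."""
    if not chain.members:
        raise ValueError("chain has no members")
    chain.b_s = min(a.genome_start for a in chain.members)
    chain.b_e = max(a.genome_end for a in chain.members)
    chain.L = chain.b_e - chain.b_s
    chain.N_b = sum(a.read_len for a in chain.members)
    total_score = float(sum(a.score for a in chain.members))
    chain.C = chain.N_b / chain.L
    chain.mu_s = total_score / chain.N_b
    chain.S = chain.C * chain.mu_s * chain.L
    return chain


def apply_chain_scores(chains: list[Chain]) -> None:
    """Assign each chain's score S to every member alignment as its
    effective score (the raw score is preserved for reporting)."""
    for c in chains:
        for a in c.members:
            a.effective_score = c.S
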