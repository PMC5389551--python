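"""Paired-end alignment pairing and insert-size screening.

Both mates of a fragment are aligned independently; because bacterial
sequence is repetitive, each mate may align to several loci on the same
genome, so candidate pairs are built by nearest-neighbour matching on
genome start coordinate (each R1 with its nearest R2 and vice versa).
This considers O(n) pairs per fragment/genome instead of the n^2 cross
product.  The library insert size is then inferred robustly: inserts in
[0, Q3 + 2*(Q3 - Q1)] contribute to a mean mu and standard deviation
sigma, and every pair with insert I >= mu + 6*sigma is demoted back to
two orphan single-end alignments (screened, not deleted).

The insert size is the OUTER distance: rightmost aligned genome
coordinate minus leftmost.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .align import Alignment


@dataclass
class AlignmentPair:
    """Two mate alignments on one genome (either may be absent)."""

    r1: Alignment | None
    r2: Alignment | None

    @property
    def insert_size(self) -> int:
        assert self.r1 is not None and self.r2 is not None
        return max(self.r1.genome_end, self.r2.genome_end) - min(
            self.r1.genome_start, self.r2.genome_start
        )

    @property
    def combined_score(self) -> float:
        s = 0.0
        if self.r1 is not None:
            s += self.r1.effective_score
        if self.r2 is not None:
            s += self.r2.effective_score
        return s


@dataclass(frozen=True)
class InsertModel:
    """Robust insert-size model: quartiles of all candidate inserts, then
    mean/SD of the inserts retained below Q3 + 2*(Q3 - Q1)."""

    q1: float
    q3: float
    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + 6.0 * self.sigma


def candidate_pairs(
    r1_alignments: list[Alignment], r2_alignments: list[Alignment]
) -> tuple[list[AlignmentPair], list[Alignment]]:
    """Nearest-neighbour candidate pairs for one (fragment, genome) group.

    Returns (pairs, orphans).  Every alignment appears in at least one
    pair or as an orphan; an alignment may be a member of more than one
    pair (both directions of the nearest-neighbour pass are kept).
    """
    if not r1_alignments or not r2_alignments:
        return [], list(r1_alignments) + list(r2_alignments)
    a1 = sorted(r1_alignments, key=lambda a: (a.genome_start, a.genome_end))
    a2 = sorted(r2_alignments, key=lambda a: (a.genome_start, a.genome_end))
    starts1 = [a.genome_start for a in a1]
    starts2 = [a.genome_start for a in a2]

    def nearest(starts, pos):
        i = bisect.bisect_left(starts, pos)
        if i == 0:
            return 0
        if i == len(starts):
            return len(starts) - 1
        # tie -> earlier (smaller start), deterministic
        return i - 1 if pos - starts[i - 1] <= starts[i] - pos else i

    seen = set()
    pairs = []
    for i, a in enumerate(a1):
        j = nearest(starts2, a.genome_start)
        if (i, j) not in seen:
            seen.add((i, j))
            pairs.append(AlignmentPair(a, a2[j]))
    for j, b in enumerate(a2):
        i = nearest(starts1, b.genome_start)
        if (i, j) not in seen:
            seen.add((i, j))
            pairs.append(AlignmentPair(a1[i], b))
    return pairs, []


def infer_insert_model(insert_sizes) -> InsertModel | None:
    """Fit the insert model; returns None (model disabled, no screening)
    with fewer than two candidate inserts."""
    x = np.asarray(sorted(insert_sizes), dtype=float)
    if len(x) < 2:
        return None
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation ("type 7")
    bound = q3 + 2.0 * (q3 - q1)
    kept = x[(x >= 0) & (x <= bound)]
    if len(kept) == 0:
        return None
    mu = float(kept.mean())
    sigma = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
    return InsertModel(q1=float(q1), q3=float(q3), mu=mu, sigma=sigma)


def screen_pairs(
    pairs: list[AlignmentPair], model: InsertModel | None
) -> tuple[list[AlignmentPair], list[Alignment]]:
    """Demote pairs with insert I >= mu + 6*sigma to orphan alignments.

    Returns (kept pairs, demoted orphan alignments).  With the model
    disabled all pairs are kept.
    """
    if model is None:
        return list(pairs), []
    kept, orphans = [], []
    for p in pairs:
        if p.insert_size >= model.threshold:
            orphans.extend(a for a in (p.r1, p.r2) if a is not None)
        else:
            kept.append(p)
    return kept, orphans
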