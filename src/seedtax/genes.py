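"""Gene inference from reference annotations.

Because real alignments are produced (not just k-mer hits), each surviving
alignment can be attributed to the annotated gene it overlaps most.  Gene
calls are aggregated into report entries keyed by
(taxid, name, protein_id, product); entries with the same key are merged
with a fragment count.  The merge key is the full tuple -- merging on ANY
matching field would chain unrelated genes transitively.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneFeature:
    """Annotated interval on a genome, 0-based half-open."""

    start: int
    end: int
    strand: str = "+"
    name: str | None = None
    protein_id: str | None = None
    product: str | None = None
    kind: str = "CDS"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")


@dataclass
class GeneCall:
    fragment_id: str
    feature: GeneFeature
    genome_id: int
    overlap_bases: int
    taxid: int


@dataclass
class GeneReportEntry:
    taxid: int
    name: str
    protein_id: str
    product: str
    count: int


def gene_for_alignment(alignment, features: list[GeneFeature]):
    """Feature with the most bases overlapping the alignment's genome
    interval; ties go to the smaller feature start.  ``features`` must be
    sorted by start.  Returns (feature, overlap) or None if nothing
    overlaps."""
    best = None
    best_overlap = 0
    for f in features:
        if f.start >= alignment.genome_end:
            break
        overlap = min(f.end, alignment.genome_end) - max(f.start, alignment.genome_start)
        if overlap > best_overlap:
            best, best_overlap = f, overlap
    if best is None:
        return None
    return best, best_overlap


def aggregate_genes(gene_calls: list[GeneCall]) -> list[GeneReportEntry]:
    """Merge gene calls into report entries.

    Group key = (taxid, name, protein_id, product) with absent fields
    normalized to "".  One call per fragment is expected (the caller keeps
    only the call from each fragment's best-scoring alignment); the count
    is the number of fragments in the group.  Output is sorted by key for
    byte-stable reports.
    """
    groups: dict[tuple, int] = {}
    for call in gene_calls:
        f = call.feature
        key = (call.taxid, f.name or "", f.protein_id or "", f.product or "")
        groups[key] = groups.get(key, 0) + 1
    return [
        GeneReportEntry(taxid=k[0], name=k[1], protein_id=k[2], product=k[3], count=n)
        for k, n in sorted(groups.items())
    ]
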