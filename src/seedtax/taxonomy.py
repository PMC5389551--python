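"""Taxonomy tree, lowest-common-ancestor classification and summaries.

A fragment that aligns to several genomes is assigned the lowest common
ancestor (LCA) of the genomes that survive a fractional score screen:
the cutoff is the fragment's best effective (chain) score multiplied by a
user-chosen fraction, and every hit below the cutoff is discarded before
the LCA is taken.  Taxid 0 is the "unclassified" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

UNCLASSIFIED = 0


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonomyTree:
    """id -> parent/rank/name maps with the NCBI convention that the root
    is its own parent.  Every node must reach the root (no cycles)."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int

    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for t in self.parent:
            seen = set()
            node = t
            while node != self.root:
                if node in seen:
                    raise TaxonomyError(f"cycle in taxonomy involving taxid {node}")
                seen.add(node)
                p = self.parent.get(node)
                if p is None:
                    raise TaxonomyError(f"orphan taxid {node} (parent missing)")
                node = p

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def depth(self, taxid: int) -> int:
        d = self._depth.get(taxid)
        if d is None:
            d = 0 if taxid == self.root else self.depth(self.parent[taxid]) + 1
            self._depth[taxid] = d
        return d

    def path_to_root(self, taxid: int) -> list[int]:
        """[taxid, ..., root]."""
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def lca(self, taxids) -> int:
        """Lowest common ancestor of a non-empty set of taxids."""
        it = iter(set(taxids))
        try:
            node = next(it)
        except StopIteration:
            raise TaxonomyError("LCA of an empty set") from None
        for other in it:
            a, b = node, other
            da, db = self.depth(a), self.depth(b)
            while da > db:
                a = self.parent[a]
                da -= 1
            while db > da:
                b = self.parent[b]
                db -= 1
            while a != b:
                a = self.parent[a]
                b = self.parent[b]
            node = a
        return node

    def is_ancestor_or_self(self, ancestor: int, taxid: int) -> bool:
        node = taxid
        while True:
            if node == ancestor:
                return True
            if node == self.root:
                return False
            node = self.parent[node]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxid`` with the given rank, or None."""
        node = taxid
        while True:
            if self.rank.get(node) == rank:
                return node
            if node == self.root:
                return None
            node = self.parent[node]


@dataclass
class TaxonHit:
    """One candidate assignment for a fragment: a taxon with the best
    effective score among the fragment's alignments to that taxon, plus
    the alignment achieving it (used for gene inference)."""

    taxid: int
    score: float
    best_alignment: object = None


@dataclass
class ClassificationResult:
    fragment_id: str
    taxid: int
    rank: str
    best_effective_score: float
    n_surviving_alignments: int
    gene: object = None         # GeneCall, filled by the gene caller


def classify_fragment(
    fragment_id: str,
    hits: list[TaxonHit],
    tree: TaxonomyTree,
    fraction: float = 0.9,
) -> ClassificationResult:
    """Fractional score screen followed by LCA.

    Hits are first merged per taxid (multiple reference sequences sharing
    a taxid count once, at their best score).  The cutoff is
    ``fraction * max score``; hits at or above the cutoff survive (ties
    with the best always survive) and the result is their LCA.  No hits
    -> unclassified (taxid 0).
    """
    if not hits:
        return ClassificationResult(fragment_id, UNCLASSIFIED, "-", 0.0, 0)
    per_taxid: dict[int, TaxonHit] = {}
    for h in hits:
        cur = per_taxid.get(h.taxid)
        if cur is None or h.score > cur.score:
            per_taxid[h.taxid] = h
    best = max(h.score for h in per_taxid.values())
    cutoff = fraction * best
    survivors = [h for h in per_taxid.values() if h.score >= cutoff - 1e-9]
    taxid = tree.lca([h.taxid for h in survivors])
    return ClassificationResult(
        fragment_id=fragment_id,
        taxid=taxid,
        rank=tree.rank.get(taxid, "-"),
        best_effective_score=best,
        n_surviving_alignments=len(survivors),
    )


def summarize_taxa(results, tree: TaxonomyTree) -> pd.DataFrame:
    """Per-taxon abundance table.

    ``count`` is the number of fragments assigned exactly to the taxon;
    ``cumulative`` adds every fragment assigned to a descendant (a
    fragment counts toward each of its ancestors); ``proportion`` is
    cumulative over total fragments.  Sorted by cumulative count, then
    taxid for determinism.
    """
    counts: dict[int, int] = {}
    cumulative: dict[int, int] = {}
    total = 0
    for r in results:
        total += 1
        if r.taxid == UNCLASSIFIED:
            continue
        counts[r.taxid] = counts.get(r.taxid, 0) + 1
        for node in tree.path_to_root(r.taxid):
            cumulative[node] = cumulative.get(node, 0) + 1
    rows = [
        {
            "taxid": t,
            "name": tree.name.get(t, ""),
            "rank": tree.rank.get(t, ""),
            "count": counts.get(t, 0),
            "cumulative": c,
            "proportion": c / total if total else 0.0,
        }
        for t, c in cumulative.items()
    ]
    df = pd.DataFrame(
        rows, columns=["taxid", "name", "rank", "count", "cumulative", "proportion"]
    )
    if len(df):
        df = df.sort_values(
            ["cumulative", "taxid"], ascending=[False, True], ignore_index=True
        )
    return df
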