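"""End-to-end classification pipeline.

Stage order per chunk of fragments:

    extract k-mers -> sort -> seed matches -> Smith-Waterman verification
    -> absolute-score screen -> mate pairing + insert-size screen
    -> pseudo-assembly chaining -> fractional screen + LCA -> gene calls

Reads are processed in chunks of ``chunk_size`` fragments so memory
scales with the chunk, not the data set; chunk boundaries never split a
fragment.  The genome k-mer list is built once and reused across chunks.
The insert-size model is estimated per chunk (a streaming constraint;
``fixed_insert_model`` freezes it instead).  The classifier itself is
deterministic -- identical inputs and configuration give identical
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kmers
from .align import (
    Alignment,
    ScoringScheme,
    screen_alignments,
    smith_waterman,
    window_for_seed,
)
from .chains import apply_chain_scores, chain_alignments
from .genes import GeneCall, aggregate_genes, gene_for_alignment
from .io import ReferenceRecord, SequenceRecord
from .kmers import SeedStats, revcomp
from .pairing import InsertModel, candidate_pairs, infer_insert_model, screen_pairs
from .taxonomy import (
    UNCLASSIFIED,
    ClassificationResult,
    TaxonHit,
    TaxonomyTree,
    classify_fragment,
)

log = logging.getLogger("seedtax")


@dataclass
class RunConfig:
    """Tunable pipeline parameters (CLI flags mirror these fields)."""

    k: int = 32
    min_score: int = 0
    fraction: float = 0.9
    min_overlap: int = 20
    chunk_size: int = 1_000_000
    pseudo_assembly: bool = True
    pairing: bool = True
    margin: int = 32
    repeat_cap: int = 1000
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    fixed_insert_model: InsertModel | None = None

    def __post_init__(self):
        if not (1 <= self.k <= 32):
            raise ValueError("k must be in 1..32")
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass
class StageCounters:
    reads_total: int = 0
    reads_too_short: int = 0
    read_kmers: int = 0
    genome_kmers: int = 0
    seeds: int = 0
    seed_blocks_skipped: int = 0
    sw_calls: int = 0
    alignments: int = 0
    alignments_screened: int = 0
    pairs_formed: int = 0
    pairs_demoted: int = 0
    chains: int = 0
    fragments_classified: int = 0
    peak_chunk_entries: int = 0   # largest sorted k-mer list held at once


@dataclass
class ClassifyOutput:
    results: list[ClassificationResult]
    gene_entries: list
    counters: StageCounters
    alignments: list[Alignment]          # survivors, for optional SAM output
    insert_models: list[InsertModel | None]
    oriented_reads: dict = field(default_factory=dict)


@dataclass
class Fragment:
    """One sequenced fragment: a read pair or a single read."""

    fragment_id: str
    r1: SequenceRecord
    r2: SequenceRecord | None = None


def fragments_from_records(records) -> list[Fragment]:
    """Group an (interleaved or single-end) record stream into fragments."""
    out = []
    by_id: dict[str, Fragment] = {}
    for rec in records:
        if rec.mate == 2 and rec.id in by_id:
            by_id[rec.id].r2 = rec
        else:
            frag = Fragment(rec.id, rec)
            by_id[rec.id] = frag
            out.append(frag)
    return out


def _chunked(items, size):
    for i in range(0, len(items), size):
        yield items[i : i + size]


def _align_seed(seed, read_seq, rc_seq, genome_seq, cfg, read_len):
    """Verify one seed with Smith-Waterman; returns the alignment in
    genome coordinates with the read oriented along the seed strand."""
    reverse = bool(seed["reverse"])
    if reverse:
        oriented = rc_seq
        r_off = read_len - cfg.k - int(seed["read_offset"])
    else:
        oriented = read_seq
        r_off = int(seed["read_offset"])
    ws, we = window_for_seed(
        int(seed["genome_offset"]), r_off, read_len, len(genome_seq), cfg.margin
    )
    return smith_waterman(
        oriented,
        genome_seq[ws:we],
        cfg.scheme,
        read_id=int(seed["read_id"]),
        genome_id=int(seed["genome_id"]),
        strand="-" if reverse else "+",
        window_start=ws,
    )


def _classify_chunk(chunk, references, tree, cfg, genome_entries, counters, output):
    # --- collect reads; reject reads shorter than k with a counted warning
    reads = []          # (fragment_index_in_chunk, mate, sequence)
    for fi, frag in enumerate(chunk):
        for mate, rec in ((1, frag.r1), (2, frag.r2)):
            if rec is None:
                continue
            counters.reads_total += 1
            if len(rec.sequence) < cfg.k:
                counters.reads_too_short += 1
                continue
            reads.append((fi, mate, rec.sequence.upper()))

    # --- k-mer extraction and the sorted list
    entry_arrays = [genome_entries]
    for rid, (_, _, seq) in enumerate(reads):
        entry_arrays.append(kmers.extract_read_kmers(seq, rid, cfg.k))
        counters.read_kmers += len(entry_arrays[-1])
    entries = kmers.sort_entries(np.concatenate(entry_arrays))
    counters.peak_chunk_entries = max(counters.peak_chunk_entries, len(entries))
    stats = SeedStats()
    seeds = kmers.find_seed_matches(entries, repeat_cap=cfg.repeat_cap, stats=stats)
    counters.seeds += stats.seeds
    counters.seed_blocks_skipped += stats.blocks_skipped

    # --- Smith-Waterman verification
    rc_cache: dict[int, str] = {}
    raw: list[Alignment] = []
    for seed in seeds:
        rid = int(seed["read_id"])
        _, mate, seq = reads[rid]
        if seed["reverse"] and rid not in rc_cache:
            rc_cache[rid] = revcomp(seq)
        aln = _align_seed(
            seed, seq, rc_cache.get(rid), references[int(seed["genome_id"])].sequence,
            cfg, len(seq),
        )
        counters.sw_calls += 1
        fi, mate, _ = reads[rid]
        aln.fragment_id = chunk[fi].fragment_id
        aln.mate = mate
        raw.append(aln)

    # --- collapse exact duplicates (overlapping windows from several
    # diagonals can rediscover the same local alignment)
    seen = set()
    unique = []
    for a in raw:
        key = (a.read_id, a.genome_id, a.strand, a.genome_start, a.genome_end, a.score)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    counters.alignments += len(unique)
    surviving = screen_alignments(unique, cfg.min_score)
    counters.alignments_screened += len(unique) - len(surviving)

    # --- pairing + insert screen
    kept_pairs = []
    orphans = []
    if cfg.pairing:
        groups: dict[tuple, tuple[list, list]] = {}
        for a in surviving:
            g = groups.setdefault((a.fragment_id, a.genome_id), ([], []))
            g[0 if a.mate != 2 else 1].append(a)
        all_pairs = []
        for (r1s, r2s) in groups.values():
            pairs, orph = candidate_pairs(r1s, r2s)
            all_pairs.extend(pairs)
            orphans.extend(orph)
        counters.pairs_formed += len(all_pairs)
        model = cfg.fixed_insert_model
        if model is None:
            model = infer_insert_model([p.insert_size for p in all_pairs])
        output.insert_models.append(model)
        if model is not None:
            log.info(
                "insert model: Q1=%.1f Q3=%.1f mu=%.1f sigma=%.1f threshold=%.1f",
                model.q1, model.q3, model.mu, model.sigma, model.threshold,
            )
        kept_pairs, demoted = screen_pairs(all_pairs, model)
        counters.pairs_demoted += len(all_pairs) - len(kept_pairs)
        orphans.extend(demoted)
    else:
        orphans = list(surviving)
        output.insert_models.append(None)

    # --- pseudo-assembly chaining over every surviving alignment
    if cfg.pseudo_assembly:
        by_genome: dict[int, list[Alignment]] = {}
        for a in surviving:
            by_genome.setdefault(a.genome_id, []).append(a)
        for gid, alns in by_genome.items():
            chains = chain_alignments(alns, cfg.min_overlap)
            counters.chains += len(chains)
            apply_chain_scores(chains)
    else:
        for a in surviving:
            a.effective_score = float(a.score)

    # --- per-fragment fractional screen + LCA + gene call
    frag_hits: dict[str, list[TaxonHit]] = {f.fragment_id: [] for f in chunk}
    for p in kept_pairs:
        members = [a for a in (p.r1, p.r2) if a is not None]
        best = max(members, key=lambda a: a.effective_score)
        frag_hits[best.fragment_id].append(
            TaxonHit(
                taxid=references[best.genome_id].taxid,
                score=p.combined_score,
                best_alignment=best,
            )
        )
    seen_orphans = set()
    for a in orphans:
        if id(a) in seen_orphans:      # an alignment may orphan out of several pairs
            continue
        seen_orphans.add(id(a))
        frag_hits[a.fragment_id].append(
            TaxonHit(
                taxid=references[a.genome_id].taxid,
                score=a.effective_score,
                best_alignment=a,
            )
        )

    results = []
    gene_calls = []
    for frag in chunk:
        res = classify_fragment(
            frag.fragment_id, frag_hits[frag.fragment_id], tree, cfg.fraction
        )
        if res.taxid != UNCLASSIFIED:
            counters.fragments_classified += 1
            hits = frag_hits[frag.fragment_id]
            best_hit = max(hits, key=lambda h: (h.score, -h.taxid))
            aln = best_hit.best_alignment
            ref = references[aln.genome_id]
            found = gene_for_alignment(aln, ref.features)
            if found is not None:
                feature, overlap = found
                call = GeneCall(
                    fragment_id=frag.fragment_id,
                    feature=feature,
                    genome_id=aln.genome_id,
                    overlap_bases=overlap,
                    taxid=res.taxid,
                )
                res.gene = call
                gene_calls.append(call)
        results.append(res)

    # bookkeeping for optional SAM output
    sam_alns = [a for p in kept_pairs for a in (p.r1, p.r2) if a is not None]
    sam_alns.extend(a for a in orphans if id(a) in seen_orphans)
    for a in sam_alns:
        rid = a.read_id
        fi, mate, seq = reads[rid]
        output.oriented_reads[(a.fragment_id, a.mate)] = (
            rc_cache.get(rid, seq) if a.strand == "-" else seq
        )
    output.alignments.extend(sam_alns)
    return results, gene_calls


def classify(
    references: list[ReferenceRecord],
    tree: TaxonomyTree,
    fragments: list[Fragment],
    cfg: RunConfig = RunConfig(),
) -> ClassifyOutput:
    """Classify fragments against the reference set.  See module docstring
    for the stage order.  Returns per-fragment results (input order),
    aggregated gene report entries and stage counters."""
    counters = StageCounters()
    output = ClassifyOutput(
        results=[], gene_entries=[], counters=counters, alignments=[], insert_models=[]
    )
    genome_entries = (
        np.concatenate(
            [kmers.extract_genome_kmers(r.sequence, gid, cfg.k)
             for gid, r in enumerate(references)]
        )
        if references
        else np.empty(0, dtype=kmers.KMER_DTYPE)
    )
    counters.genome_kmers = len(genome_entries)
    all_gene_calls = []
    for chunk in _chunked(fragments, cfg.chunk_size):
        results, gene_calls = _classify_chunk(
            chunk, references, tree, cfg, genome_entries, counters, output
        )
        output.results.extend(results)
        all_gene_calls.extend(gene_calls)
    output.gene_entries = aggregate_genes(all_gene_calls)
    log.info(
        "classified %d/%d fragments (%d seeds, %d SW calls, %d chains)",
        counters.fragments_classified, len(fragments), counters.seeds,
        counters.sw_calls, counters.chains,
    )
    return output


def evaluate(
    results: list[ClassificationResult], truth: pd.DataFrame, tree: TaxonomyTree
) -> dict:
    """Accuracy of assignments against a truth table.

    Species-level: assigned taxid's species ancestor equals the true
    species (assignments above species rank count as incorrect).
    Genus-level: genus ancestors match (assignments above genus count as
    incorrect).  Unclassified fragments are incorrect at both ranks.
    Returns overall accuracies plus a per-species table.
    """
    truth_by_id = dict(zip(truth["fragment_id"], truth["true_taxid"]))
    missing = [r.fragment_id for r in results if r.fragment_id not in truth_by_id]
    if missing:
        raise ValueError(f"fragments missing from truth table: {missing[:5]} ...")
    per_species: dict[int, dict] = {}
    n_sp = n_gen = 0
    for r in results:
        true_sp = truth_by_id[r.fragment_id]
        row = per_species.setdefault(
            true_sp, {"n": 0, "species_correct": 0, "genus_correct": 0}
        )
        row["n"] += 1
        if r.taxid == UNCLASSIFIED:
            continue
        true_gen = tree.ancestor_at_rank(true_sp, "genus")
        sp_ok = tree.ancestor_at_rank(r.taxid, "species") == true_sp
        gen_ok = (
            true_gen is not None
            and tree.ancestor_at_rank(r.taxid, "genus") == true_gen
        )
        row["species_correct"] += sp_ok
        row["genus_correct"] += gen_ok
        n_sp += sp_ok
        n_gen += gen_ok
    table = pd.DataFrame(
        [
            {
                "true_taxid": t,
                "n_fragments": v["n"],
                "species_accuracy": v["species_correct"] / v["n"],
                "genus_accuracy": v["genus_correct"] / v["n"],
            }
            for t, v in sorted(per_species.items())
        ]
    )
    n = len(results)
    return {
        "species_accuracy": n_sp / n if n else 0.0,
        "genus_accuracy": n_gen / n if n else 0.0,
        "n_fragments": n,
        "per_species": table,
    }


def wrong_clade_fraction(results, truth: pd.DataFrame, tree: TaxonomyTree) -> float:
    """Fraction of classified fragments whose assignment is NOT an
    ancestor-or-self of the true species (i.e. lies in a wrong clade)."""
    truth_by_id = dict(zip(truth["fragment_id"], truth["true_taxid"]))
    classified = wrong = 0
    for r in results:
        if r.taxid == UNCLASSIFIED:
            continue
        classified += 1
        if not tree.is_ancestor_or_self(r.taxid, truth_by_id[r.fragment_id]):
            wrong += 1
    return wrong / classified if classified else 0.0
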