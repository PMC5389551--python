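"""File formats: FASTQ/FASTA, GenBank flat files, NCBI taxonomy dumps,
per-read TSV reports, aggregated XML gene reports and optional SAM.

All internal coordinates are 0-based half-open; GenBank (1-based closed)
and SAM (1-based) are converted at this boundary.  Sequence parsing goes
through Biopython; the taxonomy dump parser is local (pipe-delimited
nodes.dmp/names.dmp dialect, "scientific name" rows only).
"""

from __future__ import annotations

import gzip
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord as _BioRecord

from .genes import GeneFeature
from .taxonomy import TaxonomyError, TaxonomyTree


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SequenceRecord:
    """A read (or any plain sequence) with optional quality and mate tag."""

    id: str
    sequence: str
    quality: str | None = None
    mate: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )


@dataclass
class ReferenceRecord:
    """A reference genome: sequence, taxon id and annotated features."""

    id: str
    sequence: str
    taxid: int
    features: list[GeneFeature] = field(default_factory=list)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fragment_id(title: str) -> str:
    """Normalize '@frag/1', '@frag 1:N:0:...' and plain ids to one
    fragment id shared by both mates."""
    head = title.split()[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def _iter_fastq_one(path):
    with _open_text(path) as handle:
        record_no = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                yield title, seq, qual
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed FASTQ near record {record_no + 1} "
                f"(line ~{record_no * 4 + 1}): {exc}"
            ) from exc


def read_fastq(path, mate_path=None):
    """Stream SequenceRecords from FASTQ (plain or gzip).

    With ``mate_path`` the two files are read in lockstep and records are
    yielded interleaved (mate 1 then mate 2 per fragment) under a shared
    normalized fragment id; unequal record counts raise FormatError.
    """
    if mate_path is None:
        for title, seq, qual in _iter_fastq_one(path):
            yield SequenceRecord(id=_fragment_id(title), sequence=seq, quality=qual)
        return
    it1 = _iter_fastq_one(path)
    it2 = _iter_fastq_one(mate_path)
    n1 = n2 = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            n1 += rec1 is not None
            n2 += rec2 is not None
            for it in (it1, it2):
                for _ in it:
                    if it is it1:
                        n1 += 1
                    else:
                        n2 += 1
            raise FormatError(
                f"mate files have unequal record counts ({n1} vs {n2}): "
                f"{path} / {mate_path}"
            )
        n1 += 1
        n2 += 1
        yield SequenceRecord(_fragment_id(rec1[0]), rec1[1], rec1[2], mate=1)
        yield SequenceRecord(_fragment_id(rec2[0]), rec2[1], rec2[2], mate=2)


def write_fastq(records, path) -> None:
    with open(path, "w") as out:
        for r in records:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            suffix = f"/{r.mate}" if r.mate else ""
            out.write(f"@{r.id}{suffix}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path):
    """Stream SequenceRecords from FASTA (plain or gzip)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(records, path) -> None:
    with open(path, "w") as out:
        for r in records:
            out.write(f">{r.id}\n")
            seq = r.sequence
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GenBank

_FEATURE_KINDS = ("CDS", "gene")
_RNA_KINDS = ("rRNA", "tRNA")


def _taxid_from_source(rec) -> int | None:
    for feat in rec.features:
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", []):
                if xref.startswith("taxon:"):
                    return int(xref.split(":", 1)[1])
    return None


def read_genbank(path, *, require_taxid=False, include_rna=False) -> list[ReferenceRecord]:
    """Parse a GenBank flat file into ReferenceRecords.

    The taxon id comes from the source feature's ``/db_xref="taxon:N"``;
    records without one are skipped with a warning (or rejected when
    ``require_taxid``).  CDS and gene features become GeneFeatures with
    1-based-closed coordinates converted to 0-based half-open; a join()
    location takes the span of its outermost bounds.  Records without
    sequence raise FormatError.
    """
    from Bio.Seq import UndefinedSequenceError

    kinds = _FEATURE_KINDS + (_RNA_KINDS if include_rna else ())
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        try:
            seq = str(rec.seq).upper()
        except UndefinedSequenceError as exc:
            raise FormatError(
                f"{path}: record {rec.id} has no ORIGIN sequence"
            ) from exc
        if not seq:
            raise FormatError(f"{path}: record {rec.id} has no ORIGIN sequence")
        taxid = _taxid_from_source(rec)
        if taxid is None:
            msg = f"{path}: record {rec.id} lacks a taxon db_xref"
            if require_taxid:
                raise FormatError(msg)
            warnings.warn(msg + "; record skipped")
            continue
        features = []
        for feat in rec.features:
            if feat.type not in kinds:
                continue
            start = int(feat.location.start)      # already 0-based in Biopython
            end = int(feat.location.end)          # outermost bounds for join()
            strand = "-" if feat.location.strand == -1 else "+"
            q = feat.qualifiers
            features.append(
                GeneFeature(
                    start=start,
                    end=end,
                    strand=strand,
                    name=q.get("gene", [None])[0],
                    protein_id=q.get("protein_id", [None])[0],
                    product=q.get("product", [None])[0],
                    kind=feat.type,
                )
            )
        features.sort(key=lambda f: (f.start, f.end))
        out.append(ReferenceRecord(id=rec.id, sequence=seq, taxid=taxid, features=features))
    return out


def write_genbank(references: list[ReferenceRecord], tree: TaxonomyTree, path) -> None:
    """Write minimal GenBank flat files for generated references."""
    records = []
    for ref in references:
        rec = _BioRecord(Seq(ref.sequence), id=ref.id, name=ref.id[:16],
                         description=tree.name.get(ref.taxid, ""))
        rec.annotations["molecule_type"] = "DNA"
        src = SeqFeature(FeatureLocation(0, len(ref.sequence)), type="source")
        src.qualifiers["db_xref"] = [f"taxon:{ref.taxid}"]
        src.qualifiers["organism"] = [tree.name.get(ref.taxid, "synthetic organism")]
        rec.features.append(src)
        for f in ref.features:
            feat = SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type=f.kind,
            )
            if f.name:
                feat.qualifiers["gene"] = [f.name]
            if f.protein_id:
                feat.qualifiers["protein_id"] = [f.protein_id]
            if f.product:
                feat.qualifiers["product"] = [f.product]
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# NCBI taxonomy dump dialect


def read_taxonomy(nodes_path, names_path) -> TaxonomyTree:
    """Parse nodes.dmp/names.dmp (pipe-delimited, tab-pipe separators).

    Only "scientific name" rows of names.dmp are used.  The root is the
    node that is its own parent.  Orphan parents and cycles raise
    TaxonomyError listing the offenders.
    """
    parent, rank, name = {}, {}, {}
    root = None
    with _open_text(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            taxid, par = int(fields[0]), int(fields[1])
            parent[taxid] = par
            rank[taxid] = fields[2] if len(fields) > 2 else ""
            if taxid == par:
                root = taxid
    if root is None:
        raise TaxonomyError(f"{nodes_path}: no root node (a node that is its own parent)")
    orphans = sorted(t for t, p in parent.items() if p not in parent)
    if orphans:
        raise TaxonomyError(f"{nodes_path}: orphan taxids (parent absent): {orphans}")
    with _open_text(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                name[int(fields[0])] = fields[1]
    return TaxonomyTree(parent=parent, rank=rank, name=name, root=root)


def write_taxonomy(tree: TaxonomyTree, nodes_path, names_path) -> None:
    with open(nodes_path, "w") as out:
        for taxid in sorted(tree.parent):
            out.write(
                f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank.get(taxid, 'no rank')}\t|\n"
            )
    with open(names_path, "w") as out:
        for taxid in sorted(tree.parent):
            nm = tree.name.get(taxid, f"taxon {taxid}")
            out.write(f"{taxid}\t|\t{nm}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# Reports

TSV_HEADER = "fragment_id\ttaxid\tname\trank\tchain_score\tgene\n"


def write_reports(results, gene_entries, tsv_path, xml_path, tree: TaxonomyTree) -> None:
    """Per-fragment TSV plus aggregated XML gene report; byte-stable for
    identical inputs.  Unclassified fragments get taxid 0 / name
    "unclassified"; fragments without a gene call get "-"."""
    with open(tsv_path, "w") as out:
        out.write(TSV_HEADER)
        for r in results:
            if r.taxid == 0:
                name, rank = "unclassified", "-"
            else:
                name = tree.name.get(r.taxid, "")
                rank = tree.rank.get(r.taxid, "")
            gene = r.gene.feature.name if r.gene and r.gene.feature.name else "-"
            out.write(
                f"{r.fragment_id}\t{r.taxid}\t{name}\t{rank}\t"
                f"{r.best_effective_score:.6g}\t{gene}\n"
            )
    root = ET.Element("gene_report")
    for e in gene_entries:
        el = ET.SubElement(root, "gene", taxid=str(e.taxid), count=str(e.count))
        ET.SubElement(el, "name").text = e.name
        ET.SubElement(el, "protein_id").text = e.protein_id
        ET.SubElement(el, "product").text = e.product
        ET.SubElement(el, "taxon_name").text = tree.name.get(e.taxid, "")
    ET.indent(root)
    ET.ElementTree(root).write(xml_path, encoding="unicode", xml_declaration=True)
    with open(xml_path, "a") as out:
        out.write("\n")


def write_sam(alignments, references: list[ReferenceRecord], reads: dict, path) -> None:
    """Optional SAM output of surviving alignments (non-normative
    convenience; one record per alignment, unpaired flags only).

    ``reads`` maps (fragment_id, mate) -> oriented read sequence as
    aligned.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r.sequence)} for r in references],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in sorted(
            alignments, key=lambda x: (x.genome_id, x.genome_start, x.fragment_id, x.mate)
        ):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.fragment_id or str(a.read_id)
            rec.reference_id = a.genome_id
            rec.reference_start = a.genome_start
            rec.flag = 16 if a.strand == "-" else 0
            seq = reads.get((a.fragment_id, a.mate))
            cigar = []
            for op, length in a.edits:
                code = {"M": 0, "X": 0, "I": 1, "D": 2}[op]
                if cigar and cigar[-1][0] == code:
                    cigar[-1] = (code, cigar[-1][1] + length)
                else:
                    cigar.append((code, length))
            if seq is not None:
                if a.read_start:
                    cigar.insert(0, (4, a.read_start))  # soft clip
                if a.read_len - a.read_end:
                    cigar.append((4, a.read_len - a.read_end))
            rec.cigartuples = cigar
            if seq is not None:
                rec.query_sequence = seq
            rec.mapping_quality = 255
            rec.set_tag("AS", int(a.score))
            out.write(rec)
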