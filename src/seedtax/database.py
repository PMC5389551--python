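"""Reference database archive: sequences + features + taxid map + taxonomy.

The archive is an implementation-internal, versioned JSON file built once
by the ``build`` subcommand and loaded at classify time.  Every reference
taxid must be present in the bundled taxonomy tree.
"""

from __future__ import annotations

import json
from pathlib import Path

from .genes import GeneFeature
from .io import FormatError, ReferenceRecord, read_fasta, read_genbank, read_taxonomy
from .taxonomy import TaxonomyTree

MAGIC = "seedtax-db"
VERSION = 1


class DatabaseError(ValueError):
    pass


def build_database(
    references: list[ReferenceRecord], tree: TaxonomyTree, out_path
) -> None:
    """Serialize references and taxonomy into a database archive.

    Raises DatabaseError on duplicate reference ids or reference taxids
    absent from the tree.
    """
    seen = set()
    for ref in references:
        if ref.id in seen:
            raise DatabaseError(f"duplicate reference id {ref.id!r}")
        seen.add(ref.id)
        if ref.taxid not in tree:
            raise DatabaseError(
                f"reference {ref.id!r}: taxid {ref.taxid} missing from taxonomy"
            )
    payload = {
        "magic": MAGIC,
        "version": VERSION,
        "references": [
            {
                "id": r.id,
                "taxid": r.taxid,
                "sequence": r.sequence,
                "features": [
                    {
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                        "name": f.name,
                        "protein_id": f.protein_id,
                        "product": f.product,
                        "kind": f.kind,
                    }
                    for f in r.features
                ],
            }
            for r in references
        ],
        "taxonomy": {
            "root": tree.root,
            "parent": {str(t): p for t, p in sorted(tree.parent.items())},
            "rank": {str(t): r for t, r in sorted(tree.rank.items())},
            "name": {str(t): n for t, n in sorted(tree.name.items())},
        },
    }
    Path(out_path).write_text(json.dumps(payload, separators=(",", ":")))


def load_database(path) -> tuple[list[ReferenceRecord], TaxonomyTree]:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DatabaseError(f"cannot read database {path}: {exc}") from exc
    if payload.get("magic") != MAGIC:
        raise DatabaseError(f"{path} is not a seedtax database")
    if payload.get("version") != VERSION:
        raise DatabaseError(f"unsupported database version {payload.get('version')}")
    refs = [
        ReferenceRecord(
            id=r["id"],
            sequence=r["sequence"],
            taxid=r["taxid"],
            features=[GeneFeature(**f) for f in r["features"]],
        )
        for r in payload["references"]
    ]
    tx = payload["taxonomy"]
    tree = TaxonomyTree(
        parent={int(t): p for t, p in tx["parent"].items()},
        rank={int(t): r for t, r in tx["rank"].items()},
        name={int(t): n for t, n in tx["name"].items()},
        root=tx["root"],
    )
    return refs, tree


def build_from_paths(
    genbank_paths=(),
    fasta_path=None,
    taxmap_path=None,
    nodes_path=None,
    names_path=None,
    out_path=None,
) -> tuple[list[ReferenceRecord], TaxonomyTree]:
    """Assemble a database from GenBank files or FASTA + taxid map, plus a
    taxonomy dump; writes the archive when ``out_path`` is given."""
    if nodes_path is None or names_path is None:
        raise DatabaseError("a taxonomy (nodes.dmp + names.dmp) is required")
    tree = read_taxonomy(nodes_path, names_path)
    refs: list[ReferenceRecord] = []
    for p in genbank_paths:
        refs.extend(read_genbank(p))
    if fasta_path is not None:
        if taxmap_path is None:
            raise DatabaseError("FASTA input requires a taxid mapping table")
        taxmap = {}
        with open(taxmap_path) as fh:
            for line in fh:
                if line.strip():
                    seq_id, taxid = line.split()[:2]
                    taxmap[seq_id] = int(taxid)
        for rec in read_fasta(fasta_path):
            if rec.id not in taxmap:
                raise DatabaseError(f"no taxid mapping for FASTA record {rec.id!r}")
            refs.append(
                ReferenceRecord(id=rec.id, sequence=rec.sequence, taxid=taxmap[rec.id])
            )
    if not refs:
        raise FormatError("no reference records found")
    if out_path is not None:
        build_database(refs, tree, out_path)
    return refs, tree
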