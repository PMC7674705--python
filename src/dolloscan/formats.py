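"""File formats: FASTA, GFF3 gene models, Newick trees, status-matrix TSV.

All coordinates are 0-based half-open internally; GFF3's 1-based closed
coordinates are converted at this boundary and nowhere else.  Minus-strand
gene models keep their exons in ascending genomic order; CDS assembly
reverse-complements the spliced concatenation (see
:func:`dolloscan.lesions.extract_cds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .tree import SpeciesTree, TreeNode

_NT = set("ACGTUNRYSWKMBDHV-")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``moltype`` is ``"nt"`` or ``"aa"``."""

    id: str
    seq: str
    moltype: str = "nt"

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        alphabet = _NT if self.moltype == "nt" else _AA
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValueError(
                f"{self.id!r}: characters {sorted(bad)} invalid for moltype {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One gene copy in one species: contig, strand, ordered exon intervals.

    Exons are genomic intervals, 0-based half-open, sorted ascending and
    non-overlapping regardless of strand.  For minus-strand genes the
    transcription order is the reverse of the stored order.
    """

    gene_id: str
    species: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 exon")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError(f"{self.gene_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping or unsorted exons")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, moltype: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file; the header token before the first whitespace is the
    record id.  Duplicate ids and empty files are hard errors."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), moltype=moltype))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read CDS features grouped by their ``Parent`` (falling back to ``ID``)
    attribute into :class:`GeneModel` objects.

    GFF3 1-based closed coordinates become 0-based half-open.  A ``species``
    attribute on the feature (our own writer emits one) populates
    ``GeneModel.species``; otherwise it is left empty.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, dict] = {}
    order: list[str] = []
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        if not parents:
            raise ValueError(f"CDS feature without ID/Parent in {path}")
        key = parents[0]
        species = (cds.attributes.get("species") or [""])[0]
        iv = (cds.start - 1, cds.end)  # GFF3 -> 0-based half-open
        if key not in groups:
            groups[key] = {
                "contig": cds.seqid,
                "strand": cds.strand,
                "species": species,
                "exons": [],
            }
            order.append(key)
        groups[key]["exons"].append(iv)
    models = []
    for key in order:
        g = groups[key]
        exons = sorted(g["exons"])
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {key!r}: overlapping exons in {path}")
        models.append(
            GeneModel(
                gene_id=key,
                species=g["species"],
                contig=g["contig"],
                strand=g["strand"],
                exons=exons,
            )
        )
    return models


def write_gff3_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id};species={m.species}"
            s0, e0 = m.exons[0][0], m.exons[-1][1]
            fh.write(
                f"{m.contig}\tdolloscan\tgene\t{s0 + 1}\t{e0}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.contig}\tdolloscan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id};species={m.species}\n"
                )


# ---------------------------------------------------------------------------
# Newick


def _dendropy_to_species_tree(dtree: dendropy.Tree) -> SpeciesTree:
    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return SpeciesTree(root)


def read_newick(source: str | Path) -> SpeciesTree:
    """Parse a rooted Newick tree from a file path or a literal string."""
    text = str(source)
    try:
        is_file = Path(text).is_file()
    except (OSError, ValueError):
        is_file = False
    if is_file:
        text = Path(text).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf label in Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf label in Newick input")
    return _dendropy_to_species_tree(dtree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Status matrix TSV


def write_status_matrix(matrix: "dict | object", path: str | Path) -> None:
    """Write a species x gene status table as TSV (first column ``species``).

    Accepts either a mapping ``{species: {gene: status}}`` or any object with
    a ``to_frame()`` method returning such a table."""
    if hasattr(matrix, "to_frame"):
        frame = matrix.to_frame()
    else:
        frame = pd.DataFrame.from_dict(matrix, orient="index")
        frame.index.name = "species"
    frame.sort_index().to_csv(path, sep="\t")


def read_status_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species")
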