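"""Genome/annotation I/O and gene-oriented sequence views.

Coordinate conventions used throughout the toolkit:

* Genomic coordinates are 0-based half-open internally; GFF3 input is 1-based
  inclusive and converted on load.  :class:`GeneAnnotation` keeps the 1-based
  coordinates as parsed so they can be compared directly with the GFF3 source.
* Gene-relative positions put 0 at the first base of the annotated start
  codon; upstream positions are negative (-1 is the base immediately 5' of the
  ATG).  For minus-strand genes all views are reverse-complemented so that
  "upstream" is always 5' of the CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DesignError, ParseError

_VALID_GENOME_CHARS = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeRef:
    """A reference genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ParseError("genome contains no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ParseError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_GENOME_CHARS
            if bad:
                raise ParseError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]


@dataclass
class GeneAnnotation:
    """A gene's CDS placement.

    ``cds_start`` is the 1-based genomic position of the first base of the
    start codon (the A of ATG); on the minus strand this is the larger
    coordinate.  ``cds_end`` is the 1-based inclusive position of the last
    CDS base.
    """

    gene_id: str
    contig: str
    strand: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.cds_start > self.cds_end:
            raise ParseError(f"gene {self.gene_id}: cds_start > cds_end on + strand")
        if self.strand == "-" and self.cds_start < self.cds_end:
            raise ParseError(f"gene {self.gene_id}: cds_start < cds_end on - strand")


@dataclass
class OrientedLocus:
    """A gene-centric window in gene orientation.

    ``window_seq`` covers gene-relative positions ``[-u, d)``; index ``i`` in
    the string corresponds to gene-relative position ``i - u``, so index ``u``
    is the A of the start codon.
    """

    gene_id: str
    window_seq: str
    u: int
    d: int

    def __post_init__(self) -> None:
        if len(self.window_seq) != self.u + self.d:
            raise DesignError(
                f"locus {self.gene_id}: window length {len(self.window_seq)} "
                f"!= u + d = {self.u + self.d}"
            )

    def slice(self, start: int, end: int) -> str:
        """Sequence for gene-relative half-open interval [start, end)."""
        if start < -self.u or end > self.d:
            raise DesignError(
                f"locus {self.gene_id}: requested [{start}, {end}) outside "
                f"window [-{self.u}, {self.d})"
            )
        return self.window_seq[start + self.u : end + self.u]

    @property
    def start_codon(self) -> str:
        return self.slice(0, 3)


def load_genome(path) -> GenomeRef:
    """Load a (multi-)FASTA file into a :class:`GenomeRef`.

    Sequences are uppercased; duplicate headers are rejected.
    """
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise ParseError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise ParseError(
                f"{path}: malformed FASTA, line {first[0]} does not start a record"
            )
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    return GenomeRef(contigs)


def load_annotation(path, genome: GenomeRef) -> list[GeneAnnotation]:
    """Parse gene/CDS features from a GFF3 file.

    One :class:`GeneAnnotation` is produced per ``gene`` feature, using the
    union of its CDS children.  The ``ID`` attribute is the gene_id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    annotations = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        if gene.seqid not in genome.contigs:
            raise ParseError(
                f"gene {gene_id}: seqid {gene.seqid!r} absent from genome"
            )
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            raise ParseError(f"gene {gene_id}: no CDS feature")
        lo = min(c.start for c in cds)
        hi = max(c.end for c in cds)
        contig_len = len(genome[gene.seqid])
        if lo < 1 or hi > contig_len:
            raise ParseError(
                f"gene {gene_id}: CDS [{lo}, {hi}] outside contig bounds "
                f"(length {contig_len})"
            )
        if gene.strand == "+":
            ann = GeneAnnotation(gene_id, gene.seqid, "+", lo, hi)
        elif gene.strand == "-":
            ann = GeneAnnotation(gene_id, gene.seqid, "-", hi, lo)
        else:
            raise ParseError(f"gene {gene_id}: missing strand")
        annotations.append(ann)
    return annotations


def orient_locus(genome: GenomeRef, ann: GeneAnnotation, u: int, d: int) -> OrientedLocus:
    """Cut a gene-oriented window covering gene-relative [-u, d).

    For minus-strand genes the genomic slice is reverse-complemented so that
    position 0 is the A of the start codon and upstream positions are 5' of
    the CDS.  A window containing N fails: synthetic designs must be fully
    specified.
    """
    contig = genome[ann.contig]
    if ann.strand == "+":
        s = ann.cds_start - 1  # 0-based index of the A
        g_start, g_end = s - u, s + d
        if g_start < 0 or g_end > len(contig):
            raise DesignError(
                f"gene {ann.gene_id}: window [-{u}, {d}) exceeds contig bounds"
            )
        window = contig[g_start:g_end]
    else:
        e = ann.cds_start - 1  # 0-based index of the A (larger coordinate)
        g_start, g_end = e - d + 1, e + u + 1
        if g_start < 0 or g_end > len(contig):
            raise DesignError(
                f"gene {ann.gene_id}: window [-{u}, {d}) exceeds contig bounds"
            )
        window = revcomp(contig[g_start:g_end])
    if "N" in window:
        raise DesignError(
            f"gene {ann.gene_id}: window contains ambiguous base N; "
            "designs require fully specified sequence"
        )
    locus = OrientedLocus(ann.gene_id, window, u, d)
    if locus.start_codon != "ATG":
        warnings.warn(
            f"gene {ann.gene_id}: annotated start codon is "
            f"{locus.start_codon!r}, not ATG"
        )
    return locus
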