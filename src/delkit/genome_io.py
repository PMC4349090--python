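"""Genome/annotation input and strand-aware gene-relative coordinate arithmetic.

All user-facing coordinates are 1-based inclusive (GFF3 convention); internal
string indexing is 0-based half-open. Gene-relative offsets follow the
transcription orientation of the gene: negative offsets count upstream of the
ATG (-1 is the base immediately 5' of the ATG), positive offsets count
downstream of the stop codon (+1 is the base immediately 3' of the gene span).
For a minus-strand gene the upstream window therefore lies at *higher*
genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Raised on malformed genome/annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic span — the unit targeted for deletion.

    The span runs ATG through stop codon inclusive (the whole annotated
    genomic block, introns included): the deletion replaces it as one piece.
    """

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise GenomeIOError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.length < 6:
            raise GenomeIOError(f"{self.gene_id}: gene span {self.length} nt < 6 nt")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """In-memory genome: chromosome name -> upper-case nucleotide string."""

    sequences: dict[str, str]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeIOError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeIOError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length_of(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def validate_gene(self, gene: GeneModel) -> None:
        if gene.chromosome not in self.sequences:
            raise GenomeIOError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome")
        if gene.end > self.length_of(gene.chromosome):
            raise GenomeIOError(
                f"{gene.gene_id}: end {gene.end} beyond chromosome "
                f"{gene.chromosome!r} length {self.length_of(gene.chromosome)}"
            )


def load_genome(path: str | Path) -> Genome:
    """Read a FASTA genome; sequences are upper-cased, record ids must be unique."""
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"genome file not found: {path}")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise GenomeIOError(f"duplicate FASTA record id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise GenomeIOError(f"record {record.id!r} in {path} has empty sequence")
        sequences[record.id] = seq
    if not sequences:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return Genome(sequences=sequences, source=str(path))


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a genome to FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_annotation(path: str | Path, genome: Genome) -> list[GeneModel]:
    """Read gene models from GFF3 and validate them against the genome.

    One GeneModel per gene id; the span is min..max over the gene's own
    feature and any CDS features attached to it.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"annotation file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    gene_features = list(db.features_of_type("gene"))
    if not gene_features:
        # fall back to CDS features grouped by their ID/Parent
        gene_features = list(db.features_of_type("CDS"))
    for feat in gene_features:
        start, end = feat.start, feat.end
        for child in db.children(feat, featuretype="CDS"):
            start = min(start, child.start)
            end = max(end, child.end)
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name_attr = feat.attributes.get("Name", [None])[0]
        gene = GeneModel(
            gene_id=gene_id, chromosome=feat.seqid, start=start, end=end,
            strand=feat.strand, name=name_attr,
        )
        genome.validate_gene(gene)
        genes.append(gene)
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.chromosome}\tdelkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def gene_relative_window(
    gene: GeneModel, rel_start: int, rel_end: int, genome: Genome | None = None
) -> tuple[int, int]:
    """Map a gene-relative offset window to a 1-based inclusive genomic interval.

    Offsets are in transcription orientation: negative upstream of the ATG,
    positive downstream of the stop codon.  Offset 0 is not a position.
    A window must lie on one side (all-negative or all-positive offsets) or
    inside the gene is not expressible here; in-gene windows use
    `orf_window` instead.
    """
    if rel_start > rel_end:
        raise GenomeIOError(f"window start {rel_start} > end {rel_end}")
    if rel_start == 0 or rel_end == 0 or (rel_start < 0) != (rel_end < 0):
        raise GenomeIOError(
            f"window ({rel_start},{rel_end}) must be all-upstream (<0) or all-downstream (>0)"
        )
    if gene.strand == "+":
        if rel_end < 0:  # upstream of ATG
            g_start = gene.start + rel_start
            g_end = gene.start + rel_end
        else:  # downstream of stop
            g_start = gene.end + rel_start
            g_end = gene.end + rel_end
    else:
        if rel_end < 0:  # upstream = higher genomic coordinates
            g_start = gene.end - rel_end
            g_end = gene.end - rel_start
        else:
            g_start = gene.start - rel_end
            g_end = gene.start - rel_start
    if g_start < 1:
        raise GenomeIOError(
            f"{gene.gene_id}: window ({rel_start},{rel_end}) runs off chromosome start"
        )
    if genome is not None and g_end > genome.length_of(gene.chromosome):
        raise GenomeIOError(
            f"{gene.gene_id}: window ({rel_start},{rel_end}) runs off chromosome end"
        )
    return g_start, g_end


def orf_window(gene: GeneModel, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic interval for a window *inside* the gene, 1-based from the ATG.

    rel_start=1 is the A of the ATG in transcription orientation.
    """
    if not (1 <= rel_start <= rel_end <= gene.length):
        raise GenomeIOError(
            f"{gene.gene_id}: in-gene window ({rel_start},{rel_end}) outside span of "
            f"length {gene.length}"
        )
    if gene.strand == "+":
        return gene.start + rel_start - 1, gene.start + rel_end - 1
    return gene.end - rel_end + 1, gene.end - rel_start + 1


def extract(genome: Genome, chromosome: str, start: int, end: int, strand: str = "+") -> str:
    """Extract genome[chromosome][start..end] (1-based inclusive).

    strand='-' returns the reverse complement, i.e. the sequence in the
    transcription orientation of a minus-strand gene.
    """
    if chromosome not in genome.sequences:
        raise GenomeIOError(f"chromosome {chromosome!r} not in genome")
    seq = genome.sequences[chromosome]
    if start < 1 or end > len(seq) or start > end:
        raise GenomeIOError(
            f"interval {start}..{end} out of bounds for {chromosome!r} (1..{len(seq)})"
        )
    sub = seq[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


def extract_gene_window(
    genome: Genome, gene: GeneModel, rel_start: int, rel_end: int
) -> str:
    """Gene-relative window sequence, in the gene's transcription orientation."""
    g_start, g_end = gene_relative_window(gene, rel_start, rel_end, genome)
    return extract(genome, gene.chromosome, g_start, g_end, gene.strand)
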