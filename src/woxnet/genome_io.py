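"""Genome and annotation input: validated gene models and strand-aware regions.

Internal coordinates are 0-based, half-open throughout; GFF3 files are read and
written as 1-based, inclusive per the GFF3 standard.  A :class:`GeneModel` stores
the genomic span canonically (``span_start < span_end``) and derives TSS/TTS from
the strand, so interval arithmetic never branches on orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

IUPAC_CORE = set("ACGTN")

Interval = tuple[int, int]  # 0-based half-open


class GenomeIOError(ValueError):
    """Raised on malformed FASTA/GFF3 input or inconsistent gene models."""


@dataclass
class GenomeSequences:
    """Uppercased contig sequences over the alphabet {A, C, G, T, N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - IUPAC_CORE
            if bad:
                raise GenomeIOError(
                    f"contig {cid!r} contains characters outside ACGTN: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}


@dataclass
class GeneModel:
    """One gene's strand-aware structure used for promoter extraction and
    motif-site classification.

    ``exons`` are sorted, non-overlapping genomic intervals covering the span
    edges; ``utr5``/``utr3``/``cds`` are contained in the exon union.  Introns
    are exactly the gaps between consecutive exons.
    """

    gene_id: str
    contig: str
    strand: str
    span_start: int
    span_end: int
    exons: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.span_start < self.span_end:
            raise GenomeIOError(f"gene {self.gene_id}: invalid span [{self.span_start}, {self.span_end})")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise GenomeIOError(f"gene {self.gene_id}: no exons")
        for (s, e) in self.exons:
            if not (self.span_start <= s < e <= self.span_end):
                raise GenomeIOError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene span "
                    f"[{self.span_start}, {self.span_end})"
                )
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise GenomeIOError(f"gene {self.gene_id}: overlapping exons at {e0}/{s1}")
        for name in ("utr5", "utr3", "cds"):
            ivs = sorted((int(s), int(e)) for s, e in getattr(self, name))
            setattr(self, name, ivs)
            for (s, e) in ivs:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise GenomeIOError(
                        f"gene {self.gene_id}: {name} interval [{s}, {e}) not contained in any exon"
                    )
        if self.exons[0][0] != self.span_start or self.exons[-1][1] != self.span_end:
            raise GenomeIOError(
                f"gene {self.gene_id}: exon union does not reach the gene span edges"
            )

    @property
    def tss(self) -> int:
        """Genomic offset of the first transcribed base (strand-aware)."""
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def tts(self) -> int:
        """Genomic offset of the last transcribed base (strand-aware)."""
        return self.span_end - 1 if self.strand == "+" else self.span_start

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]

    @property
    def length(self) -> int:
        return self.span_end - self.span_start


@dataclass
class Region:
    """A genomic interval carrying its sequence in gene orientation."""

    contig: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise GenomeIOError(f"invalid region [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise GenomeIOError("region sequence length does not match its interval")


def load_genome(fasta_path: str | Path) -> GenomeSequences:
    """Read a (multi-)FASTA file into :class:`GenomeSequences`.

    Sequences are uppercased and multi-line records concatenated.  Duplicate
    record ids, an empty file, and non-ACGTN characters are errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise GenomeIOError(f"duplicate FASTA record id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise GenomeIOError(f"no FASTA records found in {fasta_path}")
    return GenomeSequences(contigs)


def _to_half_open(start_1based: int, end_inclusive: int) -> Interval:
    return (start_1based - 1, end_inclusive)


def _select_transcript(mrnas: list[gffutils.Feature]) -> gffutils.Feature:
    # longest genomic span wins; ties broken by lexicographic transcript id
    return min(mrnas, key=lambda m: (-(m.end - m.start + 1), m.id))


def load_gene_models(gff3_path: str | Path, genome: GenomeSequences) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    For genes with several mRNA children the transcript with the longest
    genomic span is selected (ties by lexicographic transcript id).  Features
    on contigs absent from *genome*, exons outside their gene span, and
    strands other than +/- raise :class:`GenomeIOError`.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in genome.contigs:
            raise GenomeIOError(
                f"gene {gene.id}: contig {gene.seqid!r} absent from the genome"
            )
        if gene.strand not in "+-":
            raise GenomeIOError(f"gene {gene.id}: strand must be + or -, got {gene.strand!r}")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            tx = _select_transcript(mrnas)
            parent: gffutils.Feature = tx
        else:
            parent = gene
        exons = [_to_half_open(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        utr5 = [
            _to_half_open(f.start, f.end)
            for f in db.children(parent, featuretype="five_prime_UTR")
        ]
        utr3 = [
            _to_half_open(f.start, f.end)
            for f in db.children(parent, featuretype="three_prime_UTR")
        ]
        cds = [_to_half_open(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        span_start, span_end = _to_half_open(parent.start, parent.end)
        gspan_start, gspan_end = _to_half_open(gene.start, gene.end)
        if not (gspan_start <= span_start and span_end <= gspan_end):
            raise GenomeIOError(f"gene {gene.id}: transcript extends outside the gene span")
        if not exons:
            exons = [(span_start, span_end)]
        for s, e in exons:
            if not (gspan_start <= s and e <= gspan_end):
                raise GenomeIOError(
                    f"gene {gene.id}: exon [{s + 1}, {e}] (1-based) outside gene span"
                )
        clen = genome.lengths[gene.seqid]
        if span_end > clen:
            raise GenomeIOError(f"gene {gene.id}: extends past the end of contig {gene.seqid}")
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                span_start=span_start,
                span_end=span_end,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
                cds=cds,
            )
        )
    log.info("loaded %d gene models from %s", len(models), gff3_path)
    return models


def write_gene_models(models: Sequence[GeneModel], gff3_path: str | Path) -> None:
    """Serialize gene models back to GFF3 (1-based inclusive), one mRNA per gene."""
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.contig, m.span_start, m.gene_id)):
        tx_id = f"{g.gene_id}.1"

        def row(ftype: str, s: int, e: int, fid: str, parent: str | None) -> str:
            attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
            return "\t".join(
                [g.contig, "woxnet", ftype, str(s + 1), str(e), ".", g.strand, ".", attrs]
            )

        lines.append(row("gene", g.span_start, g.span_end, g.gene_id, None))
        lines.append(row("mRNA", g.span_start, g.span_end, tx_id, g.gene_id))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(row("exon", s, e, f"{tx_id}.exon{i}", tx_id))
        for i, (s, e) in enumerate(g.utr5, 1):
            lines.append(row("five_prime_UTR", s, e, f"{tx_id}.utr5.{i}", tx_id))
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(row("CDS", s, e, f"{tx_id}.cds{i}", tx_id))
        for i, (s, e) in enumerate(g.utr3, 1):
            lines.append(row("three_prime_UTR", s, e, f"{tx_id}.utr3.{i}", tx_id))
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def write_genome(genome: GenomeSequences, fasta_path: str | Path, width: int = 60) -> None:
    """Write contigs as wrapped FASTA."""
    with open(fasta_path, "w") as fh:
        for cid in genome.contigs:
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_promoter(
    gene: GeneModel, genome: GenomeSequences, promoter_len: int = 1000
) -> Region:
    """Extract the promoter (up to *promoter_len* bases immediately upstream of
    the TSS, TSS base excluded) in gene orientation.

    Truncation at contig boundaries is silent (logged at debug level).
    """
    if promoter_len <= 0:
        raise GenomeIOError(f"promoter_len must be positive, got {promoter_len}")
    clen = genome.lengths[gene.contig]
    if gene.strand == "+":
        start = max(0, gene.span_start - promoter_len)
        end = gene.span_start
        seq = genome.contigs[gene.contig][start:end]
    else:
        start = gene.span_end
        end = min(clen, gene.span_end + promoter_len)
        seq = str(Seq(genome.contigs[gene.contig][start:end]).reverse_complement())
    if end - start < promoter_len:
        log.debug(
            "promoter of %s truncated to %d bases at contig boundary",
            gene.gene_id,
            end - start,
        )
    return Region(gene.contig, start, end, gene.strand, seq)


def extract_gene_body(gene: GeneModel, genome: GenomeSequences) -> Region:
    """Extract the contiguous TSS-to-TTS genomic span (introns included), with
    the sequence reverse-complemented for minus-strand genes."""
    seq = genome.contigs[gene.contig][gene.span_start : gene.span_end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return Region(gene.contig, gene.span_start, gene.span_end, gene.strand, seq)
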