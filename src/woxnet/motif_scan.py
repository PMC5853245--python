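"""WOX-binding-motif scanning and per-site feature classification.

WUSCHEL-related homeobox factors recognize the core sequence TTAATGG/C.  This
module locates every occurrence of the motif (on either strand) within a gene's
1 kb promoter plus gene body, assigns each occurrence to one of five feature
categories — promoter, 5'UTR, exon (CDS-like), intron, 3'UTR — and summarizes
the category distribution over all sites.

Classification uses an anchor-base rule: a hit spanning a feature boundary is
classified by its 5'-most base in gene orientation, so every hit receives
exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GeneModel, GenomeSequences

CATEGORIES = ("promoter", "utr5", "exon", "intron", "utr3")

DEFAULT_PATTERNS = ("TTAATGG", "TTAATGC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise MotifError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """The motif literals to search for, optionally on both strands."""

    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.patterns:
            raise MotifError("MotifSpec requires at least one pattern")
        for p in self.patterns:
            if set(p) - set("ACGT"):
                raise MotifError(f"pattern {p!r} contains non-ACGT characters")
            if len(p) < 4:
                raise MotifError(f"pattern {p!r} shorter than 4 bases")

    @property
    def literals(self) -> list[tuple[str, str]]:
        """(literal, orientation) pairs actually matched against forward sequence."""
        out = [(p, "forward") for p in self.patterns]
        if self.search_both_strands:
            out += [(reverse_complement(p), "reverse") for p in self.patterns]
        return out


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, located genomically and classified gene-relatively."""

    gene_id: str
    contig: str
    genomic_start: int  # leftmost genomic base of the match
    orientation: str  # forward/reverse relative to the forward genomic strand
    matched_pattern: str  # the spec pattern (not its reverse complement)
    category: str
    offset_from_tss: int  # gene orientation; negative = upstream of the TSS


@dataclass
class CategoryDistribution:
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def find_motif_sites(seq: str, spec: MotifSpec) -> list[tuple[int, str, str]]:
    """All (offset, orientation, matched_pattern) motif occurrences in *seq*.

    *seq* is given in forward genomic orientation; reverse-orientation matches
    are windows equal to the reverse complement of a pattern.  Overlapping
    occurrences are all reported; the result is sorted by offset.
    """
    hits: list[tuple[int, str, str]] = []
    for pattern in spec.patterns:
        for literal, orientation in (
            [(pattern, "forward")]
            + ([(reverse_complement(pattern), "reverse")] if spec.search_both_strands else [])
        ):
            i = seq.find(literal)
            while i != -1:
                hits.append((i, orientation, pattern))
                i = seq.find(literal, i + 1)
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def _promoter_interval(
    gene: GeneModel, promoter_len: int, contig_length: int | None = None
) -> tuple[int, int]:
    if gene.strand == "+":
        return (max(0, gene.span_start - promoter_len), gene.span_start)
    end = gene.span_end + promoter_len
    if contig_length is not None:
        end = min(contig_length, end)
    return (gene.span_end, end)


def classify_position(
    genomic_pos: int,
    gene: GeneModel,
    promoter_len: int = 1000,
    contig_length: int | None = None,
) -> str:
    """Feature category of the base at *genomic_pos* for *gene*.

    Exactly one of promoter/utr5/exon/intron/utr3.  Exonic bases not covered
    by a UTR annotation are "exon" (CDS-like), so the five categories
    partition the promoter plus gene body.
    """
    ps, pe = _promoter_interval(gene, promoter_len, contig_length)
    if ps <= genomic_pos < pe:
        return "promoter"
    if not (gene.span_start <= genomic_pos < gene.span_end):
        raise MotifError(
            f"position {genomic_pos} outside promoter and gene body of {gene.gene_id}"
        )
    if not any(s <= genomic_pos < e for s, e in gene.exons):
        return "intron"
    if any(s <= genomic_pos < e for s, e in gene.utr5):
        return "utr5"
    if any(s <= genomic_pos < e for s, e in gene.utr3):
        return "utr3"
    return "exon"


def _offset_from_tss(anchor: int, gene: GeneModel) -> int:
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def scan_gene(
    gene: GeneModel,
    genome: GenomeSequences,
    spec: MotifSpec | None = None,
    promoter_len: int = 1000,
) -> list[MotifHit]:
    """Scan the contiguous promoter-plus-gene-body window of *gene* for motif
    occurrences and classify each by its anchor base (5'-most in gene
    orientation).  Hits are returned ordered by gene-orientation offset."""
    spec = spec or MotifSpec()
    clen = genome.lengths[gene.contig]
    if gene.strand == "+":
        win_start = max(0, gene.span_start - promoter_len)
        win_end = gene.span_end
    else:
        win_start = gene.span_start
        win_end = min(clen, gene.span_end + promoter_len)
    window = genome.contigs[gene.contig][win_start:win_end]
    hits: list[MotifHit] = []
    for off, orientation, pattern in find_motif_sites(window, spec):
        gstart = win_start + off
        anchor = gstart if gene.strand == "+" else gstart + len(pattern) - 1
        category = classify_position(anchor, gene, promoter_len, contig_length=clen)
        hits.append(
            MotifHit(
                gene_id=gene.gene_id,
                contig=gene.contig,
                genomic_start=gstart,
                orientation=orientation,
                matched_pattern=pattern,
                category=category,
                offset_from_tss=_offset_from_tss(anchor, gene),
            )
        )
    hits.sort(key=lambda h: (h.offset_from_tss, h.orientation, h.matched_pattern))
    return hits


def scan_genes(
    genes: Sequence[GeneModel],
    genome: GenomeSequences,
    spec: MotifSpec | None = None,
    promoter_len: int = 1000,
) -> list[MotifHit]:
    """Scan every gene independently; overlapping loci each report their own hits."""
    out: list[MotifHit] = []
    for g in genes:
        out.extend(scan_gene(g, genome, spec, promoter_len))
    return out


def flag_motif_genes(hits: Iterable[MotifHit]) -> set[str]:
    """Gene ids with at least one motif occurrence."""
    return {h.gene_id for h in hits}


def summarize_distribution(hits: Sequence[MotifHit]) -> CategoryDistribution:
    """Counts and percentages of hits per feature category, over all five
    categories including zero-count ones.

    Percentages are stored exact (they sum to 100 up to float error); reports
    round them to one decimal place at output time.
    """
    if not hits:
        raise MotifError("cannot summarize an empty hit list")
    counts = {c: 0 for c in CATEGORIES}
    for h in hits:
        counts[h.category] += 1
    total = len(hits)
    percentages = {c: 100.0 * counts[c] / total for c in CATEGORIES}
    return CategoryDistribution(counts=counts, percentages=percentages)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "contig": h.contig,
                "genomic_start": h.genomic_start,
                "orientation": h.orientation,
                "matched_pattern": h.matched_pattern,
                "category": h.category,
                "offset_from_tss": h.offset_from_tss,
            }
            for h in hits
        ],
        columns=[
            "gene_id",
            "contig",
            "genomic_start",
            "orientation",
            "matched_pattern",
            "category",
            "offset_from_tss",
        ],
    )


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """BED6 export: 0-based half-open, name = gene_id|category, strand = match orientation."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.contig, h.genomic_start, h.gene_id)):
            strand = "+" if h.orientation == "forward" else "-"
            fh.write(
                f"{h.contig}\t{h.genomic_start}\t{h.genomic_start + len(h.matched_pattern)}\t"
                f"{h.gene_id}|{h.category}\t0\t{strand}\n"
            )


def write_gene_hit_counts(hits: Sequence[MotifHit], path: str | Path) -> None:
    """TSV of per-gene hit counts."""
    df = hits_to_frame(hits)
    if df.empty:
        counts = pd.DataFrame(columns=["gene_id", "n_hits"])
    else:
        counts = (
            df.groupby("gene_id").size().rename("n_hits").reset_index().sort_values("gene_id")
        )
    counts.to_csv(path, sep="\t", index=False)
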