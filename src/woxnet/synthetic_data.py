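"""Synthetic genome, count, and catalogue generator with a known truth table.

Every input the pipeline consumes can be generated here with planted signal:
a multi-gene genome (UTR/exon/intron structure on both strands) carrying
motif sites at known feature categories, negative-binomial counts with
planted fold changes, a multi-tissue expression matrix with planted
root-specific genes, and a treated/mock time course with planted inducible
genes.  All spontaneous occurrences of the motif literals are destroyed
before planting, so the truth table is exhaustive: a scan of the generated
genome recovers exactly the planted sites.

All generators are pure functions of (config, seed); the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeSequences, write_gene_models, write_genome
from .motif_scan import (
    DEFAULT_PATTERNS,
    MotifSpec,
    find_motif_sites,
    reverse_complement,
    _promoter_interval,
)
from .catalogues import TimeCourse, write_time_course
from .diff_expr import CountMatrix

_BASES = np.array(list("ACGT"))

# site quotas default to the observed category mix: introns and promoters
# dominate, 5'UTR sites are rare
DEFAULT_CATEGORY_FRACTIONS = {
    "intron": 0.45,
    "promoter": 0.286,
    "exon": 0.16,
    "utr3": 0.078,
    "utr5": 0.026,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_genes: int = 60
    n_contigs: int = 2
    gene_length_range: tuple[int, int] = (1200, 2600)
    exon_count_range: tuple[int, int] = (1, 4)
    min_exon_len: int = 200
    min_intron_len: int = 150
    utr5_len: int = 90
    utr3_len: int = 150
    promoter_len: int = 1000
    intergenic_spacing: int = 2200
    contig_length: int | None = None  # fixed length; error if genes do not fit
    n_sites: int = 150
    site_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    n_replicates: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.10
    true_fold: float = 4.0
    n_tissues: int = 6
    root_specific_frac: float = 0.45
    root_min_expr: float = 10.0
    root_ratio: float = 2.0
    inducible_frac: float = 0.10
    time_points: tuple[float, ...] = (0, 0.5, 1, 2, 3, 5, 7, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_contigs <= 0:
            raise SimulationError("n_genes and n_contigs must be positive")
        for frac in (self.frac_up, self.frac_down, self.root_specific_frac, self.inducible_frac):
            if not 0 <= frac <= 1:
                raise SimulationError(f"fractions must lie in [0, 1], got {frac}")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be non-negative")
        if self.intergenic_spacing < 2 * self.promoter_len + 20:
            raise SimulationError(
                "intergenic_spacing must exceed twice the promoter length so that "
                "promoter windows of neighbouring genes never overlap"
            )

    def quota(self) -> dict[str, int]:
        """Integer per-category quotas by largest-remainder apportionment."""
        raw = {c: self.n_sites * f for c, f in self.site_fractions.items()}
        quota = {c: int(np.floor(v)) for c, v in raw.items()}
        short = self.n_sites - sum(quota.values())
        by_remainder = sorted(raw, key=lambda c: (quota[c] - raw[c], c))
        for c in by_remainder[:short]:
            quota[c] += 1
        return quota


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    category: str
    offset_from_tss: int  # gene orientation, negative = upstream
    orientation: str  # forward/reverse relative to the forward genomic strand
    pattern: str
    contig: str
    genomic_start: int


@dataclass
class TruthTable:
    """What the generator planted, for exact recovery checks downstream."""

    gene_ids: list[str]
    planted_sites: list[PlantedSite]
    planted_de: dict[str, tuple[str, float]]  # gene -> (direction, true fold)
    planted_root_specific: set[str]
    planted_ck_inducible: set[str]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "planted_de": {g: [d, f] for g, (d, f) in sorted(self.planted_de.items())},
            "planted_root_specific": sorted(self.planted_root_specific),
            "planted_ck_inducible": sorted(self.planted_ck_inducible),
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthTable":
        return cls(
            gene_ids=list(d["gene_ids"]),
            planted_sites=[PlantedSite(**s) for s in d["planted_sites"]],
            planted_de={g: (v[0], float(v[1])) for g, v in d["planted_de"].items()},
            planted_root_specific=set(d["planted_root_specific"]),
            planted_ck_inducible=set(d["planted_ck_inducible"]),
            seed=int(d["seed"]),
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------- gene layout


def _build_gene_structure(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str, contig: str, start: int, strand: str
) -> GeneModel:
    lo, hi = cfg.gene_length_range
    length = int(rng.integers(lo, hi + 1))
    klo, khi = cfg.exon_count_range
    k = int(rng.integers(klo, khi + 1))
    while k > 1 and k * cfg.min_exon_len + (k - 1) * cfg.min_intron_len > length:
        k -= 1
    n_parts = 2 * k - 1
    base = k * cfg.min_exon_len + (k - 1) * cfg.min_intron_len
    extra = length - base
    extra_alloc = rng.multinomial(extra, np.full(n_parts, 1.0 / n_parts)) if extra > 0 else np.zeros(n_parts, int)
    part_lens = []
    for i in range(n_parts):
        minimum = cfg.min_exon_len if i % 2 == 0 else cfg.min_intron_len
        part_lens.append(minimum + int(extra_alloc[i]))

    exons: list[tuple[int, int]] = []
    pos = start
    for i, plen in enumerate(part_lens):
        if i % 2 == 0:
            exons.append((pos, pos + plen))
        pos += plen
    span_end = pos

    if strand == "+":
        utr5 = [(start, start + cfg.utr5_len)]
        utr3 = [(span_end - cfg.utr3_len, span_end)]
    else:
        utr5 = [(span_end - cfg.utr5_len, span_end)]
        utr3 = [(start, start + cfg.utr3_len)]

    def subtract(iv: tuple[int, int], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
        pieces = [iv]
        for cs, ce in cuts:
            nxt = []
            for s, e in pieces:
                if ce <= s or cs >= e:
                    nxt.append((s, e))
                    continue
                if s < cs:
                    nxt.append((s, cs))
                if ce < e:
                    nxt.append((ce, e))
            pieces = nxt
        return pieces

    cds = []
    for ex in exons:
        cds.extend(subtract(ex, utr5 + utr3))

    return GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        span_start=start,
        span_end=span_end,
        exons=exons,
        utr5=utr5,
        utr3=utr3,
        cds=cds,
    )


def _layout_genes(rng: np.random.Generator, cfg: SimConfig) -> tuple[list[GeneModel], dict[str, int]]:
    contig_ids = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    cursors = {c: cfg.promoter_len + 50 for c in contig_ids}
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        contig = contig_ids[i % cfg.n_contigs]
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene_structure(
            rng, cfg, f"gene{i + 1:04d}", contig, cursors[contig], strand
        )
        genes.append(gene)
        cursors[contig] = gene.span_end + cfg.intergenic_spacing
    lengths = {
        c: cursors[c] - cfg.intergenic_spacing + cfg.promoter_len + 50 for c in contig_ids
    }
    if cfg.contig_length is not None:
        for c, need in lengths.items():
            if need > cfg.contig_length:
                raise SimulationError(
                    f"genes do not fit on contig {c}: need {need} bases at the requested "
                    f"spacing but contig_length is {cfg.contig_length}"
                )
        lengths = {c: cfg.contig_length for c in contig_ids}
    return genes, lengths


# -------------------------------------------------------- sequence generation


def _sanitize(
    seq: np.ndarray, rng: np.random.Generator, protected: set[int], patterns: tuple[str, ...]
) -> None:
    """Destroy every motif occurrence whose window is not fully planted, by
    redrawing one unprotected base inside it, until the scan is clean."""
    spec = MotifSpec(patterns)
    for _ in range(100):
        text = "".join(seq)
        dirty = False
        for off, _orient, pat in find_motif_sites(text, spec):
            window = [i for i in range(off, off + len(pat)) if i not in protected]
            if not window:  # the planted site itself
                continue
            i = int(rng.choice(window))
            current = seq[i]
            choices = [b for b in "ACGT" if b != current]
            seq[i] = choices[int(rng.integers(len(choices)))]
            dirty = True
        if not dirty:
            return
    raise SimulationError("sequence sanitization did not converge")


def plant_motif_sites(
    contigs: dict[str, np.ndarray],
    genes: list[GeneModel],
    quota: dict[str, int],
    rng: np.random.Generator,
    promoter_len: int = 1000,
    patterns: tuple[str, ...] = DEFAULT_PATTERNS,
) -> list[PlantedSite]:
    """Write motif 7-mers at uniformly chosen in-category positions, each at
    least 7 bases from any feature boundary, non-overlapping, with uniform
    orientation.  Raises :class:`SimulationError` naming the category when a
    quota is infeasible."""
    lengths = {c: len(a) for c, a in contigs.items()}
    pat_len = len(patterns[0])
    margin = pat_len  # distance kept from every feature boundary

    intervals: dict[str, list[tuple[GeneModel, int, int]]] = {c: [] for c in quota}
    for gene in genes:
        cat_ivs = {
            "promoter": [_promoter_interval(gene, promoter_len, lengths[gene.contig])],
            "intron": gene.introns,
            "utr5": gene.utr5,
            "utr3": gene.utr3,
            "exon": gene.cds,
        }
        for cat, ivs in cat_ivs.items():
            if cat not in intervals:
                continue
            for s, e in ivs:
                if e - s >= 2 * margin + pat_len:
                    intervals[cat].append((gene, s, e))

    occupied: dict[str, set[int]] = {c: set() for c in contigs}
    planted: list[PlantedSite] = []
    for cat in sorted(quota):
        need = quota[cat]
        if need == 0:
            continue
        cands = intervals.get(cat, [])
        if not cands:
            raise SimulationError(f"no candidate positions for category {cat!r}")
        weights = np.array([(e - margin - pat_len) - (s + margin) + 1 for _, s, e in cands], float)
        weights /= weights.sum()
        for _ in range(need):
            for _attempt in range(500):
                gene, s, e = cands[int(rng.choice(len(cands), p=weights))]
                gstart = int(rng.integers(s + margin, e - margin - pat_len + 1))
                span = set(range(gstart, gstart + pat_len))
                if span & occupied[gene.contig]:
                    continue
                orientation = "forward" if rng.random() < 0.5 else "reverse"
                pattern = patterns[int(rng.integers(len(patterns)))]
                literal = pattern if orientation == "forward" else reverse_complement(pattern)
                contigs[gene.contig][gstart : gstart + pat_len] = list(literal)
                occupied[gene.contig] |= span
                anchor = gstart if gene.strand == "+" else gstart + pat_len - 1
                offset = anchor - gene.tss if gene.strand == "+" else gene.tss - anchor
                planted.append(
                    PlantedSite(
                        gene_id=gene.gene_id,
                        category=cat,
                        offset_from_tss=offset,
                        orientation=orientation,
                        pattern=pattern,
                        contig=gene.contig,
                        genomic_start=gstart,
                    )
                )
                break
            else:
                raise SimulationError(f"quota infeasible for category {cat!r}")
    return planted


def build_synthetic_genome(cfg: SimConfig) -> tuple[GenomeSequences, list[GeneModel], TruthTable]:
    """Generate the genome, gene models, and truth table.

    The background is sanitized (all spontaneous motif matches destroyed)
    before planting, so scanning the output recovers exactly the planted
    sites.  DE, root-specificity, and inducibility memberships are also drawn
    here so one truth table covers the whole pipeline.
    """
    rng = _rng(cfg, 0)
    genes, lengths = _layout_genes(rng, cfg)
    contigs = {
        c: _BASES[rng.integers(0, 4, size=n)].copy() for c, n in lengths.items()
    }
    for c in contigs:
        _sanitize(contigs[c], rng, set(), DEFAULT_PATTERNS)
    planted = plant_motif_sites(
        contigs, genes, cfg.quota(), rng, promoter_len=cfg.promoter_len
    )
    protected = {c: set() for c in contigs}
    for s in planted:
        protected[s.contig] |= set(range(s.genomic_start, s.genomic_start + len(s.pattern)))
    for c in contigs:
        _sanitize(contigs[c], rng, protected[c], DEFAULT_PATTERNS)

    gene_ids = [g.gene_id for g in genes]
    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    de_genes = rng.choice(gene_ids, size=n_up + n_down, replace=False)
    planted_de = {g: ("up", cfg.true_fold) for g in de_genes[:n_up]}
    planted_de.update({g: ("down", cfg.true_fold) for g in de_genes[n_up:]})
    root = set(rng.choice(gene_ids, size=int(round(cfg.root_specific_frac * cfg.n_genes)), replace=False))
    ck = set(rng.choice(gene_ids, size=int(round(cfg.inducible_frac * cfg.n_genes)), replace=False))

    genome = GenomeSequences({c: "".join(contigs[c]) for c in sorted(contigs)})
    truth = TruthTable(
        gene_ids=gene_ids,
        planted_sites=planted,
        planted_de=planted_de,
        planted_root_specific=root,
        planted_ck_inducible=ck,
        seed=cfg.seed,
    )
    return genome, genes, truth


# ----------------------------------------------------------------- count data


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2; dispersion 0
    degenerates to exact (rounded) means for deterministic tests."""
    if dispersion == 0:
        return np.round(mean).astype(int)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(truth: TruthTable, cfg: SimConfig) -> CountMatrix:
    """Replicate counts for wild type and mutant, with planted fold changes
    applied to the mutant means."""
    rng = _rng(cfg, 1)
    genes = truth.gene_ids
    mu_wt = np.full(len(genes), cfg.baseline_mean)
    mu_mut = mu_wt.copy()
    for i, g in enumerate(genes):
        if g in truth.planted_de:
            direction, fold = truth.planted_de[g]
            mu_mut[i] = mu_wt[i] * fold if direction == "up" else mu_wt[i] / fold
    data = {}
    for r in range(cfg.n_replicates):
        data[f"wt_{r + 1}"] = _nb_draw(rng, mu_wt, cfg.nb_dispersion)
    for r in range(cfg.n_replicates):
        data[f"mut_{r + 1}"] = _nb_draw(rng, mu_mut, cfg.nb_dispersion)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    conditions = pd.Series(
        {s: ("wild_type" if s.startswith("wt") else "mutant") for s in counts.columns}
    )
    return CountMatrix(counts, conditions)


# ------------------------------------------------------------------ catalogues


_TISSUE_POOL = ["leaf", "shoot", "panicle", "flower", "seed", "callus", "stem"]


def simulate_tissue_matrix(truth: TruthTable, cfg: SimConfig) -> pd.DataFrame:
    """Multi-tissue expression matrix in which planted root-specific genes
    satisfy the classification rule with margin >= 1.5x the ratio threshold
    and all other genes fail it."""
    rng = _rng(cfg, 2)
    tissues = ["root"] + _TISSUE_POOL[: cfg.n_tissues - 1]
    rows = []
    for g in truth.gene_ids:
        if g in truth.planted_root_specific:
            root = rng.uniform(max(60.0, 1.5 * cfg.root_min_expr), 200.0)
            others = rng.uniform(0, root / (1.5 * cfg.root_ratio), size=len(tissues) - 1)
        else:
            root = rng.uniform(1.0, 80.0)
            others = rng.uniform(0, root, size=len(tissues) - 1)
            # force failure of the dominance rule in one random tissue
            j = int(rng.integers(len(others)))
            others[j] = root * rng.uniform(0.8, 1.5) + 1.0
        rows.append([root] + list(others))
    return pd.DataFrame(rows, index=pd.Index(truth.gene_ids, name="gene_id"), columns=tissues)


def _time_labels(cfg: SimConfig) -> list[str]:
    return [f"{t:g}" for t in cfg.time_points]


def simulate_time_course(truth: TruthTable, cfg: SimConfig) -> TimeCourse:
    """Treated/mock time course in which planted inducible genes reach a
    maximum fold change in [2.5, 8] and all others stay within [0.5, 1.5]."""
    rng = _rng(cfg, 3)
    labels = _time_labels(cfg)
    post = labels[1:]
    mock = pd.DataFrame(
        rng.uniform(5.0, 50.0, size=(len(truth.gene_ids), len(labels))),
        index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=labels,
    )
    treated = mock.copy()
    for g in truth.gene_ids:
        r0 = rng.uniform(0.8, 1.2)
        treated.at[g, labels[0]] = mock.at[g, labels[0]] * r0
        if g in truth.planted_ck_inducible:
            fc = rng.uniform(0.6, 2.0, size=len(post))
            fc[int(rng.integers(len(post)))] = rng.uniform(2.5, 8.0)
        else:
            fc = rng.uniform(0.5, 1.5, size=len(post))
        for t, f in zip(post, fc):
            treated.at[g, t] = mock.at[g, t] * r0 * f
    return TimeCourse(treated=treated, mock=mock, t0=labels[0])


# --------------------------------------------------------------------- output


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": cm.conditions.index, "condition": cm.conditions.values}
    ).to_csv(path, sep="\t", index=False)


def generate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input plus the truth table.

    Returns the paths of: genome.fasta, genes.gff3, counts.tsv, samples.tsv,
    tissues.tsv, timecourse.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = build_synthetic_genome(cfg)
    cm = simulate_counts(truth, cfg)
    tissues = simulate_tissue_matrix(truth, cfg)
    tc = simulate_time_course(truth, cfg)

    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "tissues": outdir / "tissues.tsv",
        "timecourse": outdir / "timecourse.tsv",
        "truth": outdir / "truth.json",
    }
    write_genome(genome, paths["fasta"])
    write_gene_models(genes, paths["gff3"])
    cm.counts.to_csv(paths["counts"], sep="\t")
    write_sample_sheet(cm, paths["samples"])
    tissues.to_csv(paths["tissues"], sep="\t", float_format="%.6g")
    write_time_course(tc, paths["timecourse"])
    paths["truth"].write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
    return paths
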