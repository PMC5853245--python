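"""End-to-end orchestration: scan -> differential expression -> catalogues -> report.

All stages run from one :class:`PipelineConfig`; every stage's output is
written before the next stage reads the in-memory results, and the final
report JSON echoes the configuration, the seed, and the package version so a
run is reproducible from one artifact.  Report JSON is deterministic
(sorted keys, no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .genome_io import load_gene_models, load_genome
from .motif_scan import MotifSpec, scan_genes, write_gene_hit_counts, write_hits_bed
from .diff_expr import de_summary, read_counts, run_de, write_de_table
from .catalogues import (
    PipelineReport,
    build_report,
    classify_cytokinin_inducible,
    classify_root_specific,
    read_time_course,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    fasta: Path
    gff3: Path
    counts: Path
    samples: Path
    tissues: Path
    timecourse: Path
    outdir: Path
    motif_patterns: tuple[str, ...] = ("TTAATGG", "TTAATGC")
    promoter_len: int = 1000
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    pseudocount: float = 1.0
    root_min_expr: float = 10.0
    root_ratio: float = 2.0
    root_tissue: str = "root"
    inducible_threshold: float = 2.0
    fc_mode: str = "ratio_of_ratios"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fasta", "gff3", "counts", "samples", "tissues", "timecourse", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        self.motif_patterns = tuple(self.motif_patterns)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute scan, DE calling, catalogue classification, and the intersection
    report; writes hits.bed, gene_hit_counts.tsv, de_table.tsv,
    annotation.tsv, and report.json under ``config.outdir``."""
    missing = [
        str(p)
        for p in (config.fasta, config.gff3, config.counts, config.samples,
                  config.tissues, config.timecourse)
        if not Path(p).exists()
    ]
    if missing:
        raise PipelineError(f"missing input file(s): {missing}")
    config.outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    genome = stage("load_genome", lambda: load_genome(config.fasta))
    genes = stage("load_gene_models", lambda: load_gene_models(config.gff3, genome))
    log.info("scan: %d genes on %d contigs", len(genes), len(genome.contigs))

    spec = MotifSpec(tuple(config.motif_patterns))
    hits = stage("scan", lambda: scan_genes(genes, genome, spec, config.promoter_len))
    write_hits_bed(hits, config.outdir / "hits.bed")
    write_gene_hit_counts(hits, config.outdir / "gene_hit_counts.tsv")
    log.info("scan: %d motif sites in %d genes", len(hits), len({h.gene_id for h in hits}))

    cm = stage("read_counts", lambda: read_counts(config.counts, config.samples))
    de_table = stage(
        "de",
        lambda: run_de(cm, config.fc_threshold, config.p_threshold, config.pseudocount),
    )
    write_de_table(de_table, config.outdir / "de_table.tsv")
    log.info("de: %s", de_summary(de_table))

    import pandas as pd

    tissue_matrix = stage(
        "read_tissues", lambda: pd.read_csv(config.tissues, sep="\t", index_col=0)
    )
    root_set = stage(
        "root_specific",
        lambda: classify_root_specific(
            tissue_matrix, config.root_min_expr, config.root_ratio, config.root_tissue
        ),
    )
    tc = stage("read_timecourse", lambda: read_time_course(config.timecourse))
    ck_set = stage(
        "ck_inducible",
        lambda: classify_cytokinin_inducible(tc, config.inducible_threshold, config.fc_mode),
    )
    log.info("catalogues: %d root-specific, %d cytokinin-inducible", len(root_set), len(ck_set))

    report = stage("report", lambda: build_report(de_table, hits, root_set, ck_set))
    report.annotation.to_csv(config.outdir / "annotation.tsv", sep="\t", index_label="gene_id")
    payload = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_json_dict(),
        "report": report.counts_dict(),
    }
    (config.outdir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return report
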