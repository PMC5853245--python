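"""Root-specificity and cytokinin-inducibility catalogues and the intersection report.

Two gene catalogues are intersected with the differential-expression and motif
results: (i) root-specific genes, whose root expression dominates every other
tissue under a parameterized ratio rule, and (ii) cytokinin-inducible genes,
whose treated-vs-mock fold change, normalized to pre-treatment, reaches the
threshold (inclusive) at any post-treatment time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .motif_scan import CategoryDistribution, MotifHit, summarize_distribution


class CatalogueError(ValueError):
    pass


def classify_root_specific(
    tissue_matrix: pd.DataFrame,
    min_expr: float = 10.0,
    ratio: float = 2.0,
    root_tissue: str = "root",
) -> set[str]:
    """Genes whose root expression is at least *min_expr* and at least *ratio*
    times the maximum over all non-root tissues.

    *tissue_matrix* is genes x tissues in linear units.
    """
    if ratio <= 1:
        raise CatalogueError(f"ratio must exceed 1, got {ratio}")
    if min_expr < 0:
        raise CatalogueError(f"min_expr must be non-negative, got {min_expr}")
    if root_tissue not in tissue_matrix.columns:
        raise CatalogueError(f"root tissue {root_tissue!r} absent from the matrix")
    root = tissue_matrix[root_tissue]
    others = tissue_matrix.drop(columns=[root_tissue])
    dominant = root >= ratio * others.max(axis=1)
    expressed = root >= min_expr
    return set(tissue_matrix.index[dominant & expressed])


@dataclass
class TimeCourse:
    """Treated and mock expression (linear units) per gene and time point.

    ``t0`` names the pre-treatment time point; all mock values used must be
    positive.
    """

    treated: pd.DataFrame  # genes x time labels
    mock: pd.DataFrame
    t0: str

    def __post_init__(self) -> None:
        if list(self.treated.columns) != list(self.mock.columns):
            raise CatalogueError("treated and mock tables must share time points")
        if not self.treated.index.equals(self.mock.index):
            raise CatalogueError("treated and mock tables must share genes")
        if self.t0 not in self.treated.columns:
            raise CatalogueError(f"pre-treatment point {self.t0!r} absent from the time course")

    @property
    def post_treatment(self) -> list[str]:
        return [t for t in self.treated.columns if t != self.t0]


def read_time_course(path: str | Path, t0: str | None = None) -> TimeCourse:
    """Read a TSV with first column gene_id and columns treated_<t>/mock_<t>;
    t0 defaults to the first time point in column order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    times = [c[len("treated_") :] for c in df.columns if c.startswith("treated_")]
    treated = df[[f"treated_{t}" for t in times]].set_axis(times, axis=1)
    mock = df[[f"mock_{t}" for t in times]].set_axis(times, axis=1)
    return TimeCourse(treated, mock, t0 if t0 is not None else times[0])


def write_time_course(tc: TimeCourse, path: str | Path) -> None:
    cols = {}
    for t in tc.treated.columns:
        cols[f"treated_{t}"] = tc.treated[t]
        cols[f"mock_{t}"] = tc.mock[t]
    pd.DataFrame(cols, index=tc.treated.index).to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.6g"
    )


def cytokinin_fold_change(
    tc: TimeCourse, gene: str, t: str, mode: str = "ratio_of_ratios"
) -> float:
    """Induction fold change at post-treatment time *t*.

    ``ratio_of_ratios`` (default): [treated(t)/mock(t)] / [treated(t0)/mock(t0)].
    ``treated_only``: treated(t)/treated(t0), ignoring the mock series.
    """
    if t == tc.t0:
        raise CatalogueError("fold change is defined only at post-treatment time points")
    tr_t = float(tc.treated.at[gene, t])
    tr_0 = float(tc.treated.at[gene, tc.t0])
    if mode == "ratio_of_ratios":
        mo_t = float(tc.mock.at[gene, t])
        mo_0 = float(tc.mock.at[gene, tc.t0])
        if mo_t <= 0 or mo_0 <= 0 or tr_0 <= 0:
            raise CatalogueError(f"non-positive denominator for gene {gene} at t={t}")
        return (tr_t / mo_t) / (tr_0 / mo_0)
    if mode == "treated_only":
        if tr_0 <= 0:
            raise CatalogueError(f"non-positive pre-treatment value for gene {gene}")
        return tr_t / tr_0
    raise CatalogueError(f"unknown fold-change mode {mode!r}")


def classify_cytokinin_inducible(
    tc: TimeCourse, threshold: float = 2.0, mode: str = "ratio_of_ratios"
) -> set[str]:
    """Genes whose maximum post-treatment fold change reaches *threshold*
    (inclusive >=)."""
    if threshold <= 1:
        raise CatalogueError(f"threshold must exceed 1, got {threshold}")
    out: set[str] = set()
    for gene in tc.treated.index:
        max_fc = max(
            cytokinin_fold_change(tc, gene, t, mode) for t in tc.post_treatment
        )
        if max_fc >= threshold:
            out.add(gene)
    return out


@dataclass
class PipelineReport:
    """Headline counts plus the per-gene annotation table they derive from."""

    n_de: int
    n_up: int
    n_down: int
    n_motif_de: int
    n_motif_up: int
    n_motif_down: int
    distribution: CategoryDistribution | None
    n_root_specific_down: int
    n_root_specific_up: int
    n_root_specific_down_with_motif: int
    n_ck_inducible: int
    n_ck_inducible_with_motif: int
    annotation: pd.DataFrame = field(repr=False)

    def counts_dict(self) -> dict:
        d = {
            "n_de": self.n_de,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_motif_de": self.n_motif_de,
            "n_motif_up": self.n_motif_up,
            "n_motif_down": self.n_motif_down,
            "n_root_specific_down": self.n_root_specific_down,
            "n_root_specific_up": self.n_root_specific_up,
            "n_root_specific_down_with_motif": self.n_root_specific_down_with_motif,
            "n_ck_inducible": self.n_ck_inducible,
            "n_ck_inducible_with_motif": self.n_ck_inducible_with_motif,
        }
        if self.distribution is not None:
            d["site_distribution_counts"] = dict(self.distribution.counts)
            # one decimal place, matching how such distributions are reported
            d["site_distribution_percent"] = {
                c: round(v, 1) for c, v in self.distribution.percentages.items()
            }
        return d


def build_report(
    de_table: pd.DataFrame,
    hits: Sequence[MotifHit],
    root_set: Iterable[str],
    ck_set: Iterable[str],
) -> PipelineReport:
    """Intersect catalogues with the DE and motif results by set algebra over a
    single per-gene annotation table.

    The gene universe is the DE table; every motif hit must belong to a gene
    present there.  Headline counts and the site-category distribution are
    computed over DE-called genes (up or down) only.
    """
    universe = set(de_table.index)
    hit_genes_all = {h.gene_id for h in hits}
    orphans = hit_genes_all - universe
    if orphans:
        raise CatalogueError(
            f"motif hits for genes absent from the DE table: {sorted(orphans)[:5]}"
        )
    root_set = set(root_set)
    ck_set = set(ck_set)

    de_genes = de_table[de_table["call"] != "not_de"]
    ann = pd.DataFrame(index=de_genes.index.copy())
    ann["direction"] = de_genes["call"]
    ann["motif"] = ann.index.isin(hit_genes_all)
    ann["root_specific"] = ann.index.isin(root_set)
    ann["ck_inducible"] = ann.index.isin(ck_set)
    ann = ann.sort_index()

    up = ann["direction"] == "up"
    down = ann["direction"] == "down"
    de_hits = [h for h in hits if h.gene_id in set(ann.index)]
    distribution = summarize_distribution(de_hits) if de_hits else None

    return PipelineReport(
        n_de=len(ann),
        n_up=int(up.sum()),
        n_down=int(down.sum()),
        n_motif_de=int(ann["motif"].sum()),
        n_motif_up=int((ann["motif"] & up).sum()),
        n_motif_down=int((ann["motif"] & down).sum()),
        distribution=distribution,
        n_root_specific_down=int((ann["root_specific"] & down).sum()),
        n_root_specific_up=int((ann["root_specific"] & up).sum()),
        n_root_specific_down_with_motif=int(
            (ann["root_specific"] & down & ann["motif"]).sum()
        ),
        n_ck_inducible=int(ann["ck_inducible"].sum()),
        n_ck_inducible_with_motif=int((ann["ck_inducible"] & ann["motif"]).sum()),
        annotation=ann,
    )
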