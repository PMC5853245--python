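"""Threshold differential-expression calling from a two-condition count matrix.

The decision rule is the classic one used for mutant-vs-wild-type root
transcriptomes: a gene is differentially expressed when its fold change
exceeds 2 (strictly) in either direction and its p-value is below 0.05
(strictly, uncorrected).  Upstream of that rule this module substitutes a
transparent pipeline for assembler-based quantification: counts-per-million
library-size normalization and a two-sided two-sample t-test on log2(CPM +
pseudocount).  The default test pools the variance (Student); with two or
three replicates per condition the pooled estimate is markedly more stable
than Welch's, which costs real power at these sample sizes.  Welch's test is
available via ``test_method="welch"``.

Degenerate variances (noise-free fixtures) are resolved by continuity of the
decision rule: zero variance in both groups gives p = 1 for equal means and
p = 0 for unequal means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

WILD_TYPE = "wild_type"
MUTANT = "mutant"
CONDITIONS = (WILD_TYPE, MUTANT)


class DiffExprError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Non-negative integer counts (genes x samples) with a condition label
    (wild_type/mutant) per sample."""

    counts: pd.DataFrame  # index = gene_id, columns = sample_id
    conditions: pd.Series  # index = sample_id, values in {wild_type, mutant}

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions[self.conditions.isna()].index)
            raise DiffExprError(f"samples without a condition label: {missing}")
        bad = set(self.conditions.unique()) - set(CONDITIONS)
        if bad:
            raise DiffExprError(f"unknown condition labels: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all():
            raise DiffExprError("counts must be finite")
        if (arr < 0).any():
            raise DiffExprError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise DiffExprError("counts must be integral")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions[self.conditions == condition].index)


def read_counts(counts_tsv: str | Path, samples_tsv: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene_id) and a sample sheet TSV with
    columns sample and condition."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_tsv, sep="\t")
    if not {"sample", "condition"} <= set(sheet.columns):
        raise DiffExprError("sample sheet must have columns 'sample' and 'condition'")
    conditions = sheet.set_index("sample")["condition"]
    return CountMatrix(counts, conditions)


def normalize_counts(cm: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column rescaled to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DiffExprError(f"sample(s) with zero total count: {list(zero.index)}")
    return cm.counts * (1e6 / totals)


def de_statistics(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    pseudocount: float = 1.0,
    test_method: str = "student",
) -> pd.DataFrame:
    """Per-gene fold change and two-sample t-test p-value on the normalized scale.

    fold_change = (mean_mut + pseudocount) / (mean_wt + pseudocount); the
    two-sided test is applied to log2(normalized + pseudocount), pooling the
    variance by default (*test_method* "student"; "welch" for unpooled).
    Requires at least two replicates per condition.
    """
    if test_method not in ("student", "welch"):
        raise DiffExprError(f"unknown test_method {test_method!r}")
    wt_cols = list(conditions[conditions == WILD_TYPE].index)
    mut_cols = list(conditions[conditions == MUTANT].index)
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise DiffExprError(
            f"need >= 2 replicates per condition, got {len(wt_cols)} wild_type "
            f"and {len(mut_cols)} mutant"
        )
    wt = normalized[wt_cols].to_numpy(float)
    mut = normalized[mut_cols].to_numpy(float)
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    fold_change = (mean_mut + pseudocount) / (mean_wt + pseudocount)

    log_wt = np.log2(wt + pseudocount)
    log_mut = np.log2(mut + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate values trip scipy's precision-loss warning;
        # the degenerate rows are overwritten explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            log_mut, log_wt, axis=1, equal_var=(test_method == "student")
        )
    # degenerate variances: continuity of the decision rule on noise-free data
    var_wt = log_wt.var(axis=1, ddof=1)
    var_mut = log_mut.var(axis=1, ddof=1)
    degenerate = (var_wt == 0) & (var_mut == 0)
    equal_means = np.isclose(log_wt.mean(axis=1), log_mut.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)

    return pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "fold_change": fold_change,
            "log2fc": np.log2(fold_change),
            "p_value": p,
        },
        index=normalized.index,
    )


def call_de_genes(
    statistics: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Add the DE call: up iff fold_change > fc_threshold and p < p_threshold,
    down iff fold_change < 1/fc_threshold and p < p_threshold (strict
    inequalities), else not_de."""
    if fc_threshold <= 1:
        raise DiffExprError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if not 0 < p_threshold < 1:
        raise DiffExprError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    fc = statistics["fold_change"]
    p = statistics["p_value"]
    call = np.where(
        (fc > fc_threshold) & (p < p_threshold),
        "up",
        np.where((fc < 1.0 / fc_threshold) & (p < p_threshold), "down", "not_de"),
    )
    table = statistics.copy()
    table["call"] = call
    return table


def run_de(
    cm: CountMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    test_method: str = "student",
) -> pd.DataFrame:
    """Normalize, test, and call in one step; returns the full DE table."""
    normalized = normalize_counts(cm)
    statistics = de_statistics(normalized, cm.conditions, pseudocount, test_method)
    return call_de_genes(statistics, fc_threshold, p_threshold)


def de_summary(table: pd.DataFrame) -> dict[str, int]:
    calls = table["call"]
    return {
        "n_de": int((calls != "not_de").sum()),
        "n_up": int((calls == "up").sum()),
        "n_down": int((calls == "down").sum()),
    }


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
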