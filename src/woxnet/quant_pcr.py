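"""qRT-PCR relative expression and ChIP-qPCR enrichment arithmetic.

Relative transcript levels follow the classic exponentiated delta-Ct scheme
against a reference gene (ACTIN1-style internal control): at amplification
efficiency E per cycle, level = E^(Ct_reference - Ct_target).  ChIP enrichment
is the bound/input ratio, reported as fold change relative to a control
locus or genotype.  Replicate Ct values are averaged on the Ct scale before
exponentiation.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats


class QpcrError(ValueError):
    pass


def relative_expression(ct_target: float, ct_reference: float, efficiency: float = 2.0) -> float:
    """efficiency ** (ct_reference - ct_target); 1 when target equals reference."""
    if efficiency <= 1:
        raise QpcrError(f"amplification efficiency must exceed 1, got {efficiency}")
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise QpcrError("Ct values must be finite")
    return efficiency ** (ct_reference - ct_target)


def chip_enrichment(bound_fraction: float, input_fraction: float) -> float:
    """Ratio of bound sequence over input."""
    if input_fraction <= 0:
        raise QpcrError(f"input fraction must be positive, got {input_fraction}")
    return bound_fraction / input_fraction


def fold_vs_control(sample_ratio: float, control_ratio: float) -> float:
    """Enrichment fold change relative to the control ratio."""
    if control_ratio <= 0:
        raise QpcrError(f"control ratio must be positive, got {control_ratio}")
    return sample_ratio / control_ratio


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    if len(values) < 2:
        raise QpcrError(f"need >= 2 replicate values, got {len(values)}")
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


def compare_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch two-sample p-value, for annotating group differences."""
    if len(a) < 2 or len(b) < 2:
        raise QpcrError("need >= 2 values per group")
    return float(stats.ttest_ind(list(a), list(b), equal_var=False).pvalue)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, target_id, replicate, ct, role
    (role in {target, reference, input, bound})."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_id", "replicate", "ct", "role"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    if not df["ct"].map(math.isfinite).all():
        raise QpcrError("Ct table contains non-finite Ct values")
    bad = set(df["role"]) - {"target", "reference", "input", "bound"}
    if bad:
        raise QpcrError(f"unknown roles in Ct table: {sorted(bad)}")
    return df


def _mean_ct(df: pd.DataFrame, sample: str, target: str, role: str) -> float:
    sel = df[(df["sample_id"] == sample) & (df["target_id"] == target) & (df["role"] == role)]
    if sel.empty:
        raise QpcrError(f"no {role} rows for sample {sample!r}, target {target!r}")
    return float(sel["ct"].mean())


def expression_table(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per (sample, target) relative expression against the same-sample reference.

    Replicate Cts are averaged per role before exponentiation.  The reference
    target is taken from rows with role ``reference`` in the same sample.
    """
    rows = []
    targets = ct[ct["role"] == "target"]
    for (sample, target), _ in targets.groupby(["sample_id", "target_id"]):
        ct_t = _mean_ct(ct, sample, target, "target")
        ref = ct[(ct["sample_id"] == sample) & (ct["role"] == "reference")]
        if ref.empty:
            raise QpcrError(f"sample {sample!r} has no reference rows")
        ct_r = float(ref["ct"].mean())
        rows.append(
            {
                "sample_id": sample,
                "target_id": target,
                "relative_level": relative_expression(ct_t, ct_r, efficiency),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "relative_level"])


def chip_table(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per (sample, target) bound/input enrichment ratio from Ct values.

    bound/input on the Ct scale is efficiency^(Ct_input - Ct_bound), with
    replicate Cts averaged per role first.
    """
    rows = []
    bound = ct[ct["role"] == "bound"]
    for (sample, target), _ in bound.groupby(["sample_id", "target_id"]):
        ct_b = _mean_ct(ct, sample, target, "bound")
        ct_i = _mean_ct(ct, sample, target, "input")
        rows.append(
            {
                "sample_id": sample,
                "target_id": target,
                "enrichment": relative_expression(ct_b, ct_i, efficiency),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "enrichment"])
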