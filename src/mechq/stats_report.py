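"""Statistical layer: t tests, Bonferroni, delta-delta-Ct, box summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "BoxSummary",
    "t_test_two_sided",
    "bonferroni",
    "delta_delta_ct",
    "box_summary",
    "significance_stars",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    comparison: str = ""
    adjusted_p: float | None = None


@dataclass
class BoxSummary:
    """Box-plot summary: box 25th-75th percentile, whiskers 1.5x IQR."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def t_test_two_sided(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    comparison: str = "",
    welch: bool = False,
) -> TestResult:
    """Student's unpaired two-tailed t test (pooled variance).

    Set ``welch=True`` for the unequal-variance variant.  Degenerate
    zero-variance input: identical means give p = 1; different means
    with zero pooled variance are rejected (the statistic is
    undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, len(a), len(b), comparison)
        raise ValueError(
            "zero variance with unequal means: t statistic undefined"
        )
    stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(stat), float(p), len(a), len(b), comparison)


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` with m tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    reference_condition: str,
) -> pd.DataFrame:
    """Relative fold changes by the delta-delta-Ct method.

    Per replicate ``dCt = Ct_gene - Ct_ref``; per condition
    ``ddCt = mean dCt(condition) - mean dCt(reference condition)``;
    fold change ``= 2^-ddCt``.  Adding a constant to every Ct (a plate
    shift) cancels in ``dCt`` and leaves all folds unchanged.

    Expects columns ``gene, condition, replicate, ct``; raises listing
    the gaps if the reference gene is missing from any
    (condition, replicate) cell.
    """
    required = {"gene", "condition", "replicate", "ct"}
    missing_cols = required - set(ct_table.columns)
    if missing_cols:
        raise ValueError(f"ct_table lacks columns: {sorted(missing_cols)}")

    ref = ct_table[ct_table["gene"] == reference_gene]
    cells = ct_table[["condition", "replicate"]].drop_duplicates()
    ref_cells = ref[["condition", "replicate"]].drop_duplicates()
    gaps = cells.merge(ref_cells, how="left", indicator=True)
    gaps = gaps[gaps["_merge"] == "left_only"]
    if len(gaps):
        pairs = [
            f"({r.condition}, rep {r.replicate})" for r in gaps.itertuples()
        ]
        raise ValueError(
            f"reference gene {reference_gene!r} missing in: {', '.join(pairs)}"
        )
    if reference_condition not in set(ct_table["condition"]):
        raise ValueError(
            f"reference condition {reference_condition!r} not in table"
        )

    ref_ct = ref.set_index(["condition", "replicate"])["ct"]
    work = ct_table[ct_table["gene"] != reference_gene].copy()
    work["dct"] = work["ct"].to_numpy() - ref_ct.loc[
        list(zip(work["condition"], work["replicate"]))
    ].to_numpy()

    mean_dct = (
        work.groupby(["gene", "condition"])["dct"].mean().rename("mean_dct")
    )
    rows = []
    for (gene, cond), value in mean_dct.items():
        ddct = value - mean_dct.loc[(gene, reference_condition)]
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "ddct": float(ddct),
                "fold_change": float(2.0 ** (-ddct)),
                "log2_fold_change": float(-ddct),
            }
        )
    return pd.DataFrame(rows).sort_values(["gene", "condition"]).reset_index(
        drop=True
    )


def box_summary(values: np.ndarray) -> BoxSummary:
    """Quartiles (linear interpolation) and 1.5x-IQR whiskers.

    Whiskers sit at the most extreme data points within
    ``[q1 - 1.5 IQR, q3 + 1.5 IQR]``; everything outside is an
    outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        float(q1),
        float(med),
        float(q3),
        float(inside.min()),
        float(inside.max()),
        v[(v < lo_fence) | (v > hi_fence)],
    )


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
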