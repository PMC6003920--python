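"""Replicate-free differential expression on two pooled libraries.

The test is a per-contig 2x2 Pearson chi-squared on fragment counts: the
contig's count versus the rest of the library, against the same split in
the other library.  It asks whether the contig's share of the library
differs between conditions; with one pooled library per condition this is
the only information available (no biological replication, hence no
dispersion estimate — significance reflects sampling, not between-animal,
variability).  Raw p-values are corrected with the Benjamini-Hochberg
step-up; fold changes are log2(FPKM_greg / FPKM_sol), so positive means
gregarious over-expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountTable, fpkm_table

__all__ = [
    "chi2_contingency_2x2",
    "bh_fdr",
    "log2_fold_change",
    "call_de",
    "categorize",
    "de_summary",
]

DEFAULT_ALPHA = 0.05


def chi2_contingency_2x2(count_a, count_b, total_a, total_b, yates: bool = False):
    """Pearson chi-squared (1 df) on [[c_a, T_a - c_a], [c_b, T_b - c_b]].

    Accepts scalars or aligned arrays.  Both counts zero (or any zero
    marginal) is degenerate and yields chi2 = 0, p = 1.  ``yates`` enables
    the continuity correction (off by default, matching spreadsheet
    CHITEST-style behaviour).

    Returns (chi2, p).
    """
    a = np.asarray(count_a, dtype=float)
    c = np.asarray(count_b, dtype=float)
    ta = np.asarray(total_a, dtype=float)
    tb = np.asarray(total_b, dtype=float)
    if np.any(ta <= 0) or np.any(tb <= 0):
        raise ValueError("library totals must be positive")
    if np.any(a < 0) or np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(a > ta) or np.any(c > tb):
        raise ValueError("count exceeds its library total")
    b = ta - a
    d = tb - c
    n = ta + tb
    det = np.abs(a * d - b * c)
    if yates:
        det = np.maximum(det - n / 2.0, 0.0)
    denom = ta * tb * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * det * det / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    if np.ndim(count_a) == 0 and np.ndim(count_b) == 0:
        return float(chi2), float(p)
    return chi2, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(fpkm_greg, fpkm_sol):
    """log2(FPKM_greg / FPKM_sol); one-sided zeros give +/-inf, 0/0 gives 0.

    Accepts scalars or aligned arrays.
    """
    g = np.asarray(fpkm_greg, dtype=float)
    s = np.asarray(fpkm_sol, dtype=float)
    if np.any(g < 0) or np.any(s < 0):
        raise ValueError("FPKM values must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(g) - np.log2(s)
    lfc = np.where((g == 0) & (s == 0), 0.0, lfc)
    if np.ndim(fpkm_greg) == 0 and np.ndim(fpkm_sol) == 0:
        return float(lfc)
    return lfc


def call_de(
    table: CountTable,
    lengths,
    alpha: float = DEFAULT_ALPHA,
    yates: bool = False,
) -> pd.DataFrame:
    """Full per-contig differential-expression table.

    For every row of ``table``: the 2x2 chi-squared against the library
    totals, BH correction across all tested contigs (degenerate p = 1 rows
    included), FPKMs, log2 fold change, and the call — ``greg_over`` /
    ``sol_over`` when q <= ``alpha`` with the matching fold-change sign,
    ``ns`` otherwise.  Rows are ordered by descending absolute fold change
    (infinities first, ties by ascending contig id).

    ``low_count`` flags rows where some expected cell of the 2x2 table is
    below 5 (the chi-squared approximation is unreliable there; the test is
    still reported).  ``degenerate`` flags 0/0 fold changes.
    """
    if len(table.counts) == 0:
        raise ValueError("empty count table")
    df = table.counts.copy().reset_index(drop=True)
    chi2, p = chi2_contingency_2x2(
        df["count_sol"].to_numpy(float),
        df["count_greg"].to_numpy(float),
        table.total_sol,
        table.total_greg,
        yates=yates,
    )
    q = bh_fdr(p)
    expr = fpkm_table(table, lengths)
    fpkm_sol = expr["fpkm_sol"].to_numpy()
    fpkm_greg = expr["fpkm_greg"].to_numpy()
    lfc = log2_fold_change(fpkm_greg, fpkm_sol)

    significant = q <= alpha
    call = np.where(
        significant & (lfc > 0),
        "greg_over",
        np.where(significant & (lfc < 0), "sol_over", "ns"),
    )

    # smallest expected cell of [[a, Ta-a], [c, Tb-c]]
    a = df["count_sol"].to_numpy(float)
    c = df["count_greg"].to_numpy(float)
    n = float(table.total_sol + table.total_greg)
    col1 = a + c
    col2 = n - col1
    expected_min = np.minimum.reduce(
        [
            table.total_sol * col1 / n,
            table.total_sol * col2 / n,
            table.total_greg * col1 / n,
            table.total_greg * col2 / n,
        ]
    )

    out = pd.DataFrame(
        {
            "contig_id": df["contig_id"],
            "count_sol": df["count_sol"],
            "count_greg": df["count_greg"],
            "fpkm_sol": fpkm_sol,
            "fpkm_greg": fpkm_greg,
            "chi2": chi2,
            "p": p,
            "q": q,
            "log2fc": lfc,
            "call": call,
            "low_count": expected_min < 5,
            "degenerate": (fpkm_sol == 0) & (fpkm_greg == 0),
        }
    )
    out["abs_lfc"] = np.abs(out["log2fc"])
    out = (
        out.sort_values(["abs_lfc", "contig_id"], ascending=[False, True])
        .drop(columns="abs_lfc")
        .reset_index(drop=True)
    )
    return out


def categorize(
    de: pd.DataFrame, min_reads: int = 10, min_lfc: float = 1.0
) -> pd.DataFrame:
    """Partition each phase's significant calls into three categories.

    For a contig significantly over-expressed in one phase, with ``this``
    its count in that phase and ``other`` the count in the other phase:

    - ``absent_other`` — this > min_reads and other == 0;
    - ``high_fold`` — this > min_reads and |log2fc| > min_lfc;
    - ``remainder`` — everything else significant;

    non-significant rows get ``none``.  The three categories partition each
    phase's significant set.
    """
    out = de.copy()
    call = out["call"].to_numpy()
    sol_side = call == "sol_over"
    greg_side = call == "greg_over"
    this = np.where(sol_side, out["count_sol"], out["count_greg"]).astype(float)
    other = np.where(sol_side, out["count_greg"], out["count_sol"]).astype(float)
    abs_lfc = np.abs(out["log2fc"].to_numpy())
    significant = sol_side | greg_side
    category = np.full(len(out), "none", dtype=object)
    category[significant] = "remainder"
    high = significant & (this > min_reads) & (abs_lfc > min_lfc)
    category[high] = "high_fold"
    absent = significant & (this > min_reads) & (other == 0)
    category[absent] = "absent_other"
    out["category"] = category
    return out


def de_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Counts per (call, category) plus per-call totals."""
    rows = []
    for call_value, group in de.groupby("call"):
        rows.append((call_value, "total", len(group)))
        if "category" in de.columns:
            for cat, sub in group.groupby("category"):
                rows.append((call_value, cat, len(sub)))
    return pd.DataFrame(rows, columns=["call", "category", "n"]).sort_values(
        ["call", "category"]
    ).reset_index(drop=True)
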