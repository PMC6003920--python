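"""Expression-rank structure between the two libraries.

Top/bottom decile overlap (are the most/least expressed genes the same in
both phases?), a paired t-comparison of the shared genes' expression, and
Spearman rank concordance by expression stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountTable

__all__ = [
    "DecileReport",
    "decile_sets",
    "decile_report",
    "paired_t",
    "rank_concordance",
    "min_reads_filter",
]


@dataclass(frozen=True)
class DecileReport:
    stratum: str  # "top" or "bottom"
    n_selected: int  # per library
    n_shared: int
    shared_fraction: float
    t_stat: float
    p: float
    mean_diff: float  # mean(sol - greg) over shared genes


def decile_sets(
    expr: pd.DataFrame, fraction: float = 0.10, stratum: str = "top"
) -> tuple[set, set]:
    """Top or bottom ``fraction`` of genes per library, by that library's
    expression.

    Sorting is stable with ties broken by ascending contig id; each
    library contributes ceil(fraction * N) ids.
    """
    if stratum not in ("top", "bottom"):
        raise ValueError("stratum must be 'top' or 'bottom'")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(expr))
    ascending = stratum == "bottom"
    sets = []
    for col in ("fpkm_sol", "fpkm_greg"):
        ordered = expr.sort_values(
            [col, "contig_id"], ascending=[ascending, True], kind="mergesort"
        )
        sets.append(set(ordered["contig_id"].iloc[:n]))
    return sets[0], sets[1]


def paired_t(x, y) -> tuple[float, float, int]:
    """Classical paired t on the differences x - y; returns (t, p, df).

    Degenerate cases: zero-variance differences give t = +/-inf with p = 0
    when the mean difference is nonzero, and t = 0 with p = 1 when every
    difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean), 0.0, df
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def decile_report(
    expr: pd.DataFrame,
    fraction: float = 0.10,
    stratum: str = "top",
    log_scale: bool = False,
) -> DecileReport:
    """Overlap of the per-library deciles plus a paired t on shared genes.

    ``log_scale`` compares log2(FPKM + 1) instead of raw FPKM.
    """
    set_sol, set_greg = decile_sets(expr, fraction, stratum)
    shared = sorted(set_sol & set_greg)
    n_selected = math.ceil(fraction * len(expr))
    sub = expr.set_index("contig_id").loc[shared]
    x = sub["fpkm_sol"].to_numpy(float)
    y = sub["fpkm_greg"].to_numpy(float)
    if log_scale:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if len(shared) >= 2:
        t, p, _ = paired_t(x, y)
        mean_diff = float(np.mean(x - y))
    else:
        t, p, mean_diff = float("nan"), float("nan"), float("nan")
    return DecileReport(
        stratum=stratum,
        n_selected=n_selected,
        n_shared=len(shared),
        shared_fraction=len(shared) / n_selected if n_selected else 0.0,
        t_stat=t,
        p=p,
        mean_diff=mean_diff,
    )


def rank_concordance(
    expr: pd.DataFrame, n_bins: int = 10, by: str = "sol"
) -> pd.DataFrame:
    """Spearman correlation between libraries within expression strata.

    Genes are binned by quantiles of their expression in the ``by`` library
    (bin 0 lowest); within each bin the two libraries' values are
    rank-correlated.  Binning follows one library rather than the
    two-library mean because conditioning on the mean forces a spurious
    negative within-bin correlation (genes with a fixed sum must trade off).
    Real libraries agree tightly among highly expressed genes and drift
    apart toward the bottom of the expression range.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if by not in ("sol", "greg"):
        raise ValueError("by must be 'sol' or 'greg'")
    # rank first so duplicate expression values cannot collapse bin edges
    bins = pd.qcut(expr[f"fpkm_{by}"].rank(method="first"), n_bins, labels=False)
    rows = []
    for b in range(n_bins):
        sub = expr[bins == b]
        if len(sub) < 2:
            rho = float("nan")
        else:
            rho = float(
                stats.spearmanr(sub["fpkm_sol"], sub["fpkm_greg"]).statistic
            )
        rows.append((b, len(sub), rho))
    return pd.DataFrame(rows, columns=["bin", "n", "spearman_rho"])


def min_reads_filter(table: CountTable, min_reads: int = 10) -> CountTable:
    """Keep rows with at least ``min_reads`` in at least one library.

    Library totals are library-wide quantities and are left unchanged.
    """
    counts = table.counts
    keep = (
        counts[["count_sol", "count_greg"]].max(axis=1) >= min_reads
    )
    return CountTable(
        counts=counts[keep].reset_index(drop=True),
        total_sol=table.total_sol,
        total_greg=table.total_greg,
    )
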