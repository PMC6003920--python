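"""GO-term representation between the two differential-expression sets.

Compares, term by term, how many solitarious-over versus gregarious-over
units carry the term, with the same 2x2 chi-squared used for expression.
No genome background is involved: only the two DE sets are compared
(no reference genome exists for the species, so classical enrichment
against genomic representation is not attempted).
"""

from __future__ import annotations

import logging

import pandas as pd

from .diffexp import DEFAULT_ALPHA, bh_fdr, chi2_contingency_2x2

__all__ = ["term_representation_test", "abundance_table"]

logger = logging.getLogger(__name__)


def _de_sets(de: pd.DataFrame) -> tuple[set, set]:
    sol = set(de.loc[de["call"] == "sol_over", "contig_id"])
    greg = set(de.loc[de["call"] == "greg_over", "contig_id"])
    return sol, greg


def term_representation_test(
    go_map: pd.DataFrame,
    de: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    level: int | None = None,
) -> pd.DataFrame:
    """Per-term 2x2 test of DE-set membership, BH-corrected across terms.

    For each GO term the 2x2 table is (in-term vs not-in-term) x
    (solitarious-over vs gregarious-over), with the two DE set sizes as
    totals.  Units assigned to several terms count once per term.  Terms
    with no members in either DE set are skipped (and logged).

    Parameters
    ----------
    go_map
        Columns ``unit_id``, ``go_id`` and optionally ``level``; may cover
        only a subset of the DE units.
    de
        Differential-expression table with ``contig_id`` and ``call``.
    level
        When given, restrict to assignments at that GO depth.

    Returns
    -------
    DataFrame with term, n_sol, n_greg, chi2, p, q, direction, significant.
    """
    if level is not None:
        if "level" not in go_map.columns:
            raise ValueError("go_map has no 'level' column to filter on")
        go_map = go_map[go_map["level"] == level]
    sol, greg = _de_sets(de)
    total_sol, total_greg = len(sol), len(greg)
    if total_sol == 0 or total_greg == 0:
        raise ValueError("both DE sets must be non-empty")

    rows = []
    for term, group in go_map.groupby("go_id", sort=True):
        members = set(group["unit_id"])
        n_sol = len(members & sol)
        n_greg = len(members & greg)
        if n_sol == 0 and n_greg == 0:
            logger.debug("term %s has no members in either DE set; skipped", term)
            continue
        chi2, p = chi2_contingency_2x2(n_sol, n_greg, total_sol, total_greg)
        prop_sol = n_sol / total_sol
        prop_greg = n_greg / total_greg
        direction = (
            "sol" if prop_sol > prop_greg else "greg" if prop_greg > prop_sol else "none"
        )
        rows.append((term, n_sol, n_greg, chi2, p, direction))
    if not rows:
        raise ValueError("no GO term has members in the DE sets")
    out = pd.DataFrame(
        rows, columns=["term", "n_sol", "n_greg", "chi2", "p", "direction"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out[
        ["term", "n_sol", "n_greg", "chi2", "p", "q", "direction", "significant"]
    ]


def abundance_table(go_map: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Relative abundance of each term in the two DE sets (summary table)."""
    sol, greg = _de_sets(de)
    rows = []
    for term, group in go_map.groupby("go_id", sort=True):
        members = set(group["unit_id"])
        rows.append(
            (
                term,
                len(members & sol) / len(sol) if sol else 0.0,
                len(members & greg) / len(greg) if greg else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["term", "frac_sol_over", "frac_greg_over"])
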