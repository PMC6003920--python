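"""Cross-tabulation of two transcriptome assemblies via reciprocal hits.

Given reciprocal homology searches between an NGS assembly (A) and a
reference assembly such as a Sanger EST set (B), counts how many units of
each assembly are shared versus unique, split by whether the unit itself
had a significant annotation hit.  This summarises the degree of overlap
and complementation between the two sequencing efforts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["OverlapTable", "cross_tabulate"]

DEFAULT_E_CUTOFF = 1e-6


@dataclass(frozen=True)
class OverlapTable:
    """Six-cell overlap summary; the shared cell is counted on each side.

    ``both_pos_a`` is the number of annotation-positive A units shared with
    B, ``both_pos_b`` the number of annotation-positive B units shared with
    A, and so on.  Invariant: each assembly's universe is reconstructed per
    annotation class, e.g. A positives = both_pos_a + a_only_pos.
    """

    both_pos_a: int
    both_pos_b: int
    both_neg_a: int
    both_neg_b: int
    a_only_pos: int
    a_only_neg: int
    b_only_pos: int
    b_only_neg: int

    def transpose(self) -> "OverlapTable":
        """Swap the roles of the two assemblies."""
        return OverlapTable(
            both_pos_a=self.both_pos_b,
            both_pos_b=self.both_pos_a,
            both_neg_a=self.both_neg_b,
            both_neg_b=self.both_neg_a,
            a_only_pos=self.b_only_pos,
            a_only_neg=self.b_only_neg,
            b_only_pos=self.a_only_pos,
            b_only_neg=self.a_only_neg,
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("both", "positive", self.both_pos_a, self.both_pos_b),
                ("both", "negative", self.both_neg_a, self.both_neg_b),
                ("A_only", "positive", self.a_only_pos, 0),
                ("A_only", "negative", self.a_only_neg, 0),
                ("B_only", "positive", 0, self.b_only_pos),
                ("B_only", "negative", 0, self.b_only_neg),
            ],
            columns=["overlap", "annotation", "n_a_units", "n_b_units"],
        )


def _passing_ids(hits: pd.DataFrame, column: str, e_cutoff: float) -> set:
    if len(hits) == 0:
        return set()
    return set(hits.loc[hits["evalue"] <= e_cutoff, column])


def cross_tabulate(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    annot_a: Mapping[str, bool],
    annot_b: Mapping[str, bool],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    mode: str = "union",
) -> OverlapTable:
    """Build the six-cell overlap table from reciprocal hit tables.

    A unit of A is shared when it has a passing hit with B in at least one
    direction (``mode="union"``; ``"intersection"`` demands both
    directions).  ``annot_a`` / ``annot_b`` map every unit id to its
    annotation status (True = had a significant annotation hit); an id
    referenced by a hit but missing from the annotation maps is an error.

    Hit tables need ``qseqid``, ``sseqid`` and ``evalue`` columns;
    ``hits_ab`` queries A against B, ``hits_ba`` the reverse.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")

    for hits, q_map, s_map, tag in (
        (hits_ab, annot_a, annot_b, "A->B"),
        (hits_ba, annot_b, annot_a, "B->A"),
    ):
        if len(hits) == 0:
            continue
        missing_q = set(hits["qseqid"]) - set(q_map)
        missing_s = set(hits["sseqid"]) - set(s_map)
        if missing_q or missing_s:
            raise KeyError(
                f"{tag} hits reference unknown unit(s): "
                f"{sorted(missing_q | missing_s)[:5]}"
            )

    a_as_query = _passing_ids(hits_ab, "qseqid", e_cutoff)
    a_as_subject = _passing_ids(hits_ba, "sseqid", e_cutoff)
    b_as_query = _passing_ids(hits_ba, "qseqid", e_cutoff)
    b_as_subject = _passing_ids(hits_ab, "sseqid", e_cutoff)
    if mode == "union":
        shared_a = a_as_query | a_as_subject
        shared_b = b_as_query | b_as_subject
    else:
        shared_a = a_as_query & a_as_subject
        shared_b = b_as_query & b_as_subject

    def split(universe: Mapping[str, bool], shared: set) -> tuple[int, int, int, int]:
        both_pos = both_neg = only_pos = only_neg = 0
        for unit, positive in universe.items():
            if unit in shared:
                if positive:
                    both_pos += 1
                else:
                    both_neg += 1
            elif positive:
                only_pos += 1
            else:
                only_neg += 1
        return both_pos, both_neg, only_pos, only_neg

    bp_a, bn_a, op_a, on_a = split(annot_a, shared_a)
    bp_b, bn_b, op_b, on_b = split(annot_b, shared_b)
    return OverlapTable(
        both_pos_a=bp_a,
        both_pos_b=bp_b,
        both_neg_a=bn_a,
        both_neg_b=bn_b,
        a_only_pos=op_a,
        a_only_neg=on_a,
        b_only_pos=op_b,
        b_only_neg=on_b,
    )
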