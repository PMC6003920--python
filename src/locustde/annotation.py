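"""Homology-hit triage into annotation tiers and unigene grouping.

Consumes tabular homology hits (BLAST outfmt-6 columns plus a database tag
and a taxon group) and assigns each contig to one tier of a three-database
cascade — a curated insect-protein database, then NCBI nr (protein), then
NCBI nt (nucleotide) — flagging likely contaminants on the way.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "TIER_ORDER",
    "HIT_COLUMNS",
    "triage_hits",
    "group_unigenes",
    "read_hit_table",
    "write_hit_table",
]

#: Cascade order: the first database with a passing hit wins.
TIER_ORDER = ("insect_protein", "nr", "nt")
PROTEIN_TIERS = frozenset({"insect_protein", "nr"})

#: Standard tabular columns plus the two extra columns this pipeline needs.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "db_tag",
    "taxon_group",
]

DEFAULT_E_CUTOFF = 1e-6


def _contaminant(tier: str, taxon_group: str) -> bool:
    # Protein hit to a non-animal subject, or nucleotide hit to a
    # non-arthropod subject, marks the contig as a likely contaminant.
    if tier in PROTEIN_TIERS:
        return taxon_group == "non_animal"
    if tier == "nt":
        return taxon_group == "non_arthropod"
    return False


def triage_hits(
    hits: pd.DataFrame,
    contig_ids: Iterable[str] | None = None,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> pd.DataFrame:
    """Assign each contig one annotation tier from its best passing hit.

    Databases are searched in cascade order (insect_protein, nr, nt); within
    the first database holding a hit with e-value <= ``e_cutoff`` the best
    hit is the lowest e-value, ties broken by highest bit-score then
    ascending subject id.  Contigs without a passing hit anywhere get tier
    ``"none"``.

    Parameters
    ----------
    hits
        Hit table with at least qseqid, sseqid, evalue, bitscore, db_tag,
        taxon_group columns.
    contig_ids
        Full universe of contigs; contigs absent from ``hits`` are emitted
        as tier ``"none"``.  Defaults to the contigs present in ``hits``.

    Returns
    -------
    DataFrame with columns contig_id, tier, subject_id, e_value,
    taxon_group, contaminant.
    """
    unknown = set(hits["db_tag"].unique()) - set(TIER_ORDER)
    if unknown:
        raise ValueError(f"unknown database tag(s): {sorted(unknown)}")

    passing = hits[hits["evalue"] <= e_cutoff]
    best_by_contig: dict[str, tuple[str, str, float, str]] = {}
    for (contig, db), group in passing.groupby(["qseqid", "db_tag"], sort=False):
        current = best_by_contig.get(contig)
        if current is not None and TIER_ORDER.index(current[0]) <= TIER_ORDER.index(db):
            continue
        top = group.sort_values(
            ["evalue", "bitscore", "sseqid"], ascending=[True, False, True]
        ).iloc[0]
        best_by_contig[contig] = (
            db,
            str(top["sseqid"]),
            float(top["evalue"]),
            str(top["taxon_group"]),
        )

    if contig_ids is None:
        universe = list(dict.fromkeys(hits["qseqid"]))
    else:
        universe = list(contig_ids)

    rows = []
    for contig in universe:
        if contig in best_by_contig:
            tier, subject, evalue, taxon = best_by_contig[contig]
            rows.append(
                (contig, tier, subject, evalue, taxon, _contaminant(tier, taxon))
            )
        else:
            rows.append((contig, "none", "", float("nan"), "unknown", False))
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "tier",
            "subject_id",
            "e_value",
            "taxon_group",
            "contaminant",
        ],
    )


def group_unigenes(annotations: pd.DataFrame) -> dict[str, list[str]]:
    """Group contigs into unigenes by shared best-hit subject.

    Annotated, non-contaminant contigs sharing a best-hit subject form one
    unigene (partial sequences and isoforms of the same gene); tier-none
    contigs stay as singleton non-annotated units keyed by their own id.
    Contaminants are dropped.
    """
    unigenes: dict[str, list[str]] = {}
    for row in annotations.itertuples(index=False):
        if row.contaminant:
            continue
        key = row.contig_id if row.tier == "none" else row.subject_id
        unigenes.setdefault(key, []).append(row.contig_id)
    return unigenes


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)
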