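"""Per-contig fragment counting and FPKM normalisation.

Counts come either from SAM alignments (htseq-style, one increment per
mapped fragment) or from precomputed count tables; FPKM is
10^9 * count / (contig_length * library_total).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = ["CountTable", "count_fragments", "fpkm", "fpkm_table"]


@dataclass
class CountTable:
    """Fragment counts for the two libraries plus library-wide totals.

    ``total_sol`` / ``total_greg`` are the library-wide mapped totals used
    as chi-squared and FPKM denominators; they need not equal the column
    sums when rows have been filtered after counting.
    """

    counts: pd.DataFrame  # columns: contig_id, count_sol, count_greg
    total_sol: int
    total_greg: int

    def __post_init__(self) -> None:
        required = {"contig_id", "count_sol", "count_greg"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table is missing columns {sorted(missing)}")
        if self.total_sol <= 0 or self.total_greg <= 0:
            raise ValueError("library totals must be positive")
        if (self.counts[["count_sol", "count_greg"]] < 0).any().any():
            raise ValueError("negative fragment counts")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountTable":
        """Build a table whose totals are the realized column sums."""
        return cls(
            counts=counts.reset_index(drop=True),
            total_sol=int(counts["count_sol"].sum()),
            total_greg=int(counts["count_greg"].sum()),
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_sol={self.total_sol}\ttotal_greg={self.total_greg}\n")
            self.counts.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        with open(path) as fh:
            header = fh.readline()
            m = re.match(r"#\s*total_sol=(\d+)\ttotal_greg=(\d+)", header)
            if not m:
                raise ValueError(f"{path}: missing totals header line")
            counts = pd.read_csv(fh, sep="\t")
        return cls(counts=counts, total_sol=int(m.group(1)), total_greg=int(m.group(2)))


_XA_RE = re.compile(r"([^,;]+),[-+]?\d+,[^,;]+,\d+;")


def count_fragments(
    sam_path: str | Path, policy: str = "primary"
) -> dict[str, int]:
    """Count mapped fragments per contig from a SAM stream.

    Unmapped, secondary and supplementary records are ignored; of a mapped
    pair only the first mate is counted, so one fragment increments the
    counts exactly once under the default ``"primary"`` policy.  The
    ``"expanded"`` policy additionally credits every alternative hit listed
    in the XA tag (the xa2multi-style expansion), in which case the summed
    counts exceed the number of fragments.
    """
    if policy not in ("primary", "expanded"):
        raise ValueError(f"unknown counting policy {policy!r}")
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        references = list(sam.references)
        counts: dict[str, int] = {name: 0 for name in references}
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired and rec.is_read2:
                continue  # the mate's fragment was already counted
            counts[rec.reference_name] += 1
            if policy == "expanded" and rec.has_tag("XA"):
                for alt in _XA_RE.finditer(rec.get_tag("XA")):
                    alt_ref = alt.group(1)
                    if alt_ref not in counts:
                        raise ValueError(
                            f"XA alternative hit {alt_ref!r} is not a "
                            "declared reference"
                        )
                    counts[alt_ref] += 1
    return counts


def fpkm(count: float, contig_len: int, lib_total: int) -> float:
    """Fragments per kilobase of contig per million mapped fragments."""
    if contig_len <= 0:
        raise ValueError("contig length must be positive")
    if lib_total <= 0:
        raise ValueError("library total must be positive")
    return 1e9 * count / (contig_len * lib_total)


def fpkm_table(table: CountTable, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Expression table (contig_id, fpkm_sol, fpkm_greg) for all rows."""
    missing = [c for c in table.counts["contig_id"] if c not in lengths]
    if missing:
        raise KeyError(f"no length for contig(s) {missing[:5]}")
    length = np.array([lengths[c] for c in table.counts["contig_id"]], dtype=float)
    if (length <= 0).any():
        raise ValueError("contig lengths must be positive")
    return pd.DataFrame(
        {
            "contig_id": table.counts["contig_id"],
            "fpkm_sol": 1e9 * table.counts["count_sol"].to_numpy(float)
            / (length * table.total_sol),
            "fpkm_greg": 1e9 * table.counts["count_greg"].to_numpy(float)
            / (length * table.total_greg),
        }
    )
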