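"""Contig-level quality control for a de novo transcriptome assembly.

Covers the word-size (k-mer) safety mathematics used to pick assembly
k-mers, the length / read-support filter that separates valid contigs from
likely artifacts, UCLUST-style greedy redundancy clustering, CAP3-style
suffix-prefix overlap merging, and summary statistics (N50, GC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "AssemblyStats",
    "kmer_collision_probability",
    "min_safe_kmer",
    "kmer_sweep",
    "filter_contigs",
    "greedy_cluster",
    "overlap_merge",
    "assembly_stats",
    "read_contig_fasta",
    "write_contig_fasta",
]

# Default QC thresholds: Illumina reads typically lose quality past 75% of
# their length, so a contig shorter than 75 bases is most likely supported
# by less than one full read; 4 reads imply at least two cDNA molecules.
MIN_CONTIG_LENGTH = 75
MIN_READ_SUPPORT = 4


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig with its read-support metadata."""

    id: str
    sequence: str
    read_support: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has an empty sequence")
        if self.read_support < 1:
            raise ValueError(f"contig {self.id!r} has read_support < 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence.upper()
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n50: int
    gc: float
    min_len: int
    max_len: int
    total_bases: int


# ---------------------------------------------------------------------------
# K-mer safety mathematics
# ---------------------------------------------------------------------------

def kmer_collision_probability(k: int, n_windows: float | None = None) -> float:
    """Probability of re-observing a fixed k-mer among equiprobable bases.

    A single window matches a given k-mer with probability 4**(-k).  With
    ``n_windows`` independent sliding windows the probability of at least
    one chance re-occurrence is 1 - (1 - 4**(-k))**n_windows.

    Parameters
    ----------
    k
        Word size in bases.  Assemblers use odd k only (palindrome
        avoidance); an even ``k`` triggers a warning but is computed.
    n_windows
        Number of sliding windows scanned.  Omit for the single-window
        probability 4**(-k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k % 2 == 0:
        warnings.warn(
            f"k={k} is even; assembly word sizes are odd to avoid "
            "palindromic k-mers",
            stacklevel=2,
        )
    p1 = 4.0 ** (-k)
    if n_windows is None:
        return p1
    if n_windows < 0:
        raise ValueError("n_windows must be >= 0")
    # 1 - (1-p)^n, computed stably for tiny p and huge n
    return -math.expm1(n_windows * math.log1p(-p1))


def min_safe_kmer(n_windows: float, threshold: float, k_max: int = 95) -> int:
    """Smallest odd k whose chance re-occurrence stays under ``threshold``.

    Scans odd k upward and returns the first k <= ``k_max`` for which
    :func:`kmer_collision_probability` at ``n_windows`` windows is at or
    below ``threshold``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be a probability")
    for k in range(1, k_max + 1, 2):
        if kmer_collision_probability(k, n_windows) <= threshold:
            return k
    raise ValueError(
        f"no odd k <= {k_max} keeps the re-occurrence probability under "
        f"{threshold} for {n_windows:g} windows"
    )


def kmer_sweep(read_length: int, k_min: int) -> list[int]:
    """Descending odd k-mers from 95% of the read length down to ``k_min``.

    The starting point is round(0.95 * read_length), forced odd by
    stepping downward.  For 101-base reads and k_min=19 this yields the
    39-value sweep 95, 93, ..., 19.
    """
    if read_length < 1 or k_min < 1:
        raise ValueError("read_length and k_min must be >= 1")
    start = round(0.95 * read_length)
    if start % 2 == 0:
        start -= 1
    if start < k_min:
        raise ValueError(
            f"95% of read_length ({start}) is below k_min ({k_min})"
        )
    return list(range(start, k_min - 1, -2))


# ---------------------------------------------------------------------------
# Contig filtering
# ---------------------------------------------------------------------------

def filter_contigs(
    contigs: Sequence[ContigRecord],
    blast_positive_ids: Iterable[str] = (),
    min_len: int = MIN_CONTIG_LENGTH,
    min_reads: int = MIN_READ_SUPPORT,
) -> tuple[list[ContigRecord], list[tuple[ContigRecord, str]]]:
    """Partition contigs into kept and removed-with-reason.

    A contig is removed as ``"short"`` when its length is below ``min_len``
    (unconditionally), and as ``"low_support"`` when its read support is
    below ``min_reads`` and it has no significant homology hit
    (``blast_positive_ids``).  Everything else is kept.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes[:5]}")
    positive = set(blast_positive_ids)
    kept: list[ContigRecord] = []
    removed: list[tuple[ContigRecord, str]] = []
    for c in contigs:
        if c.length < min_len:
            removed.append((c, "short"))
        elif c.read_support < min_reads and c.id not in positive:
            removed.append((c, "low_support"))
        else:
            kept.append(c)
    return kept, removed


# ---------------------------------------------------------------------------
# Pairwise identity (shared helper for clustering)
# ---------------------------------------------------------------------------

# Pigeonhole: two sequences at >=95% identity over a shorter length >=75
# share an exact run of >=14 matching bases, so a shared-14-mer screen
# cannot lose a qualifying pair at that scale.
_PREFILTER_K = 14
_PREFILTER_MIN_LEN = 75


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def pairwise_identity(a: str, b: str) -> float:
    """Alignment identity over the shorter sequence.

    The shorter sequence is aligned end-to-end against the best-matching
    stretch of the longer one (exact infix dynamic programming); identity
    is (shorter_length - edit_distance) / shorter_length, so a contained
    or near-duplicate sequence scores 1.0 regardless of the length gap.
    """
    if len(a) > len(b):
        a, b = b, a
    if len(a) == 0:
        return 0.0
    d = edlib.align(a, b, mode="HW", task="distance")["editDistance"]
    return max(0.0, (len(a) - d) / len(a))


def greedy_cluster(
    contigs: Sequence[ContigRecord], identity: float = 0.95
) -> dict[str, str]:
    """Greedy length-ordered redundancy clustering (UCLUST-like).

    Contigs are visited by descending length (ties broken by ascending id);
    each joins the first existing representative to which its global
    identity over the shorter sequence reaches ``identity``, else founds a
    new cluster.  Returns a member-id -> representative-id map in which
    representatives map to themselves.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    reps: list[ContigRecord] = []
    rep_kmers: list[frozenset[str]] = []
    assignment: dict[str, str] = {}
    for c in ordered:
        c_kmers = _kmer_set(c.sequence, _PREFILTER_K)
        home = None
        for rep, kmers in zip(reps, rep_kmers):
            if (
                min(c.length, rep.length) >= _PREFILTER_MIN_LEN
                and c_kmers.isdisjoint(kmers)
            ):
                continue
            if pairwise_identity(c.sequence, rep.sequence) >= identity:
                home = rep
                break
        if home is None:
            reps.append(c)
            rep_kmers.append(c_kmers)
            assignment[c.id] = c.id
        else:
            assignment[c.id] = home.id
    return assignment


# ---------------------------------------------------------------------------
# Suffix-prefix overlap merging
# ---------------------------------------------------------------------------

_ANCHOR_K = 12
_EXHAUSTIVE_MAX = 32


def _overlap_ok(a: str, b: str, L: int, identity: float) -> bool:
    """Ungapped check of a's L-suffix against b's L-prefix."""
    budget = math.floor(L * (1.0 - identity))
    mismatches = 0
    off = len(a) - L
    for i in range(L):
        if a[off + i] != b[i]:
            mismatches += 1
            if mismatches > budget:
                return False
    return True


def find_overlap(a: str, b: str, min_overlap: int, identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap >= ``min_overlap`` at ``identity``.

    Overlaps up to 32 bases are scanned exhaustively; longer candidates are
    anchored on exact shared 12-mers (any >=33-base overlap at >=95%
    identity necessarily contains one).  Returns 0 when no overlap
    qualifies.
    """
    max_L = min(len(a), len(b))
    candidates: set[int] = set()
    if max_L > _EXHAUSTIVE_MAX:
        b_index: dict[str, list[int]] = {}
        for j in range(len(b) - _ANCHOR_K + 1):
            b_index.setdefault(b[j : j + _ANCHOR_K], []).append(j)
        for i in range(len(a) - _ANCHOR_K + 1):
            for j in b_index.get(a[i : i + _ANCHOR_K], ()):
                L = len(a) - i + j
                if _EXHAUSTIVE_MAX < L <= max_L:
                    candidates.add(L)
    candidates.update(range(min_overlap, min(max_L, _EXHAUSTIVE_MAX) + 1))
    for L in sorted(candidates, reverse=True):
        if L >= min_overlap and _overlap_ok(a, b, L, identity):
            return L
    return 0


def _find_mergeable_pair(
    pool: list[ContigRecord], min_overlap: int, identity: float
) -> tuple[int, int, int] | None:
    """First ordered pair (by descending length, ascending id) that overlaps.

    Uses one shared 12-mer index over the whole pool to anchor long-overlap
    candidates, so the scan stays near-linear when no contigs overlap.
    Returns (index_a, index_b, overlap_length) or None.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for pos, c in enumerate(pool):
        s = c.sequence
        for j in range(len(s) - _ANCHOR_K + 1):
            index.setdefault(s[j : j + _ANCHOR_K], []).append((pos, j))
    for ia, a in enumerate(pool):
        sa = a.sequence
        long_candidates: dict[int, set[int]] = {}
        for i in range(len(sa) - _ANCHOR_K + 1):
            for ib, j in index.get(sa[i : i + _ANCHOR_K], ()):
                if ib == ia:
                    continue
                L = len(sa) - i + j
                if _EXHAUSTIVE_MAX < L <= min(len(sa), pool[ib].length):
                    long_candidates.setdefault(ib, set()).add(L)
        for ib, b in enumerate(pool):
            if ib == ia:
                continue
            max_L = min(len(sa), b.length)
            ls = sorted(long_candidates.get(ib, ()), reverse=True)
            ls += range(min(max_L, _EXHAUSTIVE_MAX), min_overlap - 1, -1)
            for L in ls:
                if _overlap_ok(sa, b.sequence, L, identity):
                    return ia, ib, L
    return None


def overlap_merge(
    contigs: Sequence[ContigRecord],
    min_overlap: int = 16,
    identity: float = 0.95,
) -> list[ContigRecord]:
    """Greedy CAP3-style merging of suffix-prefix overlapping contigs.

    Repeatedly joins the first pair (in descending-length, ascending-id
    order) whose ungapped suffix-prefix overlap reaches ``min_overlap``
    bases at ``identity``; the merged contig keeps the upstream id and the
    summed read support.  Terminates when no pair can be merged; total
    read support is conserved.
    """
    pool = sorted(contigs, key=lambda c: (-c.length, c.id))
    while True:
        hit = _find_mergeable_pair(pool, min_overlap, identity)
        if hit is None:
            return pool
        ia, ib, L = hit
        a, b = pool[ia], pool[ib]
        joined = ContigRecord(
            id=a.id,
            sequence=a.sequence + b.sequence[L:],
            read_support=a.read_support + b.read_support,
        )
        pool = [c for k, c in enumerate(pool) if k not in (ia, ib)]
        pool.append(joined)
        pool.sort(key=lambda c: (-c.length, c.id))


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[int]) -> int:
    """Length L such that contigs of length >= L hold >= half of all bases."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def assembly_stats(contigs: Sequence[ContigRecord]) -> AssemblyStats:
    if not contigs:
        raise ValueError("cannot summarise an empty assembly")
    lengths = [c.length for c in contigs]
    total = sum(lengths)
    gc_bases = sum(
        c.sequence.upper().count("G") + c.sequence.upper().count("C")
        for c in contigs
    )
    return AssemblyStats(
        n_contigs=len(contigs),
        n50=n50(lengths),
        gc=gc_bases / total,
        min_len=min(lengths),
        max_len=max(lengths),
        total_bases=total,
    )


# ---------------------------------------------------------------------------
# FASTA I/O (read support carried in the header as reads=<int>)
# ---------------------------------------------------------------------------

def read_contig_fasta(path: str | Path) -> list[ContigRecord]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        support = 1
        for token in rec.description.split():
            if token.startswith("reads="):
                support = int(token[len("reads="):])
        contigs.append(
            ContigRecord(id=rec.id, sequence=str(rec.seq), read_support=support)
        )
    return contigs


def write_contig_fasta(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(c.sequence), id=c.id, description=f"reads={c.read_support}"
        )
        for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def stats_frame(stats: AssemblyStats) -> pd.DataFrame:
    return pd.DataFrame([stats.__dict__])


def removal_frame(
    removed: Sequence[tuple[ContigRecord, str]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.id, reason) for c, reason in removed], columns=["contig_id", "reason"]
    )
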