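"""Synthetic inputs with planted truth for the whole pipeline.

Emulates the study design: two pooled, unreplicated CNS libraries (one
solitarious, one gregarious, the solitarious one ~25% deeper), a de novo
contig set with a minority of short / low-support artifact contigs, a
three-tier annotation cascade with a small contaminant admixture, GO
assignments, and qPCR Ct values — all derived from a per-transcript truth
table (baseline mean, planted log2 fold change, DE flag) so recovery can
be scored exactly.

Counts are generated directly from the truth (no read simulation): the
expected fragment count of transcript *i* in library *x* is
``lib_size_x * mean_ix / sum_j(mean_jx)``, Poisson-sampled (or
gamma-Poisson when ``dispersion > 0``).  A minimal SAM emitter is provided
so the alignment-counting path stays testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import HIT_COLUMNS
from .assembly_qc import ContigRecord
from .quantify import CountTable

__all__ = [
    "SyntheticConfig",
    "generate_transcriptome",
    "generate_counts",
    "generate_hit_table",
    "generate_go_map",
    "generate_qpcr",
    "calibration_truth",
    "write_truth_tsv",
    "write_sam",
]

REFERENCE_GENES = ("actin", "tubulin")

# stream offsets so each generator draws from an independent substream
_STREAMS = {"transcriptome": 0, "counts": 1, "hits": 2, "go": 3, "qpcr": 4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the sequencing design being emulated: ~48% of
    transcripts differentially expressed, ~90% of those over-expressed in
    the gregarious library, the solitarious library 25% deeper, contig GC
    around 40%, a ~30% non-annotated and ~5% contaminant contig minority.
    Baseline expression is lognormal (natural-log parameters mu=3,
    sigma=1.5 on a fragments-per-million scale); planted |log2FC| is
    normal(2.0, 0.5) clipped below at 0.25.  ``dispersion`` is the
    negative-binomial overdispersion (variance = m + dispersion * m^2);
    0 means Poisson, matching the sampling model the contingency test
    itself assumes.
    """

    n_transcripts: int = 2000
    length_meanlog: float = 6.8  # natural-log bases; median ~900 bp
    length_sdlog: float = 0.7
    gc_target: float = 0.40
    de_fraction: float = 0.48
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    greg_bias: float = 0.9
    lib_size_sol: int = 1_250_000
    lib_size_greg: int = 1_000_000
    dispersion: float = 0.0
    expr_meanlog: float = 3.0
    expr_sdlog: float = 1.5
    frac_non_annotated: float = 0.30
    frac_contaminant: float = 0.05
    frac_insect: float = 0.51
    frac_nr: float = 0.05
    frac_nt: float = 0.09
    n_artifact_contigs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_target",
            "de_fraction",
            "greg_bias",
            "frac_non_annotated",
            "frac_contaminant",
            "frac_insect",
            "frac_nr",
            "frac_nt",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.lib_size_sol < 1 or self.lib_size_greg < 1:
            raise ValueError("library sizes must be >= 1")
        if self.length_sdlog < 0 or self.expr_sdlog < 0 or self.lfc_sd < 0:
            raise ValueError("distribution scales must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_artifact_contigs < 0:
            raise ValueError("n_artifact_contigs must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    # exact GC placement: realized composition tracks the target even for
    # short sequences
    n_gc = int(round(gc * length))
    bases = np.empty(length, dtype="<U1")
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    at_mask = np.ones(length, dtype=bool)
    at_mask[gc_positions] = False
    bases[gc_positions] = rng.choice(np.array(["G", "C"]), size=n_gc)
    bases[at_mask] = rng.choice(np.array(["A", "T"]), size=length - n_gc)
    return "".join(bases)


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Contig records plus the planted-truth table.

    Produces ``n_transcripts`` valid contigs (length >= 75, read support
    >= 4) and ``n_artifact_contigs`` QC-violating contigs, alternating
    between short (length < 75) and low-support (< 4 reads) kinds.  The
    truth table covers every contig: baseline mean (fragments-per-million
    scale), per-library means, planted log2 fold change, DE and artifact
    flags.  Deterministic under a fixed seed.
    """
    rng = config.rng("transcriptome")
    n = config.n_transcripts

    lengths = np.maximum(
        75,
        np.round(
            rng.lognormal(config.length_meanlog, config.length_sdlog, size=n)
        ).astype(int),
    )
    support = 4 + rng.poisson(20, size=n)

    base_mean = rng.lognormal(config.expr_meanlog, config.expr_sdlog, size=n)
    is_de = rng.random(n) < config.de_fraction
    magnitude = np.clip(rng.normal(config.lfc_mean, config.lfc_sd, size=n), 0.25, None)
    sign = np.where(rng.random(n) < config.greg_bias, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * magnitude, 0.0)
    mean_sol = base_mean * 2.0 ** (-true_lfc / 2.0)
    mean_greg = base_mean * 2.0 ** (true_lfc / 2.0)

    contigs = []
    rows = []
    for i in range(n):
        cid = f"tx{i:06d}"
        contigs.append(
            ContigRecord(
                id=cid,
                sequence=_sequence(rng, int(lengths[i]), config.gc_target),
                read_support=int(support[i]),
            )
        )
        rows.append(
            (
                cid,
                int(lengths[i]),
                base_mean[i],
                mean_sol[i],
                mean_greg[i],
                true_lfc[i],
                bool(is_de[i]),
                False,
            )
        )

    for j in range(config.n_artifact_contigs):
        cid = f"art{j:04d}"
        if j % 2 == 0:  # short kind: fails the length rule
            length = int(rng.integers(30, 75))
            reads = int(4 + rng.poisson(5))
        else:  # low-support kind: fails the read-support rule
            length = int(
                max(75, round(rng.lognormal(config.length_meanlog, config.length_sdlog)))
            )
            reads = int(rng.integers(1, 4))
        mean = float(rng.lognormal(config.expr_meanlog - 4.0, 1.0))
        contigs.append(
            ContigRecord(
                id=cid,
                sequence=_sequence(rng, length, config.gc_target),
                read_support=reads,
            )
        )
        rows.append((cid, length, mean, mean, mean, 0.0, False, True))

    truth = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "length",
            "base_mean",
            "mean_sol",
            "mean_greg",
            "true_lfc",
            "is_de",
            "is_artifact",
        ],
    )
    return contigs, truth


def generate_counts(truth: pd.DataFrame, config: SyntheticConfig) -> CountTable:
    """Poisson (or gamma-Poisson) fragment counts for both libraries.

    Expected count of transcript *i* in library *x* is lib_size_x times the
    transcript's share of that library's total expression, so realized
    library totals land within sampling error of the configured sizes.
    A transcript with mean 0 in a library gets count 0 there.
    """
    rng = config.rng("counts")
    rows = []
    lam = {}
    for phase, lib_size in (("sol", config.lib_size_sol), ("greg", config.lib_size_greg)):
        means = truth[f"mean_{phase}"].to_numpy(float)
        if (means < 0).any():
            raise ValueError("negative expression means in truth table")
        total = means.sum()
        if total <= 0:
            raise ValueError("truth table has zero total expression")
        lam[phase] = lib_size * means / total
    for phase in ("sol", "greg"):
        rate = lam[phase]
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            rate = rng.gamma(shape, rate * config.dispersion)
        rows.append(rng.poisson(rate))
    counts = pd.DataFrame(
        {
            "contig_id": truth["transcript_id"],
            "count_sol": rows[0],
            "count_greg": rows[1],
        }
    )
    return CountTable.from_counts(counts)


def calibration_truth(
    n: int,
    base_mean: float = 50.0,
    lfc: float = 0.0,
    de_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Flat-expression truth table for statistical calibration runs.

    Every transcript gets the same baseline mean (so every 2x2 table has
    healthy expected cells) and the first ``de_fraction * n`` transcripts
    carry a planted symmetric log2 fold change of ``lfc`` toward the
    gregarious side.
    """
    rng = np.random.default_rng([seed, 99])
    n_de = int(round(de_fraction * n))
    true_lfc = np.zeros(n)
    true_lfc[:n_de] = lfc
    lengths = rng.integers(200, 3000, size=n)
    return pd.DataFrame(
        {
            "transcript_id": [f"tx{i:06d}" for i in range(n)],
            "length": lengths,
            "base_mean": base_mean,
            "mean_sol": base_mean * 2.0 ** (-true_lfc / 2.0),
            "mean_greg": base_mean * 2.0 ** (true_lfc / 2.0),
            "true_lfc": true_lfc,
            "is_de": true_lfc != 0.0,
            "is_artifact": False,
        }
    )


def generate_hit_table(
    contigs: Sequence[ContigRecord],
    config: SyntheticConfig,
    subject_pool_divisor: int = 4,
) -> pd.DataFrame:
    """Tabular homology hits for the annotation cascade.

    Each valid (non-artifact) contig is assigned insect-protein, nr, nt,
    contaminant or no-hit status at the configured fractions; artifact
    contigs get no hits.  Contaminant hits carry non-animal (protein) or
    non-arthropod (nucleotide) taxon groups, split ~3/97 the way real
    contamination is dominated by nucleotide hits.  All emitted e-values
    pass the 1e-6 cutoff.  Subjects are drawn from a pool about
    ``len(contigs) // subject_pool_divisor`` deep so several contigs share
    a best-hit subject and group into unigenes.
    """
    rng = config.rng("hits")
    valid = [c for c in contigs if not c.id.startswith("art")]
    n_pool = max(1, len(valid) // subject_pool_divisor)

    frac_hit = config.frac_insect + config.frac_nr + config.frac_nt
    probs = np.array(
        [
            config.frac_insect,
            config.frac_nr,
            config.frac_nt,
            config.frac_contaminant * 0.03,
            config.frac_contaminant * 0.97,
            config.frac_non_annotated,
        ]
    )
    if probs.sum() <= 0:
        raise ValueError("all assignment fractions are zero")
    probs = probs / probs.sum()
    categories = rng.choice(6, size=len(valid), p=probs)

    rows = []
    for contig, cat in zip(valid, categories):
        if cat == 5:  # no significant hit anywhere
            continue
        db_tag, taxon = {
            0: ("insect_protein", "insect"),
            1: ("nr", "other_animal"),
            2: ("nt", "arthropod"),
            3: ("nr", "non_animal"),
            4: ("nt", "non_arthropod"),
        }[int(cat)]
        subject = f"subj{rng.integers(0, n_pool):06d}"
        evalue = 10.0 ** (-rng.uniform(6.0, 50.0))
        bitscore = round(50.0 + rng.uniform(0.0, 400.0), 1)
        aln_len = int(min(contig.length, rng.integers(50, 500)))
        rows.append(
            (
                contig.id,
                subject,
                round(rng.uniform(80.0, 100.0), 2),
                aln_len,
                int(rng.integers(0, 10)),
                int(rng.integers(0, 3)),
                1,
                aln_len,
                1,
                aln_len,
                evalue,
                bitscore,
                db_tag,
                taxon,
            )
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def generate_go_map(
    unit_ids: Sequence[str],
    config: SyntheticConfig,
    n_terms: int = 80,
    max_levels: int = 16,
    coverage: float = 0.7,
    max_terms_per_unit: int = 4,
) -> pd.DataFrame:
    """Random GO assignments: each covered unit gets 1-4 terms with levels."""
    rng = config.rng("go")
    term_levels = rng.integers(1, max_levels + 1, size=n_terms)
    rows = []
    for unit in unit_ids:
        if rng.random() >= coverage:
            continue
        k = int(rng.integers(1, max_terms_per_unit + 1))
        for t in sorted(rng.choice(n_terms, size=k, replace=False)):
            rows.append((unit, f"GO:{t + 1:07d}", int(term_levels[t])))
    return pd.DataFrame(rows, columns=["unit_id", "go_id", "level"])


def generate_qpcr(
    truth: pd.DataFrame,
    genes: Sequence[str],
    config: SyntheticConfig,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table consistent with the planted fold changes under delta-delta-Ct.

    For a gene with planted log2FC ``f`` (positive = gregarious over), the
    solitarious target Ct sits f/2 cycles above and the gregarious target
    Ct f/2 cycles below a gene-specific baseline, with both reference
    genes (actin, tubulin) flat across phases; Gaussian noise of
    ``noise_sd`` cycles is added per measurement.  With ``noise_sd=0`` the
    delta-delta-Ct estimator recovers the planted fold change exactly.
    Columns: gene, phase, replicate, target_ct, ref_gene, ref_ct.
    """
    rng = config.rng("qpcr")
    lfc_map = dict(zip(truth["transcript_id"], truth["true_lfc"]))
    missing = [g for g in genes if g not in lfc_map]
    if missing:
        raise KeyError(f"gene(s) not in truth table: {missing[:5]}")
    targets = list(genes) + [g for g in REFERENCE_GENES if g not in genes]
    rows = []
    for gene in targets:
        lfc = float(lfc_map.get(gene, 0.0))  # reference genes are flat
        base_ct = float(rng.uniform(18.0, 26.0))
        for phase, shift in (("sol", lfc / 2.0), ("greg", -lfc / 2.0)):
            for rep in range(1, n_replicates + 1):
                target_ct = base_ct + shift + float(rng.normal(0.0, noise_sd))
                for ref_gene in REFERENCE_GENES:
                    ref_ct = 16.0 + float(rng.normal(0.0, noise_sd))
                    rows.append((gene, phase, rep, target_ct, ref_gene, ref_ct))
    return pd.DataFrame(
        rows,
        columns=["gene", "phase", "replicate", "target_ct", "ref_gene", "ref_ct"],
    )


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_sam(
    contigs: Sequence[ContigRecord],
    counts: dict[str, int] | pd.Series,
    path: str | Path,
    read_length: int = 50,
) -> None:
    """Minimal single-end SAM: one mapped line per counted fragment.

    Toy emitter so the SAM counting path can be exercised without an
    aligner; every record maps at position 1 of its contig.
    """
    counts = dict(counts)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{c.length}\n")
        frag = 0
        for c in contigs:
            cigar = f"{min(read_length, c.length)}M"
            for _ in range(int(counts.get(c.id, 0))):
                fh.write(
                    f"frag{frag:08d}\t0\t{c.id}\t1\t60\t{cigar}\t*\t0\t0\t*\t*\n"
                )
                frag += 1
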