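"""End-to-end orchestration of the synthetic demo pipeline.

Stages run in method order — simulate, qc, annotate, count, de, go, ranks,
compare, qpcr — each writing its TSV outputs plus a JSON manifest (inputs,
parameters, seed, row counts) into one result directory.  All randomness
flows from the single config seed, stage timings go to the console logger
only, and no output embeds a timestamp, so re-running with the same config
is byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import (
    annotation,
    assembly_qc,
    compare_assemblies,
    diffexp,
    go_representation,
    qpcr_concordance,
    quantify,
    rank_overlap,
    synthetic_data,
)

__all__ = ["DEFAULT_CONFIG", "demo_config", "load_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synthetic": {},  # overrides for synthetic_data.SyntheticConfig fields
    "alpha": 0.05,
    "min_reads": 10,
    "min_lfc": 1.0,
    "decile_fraction": 0.10,
    "rank_bins": 5,
    "qpcr_noise_sd": 0.05,
    "qpcr_n_genes": 12,
    "cluster_identity": 0.95,
    "merge_min_overlap": 16,
}


def demo_config(seed: int = 0) -> dict[str, Any]:
    """A small all-synthetic configuration that runs in well under a minute."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["seed"] = seed
    cfg["synthetic"] = {
        "n_transcripts": 300,
        "lib_size_sol": 250_000,
        "lib_size_greg": 200_000,
        "n_artifact_contigs": 20,
    }
    return cfg


def load_config(path: str | Path | None, seed: int | None = None) -> dict[str, Any]:
    """Demo defaults overlaid with a YAML key-value file, if given."""
    cfg = demo_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, value in user.items():
            if key == "synthetic":
                cfg["synthetic"].update(value or {})
            else:
                cfg[key] = value
    if seed is not None:
        cfg["seed"] = seed
    return cfg


def _synth_config(cfg: dict[str, Any]) -> synthetic_data.SyntheticConfig:
    return synthetic_data.SyntheticConfig(seed=cfg["seed"], **cfg["synthetic"])


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return len(df)


def _manifest(outdir: Path, stage: str, cfg: dict[str, Any], outputs: dict[str, int]) -> None:
    payload = {
        "stage": stage,
        "seed": cfg["seed"],
        "parameters": {k: v for k, v in cfg.items() if k != "synthetic"},
        "synthetic": cfg["synthetic"],
        "outputs": outputs,
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n"
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise StageError(stage, f"missing input {name}; run the earlier stages first")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict[str, Any], outdir: Path) -> None:
    scfg = _synth_config(cfg)
    contigs, truth = synthetic_data.generate_transcriptome(scfg)
    counts = synthetic_data.generate_counts(truth, scfg)
    hits = synthetic_data.generate_hit_table(contigs, scfg)
    go_map = synthetic_data.generate_go_map(
        [c.id for c in contigs if not c.id.startswith("art")], scfg
    )

    # validation panel mimics the study design: genes picked for their
    # differential expression, biased toward the gregarious side
    valid = truth[~truth["is_artifact"]]
    n_genes = int(cfg["qpcr_n_genes"])
    by_lfc = valid.sort_values(["true_lfc", "transcript_id"], ascending=[False, True])
    n_up = 2 * n_genes // 3
    genes = list(by_lfc.loc[by_lfc["true_lfc"] > 0, "transcript_id"].iloc[:n_up])
    down = by_lfc.loc[by_lfc["true_lfc"] < 0, "transcript_id"].iloc[::-1]
    genes += list(down.iloc[: n_genes - len(genes)])
    flat = valid.loc[valid["true_lfc"] == 0.0, "transcript_id"]
    genes += list(flat.iloc[: n_genes - len(genes)])
    ct = synthetic_data.generate_qpcr(
        truth, genes, scfg, noise_sd=float(cfg["qpcr_noise_sd"])
    )

    assembly_qc.write_contig_fasta(contigs, outdir / "contigs.fasta")
    synthetic_data.write_truth_tsv(truth, outdir / "truth.tsv")
    counts.write_tsv(outdir / "counts.tsv")
    annotation.write_hit_table(hits, outdir / "hits.tsv")
    n_go = _write_tsv(go_map, outdir / "go_map.tsv")
    ct.to_csv(outdir / "qpcr_ct.csv", index=False, float_format=_FLOAT_FORMAT)
    _manifest(
        outdir,
        "simulate",
        cfg,
        {
            "contigs.fasta": len(contigs),
            "truth.tsv": len(truth),
            "counts.tsv": len(counts.counts),
            "hits.tsv": len(hits),
            "go_map.tsv": n_go,
            "qpcr_ct.csv": len(ct),
        },
    )


def stage_qc(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "qc", "contigs.fasta", "hits.tsv")
    contigs = assembly_qc.read_contig_fasta(outdir / "contigs.fasta")
    hits = annotation.read_hit_table(outdir / "hits.tsv")
    positive = set(hits.loc[hits["evalue"] <= annotation.DEFAULT_E_CUTOFF, "qseqid"])
    kept, removed = assembly_qc.filter_contigs(contigs, positive)
    clusters = assembly_qc.greedy_cluster(kept, identity=float(cfg["cluster_identity"]))
    representatives = [c for c in kept if clusters[c.id] == c.id]
    merged = assembly_qc.overlap_merge(
        representatives, min_overlap=int(cfg["merge_min_overlap"])
    )
    stats = assembly_qc.assembly_stats(merged)

    assembly_qc.write_contig_fasta(merged, outdir / "contigs_qc.fasta")
    n_rm = _write_tsv(assembly_qc.removal_frame(removed), outdir / "removed.tsv")
    cluster_df = pd.DataFrame(
        sorted(clusters.items()), columns=["contig_id", "representative_id"]
    )
    _write_tsv(cluster_df, outdir / "clusters.tsv")
    _write_tsv(assembly_qc.stats_frame(stats), outdir / "assembly_stats.tsv")
    _manifest(
        outdir,
        "qc",
        cfg,
        {
            "contigs_qc.fasta": len(merged),
            "removed.tsv": n_rm,
            "clusters.tsv": len(cluster_df),
            "assembly_stats.tsv": 1,
        },
    )


def stage_annotate(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "annotate", "contigs_qc.fasta", "hits.tsv")
    contigs = assembly_qc.read_contig_fasta(outdir / "contigs_qc.fasta")
    hits = annotation.read_hit_table(outdir / "hits.tsv")
    annot = annotation.triage_hits(hits, contig_ids=[c.id for c in contigs])
    unigenes = annotation.group_unigenes(annot)
    unigene_df = pd.DataFrame(
        [(unit, contig) for unit in sorted(unigenes) for contig in sorted(unigenes[unit])],
        columns=["unit_id", "contig_id"],
    )
    n_annot = _write_tsv(annot, outdir / "annotation.tsv")
    n_uni = _write_tsv(unigene_df, outdir / "unigenes.tsv")
    _manifest(
        outdir, "annotate", cfg, {"annotation.tsv": n_annot, "unigenes.tsv": n_uni}
    )


def stage_count(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "count", "counts.tsv", "contigs_qc.fasta", "annotation.tsv")
    table = quantify.CountTable.read_tsv(outdir / "counts.tsv")
    contigs = assembly_qc.read_contig_fasta(outdir / "contigs_qc.fasta")
    annot = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    contaminants = set(annot.loc[annot["contaminant"], "contig_id"])
    analysable = {c.id for c in contigs} - contaminants
    # QC-passing, non-contaminant rows only; totals stay library-wide
    filtered = quantify.CountTable(
        counts=table.counts[table.counts["contig_id"].isin(analysable)].reset_index(
            drop=True
        ),
        total_sol=table.total_sol,
        total_greg=table.total_greg,
    )
    lengths = {c.id: c.length for c in contigs}
    expr = quantify.fpkm_table(filtered, lengths)
    filtered.write_tsv(outdir / "counts_analysed.tsv")
    n_expr = _write_tsv(expr, outdir / "expression.tsv")
    _manifest(
        outdir,
        "count",
        cfg,
        {"counts_analysed.tsv": len(filtered.counts), "expression.tsv": n_expr},
    )


def stage_de(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "de", "counts_analysed.tsv", "contigs_qc.fasta")
    table = quantify.CountTable.read_tsv(outdir / "counts_analysed.tsv")
    contigs = assembly_qc.read_contig_fasta(outdir / "contigs_qc.fasta")
    lengths = {c.id: c.length for c in contigs}
    de = diffexp.call_de(table, lengths, alpha=float(cfg["alpha"]))
    de = diffexp.categorize(
        de, min_reads=int(cfg["min_reads"]), min_lfc=float(cfg["min_lfc"])
    )
    summary = diffexp.de_summary(de)
    n_de = _write_tsv(de, outdir / "de.tsv")
    _write_tsv(summary, outdir / "de_summary.tsv")
    for line in summary.itertuples(index=False):
        logger.info("de summary: %s/%s = %d", line.call, line.category, line.n)
    _manifest(outdir, "de", cfg, {"de.tsv": n_de, "de_summary.tsv": len(summary)})


def stage_go(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "go", "go_map.tsv", "de.tsv")
    go_map = pd.read_csv(outdir / "go_map.tsv", sep="\t")
    de = pd.read_csv(outdir / "de.tsv", sep="\t")
    tests = go_representation.term_representation_test(
        go_map, de, alpha=float(cfg["alpha"])
    )
    abundance = go_representation.abundance_table(go_map, de)
    n_tests = _write_tsv(tests, outdir / "go_terms.tsv")
    _write_tsv(abundance, outdir / "go_abundance.tsv")
    _manifest(
        outdir,
        "go",
        cfg,
        {"go_terms.tsv": n_tests, "go_abundance.tsv": len(abundance)},
    )


def stage_ranks(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "ranks", "expression.tsv")
    expr = pd.read_csv(outdir / "expression.tsv", sep="\t")
    fraction = float(cfg["decile_fraction"])
    reports = [
        rank_overlap.decile_report(expr, fraction=fraction, stratum=stratum)
        for stratum in ("top", "bottom")
    ]
    report_df = pd.DataFrame([r.__dict__ for r in reports])
    bins = rank_overlap.rank_concordance(expr, n_bins=int(cfg["rank_bins"]))
    _write_tsv(report_df, outdir / "decile_report.tsv")
    _write_tsv(bins, outdir / "rank_concordance.tsv")
    _manifest(
        outdir,
        "ranks",
        cfg,
        {"decile_report.tsv": len(report_df), "rank_concordance.tsv": len(bins)},
    )


def stage_compare(cfg: dict[str, Any], outdir: Path) -> None:
    """Cross-tabulate the QC'd assembly against a surrogate second assembly.

    The demo has no real second sequencing effort, so a synthetic one is
    constructed as a deterministic two-thirds subset of the QC'd contigs
    (renamed est_*) with identity reciprocal hits; the cross-tabulation
    logic is exercised end to end.
    """
    _require(outdir, "compare", "contigs_qc.fasta", "annotation.tsv")
    contigs = assembly_qc.read_contig_fasta(outdir / "contigs_qc.fasta")
    annot = pd.read_csv(outdir / "annotation.tsv", sep="\t").set_index("contig_id")
    annot_a = {
        c.id: bool(annot.loc[c.id, "tier"] != "none") if c.id in annot.index else False
        for c in contigs
    }
    b_members = [c for i, c in enumerate(sorted(contigs, key=lambda c: c.id)) if i % 3]
    annot_b = {f"est_{c.id}": annot_a[c.id] for c in b_members}
    hits_ab = pd.DataFrame(
        {
            "qseqid": [c.id for c in b_members],
            "sseqid": [f"est_{c.id}" for c in b_members],
            "evalue": 0.0,
        }
    )
    hits_ba = pd.DataFrame(
        {
            "qseqid": [f"est_{c.id}" for c in b_members],
            "sseqid": [c.id for c in b_members],
            "evalue": 0.0,
        }
    )
    table = compare_assemblies.cross_tabulate(hits_ab, hits_ba, annot_a, annot_b)
    _write_tsv(table.frame(), outdir / "assembly_overlap.tsv")
    _manifest(outdir, "compare", cfg, {"assembly_overlap.tsv": 6})


def stage_qpcr(cfg: dict[str, Any], outdir: Path) -> None:
    _require(outdir, "qpcr", "qpcr_ct.csv", "de.tsv")
    ct = pd.read_csv(outdir / "qpcr_ct.csv")
    de = pd.read_csv(outdir / "de.tsv", sep="\t").set_index("contig_id")
    qpcr_lfcs = qpcr_concordance.ddct_table(
        ct, reference_genes=set(synthetic_data.REFERENCE_GENES)
    )
    rnaseq_lfcs = {
        gene: float(de.loc[gene, "log2fc"]) for gene in qpcr_lfcs if gene in de.index
    }
    report = qpcr_concordance.concordance(
        {g: v for g, v in qpcr_lfcs.items() if g in rnaseq_lfcs}, rnaseq_lfcs
    )
    _write_tsv(report.per_gene, outdir / "qpcr_concordance.tsv")
    logger.info(
        "qpcr concordance: %d/%d genes agree", report.n_agree, report.n_total
    )
    _manifest(
        outdir, "qpcr", cfg, {"qpcr_concordance.tsv": len(report.per_gene)}
    )


STAGES: dict[str, Callable[[dict[str, Any], Path], None]] = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "annotate": stage_annotate,
    "count": stage_count,
    "de": stage_de,
    "go": stage_go,
    "ranks": stage_ranks,
    "compare": stage_compare,
    "qpcr": stage_qpcr,
}


def run_pipeline(config: dict[str, Any] | str | Path, outdir: str | Path) -> Path:
    """Run every stage in order into ``outdir``; returns the result directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stage in STAGES.items():
        start = time.perf_counter()
        try:
            stage(config, out)
        except StageError:
            raise
        except Exception as exc:  # label the failing stage
            raise StageError(name, str(exc)) from exc
        logger.info("stage %-8s finished in %.2fs", name, time.perf_counter() - start)
    return out
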