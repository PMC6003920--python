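"""Relative-expression fold changes from qPCR Ct values (delta-delta-Ct)
and direction-agreement scoring against RNA-seq fold changes.

Sign convention: the returned log2 fold change is positive when the gene
is more expressed in the gregarious sample, matching the RNA-seq
log2(FPKM_greg / FPKM_sol) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ConcordanceReport", "ddct_log2fc", "ddct_table", "concordance"]


@dataclass(frozen=True)
class ConcordanceReport:
    per_gene: pd.DataFrame  # gene, qpcr_lfc, rnaseq_lfc, agree
    n_agree: int
    n_total: int


def ddct_log2fc(measurements: pd.DataFrame, efficiency: float = 2.0) -> float:
    """Delta-delta-Ct log2 fold change for one gene.

    dCt(phase) = mean(target Cts) - mean(reference Cts), pooling all
    replicates and all reference genes (averaging reference Cts is the
    log-scale equivalent of a geometric mean of their linear quantities).
    The result is dCt(sol) - dCt(greg), scaled by log2(efficiency): one
    cycle equals one doubling at the default efficiency of 2.0 (no
    efficiency correction).  Positive output means gregarious
    over-expression: fewer target cycles in the gregarious sample.

    ``measurements`` needs columns phase ("sol"/"greg"), target_ct, ref_ct.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    phases = set(measurements["phase"])
    missing = {"sol", "greg"} - phases
    if missing:
        raise ValueError(f"measurements missing phase(s): {sorted(missing)}")
    if (measurements[["target_ct", "ref_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    dct = {}
    for phase, group in measurements.groupby("phase"):
        dct[phase] = group["target_ct"].mean() - group["ref_ct"].mean()
    return math.log2(efficiency) * (dct["sol"] - dct["greg"])


def ddct_table(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    reference_genes: set[str] | None = None,
) -> dict[str, float]:
    """Per-gene delta-delta-Ct fold changes from a long-format Ct table.

    ``ct_table`` columns: gene, phase, replicate, target_ct, ref_gene,
    ref_ct.  Genes listed in ``reference_genes`` are excluded from the
    output (they are the normalisers, not targets).
    """
    reference_genes = reference_genes or set()
    out = {}
    for gene, group in ct_table.groupby("gene", sort=True):
        if gene in reference_genes:
            continue
        out[str(gene)] = ddct_log2fc(group, efficiency=efficiency)
    return out


def concordance(
    qpcr_lfcs: Mapping[str, float], rnaseq_lfcs: Mapping[str, float]
) -> ConcordanceReport:
    """Per-gene sign agreement between qPCR and RNA-seq fold changes.

    A gene agrees when the two fold changes share a strict sign; a zero on
    either side counts as disagreement unless both are zero.  Genes must
    be present in both maps.
    """
    missing = set(qpcr_lfcs) - set(rnaseq_lfcs)
    if missing:
        raise KeyError(f"no RNA-seq fold change for gene(s) {sorted(missing)[:5]}")
    rows = []
    for gene in sorted(qpcr_lfcs):
        ql = float(qpcr_lfcs[gene])
        rl = float(rnaseq_lfcs[gene])
        agree = (np.sign(ql) == np.sign(rl)) and not (ql == 0) != (rl == 0)
        rows.append((gene, ql, rl, bool(agree)))
    per_gene = pd.DataFrame(rows, columns=["gene", "qpcr_lfc", "rnaseq_lfc", "agree"])
    return ConcordanceReport(
        per_gene=per_gene,
        n_agree=int(per_gene["agree"].sum()),
        n_total=len(per_gene),
    )
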