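# Methods

## The analysis being modelled

Two pooled mRNA libraries — one from solitarious, one from gregarious
locust CNS-enriched tissue, with no biological replicates — are aligned to
a de novo transcriptome assembly, fragments are counted per contig, and
each contig is tested for a phase difference in its share of the library.
`locustde` implements every computational stage of that design at desk
scale; the sequencing, alignment and BLAST searches themselves are out of
scope (their outputs are consumed as tabular inputs, their filtering and
counting logic is re-implemented).

## The replicate-free test and its assumptions

For contig *i* with counts c₁, c₂ and library-wide mapped totals T₁, T₂,
the 2×2 table [[c₁, T₁−c₁], [c₂, T₂−c₂]] is scored with the Pearson
chi-squared statistic (1 df, no continuity correction by default; a Yates
flag exists).  The statistic is computed from the closed determinant form
N(ad−bc)²/(r₁r₂s₁s₂); the upper-tail p-value comes from
`scipy.stats.chi2`.  Assumptions and consequences:

- **Sampling-only variance.**  With one library per condition, the test
  can only see Poisson-level sampling noise.  Any between-animal or
  between-pool variability inflates the false-positive rate; this is an
  inherent property of the design, not of the implementation.
- **Compositionality.**  The test compares library shares.  When many
  transcripts are strongly over-expressed on one side, every other
  transcript's share of that library shrinks, producing significant calls
  in the opposite direction.  The synthetic demo reproduces this visibly
  (see README); the planted-truth direction agreement is still 100% among
  true positives.
- **Low counts.**  Expected cells below 5 violate the chi-squared
  approximation.  Such rows are still tested (matching the evident
  spreadsheet practice being modelled) but carry a `low_count` flag.
  Both counts zero is degenerate: χ² = 0, p = 1, and the row still enters
  the BH correction.

BH-FDR is the standard step-up, q₍ᵢ₎ = min over the rank tail of
p₍ⱼ₎·n/j capped at 1, applied across all tested contigs in one run.
Calls at q ≤ α (α = 0.05 by default; the analysis being modelled never
states its threshold, so it is configurable) are split by fold-change
sign; log₂(FPKM_greg/FPKM_sol) uses the convention ±∞ for one-sided
zeros and 0 (flagged degenerate) for 0/0.  Significant calls per phase
are partitioned into `absent_other` (>10 reads, other phase 0),
`high_fold` (>10 reads, |log₂FC| > 1) and `remainder`; "over 1 fold
increase" is read as |log₂FC| > 1 (ratio > 2) — the alternative reading
(ratio > 1) is possible but would make `high_fold` nearly coextensive
with significance, so the stricter reading was chosen.

## K-mer safety mathematics

A k-mer word seen once re-occurs by chance in a single equiprobable-base
window with probability 4⁻ᵏ, and in n sliding windows with probability
1 − (1 − 4⁻ᵏ)ⁿ (computed via `expm1`/`log1p` for numerical stability).
For k = 19 the single-window probability is 3.638·10⁻¹², and across the
8.2·10⁹ windows of a 100-million-read library plus reverse complement the
re-occurrence probability is ≈ 2.9%, under the 6% bound that justifies 19
as the smallest safe assembly word size.  `min_safe_kmer` scans odd k
upward against a threshold; `kmer_sweep` produces the descending odd
series from round(0.95 × read length) down to k_min (39 values for
101-base reads and k_min = 19).  Odd-only words avoid palindromic k-mers;
an even k is computed with a warning.

## Contig QC, clustering and merging

- **Filter:** length < 75 bases removes unconditionally (a shorter contig
  is most likely supported by less than one full-quality read); read
  support < 4 removes unless the contig has a significant homology hit.
  The filter partitions its input and is idempotent on the kept set.
- **Identity:** for clustering, identity = (shorter length − edit
  distance)/shorter length, with the shorter sequence aligned end-to-end
  against the best infix of the longer (exact dynamic programming via
  edlib).  A contained duplicate therefore scores 1.0.  A shared-14-mer
  prefilter (valid by pigeonhole for ≥95% identity at shorter length ≥75)
  skips hopeless pairs.
- **Clustering:** greedy, by descending length then ascending id; each
  contig joins the first representative at ≥95% identity or founds a
  cluster.  Representatives map to themselves, so clustering is
  idempotent.
- **Merging:** repeated greedy joining of suffix–prefix overlaps ≥16
  bases at ≥95% identity, ungapped within the overlap.  Overlaps of 16–32
  bases are scanned exhaustively; longer overlaps are located by exact
  shared 12-mer anchors (any ≥33-base overlap at ≥95% identity must
  contain one, again by pigeonhole).  Merged contigs keep the upstream id
  and the summed read support; total read support is conserved.
- **N50:** the length L at which the descending-length cumulative sum
  first reaches half the total bases.

Tie-breaking everywhere is (descending length, ascending id) for
reproducibility.

## Annotation triage

Hits arrive as standard 12-column tabular rows plus a database tag
(`insect_protein`, `nr`, `nt`) and a taxon group.  The cascade searches
the curated insect-protein database first, then nr, then nt; the first
database with a hit at e ≤ 10⁻⁶ wins, and within it the best hit is
lowest e-value, ties by highest bit-score then ascending subject id.
Contaminants are protein hits to non-animal subjects or nucleotide hits
to non-arthropod subjects.  Non-contaminant annotated contigs group into
unigenes by shared best-hit subject; tier-none contigs stay as singleton
non-annotated units.  Taxon group is an input column: resolving taxonomy
from live databases is out of scope.

## Counting and FPKM

SAM fragment counting ignores unmapped/secondary/supplementary records
and counts one increment per fragment (read 2 of a pair is skipped).  The
default policy is primary-only; an `expanded` policy also credits XA-tag
alternative hits, in which case summed counts exceed fragment counts —
provided because the pipeline being modelled used that expansion.
Library totals used for FPKM and the chi-squared test are the counted
mapped fragments of each full library (not raw reads), recorded in the
count-table header; row filtering downstream never changes them.

## GO representation and rank structure

GO terms are compared only **between the two DE sets** (in-term vs
not-in-term × sol-over vs greg-over, same chi-squared, BH across terms) —
no genome background exists for this species, so classical enrichment is
deliberately absent.  Multi-term units count once per term; an optional
GO-level filter restricts depth.

Decile analysis selects the top or bottom ceil(0.10·N) genes per library
by that library's FPKM (stable sort, ties by id), intersects the two id
sets, and compares the shared genes' expression with a classical paired t
(df = n−1; degenerate zero-variance cases return ±∞/0 or 0/1).  Rank
concordance bins genes by one library's expression quantiles and computes
within-bin Spearman correlation between libraries.  Binning follows one
library rather than the two-library mean because conditioning on the mean
forces a spurious negative within-bin correlation (a fixed sum trades
off); with one-library binning, independent libraries give ≈0 and
Poisson-like noise gives correlation rising with expression, as expected.

## Cross-assembly comparison

Two assemblies are compared through reciprocal tabular hits at e ≤ 10⁻⁶.
A unit is "shared" when it has a passing hit in at least one direction
(union; an intersection mode is available).  The six-cell table counts
the shared cell on each side (an A-unit count and a B-unit count) so that
each assembly's universe is exactly reconstructed per annotation class,
and swapping the assemblies transposes the table.  Unit granularity
(contig vs unigene) is the caller's choice of input maps.

## ΔΔCt qPCR concordance

ΔCt(phase) = mean(target Cts) − mean(reference Cts), pooling replicates
and both reference genes (averaging reference Cts on the log scale equals
a geometric mean of linear quantities).  The reported log₂ fold change is
log₂(E)·(ΔCt_sol − ΔCt_greg) with amplification efficiency E = 2.0 by
default (no efficiency correction — standard curves are out of scope).
Positive output means gregarious over-expression, matching the RNA-seq
sign convention.  Direction agreement counts strict sign matches; a zero
on one side only is a disagreement.

## Synthetic data: what it emulates and what it does not

The generator plants a per-transcript truth (baseline mean, DE flag,
log₂ fold change) and derives every pipeline input from it.  Defaults are
the study conditions: 48% DE, 90% of DE toward the gregarious side,
solitarious library 25% deeper (1.25·10⁶ vs 10⁶ fragments), GC 40%,
~30% non-annotated and ~5% contaminant contigs, lognormal baseline
expression (ln-scale μ = 3, σ = 1.5 on a fragments-per-million scale —
no expression distribution is stated for the original data, so a
right-skewed law typical of bulk RNA-seq was chosen), |log₂FC| ~
N(2.0, 0.5) clipped at 0.25, contig lengths lognormal (μ = 6.8, σ = 0.7,
floored at 75).  Counts are drawn per library as Poisson with expectation
lib_size × (transcript's share of that library's total expression), or
gamma-Poisson when `dispersion` > 0; the default 0 matches the sampling
model the chi-squared test itself assumes.  Sequences place an exact
round(GC·length) count of G/C bases at random positions so realized
composition tracks the target even at small n.

Not emulated: sequencing errors, quality strings, paired-end inserts,
isoform structure, genuine biological replicate variance, and real
homology structure (subjects are an abstract pool).  Passing tests
therefore demonstrate that the *computations* recover planted truth under
the stated sampling model — they do not certify calibration on real
replicate-free data, where extra-Poisson variance makes the test
anti-conservative (see above).

Calibration experiments (type-I error, power) use a dedicated
flat-expression truth (`calibration_truth`, constant base mean 50) so
every 2×2 table has healthy expected cells: 2000 transcripts and 10⁶
fragments per library give raw p < 0.05 at 5.0% ± 0.5 across seeds, ~0
BH calls under the null, and ≥95% sensitivity with 100% direction
agreement for planted log₂FC = 2.

## Pipeline and determinism

Stages run in method order (simulate → qc → annotate → count → de → go →
ranks → compare → qpcr); each writes TSVs plus a JSON manifest (seed,
parameters, row counts; keys sorted, no timestamps).  All randomness
derives from the single config seed through named substreams, floats are
serialised with a fixed format, and stage timings go only to the console
logger, so re-running a config is byte-identical.  The `compare` stage
constructs a deterministic surrogate second assembly (a two-thirds subset
with identity reciprocal hits) because the demo has no second sequencing
effort; it exercises the cross-tabulation logic, not a scientific claim.
The demo configuration (300 transcripts, 2.5·10⁵/2·10⁵ fragments) keeps
the full run under a few seconds; statistical checks use the 2000 ×
10⁶-fragment calibration scale.

## Known limitations

- The clustering identity is edit-distance-based; a match-maximising
  alignment could score marginal pairs slightly differently near the 95%
  boundary.
- Overlap merging is ungapped inside the overlap; an indel within a true
  overlap prevents the merge (CAP3 proper would align through it).
- The qPCR model is noise-additive on Ct with fixed efficiency; no
  standard-curve calibration or inter-plate effects.
- Headline counts of the original study (117309 valid contigs, 24770 DE,
  its t statistics and Table cells) depend on the real libraries and live
  BLAST databases and are not reproducible at this scale; the package
  validates the arithmetic and the algorithms, not those numbers.
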