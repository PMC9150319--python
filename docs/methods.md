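# Methods

## Scope and data model

`mesokit` is the classification layer of an MPM whole-genome /
transcriptome cohort analysis.  It deliberately consumes the outputs of
standard upstream tools rather than re-implementing them: allele-specific
copy-number segments (ASCAT-style TSV, 1-based inclusive coordinates),
somatic SNV VCFs plus a reference FASTA, per-position base pileups,
gene×sample TPM matrices, neoantigen tables with predicted IC50 and RNA
read support, per-gene q-value tables from three significantly-mutated-
gene (SMG) tools, an HRDetect probability column, and clinical tables.
All genome fractions are computed over the covered length of a declared
`GenomeSpec` (the uncovered genome is excluded from denominators; a
`over="genome"` flag switches to full-genome denominators).

## Classification rules

**Ploidy and WGD.** Ploidy is the length-weighted mean total copy
number.  A sample is whole-genome doubled iff ploidy > 2.7 and the
covered-genome fraction at total copy number 3–6 with minor allele ≥ 1
is > 0.5; both inequalities are strict, so boundary profiles are not
called.  An alternative preset (`call_wgd_cna_preset`: CNA fraction >
0.9 and CN 3–6 heterozygous fraction > 0.7) is exposed but not default;
the two criteria circulate in the literature describing the same cohort
and the ploidy-based form is taken as canonical.

**LOH, near-haploidization, CNA.** LOH is minor copy 0 with ≥ 1 copy
retained (homozygous deletion is a deletion, not LOH).  Near-haploid
means LOH fraction > 0.7 — the threshold is a package judgement call (the
motivating case had LOH over ~80% of its genome; no numeric threshold is
published).  The CNA fraction counts any segment whose total differs
from 2 *or* which is copy-neutral LOH, since allelic loss is an
alteration even at neutral total copy number.

**Signature refitting.** SBS96 catalogues use the standard pyrimidine-
strand channel set; purine-reference variants are reverse-complemented
(checked in tests against an independent 192→96 fold).  Exposures are
non-negative least squares fits (`scipy.optimize.nnls`).  The 10%
relative-exposure cutoff is applied iteratively: while any retained
signature holds strictly less than 10% of the fitted mass, the weakest
is dropped and the remainder refit.  A signature at exactly 10% is kept.
A one-shot variant (zero all sub-cutoff signatures, refit once) is
available behind a flag; the iterative form is the default because a
single published cutoff number does not determine the procedure and
iterative refitting is the more conservative reading.  Because SBS5 and
SBS40 are flat and mutually similar, their individual split is
unstable; dominance is therefore always assessed on their combined mass
(> 0.5, strict).

**HRD scars.** HRD-LOH counts LOH segments longer than 15 Mb not
spanning a whole chromosome; TAI counts allelic-imbalance segments
reaching a chromosome end without overlapping the centromere interval;
LST counts breakpoints between adjacent ≥ 10 Mb segments after removing
fragments < 3 Mb and merging equal-state neighbours.  These constants
follow the scar-score literature (the combined thresholds, HRD-sum > 42
with HRDetect > 0.7, are the published classification rule); all are
configurable, and `HrdConstants.scaled(f)` rescales the length
thresholds for linearly rescaled genomes.  The HRDetect probability is
an input column: its trained model is out of scope, the dual-threshold
rule is what is implemented.

**TERT promoter.** Five hotspot positions on chr5 are assessed, each
with its expected alternate base; the mutant allele fraction is the
expected-alternate count over total depth (other non-reference bases do
not count toward the call), and a site is mutant if MAF > 0.10, strict.
Zero-depth sites are reported unassessable rather than wild-type.  The
site table stores the substitution letters exactly as printed in the
source material (coding-strand letters at genomic coordinates).

**Immune profile.** The cytolytic score is the geometric mean of GZMA
and PRF1 TPM with a 0.01 offset.  Deconvolution is a transparent NNLS
mixture fit against a pluggable cell-type reference matrix — a
documented stand-in for CIBERSORT's ν-SVR, whose trained machinery is
out of scope.  Significance follows the permutation idea: the observed
statistic is the Pearson correlation between the NNLS reconstruction
and the input over the shared genes; the null permutes the gene labels
of the input 100 times and refits; p = (1 + #{null ≥ obs})/(n_perm+1).
Hot/cold grouping is average-linkage hierarchical clustering on
Euclidean distance of log2(TPM+1) over a configurable checkpoint panel
(VSIR, CD276, PDCD1, CTLA4, CD274, LAG3, HAVCR2, TIGIT; the first two
are explicitly reported cohort observations, the rest complete the
canonical panel), cut at k = 2, with the higher-mean-cytolytic group
labelled hot; identical inputs yield a degenerate single-group result,
flagged as such.  Marker–fraction correlations are Pearson r of
log2(TPM+1) vs deconvolved fractions over samples with deconvolution
p < 0.05, flagged significant at p < 0.001; constant inputs report
missing rather than zero correlation.

**Cohort statistics.** Driver consensus: a gene is included when at
least two tools report q (or FDR) strictly below 0.05, or when it is in
the exception set (default {PBRM1}) and at least one tool does.  The
vote threshold of two follows the results-level narrative (the methods
prose reads "more than two tools", which conflicts; two is the reading
consistent with the reported seven-gene list plus PBRM1).  Kaplan–Meier
and log-rank computations are delegated to `lifelines` and are checked
in tests against hand product-limit and Mantel–Cox O/E/V computations.
Wilcoxon comparisons use the exact rank-sum null for groups of ≤ 10
without ties (verified against full enumeration) and the
continuity-corrected normal approximation otherwise.  Quantile
stratification uses stable ranks, ties falling to the lower stratum,
strata sizes differing by at most one.

## Synthetic cohort generator

The generator emulates every input listed above with recorded ground
truth.  Its defaults are the study conditions: 58 samples, 17 WGD, 3
TERT-promoter mutant, 54 SBS5/40-dominant (combined truth mass 0.65
dominant / 0.20 background), 2 HR-deficient, 5 CD8-high/hot, one
near-haploid case (LOH target 0.8), ~3,000 SNVs per sample, WGD hazard
ratio 2.5 on exponential survival with baseline hazard 1/400 per day and
20% independent uniform censoring.  Counts the source states directly
(58/17/3/54) are taken as given; the remainder (HR-deficient count,
CD8-high count, hazard ratio, mutation count, noise levels) are chosen
once as realistic for this tumour type: HR deficiency is reported as
infrequent (two well-characterised cases), the hot subset is "< 10%" of
samples, and MPM carries a modest mutation burden (~1.2/Mb over a
desk-scale genome).

Design choices worth noting:

* **Toy genome.** 22 autosomes at 1/100 GRCh37 length (≈ 28.8 Mb total)
  with proportionally placed centromeres.  All fractions are scale-free;
  HRD length constants are rescaled by the recorded `genome_scale` in
  the cohort `meta.json`.  The full-size genome is available via
  `grch37_autosomes(scale=1.0)`.
* **CN profiles.** WGD profiles tile the genome with heterozygous-gain
  states (total 4–6, minor ≥ 1) plus 2+0 LOH blocks; non-WGD profiles
  use 1+1/1+0.  This guarantees the generated profile falls on the
  requested side of the WGD rule for any admissible LOH target; WGD with
  LOH target > 0.45 is rejected as unconstructible (the heterozygous-gain
  majority and the LOH fraction compete for the same genome).  Achieved
  LOH is within ±0.05 of target (per-chromosome jitter ±0.03).
  HR-deficient samples instead use a scar layout: 20 interstitial LOH
  segments of twice the HRD-LOH length floor separated by long balanced
  spacers, which guarantees HRD-sum > 42 by construction.
* **Variants.** Catalogues are multinomial draws from S·e; concrete SNVs
  realising each channel are placed without replacement on a random
  120 kb reference contig via a precomputed trinucleotide site index, so
  rebuilding the catalogue from the written VCF + FASTA is exact.
* **Expression.** Columns are noiseless mixtures `ref · fractions` with
  optional per-gene boosts and multiplicative log-normal noise
  (sd 0.1 by default).  Hot samples pin CD8 at 0.30 and boost the
  checkpoint panel 32× (≈ 5 log2 units), which separates the clusters;
  cold samples cap CD8 at 0.15.  The checkpoint boost is deliberately
  outside the mixture model (a hot tumour expresses checkpoints beyond
  its cell-type composition), so deconvolved fractions for hot samples
  are approximate while all truth *labels* (CD8-high, hot/cold) remain
  exactly recoverable; noise-free cold samples deconvolve exactly.
* **Determinism.** All randomness flows through `SeedSequence` children
  of one root seed; identical config reproduces byte-identical files.
  Generation writes to a temporary directory renamed into place, so a
  failure leaves no partial output.

What the generator does not emulate: read-level error profiles, caller
artefacts, subclonality and purity, segmentation noise, batch effects in
expression, indel/SV signature channels, and real LM22-style collinear
cell-type references.  Passing tests therefore demonstrate that the
classification rules are implemented correctly and are mutually
consistent with the generator's idealised data, not that the rules are
robust to real-data noise.

## Numerical choices and problem sizes

Strict inequalities everywhere a published rule states one; boundary
tests pin them.  NNLS solutions are accepted as returned by
`scipy.optimize.nnls` (non-negativity clipped at −1e-9 tolerance).
Dominance at an exactly-0.5 fitted boundary is numerically ill-posed
through a float refit, so boundary semantics are defined (and tested) on
exact exposure vectors.  The permutation p-value has resolution
1/(n_perm+1) and can never be 0.  Test and analysis problem sizes — 58
samples × 3,000 mutations, 120 kb contig, 100 permutations, 1,000 null
cohorts of 100 subjects for the log-rank calibration — keep the complete
suite in the tens of seconds on one CPU while leaving every estimate's
sampling error well inside the asserted tolerances.

## Known limitations

The deconvolution stand-in is NNLS, not ν-SVR: with highly collinear
references its fractions will differ from CIBERSORT's.  The SBS5/SBS40
split is not identifiable by design and only their sum is interpreted.
The HRD scar constants follow the cited scar-score conventions but the
exact upstream implementation variant (and its ploidy correction) is not
reproduced.  The indel (83-channel) and SV catalogues are supported only
as generic channel sets supplied by the user; the channel classifiers
themselves are not implemented.  Telomere-motif counting uses canonical
motif runs (≥ 2 copies, both strands) rather than the staged heuristics
of dedicated telomere tools.
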