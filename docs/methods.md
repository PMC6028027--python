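# Methods

## PSI from junction reads

A skipped-exon (SE) event is supported by three junctions: two inclusion
junctions (upstream exon → cassette, cassette → downstream exon) and one
skipping junction (upstream → downstream).  An including transcript
contributes reads to both inclusion junctions while a skipping transcript
contributes to one junction, so the event estimator doubles the skip
count:

    Ψ = (inc_up + inc_down) / (inc_up + inc_down + 2·skip)

Length normalization cancels because only junction-spanning reads are
counted.  A cell is *missing* (NaN), not zero, when the informative total
`inc_up + inc_down + skip` falls below `min_coverage` (default 10 reads):
reporting 0 there would manufacture confidently-excluded exons out of
thin coverage.  The per-junction quantification ("both orientations")
divides each junction's count by the summed counts of all junctions
sharing its donor site, and separately its acceptor site.

Coordinates: STAR `SJ.out.tab` rows are 1-based inclusive intron spans,
BED is 0-based half-open, GTF 1-based inclusive; everything is normalized
to 0-based half-open on read.  Junctions with unknown strand are matched
by coordinates alone.  An event none of whose junctions appear anywhere
in a cohort's table is dropped with a diagnostic; a junction present in
the table but absent for one sample is an observed zero for that sample,
because aligners omit zero-read junctions.

## The synthetic study

All validation runs on generated data with planted truth.  The generative
model for a responsive event e in sample s is

    logit(Ψ_es) = α_e + β_e·z_s + ε_es,   ε ~ N(0, σ)

where z_s is the standardized log expression of the regulator (raw
expression is lognormal, so z is exactly standard normal and decile
membership is unchanged by the log), α_e ~ U(−1.5, 1.5), and σ = 0.4 —
a deliberately heterogeneous, tumour-cohort-level noise.  Non-responsive
events have β = 0.  Junction coverage per event-sample is
negative-binomial (mean 50, size 5); reads split multinomially over
(inc_up, inc_down, skip) with probabilities (Ψ, Ψ, 1−Ψ)/(1+Ψ), the read
budget implied by two inclusion junctions per including isoform and one
junction per skipping isoform.  Under this split the 2·skip estimator is
consistent: substituting expectations returns exactly Ψ.

Planted effect sizes are exact by construction: unless a fixed logit
shift is supplied, each responsive event's β is solved (Gauss–Legendre ×
Gauss–Hermite quadrature plus Brent root-finding) so that the *analytic*
top-vs-bottom-decile contrast E[Ψ | z in top 10%] − E[Ψ | z in bottom
10%] equals ±0.35, the planted contrast of the default study.  For
two-condition experiments the planted quantity is the direct PSI shift
(default conditions: three replicates per condition; responsive-event
baselines are clamped so the shift fits inside (0, 1)).

miRNA expression is built as r·z + √(1−r²)·noise on the log scale, so
the sample Pearson correlation with the regulator is centred on the
target r (default −0.6; the target-evidence studies use −0.8).  In the
target-evidence generator, planted targets pass every evidence source;
decoys draw each source at ~50% and are forced to fail at least one, and
decoy correlations, where present, are shrunk to 0.7·r so no decoy can
out-rank a planted target on the tie-break (most negative mean clinical
r).

CLIP peaks for responsive events are placed by binding side: exons the
regulator *skips* get peaks with summits within 100 nt upstream of the
cassette 3' splice site; exons it *includes* get peaks within the first
100 nt of the downstream intron — mirrored for minus-strand genes — each
carrying the ACUAAC motif at its summit; background peaks are uniform
over the simulated span with random sequence.  What the generator does
**not** emulate: read-level data, alignment artifacts, sequence realism
beyond the motif, correlated events within genes, batch effects, or
cohort-specific coverage structure.  Recovery on these simulations
therefore demonstrates the estimators' correctness under their assumed
model, not performance on real libraries.

## Decile contrast and cross-cancer matrix

The cohort is split at the top and bottom `floor(0.10·n)` samples by
regulator expression (ties broken by sample id, so the split is
deterministic and disjoint).  Per event, ΔΨ is the difference of group
means over non-missing Ψ; significance is a two-sided Mann–Whitney U on
per-sample Ψ — the test is deliberately rank-based because Ψ is bounded
and non-normal — with BH q-values across events, skipping events with
fewer than 10 measured samples in either decile.  The cross-cancer
matrix keeps cohorts with ≥ 450 samples and events that are measured in
every retained cohort (non-missing ΔΨ, and Ψ coverage in ≥ 80% of each
cohort's samples — the operationalization of "constitutively expressed")
with max |ΔΨ| ≥ 0.35 in at least one cohort; rows/columns are ordered by
agglomerative clustering (Euclidean distance, average linkage; both
configurable, and the matrix is label-sorted first so input order is
irrelevant).

## Differential exon inclusion

Per event, replicate r contributes successes k_r = inc_up + inc_down of
trials n_r = k_r + 2·skip_r.  The model is beta-binomial with
condition-specific mean inclusion μ_A, μ_B and one per-event precision
s (overdispersion φ = 1/s, floored at 1e−6) shared across conditions;
all parameters fit by Nelder–Mead maximum likelihood from two starts
(the log-likelihood is written directly with `gammaln`; agreement with
`scipy.stats.betabinom` is asserted in the tests).  The test is the
likelihood ratio of μ_A = μ_B.

With three replicates per condition the χ²(1) reference is markedly
anticonservative (measured type-I ≈ 0.11 at α = 0.05 on overdispersed
nulls) because the dispersion MLE from six observations is biased low.
The default therefore refers the statistic to **F(1, m_A + m_B − 1)** —
the null-model residual degrees of freedom, in the spirit of
quasi-likelihood F-tests for overdispersed counts.  Measured type-I on
simulated overdispersed 3v3 nulls (coverage 100, logit noise 0.4; 8000
events across seeds) is ≈ 0.045; with the alternative convention
df = m_A+m_B−2 it is ≈ 0.030, and the raw χ² ≈ 0.11, which settled the
choice.  At low coverage (binomial noise dominant) the F reference is
conservative (≈ 0.02), never anticonservative.  With one replicate per
condition the test degenerates to a χ² on the pooled 2×2 table.  Calls
use |ΔΨ| ≥ 5% and BH-FDR ≤ 0.05; the stringent set additionally requires
|ΔΨ| > 20%.

Rank integration accepts any set of ordered event lists (they may come
from external programs' result files); each method contributes the
event's 1-based rank, an event absent from a list is penalized with
rank = list length + 1 (the mildest penalty consistent with "not
detected"), and events are ordered by rank sum, ties broken by number of
supporting methods, then id.  The exact weighting of multi-program
integration is an open design point; the rank-sum scheme is this
package's documented choice.

## CLIP splicing map

The map coordinate system concatenates, in transcript orientation:
upstream exon body (50 bins) | upstream-intron 5' flank (250 nt) |
upstream-intron 3' flank (250 nt) | cassette body (50 bins) |
downstream-intron 5' flank | downstream-intron 3' flank | downstream
exon body — 1150 positions; flanks are anchored at the splice sites and
zero-padded when an intron is shorter than 2×250 nt, exon bodies are
rescaled by linear interpolation, and minus-strand events are mirrored.
A peak contributes its height over every base it covers (plateau model),
not a point mass at the summit.  Group profiles are per-position means
over events; enrichment versus the background group (spliced but not
differentially spliced exons) is a one-sided Mann–Whitney U per position
with no correction across positions — the profile is descriptive, and
this is stated in the output.  Backgrounds under 5 events, or groups of
one event, set a low-confidence flag.  Motif enrichment is a one-sided
Fisher exact test on hit/no-hit counts for a supplied IUPAC motif
(default ACUAAC; de novo discovery is out of scope); the positional
profile histograms motif starts relative to the summit on the sense
strand with the reverse complement as empirical background.  Region
annotation assigns each peak by its summit with precedence
CDS > UTR > ncRNA > intron > intergenic.

## Target ranking

Per clinical cohort, per-gene Pearson r against the miRNA with the exact
t-based two-sided p (identical to `scipy.stats.pearsonr`; zero-variance
genes skipped with a diagnostic) and BH q across genes.  A cohort counts
as evidence when q ≤ 0.05 and r < 0.  Experimental evidence: linear fold
changes filtered directionally (MDCK EMT up > 1.5, HMLE EMT up > 1.3,
miR-200 transfection down > 1.5, i.e. fold < 1/1.5), plus pass-through
seed-site and Ago-CLIP flags.  Genes are ranked by the number of
satisfied sources, ties by most negative mean clinical r, then id.  The
recurrence score is deliberately transparent — the fraction of cohorts
significantly negative — and is labelled REC-surrogate in outputs: full
recurrence machinery with per-dataset regression corrections is out of
scope.

## Validation studies and their conditions

`qkisplice.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) fixes these problem sizes, chosen to finish in
minutes on one CPU while leaving no ambiguity about what passed:

| study | conditions | guarantee |
|---|---|---|
| PSI oracle | all count triples 0–20 (9261) | exact match, Ψ ∈ [0,1] |
| decile recovery | 500×200, 50 planted at ΔΨ=0.35, cov 50, 5 seeds | sensitivity ≥ 90%, FDP ≤ 10% |
| cohort null | β=0, 1000 events | q<0.05 fraction ≤ 0.05 + 2·SE |
| test calibration | 2000 overdispersed null events, 3v3, cov 100 | type-I ∈ [0.03, 0.07] |
| cross-cancer audit | 3 cohorts × 60 events | zero filter violations |
| map directionality | 10 seeds, 12+12 planted sides | planted window hit ≥ 9/10 per direction |
| target ranking | 20 seeds × 1000 genes | planted target first in ≥ 99% |
| BH oracle | all sorted p-lists ≤ 6 on the 0.05 grid (230k) | exact match |
| determinism | pipeline twice, same seed | byte-identical bundles |

## Known limitations

* Only skipped-exon events are modelled; alternative 5'/3' splice sites,
  retained introns and mutually exclusive exons are out of scope.
* One noise knob: the logit noise conflates inter-sample heterogeneity
  and replicate variability.  At the cohort-level default (0.4) a 3v3
  replicated design only resolves the strongest effects at FDR 0.05;
  the replicated-experiment driver uses 0.15, the regime of clonal
  cell-line replicates.  Neither value is calibrated to any real cohort.
* The beta-binomial F reference is a small-sample calibration validated
  on this generator's nulls; heavy-tailed real replicate structure could
  shift its type-I error.
* The splicing-map enrichment is per-position and uncorrected by design;
  it supports the figure-style profile, not positionwise inference.
* Real-data ingestion covers STAR junctions, BED peaks, GTF annotation
  and TSV matrices; BAM/FASTQ processing, peak calling and alignment are
  explicitly not part of the package.
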