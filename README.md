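# qkisplice

Junction-based analysis of alternative splicing controlled by an
RNA-binding regulator, built around the QKI / miR-200 axis in
epithelial–mesenchymal transition (EMT) and carcinomas: the epithelial
miRNAs miR-200c/miR-375 repress the splicing factor QKI, and QKI-5 in
turn drives a program of cassette-exon (skipped-exon, SE) splicing whose
footprint is visible across tumour cohorts.

The package is written for computational biologists who want to run, or
stress-test, the building blocks of such an analysis on data with known
ground truth:

* **PSI quantification** from splice-junction read counts
  (STAR `SJ.out.tab` dialect), both per SE event,
  `Ψ = (inc_up + inc_down) / (inc_up + inc_down + 2·skip)`,
  and per junction in both orientations (shared-donor and shared-acceptor
  usage fractions).
* **Expression-decile contrasts**: ΔΨ between the top and bottom 10% of
  samples ranked by regulator expression, Mann–Whitney significance,
  BH-FDR, per-gene best events, a cross-cancer ΔΨ matrix (events measured
  in every cohort, max |ΔΨ| ≥ 35% in at least one, cohorts of ≥ 450
  samples) and its unsupervised clustering.
* **Differential exon inclusion** between replicated conditions: a
  beta-binomial likelihood-ratio test with shared per-event
  overdispersion, an F(1, m_A+m_B−1) small-sample reference, calls at
  |ΔΨ| ≥ 5% / FDR ≤ 0.05 with a ΔΨ > 20% stringent set, rank-sum
  integration across methods, and evidence-set intersections.
* **CLIP splicing maps**: per-nucleotide peak-height profiles around
  regulated exons versus non-regulated background exons with one-sided
  rank-test enrichment, ACUAAC motif enrichment and summit-relative
  positioning, and genomic-region annotation of peaks.
* **miRNA target ranking**: Pearson anti-correlation across clinical
  cohorts, directional fold-change filters (up > 1.5× MDCK EMT,
  up > 1.3× HMLE EMT, down > 1.5× on miR-200 transfection), seed-site and
  Ago-CLIP flags, consistency ranking and a cross-cohort REC-surrogate
  recurrence score.
* A **synthetic-data generator** that emulates the statistical structure
  of all of the above with planted ground truth (logit-linear link from
  regulator expression to Ψ, negative-binomial junction coverage with a
  multinomial read split, direction-specific CLIP peak placement with the
  ACUAAC motif at summits, multi-source target evidence).

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
cohorts and write tables under `results/`.

```bash
python analysis/01_simulate_cohorts.py --seed 0
python analysis/02_decile_contrast.py
```

which prints (seed 0):

```
cancer1: 51 events at q<0.05; recovered 50/50 planted with correct sign
...
cancer7: 53 events at q<0.05; recovered 50/50 planted with correct sign
cross-cancer matrix: 111 events retained of 200 (89 filtered)
```

Each simulated cohort has 500 samples and 200 SE events, 50 of which
respond to regulator expression with a planted top-vs-bottom-decile
contrast of |ΔΨ| = 0.35; the decile analysis recovers all 50 per cohort
with one to three extra calls, and the cross-cancer filter keeps the 111
events that are measured everywhere and reach |ΔΨ| ≥ 0.35 in at least
one cohort (responsive sets differ between cohorts, as in real cancers).

```bash
python analysis/03_emt_differential.py
python analysis/04_clip_splicing_map.py --plot
python analysis/05_target_ranking.py
```

```
called: 42 (sensitivity 0.84, false calls 0); stringent: 42
rank integration: 10/10 of the top 10 are planted events
regulator_skipped: n=25, max enrichment at window position 524 (3'ss at 550, ...)
regulator_included: n=25, max enrichment at window position 613 (... downstream intron (600, 1100))
ACUAAC in 100% of peaks vs 0.3% of background (Fisher p = 1.83e-103)
planted target QKI ranks 1 of 1000
REC-surrogate for QKI: 1.00 (3/3 cohorts significantly negative)
```

The splicing map recovers the planted directionality: maximal enrichment
for regulator-skipped exons 26 nt upstream of the cassette 3' splice
site (window position 524 against the 3'ss at 550), and for
regulator-included exons inside the downstream intron.

A single-command end-to-end run with a manifest:

```bash
qki-splice run --simulate --seed 7 --small --outdir results/run
```

Two runs with the same seed produce byte-identical bundles.

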