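# Methods

## Scope and model overview

The package implements the two statistics at the core of compound-vs-PPI
studies — bead-proximity interaction quantitation and peak-to-TSS proximity
enrichment — plus consensus-motif over-representation, and a synthetic-data
layer that generates every input with planted effect sizes so the whole
pipeline is testable without external data.

## Bead-proximity quantitation

A titration of lysate expressing a tagged protein pair produces a unimodal
"hook-effect" curve: signal rises with analyte concentration until the bead
capture saturates, then falls. We summarise a series by the maximum of
per-step replicate means (`TitrationSeries.top`). Using the per-step mean
rather than the single brightest well damps outlier wells; the choice is
configurable in effect because callers may pass any aggregate they prefer.

* **Binding Index** `BI = (I − I_neg)/(I_ref − I_neg) × 100` normalises the
  background-subtracted top signal to a reference pair measured on the same
  grid. BI is exactly invariant under common positive rescaling of all
  signals (tested). The interaction call threshold is a convention — such
  thresholds are typically shown only graphically — and defaults to BI ≥ 20
  with the tie going to "interactor"; it is configurable and recorded in
  every CLI output.
* **Disruption** `(1 − I_compound/I_vehicle) × 100` at a single compound
  concentration, computed on replicate means (≥ 3 replicates in all
  generators). The disruption-call threshold defaults to 25%, configurable.
  Percent interaction is its complement; the two always sum to 100.
* **Dose–response**: the three-parameter log-logistic inhibition model
  `y = bottom + (top − bottom)/(1 + x/IC50)` with Hill slope fixed at 1 —
  "three-parameter" in the sense of standard curve-fitting software, where
  the slope is pinned to unity and top/bottom/IC50 are free. A free-slope
  four-parameter variant is available (`fit(fix_hill=False)`) as a
  sensitivity analysis. The fit is `scipy.optimize.curve_fit` least squares
  with the IC50 parameterised on the natural-log scale (keeps it positive
  and conditions the 0.3–300 µM range); starting values come from the data
  extremes and the concentration nearest half-maximal response.
  Non-convergence is reported via `converged=False`, never silently. The fit
  requires ≥ 4 distinct concentrations spanning ≥ 2 decades. All
  concentrations are µM throughout.

## Peak-to-TSS proximity enrichment

Distance from a gene's TSS to the nearest binding peak is the proxy for
regulatory likelihood. The procedure:

1. **Stratification.** From a DE table, down-regulated genes satisfy
   `log2FC < −1` and `padj < 0.05` (strict inequalities — a gene at exactly
   −1 is "unchanged"); up-regulated symmetric; the remainder of the expressed
   pool is unchanged. Thresholds are parameters.
2. **Nearest distance.** Peaks are reduced to a reference point — the
   narrowPeak summit when the summit column is valid, else the interval
   midpoint (configurable) — and each TSS is assigned the absolute distance
   to the nearest reference point on its chromosome via binary search
   (`numpy.searchsorted` over sorted per-chromosome points; verified against
   an O(n·m) brute-force oracle). Each TSS contributes exactly one distance;
   when two TSSs are nearest to the same peak both keep it, preserving TSS
   independence. A strict greedy one-to-one mode exists for sensitivity
   analysis. TSSs on peak-free chromosomes get +∞, are excluded from
   medians, and are counted in the report. Coordinates are 0-based
   half-open internally; 1-based annotation tables are converted on read and
   the convention recorded.
3. **Expression-matched null.** Control gene sets are drawn from the
   expressed pool (targets removed) to reproduce the target set's
   per-expression-decile composition, without replacement within a resample
   (10 quantile bins by default; "similar distribution of expression levels"
   is operationalised as decile matching). Insufficient pool in any bin is a
   hard error naming the bin.
4. **Statistic.** `median_ratio` = median over resamples of the control-set
   median distance, divided by the target median (per-resample control
   medians are retained in the result). The empirical p-value uses a +1
   pseudo-count, `p = (1 + #{control median ≤ target median})/(1 + N)`, so
   it is never zero; N < 100 is refused as too coarse. Because the
   underlying test is a resampling comparison of medians and not a named
   distributional test, a Mann–Whitney rank-sum p-value on the raw distance
   distributions is also reported, explicitly labelled secondary.
5. **Co-regulation subtraction.** When a second factor's peaks are supplied,
   genes whose nearest other-factor peak lies within the assignment window
   (default 10 kb — "a gene has a peak" is not otherwise defined) are
   removed before testing and their ids reported.

## Motif scanning

IUPAC consensus matching (no PWMs — the covered claims are consensus-level),
both strands, overlapping hits allowed, `N` never matches. For a consensus
that is its own reverse complement (e.g. the TPA-response element `TGASTCA`,
the default stand-in for AP-1/c-JUN sites since the exact matrix behind such
claims varies by database) each site is reported once. Enrichment of the
per-peak hit fraction is a one-sided binomial tail against a background rate
estimated from dinucleotide-shuffled copies of the input sequences
(Altschul–Erickson Eulerian-path shuffle, 10 shuffles per sequence by
default), reported as log10 p to survive extreme significance.

## Synthetic-data layer

The generators define the study conditions; none of the analysis code
depends on their distributional form.

* **Genome/expression**: TSS positions uniform per chromosome (genes
  apportioned to chromosomes proportionally to length), strands random,
  expression log-normal with log10 mean 1.5 and sd 0.75 (TPM-like scale with
  a realistic dynamic range).
* **DE tables**: planted groups with `log2FC = ±(1.2 + Exp(0.8))` and
  `padj = 10^U(−6, log10 0.049)` for affected genes; unchanged genes get
  `log2FC ~ N(0, 0.4)` clipped to (−1, 1). Group truth is recorded for
  round-trip tests.
* **Peaks**: 3,000 background peaks of 200 bp uniform over a 100-Mb
  chromosome (densities and widths are conventions — real peak sets vary);
  each down-regulated gene additionally receives one peak whose summit sits
  at a signed exponential offset from its TSS. The offset scale is
  calibrated by bisection (in log-scale space) against a ≥ 50-replicate
  simulation of the generator itself until the expected ratio
  median(background-only genes)/median(down genes) is within 2% of the
  planted fold; there is no convenient closed form for the median of
  min(planted offset, nearest background peak), hence simulation. The
  calibrated scale and achieved oracle ratio are recorded in the output
  metadata. `planted_fold = 1` plants nothing (exact null); folds requiring
  sub-bp offsets raise.
* **Plate data**: hook curves `S(c) = A·c/(1 + (c/h)²) + background` on a
  12-step 2-fold dilution grid with the peak concentration on-grid, so BI of
  a strength-s pair against the strength-1 reference is exactly 100·s
  noiseless; dose-response means follow the three-parameter model with
  multiplicative Gaussian noise (CV 3% in the IC50 scenarios, 5% in the
  12-pair disruption panel, 3 replicates — "at least three independent
  experiments" conditions).
* **Motif peaks**: i.i.d. background sequences at the requested GC. Exactly
  `round(p·n)` sequences receive one concrete expansion of the consensus
  (uniform over the degenerate set, random strand and offset);
  `p = (target − b)/(1 − b)` where the background hit rate `b` is estimated
  analytically (per-window union bound, forward + reverse) and then refined
  by scanning 10,000 Monte-Carlo background sequences. Planting an exact
  count rather than Bernoulli draws keeps the expectation identical while
  removing binomial noise on the planted count. Targets below the background
  rate are impossible by insertion and raise, reporting both estimates.

What the generators do **not** emulate: chromatin structure (gene clustering,
promoter CpG islands), peak-width and signal heterogeneity, correlated
expression between neighbouring genes, sequencing noise in DE estimates, or
plate positional effects. Passing tests therefore demonstrate correctness of
the statistics under the stated sampling models, not robustness to every
artefact of real data.

## Problem sizes and numerical choices

Scenario sizes (2,000 genes / 300 down / 3,000 peaks / 1,000 resamples;
10,000 × 60 bp motif peaks; 12-pair panels) mirror the scale of the
downstream products of typical ChIP-seq/RNA-seq studies while keeping each
scenario's generation-plus-analysis in seconds to a couple of minutes on one
CPU. Unit and property tests use a smaller genome (10 Mb / 300 genes / 300
peaks) where the same calibration machinery runs in under a second per seed.

The acceptance script reports, for the two proximity scenarios, the mean
median-ratio over five independently generated realisations: the planted
fold is defined as an expected ratio, and a single realisation's median over
300 genes carries ≈ 9% sampling noise, so the replicate mean is the
appropriate estimator of the scenario's statistic. All other reported
quantities come from single realisations.

Degenerate inputs are refused loudly rather than patched: empty down-groups,
reference titrations at background, zero vehicle signal, peak/TSS chromosome
name mismatches, unattainable planted folds or motif targets, resample
counts below 100.

## Known limitations

* Consensus-only motif matching; no PWM or de novo discovery.
* The proximity null matches expression only; GC content, gene density and
  chromatin context are not matched (nor are they modelled by the
  generator).
* The empirical p-value's resolution is 1/(N+1); claims below that require
  more resamples.
* The dose-response fit assumes homoscedastic noise on percent interaction;
  heavy heteroscedasticity would call for weighted fits.
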