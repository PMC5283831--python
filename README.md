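# proxscreen

Analysis toolkit for studies that connect small-molecule disruption of a
transcription factor's protein–protein interactions (PPIs) to genome-wide
transcriptional consequences. It covers the two quantitative workhorses of
such studies, exercised end-to-end on synthetic data with planted, calibrated
effect sizes:

1. **Bead-proximity (ALPHA-Screen-style) PPI quantitation** — the Binding
   Index of a titration series, percent disruption by a compound, and IC50
   from a three-parameter log-logistic fit:

   - Binding Index: `BI = (I − I_neg) / (I_ref − I_neg) × 100`, where `I` is
     the top of the hook-effect curve (maximum per-step replicate mean),
     `I_neg` the background level and `I_ref` the reference pair's top.
   - Disruption: `(1 − I_compound / I_vehicle) × 100` at one concentration.
   - Dose–response: `y = bottom + (top − bottom) / (1 + x / IC50)` (Hill
     slope fixed at 1), fitted by least squares with the IC50 on the log
     scale.

2. **Peak-to-TSS proximity enrichment** — the distance from a gene's
   transcription start site (TSS) to the nearest ChIP-seq peak as a proxy for
   regulation. Genes are stratified from a differential-expression table
   (down: `log2FC < −1` and `padj < 0.05`; up symmetric); the target group's
   median nearest-peak distance is compared against random gene sets drawn
   from the expressed pool with a *matched expression distribution*:

   `median_ratio = median over resamples of (control median) / (target median)`

   with an empirical p-value `p = (1 + #{control ≤ target}) / (1 + N)`.
   A ratio of 3.6 means the target genes sit 3.6-fold closer to the factor's
   peaks than expected by chance.

A consensus-motif scanner (IUPAC, both strands, dinucleotide-shuffled
background, binomial enrichment) and generators for every input round out
the pipeline.

## Worked example

```python
from proxscreen.synthetic import build_scenario, gen_genome, gen_de_table, gen_peaks
from proxscreen import ProximityModel

sc = build_scenario("PROX-A", seed=11)       # planted fold 3.6
tss = gen_genome(sc.genome)                  # 2,000 genes on a 100-Mb chromosome
de = gen_de_table(tss, sc)                   # 300 down, 300 up, 1,400 unchanged
peaks, meta = gen_peaks(tss, de, sc)         # 3,000 background + calibrated planted peaks

res = ProximityModel(tss, peaks, de).fit("down", n_resamples=1000, seed=3)
print(res.summary())
```

```
Proximity test — group 'down'
--------------------------------------------
target genes (finite distance) : 300
unassigned (peak-free chrom)   : 0
target median distance         : 3,070 bp
control median (of medians)    : 10,958 bp
median ratio (control/target)  : 3.57
empirical p (n=1000)        : 0.000999
rank-sum p (secondary)         : 1.75e-66
co-regulated genes excluded    : 0
```

Down-regulated genes lie a median 3.1 kb from the nearest peak summit versus
11.0 kb for expression-matched random gene sets — 3.57-fold closer (planted:
3.6), with no control resample as extreme as the observed median (p ≈ 1/1001).

The same objects drive dose–response fitting:

```python
from proxscreen.synthetic import gen_dose_response
from proxscreen import fit_ic50

fit = fit_ic50(gen_dose_response(build_scenario("ALPHA-IC50-A", seed=7)))
print(f"IC50 = {fit.ic50:.2f} µM")           # IC50 = 3.34 µM  (planted: 3.3)
```

Everything is also scriptable from the shell:

```bash
proxscreen simulate --outdir sim --seed 1              # all registered scenarios
proxscreen proximity --tss sim/PROX-A/tss.tsv --de sim/PROX-A/de.tsv \
    --peaks sim/PROX-A/peaks.narrowPeak --outdir out --group down
proxscreen alpha --plate sim/ALPHA-PANEL/plate.tsv --outdir out_alpha
proxscreen motif --fasta sim/MOTIF-A/peaks.fa --outdir out_motif
```

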