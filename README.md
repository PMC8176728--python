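# snoclass

Tissue-abundance classification of snoRNAs and correlation with their host
genes.

Small nucleolar RNAs (snoRNAs) are mostly encoded in the introns of host
genes (HGs), so their abundance is often assumed to simply track host
expression and to be uniform across tissues, like other housekeeping RNAs.
Tissue profiling shows otherwise: snoRNA abundance splits into a dominant
**uniformly expressed (UE)** class and a smaller **tissue-enriched (TE)**
class concentrated in brain and reproductive tissues, and a large fraction
of snoRNAs is non- or anticorrelated with its host. `snoclass` packages
that analysis as a tested, reusable pipeline for anyone working with
gene × sample TPM matrices of intron-embedded RNAs: it classifies genes by
tissue specificity, quantifies snoRNA/host correlation with FDR control,
runs the association battery linking the classes to gene annotations, and
ships a calibrated synthetic-cohort generator so every stage is testable
without downloading data.

## The statistics at its core

**Coefficient of variation.** For gene *g* with mean abundance
*x̄<sub>g,t</sub>* (TPM) in each tissue *t* (replicates averaged),

> CV<sub>g</sub> = 100 · sd(*x̄<sub>g,1</sub> … x̄<sub>g,T</sub>*) / mean(*x̄<sub>g,1</sub> … x̄<sub>g,T</sub>*)

with the sample standard deviation (ddof = 1) by default.

**KDE-tangent threshold.** The CVs of all genes form a bimodal
distribution. A Gaussian kernel density estimate *f* is evaluated on a
uniform grid, the point *x₀* of most negative derivative *right of the
global mode* is located, and the tangent at *x₀* is extended to the x-axis:

> threshold = *x₀* − *f(x₀)* / *f′(x₀)*.

For a pure Gaussian density N(μ, σ²) this lands exactly at μ + 2σ, so a
dominant CV mode near 65 with spread ≈ 30 reproduces the canonical cut of
CV = 125. Genes with CV strictly above the threshold are TE, the rest UE;
each TE gene is assigned the tissue of maximal mean abundance (with a
joint breast/ovary rule when those are the top two tissues within a
two-fold difference).

**Host correlation.** Each intron-embedded snoRNA is paired with its host
gene and Pearson's *r* is computed across the individual samples. Raw
p-values are Benjamini–Hochberg adjusted over all pairs in the run;
*r* < −0.25 is *anticorrelated*, −0.25 ≤ *r* ≤ 0.25 *non-correlated*, and
*r* > 0.25 *positively correlated*.

**Association battery.** Fisher's exact test (2×2, and an exact
enumeration test for 2×k tables up to k = 4) and the two-sided
Mann-Whitney U test relate the abundance and correlation classes to box
type (C/D vs H/ACA), target class (rRNA/snRNA/orphan), host biotype and
function, NMD susceptibility, promoter architecture (dual- vs
simple-initiation), phastCons conservation, and snoRNA/host abundance
ratios.

## Worked example

Simulate a default cohort (475 snoRNAs, 7 tissues × 3 replicates) and run
every stage:

```sh
snoclass simulate --seed 1 --outdir cohort/
snoclass run-all --abundance cohort/abundance.tsv \
                 --samples cohort/samples.tsv \
                 --annotation cohort/annotation.tsv \
                 --outdir results/
```

which prints

```json
{
  "n_expressed_snornas": 475,
  "abundance_classes": {
    "UE": 390,
    "TE": 85
  }
}
```

i.e. of the 475 snoRNAs passing the 1-TPM expression filter, 390 came out
uniformly expressed and 85 tissue-enriched — here recovering the simulated
ground truth split exactly. `results/` then contains the filtered matrix,
per-tissue profiles, the per-biotype abundance breakdown, the CV/threshold
diagnostics (`threshold.json`; threshold ≈ 111 CV units for this seed),
per-gene class assignments with enrichment tissues, the snoRNA/host
correlation table with BH q-values and classes, per-tissue log2 sno/host
ratios, the association battery table, and a machine-readable
`report.json` summarising all counts.

The same stages are available as library functions
(`snoclass.compute_cv`, `snoclass.steepest_descent_threshold`,
`snoclass.correlate_pairs`, `snoclass.class_association_battery`, …) on
pandas-based containers. A published per-gene supplementary table can be
re-analysed with `snoclass reproduce --table s5.tsv --column-map map.yaml`,
which recomputes the headline counts and prints them next to the published
reference values (475 expressed, 390 UE / 85 TE, 60% positively
correlated).

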