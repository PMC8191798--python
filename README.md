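# ubiprom

Analysis toolkit for **promoters with ubiquitous chromatin accessibility**.

Most regulatory elements are open in only a handful of cell types, but a
small set of promoters stays accessible in nearly every biosample assayed.
`ubiprom` implements the computational pipeline for finding and
characterizing these elements from DNase-seq Z-score compendia, and for
asking what makes them different: CpG-rich, TATA-poor sequence; dispersed
transcription initiation; housekeeping-like expression; elevated standing
variation at their centers; and strong enrichment for cell-essential and
Mendelian-disease genes.

## What it computes

- **Ubiquity calling** — an element is *high* in a biosample when its DNase
  Z-score exceeds 1.64 (the one-sided 5% standard-normal point) and
  *ubiquitous* when high in ≥ 95% of biosamples (e.g. ≥ 500 of 517 human,
  ≥ 90 of 94 mouse). Candidate cis-regulatory elements are classified
  PLS / pELS / dELS / DNase-H3K4me3 / CTCF-only / DNase-only from histone
  and CTCF flags plus TSS distance.
- **Promoter sequence features** — normalized CG content
  `fCpG / [(fC + fG)/2]²` (≥ 0.5 = CpG-rich), PWM motif scanning with exact
  p-values by dynamic programming over the background score distribution,
  and TATA-box calling 25–35 bp upstream of the TSS (forward strand,
  p ≤ 10⁻³).
- **Transcription** — quantile normalization, the tissue-specificity index
  τ = Σ(1 − xᵢ/max x)/(N − 1), and TSS peak-shape classification
  (narrow / broad / dispersed from the fraction of 5′ ends within ±2 nt of
  the summit and the peak length) with per-biosample Fisher enrichment.
- **Nucleotide diversity** — per-site π = 1 − Σ pᵢ², per-region means,
  oriented ±2 kb profiles, and a 10 000-replicate bootstrap Welch-t group
  test.
- **Enrichment statistics** — gene–promoter class assignment, a TSS-label
  permutation null for genes with both promoter types, two-sided Fisher
  exact tests with BH FDR, essentiality rank sweeps, chromatin-loop anchor
  enrichment, cofactor-responsiveness comparisons, synteny classes, and
  OMIM-style Mendelian gene filtering.
- **Synthetic data** — seeded generators for every input shape with planted
  ground truth, so the whole pipeline runs and is tested with no downloads.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_call_ubiquity.py
python analysis/06_gene_enrichment.py
```

prints (seed 1):

```
100 / 10000 elements ubiquitous (>= 95 of 100 biosamples with Z > 1.64)
  sensitivity 1.0000  specificity 1.0000
...
genes with both promoter types: observed 0, null 17.5 +/- 1.4, p < 0.0001
Mendelian x essential overlap (941/2718 vs 5312/18633): p = 6.1e-14
essential fraction by CRISPR-rank window: [1.0, 0.3, 0.0, 0.0, 0.0]
loop anchors: 71.0% of ubiquitous vs 0.0% of other promoters anchored
```

The first block says the planted 1% ubiquitous fraction was recovered
perfectly from the Z-score matrix. The second block shows the gene-level
statistics: genes sharing ubiquitous and non-ubiquitous promoters are rarer
than the permutation null expects; the published 2×2 overlap between
Mendelian-disease genes (2718 of 18 633 screened) and cell-essential genes
(5312) with 941 in common gives p = 6.1 × 10⁻¹⁴; the fraction of essential
genes falls off across CRISPR-score rank windows; and chromatin-loop
anchors concentrate on the ubiquitous set.

The numbered scripts under `analysis/` run each stage in order
(simulation, ubiquity calling, sequence features, TSS shape and
tissue-specificity, nucleotide diversity, gene enrichment) and write their
tables under `results/`. A `ubiprom` CLI exposes the same stages
(`ubiprom synth`, `ubiprom ubiquity-call`, `ubiprom scan`, `ubiprom pi`,
`ubiprom fisher`, `ubiprom run --config pipeline.yaml`).

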