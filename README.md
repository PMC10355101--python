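# g4access

Linking predicted G-quadruplexes (pG4s) to changes in chromatin
accessibility.

G-quadruplexes are four-stranded DNA structures formed by stacked tetrads
of Hoogsteen-bonded guanines in G-rich sequence. They are enriched in gene
promoters, and stabilising them with small-molecule ligands perturbs
chromatin accessibility and transcription. A recurring analysis pattern in
this area is: predict pG4s from genome sequence, call differentially
accessible regions (DARs) from replicated ATAC-seq counts, intersect the
two, and ask whether pG4 containment among promoter DARs exceeds the
promoter background. `g4access` implements that chain as a tested,
reusable library for computational epigenomics — together with a
synthetic-data generator that emulates the study structure, so the whole
pipeline runs and is testable with no external data.

## What it computes

- **pG4 calling (G4Hunter-style).** Each base in a maximal G-run of
  length *n* scores +min(*n*, 4); C-run bases score −min(*n*, 4). Means
  over sliding windows (default 25 bp) are thresholded (default 1.2),
  same-signed overlapping windows are merged, regions are refined, and
  G-rich regions are reported on the + strand, C-rich on −, with the
  region's mean |base score| as the score.
- **Feature annotation.** Peaks are assigned one class by priority
  Promoter > Exon > Intron > Downstream > Intergenic, with promoters as
  TSS windows (default −2000/+500 bp in gene orientation).
- **Differential counts.** Median-of-ratios size factors, log2 CPM with a
  0.5 prior count, moment-based NB dispersion with shrinkage, an exact
  conditional test on library-equalised group sums, and
  Benjamini–Hochberg FDR. DARs: FDR < 0.1. DEGs: FDR < 0.05 and
  |log2 FC| > 2. All thresholds configurable.
- **Enrichment statistic.** With *k* of *n* promoter DARs containing a
  pG4 and a background containment rate *p* over **all** promoter peaks,
  the report gives the upper binomial tail
  P = Σ<sub>i≥k</sub> C(n,i) p<sup>i</sup> (1−p)<sup>n−i</sup>,
  per-DAR pG4 counts with summaries, and direction-stratified tallies for
  promoter and non-promoter DARs.
- **Synthetic data.** Random genomes with planted G-rich motifs,
  non-overlapping gene models, TSS-centred and distal peaks, and
  replicated negative-binomial counts with planted true DARs — with
  exact, machine-readable ground truth.

## Worked example

```python
from pathlib import Path
from g4access import PipelineConfig, run_pipeline
from g4access.simulate import DEMO_DAR_FDR, structure_demo_config

config = PipelineConfig(output_dir=Path("demo_run"), seed=8,
                        sim=structure_demo_config(8), dar_fdr=DEMO_DAR_FDR)
report = run_pipeline(config)
print(report.n_dars, report.n_dars_with_pg4,
      round(report.background_rate, 4), round(report.binomial_tail_p, 4))
```

prints

```
22 21 0.8083 0.0576
```

Reading: of 120 promoter peaks, 22 carry a planted accessibility
reduction and are recovered as DARs; 21 of those 22 contain a pG4, while
the background containment over all promoter peaks is 97/120 ≈ 0.809. The
chance that 21 or more of 22 randomly chosen promoter regions would
contain a pG4 at that background is ≈ 0.058 — a marginal excess,
precisely because promoters are already pG4-dense. The same run is
available from the shell via `g4access run-all --config cfg.yaml`, and
each stage separately via `g4access simulate | score-g4 | annotate |
diff | enrich`. The `examples/` directory holds one short script per
capability.

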