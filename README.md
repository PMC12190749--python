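# markdyn

Histone-mark occupancy dynamics at desk scale: a Python library (with a
thin `markdyn` CLI) for the multi-omics analysis pattern used to study
activating chromatin marks — such as histone H3 lysine-18 lactylation
(H3K18La) — across development and between tissues.

The package implements, end to end:

- **Replicate-consensus peak calling** — peaks from an upstream caller
  (ENCODE narrowPeak) are filtered at −log10(q) > 6 and a locus is kept
  when peaks from ≥ 2 biological replicates transitively overlap; the
  consensus interval is the union of the contributing peaks.
- **TSS-window annotation** — each peak is classified as promoter
  (−1000..+500 bp from the TSS, strand-oriented), enhancer
  (−10 kb..−1 kb), gene body, or distal, with promoter > enhancer >
  gene body > distal precedence and midpoint membership.
- **Differential binding** — fragment counts over merged cross-condition
  consensus peaks, trimmed-mean-of-M-values (TMM) scale factors computed
  on 10 kb genome bins, and a per-peak negative-binomial likelihood-ratio
  test: counts `y ~ NB(μ, φ)` with `Var = μ + φμ²`,
  `log μ = β_g + log(library × factor)`, statistic `2Δℓ ~ χ²(1)`,
  Benjamini–Hochberg FDR across peaks.
- **Binding–expression correlation partition** — Pearson r between
  promoter binding (replicate-averaged log2 CPM per timepoint) and the
  expression trajectory of the gene, computed for differentially bound
  promoter peaks of protein-coding genes, classified at r > 0.8
  (positive) and r < −0.8 (negative).
- **Multi-mark co-occupancy dynamics** — a boolean gene × timepoint ×
  mark promoter-occupancy ledger, per-timepoint fractions of mark
  combinations among anchor-marked genes, and gene flows between
  combination states at consecutive ages.
- **Footprint-restricted motif enrichment** — controls are same-class
  regions without the mark (so GC composition is matched), PWMs are
  scanned on both strands at an exact per-position p-value threshold
  (dynamic programming over the discretized log-odds distribution,
  default p = 1e-4), and region hits are compared by one-sided Fisher
  exact test with BH adjustment.
- **Cross-tissue occupancy clustering** — pairwise phi coefficients of
  the binary gene × tissue promoter-occupancy matrix,
  `φ = (n11·n00 − n10·n01)/√(n1·n0·n·1n·0)`, Ward clustering of the
  Euclidean distances between phi-matrix rows, and UpSet-style exclusive
  intersection counts.
- **A seeded synthetic multi-omics generator** — a miniature genome with
  GC-elevated promoters, jittered/dropped replicate peaks, NB fragment
  counts with planted fold changes, expression trajectories with planted
  correlation classes, motif-planted footprints, and a block-structured
  tissue matrix — with exported ground truth, so every stage is testable
  without any download.

## Worked example

```python
from markdyn.pipeline import correlate_study
from markdyn.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=3))
partition, n_db_promoters = correlate_study(study, fdr=0.01)
print(n_db_promoters, partition.genes.corr_class.value_counts().to_dict())
```

prints

```
167 {'positive': 95, 'negative': 54, 'neutral': 18}
```

meaning: of the synthetic study's merged peaks, 167 promoter peaks of
protein-coding genes changed significantly across the four ages
(FDR < 1%); 95 genes show binding–expression Pearson r > 0.8 and 54 show
r < −0.8. Against the generator's truth this recovers 89 of the 90
planted positive genes. The co-occupancy example
(`python examples/04_cooccupancy_dynamics.py`) prints the fraction of
anchor-marked promoters carrying both other active marks rising from
38.6% at the first age to 79.0% at the last — the planted developmental
gain in promoter co-occupancy.

Each script in `examples/` demonstrates one capability and prints what
the numbers mean; `examples/07_full_pipeline.py` (equivalently
`markdyn run --seed 0 --outdir out/`) writes a full input bundle and
runs all nine stages with a sha256-digest provenance manifest.

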