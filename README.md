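# pangevo

Analysis toolkit for pangenome evolution across metagenome-assembled genome
(MAG) bins from two sites:

- **pangenome structure** — gene-cluster presence/absence matrix, frequency
  spectrum, asymmetric gene-content containment, average-linkage genome
  clustering, rarefaction (accumulation/core-decay) curves, and a
  completeness-aware Monte Carlo posterior for a cluster being truly core;
- **functional enrichment** — COG-category composition by gene frequency with
  a label-permutation null and category clustering;
- **biogeographic enrichment** — per-cluster inclusive lower-tail binomial
  CDF score for the split of containing bins between two sites, with
  inclusion filters, significance calls, and per-category Welch t-tests;
- **selection profiling** — per-ORF pN/pS from single-codon variants with
  equal-weight (Nei–Gojobori-style) potential-site normalization, plus group
  summaries with exact rank-sum tests;
- **sweep detection** — per-bin SNV density and a per-contig Poisson-deficit
  test (genes inherit their contig's P value; values below 1e-10 flagged);
- **synthetic data** — a seeded generator producing complete datasets with a
  U-shaped frequency spectrum, completeness dropout, site-biased clusters,
  class-targeted pN/pS variants, and optional swept contigs, together with a
  ground-truth table for recovery testing.

## CLI

```sh
# generate a synthetic dataset with truth tables
pangevo simulate -o data/ --seed 1 --n-clusters 2000 --n-biased 60 --n-swept-contigs 10

# run everything (stages with missing optional inputs are skipped)
pangevo all -i data/ -o results/ --seed 1

# or individual stages
pangevo pangenome -i data/ -o results/
pangevo cogfreq   -i data/ -o results/
pangevo biogeo    -i data/ -o results/
pangevo pnps      -i data/ -o results/
pangevo sweeps    -i data/ -o results/
```

Inputs are UTF-8 TSV tables with headers (`bins.tsv`, `contigs.tsv`,
`gene_calls.tsv`, `clusters.tsv`, `snvs.tsv`, `codon_variants.tsv`) plus an
optional `cds.fasta`; gene calls use 0-based half-open coordinates and SNV
positions are 0-based. See the `pangevo.io_core` module docstring for column
schemas. A YAML config (`-c config.yaml`) can override any
`PipelineConfig` field (site proportion, inclusion thresholds, CDF cutoffs,
sweep threshold, permutation/Monte Carlo counts, seed, ...).

## Library use

```python
import pangevo as pg

cfg = pg.SimulationConfig(n_clusters=2000, n_biased_clusters=60, seed=1)
dataset, truth = pg.simulate_dataset(cfg)

matrix = pg.build_matrix(dataset)
scores = pg.score_clusters(matrix, dataset.site_labels)
pnps = pg.pnps_table(dataset.sequences, dataset.codon_variants)
sweeps = pg.contig_sweep_table(dataset.snvs, dataset.contigs)
```
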