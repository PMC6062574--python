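# umisense

Analyses for UMI-based single-cell RNA-seq benchmarking, built around a
molecule-level synthetic-data generator so every estimator can be validated
end-to-end against planted ground truth — no external downloads required.

What it does:

- **simdata** — generative model for molecule-level scRNA-seq data:
  negative-binomial expression (`var = mu + phi*mu^2`), per-molecule binomial
  capture, Beta-distributed PCR efficiency with multinomial read allocation to
  a fixed per-cell depth, spike-in ladders, doublet merging and inter-cell
  crosstalk, with full ground-truth records.
- **ercc** — spike-in sensitivity: per-cell binomial logistic regression of
  detection (>= 1 UMI) on known input molecules, the molecule count at 50%
  detection probability (m50), the closed-form oracle `ln(0.5)/ln(1-p)`,
  detection efficiency, and cellular mRNA-content estimation.
- **qc** — cell filters: nearest-neighbor Spearman correlation,
  KDE-mode doublet flagging, fixed-threshold read/mapping-rate/UMI/gene
  filters, and species-mixing crosstalk quantification with a Welch t-test.
- **depth** — exact read-depth downsampling of molecule tables (multivariate
  hypergeometric; nested by default so saturation curves are monotone per
  seed), saturation curves and reads-per-UMI evenness statistics.
- **power** — two-group NB power simulation: moment estimation of gene-wise
  (mean, dispersion), planted log2 fold-changes, rank-sum testing with BH
  adjustment, TPR/FDR over a grid of sample sizes.
- **io / cli** — MatrixMarket + TSV sidecar bundles (10x-style), gzip TSV
  molecule tables, YAML run configs with strict key validation, and a
  `umisense` CLI tying the stages into a pipeline.

## CLI

```sh
# full pipeline (simulate -> qc -> depth -> spike-in sensitivity -> power)
umisense run --seed 7 --out demo_run

# individual stages
umisense simulate --out sim --seed 1 --n-cells 96 --n-genes 2000
umisense qc flag-doublets --umi-dir sim/umi --out doublets.tsv
umisense qc nn-filter --umi-dir sim/umi --out nn.tsv
umisense qc species-mix --reads-table species_reads.tsv --out calls.tsv
umisense depth downsample --molecules sim/molecules.tsv.gz --depth 10000 \
    --seed 1 --out down.tsv.gz
umisense depth saturate --molecules sim/molecules.tsv.gz \
    --depths 1e3,1e4,2e4 --out saturation.tsv
umisense ercc fit --umi-dir sim/umi --design design.tsv --out fits.tsv
umisense ercc mrna-content --umi-dir sim/umi --design design.tsv --out content.tsv
umisense power estimate --umi-dir sim/umi --out params.tsv
umisense power run --params params.tsv --sizes 24,48,96 --iters 25 --seed 1 \
    --out power.tsv
```

Spike-in designs are tab-delimited with either a `molecules_per_cell` column
or an `attomoles_per_ul` column plus `--dilution` / `--volume-ul` flags.
Every run directory contains the resolved config and a `manifest.json` with
artifact checksums; identical seeds give identical outputs.

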