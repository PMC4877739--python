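# dualomics

A tested, reusable pipeline for dual-omic (RNA-seq + 4-plex reporter-ion
proteomics) differential expression analysis:

- **Quantitation** — per-gene expression as the log2 sum of exact
  read-length alignments (RNA) or of summed peptide reporter-ion
  intensities (protein), with the standard evidence filters (≥ 2
  alignment counts per cell; ≥ 2 peptides at log(e) < −1.5 per protein).
- **Contrast scores** — per gene, four raw log2 differences against a
  reference condition (two intra-replicate, two cross-state), each
  population normalized to mean 0 / SD 1, with the cross-state pair merged
  into a single normalized contrast score (**Znet**; R-labelled for RNA,
  P-labelled for protein).  A single-replicate cross-state-only mode
  covers the proteomic case.
- **Signal-to-noise + FDR** — a dataset-level S/N (mean cross-state SD over
  mean intra-replicate SD), a per-gene S/N (cross/intra 2-vector magnitude
  ratio scaled by the system S/N), and a seeded Monte-Carlo false
  discovery rate over S/N cutoffs.
- **COG tabulation** — up/down counts per COG letter per contrast and
  omic, plus RNA∩protein same-direction overlap counts (category S and
  hypothetical genes excluded from the overlap).
- **Motif scanning** — degenerate IUPAC consensus search on both strands
  with a mismatch budget, and strand-aware overlap/upstream-adjacency
  classification of hits against gene annotations.
- **Fermentation metrics** — exponential-phase growth rate / doubling
  time, carbon recovery and oxidation:reduction ratio with an editable
  redox table.
- **Synthetic data** — seeded generators for annotated genomes with
  planted motif sites, exact-substring read sets, dual-omic experiments
  with per-gene ground truth, and stoichiometrically closed fermentation
  time courses, so the whole pipeline is testable offline.

## Command line

```bash
# full seeded pipeline (synthesis → quantitation → contrasts → S/N-FDR →
# COG table → motif scan → fermentation), with a checksum manifest
dualomics run --config config.yaml

# individual stages
dualomics count genes.fasta --reads cond:A=reads.fasta --out counts.tsv
dualomics quantify-rna counts.tsv --min-counts 2 --out rna.tsv
dualomics quantify-protein peptides.tsv --min-peptides 2 --peptide-log-e -1.5 --out prot.tsv
dualomics contrast rna.tsv --reference cellobiose --threshold 1.65 --outdir contrasts/
dualomics snr contrasts/contrast_R0.tsv --cutoffs 1,2,2.8,4 --mc-replicates 100 \
    --seed 1 --out with_snr.tsv --fdr-out fdr.tsv
dualomics scan genome.fasta --consensus TGWAANCGNTNWCA --max-mismatches 1 \
    --annotations annotations.gff3 --out hits.tsv
dualomics ferment series.csv --substrate glucose --window 0,20 --out metrics.json
```

A minimal pipeline config:

```yaml
seed: 1
outdir: run1
design:
  conditions: [cellobiose, xylose, alpha_cellulose, xylan]
  reference: cellobiose
  replicates: [A, B]
genome:
  n_genes: 120
  motif: {consensus: TGWAANCGNTNWCA, n_planted: 5}
omics: {frac_de: 0.1, effect_magnitude: 2.0, noise_sd: 0.25}
thresholds: {znet: 1.65, secondary: 1.96, snr_cutoff: 2.8}
monte_carlo: {replicates: 100, cutoffs: [1.0, 2.0, 2.8, 4.0]}
fermentation:
  mu: 0.15
  substrate: glucose
  stoichiometry: {ethanol: 2.0, CO2: 2.0}
  timepoints: [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
  window: [0, 10]
```

## Layout

| module | contents |
| --- | --- |
| `dualomics.core_io` | domain types (annotations, designs, matrices, peptide evidence) and FASTA/GFF3/TSV readers-writers |
| `dualomics.synthetic` | seeded genome/read/omics/fermentation generators with ground truth |
| `dualomics.quantitation` | exact read-length alignment counting, RNA/protein matrix building, OLS R² |
| `dualomics.differential` | raw differences, population normalization, Znet merging, regulation calls, COG tables |
| `dualomics.snr_fdr` | system and gene S/N, Monte-Carlo FDR calibration |
| `dualomics.motif_scan` | IUPAC consensus scanning and hit-gene association |
| `dualomics.fermentation` | doubling time, carbon recovery, O/R ratio, redox tables |
| `dualomics.cli` | click CLI and the config-driven pipeline with run manifest |
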