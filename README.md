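# dmmrkit

Analysis toolkit for mismatch-repair-deficient (dMMR) tumor cohorts:

- **Cohort statistics** — clinical-table model, summary statistics,
  Spearman correlation matrix (pairwise-complete, t-approximation or exact
  permutation p-values), and a log2FC/Benjamini–Hochberg DEG filter.
- **MSI calling** — electropherogram peak detection, paired healthy/tumor
  locus comparison with ±1 bp tolerance, and MSS / MSI-low / MSI-high
  classification (0 / 1 / ≥2 unstable loci).
- **Mutation spectrum** — TMB (mut/Mbp, high strictly above 10), SBS96
  trinucleotide spectra from VCF + FASTA, cosine-similarity signature
  matching, and cross-species hotspot codon statistics (±5-codon window,
  same-residue, exact-change).
- **Methylation / CIMP** — MethyLight-style percent methylation
  (PMR: calibrator-referenced, CpG-free control normalized), paired
  tumor/normal marker calls with the >20-point rule, CIMP classification
  (≤2 / 3 / ≥4 of 5 markers), MLH1 dual-probe concordance, and 2^-ddCt
  relative expression.
- **Shape topology** — methylation-aware DNA-shape prediction by pentamer
  lookup over an extended alphabet (M = 5mC, W = G paired to methylated C),
  per-position percentile envelopes over aligned binding-site sets, and a
  departure score for methylated vs unmethylated motif instances.
- **Synthetic data** — seeded, deterministic generators for every input
  (reference FASTA, context-weighted VCFs, stutter-laddered traces, qPCR
  plates from known methylation fractions, motif site sets, shape tables,
  promoters, cohort tables) with ground-truth sidecars.
- **CLI / pipeline** — a single `dmmrkit` entry point and an end-to-end
  `run` command producing per-sample TSV/JSON reports with input hashes.

Two small in-repo fixtures (a 24-animal clinical cohort table and a
16-tumor curated variant table, `src/dmmrkit/data/`) let the cohort and
variant analytics run without any downloads.

## CLI

```bash
# synthetic input bundle (FASTA, VCFs, traces, plate, sites, shape table…)
dmmrkit simulate all --seed 1 --out bundle/

# single stages
dmmrkit cohort summarize cohort.tsv
dmmrkit cohort correlate features.tsv --alpha 0.05
dmmrkit msi --traces traces.tsv --tol 1 --rel-threshold 0.10
dmmrkit tmb --variants variants.tsv --callable-mbp 34.0 --threshold 10
dmmrkit spectrum --vcf s.vcf --fasta ref.fa --signatures sig.tsv --plot
dmmrkit hotspots --rhesus variants.tsv --catalog catalog.tsv --window 5
dmmrkit methylight --plate plate.tsv --threshold 20
dmmrkit expression --plate plate.tsv --target MLH1 --reference GAPDH
dmmrkit shape profile --fasta q.fa --meth-positions 12,30 --table tab.tsv
dmmrkit shape envelope --sites sites.fa --table tab.tsv --out env.json
dmmrkit shape departure --query q.fa --envelope env.json --table tab.tsv

# everything at once, from a YAML config with per-stage blocks
dmmrkit run --config config.yaml
```

A minimal pipeline config (paths relative to the config file):

```yaml
out: report
msi: {traces: bundle/traces.tsv}
spectrum:
  vcf_dir: bundle/vcf
  fasta: bundle/reference.fa
  signatures: bundle/signatures.tsv
  callable_mbp: 34.0
methylight: {plate: bundle/plate.tsv}
cohort: {table: bundle/cohort.tsv}
```

## File formats

All tables are UTF-8 TSV with `#` comment lines. Genomic positions are
1-based in files (VCF convention) and 0-based half-open internally.
Shape tables carry columns `pentamer, MGW, ProT, HelT1, HelT2, Roll1,
Roll2` over the `ACGTMW` alphabet; a loader accepts externally derived
tables in the same schema, so real DNAshape-style tables can be swapped in
for the packaged synthetic ones (and the qualitative expectation — CpG
methylation lowers propeller twist and raises roll while barely moving
minor groove width and helix twist — can then be checked against them).
Site sets are FASTA files of equal-length aligned sequences. qPCR plates
carry `sample, tissue, assay, role, ct, replicate` with `undetermined`
allowed for Ct.
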