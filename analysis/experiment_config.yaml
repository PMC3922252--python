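# Example configuration for `regionpred all --config analysis/experiment_config.yaml`.
# Runs the full simulated comparison design end to end and writes
# cv_results.tsv, dendrogram.nwk, qc_report.tsv and manifest.json to out_dir.
seed: 7
out_dir: results/experiment_demo
n_animals: 150
n_chrom: 2
chrom_length: 400000
genes_per_chrom: 5
snp_density: 0.002
target_class: Genes     # concentrate causal effects in genic SNPs
h2: 0.33
systematic_share: 0.20
snp_missing_rate: 0.01
regions: [CDS, Genes, IGR, ALL]
cv_folds: 5
cv_replicates: 3
mcmc_preset: reduced
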