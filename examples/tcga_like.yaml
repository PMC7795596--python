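# RNA-seq cohort profile (TCGA-like).
#
# Expression arrives as RSEM estimated abundances (or TPM); CYT is the
# geometric mean of GZMA/PRF1 TPM.  The CYT cutoff retains the top 40% of
# the cohort, the CD8 cutoff the top 85% -- cutoffs are always calibrated on
# the cohort being classified, never transferred.
inputs:
  expression: cohort/expression.tsv   # tab-delimited, Hugo_Symbol first column
  scale: rsem                         # rsem | tpm | zscore | log2
  fractions: cohort/fractions.tsv     # 22 CIBERSORT-style cell types, rows sum to 1
  clinical: cohort/clinical.tsv
  features: cohort/features.tsv       # TMB, mutation rates, neoantigens, checkpoint genes
  gene_sets: cohort/hallmark.gmt

scoring:
  pseudocount: 0.01                   # TPM added to each gene before the geometric mean

phenotyping:
  cd8_top_fraction: 0.85
  cyt_top_fraction: 0.40

dge:
  pairs: [[HTI, NI], [HTI, CTI], [CTI, NI]]

gsea:
  n_perm: 1000
  seed: 17
  nes_threshold: 1.7
  q_threshold: 0.01

survival:
  endpoints: [OS, PFS]

output_dir: out/tcga_like
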