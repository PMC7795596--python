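# Microarray cohort profile (METABRIC-like).
#
# Expression arrives as per-gene cohort z-scores, where a geometric mean is
# undefined; the pipeline falls back to the rank-based CYT surrogate (mean
# of the two genes' within-cohort fractional ranks).  The CYT cutoff retains
# only the top 8% of the cohort, reflecting the much smaller hot fraction
# calibrated for this cohort type.
inputs:
  expression: cohort/expression_zscores.tsv
  scale: zscore
  fractions: cohort/fractions.tsv
  clinical: cohort/clinical.tsv
  gene_sets: cohort/hallmark.gmt

phenotyping:
  cd8_top_fraction: 0.85
  cyt_top_fraction: 0.08

dge:
  pairs: [[HTI, NI], [HTI, CTI], [CTI, NI]]

gsea:
  n_perm: 1000
  seed: 17

survival:
  endpoints: [BCSS, RFS_distant, RFS_local]

output_dir: out/metabric_like
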