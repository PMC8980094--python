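# Complete pipeline configuration (all values shown are the defaults).
# Unknown keys are rejected at load time; every block may be omitted.

seed: 0            # root seed; all randomness (simulation, permutations) descends from it
log_level: INFO

qc:                # paired tumor/normal high-quality variant filter (bounds inclusive)
  min_t_depth: 30  # minimum tumor read depth
  min_n_depth: 15  # minimum matched-normal read depth
  min_t_vaf: 0.05  # minimum tumor variant allele fraction
  max_n_vaf: 0.01  # maximum normal variant allele fraction
  driver_max_maf: 0.01  # population-frequency bound for driver candidates (strict <)

rescue:            # deep-targeted re-genotyping of union mutations
  enabled: true
  min_alt: 5       # minimum deep alt reads to call a presence
  min_vaf: 0.01    # minimum deep VAF to call a presence

scna:
  log2_cutoff: 0.25   # |log2| for a gene-level gain/loss call
  min_patients: 4     # recurrence threshold across the cohort
  de_p_cut: 0.05      # differential-expression significance for integration
  de_fc_cut: 1.5      # linear fold-change bound (direction-concordant)

enrichment:
  n_perm: 1000        # gene-label permutations per GSEA p-value
  weight_exponent: 1.0  # |score| exponent in the running-sum weights
  tau: 0.05           # truncation point of the truncated product method
  top_percentile: 15.0  # percentile-rank cut for drug-target candidates
  de_p_cut: 0.05
  de_fc_cut: 1.5

simulation:           # synthetic-cohort generator (deep-validation scenario)
  n_patients: 14
  sites_min: 2        # sites per patient drawn uniformly from [sites_min, sites_max]
  sites_max: 5
  n_mutations_per_patient: 40
  clone_fractions: [0.60, 0.25, 0.15]  # trunk / branch / private
  tumor_purity: 0.4
  depth_wes: 228.0    # exome-tier mean coverage
  depth_deep: 3700.0  # deep-targeted mean coverage
  sequencing_error: 0.001  # per-base error rate
  # site_counts: [2, 2, 3, 5, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  #   optional fixed per-patient site counts (overrides sites_min/max);
  #   single-site patients are skipped by the phylogeny stage
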