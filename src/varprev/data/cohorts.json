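{
  "gnomAD": {
    "description": "gnomAD v2.1.1 exomes, TTR locus summary",
    "unit": "alleles",
    "n_average_exomes": 125780,
    "n_sequenced": 125748,
    "summary_table": "gnomad_ttr_disease_causing.tsv",
    "dialect": "gnomad_like",
    "stratification": {
      "African/African-American": {
        "allele_count": 402,
        "homozygote_count": 3,
        "n_individuals": 12487
      },
      "non-African": {
        "allele_count": 65,
        "homozygote_count": 0,
        "n_individuals": 113261
      }
    }
  },
  "ChinaMAP": {
    "description": "ChinaMAP (beta 2020-03) population cohort, TTR disease-causing variants",
    "unit": "alleles",
    "n_individuals": 10588,
    "summary_table": "chinamap_ttr_disease_causing.tsv",
    "dialect": "chinamap_like"
  },
  "Amcarelab": {
    "description": "Clinical referral exome laboratory cohort, TTR pathogenic/likely-pathogenic carriers",
    "unit": "individuals",
    "n_individuals": 45392,
    "summary_table": "amcarelab_ttr_pathogenic.tsv",
    "dialect": "clinical_exome_like"
  }
}
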