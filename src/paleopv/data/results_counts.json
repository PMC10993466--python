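{
  "clinvar_total_pvs": 20272,
  "clinvar_genes_with_pvs": 91,
  "ddr_panel_genes": 169,
  "snv_pvs": 7432,
  "snv_genes": 87,
  "shared_pvs": 1497,
  "species_total": 100,
  "species_sharing": 97,
  "ancient_samples": 5031,
  "ancient_pvs": 1266,
  "ancient_carriers": 1019,
  "ancient_genes": 73,
  "dated_carriers": 959,
  "carriers_within_5000": 717,
  "carriers_5000_10000": 214,
  "carriers_before_10000": 28,
  "recurrent_pvs": 67,
  "recurrent_genes": 33,
  "founder_pvs": 68,
  "founder_genes": 7,
  "modern_cohort_pvs": 1781,
  "primate_shared_entries": 53,
  "neanderthal_pvs": 5,
  "ancient_date_min_bp": 100,
  "ancient_date_max_bp": 45045
}
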