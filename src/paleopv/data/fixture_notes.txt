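Notes on the packaged fixture tables
====================================

table2_primate_sharing.tsv
  Transcription of the printed primate-sharing table. The table lists 24
  Bushbaby entries while the surrounding text says Bushbaby "shared 23 human
  DDR PVs"; the fixture carries the 24 table rows and the discrepancy is left
  unresolved. The 53-entry total is the sum over all nine primate species.
  MYA values are divergence-time annotations (TimeTree) carried as metadata.

table4_gene_counts.tsv
  Per-gene counts of pathogenic variants detected in ancient genomes, 73
  genes summing to 1266.

table5_chek2.tsv
  CHEK2 pathogenic variants in ancient carriers: 28 variants, carrier column
  sums to 42. "NA" dates are carriers without a dated sample.

table6_founders.tsv
  Literature-curated founder pathogenic variants with haplotype-dated ages:
  68 records, 44 of them in BRCA1. Ages may be points ("3800"), ranges
  ("1500-750", "220-140"), or one-sided bounds ("<200", ">250"); the loader
  exposes a midpoint representative age (bounds collapse to their stated
  endpoint), which reproduces the published overall range 8675-180 years BP.

results_counts.json
  Headline counts printed in the study summary (catalog sizes, sharing
  counts, ancient-carrier and timing-bin counts). Two printed percentages
  are internally inconsistent with their own counts ("97 (98.0%) of the 100
  species"; "1266 (5.3%)" ancient PVs) and are not reproduced; all derived
  percentages in this package are computed from the counts by exact
  arithmetic.

ddr_gene_pathways.tsv
  DNA-damage-repair gene panel with pathway membership over the eight
  pathways (FA, HR, MMR, NER, NHEJ, DDR_response, BER, DR). The panel is a
  curated, user-replaceable data file assembled from the standard KEGG
  "replication and repair" and Wood-laboratory gene lists; it covers every
  gene in table4_gene_counts.tsv. A gene may belong to multiple pathways;
  nonredundant totals deduplicate genes across pathways.

species_clades.tsv
  Toy species/assembly/clade map for the simulator and the sharing engine,
  spanning the eight vertebrate clades. User-replaceable.
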