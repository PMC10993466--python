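"""Recompute every headline number from the packaged fixture tables.

The fixtures are transcriptions of published summary tables: per-gene
ancient PV counts (73 genes), the primate sharing table, the CHEK2 carrier
table, and the founder-variant table. All percentages below are exact
arithmetic on those counts.
"""

import json

import paleopv as pv
from paleopv.pipeline import fixture_report

# individual tables are available directly...
t4 = pv.load_paper_fixtures("table4_gene_counts")
profile = pv.abundance_profile(t4)
print(f"ancient PVs: {profile.total} across {len(profile.counts)} genes; "
      f"top genes: "
      f"{sorted(profile.counts, key=profile.counts.get, reverse=True)[:3]}")

t6 = pv.load_paper_fixtures("table6_founders")
founders = pv.founder_summary(t6)
print(f"founder PVs: {founders['n_founders']} in {founders['n_genes']} genes, "
      f"dated {founders['oldest_bp']:.0f}-{founders['youngest_bp']:.0f} BP")

# ...and the full recomputed report in one call:
print(json.dumps(fixture_report(), indent=2))
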