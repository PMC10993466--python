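"""Load a ClinVar-style variant table, apply the clinical filters, and tag
repair pathways.

The catalog workflow mirrors how a pathogenic-variant universe is defined:
keep pathogenic / likely-pathogenic assertions with enough review support,
restrict to single-nucleotide variants, and annotate each variant with its
gene's repair-pathway membership.
"""

import tempfile
from pathlib import Path

import paleopv as pv

TABLE = """chrom	pos	ref	alt	gene	clin_class	review_stars	hgvs_c
chr17	43057062	C	T	BRCA1	pathogenic	3	c.5503C>T
chr13	32340301	G	A	BRCA2	likely_pathogenic	3	c.4689G>A
chr3	37025749	C	T	MLH1	pathogenic	2	c.208-3C>T
chr22	28695219	G	A	CHEK2	benign	3	c.283C>T
chr11	108244076	CA	C	ATM	pathogenic	3	c.2341del
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "catalog.tsv"
    path.write_text(TABLE)
    catalog = pv.load_variant_table(path, "tsv")
    print(f"loaded           : {len(catalog)} variants")

    catalog = pv.filter_clinical(catalog, min_stars=3)
    print(f"P/LP, >=3 stars  : {len(catalog)} variants")

    catalog = pv.select_snvs(catalog)
    print(f"SNVs only        : {len(catalog)} variants")

    catalog = pv.assign_pathways(catalog, pv.load_gene_panel())
    for v in catalog:
        print(f"  {v.gene:6s} {v.label:22s} pathways={','.join(sorted(v.pathways))}")

# The filter trail records every step, so |input| == |kept| + |removed|
# is auditable after the fact.
for entry in catalog.filter_trail:
    print(f"{entry['op']:16s} kept {entry['n_kept']:2d} removed {entry['n_removed']}")
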