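"""Simulate a vertebrate alignment with planted convergent alleles, then ask
which species share each human alternate allele.

"Shared" means the species' base at the orthologous alignment column equals
the human ALTERNATE allele — the signature that would look like cross-species
conservation of a pathogenic variant. The simulator plants convergent
alleles in distal species (chicken, frog) so the closed loop is checkable.
"""

import tempfile
from pathlib import Path

import paleopv as pv

tree = ("((human:0.02,chimp:0.02):0.05,"
        "((mouse:0.2,rat:0.2):0.05,(chicken:0.3,frog:0.4):0.1):0.1);")
seqs = pv.simulate_species_alignment(tree, 1000, seed=7)

# plant 15 SNVs; make two of them convergently present in distal species
plan = {0: ["chicken"], 1: ["frog", "chicken"]}
catalog, seqs, truth = pv.plant_variants(seqs, 15, convergent_plan=plan, seed=8)

with tempfile.TemporaryDirectory() as tmp:
    maf = Path(tmp) / "alignment.maf"
    pv.write_maf(seqs, maf, n_blocks=4)
    index = pv.index_maf(maf, "human")
    species = sorted(sp for sp in seqs if sp != "human")
    clades = {"chimp": "Primate", "mouse": "Euarchontoglires",
              "rat": "Euarchontoglires", "chicken": "Aves",
              "frog": "Sarcopterygii"}
    matrix = pv.build_sharing_matrix(catalog, index, species, clades)

summary = pv.sharing_summary(matrix)
print(f"variants            : {summary['n_variants']}")
print(f"shared in >=1 sp    : {summary['n_shared_any']} "
      f"({summary['percent_shared']}% of the catalog)")
print(f"per-species shared  : {summary['per_species_shared']}")
print(f"planted truth       : "
      f"{ {k: sorted(v) for k, v in truth.planted.items() if v} }")
# Every planted (variant, species) pair must be called shared; additional
# shared cells are chance identity from the substitution process itself.
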