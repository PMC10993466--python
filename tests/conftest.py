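import numpy as np
import pandas as pd
import pytest

import paleopv as pv


CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "clin_class",
                   "review_stars", "hgvs_c"]


def write_catalog_tsv(path, rows):
    """rows: iterable of dicts with the catalog TSV schema."""
    df = pd.DataFrame(rows)
    for col in CATALOG_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "hgvs_c" else None
    df[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def make_row(chrom="chr1", pos=100, ref="C", alt="T", gene="BRCA1",
             clin_class="pathogenic", review_stars=3, hgvs_c="c.1C>T"):
    return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                clin_class=clin_class, review_stars=review_stars,
                hgvs_c=hgvs_c)


@pytest.fixture
def small_catalog(tmp_path):
    rows = [
        make_row(pos=10, ref="C", alt="T", gene="BRCA1"),
        make_row(pos=20, ref="G", alt="A", gene="BRCA2",
                 clin_class="likely_pathogenic"),
        make_row(pos=30, ref="A", alt="G", gene="TP53", clin_class="benign"),
    ]
    path = write_catalog_tsv(tmp_path / "catalog.tsv", rows)
    return pv.load_variant_table(path, "tsv")


@pytest.fixture
def toy_alignment():
    """Four-species simulated alignment with planted variants and a
    convergent-sharing plan; returns (catalog, seqs, truth)."""
    tree = "((human:0.02,chimp:0.02):0.05,(mouse:0.2,chicken:0.4):0.1);"
    seqs = pv.simulate_species_alignment(tree, 800, seed=101)
    plan = {0: ["chicken"], 1: ["mouse", "chicken"], 2: ["chimp"]}
    return pv.plant_variants(seqs, 12, convergent_plan=plan, seed=102)
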