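"""Pipeline orchestration, configuration, and result export.

The pipeline chains catalog -> sharing -> ancient scan -> comparisons as
configured and exports TSV/JSON tables plus a single-file SQLite mirror of
the carrier annotations (accession, dated time, location, depth, HGVS).
:func:`fixture_report` recomputes every headline quantity from the packaged
fixture tables by exact arithmetic; it is what the acceptance machinery and
the `paleopv fixtures` subcommand run.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import ValidationError, percent
from . import ancient_calling as ac
from . import comparison_stats as cs
from . import maf_sharing as ms
from . import pv_catalog as pc
from .synthetic_data import load_paper_fixtures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run; serialized verbatim into
    every output directory."""

    out_dir: str
    catalog: str | None = None
    catalog_format: str = "tsv"
    maf: str | None = None
    reference_assembly: str = "human"
    species_map: str | None = None
    pileups: str | None = None
    metadata: str | None = None
    gene_panel: str | None = None
    keep_classes: tuple = ("pathogenic", "likely_pathogenic")
    min_stars: int = 3
    k: int = 3
    min_baseq: int = 1
    min_clean_alt: int = 1
    bin_edges: tuple = cs.DEFAULT_BIN_EDGES
    n_boot: int = 1000
    seed: int = 0
    version: str = "1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        missing = [k for k in ("out_dir",) if k not in raw]
        if missing:
            raise ValidationError(f"config missing required key(s): {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config has unknown key(s): {sorted(unknown)}")
        for key in ("keep_classes", "bin_edges"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()}, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all output tables.

    Returns the machine-readable summary (also written as summary.json).
    Any stage failure aborts with the stage named in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config.yaml")
    summary: dict = {"stages": []}

    catalog = None
    if config.catalog:
        try:
            catalog = pc.load_variant_table(config.catalog, config.catalog_format)
            panel = pc.load_gene_panel(config.gene_panel)
            catalog = pc.filter_clinical(catalog, config.keep_classes,
                                         config.min_stars)
            catalog = pc.select_snvs(catalog)
            catalog = pc.assign_pathways(catalog, panel)
        except Exception as e:
            raise RuntimeError(f"stage=catalog input={config.catalog}: {e}") from e
        catalog.to_dataframe().to_csv(out / "catalog.tsv", sep="\t", index=False)
        summary["stages"].append("catalog")
        summary["catalog"] = {"n_snvs": len(catalog),
                              "filter_trail": list(catalog.filter_trail)}

    if config.maf and catalog is not None:
        try:
            spmap = ms.load_species_map(config.species_map)
            species = [s for s in spmap["species"]
                       if s != config.reference_assembly]
            clades = dict(zip(spmap["species"], spmap["clade"]))
            index = ms.index_maf(config.maf, config.reference_assembly)
            matrix = ms.build_sharing_matrix(catalog, index, species, clades)
        except Exception as e:
            raise RuntimeError(f"stage=sharing input={config.maf}: {e}") from e
        matrix.statuses.to_csv(out / "sharing_matrix.tsv", sep="\t")
        summary["stages"].append("sharing")
        summary["sharing"] = ms.sharing_summary(matrix)

    calls = None
    if config.pileups and config.metadata and catalog is not None:
        try:
            pileup = ac.read_pileup_tsv(config.pileups)
            samples = ac.read_sample_metadata(config.metadata)
            calls = ac.scan_samples(catalog, pileup, samples,
                                    min_baseq=config.min_baseq, k=config.k,
                                    min_clean_alt=config.min_clean_alt)
        except Exception as e:
            raise RuntimeError(f"stage=ancient input={config.pileups}: {e}") from e
        calls.to_csv(out / "carriers.tsv", sep="\t", index=False)
        export_sqlite(calls, out / "carriers.sqlite")
        summary["stages"].append("ancient")
        summary["ancient"] = ac.scan_summary(calls)
        present = calls[calls["status"] == "present"]
        timing = cs.timing_summary(present, config.bin_edges)
        recurrence = cs.recurrence_summary(calls)
        summary["timing"] = {k: v for k, v in timing.items() if k != "per_pv"}
        summary["recurrence"] = {
            k: v for k, v in recurrence.items() if k != "recurrent"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def export_sqlite(calls: pd.DataFrame, path: str | Path,
                  table: str = "carriers") -> None:
    """Mirror the carrier table into a single-file SQLite database
    (accession, dated time, location, depth, and variant annotation)."""
    with sqlite3.connect(str(path)) as conn:
        calls.to_sql(table, conn, if_exists="replace", index=False)


def fixture_report() -> dict:
    """Recompute every headline quantity from the packaged fixture tables.

    All percentages are exact arithmetic on the printed counts, rounded half
    away from zero to the printed precision. Where a printed percentage is
    internally inconsistent with its own counts, the exact value is reported.
    """
    counts = load_paper_fixtures("results_counts")
    t2 = load_paper_fixtures("table2_primate_sharing")
    t4 = load_paper_fixtures("table4_gene_counts")
    t5 = load_paper_fixtures("table5_chek2")
    t6 = load_paper_fixtures("table6_founders")

    profile = cs.abundance_profile(t4)
    founders = cs.founder_summary(t6)

    # Timing bins recomputed by running the binning on a carrier table built
    # from the printed dated-carrier counts (one row per dated carrier).
    dates = ([2500.0] * counts["carriers_within_5000"]
             + [7500.0] * counts["carriers_5000_10000"]
             + [15000.0] * counts["carriers_before_10000"])
    timing = cs.timing_summary(pd.DataFrame({"date_bp": dates}))

    # Headline sharing percentage recomputed through the matrix summary on a
    # catalog-sized single-species matrix with the printed shared count.
    statuses = pd.DataFrame({
        "nonhuman": [ms.SHARED] * counts["shared_pvs"]
        + [ms.NOT_SHARED] * (counts["snv_pvs"] - counts["shared_pvs"])})
    statuses.index = [f"v{i}" for i in range(len(statuses))]
    sharing = ms.sharing_summary(ms.SharingMatrix(statuses, {}))

    panel = pc.load_gene_panel()
    pathway = cs.pathway_summary(t4, panel)
    total_row = pathway[pathway["pathway"] == "Total"].iloc[0]

    return {
        "snv_pvs": counts["snv_pvs"],
        "shared_pvs": counts["shared_pvs"],
        "percent_pvs_shared": sharing["percent_shared"],
        "species_sharing": counts["species_sharing"],
        "percent_species_sharing": percent(counts["species_sharing"],
                                           counts["species_total"], 1),
        "primate_shared_entries": int(len(t2)),
        "ancient_pvs_total": profile.total,
        "ancient_genes_with_pvs": len(profile.counts),
        "percent_genes_with_ancient_pvs": percent(len(profile.counts),
                                                  counts["snv_genes"], 1),
        "mlh1_ancient_abundance_percent": percent(profile.counts["MLH1"],
                                                  profile.total, 1),
        "tp53_ancient_abundance_percent": percent(profile.counts["TP53"],
                                                  profile.total, 1),
        "msh2_ancient_abundance_percent": percent(profile.counts["MSH2"],
                                                  profile.total, 1),
        "percent_recurrent_pvs": percent(counts["recurrent_pvs"],
                                         counts["ancient_pvs"], 1),
        "percent_recurrent_genes": percent(counts["recurrent_genes"],
                                           counts["ancient_genes"], 1),
        "chek2_pv_count": int(len(t5)),
        "chek2_carrier_total": int(t5["carriers"].sum()),
        "founder_pv_count": founders["n_founders"],
        "founder_gene_count": founders["n_genes"],
        "brca1_founder_percent": founders["gene_percent"]["BRCA1"],
        "founder_oldest_bp": founders["oldest_bp"],
        "founder_youngest_bp": founders["youngest_bp"],
        "timing_within_5000_percent": timing["percent"]["within_5000"],
        "timing_5000_to_10000_percent": timing["percent"]["5000_to_10000"],
        "timing_before_10000_percent": timing["percent"]["before_10000"],
        "dated_carriers": timing["n_dated"],
        "pathway_total_pvs": int(total_row["pvs"]),
        "pathway_total_genes": int(total_row["genes_with_pvs"]),
    }
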