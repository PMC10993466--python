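"""Cohort comparison statistics: per-gene PV abundance, Pearson correlation,
Kruskal-Wallis group comparison, carrier-timing bins, recurrence, pathway and
founder-variant summaries.

All printed percentages use exact rational arithmetic rounded half away from
zero; re-running any summary on permuted input rows yields identical output
(tables are canonically sorted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ContractError, ValidationError, percent, round_half_away
from .pv_catalog import DdrGeneSet, PATHWAYS

logger = logging.getLogger(__name__)

#: Carrier-date bins in years BP: "within 5000" = (0, 5000],
#: "between 5000 and 10,000" = (5000, 10000], "before 10,000" = (10000, inf).
DEFAULT_BIN_EDGES = (0.0, 5000.0, 10000.0)


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-gene PV counts and their ratios to the cohort total."""

    counts: Mapping[str, int]
    total: int

    def ratio(self, gene: str) -> float:
        return self.counts.get(gene, 0) / self.total

    @property
    def ratios(self) -> dict:
        return {g: n / self.total for g, n in self.counts.items()}


@dataclass(frozen=True)
class ComparisonResult:
    pearson_r: float
    p_two_tailed: float
    n_genes: int
    note: str = ""
    degenerate: bool = False


def abundance_profile(pv_table, by: str = "gene") -> AbundanceProfile:
    """Per-gene counts and ratios (count_g / total) from either a table with
    one row per PV or a (gene, count) table with a 'pvs' column."""
    if isinstance(pv_table, pd.DataFrame):
        if len(pv_table) == 0:
            raise ValidationError("abundance_profile requires at least one PV")
        if "pvs" in pv_table.columns:
            counts = dict(zip(pv_table[by], pv_table["pvs"].astype(int)))
        else:
            counts = pv_table.groupby(by).size().astype(int).to_dict()
    else:
        counts = {g: int(n) for g, n in dict(pv_table).items()}
        if not counts:
            raise ValidationError("abundance_profile requires at least one PV")
    total = int(sum(counts.values()))
    if total <= 0:
        raise ValidationError("abundance_profile requires a positive total")
    profile = AbundanceProfile(counts=counts, total=total)
    assert abs(sum(profile.ratios.values()) - 1.0) < 1e-12
    return profile


def compare_abundance(profile_a: AbundanceProfile,
                      profile_b: AbundanceProfile) -> ComparisonResult:
    """Pearson correlation of aligned per-gene ratio vectors.

    Genes are aligned by symbol over the union; a gene absent from one cohort
    enters with count 0. The two-tailed p-value is the t-test with n-2
    degrees of freedom. Zero-variance vectors are flagged degenerate.
    """
    genes = sorted(set(profile_a.counts) | set(profile_b.counts))
    if len(genes) < 3:
        raise ContractError("compare_abundance needs >= 3 genes in the union")
    a = np.array([profile_a.ratio(g) for g in genes])
    b = np.array([profile_b.ratio(g) for g in genes])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ComparisonResult(float("nan"), float("nan"), len(genes),
                                note="zero-variance ratio vector", degenerate=True)
    r, p = stats.pearsonr(a, b)
    return ComparisonResult(float(r), float(p), len(genes),
                            note="Pearson r on per-gene PV ratios")


def group_compare(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis one-way rank test (tie-corrected) across groups."""
    groups = {k: list(v) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ContractError("group_compare needs >= 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ContractError("every group needs >= 1 observation")
    sample_values = [v for vals in groups.values() for v in vals]
    if len(set(sample_values)) == 1:
        # All observations identical: H = 0 by definition, p = 1.
        return {"H": 0.0, "p": 1.0, "df": len(groups) - 1}
    h, p = stats.kruskal(*groups.values())
    return {"H": float(h), "p": float(p), "df": len(groups) - 1}


def timing_summary(carrier_table: pd.DataFrame,
                   bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> dict:
    """Bin dated carriers by years BP and summarize per-PV date spans.

    Bins are (e0, e1], (e1, e2], (e2, inf); undated carriers are counted
    separately. 'Earliest' means the largest BP value. Percentages are over
    the dated carriers, to one decimal.
    """
    e0, e1, e2 = bin_edges
    dated = carrier_table[carrier_table["date_bp"].notna()]
    undated = len(carrier_table) - len(dated)
    d = dated["date_bp"].astype(float)
    bins = {
        f"within_{int(e1)}": int(((d > e0) & (d <= e1)).sum()),
        f"{int(e1)}_to_{int(e2)}": int(((d > e1) & (d <= e2)).sum()),
        f"before_{int(e2)}": int((d > e2).sum()),
    }
    n_dated = int(len(d))
    assert sum(bins.values()) == n_dated
    per_pv = None
    if "variant" in carrier_table.columns and len(dated):
        per_pv = (dated.groupby("variant")["date_bp"]
                  .agg(earliest_bp="max", latest_bp="min", carriers="count")
                  .sort_index())
    percents = {k: (percent(v, n_dated, 1) if n_dated else 0.0)
                for k, v in bins.items()}
    return {"bins": bins, "percent": percents, "n_dated": n_dated,
            "n_undated": int(undated), "per_pv": per_pv}


def recurrence_summary(carrier_table: pd.DataFrame,
                       min_carriers: int = 2) -> dict:
    """Recurrent PVs (>= min_carriers distinct carriers) among present calls.

    Fraction is recurrent PVs / total distinct PVs, to one decimal.
    """
    present = carrier_table
    if "status" in carrier_table.columns:
        present = carrier_table[carrier_table["status"] == "present"]
    if len(present) == 0:
        return {"recurrent": pd.DataFrame(), "n_recurrent_pvs": 0,
                "n_total_pvs": 0, "n_recurrent_genes": 0,
                "percent_recurrent": 0.0}
    grouped = present.groupby("variant").agg(
        carriers=("sample_id", "nunique"),
        gene=("gene", "first"),
        first_bp=("date_bp", "max"),
        last_bp=("date_bp", "min"),
    ).sort_index()
    recurrent = grouped[grouped["carriers"] >= min_carriers]
    n_total = int(len(grouped))
    return {
        "recurrent": recurrent,
        "n_recurrent_pvs": int(len(recurrent)),
        "n_total_pvs": n_total,
        "n_recurrent_genes": int(recurrent["gene"].nunique()),
        "percent_recurrent": percent(len(recurrent), n_total, 1) if n_total else 0.0,
    }


def pathway_summary(pv_table: pd.DataFrame, geneset: DdrGeneSet) -> pd.DataFrame:
    """Per-pathway (genes with PVs, gene %, PV count) plus nonredundant totals.

    A gene in several pathways contributes to each of its pathway rows; the
    Total row deduplicates genes and PVs across pathways. Expects a table
    with a 'gene' column and either one row per PV or a 'pvs' count column.
    """
    if "pvs" in pv_table.columns:
        counts = dict(zip(pv_table["gene"], pv_table["pvs"].astype(int)))
    else:
        counts = pv_table.groupby("gene").size().astype(int).to_dict()
    rows = []
    for pw in PATHWAYS:
        panel = geneset.genes_in(pw)
        with_pvs = sorted(g for g in counts if pw in geneset.pathways_of(g))
        n_pvs = sum(counts[g] for g in with_pvs)
        rows.append({
            "pathway": pw,
            "panel_genes": len(panel),
            "genes_with_pvs": len(with_pvs),
            "gene_percent": percent(len(with_pvs), len(panel), 1) if panel else 0.0,
            "pvs": int(n_pvs),
        })
    on_panel = sorted(g for g in counts if g in geneset)
    rows.append({
        "pathway": "Total",
        "panel_genes": len(geneset),
        "genes_with_pvs": len(on_panel),
        "gene_percent": percent(len(on_panel), len(geneset), 1),
        "pvs": int(sum(counts[g] for g in on_panel)),
    })
    off_panel = sorted(set(counts) - geneset.genes)
    if off_panel:
        logger.warning("pathway_summary: %d gene(s) off panel: %s",
                       len(off_panel), ", ".join(off_panel))
    return pd.DataFrame(rows)


def parse_age_bp(raw) -> tuple[float, float, float]:
    """Parse a founder age that may be a point, a 'hi-lo' range, or a one-
    sided bound ('<x', '>x'). Returns (lower, upper, representative) where
    the representative is the range midpoint and bounds collapse to their
    stated endpoint."""
    s = str(raw).strip().replace(",", "").replace("–", "-").replace("—", "-")
    if s.startswith("<") or s.startswith(">"):
        v = float(s[1:])
        return (v, v, v)
    if "-" in s and not s.startswith("-"):
        hi, lo = (float(x) for x in s.split("-", 1))
        lo, hi = min(lo, hi), max(lo, hi)
        return (lo, hi, (lo + hi) / 2.0)
    v = float(s)
    return (v, v, v)


def founder_summary(founder_table: pd.DataFrame) -> dict:
    """Per-gene founder-PV counts, gene fractions (1 d.p.), and the overall
    representative age range. Order-invariant."""
    df = founder_table.copy()
    ages = df["year_bp"].map(parse_age_bp)
    df["age_rep"] = [a[2] for a in ages]
    if (df["age_rep"] <= 0).any():
        raise ValidationError("founder ages must be > 0")
    per_gene = df.groupby("gene").size().sort_index()
    total = int(len(df))
    return {
        "n_founders": total,
        "n_genes": int(per_gene.size),
        "per_gene": per_gene.astype(int).to_dict(),
        "gene_percent": {g: percent(n, total, 1) for g, n in per_gene.items()},
        "oldest_bp": round_half_away(float(df["age_rep"].max()), 0),
        "youngest_bp": round_half_away(float(df["age_rep"].min()), 0),
    }
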