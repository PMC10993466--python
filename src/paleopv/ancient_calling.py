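"""Detection of catalog PVs in ancient-sample pileups with deamination-aware
filtering.

Post-mortem cytosine deamination reads as C->T mismatches near 5' read ends
(and G->A near 3' ends on the complementary strand), with a per-position
rate decaying roughly exponentially into the read: rate(i) = d0 * exp(-lam*i).
The damage filter discards deamination-consistent alternate-allele support
within ``k`` bases of the relevant read end; presence is a detection call
(>= ``min_clean_alt`` surviving alternate reads), not a diploid genotype.

The canonical input is a pileup TSV (one row per read observation per site);
an optional SAM reader producing the same rows is provided via pysam.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ContractError, SchemaError, ValidationError
from .pv_catalog import PvCatalog, Variant

logger = logging.getLogger(__name__)

SAMPLE_GROUPS = frozenset({"ancient_human", "neanderthal", "denisovan"})

PILEUP_COLUMNS = ("sample_id", "chrom", "pos", "ref", "base", "baseq",
                  "dist5", "dist3", "strand", "read_id")

#: Header line identifying the pileup TSV dialect.
PILEUP_VERSION_LINE = "#paleopv-pileup\tv1"


@dataclass(frozen=True)
class ReadObservation:
    base: str
    baseq: int
    dist5: int      # 0-based distance from the read's 5' end
    dist3: int      # 0-based distance from the read's 3' end
    strand: str = "+"
    read_id: str = ""

    def __post_init__(self):
        if self.baseq < 0 or self.dist5 < 0 or self.dist3 < 0:
            raise ValidationError("baseq/dist5/dist3 must be non-negative")


@dataclass(frozen=True)
class PileupSite:
    sample_id: str
    chrom: str
    pos: int        # 1-based
    ref: str
    observations: tuple = ()

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class AncientSample:
    sample_id: str
    date_bp: float | None = None
    location: str = ""
    group: str = "ancient_human"

    def __post_init__(self):
        if self.group not in SAMPLE_GROUPS:
            raise ValidationError(f"unknown sample group {self.group!r}")
        if self.date_bp is not None and not self.date_bp > 0:
            raise ValidationError("date_bp must be > 0 when present")


@dataclass(frozen=True)
class DamageModel:
    """Exponentially decaying terminal deamination: rate(i) = d0*exp(-lam*i)."""

    d0: float
    lam: float
    k: int = 3
    frequencies: tuple = field(default=(), compare=False)  # raw per-position C->T freq

    def __post_init__(self):
        if not 0.0 <= self.d0 <= 1.0 or self.lam < 0 or self.k < 0:
            raise ContractError("require 0 <= d0 <= 1, lam >= 0, k >= 0")

    def rate(self, i: int) -> float:
        return self.d0 * float(np.exp(-self.lam * i))


@dataclass(frozen=True)
class CarrierCall:
    sample_id: str
    variant_key: tuple
    depth: int
    alt_total: int
    alt_clean: int
    status: str                 # present / absent / no_data
    low_depth: bool = False
    damage_only: bool = False

    def __post_init__(self):
        if not (self.alt_clean <= self.alt_total <= self.depth):
            raise ValidationError("require alt_clean <= alt_total <= depth")


def damage_suspect(obs: ReadObservation, ref: str, alt: str, k: int) -> bool:
    """True iff this observation's alternate support is consistent with
    terminal deamination: a C->T mismatch within k bases of the 5' end or a
    G->A mismatch within k bases of the 3' end. All other substitution
    classes are never suspect."""
    if ref == "C" and alt == "T" and obs.base == "T" and obs.dist5 < k:
        return True
    if ref == "G" and alt == "A" and obs.base == "A" and obs.dist3 < k:
        return True
    return False


def call_variant_presence(site: PileupSite, variant: Variant,
                          min_baseq: int = 1, k: int = 3,
                          min_clean_alt: int = 1) -> CarrierCall:
    """Presence call at one site: quality filter, then damage filter, then a
    >= min_clean_alt detection threshold.

    ``min_baseq`` defaults to 1 (maximally permissive, matching the upstream
    calling convention). ``damage_only`` marks sites whose entire alternate
    support was removed by the damage filter.
    """
    if (site.chrom, site.pos) != (variant.chrom, variant.pos):
        raise ContractError(
            f"site {site.chrom}:{site.pos} does not match variant {variant.label}"
        )
    obs = [o for o in site.observations if o.baseq >= min_baseq]
    depth = len(obs)
    if depth == 0:
        return CarrierCall(site.sample_id, variant.key, 0, 0, 0, "no_data")
    alt_obs = [o for o in obs if o.base == variant.alt]
    alt_total = len(alt_obs)
    alt_clean = sum(
        1 for o in alt_obs if not damage_suspect(o, variant.ref, variant.alt, k)
    )
    status = "present" if alt_clean >= min_clean_alt else "absent"
    return CarrierCall(
        sample_id=site.sample_id, variant_key=variant.key, depth=depth,
        alt_total=alt_total, alt_clean=alt_clean, status=status,
        low_depth=depth < 2, damage_only=(alt_total >= 1 and alt_clean == 0),
    )


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    """Read the canonical pileup TSV (versioned '#paleopv-pileup' header
    optional)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "chrom": str, "ref": str,
                            "base": str, "strand": str, "read_id": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: pileup TSV missing column(s): {sorted(missing)}")
    return df


def read_sample_metadata(path: str | Path) -> dict:
    """Sample metadata TSV (sample_id, date_bp, location, group) ->
    {sample_id: AncientSample}."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "date_bp", "location", "group"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: metadata missing column(s): {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        date = None if pd.isna(row.date_bp) else float(row.date_bp)
        out[row.sample_id] = AncientSample(row.sample_id, date,
                                           str(row.location), str(row.group))
    return out


def sites_from_pileup(pileup: pd.DataFrame) -> dict:
    """Group pileup rows into PileupSite objects keyed by
    (sample_id, chrom, pos)."""
    sites = {}
    for (sid, chrom, pos), grp in pileup.groupby(["sample_id", "chrom", "pos"],
                                                 sort=True):
        ref = grp["ref"].iloc[0]
        obs = tuple(
            ReadObservation(base=r.base, baseq=int(r.baseq), dist5=int(r.dist5),
                            dist3=int(r.dist3), strand=r.strand,
                            read_id=str(r.read_id))
            for r in grp.itertuples(index=False)
        )
        sites[(sid, chrom, int(pos))] = PileupSite(sid, chrom, int(pos), ref, obs)
    return sites


def scan_samples(catalog: PvCatalog, pileup: pd.DataFrame,
                 samples: Mapping[str, AncientSample],
                 min_baseq: int = 1, k: int = 3,
                 min_clean_alt: int = 1) -> pd.DataFrame:
    """Carrier-call table over (sample, catalog SNV) pairs with pileup data.

    Joins sample dates/locations/groups; deterministic. Raises when the
    pileup carries sample ids missing from the metadata.
    """
    orphan = sorted(set(pileup["sample_id"]) - set(samples))
    if orphan:
        raise ValidationError(f"pileup sample id(s) missing from metadata: {orphan}")
    by_pos = {}
    for v in catalog:
        if v.is_snv:
            by_pos.setdefault((v.chrom, v.pos), []).append(v)
    sites = sites_from_pileup(pileup)
    records = []
    for (sid, chrom, pos), site in sites.items():
        for v in by_pos.get((chrom, pos), ()):
            call = call_variant_presence(site, v, min_baseq=min_baseq, k=k,
                                         min_clean_alt=min_clean_alt)
            meta = samples[sid]
            records.append({
                "sample_id": sid, "chrom": chrom, "pos": pos, "ref": v.ref,
                "alt": v.alt, "gene": v.gene, "variant": v.label,
                "depth": call.depth, "alt_total": call.alt_total,
                "alt_clean": call.alt_clean, "status": call.status,
                "low_depth": call.low_depth, "damage_only": call.damage_only,
                "date_bp": meta.date_bp, "location": meta.location,
                "group": meta.group,
            })
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "variant",
            "depth", "alt_total", "alt_clean", "status", "low_depth",
            "damage_only", "date_bp", "location", "group"]
    table = pd.DataFrame.from_records(records, columns=cols)
    return table.sort_values(["sample_id", "chrom", "pos", "alt"],
                             kind="mergesort").reset_index(drop=True)


def scan_summary(calls: pd.DataFrame) -> dict:
    """Headline counts over a carrier-call table."""
    present = calls[calls["status"] == "present"]
    return {
        "n_calls": len(calls),
        "n_present": len(present),
        "n_distinct_pvs": int(present["variant"].nunique()),
        "n_carriers": int(present["sample_id"].nunique()),
        "n_genes": int(present["gene"].nunique()),
    }


def estimate_damage_profile(pileup: pd.DataFrame, max_pos: int = 20,
                            k: int = 3) -> DamageModel:
    """Fit the exponential deamination model from 5' C->T mismatch counts.

    For each 5'-distance i < max_pos, mismatches are T observations among
    C/T observations whose site reference is C. (d0, lam) maximize the
    binomial likelihood with p_i = d0*exp(-lam*i), initialized from a
    least-squares line through the log-frequencies (zero-count positions
    skipped). Needs >= 2 positions with nonzero mismatch counts to identify
    two parameters; warns below 1000 C-reference observations.
    """
    from scipy.optimize import minimize

    cref = pileup[(pileup["ref"] == "C") & (pileup["dist5"] < max_pos)
                  & (pileup["base"].isin(["C", "T"]))]
    if len(cref) == 0:
        raise ValidationError("no C-reference observations; cannot estimate damage")
    if len(cref) < 1000:
        warnings.warn(
            f"only {len(cref)} C-reference observations; damage estimate may be "
            "unstable", stacklevel=2)
    freqs = np.zeros(max_pos)
    xs, ts, ns = [], [], []
    for i in range(max_pos):
        sub = cref[cref["dist5"] == i]
        if len(sub) == 0:
            continue
        t = int((sub["base"] == "T").sum())
        freqs[i] = t / len(sub)
        xs.append(float(i))
        ts.append(float(t))
        ns.append(float(len(sub)))
    xs, ts, ns = np.array(xs), np.array(ts), np.array(ns)
    nonzero = ts > 0
    if nonzero.sum() < 2:
        raise ValidationError(
            "fewer than 2 positions with nonzero C->T counts; cannot fit a "
            "two-parameter decay")
    slope, intercept = np.polyfit(xs[nonzero], np.log(ts[nonzero] / ns[nonzero]), 1)
    x0 = (float(np.clip(np.exp(intercept), 1e-4, 1.0)),
          float(np.clip(-slope, 0.0, 10.0)))

    def nll(theta):
        d0, lam = theta
        p = np.clip(d0 * np.exp(-lam * xs), 1e-12, 1 - 1e-12)
        return -np.sum(ts * np.log(p) + (ns - ts) * np.log(1 - p))

    fit = minimize(nll, x0=x0, bounds=[(1e-6, 1.0), (0.0, 10.0)],
                   method="L-BFGS-B")
    d0, lam = (float(v) for v in fit.x)
    return DamageModel(d0=d0, lam=lam, k=k, frequencies=tuple(freqs))


def sam_to_pileup(sam_path: str | Path, sites: Iterable[tuple],
                  sample_id: str) -> pd.DataFrame:
    """Optional SAM ingestion: extract per-read observations at the requested
    (chrom, 1-based pos) sites into the canonical pileup schema.

    Streams the file once (no index required); the reference column is left
    as 'N' — callers match observations against catalog alleles. Distances
    are from the sequenced molecule's 5'/3' ends (reverse-strand aware);
    bases are reported in reference orientation, matching the pileup
    convention.
    """
    import pysam

    wanted = {}
    for chrom, pos1 in sites:
        wanted.setdefault(chrom, set()).add(int(pos1))
    records = []
    with pysam.AlignmentFile(str(sam_path), "r") as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in wanted:
                continue
            positions = wanted[read.reference_name]
            rlen = read.query_length
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos + 1 not in positions:
                    continue
                if read.is_reverse:
                    dist5, dist3, strand = rlen - 1 - qpos, qpos, "-"
                else:
                    dist5, dist3, strand = qpos, rlen - 1 - qpos, "+"
                records.append({
                    "sample_id": sample_id, "chrom": read.reference_name,
                    "pos": rpos + 1, "ref": "N",
                    "base": read.query_sequence[qpos].upper(),
                    "baseq": int(read.query_qualities[qpos]),
                    "dist5": dist5, "dist3": dist3, "strand": strand,
                    "read_id": read.query_name,
                })
    return pd.DataFrame.from_records(records, columns=list(PILEUP_COLUMNS))
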