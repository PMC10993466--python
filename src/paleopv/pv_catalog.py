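"""Modern-human pathogenic-variant catalog for DNA-damage-repair (DDR) genes.

The catalog is the study's fixed point: ClinVar-style pathogenic and likely
pathogenic variants (PVs) in a DDR gene panel, filtered by review confidence,
restricted to single-nucleotide variants, and tagged with repair-pathway
membership. Coordinates are 1-based, fully closed, VCF-style throughout;
conversion to 0-based alignment coordinates happens only at the MAF boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from ._util import ContractError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

CLIN_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign",
     "conflicting"}
)

#: The eight DDR pathways used for panel annotation.
PATHWAYS = ("FA", "HR", "MMR", "NER", "NHEJ", "DDR_response", "BER", "DR")

_BASES = frozenset("ACGT")

# ClinVar CLNSIG vocabulary -> internal clinical class.
_CLNSIG_MAP = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "pathogenic/likely_pathogenic": "pathogenic",
    "uncertain_significance": "uncertain",
    "likely_benign": "likely_benign",
    "benign": "benign",
    "benign/likely_benign": "benign",
}

# ClinVar CLNREVSTAT vocabulary -> review stars (0-4).
_REVSTAT_STARS = {
    "practice_guideline": 4,
    "reviewed_by_expert_panel": 3,
    "criteria_provided,_multiple_submitters,_no_conflicts": 2,
    "criteria_provided,_conflicting_interpretations": 1,
    "criteria_provided,_single_submitter": 1,
    "no_assertion_criteria_provided": 0,
    "no_assertion_provided": 0,
}


def normalize_clin_class(raw: str) -> str:
    """Map a ClinVar significance string onto the closed class vocabulary."""
    token = str(raw).strip().lower().replace(" ", "_")
    if "conflicting" in token:
        return "conflicting"
    if token in CLIN_CLASSES:
        return token
    if token in _CLNSIG_MAP:
        return _CLNSIG_MAP[token]
    raise ValidationError(f"unrecognized clinical class {raw!r}")


@dataclass(frozen=True)
class Variant:
    """One catalog variant in 1-based closed coordinates.

    ``is_snv`` is derived from allele lengths; indels carry their raw allele
    strings. ``pathways`` / ``off_panel`` are filled by :func:`assign_pathways`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    clin_class: str
    review_stars: int
    hgvs_c: str = ""
    hgvs_p: str | None = None
    rsid: str | None = None
    is_snv: bool = field(default=False)
    pathways: frozenset = frozenset()
    off_panel: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.clin_class not in CLIN_CLASSES:
            raise ValidationError(f"unknown clinical class {self.clin_class!r}")
        if not 0 <= self.review_stars <= 4:
            raise ValidationError(f"review_stars out of range: {self.review_stars}")
        snv = len(self.ref) == 1 == len(self.alt) and {self.ref, self.alt} <= _BASES
        object.__setattr__(self, "is_snv", snv)
        if snv and self.ref == self.alt:
            raise ValidationError(
                f"SNV with ref == alt ({self.ref}) at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


class DdrGeneSet:
    """Gene -> pathway-set map over the eight DDR pathways."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset] = {}
        for gene, pws in mapping.items():
            pws = frozenset(pws)
            bad = pws - set(PATHWAYS)
            if bad:
                raise ValidationError(f"unknown pathway label(s) {sorted(bad)} for {gene}")
            self._map[gene] = pws

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def genes(self) -> frozenset:
        return frozenset(self._map)

    def pathways_of(self, gene: str) -> frozenset:
        return self._map.get(gene, frozenset())

    def genes_in(self, pathway: str) -> frozenset:
        if pathway not in PATHWAYS:
            raise ContractError(f"unknown pathway {pathway!r}")
        return frozenset(g for g, pws in self._map.items() if pathway in pws)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DdrGeneSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(df, ["gene", "pathways"], path)
        return cls({r.gene: r.pathways.split(",") for r in df.itertuples()})


def load_gene_panel(path: str | Path | None = None) -> DdrGeneSet:
    """Load the gene->pathway panel (packaged default, user-replaceable)."""
    if path is not None:
        return DdrGeneSet.from_tsv(path)
    ref = resources.files("paleopv.data") / "ddr_gene_pathways.tsv"
    with resources.as_file(ref) as p:
        return DdrGeneSet.from_tsv(p)


@dataclass
class PvCatalog:
    """An immutable-by-convention variant list plus an append-only filter trail."""

    variants: tuple
    geneset: DdrGeneSet | None = None
    filter_trail: tuple = ()

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def _derive(self, variants: Sequence[Variant], op: str, params: dict) -> "PvCatalog":
        entry = {
            "op": op,
            "params": dict(params),
            "n_in": len(self.variants),
            "n_kept": len(variants),
            "n_removed": len(self.variants) - len(variants),
        }
        return PvCatalog(tuple(variants), self.geneset, self.filter_trail + (entry,))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "clin_class": v.clin_class,
                "review_stars": v.review_stars, "hgvs_c": v.hgvs_c,
                "hgvs_p": v.hgvs_p, "rsid": v.rsid, "is_snv": v.is_snv,
                "pathways": ",".join(sorted(v.pathways)), "off_panel": v.off_panel,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


_REQUIRED_TSV = ("chrom", "pos", "ref", "alt", "gene", "clin_class", "review_stars")


def load_variant_table(path: str | Path, format: str = "tsv") -> PvCatalog:
    """Load a variant catalog from a TSV (documented schema) or minimal VCF.

    Duplicate (chrom, pos, ref, alt) rows are rejected with the full list of
    offending keys; single-base alleles outside A/C/G/T raise a row-level
    validation error naming the line.
    """
    if format == "tsv":
        variants = _load_tsv(path)
    elif format == "vcf":
        variants = _load_vcf(path)
    else:
        raise ContractError(f"format must be 'tsv' or 'vcf', got {format!r}")

    seen: dict[tuple, int] = {}
    dups = []
    for v in variants:
        if v.key in seen:
            dups.append(v.key)
        seen[v.key] = seen.get(v.key, 0) + 1
    if dups:
        keys = ", ".join(f"{c}:{p}{r}>{a}" for c, p, r, a in sorted(set(dups)))
        raise ValidationError(
            f"{len(set(dups))} duplicate variant key(s) in {path}: {keys}"
        )

    cat = PvCatalog(tuple(variants))
    return cat._derive(variants, "load", {"path": str(path), "format": format})


def _load_tsv(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "gene": str})
    _require_columns(df, _REQUIRED_TSV, path)
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        for name, allele in (("ref", ref), ("alt", alt)):
            if len(allele) == 1 and allele not in _BASES:
                raise ValidationError(
                    f"{path} line {i}: non-ACGT {name} allele {allele!r}"
                )
        try:
            variants.append(
                Variant(
                    chrom=str(row.chrom), pos=int(row.pos), ref=ref, alt=alt,
                    gene=str(row.gene),
                    clin_class=normalize_clin_class(row.clin_class),
                    review_stars=int(row.review_stars),
                    hgvs_c=str(getattr(row, "hgvs_c", "") or ""),
                    hgvs_p=getattr(row, "hgvs_p", None),
                    rsid=getattr(row, "rsid", None),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path} line {i}: {e}") from e
    return variants


def _load_vcf(path) -> list[Variant]:
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            clnsig = _info_str(info, "CLNSIG")
            revstat = _info_str(info, "CLNREVSTAT")
            geneinfo = _info_str(info, "GENEINFO")
            if clnsig is None or geneinfo is None:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} missing INFO "
                    "CLNSIG/GENEINFO"
                )
            gene = geneinfo.split(":")[0]
            stars = _REVSTAT_STARS.get((revstat or "").lower(), 0)
            for alt in rec.alts or ():
                variants.append(
                    Variant(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref.upper(),
                        alt=alt.upper(), gene=gene,
                        clin_class=normalize_clin_class(clnsig),
                        review_stars=stars,
                        rsid=rec.id if rec.id not in (None, ".") else None,
                    )
                )
    return variants


def _info_str(info, key):
    if key not in info:
        return None
    val = info[key]
    if isinstance(val, tuple):
        val = "|".join(str(x) for x in val)
    return str(val)


def filter_clinical(
    catalog: PvCatalog,
    keep_classes: Iterable[str] = ("pathogenic", "likely_pathogenic"),
    min_stars: int = 3,
    exclude_conflicting: bool = True,
) -> PvCatalog:
    """Restrict to clinical classes / review confidence.

    The review-star cutoff reads "over three stars" as >= 3 by default (the
    star scale tops out at 4, so a strict reading would leave only
    practice-guideline assertions); the choice is logged and configurable.
    """
    keep = frozenset(keep_classes)
    if not keep or not keep <= CLIN_CLASSES:
        raise ContractError(f"keep_classes must be a non-empty subset of {sorted(CLIN_CLASSES)}")
    logger.info(
        "filter_clinical: keep=%s min_stars=%d (star cutoff read as '>= %d'; "
        "ClinVar maximum is 4) exclude_conflicting=%s",
        sorted(keep), min_stars, min_stars, exclude_conflicting,
    )
    kept = [
        v for v in catalog
        if v.clin_class in keep
        and v.review_stars >= min_stars
        and not (exclude_conflicting and v.clin_class == "conflicting")
    ]
    if not kept:
        warnings.warn("filter_clinical produced an empty catalog", stacklevel=2)
    return catalog._derive(
        kept, "filter_clinical",
        {"keep_classes": sorted(keep), "min_stars": min_stars,
         "exclude_conflicting": exclude_conflicting},
    )


def select_snvs(catalog: PvCatalog) -> PvCatalog:
    """Keep single-nucleotide variants only."""
    kept = [v for v in catalog if v.is_snv]
    if not kept:
        warnings.warn("select_snvs produced an empty catalog", stacklevel=2)
    logger.info("select_snvs: retained %d of %d", len(kept), len(catalog))
    return catalog._derive(kept, "select_snvs", {})


def assign_pathways(catalog: PvCatalog, geneset: DdrGeneSet) -> PvCatalog:
    """Tag each variant with its gene's pathway set; off-panel genes are
    flagged, never dropped."""
    tagged = []
    for v in catalog:
        pws = geneset.pathways_of(v.gene)
        tagged.append(replace(v, pathways=pws, off_panel=v.gene not in geneset))
    out = catalog._derive(tagged, "assign_pathways", {"panel_genes": len(geneset)})
    out.geneset = geneset
    return out
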