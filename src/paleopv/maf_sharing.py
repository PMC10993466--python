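"""Cross-species allele sharing against UCSC-style multiple alignments.

A human single-nucleotide PV is "shared" by another species when that
species' base at the orthologous alignment column equals the human
ALTERNATE allele. Unaligned species (gap or absent from the block) count as
not shared in percentage denominators, so the headline percentage is
|variants shared in >= 1 species| / |catalog|.

MAF blocks are parsed with Bio.AlignIO; coordinates follow the MAF
convention (0-based starts, minus-strand starts reckoned on the reverse
complement). Conversion to the catalog's 1-based closed human coordinates
happens in :func:`column_at` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from intervaltree import IntervalTree

from ._util import ContractError, SchemaError
from .pv_catalog import PvCatalog, Variant

logger = logging.getLogger(__name__)

#: The eight vertebrate clades used for grouping species.
CLADES = ("Primate", "Euarchontoglires", "Laurasiatheria", "Afrotheria",
          "Mammalia", "Aves", "Sarcopterygii", "Fish")

SHARED = "shared"
NOT_SHARED = "not_shared"
UNALIGNED = "unaligned"
REF_MISMATCH = "ref_mismatch"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MafRow:
    species: str
    src_chrom: str
    start: int          # 0-based, on the strand's reckoning per MAF
    size: int           # ungapped length
    strand: str         # '+' or '-'
    src_size: int
    text: str           # aligned sequence with '-' gaps


@dataclass(frozen=True)
class MafBlock:
    score: float
    rows: tuple          # MafRow, reference row first
    offset: int          # block ordinal in file (tie-break key)

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


@dataclass(frozen=True)
class AlignmentColumn:
    chrom: str
    pos1: int                      # 1-based human position
    human_base: str
    entries: Mapping[str, str]     # species -> base / "gap" / absent from map
    block_id: int


@dataclass
class MafIndex:
    reference_assembly: str
    blocks: list = field(default_factory=list)
    _trees: dict = field(default_factory=dict)

    def overlapping(self, chrom: str, pos0: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos0]]


def _species_of(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
    else:
        sp, chrom = src, ""
    return sp, chrom


def index_maf(maf_path: str | Path, reference_assembly: str) -> MafIndex:
    """Parse a MAF file and build an interval index from reference (chrom,
    0-based half-open interval) to blocks. Blocks lacking a reference row are
    skipped with a warning; ragged blocks are a parse error."""
    index = MafIndex(reference_assembly=reference_assembly)
    with open(maf_path) as handle:
        try:
            alignments = list(AlignIO.parse(handle, "maf"))
        except ValueError as e:
            raise SchemaError(f"{maf_path}: MAF parse error: {e}") from e

    for offset, aln in enumerate(alignments):
        rows = []
        lengths = {len(rec.seq) for rec in aln}
        if len(lengths) > 1:
            raise SchemaError(f"{maf_path}: block {offset} has ragged row lengths")
        for rec in aln:
            sp, chrom = _species_of(rec.id)
            ann = rec.annotations
            rows.append(MafRow(
                species=sp, src_chrom=chrom, start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                src_size=int(ann.get("srcSize", 0)), text=str(rec.seq),
            ))
        for r in rows:
            if len(r.text.replace("-", "")) != r.size:
                raise SchemaError(
                    f"{maf_path}: block {offset} row {r.species}: ungapped length "
                    f"!= declared size {r.size}"
                )
        ref = next((r for r in rows if r.species == reference_assembly), None)
        if ref is None:
            logger.warning("block %d has no %s row; skipped", offset, reference_assembly)
            continue
        if ref.strand != "+":
            logger.warning("block %d reference row on '-' strand; skipped", offset)
            continue
        # reference row first
        rows = [ref] + [r for r in rows if r is not ref]
        # MafIterator stores the a-line score in the alignment's annotations
        ann = getattr(aln, "annotations", None) or getattr(aln, "_annotations", {})
        score = float(ann.get("score", 0.0))
        block = MafBlock(score=score, rows=tuple(rows), offset=offset)
        index.blocks.append(block)
        tree = index._trees.setdefault(ref.src_chrom, IntervalTree())
        if ref.size > 0:
            tree[ref.start:ref.start + ref.size] = len(index.blocks) - 1
    return index


def column_at(index: MafIndex, chrom: str, pos1: int) -> AlignmentColumn | None:
    """Alignment column at a 1-based human position, or None if uncovered.

    Walks the reference row's gapped text counting non-gap characters to
    locate the column. When several blocks overlap, the highest-score block
    wins; ties go to the lowest file offset.
    """
    if pos1 < 1:
        raise ContractError("pos1 must be >= 1")
    pos0 = pos1 - 1
    hits = index.overlapping(chrom, pos0)
    if not hits:
        return None
    if len(hits) > 1:
        logger.debug("position %s:%d covered by %d blocks; using best score",
                     chrom, pos1, len(hits))
    block_id = min(hits, key=lambda i: (-index.blocks[i].score, index.blocks[i].offset))
    block = index.blocks[block_id]
    ref = block.rows[0]
    target = pos0 - ref.start
    seen = -1
    col = None
    for j, ch in enumerate(ref.text):
        if ch != "-":
            seen += 1
            if seen == target:
                col = j
                break
    if col is None:  # pragma: no cover - interval index guarantees coverage
        return None
    entries = {}
    for r in block.rows[1:]:
        ch = r.text[col]
        entries[r.species] = "gap" if ch == "-" else ch.upper()
    return AlignmentColumn(chrom=chrom, pos1=pos1, human_base=ref.text[col].upper(),
                           entries=entries, block_id=block_id)


def call_sharing(variant: Variant, column: AlignmentColumn,
                 species_list: Sequence[str]) -> dict | str:
    """Per-species sharing statuses for one SNV at its alignment column.

    Returns ``REF_MISMATCH`` when the human base at the column differs from
    the variant's reference allele (the variant is then excluded from
    summaries); otherwise a species -> status dict.
    """
    if not variant.is_snv:
        raise ContractError(f"call_sharing requires an SNV, got {variant.label}")
    if column.human_base != variant.ref:
        return REF_MISMATCH
    out = {}
    for sp in species_list:
        base = column.entries.get(sp)
        if base is None or base == "gap" or base not in _BASES:
            out[sp] = UNALIGNED
        elif base == variant.alt:
            out[sp] = SHARED
        else:
            out[sp] = NOT_SHARED
    return out


@dataclass
class SharingMatrix:
    """variant x species sharing statuses plus a species -> clade map."""

    statuses: pd.DataFrame          # index: variant label, columns: species
    clade_map: dict
    ref_mismatch: tuple = ()        # variant labels excluded from summaries

    @property
    def species(self) -> list:
        return list(self.statuses.columns)

    @property
    def n_variants(self) -> int:
        return len(self.statuses)


def build_sharing_matrix(catalog: PvCatalog, index: MafIndex,
                         species_list: Sequence[str],
                         clade_map: Mapping[str, str] | None = None) -> SharingMatrix:
    """Full sharing matrix over an SNV catalog; deterministic given inputs."""
    species_list = list(species_list)
    rows = {}
    mismatches = []
    for v in catalog:
        if not v.is_snv:
            raise ContractError("build_sharing_matrix requires an SNV-only catalog")
        col = column_at(index, v.chrom, v.pos)
        if col is None:
            rows[v.label] = {sp: UNALIGNED for sp in species_list}
            continue
        res = call_sharing(v, col, species_list)
        if res == REF_MISMATCH:
            logger.info("ref mismatch at %s; excluded from summaries", v.label)
            mismatches.append(v.label)
            rows[v.label] = {sp: REF_MISMATCH for sp in species_list}
        else:
            rows[v.label] = res
    statuses = pd.DataFrame.from_dict(rows, orient="index", dtype="object")
    if len(statuses):
        statuses = statuses.reindex(columns=species_list)
    else:
        statuses = pd.DataFrame(columns=species_list, dtype="object")
    return SharingMatrix(statuses=statuses, clade_map=dict(clade_map or {}),
                         ref_mismatch=tuple(mismatches))


def sharing_summary(matrix: SharingMatrix) -> dict:
    """Per-species and per-clade shared counts plus the headline percentage.

    percent_shared = 100 * |variants shared in >= 1 species| / |catalog|,
    reported to two decimals (half away from zero); ref-mismatch variants are
    excluded from both numerator and denominator.
    """
    from ._util import percent

    ok = matrix.statuses.drop(index=list(matrix.ref_mismatch), errors="ignore")
    n_variants = len(ok)
    shared_mask = ok.eq(SHARED)
    n_shared_any = int(shared_mask.any(axis=1).sum()) if n_variants else 0
    per_species = shared_mask.sum(axis=0).astype(int) if n_variants else \
        pd.Series(0, index=matrix.species, dtype=int)
    per_clade: dict[str, list] = {}
    for sp, count in per_species.items():
        clade = matrix.clade_map.get(sp)
        if clade is not None:
            per_clade.setdefault(clade, []).append(int(count))
    return {
        "n_variants": n_variants,
        "n_shared_any": n_shared_any,
        "percent_shared": percent(n_shared_any, n_variants, 2) if n_variants else 0.0,
        "per_species_shared": per_species.to_dict(),
        "per_clade_shared": per_clade,
        "n_species_with_shared": int((per_species > 0).sum()),
        "n_ref_mismatch": len(matrix.ref_mismatch),
    }


def load_species_map(path: str | Path | None = None) -> pd.DataFrame:
    """Species/assembly/clade map (packaged toy default, user-replaceable)."""
    if path is None:
        ref = resources.files("paleopv.data") / "species_clades.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"species", "assembly", "clade"} - set(df.columns)
    if missing:
        raise SchemaError(f"species map missing column(s): {sorted(missing)}")
    bad = set(df["clade"]) - set(CLADES)
    if bad:
        raise SchemaError(f"species map has unknown clade label(s): {sorted(bad)}")
    return df
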