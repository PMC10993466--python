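"""Synthetic inputs with known ground truth, plus the packaged fixture tables.

Every generator here is a pure function of (parameters, seed): identical
seeds give identical bytes. The generators emulate the study conditions the
pipeline was designed for — a vertebrate species alignment with planted
convergent alternate alleles, ancient sequencing reads with exponentially
decaying terminal deamination over samples dated 100-45,000 years BP, and
codon pairs evolved at chosen omega — at desk scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._util import ContractError, IntegrityError, SchemaError, ValidationError
from .ancient_calling import AncientSample, DamageModel, PILEUP_COLUMNS, PILEUP_VERSION_LINE
from .pv_catalog import PvCatalog, Variant

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# species alignment (HKY down a newick tree) and MAF emission

def _hky_q(kappa: float, base_freqs: Sequence[float]) -> np.ndarray:
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
        raise ContractError("base_freqs must be 4 positive values summing to 1")
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    q = np.zeros((4, 4))
    for i, a in enumerate(_BASES):
        for j, b in enumerate(_BASES):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (a, b) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * q.diagonal()).sum()
    return q / scale


def simulate_species_alignment(tree_newick: str, length: int,
                               kappa: float = 2.0,
                               base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                               seed: int = 0,
                               human_leaf: str = "human") -> dict:
    """Evolve ungapped sequences down a newick tree under an HKY process.

    Branch lengths are substitutions/site. Returns {species: sequence};
    the human leaf must be present (it becomes the MAF reference row).
    """
    if length < 1:
        raise ContractError("length must be >= 1")
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if human_leaf not in labels:
        raise ValidationError(f"human leaf {human_leaf!r} not in tree: {labels}")
    rng = np.random.default_rng(seed)
    pi = np.asarray(base_freqs, dtype=float)
    q = _hky_q(kappa, pi)
    root_states = rng.choice(4, size=length, p=pi)
    seqs: dict[str, np.ndarray] = {}

    def _evolve(node, states):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl > 0:
                p = expm(q * bl)
                p = np.clip(p, 0, None)
                p /= p.sum(axis=1, keepdims=True)
                cum = np.cumsum(p, axis=1)
                u = rng.random(length)
                child_states = np.empty(length, dtype=np.int64)
                for s in range(4):
                    mask = states == s
                    child_states[mask] = np.searchsorted(cum[s], u[mask])
                child_states = np.minimum(child_states, 3)
            else:
                child_states = states.copy()
            if child.is_leaf():
                seqs[child.taxon.label] = child_states
            else:
                _evolve(child, child_states)

    root = tree.seed_node
    if root.is_leaf():  # degenerate single-leaf tree
        seqs[root.taxon.label] = root_states
    _evolve(root, root_states)
    return {sp: "".join(_BASES[i] for i in states) for sp, states in seqs.items()}


def write_maf(seqs: Mapping[str, str], path: str | Path,
              reference: str = "human", chrom: str = "chrSim",
              n_blocks: int = 1, score: float = 0.0) -> None:
    """Emit aligned (equal-length, ungapped) sequences as a UCSC-dialect MAF,
    reference row first; ``n_blocks`` > 1 fragments the region for index
    testing."""
    if reference not in seqs:
        raise ContractError(f"reference {reference!r} not among sequences")
    length = len(seqs[reference])
    if any(len(s) != length for s in seqs.values()):
        raise ContractError("all sequences must have equal length")
    bounds = np.linspace(0, length, n_blocks + 1).astype(int)
    others = sorted(sp for sp in seqs if sp != reference)
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=synthetic\n\n")
        for b in range(n_blocks):
            start, end = int(bounds[b]), int(bounds[b + 1])
            if start == end:
                continue
            fh.write(f"a score={score:.1f}\n")
            for sp in [reference] + others:
                text = seqs[sp][start:end]
                src = f"{sp}.{chrom}"
                fh.write(f"s {src} {start} {end - start} + {length} {text}\n")
            fh.write("\n")


@dataclass
class SharingTruth:
    """Planted sharing ground truth: variant label -> set of species planted
    as carrying the alternate allele."""

    catalog: PvCatalog
    planted: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)  # label -> pos1
    seed: int = 0


def plant_variants(seqs: Mapping[str, str], n: int,
                   convergent_plan: Mapping[int, Iterable[str]] | None = None,
                   seed: int = 0, reference: str = "human",
                   chrom: str = "chrSim", genes: Sequence[str] = ("GENE1",),
                   spectrum: Mapping[str, float] | None = None,
                   region: tuple | None = None) -> tuple:
    """Plant n SNVs on the reference sequence and mark chosen species as
    convergent carriers of the alternate allele.

    ``convergent_plan`` maps variant index (0..n-1) to the species whose
    aligned base is overwritten with the alt allele. ``spectrum`` optionally
    weights substitution classes ("C>T", "A>G", ...). ``region`` restricts
    planted positions to a 0-based half-open interval (e.g. to keep variants
    away from read-coverage edge effects). Returns
    (catalog, updated_seqs, SharingTruth).
    """
    rng = np.random.default_rng(seed)
    plan = {int(k): list(v) for k, v in (convergent_plan or {}).items()}
    for idx, species in plan.items():
        unknown = [sp for sp in species if sp not in seqs]
        if unknown:
            raise ValidationError(f"convergent plan references unknown species {unknown}")
        if not 0 <= idx < n:
            raise ValidationError(f"convergent plan index {idx} out of range")
    ref_seq = seqs[reference]
    length = len(ref_seq)
    lo, hi = (0, length) if region is None else region
    if not 0 <= lo < hi <= length:
        raise ContractError(f"invalid region {region!r}")
    if n > hi - lo:
        raise ContractError("n exceeds usable positions")
    positions = lo + rng.choice(hi - lo, size=n, replace=False)
    positions.sort()
    mutable = {sp: list(s) for sp, s in seqs.items()}
    variants, truth, pos_map = [], {}, {}
    for i, pos0 in enumerate(positions):
        ref_base = ref_seq[pos0]
        alts = [b for b in _BASES if b != ref_base]
        if spectrum:
            weights = np.array([spectrum.get(f"{ref_base}>{a}", 0.0) for a in alts])
            if weights.sum() > 0:
                alt = alts[int(rng.choice(3, p=weights / weights.sum()))]
            else:
                alt = alts[int(rng.integers(3))]
        else:
            alt = alts[int(rng.integers(3))]
        v = Variant(chrom=chrom, pos=int(pos0) + 1, ref=ref_base, alt=alt,
                    gene=genes[i % len(genes)], clin_class="pathogenic",
                    review_stars=3)
        variants.append(v)
        shared_species = plan.get(i, [])
        for sp in shared_species:
            mutable[sp][pos0] = alt
        truth[v.label] = set(shared_species)
        pos_map[v.label] = int(pos0) + 1
    catalog = PvCatalog(tuple(variants))
    updated = {sp: "".join(chars) for sp, chars in mutable.items()}
    return catalog, updated, SharingTruth(catalog=catalog, planted=truth,
                                          positions=pos_map, seed=seed)


# ---------------------------------------------------------------------------
# ancient reads

def simulate_ancient_reads(human_seq: str, genotypes: Mapping[int, tuple],
                           coverage: float, read_len: int,
                           damage: DamageModel, seq_error: float = 0.0,
                           seed: int = 0, sample_id: str = "S1",
                           chrom: str = "chrSim", baseq: int = 30,
                           sites: Sequence[int] | None = None,
                           zygosity: str = "het") -> pd.DataFrame:
    """Sample uniform reads from a reference, apply terminal deamination and
    sequencing error, and report pileup rows at the sites of interest.

    ``genotypes`` maps 1-based position -> (ref, alt) for carrier sites; a
    heterozygous carrier emits the alt allele on each overlapping read with
    probability 1/2 (``zygosity="hom"`` emits it always). Deamination is
    applied in reference orientation: C->T with probability d0*exp(-lam*dist5)
    and G->A with probability d0*exp(-lam*dist3), matching the damage filter's
    read-end convention. Reproducible by seed.
    """
    if coverage <= 0 or read_len < 2:
        raise ContractError("require coverage > 0 and read_len >= 2")
    if not 0.0 <= seq_error < 1.0:
        raise ContractError("seq_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    length = len(human_seq)
    if read_len > length:
        raise ContractError("read_len exceeds reference length")
    sites = np.array(sorted(sites if sites is not None else genotypes.keys()),
                     dtype=np.int64)
    n_reads = int(round(coverage * length / read_len))
    starts = rng.integers(0, length - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    records = []
    for r, (start, minus) in enumerate(zip(starts, strands)):
        start = int(start)
        end = start + read_len
        lo = int(np.searchsorted(sites, start + 1, side="left"))
        hi = int(np.searchsorted(sites, end, side="right"))
        covered_sites = sites[lo:hi]
        if len(covered_sites) == 0:
            continue
        bases = list(human_seq[start:end])
        # carrier alleles
        for pos1, (ref, alt) in genotypes.items():
            pos0 = pos1 - 1
            if start <= pos0 < end:
                if zygosity == "hom" or rng.random() < 0.5:
                    bases[pos0 - start] = alt
        # deamination then sequencing error, in reference orientation
        for j in range(read_len):
            dist5 = j if not minus else read_len - 1 - j
            dist3 = read_len - 1 - dist5
            if bases[j] == "C" and rng.random() < damage.rate(dist5):
                bases[j] = "T"
            elif bases[j] == "G" and rng.random() < damage.rate(dist3):
                bases[j] = "A"
            if seq_error > 0 and rng.random() < seq_error:
                bases[j] = _BASES[(_BASE_INDEX[bases[j]] + int(rng.integers(1, 4))) % 4]
        read_id = f"{sample_id}_r{r}"
        for pos1 in covered_sites:
            pos0 = int(pos1) - 1
            j = pos0 - start
            dist5 = j if not minus else read_len - 1 - j
            records.append({
                "sample_id": sample_id, "chrom": chrom, "pos": int(pos1),
                "ref": human_seq[pos0], "base": bases[j], "baseq": baseq,
                "dist5": dist5, "dist3": read_len - 1 - dist5,
                "strand": "-" if minus else "+", "read_id": read_id,
            })
    return pd.DataFrame.from_records(records, columns=list(PILEUP_COLUMNS))


def simulate_cohort(human_seq: str, catalog: PvCatalog,
                    carrier_truth: Mapping[str, Sequence[str]],
                    samples: Sequence[AncientSample], coverage: float,
                    read_len: int, damage: DamageModel,
                    seq_error: float = 0.0, seed: int = 0,
                    chrom: str = "chrSim") -> tuple:
    """Simulate pileups for a cohort; ``carrier_truth`` maps sample_id -> the
    variant labels that sample carries. Returns (pileup DataFrame, truth)."""
    by_label = {v.label: v for v in catalog}
    sites = [v.pos for v in catalog]
    frames = []
    for i, sample in enumerate(samples):
        genotypes = {}
        for label in carrier_truth.get(sample.sample_id, ()):
            v = by_label[label]
            genotypes[v.pos] = (v.ref, v.alt)
        frames.append(simulate_ancient_reads(
            human_seq, genotypes, coverage, read_len, damage,
            seq_error=seq_error, seed=seed + 1000 * (i + 1),
            sample_id=sample.sample_id, chrom=chrom, sites=sites))
    pileup = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=list(PILEUP_COLUMNS))
    return pileup, {sid: set(labels) for sid, labels in carrier_truth.items()}


def write_pileup_tsv(pileup: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(PILEUP_VERSION_LINE + "\n")
        pileup.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixture tables (transcribed printed tables; checksums pinned)

FIXTURE_CHECKSUMS = {
    "table2_primate_sharing": ("table2_primate_sharing.tsv",
        "1eac0e4e1bebdaf53fec0d590fc95200296eeaa1e86a8fd2a8434859dcdf7099"),
    "table4_gene_counts": ("table4_gene_counts.tsv",
        "5ea1deb879a40aa1f9cba6d063ea8452b68942e6ef95c482abb1755c73c498d4"),
    "table5_chek2": ("table5_chek2.tsv",
        "28774e6039191766bc59525f6245547f60c586f9bddfa599a67628f3fd09cd81"),
    "table6_founders": ("table6_founders.tsv",
        "95f023fc92a2abb2481c34533101b31da34748da95970df550800756971c04f8"),
    "results_counts": ("results_counts.json",
        "89d98a14a0278540a4bfa0ae8571853e94008d145970393fbd0756833c1a7765"),
}

_FIXTURE_SCHEMAS = {
    "table2_primate_sharing": {"species", "mya", "gene", "hgvs_c", "hgvs_p"},
    "table4_gene_counts": {"gene", "pvs"},
    "table5_chek2": {"time_bp", "hgvs_c", "hgvs_p", "rsid", "position",
                     "variation_type", "locations", "carriers"},
    "table6_founders": {"gene", "hgvs_c", "hgvs_p", "pubmed_id", "population",
                        "year_bp"},
}


def load_paper_fixtures(name: str):
    """Load a packaged fixture table by name, verifying its pinned checksum
    and schema. Returns a DataFrame (tables) or dict (results_counts)."""
    if name not in FIXTURE_CHECKSUMS:
        raise ContractError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_CHECKSUMS)}")
    filename, expected = FIXTURE_CHECKSUMS[name]
    ref = resources.files("paleopv.data") / filename
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise IntegrityError(f"fixture {filename} checksum mismatch: {digest}")
    if filename.endswith(".json"):
        return json.loads(raw.decode())
    from io import StringIO
    df = pd.read_csv(StringIO(raw.decode()), sep="\t")
    missing = _FIXTURE_SCHEMAS[name] - set(df.columns)
    if missing:
        raise IntegrityError(f"fixture {filename} missing column(s): {sorted(missing)}")
    if name == "table5_chek2" and df["carriers"].isna().any():
        raise IntegrityError("table5_chek2: carrier counts must be present")
    if name == "table6_founders":
        from .comparison_stats import parse_age_bp
        if any(parse_age_bp(v)[2] <= 0 for v in df["year_bp"]):
            raise IntegrityError("table6_founders: all ages must be > 0")
    return df
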