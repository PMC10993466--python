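"""Pairwise dN/dS (omega) estimation and selection-type classification.

Estimation uses Nei-Gojobori (1986) counting: expected synonymous (S) and
nonsynonymous (N) site counts per codon from the fraction of single-base
changes that preserve the amino acid, observed differences (Sd, Nd) averaged
with equal weight over all minimal mutational pathways between the two codons
(pathways through stop codons excluded), and Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) applied to the proportions pN = Nd/N and pS = Sd/S.

Classification follows the sign of omega - 1: omega > 1 positive selection,
omega < 1 negative (purifying), with "neutral" operationalized as a
codon-column bootstrap percentile interval for omega covering 1 (exact
equality being measure-zero). omega is undefined when dS == 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from ._util import ContractError, ValidationError

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code
_STOPS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else _AA[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one sense codon.

    Each of the nine single-base changes is classified; changes to stop
    codons count as nonsynonymous, so n + s == 3 exactly.
    """
    if codon in _STOPS or codon not in _AA:
        raise ContractError(f"not a sense codon: {codon!r}")
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if mutant not in _STOPS and _translate(mutant) == _translate(codon):
                s += 1.0 / 3.0
    return (3.0 - s, s)


@lru_cache(maxsize=None)
def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) observed differences between two sense
    codons, averaged with equal weight over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; in the rare case that
    every ordering is excluded, the average falls back to all orderings so
    the difference count is never lost.
    """
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return (0.0, 0.0)
    pathways = []
    for order in itertools.permutations(diffs):
        current = a
        steps = []
        through_stop = False
        for i in order:
            nxt = current[:i] + b[i] + current[i + 1:]
            if nxt in _STOPS:
                through_stop = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((through_stop, steps))
    valid = [steps for through, steps in pathways if not through]
    if not valid:
        valid = [steps for _, steps in pathways]
    nd = sd = 0.0
    for steps in valid:
        for pre, post in steps:
            if pre not in _STOPS and post not in _STOPS and \
                    _translate(pre) == _translate(post):
                sd += 1.0
            else:
                nd += 1.0
    n_paths = len(valid)
    return (nd / n_paths, sd / n_paths)


@dataclass(frozen=True)
class CodonSequencePair:
    """Two aligned coding sequences over {A,C,G,T,-}, length divisible by 3.

    Codon columns containing a gap or ambiguity in either sequence are
    excluded whole from counting. Internal stops in either ungapped
    translation are a validation error naming the codon index.
    """

    label_a: str
    label_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValidationError("aligned sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValidationError("alignment length must be divisible by 3")
        for label, seq in ((self.label_a, a), (self.label_b, b)):
            codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            ungapped = [c for c in codons if set(c) <= set(_BASES)]
            for idx, c in enumerate(ungapped[:-1]):
                if c in _STOPS:
                    raise ValidationError(
                        f"{label}: internal stop codon {c} at ungapped codon "
                        f"index {idx}")

    @property
    def codon_columns(self) -> list:
        return [(self.seq_a[i:i + 3], self.seq_b[i:i + 3])
                for i in range(0, len(self.seq_a), 3)]

    @property
    def resolved_columns(self) -> list:
        """Codon columns fully resolved (ACGT only, sense) in both sequences."""
        ok = set(_BASES)
        return [(ca, cb) for ca, cb in self.codon_columns
                if set(ca) <= ok and set(cb) <= ok
                and ca not in _STOPS and cb not in _STOPS]


def codon_column_stats(pair: CodonSequencePair) -> np.ndarray:
    """Per resolved codon column: [N, S, Nd, Sd], with site counts averaged
    over the two sequences. Shape (n_columns, 4)."""
    cols = pair.resolved_columns
    out = np.empty((len(cols), 4))
    for row, (ca, cb) in enumerate(cols):
        na, sa = codon_sites(ca)
        nb, sb = codon_sites(cb)
        nd, sd = codon_pair_differences(ca, cb)
        out[row] = ((na + nb) / 2.0, (sa + sb) / 2.0, nd, sd)
    return out


def ng86_counts(pair: CodonSequencePair) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) summed over resolved codon columns."""
    stats = codon_column_stats(pair)
    if len(stats) == 0:
        raise ValidationError("no fully resolved codon columns")
    n, s, nd, sd = stats.sum(axis=0)
    return (float(n), float(s), float(nd), float(sd))


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC distance for a proportion of differences; returns (d, saturated)."""
    if p == 0.0:
        return (0.0, False)
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return (float("nan"), True)
    return (-0.75 * float(np.log(arg)), False)


@dataclass
class DnDsResult:
    label_a: str
    label_b: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float                 # nan when undefined
    n_codons: int                # resolved codon columns
    saturated: bool = False
    ci: tuple | None = None      # bootstrap percentile interval for omega
    classification: str | None = None
    column_stats: np.ndarray | None = field(default=None, repr=False)
    method: str = "NG86 + Jukes-Cantor (pairwise)"

    @property
    def omega_defined(self) -> bool:
        return np.isfinite(self.omega)


def dnds(pair: CodonSequencePair) -> DnDsResult:
    """Pairwise dN/dS with NG86 counts and Jukes-Cantor correction.

    omega is undefined (NaN) when dS == 0 or when either proportion is
    saturated (p >= 3/4, log argument non-positive); saturation flags the
    result rather than raising.
    """
    stats = codon_column_stats(pair)
    if len(stats) == 0:
        raise ValidationError("no fully resolved codon columns")
    n, s, nd, sd = (float(x) for x in stats.sum(axis=0))
    pn, ps = nd / n, sd / s
    dn, sat_n = jukes_cantor(pn)
    ds, sat_s = jukes_cantor(ps)
    saturated = sat_n or sat_s
    if saturated or ds == 0.0 or not np.isfinite(ds):
        omega = float("nan")
    else:
        omega = dn / ds
    return DnDsResult(
        label_a=pair.label_a, label_b=pair.label_b, N=n, S=s, Nd=nd, Sd=sd,
        pN=pn, pS=ps, dN=dn, dS=ds, omega=omega, n_codons=len(stats),
        saturated=saturated, column_stats=stats,
    )


def _omega_from_sums(sums: np.ndarray) -> np.ndarray:
    """Vectorized omega over rows of [N, S, Nd, Sd] sums (NaN when undefined)."""
    n, s, nd, sd = sums[:, 0], sums[:, 1], sums[:, 2], sums[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        argn = 1.0 - (4.0 / 3.0) * nd / n
        args = 1.0 - (4.0 / 3.0) * sd / s
        dn = np.where(argn > 0, -0.75 * np.log(np.maximum(argn, 1e-300)), np.nan)
        ds = np.where(args > 0, -0.75 * np.log(np.maximum(args, 1e-300)), np.nan)
        omega = np.where((ds > 0) & np.isfinite(dn), dn / ds, np.nan)
    return omega


def classify_selection(result: DnDsResult, n_boot: int = 1000,
                       alpha: float = 0.05, seed: int = 0) -> str:
    """Classify selection from a codon-column bootstrap of omega.

    Neutral iff the (1 - alpha) percentile interval covers 1; otherwise
    positive/negative by the sign of omega - 1. Deterministic given seed.
    Returns 'undefined' (and sets it on the result) when omega is undefined.
    """
    if not result.omega_defined or result.column_stats is None:
        result.classification = "undefined"
        return "undefined"
    rng = np.random.default_rng(seed)
    cols = result.column_stats
    m = len(cols)
    idx = rng.integers(0, m, size=(n_boot, m))
    sums = cols[idx].sum(axis=1)            # (n_boot, 4)
    omegas = _omega_from_sums(sums)
    omegas = omegas[np.isfinite(omegas)]
    if len(omegas) < max(10, n_boot // 10):
        result.classification = "undefined"
        return "undefined"
    lo, hi = np.percentile(omegas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    result.ci = (float(lo), float(hi))
    if lo <= 1.0 <= hi:
        result.classification = "neutral"
    elif result.omega > 1.0:
        result.classification = "positive"
    else:
        result.classification = "negative"
    return result.classification


def _gy94_matrices(omega: float, kappa: float):
    """GY94-style 61-state rate matrix (uniform codon frequencies), scaled to
    one expected substitution per codon per unit time."""
    n = len(SENSE_CODONS)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    q = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in _BASES:
                if b == a[pos]:
                    continue
                mutant = a[:pos] + b + a[pos + 1:]
                j = index.get(mutant)
                if j is None:
                    continue
                rate = 1.0 / n
                if (a[pos], b) in _TRANSITIONS:
                    rate *= kappa
                if _translate(a) != _translate(mutant):
                    rate *= omega
                q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(q.diagonal().mean())  # uniform frequencies
    if scale > 0:
        q /= scale
    return q


def simulate_codon_pair(omega: float, kappa: float, t: float, n_codons: int,
                        seed: int, labels: tuple = ("seq_a", "seq_b")) -> CodonSequencePair:
    """Evolve two sequences from a uniform-sense-codon ancestor for t/2 each
    under a GY94-style codon model; reproducible by seed."""
    if omega < 0 or kappa <= 0 or t < 0 or n_codons < 1:
        raise ContractError("require omega >= 0, kappa > 0, t >= 0, n_codons >= 1")
    from scipy.linalg import expm

    rng = np.random.default_rng(seed)
    ancestors = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    if t == 0:
        seq = "".join(SENSE_CODONS[i] for i in ancestors)
        return CodonSequencePair(labels[0], labels[1], seq, seq)
    q = _gy94_matrices(omega, kappa)
    p = expm(q * (t / 2.0))
    p = np.clip(p, 0, None)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    seqs = []
    for _ in range(2):
        u = rng.random(n_codons)
        states = np.array([np.searchsorted(cum[anc], x) for anc, x in
                           zip(ancestors, u)])
        states = np.minimum(states, len(SENSE_CODONS) - 1)
        seqs.append("".join(SENSE_CODONS[i] for i in states))
    return CodonSequencePair(labels[0], labels[1], seqs[0], seqs[1])
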