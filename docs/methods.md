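# Methods

This note documents the models implemented in `paleopv`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions used throughout.

## Variant catalog

A catalog row is a 1-based, fully closed, VCF-style variant
(chrom, pos, ref, alt) with a gene symbol, a clinical class from the closed
vocabulary {pathogenic, likely_pathogenic, uncertain, likely_benign, benign,
conflicting}, and a review-star confidence (0–4). Likely-pathogenic is kept
with pathogenic by default, since both are treated as one clinically
actionable class. The review-star cutoff is a required parameter with
default `min_stars = 3`, read as "three or more": the star scale tops out at
4, so a strictly-greater reading would leave only practice-guideline
assertions; the chosen reading is logged on every filter call. Conflicting
classifications are excluded by default.

The DDR gene→pathway panel ships as a replaceable TSV over the eight
pathways (FA, HR, MMR, NER, NHEJ, DDR_response, BER, DR), assembled from the
standard KEGG replication-and-repair and Wood-laboratory gene lists. A gene
may belong to several pathways; per-pathway summaries count it in each,
while "nonredundant" totals deduplicate genes and variants across pathways.
Genes absent from the panel are flagged `off_panel`, never dropped — the
panel is data, not code.

Coordinates are converted to 0-based half-open only at the MAF boundary.

## Cross-species sharing

MAF blocks are parsed with Biopython and indexed by the reference
(human) row's interval. A variant's alignment column is found by walking the
reference row's gapped text counting non-gap characters; each species'
character at that column is uppercased (soft-masking carries no meaning
here) and classified against the variant:

- `shared` — species base equals the human **alternate** allele. This is
  the only reading under which a human pathogenic allele can be said to be
  "present" in another species.
- `not_shared` — a different base; `unaligned` — gap, absent species, or an
  ambiguity code.
- `ref_mismatch` — the human base at the column differs from the catalog
  reference allele; the whole variant is excluded from summaries (it
  indicates an assembly/coordinate mismatch, not biology).

When blocks overlap, the highest-scoring block wins; ties go to the earliest
block in the file, and the choice is logged. The headline percentage is
`100 · |variants shared in ≥1 species| / |catalog|`, reported to two
decimals — unaligned species count against sharing, so the denominator is
the full catalog. MAF minus-strand rows need no special handling for
sharing because row texts are already oriented to the reference strand; the
strand field only changes coordinate reckoning (covered by a dedicated
test).

## Ancient-genome presence calls

Calls are detection calls, not diploid genotypes: ancient coverage is far
too low for genotype likelihoods, and the downstream questions (is this PV
present in this individual?) need only detection. At each catalog site:

1. observations below `min_baseq` (default 1 — maximally permissive,
   matching low-coverage ancient practice) are discarded;
2. alternate-allele observations that are deamination-consistent are
   discarded: ref C→alt T observed as T within `k` bases of the read's 5′
   end, or ref G→alt A observed as A within `k` bases of the 3′ end. No
   other substitution class is ever filtered;
3. the call is `present` when `alt_clean ≥ min_clean_alt` (default 1),
   `no_data` at zero filtered depth, otherwise `absent`. `damage_only`
   flags sites whose entire alternate support was removed in step 2;
   `low_depth` flags depth < 2 rather than hard-filtering it.

The window rule with default `k = 3` is this package's own operationalization
of "remove deamination artifacts": it is standard practice for
double-stranded ancient libraries, cheap to reason about, and directly
testable. UDG-treated libraries are handled by `k = 0`. A variant is
"recurrent" when present in ≥ 2 distinct samples.

The damage profile itself is estimated from the data: per 5′-distance `i`,
the C→T mismatch count among C-reference observations is modeled as
binomial with `p_i = d0·exp(−λ·i)`; `(d0, λ)` maximize the binomial
likelihood, initialized from a least-squares line through the non-zero
log-frequencies. The MLE is used rather than the log-linear fit alone
because far-from-end positions have tiny rates whose log-frequencies are
dominated by sampling noise (and zero counts must be dropped from a log
fit), which biases an unweighted regression; the binomial likelihood weights
positions by their information. Estimation needs ≥ 2 positions with
non-zero counts and warns below 1000 C-reference observations. At ~50,000
windowed observations the estimator recovers `d0` well within ±0.05
(standard error ≈ 0.01).

## Abundance, timing, and comparison statistics

Per-gene abundance is `r_g = n_g / N` over a cohort's PV counts; cohorts are
compared by Pearson correlation of the ratio vectors aligned by gene symbol
over the union, absent genes entering as zero (ratios, not raw counts, so
cohorts of different size are comparable). The two-tailed p-value is the
t-test with n−2 degrees of freedom. Clade-level sharing counts are compared
with the tie-corrected Kruskal–Wallis test (two identical-value groups are
defined as H = 0, p = 1, where the rank test is undefined).

Carrier dates in years BP are binned as (0, 5000], (5000, 10000],
(10000, ∞) — right-closed so that a carrier "within 5000 years" includes
5000 exactly, which is the only boundary policy under which the packaged
timing counts (717/214/28 of 959 dated) partition cleanly; the edges are
configurable. "Earliest" always means the larger BP value.

Founder-variant ages may be points, ranges ("1500-750"), or one-sided bounds
("<200", ">250"). Summaries use a representative age: the midpoint of a
range, the stated endpoint of a bound. This is the only convention under
which the packaged founder table reproduces its published overall range
(8675–180 years BP), and it is applied uniformly.

All printed percentages are exact rational arithmetic rounded half away from
zero (Python's default banker's rounding would print 2.25% as 2.2%). Two
published percentages are internally inconsistent with their own counts
(97/100 species printed as "98.0%"; 73/87 genes printed as "84.0%" where
exact arithmetic gives 83.9%); this package always reports the exact value.

## Pairwise dN/dS

NG86 counting: per sense codon, each of the nine single-base changes is
classified synonymous/nonsynonymous (changes to stop codons count as
nonsynonymous), giving site counts with `n + s = 3` per codon, averaged over
the two sequences. Observed differences between two codons are averaged with
equal weight over all minimal mutational pathways, excluding pathways
through stop codons (if every ordering passes through a stop, the average
falls back to all orderings rather than discarding the codon). Gapped or
ambiguous codon columns are dropped whole; internal stops are a validation
error. Proportions `pN = Nd/N`, `pS = Sd/S` are Jukes–Cantor corrected;
ω = dN/dS is undefined at `dS = 0` and flagged (not raised) at saturation
(`p ≥ 3/4`).

"Neutral" is operationalized as a codon-column bootstrap: columns are
resampled with replacement, ω recomputed per replicate (1000 by default),
and the classification is neutral iff the (1−α) percentile interval covers
1, otherwise positive/negative by the sign of ω − 1. Exact equality ω = 1
is measure-zero, so an interval rule is the only workable definition.

The pair simulator evolves both sequences from a uniform sense-codon
ancestor for `t/2` each under a GY94-style 61-state rate matrix with
transition/transversion ratio κ and nonsynonymous scaling ω, normalized to
one expected substitution per codon per unit `t`.

**Known limitation.** NG86 counting assumes no transition/transversion
bias. Under κ = 2 simulation, synonymous opportunity is undercounted and ω
is biased downward (median ≈ 0.83 at true ω = 1 with 2000 codons), so
bootstrap neutrality calls degrade even though rank order across planted ω
values is preserved. Neutrality calibration is therefore validated at κ = 1
(the process the counting scheme is calibrated for), the bias direction at
κ = 2 is pinned by its own test, and ω-monotonicity and purifying-selection
recovery are validated at κ = 2. Maximum-likelihood codon models would
remove this bias at the cost of a far heavier estimator; the qualitative
classification (ω ≷ 1) is the quantity of interest here.

## Synthetic data

Every generator is a pure function of (parameters, seed): identical seeds
give identical bytes. The species-alignment generator evolves ungapped
sequences down a newick tree under HKY (κ = 2, uniform base frequencies by
default) and emits single- or multi-block MAF with the human leaf as
reference; planted variants place SNVs at distinct positions and overwrite
chosen species' bases with the alternate allele (the convergence phenomenon
the sharing engine must detect). The read simulator samples uniform reads,
emits alternate alleles on each overlapping read with probability 1/2 for
heterozygous carriers (the relevant model for presence calls; a homozygous
mode exists), applies deamination in reference orientation — C→T with
probability `d0·exp(−λ·dist5)`, G→A with `d0·exp(−λ·dist3)`, matching the
filter's convention — then uniform sequencing error. Study-condition
defaults mirror a heavily damaged double-stranded library (`d0 = 0.3,
λ = 0.5`), sample dates spanning the 100–45,000 years BP range, and
desk-scale problem sizes (kilobase regions, tens of samples, ≤ 2000 codons,
100-replicate calibrations) chosen so the full validation runs in well under
a minute per engine.

What the generators do **not** emulate: indels and alignment gaps in MAF
(gap handling is tested on hand-built blocks), contamination, reference
bias, library-preparation strand asymmetries, linkage/haplotypes, and
demography. Passing the closed-loop tests therefore shows the engines are
correct against their stated models, not that the models capture every
artifact of real ancient data.

The packaged fixture tables are checksum-pinned transcriptions of published
summary tables, including their internal discrepancies (documented in
`src/paleopv/data/fixture_notes.txt`); the loader validates schema and
checksum on every read.

## Degenerate inputs and tie-breaks

- Empty filter results warn, never raise; empty catalogs produce empty
  matrices and zero-percent summaries.
- Overlapping MAF blocks: highest score, then lowest file offset.
- Zero-variance abundance vectors make Pearson r undefined and are flagged
  `degenerate` rather than raising.
- Bootstrap replicates with undefined ω are dropped; if fewer than 10% of
  replicates survive, the classification is `undefined`.
- Duplicate catalog keys are a load-time error listing every offending key.
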