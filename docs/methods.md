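# Methods

Statistical definitions, estimator choices and numerical conventions
used by `mlgpop`. Everything stated here is either a definition or a
property exercised by the test suite / `scripts/acceptance.py`; no
claims are made about empirical datasets.

## Data model

Genotypes are unordered diploid allele pairs (amplicon sizes in bp) at
an ordered panel of microsatellite loci. Missing data use the sentinel
0; a locus is missing only when both calls are absent — half-missing
loci are rejected at parse time since a single call is ambiguous for a
diploid. Individuals with more than `max_missing` (default 3) missing
loci are excluded on read and reported. Repeat counts are
`round((size − offset) / motif)` with banker's rounding; panels carry
per-locus motif lengths and optional primer-flank offsets.

Strata (estate, appellation, farming, compartment, vintage) are
metadata labels; all grouped statistics take the stratum name and sort
group labels lexicographically, which together with fixed seeds makes
every output deterministic.

## Clonal structure

An MLG class is an exact multiset match of allele pairs across loci
(`strict`), or a match over mutually typed loci with single-linkage
merging (`ignore_missing`). `strict` never collapses distinct strains
through missing data and is the default everywhere. Clone correction
keeps the lexicographically smallest individual id per class *within*
each group of a stratum (estates by default): the same MLG recovered
at two estates is signal, not pseudo-replication, so both copies stay.
The operation is idempotent and never increases counts.

## Bruvo distance

Per allele `d = 1 − 2^(−|x−y|)` in repeat units (one step = 0.5,
saturating at 1, consistent with stepwise mutation). Per diploid locus
the minimum over the two perfect matchings of the mean per-allele
distance; per genotype the mean over loci typed in both individuals
(pairs with no comparable locus are an error rather than silently 0).
The organism is diploid throughout, so no genome-addition/loss model
for ploidy change is needed. The matrix implementation is fully
vectorised and is tested to 1e-12 against a brute-force
permutation-based implementation.

Trees: neighbor joining via scikit-bio, negative branch lengths (an NJ
artefact) clamped to zero, midpoint rooting by default; branch support
by resampling loci with replacement and counting bipartitions.
Minimum spanning networks use Kruskal with lexicographic tie-breaking
so equal-distance data give a reproducible tree; nodes carry MLG class
multiplicities.

## Diversity

With `Ni` individuals in genotype class i, `N = Σ Ni`, `S` classes:
Shannon `H′ = −Σ (Ni/N) ln(Ni/N)` (nats), Pielou `J′ = H′/ln S`
(defined as 1 when S = 1), Simpson `D = Σ Ni(Ni−1) / (N(N−1))`
(unbiased, without replacement) with complement `1 − D` and inverse
`1/D`. `N` counts individuals and `S` counts classes — the only
reading under which `Σ Pi = 1`.

Richness at depth `d ≤ N` uses the hypergeometric closed form
`E[S_d] = Σ_i (1 − C(N−Ni, d)/C(N, d))`; the Monte-Carlo subsampler
(seeded, without replacement) exists for standard deviations and is
tested to agree with the closed form within Monte-Carlo error. Depths
beyond `N` use the Chao1-based extrapolation
`S + f0 (1 − (1 − f1/(N f0 + f1))^(d−N))` with `f0 = Chao1 − S` and
the bias-corrected Chao1 when no doubletons exist.

## AMOVA and fixation indices

The AMOVA engine is a general unbalanced nested variance-component
decomposition: sums of squared deviations are differences of
within-partition SSDs between successive hierarchy levels, and
expected-mean-square coefficients are the Searle-type
`k_{l,m} = Σ_j n_j² / n_{ancestor_l(j)}` over level-m groups j.
For codominant data the units are the 2N gene copies, one-hot encoded
per locus and scaled by √0.5 so the squared Euclidean distance between
copies equals the allele mismatch count; the deepest level is the
individual, which yields a within-individual component and a
"Phi for individuals" (an Fis analogue, large under selfing).
Components are estimated per locus (per-locus missing exclusion) and
summed. Negative components are retained raw and flagged. With
`distance="bruvo"` the individuals are the units and the Bruvo values
serve directly as squared distances (no within-individual level).

Phi statistics: top level σ₁/σ_total; nested level l
σ_l / Σ_{m≥l} σ_m; individuals σ_ind/(σ_ind + σ_w). Permutation
schemes: individuals among deepest-stratum groups within parents;
subgroups among parent groups for higher levels; gene copies among
individuals within populations for the individual level. p-values use
the `(hits + 1)/(B + 1)` correction and are floored at `1/(B+1)`.

Pairwise Fst offers two estimators. ΦPT (default) runs the one-level
AMOVA on individuals with allele-count features — the convention of
the GenAlEx lineage. Under random mating ΦPT estimates `2F/(1+F)`
rather than `F`, because it folds the within-individual variance into
the denominator; the two coincide as selfing → 1, which suits a highly
selfing yeast but matters for outcrossed data. Weir–Cockerham θ
(1984; a/b/c components summed over alleles and loci) is provided as
the unbiased alternative and is the estimator used for the
island-model validation and the balanced compartment comparison.

The balanced comparison draws at most `cap` individuals per estate per
compartment per replicate (smaller groups taken whole), pools each
side, and computes the two-population Fst; capping removes the
clonal-amplification bias of unbalanced vat samples. Means and
standard deviations over seeded replicates are reported.

Mantel tests correlate off-diagonal upper triangles (Pearson r) with
joint row/column permutations of the second matrix; an exhaustive mode
enumerates all n! permutations (identity included — the exact test)
and is the oracle for the Monte-Carlo mode.

## Directional migration

For an ordered pair (i → j) a hypothetical pool combines both samples
and the allelic differentiation between pool and the *receiving*
population j is converted to a gene-flow proxy `(1 − D)/D`; the matrix
is normalised by its maximum. The differentiation uses a directional
variant of Jost's D in which the within-population heterozygosity term
is the focal (receiving) population's bias-corrected estimate only.
The symmetric two-population D is unsuitable here: the receiving
population has the *higher* heterozygosity, and since the symmetric
estimator scales like `2(Ht − Hs)/(1 − Hs)` its value to the pool
*rises* with Hs, inverting the inferred direction. With the focal-Hs
form, forward simulations with 50× asymmetric migration recover the
dominant direction reliably (see `tests/test_migration.py`).
Bootstrap resampling of individuals yields percentile intervals for
the normalised difference `m_ij − m_ji`; an interval excluding zero
flags significant asymmetry.

## Starter attribution

Allele sharing between an isolate and a starter profile is the
per-locus multiset intersection summed over mutually typed loci,
divided by `2 × L_compared`. Isolates with any missing locus are
ineligible (the rule requires complete profiles). Categories:
`identical` (0 differing loci), `clonal_variant` (1–2, read as recent
mutation during clonal expansion), `related` (sharing ≥ 0.75 — the
threshold is inclusive and configurable — with ≥ 3 differing loci),
otherwise `unrelated`. Ties are reported in full with the
alphabetically first starter as best match. The starter-centred
spanning network scores "star-likeness" as the fraction of related MLG
classes within two edges of the starter — a recently expanded clone
set is star-shaped, an established local cluster is not.

## Simulator

A forward Wright–Fisher diploid metapopulation: per generation each
offspring in deme i draws parent demes from backward-migration matrix
row i, selfs with probability `selfing_rate`, inherits one random
allele per parent per locus, then mutates each allele copy with
probability μ by exactly ±1 repeat (strict stepwise model, matching
the Bruvo distance assumption; repeats floored at 2). Initial
variation is a per-locus Gaussian spread around a random base repeat
count. Sampling imposes clonal expansion: the distinct sampled
individuals receive Dirichlet(`clonal_skew`) weights and the sample is
drawn multinomially, so small skew values make a few genotypes
dominate — the fermenting-must situation. Optional stages spike a
fraction of isolates with starter-derived profiles carrying 0–2
single-step edits (ground truth recorded in `collection.truth`) and
inject missing data (spiked isolates stay complete so that attribution
truth is recoverable under the completeness rule). One root seed
drives stage-specific child generators via `SeedSequence.spawn`;
identical seeds give byte-identical tables.

What the synthetic data shows: equilibrium island-model
differentiation (`Fst ≈ 1/(1 + 4Nm (d/(d−1))²)`, which the estimators
recover within ±0.05 for Nm ∈ {0.5, 1, 5}), heterozygote deficit under
selfing, clone-dominated abundance spectra, and recoverable starter
provenance. What it does not show: isolation by distance (migration
has no spatial kernel), locus-specific mutation-rate variation, allele
size constraints or homoplasy beyond the stepwise walk, null alleles
(missingness is uniform, not genotype-dependent), and temporal
structure across vintages. Conclusions about those phenomena cannot
be validated against this generator.

## Numerical conventions

- All randomised procedures take explicit integer seeds; derived seeds
  come from spawned `SeedSequence`s or bounded draws (< 2³¹).
- JSON reports are written with sorted keys; genotype tables are
  sorted by individual id — reruns are byte-identical.
- Distance matrices are symmetrised exactly (`(M + Mᵀ)/2`) before
  entering containers that enforce symmetry.
- Permutation p-values never report 0: the observed statistic counts
  as one of the permutations.
- Negative variance components and negative pairwise Fst estimates are
  sampling noise around zero; components are reported raw with a flag,
  pairwise matrices are clamped at 0 only where the container requires
  non-negativity.

## Limitations

- The AMOVA permutation test at higher hierarchy levels permutes
  subgroups among parents; with few subgroups (e.g. 12 estates in 4
  appellations) the permutation space is small and p-values are
  coarse.
- ΦPT's upward bias under random mating is inherent to the estimator,
  not a bug; use `estimator="weir_cockerham"` when Hardy–Weinberg-ish
  data are analysed.
- Bootstrap intervals for directional-migration asymmetry are
  percentile intervals over individuals and can be wide for small
  samples; a non-significant interval does not mean symmetric flow.
- Rarefaction extrapolation inherits Chao1's assumptions; far beyond
  2N the curve is an asymptote statement, not a prediction.
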