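# Methods

## Problem and data model

The package tests whether two sympatric lineages of a diploid organism —
one sexual, one asexual (thelytokous) — behave as genetically isolated gene
pools, using codominant multi-locus genotypes (microsatellites). Lineage
membership is an *input label*: it comes from an upstream wet-lab assay
(e.g. a mitochondrial PCR-SSP marker) and is never inferred here. The
universal container is a `GenotypeTable`: an ordered list of loci and of
individuals, each individual carrying an unordered allele pair per locus
(or a per-locus missing marker) plus lineage and sampling-location labels.
Allele codes are opaque positive integers; fragment lengths are taken as
called and never binned or size-corrected. A half-called diploid genotype
(one allele missing) is rejected as ambiguous rather than guessed.

## Allele-sharing distance

For individuals *i*, *j* and locus *l*, the distance term is

- 0 if the two unordered allele pairs are identical,
- 0.5 if they share a single allele,
- 1.0 if they have no common allele,

and the pairwise distance is the mean over loci. "Share a single allele" is
read by **copy number** (multiset intersection of size 1): {A,A} vs {A,B}
scores 0.5, {A,A} vs {A,A} scores 0. For diploids an intersection of size 2
with unequal genotypes is impossible, so the three-way rule is exhaustive.
Missing genotypes are handled by **pairwise deletion** — the mean runs over
loci typed in both individuals, and the per-pair count of loci used is kept
in the distance matrix (`loci_used`) so reduced support is visible. A pair
with no commonly typed locus is an error naming both individuals. The
distance is a semimetric; no triangle inequality is claimed and neighbor
joining does not need one.

## Neighbor joining and monophyly

Canonical Saitou–Nei agglomeration: at each round join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with the standard
branch-length and distance-update formulas, finishing with the closed-form
three-taxon join. Numerical choices, fixed as this package's contract
because upstream tools leave them unspecified:

- **Tie-break**: among Q-minimizing pairs, the lexicographically smallest
  index pair in current matrix order. Ties are measure-zero on continuous
  data but common on toy integer matrices; the rule makes output
  deterministic and permutation-equivariant.
- **Negative branch lengths** are retained in the tree and the Newick
  output (a warning is recorded); clamping would silently break the
  additivity properties the tests rely on. Monophyly uses topology only.
- **Serialization**: Newick rooted at the final (trifurcating) join node,
  branch lengths at 6 decimals, labels quoted per the Newick standard.

A leaf set is monophyletic on an unrooted tree iff some edge induces the
bipartition {set, complement}; a group is therefore monophyletic exactly
when its complement is. Consistency is verified on random additive matrices
(exact topology and 1e-9 branch-length recovery) and against an independent
NJ implementation; no bootstrap is computed (single-tree analysis by
design).

## Exact differentiation tests

Per locus, allele counts (gene copies: two per typed individual) for the
two lineages form an R×2 table. The test is the conditional exact test
under the multivariate hypergeometric null with fixed margins, two-sided by
the **table-probability criterion**: p = total probability of tables no
more probable than the observed one (log-probabilities compared with 1e-7
slack). Mode `exhaustive` enumerates all tables by depth-first search with
margin pruning; `auto` does so while the table count (computed first by
dynamic programming) is at most `max_tables`, else falls back to
Monte-Carlo sampling of `n_mc` tables with the add-one estimator
p = (1+hits)/(1+n_mc), seed mandatory. The default `max_tables` is 1e5,
chosen so a 9-locus analysis stays interactive; the bound is configurable.
Zero-margin allele rows are dropped with a warning. The family for
Bonferroni correction is the set of testable loci within one comparison
(adjusted p = min(1, p·m), m = 9 in the reference design); whether the
historical analyses tested allele counts or genotype tables is usually
unstated — this package tests allele counts and says so.

## Private alleles

The per-locus proportion of lineage-specific alleles is count-based:
(# distinct alleles observed in exactly one lineage) / (# distinct alleles
observed at the locus). Because the definition in figure-level summaries of
field studies is often ambiguous, a frequency-weighted variant — the share
of pooled gene copies carried by private alleles — is always emitted
alongside. Both are computed globally and per sampling location. A locus
untyped in either lineage is flagged undefined rather than zeroed.

## F<sub>ST</sub>: Weir–Cockerham θ and permutation

θ follows Weir & Cockerham (1984): per locus and allele, with r groups,
group sizes n_i (typed individuals), allele frequencies p_i and
heterozygote frequencies h_i, the among-group (a), among-individual (b) and
within-individual (c) variance components are computed from n̄, n_c, p̄, s²
and h̄; the multi-locus estimator is the **ratio of sums**
θ = Σa / Σ(a+b+c) over loci and alleles. This is the fully specified
open-literature estimator; AMOVA-style variants used by some legacy
programs are closely related but not identical, and the difference is
documented rather than emulated. Monomorphic-everywhere data raise an
explicit error (0/0). Loci where fewer than two groups have typed
individuals are skipped.

The permutation test reallocates **individuals between groups** (genotypes
intact, group sizes preserved), recomputes multi-locus θ each round, and
reports p = (1 + #{θ_perm ≥ θ_obs}) / (1 + n_perm) — the add-one rule, so
the smallest reportable p is 1/(n_perm+1) and can never be overstated.
Default n_perm = 10000 (reported p floor 1e-4); the driver scripts use
9999.

## Synthetic generator

`simulate_two_lineages` produces the structure the analysis assumes, per
locus:

1. A contiguous block of `alleles_per_locus` integer codes is drawn
   (uniform start in 100–280, mimicking fragment lengths). A
   Binomial(A, divergence) number of alleles is marked private (at least
   one when divergence > 0), split evenly at random between lineages;
   **private-to-sexual alleles take the low codes, private-to-asexual the
   high codes, shared alleles the middle**. The asexual pool
   (shared + asexual-private) is thus contiguous, so reflected ±1 stepwise
   mutation can never leave it — with divergence = 1 the pools are disjoint
   and every between-lineage locus distance is exactly 1, with
   probability 1, mutation included.
2. Sexual lineage: ancestral frequencies ~ symmetric
   Dirichlet(`dirichlet_concentration`); per-site frequencies are a
   Balding–Nichols perturbation Dirichlet(p·(1−F)/F) with
   F = `sexual_site_fst`; individuals draw two alleles independently
   (Hardy–Weinberg within site).
3. Asexual lineage: `n_clone_founders` founder genotypes from a single
   Dirichlet over the asexual pool, shared across sites; each individual
   copies a uniformly random founder (deliberately no site structure), then
   each locus mutates with probability `clone_mutation_rate` by a reflected
   ±1 step on one allele copy.

One `numpy.random.Generator` seeded from `config.seed` drives everything;
identical config + seed is bit-identical.

Defaults and why: `n_loci=9`, two sites, `n_sexual_per_site` =
`n_asexual_per_site` = 20 mirror the reference sampling design (20 females
per lineage per site, nine loci). The remaining defaults are this package's
choices of a realistic regime, fixed once: `alleles_per_locus=8` (typical
microsatellite richness at this sample size), `divergence=0.5` (private
alleles common but pools overlapping; the driver scripts use 0.8 for a
strong-isolation dataset), `sexual_site_fst=0.02` (mild within-species
geographic structure), `n_clone_founders=3` and `clone_mutation_rate=0.01`
(a few clonal families with occasional somatic-lineage mutation —
within-clonal diversity in the field arises by mutation, but its magnitude
is not quantified anywhere to calibrate against), `dirichlet_concentration=1`
(uniform over the frequency simplex).

What the generator does *not* emulate: linkage between loci, selection,
genotyping error and allelic dropout, homoplasy constraints of real repeat
loci, migration between sites, and any overlap regime where the lineages
exchange genes. Passing tests therefore show the chain detects isolation
when it is present and stays quiet under the null — not that it would date
or quantify partial gene flow in real populations.

`null_shuffle` permutes lineage labels uniformly (genotypes untouched),
conserving the label multiset — the fixture for all type-I-error suites. A
Monte-Carlo conditional Hardy–Weinberg check (`hwe_montecarlo_test`:
gene copies re-paired uniformly within a deme, heterozygote count as
statistic, two-sided add-one p) QCs the sexual lineage; it is a QC utility,
not part of the analysis report.

## Pipeline and reproducibility

Stage order is fixed: load → validate → per-scope differentiation (global
and per location) → FST + permutation → distance matrix → NJ → monophyly →
report; each stage failure aborts with the stage name, and partial JSON is
flushed per stage. All randomness derives from the single config seed via
stage-keyed substreams (CRC32 of the stage name mixed with the seed, kept
below 2³¹), so any stage can be reproduced in isolation and a full rerun is
byte-identical (no timestamps in the report). Validation requires at least
two known lineage labels; tables without them abort with instructions to
supply the metadata sidecar, because lineage assignment is a lab step.

## Test-suite problem sizes

The suites run at desk scale, chosen to keep the default run fast while the
statistical assertions retain power: NJ consistency on 100 random 5–8-taxon
additive matrices; exact-test oracle comparison on ~30–40 random tables
small enough for rational-arithmetic enumeration; θ null calibration on 100
label shuffles of a 40-individual, 9-locus table; permutation type-I error
over 200 null datasets at 199 permutations each; end-to-end runs at the
reference design (80 individuals, 9 loci) with 999 permutations.

## Known limitations

- The exact test covers two groups (R×2); multi-group differentiation goes
  through θ only.
- θ is the two-level estimator; no hierarchical (site-within-lineage) AMOVA.
- NJ only — no UPGMA/ML alternatives, no bootstrap support values, no tree
  rendering.
- Missing data enters distances by pairwise deletion and θ by per-locus
  sample-size adjustment; no imputation.
- Allele codes are not constrained to a repeat-unit ladder; stepwise
  mutation in the simulator moves codes by ±1 regardless of the real motif
  length.
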