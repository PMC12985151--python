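# Methods

## Data model

A genotype is an unordered pair of amplicon lengths (nt) stored canonically
sorted. Three per-cell states are kept distinct throughout: a called
genotype, a homozygous-null genotype (the marker amplifies in the
population but not in this sample; sentinel allele `0` for both positions),
and missing data (the sample was not scored). The distinction matters
because a null homozygote is an observation — two null homozygotes *match*
in identity comparisons — while missing cells are simply skipped. A single
observed peak is recorded as two identical alleles, the standard diploid
SSR convention; the file dialect (wide CSV/TSV, `<marker>_1`/`<marker>_2`
columns) always carries both columns.

Replicate rows share a sample label. Consolidation takes the majority
("prevailing") call per marker; a tied vote falls back to the call of the
earliest-listed replicate and flags the marker `unresolved`. Ties have no
principled majority, so the rule is chosen to be deterministic and
auditable rather than statistically motivated; conflicting calls are always
reported with multiplicities.

## Diversity statistics

All per-locus statistics derive from empirical allele proportions in which
each called allele contributes one gene copy. Homozygous-null genotypes
contribute no observable gene copies and are excluded from both the
frequency denominator and the observed-heterozygosity denominator; treating
them as data would bias He and Ho downward at markers segregating a null.

- `He = 1 − Σ p_i²` is the default ("biased") Nei gene diversity. The
  unbiased small-sample form (`× n/(n−1)` over gene copies) is available by
  flag. The biased form is the default because it satisfies
  `Ae = 1/(1 − He)` exactly, an identity the bundled published marker
  tables obey to within their printed rounding (checked on the He scale,
  `|1 − 1/Ae − He| ≤ 0.01`; the Ae scale amplifies rounding at high
  diversity).
- `PIC` is the Botstein form `1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`. It is
  bounded above by He, with equality only in degenerate cases.
- `PI = Σ p_i⁴ + Σ_{i<j} (2p_i p_j)²` equals the probability that two
  independent Hardy–Weinberg genotypes at the locus coincide; the test
  suite verifies this against brute-force enumeration of genotype pairs to
  1e-12, and against empirical match frequencies in simulation. Panel-level
  `PI_t` multiplies per-locus values, which assumes statistically
  independent loci — the reason panel design enforces a minimum physical
  distance between same-chromosome markers.
- Allelic richness uses exact hypergeometric rarefaction to `g` gene copies
  (`k − Σ_a C(N−N_a, g)/C(N, g)`), by default the smallest per-marker
  gene-copy count so markers with different completeness are comparable.
- The null-allele rate defaults to the Chakraborty heterozygote-deficit
  estimator `(He − Ho)/(He + Ho)`; Brookfield's `(He − Ho)/(1 + He)` is
  available by flag. Negative values are legitimate output (heterozygote
  excess) and are not clipped. Both estimators are assumptions rather than
  recomputations of any published figure, and are exercised only by
  directional properties (injected nulls push the estimate positive).
- Shannon's index uses natural logarithms.

Report output is rounded to 3 decimals; internal computation is full
precision.

## Identity and deduplication

Profile comparison counts allele-level differences: per shared locus,
`2 − |multiset intersection|` of the two allele pairs. Loci missing on
either side are excluded from both tallies, and a pair with fewer than half
the panel's loci comparable is flagged low-confidence rather than trusted.
Clusters are single-linkage over pairs within the mismatch threshold; at
threshold 0 they are exact equivalence classes and deduplication (keep the
first member in input order) is idempotent. Pairs one or two alleles apart
are *reported, not merged* — in clonally propagated germplasm these may be
somatic mutants, scoring slips, or genuinely distinct siblings, and that
judgment is curatorial.

## Parentage

A locus is compatible with a candidate pair when the offspring's alleles
can be split one-per-parent; the trio mismatch count is the number of fully
scored loci failing the test, and the search keeps pairs with zero
mismatches (strict exclusion, no error tolerance). Loci with missing or
homozygous-null data in any trio member are skipped — failing on nulls
would fabricate exclusions at null-segregating markers. Selfing is
permitted (one sample serving as both parents); the offspring is never its
own candidate parent. Candidate pairs identical up to clone-cluster
membership are counted once.

LOD ranking is the error-free Marshall-style likelihood ratio: per locus,
`log10` of the Mendelian transmission probability (enumeration of the four
gamete combinations) over the Hardy–Weinberg genotype probability, summed
over scored loci. There is no genotyping-error model; the zero-mismatch
counts do not depend on the LOD at all, which is used only to order
compatible pairs.

The search is `O(n²)` candidate pairs per offspring with early exit on the
first mismatching locus; loci are screened in descending-PIC order, which
rejects incompatible pairs on the most informative loci first. On a
150-sample synthetic cohort the full all-offspring search takes seconds.

## Marker selection and multiplex design

Candidate filtering is a pure conjunction of criteria — at most 2 mapping
failures in the discovery cohort, at least 3 alleles, repeat tract ≤ 60 nt
(longer tracts stutter), no allele above frequency 0.5, and sequence-based
PIC at or above 0.8/0.7/0.6 for di-/tri-/longer-motif repeats. Criteria
whose inputs are absent from a record are not applied, and every verdict
lists the failed criteria. The 60 nt rule is applied to the stored
repeat-tract length; whether it should instead bound the longest observed
allele is ambiguous, and the field name documents the choice.

The multiplex designer assigns markers to a 4-dye × 4-window grid (nominal
windows 100–150, 200–250, 300–350, 400–450 nt) maximizing total quality
score greedily with a local swap-repair pass, under: one marker per slot,
expected size range inside the window minus a 5 nt guard, at most two
markers per chromosome, and same-chromosome pairs at least 1 Mbp apart
(markers without a position on the working reference are exempt from the
distance rule). Instances are tiny, so the deterministic greedy+repair is
adequate; with `require_full` an unfillable grid raises instead of
returning a silent partial design.

The validator treats *window excursions as warnings of any size* and
reserves hard errors for overlapping observed ranges within one dye, slot
collisions, chromosome overloads, and linkage violations. Rationale: the
windows are approximate guides for eyeballing channels, and published
panels include markers whose observed allele ranges leave their nominal
window by 10–14 nt while remaining unambiguous because nothing else in the
dye overlaps them. What actually breaks scoring is within-dye overlap, so
that is what fails.

## Clustering

The between-profile distance is the allele-sharing distance
`1 − shared/(2 × loci compared)` with pairwise deletion of missing loci.
This is a package choice: published dendrogram/Mantel figures built on
unspecified "custom" distances cannot be reproduced exactly, so no
distance-dependent published number is asserted anywhere. UPGMA uses
scipy's size-weighted average linkage over labels pre-sorted
lexicographically (deterministic tie-break); node heights are half the
merge distance, making the tree ultrametric, and trees serialize to
newick. The Mantel test is one-sided ("greater"),
`p = (1 + #{r* ≥ r})/(1 + n_perm)` with joint row/column permutation of the
second matrix, default 999 permutations, fully seeded; the correlation
statistic is cross-checked against an independent library implementation
in the test suite.

## Synthetic data

The generator emulates the statistical structure of a germplasm study, not
its chemistry: allele frequencies are Dirichlet draws over lengths on a
motif lattice (base + m × motif length), optionally rejection-sampled to a
target PIC (±0.02, with the k-allele equifrequency ceiling enforced);
populations are Hardy–Weinberg (two independent gene-copy draws);
crosses transmit one uniformly chosen allele per parent, with an optional
single-step (±1 repeat) mutation model defaulting to rate 0; founder
populations breed each generation by random crosses among the previous one,
so the allele pool can only shrink — the mechanism behind the
founder-effect declines in PIC and Ae that the property suite checks.
Artifact injection overlays hidden null alleles (a null-carrying
heterozygote *appears* homozygous; a double null appears as
no-amplification), planted clone rows, and single-repeat typos, with a
ground-truth log for recovery tests.

Defaults (16 markers, 4–12 alleles each, Dirichlet concentration 1, 100
samples) reflect a realistic highly polymorphic fingerprinting panel on a
medium-sized collection. Everything stochastic takes an explicit seed
(numpy PCG64) and is reproducible across platforms.

What a green synthetic test establishes: the estimators recover their
generating parameters, the trio test never excludes a true error-free
parent pair, planted clones are recovered exactly, and diversity statistics
respond to bottlenecks in the expected direction. What it does not
establish: behavior under real-world stutter mis-scoring, allele binning
drift between instruments, population structure, or genotyping error in
parents — none of which are simulated.

## Known limitations

- The parentage likelihood has no error model, so a single scoring error
  excludes a true parent (by design: strict exclusion).
- `PI_t` assumes locus independence; markers left in a panel despite
  linkage would overstate discriminating power.
- The null-allele and richness estimators are standard but unverifiable
  against the published analysis, which did not print its formulas; they
  are covered by property tests only.
- Published per-sample genotype listings are not redistributable, so the
  collection-level published figures (unique-genotype count, resolved
  offspring count, collection PI_t) are represented by failing-with-message
  acceptance tests unless the data is supplied locally.
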