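# Methods

## Statistical model and conventions

**Units.** The accession (a farm-collected seed lot) is the analysis
unit; individuals are diploid plants genotyped at L codominant SSR loci,
with allele codes equal to scored fragment sizes in bp.  A locus call is
either two alleles or wholly missing: half-calls are treated as scoring
artifacts and rejected by the CSV parsers (GENEPOP's in-band
half-missing codes are demoted to wholly missing, since a codominant
call with one unreadable allele carries no usable genotype).

**Diversity.** H_E uses Nei's unbiased small-sample correction
(2n/(2n−1))(1 − Σp²) because accession samples are ~10 plants.  N_e is
1/Σp² per locus combined as a harmonic mean over loci.  Allelic richness
uses hypergeometric rarefaction at g gene copies; g defaults to the
smallest non-missing copy count across (group, locus) cells, and is
recorded in the output, because published values depend on the g the
original software chose.  Private allelic richness follows Kalinowski:
P(allele present in a g-subsample of the focal group) × Π over other
groups of P(absent from their g-subsamples).  Accession averages are
unweighted over loci; loci with no data in a group drop out of that
group's averages.

**Distances.** The chord distance defaults to
D = sqrt((1/L) Σ_l (1 − Σ_a √(p q))), bounded in [0, 1].  A
GENDIST-style dialect multiplying the radicand by 8/π² (the 2√2/π chord
factor) is selectable, because published averages are dialect-dependent
and the dialect used for any given reported value should be stated, not
guessed.  D_PSA uses the min-allele-count sharing rule over loci typed
in both individuals.  Pairwise F_ST is Weir–Cockerham θ as a
ratio-of-sums over loci and alleles; slightly negative estimates are
reported as computed and only clamped to 0 when linearised for
isolation by distance.

**Trees.** Neighbor joining is the Saitou–Nei agglomeration with two
determinism rules: Q-matrix ties break at the lowest (row, col) index
pair, and negative branch lengths are clamped to 0 with the clamp count
reported.  Bootstrap resamples loci with replacement (the natural unit
for multilocus frequency data); each internal edge of the full-data
tree carries the percentage of replicate trees containing the same leaf
bipartition.

**AMOVA.** Operates on gene copies (2 per individual per locus) with
squared inter-copy distance = number of loci with differing alleles;
sums of squares are partitioned Excoffier–Smouse–Quattro style, with
within-accession df = 2N_ind − N_acc.  Permutation schemes: gene copies
among accessions for Φ_ST, copies among accessions within groups for
Φ_SC, whole accessions among groups for Φ_CT; p = (hits + 1)/(nperm + 1).
The alternative individual-level hierarchy (intra-individual
heterozygosity as its own stratum) is not implemented; the adopted df
arithmetic is the one consistent with gene-copy units.

**Isolation by distance.** F_ST/(1−F_ST) against ln(great-circle km,
radius 6371.0); co-located accessions are floored at 1 km before the
log because the regression is undefined at zero distance (the floor is
recorded).  The Mantel test is one-sided (greater) by default — the
standard alternative for IBD — with permutations jointly shuffling
rows/columns of the distance matrix.  Permutation counts written as
"10^6" in some sources are plainly meant as one million; the default
here is 9,999 with larger counts available by flag.

**Classification.** The assignment threshold τ = 0.75 is inclusive
(max Q ≥ τ assigns): where sources alternate between "at least 75 %"
and "higher than 75 %", the operational assignment sentence wins.
Decision order per accession: (i) max accession Q ≥ τ and a unique
called phaseolin haplotype matching the assigned cluster → TrueType;
(ii) max Q ≥ τ otherwise → NonCorresponding; (iii) max Q < τ with
< 50 % of individuals admixed → Composite; (iv) max Q < τ with ≥ 50 %
admixed → Hybrid.  Haplotype uniqueness is evaluated over individuals
with successful calls; accessions with zero reference-matching calls
are flagged rather than guessed, and accessions reaching Composite with
zero admixed individuals (possible only through near-threshold noise)
carry a review flag.  The external admixture sampler is out of scope:
Q-matrices are inputs.  `beandiv.admixture` ships a small supervised EM
estimator (pool frequencies known, only q estimated) purely so the
classifier, pipeline and tests run on simulated collections without
external software; it is plumbing, not an admixture inference tool.

**Morphology.** G = 2 Σ O ln(O/E) with O = 0 cells contributing 0 and
structural-zero rows/columns dropped with a warning; df = (r−1)(c−1).
Stepwise discriminant analysis enters the candidate with the largest
partial r² = 1 − Λ(S∪{x})/Λ(S) while its ANCOVA F-test p ≤ 0.15 (the
common stepwise-entry default, exposed as a flag); classification uses
linear discriminants with equal priors and leave-one-out
cross-validation.  Seed-size boundaries: small < 25 g, medium 25–40 g
inclusive, large > 40 g per 100 seeds.  The qualitative color
vocabulary includes a "patterned" placeholder state so the five
core-collection traits total 25 states.

**Core collections.** Selection operates on one representative
individual per accession — the carrier of the accession's most frequent
complete multilocus genotype, ties to the smallest id.  The M-strategy
objective is covered item count (locus-allele pairs + trait states)
with Shannon diversity as tie-break among replicate optima, previous
cores forced into larger sizes; restart r seeds its generator with
seed + r so replicates are reproducible under parallel execution.  The
coverage-complete selector is deterministic greedy set cover (ties by
accession id) with redundancy elimination, guaranteeing 100 % coverage;
its near-optimality is verified against exhaustive minimum covers on
small universes, not proven.  Core-vs-collection comparison uses paired
Wilcoxon signed-rank across loci (with Bonferroni across core sizes
left to the caller) in place of a repeated-measures GLM: the original
mixed-model machinery is proprietary-software-specific, and a paired
nonparametric test answers the same question about per-locus
differences.

## Synthetic collections

The generator emulates the data-generating situation the analysis
assumes; its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_pools | 2 | ancestral gene pools (a 3rd pool with its own linked haplotype is supported) |
| n_loci | 21 | SSR loci, 2–12 alleles each |
| δ | 0.6 | between-pool divergence; pool frequencies ~ Dirichlet(base·(1−δ)/δ) |
| n_accessions | 175 | accessions |
| individuals_per_accession | 10 | plants genotyped per accession |
| admixed_fraction | 0.33 | accessions of mixed ancestry |
| selfing_F | 0.95 | P(locus call is a duplicated single draw) |
| founders_per_accession | 4 | inbred founder haplotypes per seed lot |
| founder_weight_concentration | 0.2 | Dirichlet skew of founder contributions (pure lots) |
| phaseolin_epsilon | 0.02 | accession-level haplotype–pool discordance |

Each accession is founded by a few fully inbred haplotypes whose source
pools are drawn from the accession's membership vector q; pure lots get
strongly skewed founder weights (one dominant line), admixed lots even
weights (a genuine mixture).  Selfing is modeled as a probability-F
identical-by-state duplication of a single founder draw per locus, not
an explicit pedigree — it reproduces the two features the analysis
exploits (low H_O, high among-accession variance) with one knob.  The
generator consumes (u, j1, j2) draws per genotype cell regardless of F
and splits structural vs. genotype RNG streams, so changing F alone
leaves the collection's ancestral structure bit-identical — this is
what makes "% among-accession variance is monotone in F" a testable
property rather than a noisy tendency.  Phaseolin travels with the seed
lot (one haplotype per accession, flipped at rate ε), quantitative
traits are Normal around q-weighted pool means (Mesoamerican
small-seeded, Andean large-seeded), qualitative states come from
q-mixed pool-specific categoricals, and GPS coordinates are uniform in
an Iberian-like bounding box with no spatial genetic signal, so
isolation by distance is a true null.

**Calibration.** founder_weight_concentration = 0.2 with 4 founders was
chosen once so that the default collection lands near the empirical
profile of a heavily selfing landrace collection: accession-level
H_E ≈ 0.10–0.15 and N_a ≈ 1.3–1.4.  Under the IBS-duplication model
H_O ≈ (1−F)·H_E, so F = 0.95 yields H_O ≈ 0.007 — the right order of
magnitude but below the ≈ 0.03 a real collection with the same H_E and
F_IS ≈ 0.74 would show; matching both exactly would require F ≈ 0.75,
and the stated default F was kept instead.  Emergent, uncalibrated
quantities behave accordingly: ~65–70 % of AMOVA variance among
accessions (vs ≈ 84 % in comparable real collections — simulated
admixed lots are internally more diverse than real ones), mean chord
distance ≈ 0.6 (independent founder draws produce fewer near-duplicate
accessions than real landrace populations contain), and only ~40–50 %
of planted admixed accessions are detected as offtypes (a skewed
mixture legitimately passes the 75 % rule; its phaseolin then usually
still matches its dominant pool).

**What passing tests show.** The generator has clean IBS structure, no
genotyping error, no null alleles, no linkage, no missing data and no
spatial signal.  Tests passing on it validate the estimators and the
decision logic, not robustness to real-data artifacts (allele-binning
noise, null-allele heterozygote deficit, missingness patterns).

## Problem sizes

The default test suite runs in well under a minute: oracle sweeps are
exhaustive only where enumeration is tiny (rarefaction N ≤ 8, Mantel
4×4, minimum covers ≤ 12 accessions, NJ ≤ 6 taxa), and simulation-based
checks use 15–60 accessions.  Parameter-recovery assertions aggregate
20 simulator seeds at 30 accessions each.  The acceptance script
analyses one full 175-accession collection (bootstrap B = 100, AMOVA
199 permutations, Mantel 999 permutations over 134 accessions, M-strategy
20 replicates × 50 iterations) plus the 20-seed recovery sweep.  The
analysis drivers use larger replication (1,000 AMOVA and 9,999 Mantel
permutations, B = 200, 50 M-strategy replicates); all counts are
parameters.

## Known limitations

* The supervised EM estimator assumes known pool frequencies; it cannot
  choose K and is no substitute for full admixture inference.
* Evanno ΔK requires ≥ 2 runs per K over a contiguous range of ≥ 3 and
  is undefined where run-to-run sd of lnP is 0.
* The M-strategy local search is a greedy+swap stand-in whose
  optimality is only oracle-verified on small instances.
* Rarefaction g is a free parameter; cross-study comparisons require
  matching g, which published tables do not always state.
* No linkage, mutation model, genotyping error or coalescent realism in
  the generator; see above.
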