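# Methods

This note documents the statistical model, the defaults and why they are
set as they are, the synthetic-data generator's scope, and the numerical
and design choices made where the design was genuinely open.

## Disease model and carrier logic

The pipeline assumes an autosomal-dominant, fully penetrant model:
"carrier" means at least one alternate allele everywhere (heterozygous
and homozygous carriers are equivalent), and a causal variant is
expected in every affected member of a family and in no unaffected
member. Three phenotype states are modelled — affected, suggestive
(an intermediate phenotype: disease-typical tissue changes without the
defining lesion), and unaffected — and suggestive individuals are
deliberately ignored by every carrier constraint in both directions:
they neither veto a variant nor are required to carry it. Chromosome X
hemizygosity is not specially modelled; carriage is alt count ≥ 1 on
every chromosome.

Reduced penetrance is handled by *exemptions*: a configured list of
unaffected individuals released from the "absent in unaffected"
constraint at both the global and the per-family stage. Supplying the
exemptions as configuration generalises the single-family reduced-
penetrance case such cohorts typically contain, instead of hard-coding
a family identifier.

Missing genotypes are treated conservatively and the policy is
configurable (`MissingGenotypePolicy`): a missing call in an affected
member fails "present in all affected" (a family cannot vouch for a
variant it has not observed in a required carrier), while a missing
call in an unaffected member never counts as carriage. Half-missing
diploid calls (e.g. `0/.`) are recorded as missing at parse time;
policy ownership stays downstream.

The specification text describes unaffected-carrier removal as a global
pass over all families followed by per-family segregation calls. Both
orderings give identical retained sets under these rules (asserted by a
test); the two-stage form is kept for fidelity to the described
workflow and for its per-stage tallies.

## QC prefilter

*Multiallelic decomposition.* Each alt allele becomes one biallelic
record; a sample's count for record *k* is the number of allele-*k*
copies in its original genotype, so a `1/2` genotype contributes one
copy to each derived record. Shared bases are trimmed — leading first
(advancing the position), then trailing, always keeping at least one
base of each allele. Full left-alignment against a reference genome is
*not* performed: the package has no FASTA dependency, and prefix/suffix
trimming is sufficient for non-repetitive contexts. Variants from
highly repetitive indel regions may therefore normalise differently
than `bcftools norm` output; this is a known limitation.

*Hardy–Weinberg exact test.* The conditional exact test: with allele
counts fixed, each heterozygote count h (parity-matched to the minor
allele count) has probability
`2^h · n! / (n_rr! h! n_cc!) · n_rare! n_common! / (2n)!`,
and the p-value sums every P(h) ≤ P(h_obs). The implementation works in
log-gamma space, normalises the exponentiated vector, and uses a
relative tie tolerance of 1e-12 in the ≤ comparison to absorb float
noise among exactly tied outcomes; terms are arranged in canonical
(rare, common) order so the result is exactly symmetric under allele
relabelling. Monomorphic sites return p = 1. An exhaustive sweep against
an exact rational-arithmetic enumeration oracle (all configurations up
to 200 individuals) agrees to < 1e-12.

The test is computed over all genotyped samples of the joint input by
default, matching a joint families-plus-cohort callset; relatedness
between family members biases it toward heterozygote excess, which is
one reason the exclusion threshold is extreme (p < 1e-8, strict "<":
equality retains). The sample set is configurable. Missing genotypes
are excluded from the genotype counts, never imputed.

*Minor allele count.* After the joint steps, only variants with at
least one copy of the minor allele — min(alt copies, ref copies) ≥ 1 —
among the family samples are retained, removing both the sites fixed
hom-ref and the (rare) sites fixed hom-alt in the families.

## Rarity cascade defaults

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | max reference-panel frequency for "rare" |
| `flipped_threshold` | 0.99 | min frequency for reference-flipped sites |
| `control_maf_threshold` | 0.01 | in-cohort control MAF must be strictly below |
| `cadd_threshold` | 20 | CADD phred cutoff (≈ top 1% most deleterious) |
| `retained_effects` | protein-altering set | frameshift/nonframeshift indel, nonsynonymous, stop gain/loss, unknown effect |
| `excluded_genes` | ACMG secondary-findings genes | BRCA1, BRCA2, MLH1, MSH2, MSH6, PMS2, MUTYH |

Choices worth flagging:

- A variant **absent from every reference panel counts as rare** — a
  variant unseen by large panels is at most very rare; the behaviour is
  explicit in `is_population_rare` and configurable via the source list.
- The CADD rule is **≥ 20**, inclusive; a missing CADD score passes for
  indels only (substitutions are essentially always scorable, indels
  are not).
- The ≥ 99% flip branch applies only to reference-panel frequencies;
  the in-cohort control MAF is already folded to the minor allele, so
  only the strict < 1% test applies there.
- Each removed variant is tagged with the **first** rule it fails, in
  cascade order (population rarity → effect/CADD → excluded gene); the
  retained set is order-independent because the rules are per-variant
  predicates.

## Gene-dropping burden test

The observed statistic for a gene with qualifying variant set V is

    S = Σ_families [ #(genotyped affected carrying ≥1 allele of V)
                    − #(genotyped non-exempt unaffected carrying ≥1 allele of V) ]

The qualifying set is the gene's rare variants surviving the cascade,
*before* any segregation filtering, pooled over families.

The null distribution conditions on founder genotypes — in the
rare-variant setting the variant's presence in a family is a given, and
resampling founder carrier status from population frequencies would
test a different (and uninteresting) hypothesis — and re-transmits
alleles by Mendelian gene-dropping: every non-founder draws one allele
uniformly from each parent's two, independently across meioses and
iterations. For unphased counts this reduces to transmitting the alt
with probability c/2 for a parent with count c, which is exact. The
one-sided p-value uses the add-one convention
p = (1 + #{S_null ≥ S_obs}) / (B + 1), so p ∈ [1/(B+1), 1].

Founders without an observed genotype are imputed hom-ref, unless the
family's observed carriers have no observed carrier founder; then one
heterozygous founder is chosen uniformly per iteration among the
unobserved founders ancestral to an observed carrier (the minimal
explanations of the data). This keeps the null reachable but is an
approximation: when a truly carrying founder is unobserved, the null
under-disperses and the test can become anti-conservative. The
calibration study therefore uses fully observed founders (below); in
real data, genes whose carriage depends heavily on ungenotyped founders
deserve caution.

A master seed expands to per-gene independent streams (seed sequence
keyed by a CRC of the gene symbol), so results are invariant to gene
evaluation order. B defaults to 100,000 iterations.

The statistic is deliberately isolated behind `GeneDropConfig.statistic`
so an alternative family-burden formulation can be slotted in without
touching the permutation machinery.

## Synthetic data

`simulate_dataset` generates a complete cohort at the called-VCF level:
pedigrees of 2–4 generations with a configurable number of genotyped
members per family (default 18 families of 2–7, mirroring the target
study design), phenotypes drawn to hit a 46% affected / 25% suggestive
mix in expectation with at least one genotyped affected per family,
background variants with log-uniform MAF on [1e-4, 0.2] whose founder
genotypes are Hardy–Weinberg draws at the variant's MAF and whose
non-founder genotypes descend by gene-dropping (so HWE holds for
founders in expectation and familial correlation is realistic),
per-source frequency jitter (±20% relative) so the multi-source rarity
rule sees discordant panels, and a configurable missing-genotype rate
applied to background variants only (planted variants stay fully
observed so their truth-table fate is deterministic).

Planted variants come in three modes: `fully_segregating` (all
genotyped affected of each target family heterozygous, suggestive
members carriers with probability 1/2, unaffected non-carriers),
`incomplete` (additionally one unaffected carrier), and `null`
(phenotype-independent carriers). Reduced penetrance flips each planted
affected carrier to unaffected with probability 1−penetrance and lists
the individual as an exemption candidate in the truth table. Deliberate
violators — synonymous, common-in-one-panel, common-in-controls,
low-CADD, LCR-resident, universal-heterozygosity (HWE), excluded-gene,
and zero-MAC variants, each passing every other rule — guarantee every
removal tally is nonzero. Chromosome 22 is reserved for the synthetic
LCR so only deliberate violators fall in it.

Planted carrier patterns are written directly rather than dropped
through the pedigree, so a planted variant's genotypes need not be
Mendelian-consistent with its family structure; this is irrelevant to
the filter and segregation stages (which consume genotypes as data) but
means planted variants are not meaningful inputs to the burden test's
founder-conditioned null.

What passing tests on synthetic data do **not** show: the generator has
no linkage disequilibrium, no realistic exome site density, no
genotyping error beyond missingness, and no sequence context, so it
validates the decision logic and the statistics, not robustness to
upstream calling artefacts.

## Burden-test calibration design

Type-I error is checked on ≥ 2,000 genes whose genotypes are
gene-dropped with no phenotype link. Two design choices matter:

1. **Fully observed founders** (`simulate_calibration_cohort` marks all
   members genotyped): conditioning is then exact and no imputation
   enters the null — the quantity being calibrated is the permutation
   test itself, not the imputation heuristic.
2. **Large families** (36 families of 16–20, founder allele frequency
   0.35): S is integer-valued, and the add-one convention counts the
   entire tie mass P(S_null = S_obs) against the numerator, so with a
   coarse null support P(p ≤ α) sits well below α. Larger families give
   S a fine-grained support; with this design the empirical rate at
   α = 0.05 is ≈ 0.049–0.05 (nominal), whereas a small-cohort design
   with ~90 informative members yields ≈ 0.03 — valid but conservative.

The per-gene permutation count in the calibration study is 399 (p
resolution 1/400 = 0.0025 at α = 0.05), keeping the 2,000-gene scan
around a minute; the agreement of the Monte-Carlo p with exact
enumeration is checked separately at 100,000 iterations on small
pedigrees where full transmission-pattern enumeration is feasible.

## Numerical and formatting choices

- All output orderings are fixed (chromosome-aware sort, then position,
  then alt; genes alphabetical), and no timestamps enter any report, so
  identically configured runs are byte-identical.
- The run report's configuration hash covers analysis parameters
  (thresholds, seeds, exemptions, toggles) and deliberately excludes
  file paths.
- BED input is 0-based half-open and converted at parse time; VCF and
  all reports are 1-based.
- The 2×2 odds-ratio helper applies the Haldane–Anscombe +0.5
  correction to OR and CI only when a cell is zero (flagged in the
  result); the Fisher exact p-value always uses the raw counts.
- Degenerate inputs are defined, not crashes: a gene with no qualifying
  variants returns S = 0, p = 1; families with no genotyped affected
  member yield empty segregation results; families with no genotyped
  members are skipped by the burden test and reported as such.

## Known limitations

- No reference-genome left-alignment of indels (trimming only).
- The HWE test over a joint related-sample cohort is biased toward
  heterozygote excess; founder-only testing is possible via the
  configurable sample set but not the default.
- Founder-genotype imputation in the burden test can be
  anti-conservative when carrying founders are ungenotyped (see above).
- Multi-gene variants are not handled: the annotation table's single
  gene column is taken as authoritative.
- No compound-heterozygote interpretation; within-family multi-hit
  genes are reported, not modelled.
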