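# Methods

## Deterministic cage model

State is the triple of diploid genotype fractions (f_WT/WT, f_WT/KO, f_KO/KO)
at a single autosomal locus. One generation consists of:

1. **Random mating.** The frequency of each of the nine mother × father
   genotype pairings is the product of the maternal and paternal genotype
   fractions; each pairing contributes its exact Mendelian offspring
   distribution weighted by that frequency. With identical parental sexes this
   collapses to Hardy–Weinberg proportions ((1−q)², 2q(1−q), q²) at the
   parental KO-allele frequency q — an identity the test suite checks against
   the explicit nine-pair enumeration to 1e-9.
2. **Viability selection.** Offspring fractions are multiplied by relative
   viabilities (F_WT = 1, F_het, F_KO) and renormalized to sum to 1. The
   heterozygote viability is not free: it is set by the dominance scenario
   (equal to WT, equal to KO, or the arithmetic midpoint).

The population is infinite and generations are discrete and non-overlapping.
Sexes are tracked separately only at generation 0, because the experimental
founder mix is sex-asymmetric (all-KO females; half-WT males); from
generation 1 on, nothing makes genotype depend on sex, so both sexes share the
post-selection distribution. Generation g ≥ 1 records both the pre-selection
offspring pool and the post-selection distribution; observed flies are scored
as eclosed adults, i.e. viability survivors, so fitting uses the
post-selection homozygous-WT fraction (both are exported in the trajectory
TSV for inspection). Fitness acts on each individual's genotype each
generation; parental-genotype (maternal) effects are deliberately not modeled.

Distributions are validated to sum to 1 within 1e-9 and renormalized after
every selection step to control float drift.

## Grid inference

For a candidate F_KO and scenario, the model is run for 35 generations from
the founder mix and the mean absolute error is computed over all observation
records, replicates pooled as independent equally weighted datapoints:
MAE = mean |n_homWT/n_total − model f_WT/WT at that generation|. The grid is
F_KO ∈ {0.4 + k·0.001} up to 1.0 inclusive (601 points, generated as
lo + k·step, never by cumulative addition). Ties are broken toward the
largest F_KO — the weakest selection consistent with the data. Model
selection evaluates the scenarios in the fixed order (het = WT, additive,
het = KO) and keeps the global MAE minimizer, earlier scenario on an exact
tie. No confidence intervals are produced; the estimator is a plain grid
minimizer, matching the precision the design warrants at three replicates.

A 1-D allele-frequency recursion (q′ = q(p·F_het + q·F_KO)/w̄ with the
matching generation-1 seed) serves as an independent oracle for the full
genotype recursion in the tests.

## Stochastic cage simulator

The simulator reproduces the experimental design rather than the idealized
model: each replicate bottle starts from 50 KO/KO females with 25 KO/KO and
25 WT/WT males. Per generation, each scored offspring draws a uniform mother
and father and one allele from each; it survives with probability
(viability)/(max viability) — rejection sampling, which makes survivors an
exact draw from the selection-reweighted offspring distribution, matching the
deterministic model in expectation. Scoring stops at 400 survivors per bottle
per generation (bottle yields are not part of the experimental record; 400 is
a realistic bottle productivity and is configurable). Sex is assigned
independently with probability 1/2 (the locus is autosomal). The next
generation's founders are 50 females and 50 males sampled uniformly without
replacement from the scored survivors — the census-100 bottleneck that
produces genetic drift; founders remain in the scored total, as in the
experiment where passaged flies were frozen back into their generation's
count. A generation with fewer than 50 scored survivors of either sex raises
an error naming the replicate and generation.

Replicate r runs on RNG stream `rng_seed + r`, so replicates are independent
and individually reproducible, and whole tables are byte-identical given the
same inputs. There is no mutation, migration, fecundity variation, maternal
effect or mating structure (virginity/remating ignored): fixation is
absorbing, and the simulator emulates only drift, the founder bottleneck and
viability selection. Passing tests therefore demonstrate correct sampling
behavior under those forces, not realism of bottle ecology.

What the generator emulates vs real data: real cages also carry
maternal-genotype effects on offspring survival, non-random mating and
variable bottle yields; none of these are modeled (the deterministic model
they feed ignores them too, so the pair is self-consistent).

## McDonald–Kreitman test

Input is an in-frame codon alignment of many ingroup strains plus one
outgroup sequence (FASTA; alphabet A, C, G, T, N, `-`). Processing:

- **Strain filter** (default on): ingroup strains containing any N are
  dropped; the outgroup is always kept. Turning the filter off supports
  panels where runs of N encode a known indel rather than low quality.
- **Codon columns** with a gap or N in the outgroup or any retained strain
  are excluded entirely (MK counting is substitution-based; indel
  polymorphisms are outside its scope).
- **Rare-variant mask**: an ingroup codon variant is retained iff its
  frequency among retained strains is ≥ the threshold (default 0.05; "below
  5% ignored" means a variant at exactly 1/20 = 5% is kept). Frequencies are
  per variant, so three-allele sites are masked allele by allele.
- **Polymorphism**: each retained minor variant is compared to the major
  variant (most frequent; alphabetical tie-break for determinism). Each
  single-base step is synonymous iff the translation is unchanged (standard
  genetic code; steps to/from stops count as nonsynonymous). Codons differing
  at ≥ 2 positions are resolved by enumerating all orderings of the changes
  and averaging over paths, giving fractional counts.
- **Divergence** (unpolarized): positions where every retained ingroup codon
  agrees but differs from the outgroup, path-averaged on the major-codon
  background. A position polymorphic within the ingroup never also counts as
  divergence.
- An internal stop in the ingroup major-allele translation is a validation
  error; the terminal codon may be a stop.

The 2×2 table (rows divergence/polymorphism, columns nonsyn/syn) is tested by
χ² without continuity correction by default; Fisher's exact test (one- or
two-sided) and the G-test are selectable. Fractional path-averaged counts are
rounded to the nearest integer only for Fisher, whose hypergeometric null
requires integers. A table with an empty margin carries no contrast and is
reported as statistic 0, p = 1. NI = (Pn/Ps)/(Dn/Ds) and α = 1 − NI are
reported when Ps, Dn and Ds are all positive.

## Problem sizes and numerical choices

The grid fit evaluates 601 candidate viabilities over a 35-generation
horizon. Monte-Carlo checks use 50 simulated cage datasets for parameter and
scenario recovery and 20 seeds × 3 replicates for the generation-20 average;
these sizes keep the whole suite in single-digit seconds while leaving the
Monte-Carlo error well inside the asserted tolerances. Identical trajectories
requested repeatedly during grid fits are memoized (they are immutable and
depend only on seed, scenario, F_KO and horizon).

## Known limitations

- The MAE objective weights every datapoint equally; no binomial weighting by
  n_total, so a 100-fly and a 400-fly sample count the same.
- Dominance scenarios are three discrete hypotheses; intermediate dominance
  coefficients other than 1/2 are not explored.
- The MK implementation reports a single gene per run; no multiple-gene batch
  correction.
- With >2 retained alleles at a codon, polymorphism counting is
  major-vs-each-minor; mutational paths between two minor alleles are not
  counted.
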