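# Methods

This note documents the models and procedures implemented in
`famburden`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Two-stage design

The central idea is a division of labour: a family panel (sib pairs
with known affection status) is used only to derive per-variant
weights, and an independent panel of unrelated cases and controls is
used only for the association test.  Because the weights are a function
of the family data alone, they are fixed constants from the point of
view of the case-control sampling distribution, and the gene-level test
keeps a clean two-sample null: under "no variant in this gene is
associated", the case and control means of the weighted burden score
are equal regardless of what the weights happen to be.  This is what
makes the type-I-error calibration (below) work even though the weights
are highly data-dependent.

## Sib-pair genotype score

For one gene with L variants, a variant is *rare* when its MAF
p ≤ α (default α = 0.01; p estimated in the unrelated panel, cases and
controls combined, configurable to controls only).  Common variants
always score 0 and never receive weight.

For a concordant-affected pair and rare variant j, the score is

| event | score |
|---|---|
| both sibs carry the minor allele | 2 |
| neither carries | 0 |
| exactly one carries | 1 / (1 + K) |

with K = number of *other* rare variants in the gene carried by the
non-carrying sib.  For a discordant pair (affected sib listed first)
the supportive event is "affected carries, unaffected does not" (score
2), "affected does not carry" scores 0, and "both carry" is the
ambiguous event, scored 1/(1+K) with K counted on the affected sib
(excluding variant j itself).  "Carries" means dosage ≥ 1.

The rationale for the K discount: when the relevant sib carries several
other rare alleles in the same gene, any one of them could explain the
pair's affection pattern, so the evidence attributable to variant j is
diluted.  1/(1+K) equals 1 when no alternative explanation exists and
decays smoothly; the three case values (2, 0, mixed rule) are exposed
in `PairScoreConfig` because only their ordering, not their exact
values, is forced by the method's logic — the weight pipeline is
equivariant under a common positive scaling of all three (a tested
property), so the choice of scale cannot change which variants are
retained or how they are ranked relative to one another.

Affected and discordant pairs are never mixed in one weight vector:
they measure different sharing events, and the two scoring rules are
not on a common scale.  `mean_pair_scores` enforces a single pair type;
the affected-pair weights are the default throughout (ascertained
concordant pairs are the more informative design for enrichment).

## Standardization and truncation

Per variant, s̄_j is the mean pair score over the N_sib pairs, and

    b_j = s̄_j / sqrt(p_j (1 − p_j))

puts variants of different frequency on a comparable scale — a given
amount of sharing is more surprising for a rarer allele.  This is the
same inverse-binomial-SD scale the Madsen–Browning weights use;
`inv_var` (divide by p(1−p)) and `none` are available as alternatives.
Degenerate inputs are defined away rather than erroring: b_j = 0 when
p_j = 0 (monomorphic), when p_j > α, and when s̄_j = 0.

Within each gene, b_j is ranked in descending order over the eligible
(rare) variants and only the top quartile retains weight w_j = b_j;
the slot count is ceil(top_fraction · n_eligible) with top_fraction
defaulting to 0.25.  Ties at the cut are broken by ascending variant
index so results are deterministic; a variant with b_j = 0 never
receives positive weight even when the slot count would reach it.  The
truncation acts as hard shrinkage: most rare variants in a gene are
neutral, and carrying their noise into the burden score costs more
power than discarding the occasional weakly-supported causal variant.

K is counted within the gene only, and weights are computed per gene
independently.  One reading note: the source description counts
"other rare SNPs carried" for the affected-pair case and "rare alleles
present at other SNPs" for the discordant case; the implementation
counts *variants* (dosage ≥ 1) in both cases for symmetry, and the
difference only matters for homozygous rare carriers, which are
vanishingly frequent at these MAFs.

## The burden test

γ_k = Σ_j w_j g_kj over the gene's variants, and

    T = (μ̂_D − μ̂_C) / sqrt(s²_D/N_D + s²_C/N_C)

with unbiased (n−1) sample variances, two-sided standard-normal
p-value.  One-sided testing is available (`alternative="greater"`)
since the weight construction makes case enrichment the natural
alternative, but two-sided is the default.  A gene with no retained
variant, or with zero score variance in both arms, reports p = 1 with
an undefined (NaN) statistic — a deliberate "no evidence" convention
rather than NA, so genome scans and multiplicity corrections need no
special-casing.

Missing genotypes are imputed to 0 copies for scoring (counted and
logged).  Zero-imputation can only shrink a carrier count, which is the
conservative direction for a burden statistic.

## Madsen–Browning comparator

Weights 1/sqrt(n_U q_j (1−q_j)) for variants with control MAF < α, 0
otherwise; q_j uses the original pseudocount estimator
(m_j + 1)/(2 n_U + 2) by default, with a plain m_j/(2 n_U) option (the
plain estimator needs, and gets, a guard for variants monomorphic in
controls).  The observed case rank sum X (midranks for ties — sparse
rare-variant scores tie constantly) is standardized by the mean and SD
of X over B = 1,000 random label permutations with the case count held
fixed, and Z is referred to N(0,1) two-sided.  sd = 0 (all scores
tied) again reports p = 1.  The permutation stream for each gene is
seeded from (global seed, CRC32 of the gene id), so per-gene p-values
are reproducible and independent of evaluation order or parallel
scheduling.

## Synthetic cohorts

The generator produces the structure the method assumes, at parameters
chosen to mimic an exome-style rare-variant study:

- **MAF spectrum** — 80% of sites uniform on (0.0005, 0.01), 20%
  uniform on (0.01, 0.3): a spectrum concentrated below 1% with enough
  common sites to exercise the α filter.
- **Disease model** — logistic liability, logit P(affected) =
  logit(prevalence) + Σ β_j g_j, prevalence 0.1.  In each causal gene a
  fraction (default 0.5) of the rare sites carries β uniform on
  (1.5, 3.0) per allele; everything else has β = 0.  Logistic rather
  than probit liability gives a closed-form per-individual probability,
  which the tests exploit directly.
- **Families** — parent haplotypes drawn from population frequencies,
  two offspring per family by per-site Mendelian transmission.  Sites
  are in linkage equilibrium, so per-site independent transmission is
  exact (no recombination map is needed) and every moment is checkable:
  offspring MAF equals population MAF, and the sib dosage correlation
  at a neutral site is exactly 1/2.
- **Ascertainment** — rejection sampling until the target counts of
  concordant-affected pairs, discordant pairs, cases and controls are
  met, with an attempt cap that turns an unattainable configuration
  into a clear error rather than a hang.

What the generator does *not* emulate: linkage disequilibrium,
population stratification, genotyping error, covariates, variable
sibship sizes, or any particular real dataset's causal architecture.
Passing tests therefore demonstrate correctness of the machinery and
the method's behaviour under its own assumptions — not robustness to
the confounders of real studies.

## Study sizes used by the test suite and acceptance script

These are the package's committed desk-scale study conditions:

- **Calibration** — 2,000 null genes of 10 variants, weights from 100
  concordant-affected pairs, tests on 1,000 cases / 1,000 controls.
  Genes are independent under linkage equilibrium, so the empirical
  rejection rate at nominal 0.05 is compared against the 99% binomial
  band 0.05 ± 2.576·sqrt(0.05·0.95/2000) ≈ (0.037, 0.063).
- **Power comparison** — equal genotyping budget, pairs counting as two
  individuals: 100 affected pairs + 500/500 unrelateds for the
  family-weighted test versus 600/600 for Madsen–Browning; 200
  replicates.  The causal architecture is deliberately *deep-rare*
  (rare sites uniform on (0.0005, 0.003), 40 variants per gene, 30% of
  the causal gene's rare sites causal): very rare causal alleles stay
  below the α cutoff even after case enrichment, and the minority-
  causal design is exactly the regime where informed weighting should
  beat indiscriminate frequency weighting.  With MAFs near 0.01 and
  strong effects, case enrichment pushes the combined-panel MAF of
  causal variants above α and the family-weighted test discards them —
  a real limitation of the combined-MAF filter, visible in the
  diagnostics, and the reason the committed architecture is deep-rare.
- **Enrichment check** — 200 affected pairs, one 40-variant causal
  gene; mean b_j over causal variants is required to exceed 3× the mean
  over neutral rare variants in the same gene (pilot runs showed
  ratios of 7–12).

## Known limitations

- The weight stage needs carriers among the sib pairs: with few pairs
  and very rare alleles many genes retain no weight and report p = 1,
  making the family-weighted test conservative gene-by-gene (the
  calibration band is still met at the committed sizes).
- The combined case-control MAF estimate used for the α filter is
  biased upward for truly causal variants in ascertained panels; with
  common-ish rare variants (MAF near α) and large effects this can
  exclude exactly the variants carrying the signal.  Controls-only MAF
  estimation is available as a configuration knob.
- Permutation standardization with B = 1,000 limits how extreme a
  Madsen–Browning Z can be resolved; the normal approximation of Z
  supplies tail p-values beyond 1/B, as in the original method.
- Sibships larger than two contribute all qualifying pairs, so pairs
  within one family are not independent; the weight average does not
  model this (it is a point estimate, not a variance-weighted one).
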