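# Methods

## The analysis problem

Gene-level association between rare loss-of-function (LoF) variants and an
autism diagnosis is awkward for standard case-control machinery for two
reasons. First, the groups are wildly unbalanced (thousands of diagnosed
individuals against hundreds of thousands of undiagnosed ones), and the
very definition of a "rare" variant — a singleton — depends on group size.
Second, per-gene carrier counts are small, so asymptotic tests are
unreliable and zero cells (genes with no undiagnosed carrier at all) are
common and informative rather than pathological. The package addresses
both with a sub-sampling odds-ratio estimator and a relabeling bootstrap,
applied to a stringently filtered variant class.

## Variant classification

A variant-call record reaches the stringent LoF class (S-LoF) only if every
filter passes:

| filter | rule | strictness |
|---|---|---|
| call rate | > 0.9 | strict |
| genotype quality | ≥ 30 | inclusive |
| depth | > 20 | strict |
| allelic fraction | ≥ 0.25, and ≤ 0.75 on autosomes | inclusive both ends |
| frequency (`strict` mode) | reference-population AF = 0 and sample AF ≤ 1% | exact zero |
| frequency (`maf` mode) | reference AF ≤ 1% and sample AF ≤ 1% | inclusive |
| recurrent genes | gene not in the 9-gene blocklist | — |
| Loftee | high confidence, no auxiliary flag | — |
| MNV phase | no in-phase partner within 2 bp changing the joint consequence away from LoF | unknown phase retained, logged |
| brain exon expression | max pext over 13 brain tissues > 0.10 | strict |
| protein truncation | 1 − cds_position/cds_length > 0.10 | strict |

Boundary conventions follow the printed symbols and are pinned by explicit
boundary tests. Two frequency modes exist because "absent from the
reference population" and "MAF ≤ 1%" are both legitimate readings of the
rarity rule; `strict` is the default. Splice-site variants adopt the CDS
coordinate of the closest coding-exon boundary when within ±3 bp
(inclusive); farther variants are unmappable and classified OTHER. The
pext maximum is taken over available tissues, erroring only when all 13
are missing; the MNV "close vicinity" window defaults to 2 bp (same codon)
and is configurable. Synonymous variants passing the shared QC, frequency,
recurrent-gene, pext and truncation filters form the S-SYN negative
control; the Loftee and MNV rules are LoF-specific and skipped for them.

## Gene-level autism OR

With matched group sizes n (the diagnosed count on both margins):

    OR = cd · (n − c̄u) / (c̄u · (n − cd))

cd is the diagnosed carrier count, computed once on the full diagnosed
group. c̄u is the mean undiagnosed carrier count over 100 iterations, each
drawing n undiagnosed individuals without replacement and re-selecting
singleton variants within each group separately (`per_group_singletons`;
`prefiltered_only` disables the re-selection). c̄u is used as a real
number, never rounded. When the undiagnosed pool already has size n every
iteration is the whole pool and the estimator reduces exactly to the direct
full-sample OR (a tested identity). The OR is +inf when cd > 0 and
c̄u = 0, and undefined (NaN, excluded from summaries) when cd = 0. For
plotting and correlation analyses, +inf values are replaced by the highest
finite OR in the gene set.

Significance uses a relabeling bootstrap: each of N replicates draws a
pseudo-diagnosed set of size n from the pooled cohort (without
replacement — the natural exchangeability null), labels the remainder
undiagnosed and reruns the same estimator. With M the number of replicate
ORs ≥ the observed OR (inf ties count), the empirical P is (M+1)/(N+1),
its 95% CI is P ± 1.96·√(P(1−P)/(N+1)) clamped to [0,1], and a gene is
significant when the CI's upper bound is < 0.05. The bootstrap reruns the
full inner sub-sampling by default; `n_iterations_boot=1` gives a fast
single-pass variant. When every variant has a single carrier and the
relabelled remainder equals the diagnosed size, the replicate computation
reduces exactly to a closed-form count and is vectorised; the general loop
is used otherwise, and the two paths are cross-checked in tests.

### Discreteness of the empirical P at small scale

At production scale (pool ≫ diagnosed group) c̄u is an averaged non-integer
and ORs are effectively continuous, so under the null the empirical P is
uniform on {1/(N+1), …, 1}. At small, balanced scale (pool = diagnosed
size) the OR degenerates to a monotone function of an integer carrier
count; replicate ORs then tie with the observed OR with appreciable
probability, and the "≥" tie rule makes the empirical P conservatively
super-uniform (its null mean rises to ~0.59 with ~20 carriers per gene). A
Kolmogorov–Smirnov uniformity check across a few hundred genes detects
this intrinsic discreteness — a property of the procedure at that scale,
not an implementation artefact; an idealized hypergeometric re-derivation
reproduces it. The conservativeness never inflates significance claims.

## Burden statistics

Carrier proportion CIs use the normal approximation p ± 1.96·√(p(1−p)/n),
which reproduces the published interval pairs (3.66–4.33%, 0.99–1.29%,
0.54–0.61%) exactly at two-decimal rounding (half away from zero); Wilson
or Clopper–Pearson would not. Note 223/19,488 computes to 1.14% although
1.13% is the published point value — the published CI matches the computed
fraction, and the package reports the computed value. Fisher exact tests
are two-sided by the probability-mass rule (sum of hypergeometric tables
no more probable than the observed one). Mann-Whitney U is exact by full
enumeration of label assignments (ties half-counted) when the smaller
sample has ≤ 8 observations, and a tie-corrected normal approximation
otherwise. OR-expression correlations default to Kendall tau-b, with
Pearson on log10(OR) vs log10(expression) exposed as `pearson_log10`; the
two conventions coexist in the source material, so both are provided and
the choice is explicit in the API. Expression values ≤ 1 are excluded, and
the single-donor region-period cell (R4/P1) is simply absent from input
matrices.

## Multivariable models

Carrier indicators are split at gene OR ≤ 10 (low) vs > 10 (high; +inf
counts as high; an individual can be 1 in both). The model formulas are
available as named presets (diagnosis, family trait, population trait,
socioeconomic ordinal, brain global/regional/covariate), all expressed
through a generic term grammar (columns, `age2`, `a:b` interactions).
Conventions:

- Continuous predictors and continuous outcomes are z-scored; binary
  indicators are left raw so LoF effects read per carrier. With a binary
  sex covariate the intercept is therefore only approximately zero.
- Sex is coded 0/1 with female = 1.
- The diagnosis outcome has two levels, so the "ordinal" status model is
  fit as binary logistic (they coincide at two levels).
- Ordinal outcomes use a proportional-odds logit fit; the
  proportional-odds assumption is not tested automatically. Empty
  intermediate bands raise unless `empty_levels='collapse'`.
- Quasi-separation in logistic fits is flagged; the fit falls back to (or
  can be forced into) a small L2 penalty.
- The Townsend index is negated before modelling (deprivation = negative);
  the negation provably flips fitted coefficients exactly.
- BH-FDR is applied separately per covariate within outcome groups
  ((1) diagnosis and core autism traits, (2) developmental milestones,
  (3) socioeconomic/fluid intelligence; brain-anatomy presets pool all
  regressions), via the `group_cols` argument.
- Participation ORs are 2×2 with Woolf logit CIs; zero cells report the
  raw point OR with Haldane-corrected (+0.5) CIs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structures the analysis consumes: a family
study (probands with always-undiagnosed parents and some undiagnosed
siblings) plus a population sample; a 4:1 male:female ratio among
diagnosed individuals; a standardized PGS with a +0.2 SD shift in the
diagnosed group (a free parameter — no published value exists); per-gene
carrier frequencies with diagnosed/undiagnosed contrasts (including genes
with zero undiagnosed carriers, the source of infinite ORs); annotation
noise that exercises every filter (low-confidence and flagged Loftee
calls, nonzero reference-population frequencies, splice encodings beyond
the mappable window, QC metrics with controllable failure fractions); and
phenotypes generated by exactly the linear/latent-threshold/Bernoulli
models the regression stage fits, with the published effect sizes as
defaults (fluid intelligence −0.19/−0.37 for low/high-OR carriers, income
latent log-ORs ln 0.62/ln 0.51, qualification ln 0.82/ln 0.49, Townsend
+0.2/+0.15 on the raw deprivation scale, participation OR 0.8).

Deliberate simplifications: one variant per carrier per gene (carrier
status is binary downstream; a multi-variant flag exists), no LD or
haplotype structure, no pedigree transmission beyond role labels, no
sequence-level reads, PGS simulated directly rather than from SNPs. The
default scaled-down gene panel (120 genes) uses per-gene carrier
frequencies larger than the real study's so that per-gene ORs remain
measurable in cohorts of a few thousand; aggregate carrier proportions in
simulated studies are correspondingly higher than the published 4%/0.58%.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under the assumed generative models, not robustness to the
artefacts of real sequencing data (batch effects, relatedness, ancestry
misspecification, annotation error beyond the modelled kinds).

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down configurations chosen as
the package's own defaults: null calibration on 2,000 + 2,000 individuals
with 200 genes and 2,000 bootstraps; estimator consistency on 5,000 +
50,000 with 25–50 replicates; regression recovery at n = 100,000 (150,000
for participation). All randomness flows through seeded
`numpy.random.Generator` instances; identical (spec, seed) produce
byte-identical outputs, and the pipeline stamps every output with its seed
and a configuration hash. Ordinal fits use BFGS with a 200-iteration cap;
the recovery tolerance of the ordinal latent β (±0.1) reflects both
Monte-Carlo and optimizer error. Monte-Carlo recovery checks either use a
single pre-registered seed or average a handful of replicate estimates
when the single-replicate sampling SD is comparable to the tolerance.
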