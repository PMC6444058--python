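# Methods

## Harmonization and the concordance statistic

The two classification schemes are compared on three harmonized buckets:
pathogenic and likely pathogenic map to *disease*, benign and likely
benign to *polymorphism*, uncertain significance to *unclassified*.
Agreement is always defined at bucket level — a curated "disease" call
against a repository "likely pathogenic" is concordant — because the two
schemes have no finer common refinement.

Per-bucket concordance divides the diagonal cell of the 3×3 cross-table
by the union of the bucket's row and column marginals
(`row + col − diagonal`), i.e. by the number of interpretations placed
in that bucket by *either* resource. This penalizes disagreement on both
sides symmetrically and is bounded by 100, attaining it exactly when the
bucket has no off-diagonal mass in its row or column. A bucket empty in
both resources has an undefined concordance and raises rather than
returning a sentinel. Overall agreement is trace over grand total.
Percentages are reported unrounded and displayed rounded to the nearest
integer, half away from zero.

The post-re-curation projection combines the current agreement rate
`a = trace/total` with two empirical rates measured on re-curation
samples: the retention rate `r` (fraction of concordant interpretations
confirmed) and the resolution rate `s` (fraction of discordant ones
resolved into agreement): `100·[a·r + (1−a)·s]`. This is the natural
rate-combination estimate; it assumes the samples are representative of
their strata and is labelled a projection, not an observation.

## Matching and inclusion filters

Identifiers are compared as exact strings after whitespace stripping;
rsIDs are normalized to a lowercase `rs` prefix; protein-level HGVS
names are qualified by the protein accession. No transcript-version
forgiveness is applied — a versioned mismatch is no match — because the
input dialects carry fully versioned names. Key precedence is
rsid > transcript HGVS > protein HGVS, and a variant matched at a higher
precedence is not re-matched lower down. Duplicate identities are all
paired and flagged ambiguous rather than dropped.

The study filters retain missense variants in 2-star repository records
for Mendelian diseases. Exclusions are attributed to the first failing
filter in the fixed order missense → stars → Mendelian, so the exclusion
counts partition the matched pairs exactly; the order is a
reproducibility convention, not a scientific claim.

Review stars are derived from submissions as: 4 for practice-guideline
groups, 3 for expert panels, 2 for ≥2 criteria-providing submitters
agreeing at bucket level, 1 for ≥1 criteria-providing submitter, else 0.
Bucket-level agreement (P with LP) suffices for 2-star status, mirroring
the bucket-level comparison used throughout. When an aggregate record
mixes confidence within one bucket, its single 5-tier label is the less
confident member (LP or LB) — a display choice only; every statistic
consumes the bucket.

## The evidence-combination engine

Evidence codes carry a polarity and a default strength determined by
their prefix (PVS very strong, PS strong, PM moderate, PP supporting;
BA stand-alone, BS strong, BP supporting). Strengths may be re-weighted
with a mandatory justification; polarity is immutable, and stand-alone
strength is reserved for benign evidence. Repeated codes count once:
criteria are counted, not citations.

The combining rules are frozen as package data
(`data/acmg_rules.yaml`); each rule lists minimum counts of applied
strengths and fires under ≥ semantics, with pathogenic taking precedence
over likely pathogenic and benign over likely benign on their own sides.
The tests pin the table bit-exactly against an independent
nested-conditional encoding over every count vector with entries ≤ 4.
Two consequences of the literal table are worth noting: a lone
very-strong criterion (or two, reachable only through re-weighting)
fires nothing and yields uncertain significance, and a benign criterion
re-weighted to very strong is binned with strong benign evidence, since
the benign side has no very-strong bin.

Conflict policy: the result is uncertain significance with
`conflicting=True` whenever evidence of both polarities is present and
the classification is VUS — this covers both the case where rules fire
on both sides and the case where mixed evidence satisfies neither side
(e.g. PM2 + PM3 against BS3). A conflict can therefore arise without any
rule firing, which matches how curators describe such variants.

## Frequency evidence

The maximum credible population allele frequency is
`prevalence × allelic heterogeneity × genotypic contribution / penetrance`,
with defaults heterogeneity 1 and genotypic contribution 1/2 for
autosomal dominant disease (one allele of two) and 1 otherwise. These
defaults are deliberately conservative (they maximize the threshold);
callers with literature values should pass them explicitly. For
autosomal recessive disease with a reported carrier frequency the
comparison scale is the carrier allele frequency (carrier frequency / 2)
directly, because prevalence-derived products are unreliable when the
prevalence itself is underdiagnosed.

The frequency bands are evaluated mutually exclusively, highest first:
above 5% → BA1 (stand-alone); above the disease-specific threshold →
BS1; below the extremely-low cutoff (default 1e-4 for dominant disease;
the carrier-scale threshold for recessive) with zero homozygotes where
recessive → PM2; otherwise no frequency code. BS1 and PM2 can therefore
never co-fire. Without a usable threshold (no prevalence, no carrier
frequency) BS1 is disabled and only the BA1/PM2 logic runs, with a log
note. BS2 (healthy adult observed in the relevant genotype — homozygous
for recessive, any carrier for dominant or X-linked) is independent of
the bands.

Computational predictions yield PP3/BP4 only when all three predictors
agree; any disagreement or unknown verdict contributes nothing.
Functional assays yield PS3/BS3 only when the assay reflects the disease
biology; otherwise the finding is disregarded entirely rather than
down-weighted — disregarding is itself a curatorial judgement and is
logged. In-trans (PM3) and segregation-type evidence are accepted as
supplied assignments, since they are literature facts, not derivable
quantities.

## Synthetic data

The generator emulates the statistical structure of a two-resource
comparison, not its biological content: identities are schematic
(GENE00001, reserved-range rs numbers), diseases are placeholders, and
amino-acid changes are uniform random missense substitutions. Defaults
mirror the packaged 4286-variant comparison: bucket mixture from its row
marginals (1533/2502/251), concordance target 0.88, and a discord kernel
proportional to its off-diagonal counts, so synthetic disagreement
"looks like" the real pattern. The star distribution
(0.10, 0.45, 0.40, 0.04, 0.01) is a plausible repository-wide profile —
most records have one or two criteria-backed submitters, few are
panel-reviewed — and the Mendelian fraction defaults to 0.95; neither is
estimated from data. Submission lists are fabricated to realize the
drawn star level, and the recomputed star status is asserted equal to
the drawn one.

Evidence-profile templates are pure by design: each latent bucket's
templates provably recover that bucket under the combining engine. Real
evidence is messier; passing template-recovery tests shows the engine
and generator are consistent, not that real-world profiles classify
cleanly. Likewise, concordance recovery within binomial confidence
intervals validates the matching/tallying machinery, not the realism of
the synthetic tables. All randomness flows from one integer seed through
a single generator (a derived stream for evidence profiles), so a fixed
seed yields byte-identical files across platforms.

## Problem sizes and numerical choices

The test suite exercises the generator at n = 2000 with 20 seeds for
recovery properties (binomial 99% CI, mean error < 1 percentage point)
and n ≤ 1000 elsewhere; the packaged comparison is re-tallied at its
full 4286 records. These sizes give sub-minute suites while keeping the
confidence intervals tight enough to detect real defects. Exact integer
arithmetic is used for all contingency counts; percentages are floats
with display rounding half away from zero; simplex-valued generator
parameters are validated to sum to 1 within 1e-9.

## Known limitations

- HGVS handling covers missense protein substitutions and exact-string
  transcript names; no genomic coordinates, liftover or VCF
  normalization, and no isoform-aware fuzzy matching.
- The engine implements the categorical combining rules, not later
  Bayesian point-scale refinements; frequency filtering uses point
  estimates, not confidence-interval-based filtering allele frequencies.
- Chance-corrected agreement (kappa) is deliberately out of scope; the
  statistic is raw percent agreement with a union denominator.
- Multiple conditions per repository record are treated as separate
  variant × condition records; no cross-condition collapsing is
  attempted.
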