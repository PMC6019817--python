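# Methods

This note documents the models, the synthetic-data generators, the
numerical conventions, and the design choices made where the procedure was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Covariate correction of cross phenotypes

Tooth number in a cross is corrected for standard length, sex and family
before any genotype test. Each candidate covariate is first tested
marginally (length: regression slope t-test; sex and family: one-way
ANOVA) at level α = 0.05 — the default mirrors the convention of testing
each covariate for significance before correcting for it — and the
significant ones enter a single joint linear model. Corrected values are
the OLS residuals plus the raw mean, i.e. the fitted value at the mean
standard length with factor effects at their observed proportions. This
back-transformation keeps corrected values on the tooth-number scale and
makes mean(corrected) = mean(raw) an exact identity; anchoring instead at
a first-level factor baseline would shift the mean by the baseline's
deviation, so baselines appear only in the coefficient metadata. Sex and
family are fixed effects (a random-effects treatment is defensible for
family but adds machinery the cell-means tests downstream do not need).
Constant responses pass through with a warning; single-level factors are
skipped, not fatal.

## Genotype classes and the direction test

Diploid classes are scored from the two flanking markers: each
phase-ordered haplotype is M (marine alleles at both markers), B (benthic
at both), or R when it matches the configured recombinant two-locus
haplotype; anything else is off-design and the fish is excluded with a
logged reason. Class labels are canonicalised (MM, MB, BB, RM, RB).

The direction test fits Gaussian cell-means models by maximum likelihood
(MLE variance), so twice the log-likelihood ratio of a nested pair is
n·log(RSS_reduced/RSS_full). No distributional family is dictated by the
design; Gaussian linear models are the natural companion of the ANOVA used
on the same phenotypes. Three models are fitted: FULL, R≡M, and R≡B. The
two merged models are not nested in each other, so each is anchored
against FULL (df = reduction in class count) and the direction is called
from that pair of comparisons: the supported direction is the
higher-likelihood merge, declared only when the opposite merge is rejected
at α and the supported one is not; if both or neither are rejected the
call is indeterminate and both p-values are reported. The headline p-value
is that of rejecting the opposite merge. The α of the decision protocol is
a parameter; the power simulations in the tests and acceptance script use
α = 0.01, i.e. a direction is claimed only with p < 0.01 against the
alternative direction.

## Per-benthic-chromosome LRT

In an F2 cross whose two benthic chromosomes are distinguishable at a
four-allele marker, each fish carries a dosage n₁, n₂ ∈ {0, 1} of each
benthic chromosome. The natural comparison of "chromosome i has no
effect" against "both benthic chromosomes carry an equal effect" pits two
non-nested two-parameter models against each other; twice their
log-likelihood difference has no χ²(1) null and is not calibrated (under
a true zero effect of chromosome i the statistic is usually negative). The
test implemented is therefore the nested one: full model
μ + d₁n₁ + d₂n₂ against the reduced model with dᵢ = 0 and the other
effect free, df = 1, which is calibrated under the null and answers the
same scientific question; the equal-effect model's log-likelihood is kept
in the result metadata. When the benthic chromosomes cannot be
molecularly distinguished the result is reported not-applicable with a
reason rather than silently skipped.

## Variant screen

Filter chain, in fixed order with a per-rule removal tally: (1) site QUAL
strictly greater than 400 — a site at exactly 400 is removed; (2) no
high-coverage sample missing or with GQ < 10; (3) at most two samples in
total missing or with GQ < 10. A call with GT present but no GQ passes
rule (2)/(3) with a log entry, since the rules target demonstrably
low-confidence calls. The awkward "in no more than two genomes" phrasing
of the third rule is read as "at most two genomes may be bad".

Flank uniqueness: the 100 bp on each side of the variant (1-based
inclusive; truncated and logged at sequence ends) are matched against the
genome; a variant is removed when the flanks match more than six places
(the variant's own locus counts as one, so seven total occurrences remove
and six retain). The built-in matcher is exact-substring — both flanks
must match around a free middle base; the matcher is pluggable so an
external similarity-search tool honouring the 99 % identity and 10⁻³⁰
e-value settings can be substituted without changing the filter logic.

Concordance is counted per called chromosome (allele frequency: hom_alt
contributes 2/2, het 1/2; missing calls leave the denominator). A
per-fish carrier-proportion mode is available behind a switch; on panels
of essentially homozygous samples the two readings coincide, and the
frequency reading is the well-defined one when heterozygotes occur. A
group with no called samples yields a flagged undefined score, never a
silent zero. Coordinates are 1-based inclusive everywhere except the BED
writer, which converts to 0-based half-open at write time only.
Multiallelic VCF records are split on ingest; sample alleles belonging to
a different alt are treated as missing in the split record, and symbolic
alleles are rejected.

## Enrichment

Per-gene tests are pooled-variance (Student) two-sample t-tests at n = 3
per group — pooling is the stabler choice at this n and is switchable to
Welch — on log2(FPKM + 1); the pseudocount is configurable and the
transform is the standard one for FPKM-like values. The signed z is
Φ⁻¹(F_t(t)), the probit of the t cumulative probability: exactly standard
normal under the per-gene null at any group size, monotone in t, and
signed by the direction of change (positive = up in mutant). Genes with
mean raw abundance below 1 FPKM across all samples ("not expressed") or
with zero variance in both groups are excluded with recorded reasons and
do not enter the permutation pool; the pool is the scored background, so
null subsets are exchangeable with real sets.

The set statistic is a 1-sample t of member z's against 0 (two-sided). A
zero-variance set has p = 1 when the common z is 0 and p = 0 otherwise,
by convention and logged. The permutation null draws subsets of the
matched effective size without replacement, 10,000 by default, and places
cutoffs at the (2.5/N, 100 − 2.5/N) percentiles with linear interpolation
between order statistics (N = number of sets). Significance requires both
the Bonferroni-corrected p < 0.05 and the observed t outside the band —
reporting both criteria rather than collapsing them keeps the decision
auditable. Nulls are cached per effective set size within a run, drawing
from one seeded generator in set order, so results are deterministic
under a fixed seed.

## Synthetic-data generators

All generators are pure functions of (params, seed); the seed is split
into named sub-streams (SeedSequence spawning) so adding a parameter does
not perturb earlier draws, and planted truth is always returned.

**Crosses.** Diploid classes are drawn with equal probability from the
configured class-mean map (one class per Punnett cell); tooth number is
class mean + slope·(length − mean length) + sex/family offsets + Gaussian
residual. Defaults (150 offspring, residual sd 4 teeth, 30 ± 2 mm length,
1.5 teeth/mm) are plausible magnitudes for a juvenile stickleback cross
of this design. Tooth counts are continuous by default — the downstream
models are Gaussian — with an integer-rounding flag for realism when
writing tables; real phenotype TSVs carry integer counts.

**Variant panels.** Defaults mirror the screen's study conditions: 372
differentiated variants (indel fraction 49/372, planted variants all
SNPs) across an 884 kb interval, 10 perfect variants clustered within
4.4 kb, 7 QTL-positive vs 3 QTL-negative samples, 2 high-coverage.
Positions keep a minimum spacing of 2·flank + 1 bp so flank windows never
overlap, which makes the repeat-counting oracle exact and protects the
planted cluster. Perfect variants are constructed to represent the
surviving causal cluster: full calls, site quality above the QUAL filter,
unique flanks. Noise variants flip each group-consistent genotype to the
opposite homozygote with probability 0.15, with at least one flip forced
onto a sample left callable — otherwise ≈ 0.85¹⁰ ≈ 20 % of noise variants
would be accidentally perfect and "exact recovery of the planted set"
would be ill-posed. Missingness (3 %), low-GQ calls (2 %), site quality
uniform on [100, 3000] and a 5 % repeat fraction provide the filter chain
with work; repeat flank windows are pasted six extra times outside the
interval (seven total occurrences trips the more-than-six rule). The toy
genome is uniform-random nucleotides, so flank matches other than the
constructed repeats are vanishingly unlikely at these lengths.

**Expression.** log2 abundances are baseline (Normal, mean 5, sd 2) plus
Normal noise (sd 0.5) per sample, exponentiated to non-negative
FPKM-like values; injected set shifts are added in log2 space to the
mutant columns; sets are disjoint so the truth labels are unambiguous.
n = 3 per group matches the design the pipeline targets. Count-level
noise (library size, overdispersion) is not simulated because the
pipeline consumes normalised matrices — passing tests therefore speak to
the statistics given well-normalised input, not to quantification noise.
Likewise, crosses have no linkage or genotyping error, and the panels'
genotypes have no allele-specific bias; the generators exercise the
pipeline's contracts, not sequencing physics.

## Problem sizes in tests and acceptance

Calibration checks use 500 replicates (Kolmogorov–Smirnov at p > 0.01)
with 60–80 observations per replicate; power checks use 100 seeded
replicates at the study effect sizes (direction: d = 2, sd = 1, n = 150;
enrichment: δ = −1, 50-gene set, noise 0.5, 1,000-gene matrix with
1,000 permutations per set). The acceptance script runs the full-scale
panel (884 kb, 372 variants) once and the two power loops; these sizes
give stable rates while keeping the whole suite quick to re-run.

## Known limitations

* Tooth counts are modelled as continuous Gaussians; no count likelihood
  (Poisson/negative-binomial) in this version.
* The direction test's anchoring of two non-nested merges against the
  FULL model is a documented choice; other resolutions (e.g. Vuong-style
  non-nested comparison) would also be defensible.
* The exact-substring flank matcher is stricter than a similarity search
  at the same thresholds; near-identical repeats below 100 % identity are
  only caught when an external matcher is plugged in.
* The enrichment z-transform assumes independent genes under the null;
  correlated expression inflates the set statistic's variance, which is
  precisely why the permutation band is kept alongside Bonferroni.
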