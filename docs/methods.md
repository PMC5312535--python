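# Methods

This note records the models, estimators, conventions and design
decisions behind breedscan, and what the synthetic-data loop does and
does not establish.

## Coordinates and data model

All internal coordinates are 0-based half-open. VCF (1-based) and GFF3
(1-based inclusive) are converted at the readers; BED passes through
unchanged. One convention everywhere removes whole classes of off-by-one
bugs; a property test asserts that BED and GFF3 encodings of the same
interval compare equal after loading.

Genotypes are alt-allele dosages in {0, 1, 2} with −1 for missing.
Multi-allelic and non-SNP records are dropped (with counts logged), never
split: every statistic in the package is defined on biallelic SNPs.
Missing genotypes are propagated, never imputed; each estimator defines
its own handling (heterozygosity and F_ST use per-site called counts, r²
uses pairwise-complete samples).

## Estimators

**Heterozygosity.** Per sample and window: heterozygous calls / usable
calls, where a call is usable if genotyped and, when a depth threshold is
set, covered ≥ `min_depth` (default 5) in that sample at that site — the
literal per-sample reading of a "coverage at least five times" rule for
restriction-site data. Windows with zero usable sites are undefined
(NaN), never zero.

**Weir–Cockerham F_ST (1984), two populations.** Per site the variance
components a (among populations), b (among individuals within), c
(within individuals) are computed from sample sizes, allele frequencies
and observed heterozygote frequencies; the windowed estimate is the
"weighted" ratio of sums Σa / Σ(a+b+c) over the SNPs in the window —
the standard windowed form and the behavior of the widely used VCF
toolkit's windowed mode. Sites need ≥ 2 called diploids in each
population; windows with fewer than `min_snps` (default 10) informative
SNPs, or a zero denominator, are undefined and excluded from quantile
ranking (this prevents single-SNP outlier windows). Negative raw
estimates are preserved in `fst_raw` and clamped to 0 — and estimates ≥ 1
to 1−10⁻⁹ — in `fst`, keeping T = −log(1−F_ST) finite and non-negative.

**PBS.** (T_CI + T_CT − T_IT)/2 with natural-log T. The additivity
identity PBS_focal + PBS_sister = T(focal, sister) is exact algebra and is
property-tested to 10⁻¹². A window is undefined whenever any of its three
pairwise F_ST values is.

**r² and the H statistic.** r² is the phase-free Rogers–Huff composite
estimator: squared Pearson correlation of dosage vectors over samples
non-missing at both sites. This differs from the EM haplotype-frequency
r² of phased tools; on unphased diploid data the two agree closely except
at strong deviations from Hardy–Weinberg, and phase is unavailable here.
Pairs with a monomorphic member are skipped (r² undefined). Distance bins
are left-open right-closed — a pair at exactly 5 kb falls in bin 1 — an
arbitrary but fixed choice. H sums the 100 per-bin means with empty bins
contributing 0 (they remain NaN in the table for inspection);
0 ≤ H ≤ 100. No minor-allele-frequency filter is applied anywhere by
default: the statistics' definitions do not require one and adding one
silently would change r² and F_ST.

**Top-quantile selection.** The threshold is the ⌈q·n⌉-th largest defined
score; everything scoring ≥ it is kept, so ties only add windows, output
counts are ≥ ⌈q·n⌉, and selections nest monotonically in q. Quantiles are
taken over windows (not merged regions). The second scan track is
ingested, never recomputed — the composite-likelihood sweep statistic is
an external tool's output; a PBS-only mode exists behind an explicit flag
and warns that it deviates from the dual-scan design. Genome fraction uses
the sum of chromosome lengths as denominator.

## RAD locus cascade

Constants (`DigestConfig`): motif ACTAGT, flank 100 bp, trim 3 bp
(200 bp loci), per-base per-individual depth ≥ 5, exon distance 10 kb,
CNE distance 100 bp, spacing 100 kb. Two deliberate asymmetries mirror
the wording of the rules they implement: "at least 10 kb from exons" is
inclusive (distance ≥ 10,000 passes) while "more than 100 bp from CNEs"
is strict (distance > 100 passes). Distance is the end-gap in bp on the
half-open system, 0 when overlapping.

The pipeline order is fixed: digest → extract → annotation → coverage →
thin. The annotation predicates are mutually independent, so their
internal order affects only the recorded rejection reason, and a test
verifies order-independence of the pass set. Thinning is greedy
left-to-right with a ≥ 100 kb minimum gap — guaranteeing the independence
property that no two retained loci are closer than the spacing, which
fixed 100-kb binning would not — and runs last so that loci rejected for
coverage or annotation cannot shadow a passing neighbor. Loci whose raw
flanks cross a contig boundary or an N run are rejected with reason
"edge"; N-run rejection and gap-track rejection are logged separately
because a gap annotation and literal Ns need not coincide.

`find_cut_sites` scans the forward strand case-insensitively; ACTAGT is
its own reverse complement, so this covers both strands (property-tested
by scanning reverse complements). Applied to a full reference genome this
digest is what predicts the enzyme's genome-wide cut-site count.

## Demographic scaling

Ne = θ/(4 μ_year g), T_years = τ/μ_year, with defaults
μ_year = 2.2×10⁻⁹ (calibrated comparative-genomics rate for the dog
lineage) and g = 3 years. The migration conversion 2Nm = m·θ_target/2
follows the G-PhoCS manual convention (its m is the per-generation rate
divided by mutation rate); because samplers differ here, the convention
string is carried in the output metadata rather than assumed.

Trace pooling removes burn-in per replicate before concatenation; the
loader accepts both pre-thinned files (the usual dialect: one row per
`thinning` iterations) and full-resolution files thinned on load.
Posterior intervals use linear-interpolation empirical quantiles
(numpy's default), fixed so the documented order-statistics examples are
exact. Between-replicate consistency is flagged with a simple R̂: the
between-chain variance of replicate means against the mean within-chain
variance, flagged above 1.1.

## Synthetic data

`SimConfig` encodes the three-population model used as ground truth:
wolf/dog split 31,700 years, breed split 8,300 years (converted to
generations with g = 3, the same constant the scaling module uses, so
simulation truth and conversions are mutually consistent), and symmetric
migration among the contemporary populations at 2Nm = 0.5 (the "low,
≤ 1" regime), implemented per recipient as m = 2Nm/(2N_recipient).
The published model reports its population sizes only graphically, so the
defaults here are plausible placeholders chosen once and documented as
ours: root 25,000; wolf 20,000; ancestral dog 5,000 (small, per the
qualitative description); indigenous 25,000 (rapid post-split expansion);
breed 3,000 (mild bottleneck). Split times of zero are clamped to an
epsilon generation, which is operationally panmixia. Chromosomes are
simulated independently at recombination rate 10⁻⁸/bp/gen and mutation
rate μ_year·g per generation.

**Sweep emulation** is a frequency transform on neutral coalescent
output, not a forward selection simulation: within `radius` (default
100 kb) of the sweep position each target-population individual is, with
probability `strength` (default 0.95, full on a plateau of radius/2,
exponential tail with scale radius/6 beyond it), made homozygous for a
"swept" allele drawn once per site proportional to its target-population
frequency — emulating fixation of one hitchhiking haplotype, which is
what produces a branch-specific signal even for alleles shared with the
source population. The plateau/tail shape and default strength were
calibrated once so that the planted window is the top-ranked PBS window
in ≥ 90% of seeded replicates at the fixture's panel size; that
calibration is part of the fixture's definition. This transform exercises
the scan and intersection machinery but does not reproduce the site
frequency spectrum distortions of a real sweep — passing tests show the
scan ranks engineered frequency differentiation correctly, not that it
has any particular power on real data.

**Toy genomes** destroy spurious motif occurrences by single-base edits,
so the digest provably finds exactly the planted sites; ground-truth
locus statuses come from an independent plain-loop predicate evaluator
inside the generator, and the cascade must reproduce them exactly (tested
on 100 random genomes). **Depth tables** are gamma-Poisson (negative
binomial) with mean 36 (the deep restriction-site coverage regime) and
dispersion 100 — variance ≈ 49, mildly overdispersed; at that depth the
chance of any base dipping below 5× is negligible, so the dropout
parameter (a per-locus, per-sample total loss) is the mechanism that
makes the coverage filter bite. **Traces** are AR(1) walks (φ = 0.9,
stationary relative sd = `noise`, default 5%) centered exactly on the
truth; effective sample size n(1−φ)/(1+φ) is used for the recovery
tests' standard errors. The generator's default MCMC shape mirrors the
sampler conditions it emulates (5.2 M iterations, sampled every 10,
200 k burn-in, five replicates).

## Problem sizes

Tests and the acceptance script run desk-scale versions chosen as a
deliberate trade-off between Monte-Carlo error and turnaround: sweep
power uses 50 replicates of a 2 Mb chromosome with 10/15/10 diploid
samples; F_ST monotonicity uses 10 seeds × 3 split times on 300 kb;
panmixia 5 seeds on 400 kb; trace recovery 5 replicates × 520 k
iterations (acceptance script: the full 5.2 M); the locus-cascade
equivalence 100 toy genomes of 2 × 120 kb with 12 sites each. At these
sizes the full suite runs in a few minutes.

## Known limitations

- The Weir–Cockerham implementation is two-population; the PBS scan
  composes three pairwise runs rather than a single r-population fit.
- r² is genotype-based; no haplotype phasing or EM estimator is offered.
- The sweep transform and the AR(1) traces are stand-ins for forward
  simulation and a real MCMC sampler; parameter-recovery results measure
  the scaling/pooling arithmetic, not sampler correctness.
- Enrichment against user-supplied gene lists is plain set intersection;
  no modified-Fisher GO statistic is implemented.
- No ascertainment-bias modelling for SNP-array-merged panels; no
  read-level (FASTQ/BAM) simulation.
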