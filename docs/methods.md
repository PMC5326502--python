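# Methods

## Model

At each heterozygous SNP the observation is a set of *N* count pairs
(*aₙ*, *dₙ*) — reference-allele reads out of total biallelic reads — from
the samples whose peaks cover the SNP. All samples share one allelic balance
ratio η; there is no per-sample heterogeneity. The likelihood is
beta-binomial with mean θ and precision Λ (shapes α = θΛ, β = (1−θ)Λ), which
absorbs the overdispersion of sequencing counts that a plain binomial
understates, especially at high coverage.

Copy number enters through the reparameterization θ = ηρ / (ηρ + (1−η)(1−ρ)).
It treats the ChIP experiment as Bayes' rule: a chromatin fragment carries
the reference allele with prior probability ρ (the reference-allele
frequency, RAF), binding retains it with probability η, and θ is the
posterior probability that a retained (sequenced) fragment is reference.
Reference-mapping bias enters through the prior: θ ~ Beta with mean μ (the
empirical reference ratio at balanced sites) and variance λ, transported to
η by the change of variables with Jacobian ∂θ/∂η, which is strictly
positive, so the map is monotone and the prior proper. When the induced Beta
shapes fall below 1 the prior density has integrable algebraic singularities
at 0 and 1; tests integrate it with endpoint-weighted quadrature rather than
a uniform grid for exactly this reason.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| Λ (precision) | 1000 | beta-binomial precision; larger → closer to binomial |
| λ (prior variance) | 0.05 | spread of the Beta prior on θ around μ |
| HPD mass | 0.95 | posterior mass of the credible interval |
| exclusion zone | (0.4, 0.6) | the whole HPD interval must clear it for a call |
| min_mapq / min_baseq | 15 / 10 | strict (>) pileup quality thresholds |
| min_sites | 200 | sites per allele-pair category before μ is category-specific |
| min_cov | 10 | gDNA depth below which a RAF estimate is unusable |

λ must satisfy λ < μ(1−μ); violating it would make the Beta shapes
non-positive, so it is a hard configuration error, not a silent clamp. ρ or
μ supplied as exactly 0 or 1 are clamped to ±1e−6 with a warning: at ρ = 1
the data carry no information about η (the LOH limit) and the change of
variables degenerates.

The calling rule is configurable. The default zone (0.4, 0.6) requires the
interval to clear a buffer around 0.5; setting the zone to (0.5, 0.5)
recovers the looser rule "the interval does not contain 0.5". The reported
point estimate is the posterior mean of the trace; the HPD endpoints are the
reported credible interval.

## Inference

Random-walk Metropolis–Hastings on η with a Gaussian proposal (sd 0.05),
5000 iterations, 1000 burn-in, chain initialized at 0.5; proposals outside
(0, 1) are rejected. These defaults were chosen because the per-SNP
posterior is unimodal on (0, 1) and cheap to sample; they are overridable in
configuration. Proposals for many SNPs run as independent chains in
lockstep (vectorized across SNPs), which is what makes the benchmark and
table-level calling fast; a chain that accepts nothing over the whole run
raises rather than returning a frozen trace. The HPD interval is the
narrowest contiguous window of ⌈0.95·n⌉ sorted samples, ties broken toward
the smaller lower bound.

## QC pipeline

Order: (1–2) pileup restricted to peaks with strict quality thresholds —
the threshold semantics follow "quality > threshold"; duplicate-flagged,
secondary, supplementary and QC-fail alignments are skipped, and
overlapping mates count once per fragment; (3) removal of SNPs in
user-supplied problematic-alignment region sets (blacklists, low
mappability, collapsed repeats; BED, 0-based half-open); (4) the
simulated-read filter: every possible read overlapping the SNP is generated
for both alleles and strands (4 × read-length reads, uniform base quality,
no depth variation) and realigned — the SNP survives only if exactly
2 × read-length reads per allele map uniquely back to its own locus;
(5) replicate consistency: within an experiment a SNP must have nonzero
coverage in every replicate, else it is masked for that experiment;
(6) possible homozygotes: SNPs where pooled counts show only one allele are
removed. Bases matching neither allele are excluded from *a* and *d* (the
model is strictly biallelic) and tallied in a log; including them would
inflate *d* with sequencing errors.

The built-in realigner for filter (4) is a full-scan near-exact matcher: a
read aligns uniquely if its sequence (either strand) occurs at exactly one
genome locus allowing at most one mismatch (the allele substitution). This
makes the filter testable without an external binary; a process-call
adapter accepts any SAM-emitting aligner for real genomes, where the
user's aligner defines the mismatch policy.

Reference-mapping bias μ is the pooled ratio Σa/Σd over QC-passing sites,
computed per ordered ref→alt allele pair (12 categories — the ordered
convention, since bias is asymmetric in which base the reference carries);
categories with fewer than 200 sites fall back to the global pooled
estimate.

RAF precedence per SNP: a user-supplied RAF column wins; otherwise gDNA
counts (a/d, requiring depth ≥ 10 — direct measurement); otherwise
BAF conversion (RAF = BAF when the reference allele is the array's B
allele, 1 − BAF when it is the A allele). SNPs with no usable source are
excluded and logged rather than defaulted to 0.5, since an unmodeled
copy-number skew is precisely the failure mode the model exists to avoid.

## Synthetic data

Two generators, both pure functions of the seed.

The **count-level generator** draws, per sample, the number of
reference-allele templates t ~ Binomial(d, ρ) and then the reference reads
a ~ Binomial(t, 2η) for η ≤ 0.5 (mirrored through the alternative allele
for η > 0.5), so E[a] = 2ηρd on the low branch. The default validation
grid is N = 1..45, ρ = 0.1..0.9 (step 0.1), d = 1..100 (step 7), and 1000 η
values evenly spaced in [0.1, 0.9] — 6,075,000 configurations; truth labels
mark η outside [0.45, 0.55] as genuinely imbalanced. The ROC benchmark
defaults to a desk-scale sub-grid (N ∈ {3,5,15}, d ∈ {1,8,15},
ρ ∈ {0.5,0.3,0.1}, 200 η values) that spans the regimes where the
correction matters while completing in minutes on one CPU. The Bayesian
model's ranking statistic is |posterior mean − 0.5| (monotone in call
confidence under the symmetric zone); the binomial baselines rank by the
distance between their null and the midpoint of the Clopper–Pearson 95%
confidence interval.

The **read-level fixture generator** plants het SNPs in a random kilobase
genome, draws per-sample counts from the count-level hierarchy, and writes
reads (uniform quality 40, mapq 60, single-end, forward strand) to indexed
BAMs plus matching BED/SNP/BAF/truth tables. It emulates what the pileup
and filters consume; it does **not** emulate indels, soft-clipping,
paired-end fragments, quality gradients along reads, or real aligner
mismatch behavior — so passing end-to-end tests demonstrate the plumbing
and the model on clean data, not robustness to alignment artifacts.
Mate-overlap handling and duplicate skipping are exercised by hand-built
alignment fixtures in the unit tests instead.

## Numerical choices

Beta-binomial log-pmf via log-gamma arithmetic (cross-checked against
scipy's `betabinom` in tests); the empty experiment (a = d = 0) has
log-probability 0. The two-sided exact binomial test is scipy's
`binomtest` (sum of outcome probabilities ≤ the observed one), verified
against full enumeration for all d ≤ 25. BH-FDR uses statsmodels;
ROC/AUC uses scikit-learn with tied scores collapsing to one threshold.
Benchmark strata derive independent RNG substreams from (seed, stratum
index), so strata are reproducible individually and in any order.

## Known limitations

Single shared η per SNP (no per-sample heterogeneity, no multi-chain
convergence diagnostics by default); no peak calling, duplicate marking, or
genotype calling (all upstream); no tumor-purity or subclonal copy-number
modeling — ρ is taken as a point value per SNP; SNP-array A/B allele
identity must be supplied by the user (no manifest parsing). The benchmark
asserts direction and ordering of methods, not absolute AUC values, which
at desk scale carry Monte-Carlo noise.
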