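# Methods

This note records the statistical model behind each module, the default
parameters and where they come from, and the deliberate simplifications.

## 1. Synthetic cohort generator (`cohort`)

The generator draws a cohort intended to resemble a real pan-cancer
liquid-biopsy study population rather than any particular dataset.

**Patients.** Tissue of origin is multinomial over
lung/breast/colorectal/bladder/ovarian/esophageal/sarcoma with weights
93/42/22/12/9/1/1; stage is early/advanced/unknown with weights
36/133/11. Both are configurable maps validated to sum to one.

**Tumor profiles.** The number of mutations per tumor is drawn from
{1: 58/98, 2: 18/98, 3: 17/98, 4: 5/98}, i.e. ~59% of tumors carry a
single trackable mutation and ~36% carry two or three. Genes come from
a weighted pool headed by TP53, EGFR, KRAS, PIK3CA. Tumor MAFs are
log-uniform on [0.28%, 94.7%].

**Plasma shed.** Whether a tumor's mutations are detectable in plasma
is Bernoulli with stage-dependent probability (0.32 early, 0.82
advanced, 0.72 unknown) — ctDNA shed scales with tumor burden, and
stage is the simulator's proxy for burden. Detectable samples get
per-variant plasma MAFs log-uniform between the detection threshold and
a few percent; undetectable samples carry true MAF 0 at every variant.

**cfDNA yield** is log-uniform within stage-specific ranges (early
7.13–80 ng/mL, advanced 15–405 ng/mL), validated so the advanced mean
dominates the early mean.

**Survival.** Event times are exponential per ctDNA group with default
daily hazards 0.00462 (high), 0.00199 (low), 0.00161 (not detected) and
administrative censoring at the study horizon (27 months × 30.44
days/month ≈ 822 days). Groups are assigned by comparing the
representative mutation's copies/mL against the cut point (§5).

**What is not modeled:** clonal hematopoiesis, fragment-length biases,
assay dropout, inter-gene MAF correlation, competing risks, and accrual
is instantaneous by default (`accrual_days = 0`).

## 2. Read-family simulator (`reads`)

Each cfDNA molecule is assigned a true allele (alt with probability
MAF), a family size from a configurable distribution (default mean ≈ 6
reads/family), and a family key per chemistry:

- **positional** — unique fragment start/end coordinates around the
  locus; an optional `collision_rate` makes a molecule reuse an earlier
  key, merging two molecules into one apparent family (the failure mode
  of positional deduplication);
- **tagged_umi** — a unique molecular identifier per molecule;
- **amplicon** — one fixed amplicon key for every molecule (no family
  structure survives PCR).

Per read, sequencing error flips ref↔alt with probability *e* and
substitutes a third ("other") base with probability *e*/3. This keeps
the useful invariant that at MAF = 0 the alt-read fraction concentrates
at *e*, while still producing non-ref/alt noise that consensus must
tolerate. Coordinates are 0-based half-open throughout. Tables
round-trip through a plain-TSV SAM-like format (with line-numbered
parse errors) or real SAM via pysam (allele, sample, and UMI carried in
ZA/ZS/RX tags).

## 3. Detection procedures (`calling`)

All count gates are **inclusive** (≥); the one exception is noted.

**Family construction.** Reads sharing a key (position pair, or UMI)
form a family. A family's consensus is the strict-majority allele (ties
yield no consensus) and its consistency is the majority fraction.

- **Positional consensus caller:** detected iff ≥ 2 families of size
  ≥ 5 reads have consensus = alt with consistency **strictly > 95%**
  (a 19/20 family fails; 20/21 passes).
- **Tagged-UMI consensus caller:** families collapse to one consensus
  read each; detected iff the consensus-level supporting-read
  percentage (%SR) is ≥ 0.4% for SNVs or ≥ 0.2% for multi-base indels.
- **Minimum-family gate:** detected iff ≥ 2 families of size ≥ 3
  support the variant.
- **Amplicon binomial caller:** gates in order — depth ≥ 10, variant
  reads ≥ 2, %SR ≥ 0.3% (SNV) / 0.2% (indel), then confidence ≥ 50,
  where confidence = −10·log₁₀ P(X ≥ k) for X ~ Binomial(depth, e₀)
  with null error rate e₀ = 0.001. A score of 50 corresponds to
  p = 10⁻⁵. Undetected calls carry a machine-readable `reason`.

## 4. ddPCR quantification (`ddpcr`)

With fraction *p* of *N* droplets positive, the mean occupancy is
λ = −ln(1 − *p*) and the reaction contains λ·*N* molecules of that
species. Copies are scaled to the full eluate (÷ fraction loaded) and
to one mL of source plasma (÷ mL extracted). MAF = mutant/(mutant +
wild-type); every volume constant cancels in this ratio, a property the
tests assert. A sample is ctDNA-positive iff MAF ≥ 0.03% (inclusive).
Saturated wells (all droplets positive) raise an error rather than
returning infinity.

The yield conversion `copies/mL = (yield·1000/3.3) · MAF/100` uses 3.3
pg per haploid genome; at the 22 ng/mL median yield and threshold MAF
this gives the 2 copies/mL detection floor. The forward simulator drops
molecules uniformly into droplets and counts occupied ones, making the
estimator testable for bias.

## 5. Concordance (`concordance`)

A sample is **concordant** when ≥ 1 of its tumor mutations is detected
in plasma (a `require_all_variants` switch tightens this to all).
Plasma results at loci absent from the tumor profile are warned about
and ignored — the analysis is a tracking design, not de novo discovery.
Summaries stratify by stage (unknown excluded from the stage block),
tissue, and platform; samples run on both platforms count in both
platform rows. Percentages are rounded half-up to two decimals via
`decimal.Decimal` so printed tables match hand division (2.675 → 2.68,
not banker's 2.67).

## 6. Survival analysis (`survival`)

**Kaplan–Meier** curves and the k-group **log-rank** test delegate to
lifelines. The **signed two-group log-rank Z** used inside the
cut-point search is implemented directly (vectorized with
`searchsorted`/`bincount`) and agrees with lifelines to machine
precision (Z² = χ²).

**Maximally selected cut point:** candidates are midpoints of adjacent
unique ctDNA values whose induced split leaves ≥ `min_group_fraction`
(default 0.1) of samples on each side; the candidate maximizing |Z|
wins. The search is rank-invariant (any monotone transform of the
values selects the equivalent cut). Results carry a `reliable` flag
(false when no split separates at all) and the candidate count. No
multiple-testing correction is applied to the selected statistic — the
cut point is descriptive, and the default constant (210.53 copies/mL)
is a fixed fallback, not an estimate.

**Stratification:** not-detected samples form their own group;
detected samples are high if copies/mL **strictly >** the cut point,
low otherwise.

**Cox proportional hazards** (univariate, group indicator vs a
reference level) is fit by Newton's method with step halving on the
**Breslow** partial likelihood (suffix-cumsum vectorization; gradient
norm < 10⁻⁸ for convergence). Confidence intervals are Wald intervals
from the inverse observed information. When a group has no events the
likelihood is monotone and the true MLE is infinite; the fit stops,
flags `converged = False`, and explains the offending group in
`diagnostics` rather than reporting a spuriously finite HR. On tie-free
data the fitter matches lifelines; with ties it is exact for Breslow
(verified against direct enumeration).

**Report:** per-group KM medians, median-survival differences vs the
reference group, global and pairwise log-rank p-values, and the Cox
HRs, rendered as plain text.

## 7. Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng`; the pipeline
  fans out per-stage seeds via `SeedSequence.spawn`, so stage outputs
  are bit-identical across runs and the manifest records the config
  SHA-256.
- Hot loops (log-rank, Breslow likelihood, family grouping) are
  vectorized; brute-force enumeration versions of each live in the test
  suite as oracles, not in the package.
- Percentages destined for tables are rounded half-up (§5); internal
  arithmetic is never rounded.
- Binomial tails use `scipy.stats.binom.sf`; the Phred transform maps a
  zero tail to +∞ rather than overflowing.

## 8. Limitations

The cohort and read simulators are calibrated to plausible marginal
distributions, not to any patient-level dataset; absolute concordance
percentages from simulation should be read as qualitative. The survival
model is exponential within group (constant hazards), the Cox model is
univariate, and the cut-point p-values are not adjusted for the
maximal selection. The ddPCR model assumes perfect probe specificity —
false-positive droplets are not simulated.
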