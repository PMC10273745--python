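# Methods

## The analysis model

The package operates entirely on GWAS summary statistics: per variant, an
effect estimate β on the log-odds scale, its standard error, and a
two-sided p-value, plus the allele pair the effect is expressed on.
Nothing genotype-level is ever touched, which brings the usual
summary-statistics assumptions: effects are Wald-normal (β̂ ~ N(β, SE²)),
p-values are two-sided, and LD information must come from an external
source (a proxy table and a block partition) rather than the samples
themselves.

### Harmonization

Two traits are compared variant-by-variant only after allele
reconciliation. Variants are matched by id first and by (chromosome,
position) with an allele-compatibility check for id mismatches. A record
whose effect/other alleles are swapped relative to the partner table has
its β sign flipped; strand-ambiguous SNVs (A/T, C/G) are removed outright,
because a swapped coding and an opposite-strand coding are
indistinguishable for them; incompatible allele sets are removed as
mismatches. Indels are matched by exact string or swap only — no
left-alignment or normalization is attempted. Multi-allelic sites survive
as separate records as long as their ids differ; duplicated ids keep the
most significant record. All drops are counted by reason in a load/drop
census that the pipeline writes into its run log.

p-values are stored and compared on the natural scale. The smallest
representable value is the smallest positive double (~5e-324); the
generator floors simulated p-values there. All threshold comparisons are
strict (p < α/m), so a p-value exactly at the threshold does not count.

### Gatekeeper testing

The multiplicity count m is the number of pooled lead variants that are
present — or proxy-rescuable at r² > 0.8 (strict) — in the other trait's
statistics. Proxy ties at the maximal r² break to the candidate nearest
the query position, then to the lexicographically smallest id, making the
lookup invariant to proxy-table row order. No distance cap is applied to
proxy search; candidates come from whatever the supplied table contains.

A variant that is a lead for *both* traits is tested in both directions
but counted once in m by default (`count_mode="variants"`); the
alternative, counting each direction (`count_mode="tests"`), is exposed as
a configuration switch since published lead censuses are usually disjoint
and do not disambiguate the two conventions.

The MHC/HLA exclusion interval defaults to chr6:25,000,000–35,000,000
(hg38, 1-based inclusive) — a conventional extended-MHC span — and is
configurable. Extra leads (e.g. an APOE-defining variant excluded from a
source GWAS's own scan) are injected by configuration, not code.

Under the global null with independent targets, the probability of any
false declaration is 1 − (1 − α/m)^m, which is ≤ α for every m ≥ 1 with
equality only at m = 1. Correlation between target-trait p-values (shared
controls, LD between leads) makes the procedure conservative rather than
anticonservative in the FWER sense.

### Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor
log ABF = ½log(1−r) + z²r/2 with r = W/(SE²+W). The effect-scale prior
SD defaults to 0.2 per trait on the log-odds scale, and the per-variant
configuration priors to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ — the documented
defaults of the reference colocalization implementation for case-control
traits; all four are configuration-exposed. The five hypothesis weights
are accumulated in log space:

    H0: 0
    H1: log p1 + LSE(labf1)
    H2: log p2 + LSE(labf2)
    H3: log p1 + log p2 + log(exp(LSE(labf1)+LSE(labf2)) − exp(LSE(labf1+labf2)))
    H4: log p12 + LSE(labf1+labf2)

with LSE = log-sum-exp, and the H3 difference computed as
a + log1p(−e^(b−a)) for a ≥ b. At n = 1 the H3 configuration set is empty
and its weight is exactly −∞ (posterior 0), never an exception; p12 = 0
likewise zeroes H4 exactly. Posteriors are the normalized exponentials and
sum to 1 within 1e-12. The test suite checks the whole computation against
a brute-force enumeration of all 1 + 2n + n² causal configurations.

Each significant cross-test is colocalized over the harmonized variants in
the approximately independent LD block containing the tested variant
(BED-convention half-open intervals; a 1-based position p falls in the
block covering p−1). Variants missing (β, SE) in either trait are dropped
from the block with counts logged. Hits whose blocks coincide share one
posterior and are cross-annotated in the report. The single-causal-variant
assumption per trait per block is inherited from the method; no
multi-signal extension (which would require an LD matrix) is attempted.

### Small utilities

SE back-calculation assumes the p-value is a two-sided Wald p:
SE = |estimate|/z with z the upper (1 − p/2) normal quantile, diverging to
infinity as p → 1. Confidence intervals use 1.96 verbatim (not the exact
quantile), matching printed-table convention; the multiplier is exposed.

## The synthetic-data generator

Each locus draws MAF ~ U[0.05, 0.5] per variant (shared by both traits, as
for two cohorts of the same ancestry), sets
SE_i = 1/√(2·MAF_i·(1−MAF_i)·N_eff) with N_eff from the harmonic
case-control formula, and draws the marginal z-scores from
MVN(R·λ, R) where R is AR(1) with entries ρ^|i−j| and λ is nonzero only at
causal indices. β_i = z_i·SE_i and p_i is the two-sided normal tail. The
causal signal is parameterized by its expected marginal z (default 6, a
clearly genome-wide-significant signal); a log-odds β may be given
instead, in which case λ_c = β/SE_c and the realized z depends on the
causal variant's MAF.

Defaults are chosen to emulate one approximately independent LD block of a
well-powered case-control GWAS: 300 variants per locus, ρ = 0.95 (several
r² > 0.8 neighbors per variant, as proxy rescue requires; the two causal
variants of a "distinct" locus sit 150 steps apart and are effectively
uncorrelated), 25,000 cases / 50,000 controls per trait (N_eff ≈ 66,667,
SEs around 0.006). Locus size matters for hypothesis recovery: with only a
few dozen variants, the locus-level evidence for one trait fails to clear
the 1/p2 = 10⁴ prior odds whenever that trait's observed causal z (mean 6,
sd 1) dips below ≈5, capping distinct-locus recovery near 75%; block-scale
loci supply enough correlated evidence to recover ≥ 80% of both shared and
distinct loci, which the acceptance suite verifies at 200 loci per
configuration.

Synthetic lead variants are each locus's minimum-p variant among those
with p < 5×10⁻⁸ (the conventional genome-wide threshold), per trait. The
emitted proxy table contains r² = R_ij² for pairs above an emission floor
(0.5 by default), so proxy lookups in tests agree algebraically with the
simulated LD. A withhold option removes chosen variant ids from one
trait's emitted table *before* that trait's lead calling, forcing the
proxy-rescue path end to end.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: realistic haplotype structure (AR(1) LD
has no block substructure or long-range LD), sample overlap between traits
(shared controls induce correlated errors and would inflate apparent
pleiotropy; an extension hook, not implemented), allele-frequency
mismatches between cohorts, imputation-quality variation (INFO is emitted
as 1), population stratification, and the winner's-curse selection of real
published lead lists.

## Numerical and design choices

- All posterior accumulation is in log space; no intermediate
  exponentiation of large Bayes factors occurs.
- Thresholds are displayed at two significant figures in logs/reports but
  always compared at full precision.
- Reported ORs are exp(β) of the harmonized effect allele; direction
  concordance is the sign agreement of the two harmonized βs, with a zero
  β giving "indeterminate".
- Block sets must be non-overlapping within chromosome; overlap is a
  configuration error at load time, so block assignment is always unique.
- An empty pooled lead set yields an empty report and success (there are
  no hypotheses); a nonempty pooled set with m = 0 testable variants is a
  refusal with a diagnostic (there were hypotheses but none could be
  looked up).
- Nearest-gene annotation is optional and purely interval-distance-based,
  with ties reported joined by "/"; it implies nothing about causality.
- Determinism: every stochastic routine takes a numpy Generator or seed;
  identical seeds give byte-identical bundles and reports.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
recovery checks use 200 loci × 3 configurations at the default 300-variant
locus; the FWER simulation uses 2,000 replicates of 172 null p-values;
oracle-equivalence checks enumerate configurations for 1,000 random loci
of up to 8 variants. The full suite completes in well under a minute on a
single CPU.

## Known limitations

- Single causal variant per trait per block; allelic series or secondary
  signals at a locus violate the colocalization model (though not the
  gatekeeper test itself).
- Proxy substitution tests the proxy's association, not the lead's; with
  r² > 0.8 the attenuation is modest but real.
- The harmonizer trusts ids and coordinates; it performs no reference
  panel or frequency sanity checks, and no build liftover.
- FWER control is exact only under independence of the target-trait
  p-values; correlated targets make the procedure conservative.
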