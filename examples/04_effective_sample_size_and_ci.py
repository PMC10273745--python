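"""Effective sample sizes for case-control GWAS and CI back-calculation.

Shows the two N_eff conventions — per-variant from MAF/INFO/BETA/SE and
study-level from case/control counts — and the recovery of a 95%
confidence interval from a printed (estimate, p-value) pair.
"""

from pleioscan import ci95, neff_from_counts, neff_per_variant, se_from_estimate_and_p

# Study-level: a GWAS of 21,982 cases and 41,944 controls.
neff = neff_from_counts(21_982, 41_944)
print(f"N_eff(21982 cases, 41944 controls) = {neff:,.0f}")
print(f"N_eff(n, n) = 2n check: {neff_from_counts(1000, 1000):,.0f}")

# Per-variant: a common variant (MAF 0.5, INFO 1) with SE 0.01.
print(f"N_eff(maf=0.5, info=1, beta=0, se=0.01) = {neff_per_variant(0.5, 1.0, 0.0, 0.01):,.0f}")
print(f"N_eff(maf=0.5, info=1, beta=0.1, se=0.01) = {neff_per_variant(0.5, 1.0, 0.1, 0.01):,.0f}")

# Back-calculate the SE behind a published genetic correlation of 0.16
# with p = 7.5e-4, then rebuild its 95% CI.
se = se_from_estimate_and_p(0.16, 7.5e-4)
ci = ci95(0.16, se)
print(f"estimate 0.16, p=7.5e-4 -> se={se:.4f}, "
      f"95% CI [{ci.ci_low:.2f}, {ci.ci_high:.2f}]")
# The interval should land close to the published [0.07, 0.25].
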