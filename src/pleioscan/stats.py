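"""Small statistical utilities: SE back-calculation and 95% intervals.

Published tables often print an estimate and a two-sided p-value but no
standard error.  Assuming the p-value came from a Wald test, the SE can be
recovered as |estimate| / z where z is the upper (1 - p/2) standard normal
quantile, after which a conventional 95% confidence interval is
estimate +/- 1.96 * SE.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["EstimateWithCI", "se_from_estimate_and_p", "ci95", "Z_95"]

#: The conventional 95% multiplier, used verbatim to match printed tables
#: (rather than the exact quantile 1.95996...).
Z_95 = 1.96


@dataclass(frozen=True)
class EstimateWithCI:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


def se_from_estimate_and_p(estimate: float, p: float) -> float:
    """Back-calculate a Wald standard error from an estimate and p-value.

    Returns |estimate| / z with z the upper (1 - p/2) normal quantile.
    As p -> 1 the implied z tends to 0 and the SE diverges to infinity,
    which is returned rather than raised.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if estimate == 0:
        raise ValueError("estimate must be nonzero")
    z = norm.isf(p / 2.0)
    if z <= 0:
        return float("inf")
    return abs(estimate) / z


def ci95(estimate: float, se: float, z: float = Z_95) -> EstimateWithCI:
    """Symmetric 95% confidence interval, estimate +/- z * se."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    return EstimateWithCI(
        estimate=estimate,
        se=se,
        ci_low=estimate - z * se,
        ci_high=estimate + z * se,
    )
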