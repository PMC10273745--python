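"""Single-causal-variant Bayesian colocalization from summary statistics.

Given two traits' per-variant effect estimates over the variants of one LD
block, the method compares five hypotheses about the block:

- H0: neither trait has a causal variant;
- H1 / H2: only trait 1 / only trait 2 has a causal variant;
- H3: both traits have causal variants, but distinct ones ("PP_distinct");
- H4: both traits share a single causal variant ("PP_shared").

Evidence per variant is the Wakefield approximate Bayes factor computed
from (beta, se) and a Gaussian prior on the true effect with standard
deviation ``prior_sd``.  Each hypothesis weight sums the Bayes factors of
its variant configurations times the prior probability of that
configuration (p1, p2 for single-trait causality, p12 for shared), and the
five posteriors are the normalized weights.  At most one causal variant per
trait per block is assumed.

All accumulation happens in log space via log-sum-exp; the H3 term, a
difference of exponentials, uses log(e^a - e^b) = a + log1p(-e^(b-a)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocPosterior",
    "LocusData",
    "log_abf",
    "coloc_posteriors",
    "colocalize_locus",
    "DEFAULT_PRIOR_SD",
]

#: Default effect-scale prior SD on the log-odds scale for case-control
#: traits, as released with the reference colocalization implementation.
DEFAULT_PRIOR_SD = 0.2


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality.

    p1 (p2): a given variant is causal for trait 1 (trait 2) only;
    p12: causal for both.  Defaults are the reference implementation's
    documented defaults.  n * (p1 + p2 + p12) must stay below 1 for any
    analyzed block.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0 or self.p12 < 0:
            raise ValueError("priors must be positive (p12 may be 0 to disable H4)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors sum to >= 1")


@dataclass(frozen=True)
class ColocPosterior:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n: int

    @property
    def pp_shared(self) -> float:
        """Posterior probability the traits share one causal variant (H4)."""
        return self.pp_h4

    @property
    def pp_distinct(self) -> float:
        """Posterior probability of two distinct causal variants (H3)."""
        return self.pp_h3

    def as_array(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])

    @property
    def best_hypothesis(self) -> str:
        return f"H{int(np.argmax(self.as_array()))}"


@dataclass
class LocusData:
    """Aligned (beta, se) vectors for two traits over one LD block."""

    label: str
    block: tuple[str, int, int] | None
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        n = len(self.beta1)
        if n < 1:
            raise ValueError("locus must contain at least one variant")
        if not (len(self.se1) == len(self.beta2) == len(self.se2) == n):
            raise ValueError("per-trait vectors must have equal length")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.beta1)


def log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log Wakefield approximate Bayes factor for association.

    With V = se², W = prior_sd², z = beta/se and shrinkage r = W/(V+W):

        log ABF = 1/2 * log(1 - r) + z² * r / 2.

    Accepts scalars or arrays.  As prior_sd -> 0 the prior collapses onto
    the null and the ABF tends to 1 (log 0); a null estimate (beta = 0) is
    penalized by the prior width, giving log ABF < 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf when the difference underflows."""
    if b >= a or np.isinf(b) and np.isinf(a):
        return -np.inf
    d = b - a
    with np.errstate(divide="ignore"):
        return a + np.log1p(-np.exp(d)) if d < 0 else -np.inf


def coloc_posteriors(labf1, labf2, priors: ColocPriors = ColocPriors()) -> ColocPosterior:
    """Five-hypothesis posterior from two traits' per-variant log ABFs.

    The unnormalized log weights are

        H0: 0
        H1: log p1 + LSE(labf1)
        H2: log p2 + LSE(labf2)
        H3: log p1 + log p2 + log( exp(LSE(labf1) + LSE(labf2))
                                   - exp(LSE(labf1 + labf2)) )
        H4: log p12 + LSE(labf1 + labf2)

    where LSE is log-sum-exp over variants.  The H3 sum runs over ordered
    pairs of distinct variants; with a single variant no such pair exists
    and PP_H3 is exactly 0.  With p12 = 0, PP_H4 is exactly 0.
    """
    labf1 = np.atleast_1d(np.asarray(labf1, dtype=float))
    labf2 = np.atleast_1d(np.asarray(labf2, dtype=float))
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("labf vectors must be 1-D and equal length")
    n = len(labf1)
    if n * (priors.p1 + priors.p2 + priors.p12) >= 1:
        raise ValueError(f"priors too large for a locus of {n} variants")

    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12 = float(logsumexp(labf1 + labf2))

    with np.errstate(divide="ignore"):
        log_p12 = np.log(priors.p12)
    h = np.array(
        [
            0.0,
            np.log(priors.p1) + l1,
            np.log(priors.p2) + l2,
            np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(l1 + l2, l12),
            log_p12 + l12,
        ]
    )
    pp = np.exp(h - logsumexp(h))
    pp /= pp.sum()
    return ColocPosterior(*(float(x) for x in pp), n=n)


def colocalize_locus(
    locus: LocusData,
    priors: ColocPriors = ColocPriors(),
    prior_sd: tuple[float, float] = (DEFAULT_PRIOR_SD, DEFAULT_PRIOR_SD),
) -> ColocPosterior:
    """Colocalize one locus: per-variant ABFs for each trait, then posteriors.

    Variants with missing (NaN) beta or se in either trait are dropped from
    the block before analysis.
    """
    keep = ~(
        np.isnan(locus.beta1) | np.isnan(locus.se1)
        | np.isnan(locus.beta2) | np.isnan(locus.se2)
    )
    if not keep.any():
        raise ValueError(f"locus {locus.label}: no variant has complete statistics")
    labf1 = log_abf(locus.beta1[keep], locus.se1[keep], prior_sd[0])
    labf2 = log_abf(locus.beta2[keep], locus.se2[keep], prior_sd[1])
    return coloc_posteriors(labf1, labf2, priors)
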