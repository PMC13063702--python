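"""Bayesian colocalization by enumeration over per-variant approximate Bayes factors.

For each variant, the evidence of association with a trait is summarized by
Wakefield's approximate Bayes factor computed from the estimated effect and
its standard error under a normal prior on the true effect. Assuming at most
one causal variant per trait in the region, the five hypotheses

    H0: no association with either trait
    H1: association with trait 1 only
    H2: association with trait 2 only
    H3: both traits, distinct causal variants
    H4: both traits, one shared causal variant

are scored by summing ABFs over the allowed configurations, weighted by the
per-variant prior probabilities ``p1``, ``p2`` (trait-specific causality) and
``p12`` (shared causality). All sums are carried in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from cismr.sumstats import VariantAssociation

#: Conventional prior SD on a standardized quantitative trait effect.
PRIOR_SD_QUANT = 0.15
#: Conventional prior SD on a log hazard-ratio (binary/survival trait) effect.
PRIOR_SD_BINARY = 0.2


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    p1: float
    p2: float
    p12: float
    n_variants: int
    variant_ids: list[str]
    per_variant_h4: np.ndarray  # posterior over shared-variant configurations

    def posteriors(self) -> dict[str, float]:
        return {
            "PP.H0": self.pp_h0, "PP.H1": self.pp_h1, "PP.H2": self.pp_h2,
            "PP.H3": self.pp_h3, "PP.H4": self.pp_h4,
        }

    @property
    def best_hypothesis(self) -> str:
        pp = self.posteriors()
        return max(pp, key=pp.get)


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one variant-trait association.

    With ``z = beta/se``, ``V = se^2`` and ``W = prior_sd^2``,
    ``r = W/(V+W)`` and ``log ABF = 0.5*log(1-r) + 0.5*z^2*r``.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z = beta / se
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


def _log_abfs(records: Sequence[VariantAssociation], prior_sd: float) -> np.ndarray:
    return np.array([wakefield_abf(v.beta, v.se, prior_sd) for v in records])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf at a == b."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    trait1: Sequence[VariantAssociation],
    trait2: Sequence[VariantAssociation],
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = PRIOR_SD_QUANT,
    prior_sd2: float = PRIOR_SD_BINARY,
) -> ColocResult:
    """Enumeration posteriors PP.H0-PP.H4 over a shared variant set.

    The two tables must cover the identical variants (harmonize first);
    trait 2 is reordered to trait 1's order. ABFs depend on z^2, so allele
    coding does not affect the result once the variant sets match.
    """
    ids1 = [v.variant_id for v in trait1]
    by_id2 = {v.variant_id: v for v in trait2}
    if set(ids1) != set(by_id2) or len(ids1) != len(trait2):
        raise ValueError("trait1 and trait2 must cover the identical variant set")
    trait2 = [by_id2[i] for i in ids1]

    l1 = _log_abfs(trait1, prior_sd1)
    l2 = _log_abfs(trait2, prior_sd2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)  # shared-variant configurations

    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    # H3 sums ABF1_i * ABF2_j over distinct pairs i != j.
    lh3 = np.log(p1) + np.log(p2) + _logdiffexp(lsum1 + lsum2, lsum12)
    lh4 = np.log(p12) + lsum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()

    per_h4 = np.exp(l1 + l2 - lsum12)
    return ColocResult(
        pp_h0=float(pp[0]), pp_h1=float(pp[1]), pp_h2=float(pp[2]),
        pp_h3=float(pp[3]), pp_h4=float(pp[4]),
        p1=p1, p2=p2, p12=p12,
        n_variants=len(ids1), variant_ids=ids1, per_variant_h4=per_h4,
    )
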