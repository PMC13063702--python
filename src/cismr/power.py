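"""Minimally detectable hazard ratio for summary-MR of a case-only survival outcome.

Mortality among cases is treated as a binary outcome (time to event is
ignored). For a two-sample MR with instruments explaining a fraction ``r2``
of the exposure variance, tested at two-sided level ``alpha`` with the given
power, the smallest detectable log hazard ratio per SD of exposure is

    b_min = (z_{1-alpha/2} + z_{power}) / sqrt(n_cases * r2 * r * (1 - r))

where ``r = n_events / n_cases`` is the event fraction, and the minimally
detectable HR is ``exp(b_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the minimally-detectable-HR calculation."""

    n_cases: int
    n_events: int
    r2: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.n_events <= self.n_cases):
            raise ValueError("need 0 < n_events <= n_cases")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must lie in (0,1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0,1)")


def min_detectable_hr(spec: PowerSpec) -> float:
    """Smallest HR per SD exposure detectable at the given level and power."""
    r = spec.n_events / spec.n_cases
    if r >= 1.0:
        raise ValueError("degenerate event fraction (all cases are events)")
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(spec.power)
    b_min = z / np.sqrt(spec.n_cases * spec.r2 * r * (1.0 - r))
    return float(np.exp(b_min))
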