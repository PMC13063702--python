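"""MR-PRESSO-style global heterogeneity test and per-variant outlier detection.

The global test compares the observed sum of weighted squared residuals —
each variant's outcome association measured against the leave-that-variant-out
IVW slope — with its parametric null distribution, obtained by redrawing every
outcome association from ``Normal(slope_{-j} * bX_j, se_Y_j^2)`` and
recomputing the statistic. Per-variant outliers are flagged by the same
simulated residual distributions with Bonferroni correction over the panel.
Requires independent instruments. The smallest reportable p-value is
``1/(n_sim+1)``. The add-one-in distortion test of the original method is
not implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cismr.mr import MREstimate, MRError, ivw_correlated
from cismr.sumstats import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class PressoResult:
    """Global and per-variant PRESSO outputs."""

    global_rss_obs: float
    global_pval: float
    per_variant_pvals: list[float]
    outlier_ids: list[str]
    n_sim: int
    seed: int
    ivw_outlier_removed: MREstimate | None = None

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_ids) > 0


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out identity-IVW slopes for every variant, vectorized.

    ``by`` may be a matrix (n_sim, k); slopes are returned with matching shape.
    """
    sxx = (w * bx * bx).sum()
    sxy = (w * bx * by).sum(axis=-1, keepdims=by.ndim > 1)
    if by.ndim == 1:
        sxy = float((w * bx * by).sum())
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso_test(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Run the global heterogeneity test and flag per-variant outliers.

    ``outlier_alpha`` applies to the Bonferroni-adjusted per-variant p-values.
    Deterministic for a fixed seed; row order only permutes the per-variant
    output.
    """
    if h.k < 4:
        raise MRError("insufficient instruments for PRESSO (k >= 4 required)")
    if not np.allclose(h.ld.rho, np.eye(h.k)):
        logger.warning("PRESSO requires independent instruments; forcing identity")
        h = h.with_identity_ld()
    bx, by, se_y = h.bx, h.by, h.se_y
    w = 1.0 / se_y**2

    slopes_obs = _loo_slopes(bx, by, w)
    resid_obs = w * (by - slopes_obs * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    # Null draws centered on the leave-one-out predictions.
    by_sim = rng.normal(slopes_obs * bx, se_y, size=(n_sim, h.k))
    slopes_sim = _loo_slopes(bx, by_sim, w)
    resid_sim = w * (by_sim - slopes_sim * bx) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + float((rss_sim >= rss_obs).sum())) / (n_sim + 1.0)
    per_raw = (1.0 + (resid_sim >= resid_obs).sum(axis=0)) / (n_sim + 1.0)
    per_adj = np.minimum(1.0, per_raw * h.k)
    outliers = [
        vid for vid, p in zip(h.variant_ids, per_adj) if p < outlier_alpha
    ]

    ivw_removed = None
    if outliers and h.k - len(outliers) >= 1:
        trimmed = h
        for vid in outliers:
            trimmed = trimmed.drop_variant(vid)
        ivw_removed = ivw_correlated(trimmed)

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=float(global_pval),
        per_variant_pvals=[float(p) for p in per_adj],
        outlier_ids=outliers,
        n_sim=n_sim,
        seed=seed,
        ivw_outlier_removed=ivw_removed,
    )
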