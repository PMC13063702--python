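"""Summary-statistics MR estimation for correlated cis-instruments.

The estimators operate on a :class:`~cismr.sumstats.HarmonizedSet` holding
per-variant exposure associations ``bX`` (SD units of the standardized
protein), outcome associations ``bY`` (log hazard ratios) with standard
errors ``se_Y``, and the instrument correlation matrix ``rho``.

The generalized (correlated-instrument) IVW estimator weights by
``Omega^{-1}`` with ``Omega_ij = se_Y_i * se_Y_j * rho_ij``:

    beta_hat = (bX' Omega^-1 bX)^-1 (bX' Omega^-1 bY)

with heterogeneity Q = (bY - beta_hat bX)' Omega^-1 (bY - beta_hat bX) and a
multiplicative random-effects variance multiplier phi = max(1, Q/(k-1)).
MR-Egger adds a free intercept (directional-pleiotropy test) to the same
generalized regression after orienting all variants to non-negative bX.
Confidence intervals use the normal reference distribution by default; a
t reference with k-1 (IVW) or k-2 (Egger) degrees of freedom is available
via ``use_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from cismr.sumstats import HarmonizedSet

_Z95 = stats.norm.ppf(0.975)


class MRError(ValueError):
    """Raised when an MR estimator cannot be applied to the given set."""


@dataclass
class MREstimate:
    """A single MR estimate on the log hazard-ratio per-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k_snps: int
    q_stat: float = float("nan")
    q_pval: float = float("nan")
    phi: float = 1.0

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def hr_ci(self) -> tuple[float, float]:
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))

    def format_hr(self, digits: int = 2) -> str:
        lo, hi = self.hr_ci
        return f"{self.hr:.{digits}f} ({lo:.{digits}f}, {hi:.{digits}f})"

    def to_dict(self) -> dict:
        lo, hi = self.hr_ci
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "hr": self.hr, "hr_ci_low": lo, "hr_ci_high": hi,
            "k_snps": self.k_snps, "q_stat": self.q_stat,
            "q_pval": self.q_pval, "phi": self.phi,
        }


def _omega(h: HarmonizedSet) -> np.ndarray:
    se_y = h.se_y
    return np.outer(se_y, se_y) * h.ld.rho


def _solve_spd(omega: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(omega)
        return linalg.cho_solve((c, low), rhs)
    except linalg.LinAlgError as exc:
        raise MRError("ill-conditioned weight matrix") from exc


def _interval(beta: float, se: float, df: int | None) -> tuple[float, float, float]:
    """(ci_low, ci_high, two-sided p) under normal or t reference."""
    if se == 0:
        return beta, beta, 0.0 if beta != 0 else 1.0
    z = beta / se
    if df is None:
        crit = _Z95
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(z), df)
    return beta - crit * se, beta + crit * se, float(p)


def ivw_correlated(h: HarmonizedSet, use_t: bool = False) -> MREstimate:
    """Generalized random-effects IVW with an instrument correlation matrix.

    With identity correlation this reduces to the textbook IVW weighted
    average of per-variant ratio estimates. A single instrument reduces to
    the Wald ratio ``bY/bX`` with first-order se ``se_Y/|bX|``.
    """
    k = h.k
    if k == 0:
        raise MRError("no instruments")
    if k == 1:
        bx, by, se_y = float(h.bx[0]), float(h.by[0]), float(h.se_y[0])
        if bx == 0:
            raise MRError("exposure association is exactly zero")
        beta, se = by / bx, se_y / abs(bx)
        lo, hi, p = _interval(beta, se, None)
        return MREstimate("wald_ratio", beta, se, lo, hi, p, 1)
    omega = _omega(h)
    oinv_bx = _solve_spd(omega, h.bx)
    denom = float(h.bx @ oinv_bx)
    if denom <= 0:
        raise MRError("ill-conditioned weight matrix")
    beta = float(h.bx @ _solve_spd(omega, h.by)) / denom
    resid = h.by - beta * h.bx
    q = float(resid @ _solve_spd(omega, resid))
    q = max(q, 0.0)
    phi = max(1.0, q / (k - 1))
    se = float(np.sqrt(phi / denom))
    q_pval = float(stats.chi2.sf(q, k - 1))
    lo, hi, p = _interval(beta, se, k - 1 if use_t else None)
    return MREstimate("ivw", beta, se, lo, hi, p, k, q, q_pval, phi)


def mr_egger_correlated(
    h: HarmonizedSet, use_t: bool = False
) -> tuple[MREstimate, MREstimate]:
    """Generalized MR-Egger regression: slope estimate and pleiotropy intercept.

    Variants are oriented so every exposure association is non-negative
    (flipping the outcome association jointly), then ``bY`` is regressed on
    ``[1, bX]`` with weight matrix ``Omega^{-1}``. A non-zero intercept is
    evidence of directional pleiotropy.
    """
    k = h.k
    if k < 3:
        raise MRError("insufficient instruments for Egger (k >= 3 required)")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx = h.bx * sign
    by = h.by * sign
    rho = sign[:, None] * h.ld.rho * sign[None, :]
    omega = np.outer(h.se_y, h.se_y) * rho
    X = np.column_stack([np.ones(k), bx])
    oinv_X = _solve_spd(omega, X)
    xtx = X.T @ oinv_X
    coef = np.linalg.solve(xtx, oinv_X.T @ by)
    resid = by - X @ coef
    q = max(float(resid @ _solve_spd(omega, resid)), 0.0)
    phi = max(1.0, q / (k - 2))
    cov = phi * np.linalg.inv(xtx)
    df = k - 2 if use_t else None
    se_slope = float(np.sqrt(cov[1, 1]))
    lo_s, hi_s, p_s = _interval(float(coef[1]), se_slope, df)
    slope = MREstimate(
        "egger_slope", float(coef[1]), se_slope, lo_s, hi_s, p_s, k,
        q, float(stats.chi2.sf(q, k - 2)), phi,
    )
    se_int = float(np.sqrt(cov[0, 0]))
    lo_i, hi_i, p_i = _interval(float(coef[0]), se_int, df)
    intercept = MREstimate(
        "egger_intercept", float(coef[0]), se_int, lo_i, hi_i, p_i, k,
        q, float(stats.chi2.sf(q, k - 2)), phi,
    )
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / weights.sum()
    breakpoints = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, breakpoints, th))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median MR estimate (valid if >=50% of weight is on valid SNPs).

    Requires independent instruments: any non-identity correlation matrix is
    replaced by the identity with a warning. Per-variant ratio estimates
    ``theta_j = bY_j/bX_j`` carry weights proportional to ``bX_j²/se_Y_j²``;
    the estimate interpolates the weighted empirical quantile function at
    0.5. The standard error comes from a seeded parametric bootstrap.
    """
    if h.k < 3:
        raise MRError("insufficient instruments for weighted median (k >= 3)")
    if not np.allclose(h.ld.rho, np.eye(h.k)):
        import logging
        logging.getLogger(__name__).warning(
            "weighted median assumes independent instruments; "
            "forcing identity correlation"
        )
        h = h.with_identity_ld()
    theta = h.by / h.bx
    weights = (h.bx / h.se_y) ** 2
    beta = _weighted_median_point(theta, weights)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(h.bx, h.se_x)
        by_b = rng.normal(h.by, h.se_y)
        boot[b] = _weighted_median_point(by_b / bx_b, (bx_b / h.se_y) ** 2)
    se = float(boot.std(ddof=1))
    lo, hi, p = _interval(beta, se, None)
    return MREstimate("weighted_median", beta, se, lo, hi, p, h.k)


def cochrans_q(h: HarmonizedSet, beta_hat: float) -> tuple[float, float] | None:
    """Heterogeneity Q around a fitted slope, with chi-square (k-1) p-value.

    Returns None (with a warning) for k < 2, where Q is undefined.
    """
    if h.k < 2:
        import logging
        logging.getLogger(__name__).warning("Cochran's Q undefined for k < 2")
        return None
    resid = h.by - beta_hat * h.bx
    q = max(float(resid @ _solve_spd(_omega(h), resid)), 0.0)
    return q, float(stats.chi2.sf(q, h.k - 1))


def leave_one_out(h: HarmonizedSet, use_t: bool = False) -> list[MREstimate]:
    """IVW re-estimated with each instrument removed in turn (input order)."""
    if h.k < 2:
        raise MRError("leave-one-out requires k >= 2")
    return [ivw_correlated(h.drop_variant(v), use_t) for v in h.variant_ids]


def bonferroni_adjust(
    pvals: Sequence[float], m: int
) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, m*p); m tests per family."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in pvals:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value outside (0,1]: {p}")
        out.append(min(1.0, m * p))
    return out


# ---------------------------------------------------------------------------
# Model / Results front-end


class MRModel:
    """Mendelian-randomization model over a harmonized exposure/outcome set.

    Parameters
    ----------
    harmonized
        Aligned per-variant exposure and outcome associations plus the
        instrument correlation matrix.
    correlated
        If False the correlation matrix is replaced by the identity, i.e. the
        instruments are treated as independent (appropriate after clumping at
        a stringent r² threshold).
    use_t
        Use a t reference distribution (k-1 / k-2 df) instead of normal for
        confidence intervals and p-values.
    """

    def __init__(
        self,
        harmonized: HarmonizedSet,
        correlated: bool = True,
        use_t: bool = False,
    ):
        self.h = harmonized if correlated else harmonized.with_identity_ld()
        self.correlated = correlated
        self.use_t = use_t

    @classmethod
    def from_tables(
        cls,
        exposure_path,
        outcome_path,
        ld_path=None,
        palindrome_eaf_window: float = 0.08,
        **kwargs,
    ) -> "MRModel":
        """Build a model from summary-statistic files (and optional LD file)."""
        from cismr.sumstats import harmonize, read_ld_matrix, read_sumstats

        exposure = read_sumstats(exposure_path, "exposure")
        outcome = read_sumstats(outcome_path, "outcome")
        ld = read_ld_matrix(ld_path) if ld_path is not None else None
        h = harmonize(exposure, outcome, ld, palindrome_eaf_window)
        return cls(h, **kwargs)

    def fit(
        self,
        methods: Sequence[str] = ("ivw", "egger"),
        n_boot: int = 1000,
        seed: int = 0,
    ) -> "MRResults":
        """Run the requested estimators and return a results container.

        Recognized methods: ``ivw`` (Wald ratio at k=1), ``egger``
        (slope + intercept, k>=3), ``weighted_median`` (k>=3, independent
        instruments).
        """
        estimates: dict[str, MREstimate] = {}
        errors: dict[str, str] = {}
        for m in methods:
            try:
                if m == "ivw":
                    estimates["ivw"] = ivw_correlated(self.h, self.use_t)
                elif m == "egger":
                    slope, intercept = mr_egger_correlated(self.h, self.use_t)
                    estimates["egger_slope"] = slope
                    estimates["egger_intercept"] = intercept
                elif m == "weighted_median":
                    estimates["weighted_median"] = weighted_median(
                        self.h, n_boot=n_boot, seed=seed
                    )
                else:
                    raise ValueError(f"unknown method {m!r}")
            except MRError as exc:
                errors[m] = str(exc)
        return MRResults(self, estimates, errors)


@dataclass
class MRResults:
    """Fitted MR estimates with heterogeneity diagnostics and a summary table."""

    model: MRModel
    estimates: dict[str, MREstimate]
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ivw(self) -> MREstimate | None:
        return self.estimates.get("ivw")

    @property
    def egger_slope(self) -> MREstimate | None:
        return self.estimates.get("egger_slope")

    @property
    def egger_intercept(self) -> MREstimate | None:
        return self.estimates.get("egger_intercept")

    @property
    def q_stat(self) -> float:
        return self.ivw.q_stat if self.ivw is not None else float("nan")

    @property
    def q_pval(self) -> float:
        return self.ivw.q_pval if self.ivw is not None else float("nan")

    def leave_one_out(self) -> pd.DataFrame:
        """Leave-one-out IVW table (one row per excluded variant)."""
        loo = leave_one_out(self.model.h, self.model.use_t)
        rows = []
        for vid, est in zip(self.model.h.variant_ids, loo):
            d = est.to_dict()
            d["excluded_variant"] = vid
            rows.append(d)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.estimates.values()])

    def summary(self) -> str:
        """Human-readable summary of all fitted estimates."""
        lines = [
            "MR results (log hazard ratio per 1 SD exposure)",
            f"  instruments: k = {self.model.h.k}"
            f" ({'correlated' if self.model.correlated else 'independent'})",
            f"  {'method':<18}{'HR (95% CI)':<24}{'beta':>9}{'se':>9}{'p':>11}",
        ]
        for est in self.estimates.values():
            lines.append(
                f"  {est.method:<18}{est.format_hr():<24}"
                f"{est.beta:>9.4f}{est.se:>9.4f}{est.pval:>11.3g}"
            )
        for m, msg in self.errors.items():
            lines.append(f"  {m:<18}not estimated: {msg}")
        if self.ivw is not None and self.model.h.k >= 2:
            lines.append(
                f"  Cochran's Q = {self.q_stat:.3f} "
                f"(df={self.model.h.k - 1}, p = {self.q_pval:.3g}), "
                f"phi = {self.ivw.phi:.3f}"
            )
        return "\n".join(lines)
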