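"""Case-only collider-bias simulation for survival MR.

Restricting a survival analysis to disease cases conditions on a collider:
if a genetically instrumented exposure and a confounder (here BMI, plus age)
both raise disease incidence, genotype and confounder become negatively
correlated among cases even though they are independent in the population.
The simulation quantifies how much bias this selection alone induces in a
two-SNP MR of the exposure on case mortality when the true exposure effect
on mortality is exactly zero.

Per replicate: (1) a large population carries genotypes at two
nearly-independent exposure-associated SNPs; (2) BMI and age are drawn
independently of genotype; (3) disease incidence follows a proportional
hazards model (constant baseline hazard) in exposure, BMI and age; (4) only
cases are retained; (5) case mortality follows an exponential proportional
hazards model in BMI and age only; (6) a two-sample-style MR is run among
cases (per-SNP outcome associations from a univariate Cox fit of death on
genotype, exposure associations fixed at the true per-allele effects,
generalized IVW with the realized genotype correlation), and each SNP is
tested for a spurious association with BMI. Aggregates over replicates give
bias, type-I error, CI coverage, and spurious-association rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from cismr.mr import MREstimate, ivw_correlated
from cismr.sumstats import HarmonizedSet, LDMatrix


@dataclass
class SimConfig:
    """Parameters of the collider simulation (all hazards per year).

    Defaults give a population cumulative disease incidence of ~4% over the
    ``tau``-year horizon and a case fatality of ~24% over ``tau_mort`` years,
    with two exposure SNPs jointly explaining ~2.5% of the (unit-variance)
    exposure. The true exposure effect on mortality is zero by construction.
    """

    n_pop: int = 500_000
    n_reps: int = 1000
    snp_mafs: tuple[float, ...] = (0.3, 0.25)
    snp_r2: float = 0.001
    gamma_tnf: tuple[float, ...] = (0.2, 0.15)  # per-allele, SD units
    beta_inc_tnf: float = float(np.log(1.2))   # per SD exposure
    beta_inc_bmi: float = float(np.log(1.03))  # per BMI unit
    beta_inc_age: float = float(np.log(1.05))  # per year
    lambda0_inc: float = 0.004
    tau: float = 10.0
    beta_mort_bmi: float = float(np.log(1.02))
    beta_mort_age: float = float(np.log(1.03))
    lambda0_mort: float = 0.027
    tau_mort: float = 10.0
    bmi_mean: float = 27.2
    bmi_sd: float = 4.6
    age_mean: float = 64.0
    age_sd: float = 9.0
    alpha: float = 0.05
    seed: int = 0
    outcome_model: str = "cox"  # or "logistic"
    # With k=2 the heterogeneity statistic has a single degree of freedom and
    # a multiplicative random-effects correction is too noisy to calibrate;
    # fixed-effect IVW is the standard for very small panels and is the
    # estimator whose selection-bias behaviour the study examines.
    ivw_random_effects: bool = False
    min_cases: int = 50

    def __post_init__(self) -> None:
        if self.n_pop < 1 or self.n_reps < 1:
            raise ValueError("n_pop and n_reps must be >= 1")
        if len(self.snp_mafs) != len(self.gamma_tnf):
            raise ValueError("one effect per SNP required")
        if any(not 0 < m < 1 for m in self.snp_mafs):
            raise ValueError("MAFs must lie in (0,1)")
        for lam in (self.lambda0_inc, self.lambda0_mort):
            if lam <= 0:
                raise ValueError("baseline hazards must be > 0")
        if self.outcome_model not in ("cox", "logistic"):
            raise ValueError("outcome_model must be 'cox' or 'logistic'")


@dataclass
class SimResult:
    """Per-replicate MR outputs and aggregate performance metrics."""

    replicates: pd.DataFrame
    mean_bias: float
    empirical_type1_error: float
    ci_coverage: float
    mean_spurious: float
    frac_reps_with_any_spurious: float
    max_spurious: int
    n_failed: int
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            "Collider-bias simulation "
            f"({len(self.replicates)} replicates, {self.n_failed} failed)\n"
            f"  mean bias of MR estimate (true effect 0): {self.mean_bias:+.4f}"
            f"  (HR ~= {np.exp(self.mean_bias):.3f})\n"
            f"  empirical type-I error at alpha="
            f"{self.config.get('alpha', 0.05)}: "
            f"{100 * self.empirical_type1_error:.1f}%\n"
            f"  95% CI coverage of zero: {100 * self.ci_coverage:.1f}%\n"
            f"  spurious SNP-BMI associations per replicate: "
            f"mean {self.mean_spurious:.3f}, max {self.max_spurious}; "
            f">=1 in {100 * self.frac_reps_with_any_spurious:.1f}% of replicates"
        )


# ---------------------------------------------------------------------------
# Population and event generation


def _correlated_genotypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Genotypes at the SNPs with pairwise squared correlation ~= snp_r2.

    Two SNPs are generated from shared haplotypes whose alleles carry
    correlation sqrt(snp_r2) (summing two independent haplotypes preserves
    the allelic correlation at the genotype level). More than two SNPs are
    generated independently, which requires snp_r2 = 0.
    """
    mafs = np.asarray(cfg.snp_mafs)
    if len(mafs) != 2:
        if cfg.snp_r2 > 0:
            raise ValueError("correlated genotypes implemented for 2 SNPs only")
        return rng.binomial(2, mafs, size=(cfg.n_pop, len(mafs))).astype(float)
    m1, m2 = mafs
    r = np.sqrt(cfg.snp_r2)
    p11 = m1 * m2 + r * np.sqrt(m1 * (1 - m1) * m2 * (1 - m2))
    p10, p01 = m1 - p11, m2 - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p00, p01, p10, p11])
    if np.any(probs < 0):
        raise ValueError(f"infeasible snp_r2={cfg.snp_r2} for MAFs {cfg.snp_mafs}")
    # Each haplotype is one of 4 joint allele states; genotype = sum of two.
    cum = np.cumsum(probs)
    hap = np.searchsorted(cum, rng.random((cfg.n_pop, 2)))
    a1 = (hap >= 2).sum(axis=1)  # allele at SNP 1
    a2 = (hap % 2).sum(axis=1)   # allele at SNP 2
    return np.column_stack([a1, a2]).astype(float)


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Normal draws with out-of-bounds values redrawn (bounds are far tails)."""
    x = rng.normal(mean, sd, n)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def simulate_population(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Genotypes, exposure, and confounders for one synthetic population.

    The exposure (TNF) is the genetic score plus independent noise, scaled to
    unit variance. BMI and age are truncated normals ([15, 60] and [18, 100])
    independent of genotype — the independence that case selection later
    breaks.
    """
    g = _correlated_genotypes(cfg, rng)
    mafs = np.asarray(cfg.snp_mafs)
    gamma = np.asarray(cfg.gamma_tnf)
    centered = g - 2 * mafs
    var_g = float(np.sum(gamma**2 * 2 * mafs * (1 - mafs)))
    if len(mafs) == 2 and cfg.snp_r2 > 0:
        cov12 = np.sqrt(cfg.snp_r2) * np.sqrt(
            2 * mafs[0] * (1 - mafs[0]) * 2 * mafs[1] * (1 - mafs[1])
        )
        var_g += 2 * gamma[0] * gamma[1] * cov12
    if var_g >= 1.0:
        raise ValueError("genetic variance of exposure exceeds 1 SD^2")
    tnf = centered @ gamma + rng.normal(0.0, np.sqrt(1.0 - var_g), cfg.n_pop)
    bmi = _truncated_normal(cfg.bmi_mean, cfg.bmi_sd, 15, 60, cfg.n_pop, rng)
    age = _truncated_normal(cfg.age_mean, cfg.age_sd, 18, 100, cfg.n_pop, rng)
    pop = {f"g{j}": g[:, j] for j in range(g.shape[1])}
    pop.update({"tnf": tnf, "bmi": bmi, "age": age})
    return pd.DataFrame(pop)


def simulate_incidence(
    pop: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disease onset under a proportional-hazards model with constant baseline.

    Event time is drawn by inverse transform, ``T = -log(U) / (lambda0 *
    exp(lp))``; an individual is a case if onset occurs within ``tau`` years.
    Returns (case indicator, onset time).
    """
    lp = (
        cfg.beta_inc_tnf * pop["tnf"].to_numpy()
        + cfg.beta_inc_bmi * (pop["bmi"].to_numpy() - cfg.bmi_mean)
        + cfg.beta_inc_age * (pop["age"].to_numpy() - cfg.age_mean)
    )
    u = rng.uniform(size=len(pop))
    t = -np.log(u) / (cfg.lambda0_inc * np.exp(lp))
    return (t <= cfg.tau), t


def simulate_mortality(
    cases: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Death among cases under an exponential PH model in BMI and age only.

    Neither the exposure nor the genotypes enter the mortality model: the
    true causal effect is null by construction. Returns (death indicator
    within ``tau_mort``, observed time censored at ``tau_mort``).
    """
    if len(cases) == 0:
        raise ValueError("no cases generated")
    rate = cfg.lambda0_mort * np.exp(
        cfg.beta_mort_bmi * (cases["bmi"].to_numpy() - cfg.bmi_mean)
        + cfg.beta_mort_age * (cases["age"].to_numpy() - cfg.age_mean)
    )
    t = rng.exponential(1.0 / rate)
    death = t <= cfg.tau_mort
    return death, np.minimum(t, cfg.tau_mort)


# ---------------------------------------------------------------------------
# Case-only analysis


def _cox_univariate(
    x: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 25, tol: float = 1e-8,
) -> tuple[float, float]:
    """Newton solver for a one-covariate Cox partial likelihood (Breslow).

    Simulated event times are continuous, so ties are not a concern. Returns
    (log hazard ratio, standard error).
    """
    order = np.argsort(time)
    x = x[order].astype(float)
    event = event[order]
    if event.sum() == 0 or np.ptp(x) == 0:
        raise ValueError("degenerate Cox fit (no events or constant covariate)")
    beta = 0.0
    for _ in range(max_iter):
        ebx = np.exp(beta * x)
        # Risk set at each ordered time = suffix sums.
        s0 = np.cumsum(ebx[::-1])[::-1]
        s1 = np.cumsum((x * ebx)[::-1])[::-1]
        s2 = np.cumsum((x * x * ebx)[::-1])[::-1]
        mu = s1 / s0
        score = float((x[event] - mu[event]).sum())
        info = float((s2[event] / s0[event] - mu[event] ** 2).sum())
        if info <= 0:
            raise ValueError("non-positive Cox information")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    else:
        raise ValueError("Cox fit did not converge")
    return beta, 1.0 / np.sqrt(info)


def _logistic_univariate(
    x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[float, float]:
    """Newton solver for logistic regression of y on [1, x]; returns slope, se."""
    if y.sum() in (0, len(y)) or np.ptp(x) == 0:
        raise ValueError("degenerate logistic fit")
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    b = np.zeros(2)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-X @ b))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        b += step
        if np.abs(step).max() < tol:
            break
    else:
        raise ValueError("logistic fit did not converge")
    cov = np.linalg.inv(hess)
    return float(b[1]), float(np.sqrt(cov[1, 1]))


def _ols_pval(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value for the slope of y ~ x (simple linear regression)."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return 1.0
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return float(2 * stats.t.sf(abs(slope / se), n - 2))


def run_mr_on_cases(
    cases: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> dict:
    """MR of the exposure on case mortality, plus spurious SNP-BMI tests.

    Per-SNP outcome associations come from a univariate Cox (or logistic)
    model of death among cases; exposure associations are the true per-allele
    effects (two-sample design); the IVW uses the genotype correlation
    realized in the case sample. ``spurious_count`` counts SNPs whose linear
    regression against BMI among cases has p < alpha.
    """
    n_snps = len(cfg.snp_mafs)
    g = cases[[f"g{j}" for j in range(n_snps)]].to_numpy()
    death = cases["death"].to_numpy(bool)
    time = cases["death_time"].to_numpy(float)
    by = np.empty(n_snps)
    se_y = np.empty(n_snps)
    for j in range(n_snps):
        if cfg.outcome_model == "cox":
            by[j], se_y[j] = _cox_univariate(g[:, j], time, death)
        else:
            by[j], se_y[j] = _logistic_univariate(g[:, j], death.astype(float))
    rho = np.corrcoef(g, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    ld = LDMatrix([f"g{j}" for j in range(n_snps)], rho)
    h = HarmonizedSet.from_arrays(
        ld.variant_ids, np.asarray(cfg.gamma_tnf), np.zeros(n_snps),
        by, se_y, ld,
    )
    est = ivw_correlated(h)
    if not cfg.ivw_random_effects and est.phi > 1.0:
        se = est.se / np.sqrt(est.phi)
        z = est.beta / se
        est = MREstimate(
            "ivw_fixed", est.beta, se,
            est.beta - 1.959963984540054 * se,
            est.beta + 1.959963984540054 * se,
            float(2 * stats.norm.sf(abs(z))), est.k_snps,
            est.q_stat, est.q_pval, 1.0,
        )
    bmi = cases["bmi"].to_numpy(float)
    spurious = sum(_ols_pval(g[:, j], bmi) < cfg.alpha for j in range(n_snps))
    return {
        "mr_beta": est.beta,
        "mr_se": est.se,
        "mr_pval": est.pval,
        "ci_covers_zero": bool(est.ci_low <= 0.0 <= est.ci_high),
        "n_cases": len(cases),
        "n_deaths": int(death.sum()),
        "n_spurious_snps": int(spurious),
    }


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Counter-based child stream: stable per replicate as n_reps changes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def run_one_replicate(cfg: SimConfig, rep: int) -> dict:
    rng = _replicate_rng(cfg.seed, rep)
    pop = simulate_population(cfg, rng)
    is_case, _ = simulate_incidence(pop, cfg, rng)
    cases = pop[is_case].reset_index(drop=True)
    if len(cases) < cfg.min_cases:
        raise ValueError(f"replicate {rep}: only {len(cases)} cases")
    death, dtime = simulate_mortality(cases, cfg, rng)
    cases = cases.assign(death=death, death_time=dtime)
    out = run_mr_on_cases(cases, cfg, rng)
    out["replicate"] = rep
    return out


def run_simulation_study(cfg: SimConfig, progress: bool = False) -> SimResult:
    """Run all replicates and aggregate the performance metrics.

    Aggregates: mean bias of the MR estimate around the true null, empirical
    type-I error (p < alpha), 95% CI coverage of zero, and the distribution
    of spurious SNP-BMI association counts. More than 5% failed replicates
    aborts with an error.
    """
    rows = []
    n_failed = 0
    iterator = range(cfg.n_reps)
    if progress:
        import logging
        log = logging.getLogger(__name__)
    for rep in iterator:
        try:
            rows.append(run_one_replicate(cfg, rep))
        except ValueError as exc:
            n_failed += 1
            import logging
            logging.getLogger(__name__).warning("replicate %d failed: %s", rep, exc)
        if progress and (rep + 1) % 100 == 0:
            log.info("completed %d/%d replicates", rep + 1, cfg.n_reps)
    if n_failed > 0.05 * cfg.n_reps:
        raise RuntimeError(
            f"unstable configuration: {n_failed}/{cfg.n_reps} replicates failed"
        )
    reps = pd.DataFrame(rows)
    spurious = reps["n_spurious_snps"]
    return SimResult(
        replicates=reps,
        mean_bias=float(reps["mr_beta"].mean()),
        empirical_type1_error=float((reps["mr_pval"] < cfg.alpha).mean()),
        ci_coverage=float(reps["ci_covers_zero"].mean()),
        mean_spurious=float(spurious.mean()),
        frac_reps_with_any_spurious=float((spurious >= 1).mean()),
        max_spurious=int(spurious.max()),
        n_failed=n_failed,
        config=asdict(cfg),
    )
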