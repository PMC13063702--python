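"""Synthetic GWAS summary statistics with known ground truth.

Exposure (pQTL) and outcome (survival) summary tables are generated directly
from their asymptotic sampling distributions rather than from individual
-level data: for a standardized exposure measured in ``n`` individuals, the
per-allele standard error is ``1/sqrt(2 n p (1-p))`` and the estimated
marginal effects are jointly normal around the LD-propagated true effects
with correlation equal to the LD matrix. Outcome log hazard ratios follow
the same construction with the event count in place of the sample size. This
matches the assumptions of two-sample summary MR exactly and makes every
pipeline stage testable without any external download; individual-level
generation lives only in :mod:`cismr.collider`, where selection must act on
individuals.

Truth records store the *joint* (conditional) effects on the standardized
-genotype scale; emitted summaries are *marginal* (LD-propagated), matching
real GWAS output.

Scenario presets mirror published instrument-set characteristics (counts,
explained variance, sample and event counts) so tests can be phrased against
named configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from cismr.sumstats import LDMatrix, VariantAssociation

_TINY_P = 5e-324  # smallest positive subnormal; keeps pval in (0,1]

#: Non-palindromic allele pairs cycled across generated variants.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class ScenarioSpec:
    """Configuration of one synthetic exposure/outcome scenario.

    ``ld_blocks`` is a list of ``(size, within_block_rho)`` pairs summing to
    the variant count. ``gamma`` (joint effects on the standardized-genotype
    scale) may be given directly; otherwise equal effects are solved to hit
    ``target_r2``. ``noise_scale=0`` is a test hook that emits the exact
    marginal truth. ``pleiotropy`` optionally injects a direct outcome effect
    ``(variant_index, effect)`` bypassing the exposure.
    """

    k_instruments: int = 13
    mafs: tuple[float, ...] | None = None
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma: tuple[float, ...] | None = None
    target_r2: float = 0.1
    n_exposure: float = 35_559
    n_cases: float = 16_964
    n_events: float = 4_010
    theta: float = 0.0  # true causal log-HR per SD exposure
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    pleiotropy: tuple[int, float] | None = None
    region_size_variants: int = 200
    noise_scale: float = 1.0
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 154_000_000
    pos_step: int = 5_000

    def __post_init__(self) -> None:
        if self.n_events > self.n_cases:
            raise ValueError("n_events cannot exceed n_cases")
        if self.mafs is not None and len(self.mafs) != self.k_instruments:
            raise ValueError("one MAF per instrument required")


#: Named presets mirroring published instrument-set characteristics.
SCENARIOS: dict[str, dict] = {
    # 13 independent instruments (stringent clumping), R^2 = 49%, pQTL GWAS
    # n = 35,559; outcome 16,964 cases with 4010 events; weak positive truth.
    "sIL6RA_decode": dict(
        k_instruments=13, target_r2=0.49, n_exposure=35_559,
        n_cases=16_964, n_events=4_010, theta=0.058,
        ld_blocks=tuple((1, 0.0) for _ in range(13)),
    ),
    "sIL6RA_ukbb": dict(
        k_instruments=11, target_r2=0.25, n_exposure=46_861,
        n_cases=16_964, n_events=4_010, theta=0.086,
        ld_blocks=tuple((1, 0.0) for _ in range(11)),
    ),
    # Correlated panels (relaxed r^2 < 0.1 clumping) in LD blocks.
    "IL6ST_decode": dict(
        k_instruments=19, target_r2=0.069, n_exposure=35_559,
        n_cases=16_964, n_events=4_010, theta=0.0,
        ld_blocks=((5, 0.25), (5, 0.25), (5, 0.25), (4, 0.25)),
    ),
    "IL6ST_ukbb": dict(
        k_instruments=9, target_r2=0.033, n_exposure=46_861,
        n_cases=16_964, n_events=4_010, theta=0.0,
        ld_blocks=((5, 0.25), (4, 0.25)),
    ),
    "TNFa_ukbb": dict(
        k_instruments=9, target_r2=0.026, n_exposure=46_861,
        n_cases=16_964, n_events=4_010, theta=0.0,
        ld_blocks=((5, 0.25), (4, 0.25)),
    ),
}


def scenario(name: str, **overrides) -> ScenarioSpec:
    """Instantiate a named preset, optionally overriding any field."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return ScenarioSpec(**params)


def generate_ld_matrix(spec: ScenarioSpec) -> LDMatrix:
    """Block-diagonal correlation matrix from the spec's block structure.

    Each block is compound-symmetric (constant within-block correlation),
    positive semi-definite by construction for rho in (-1/(s-1), 1).
    """
    blocks = spec.ld_blocks or ((spec.k_instruments, 0.0),)
    sizes = [s for s, _ in blocks]
    if sum(sizes) != spec.k_instruments:
        raise ValueError("block sizes must sum to the instrument count")
    mats = []
    for s, rho in blocks:
        if abs(rho) >= 1:
            raise ValueError("within-block |rho| must be < 1")
        if s > 1 and rho <= -1.0 / (s - 1):
            raise ValueError("compound-symmetric block would not be PSD")
        mats.append(np.full((s, s), rho) + (1 - rho) * np.eye(s))
    rho_full = np.zeros((spec.k_instruments, spec.k_instruments))
    off = 0
    for m in mats:
        s = m.shape[0]
        rho_full[off:off + s, off:off + s] = m
        off += s
    ids = [f"rs{1000 + j}" for j in range(spec.k_instruments)]
    return LDMatrix(ids, rho_full)


def _resolve_mafs(spec: ScenarioSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    if spec.mafs is not None:
        return np.asarray(spec.mafs, float)
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, size=k)


def _joint_gamma(spec: ScenarioSpec, rho: np.ndarray) -> np.ndarray:
    """Joint standardized-genotype effects; equal sizes solved for target R²."""
    if spec.gamma is not None:
        return np.asarray(spec.gamma, float)
    total = float(np.ones(len(rho)) @ rho @ np.ones(len(rho)))
    c = np.sqrt(spec.target_r2 / total)
    return np.full(len(rho), c)


def _records(
    ids, chrom, positions, alleles, eaf, beta, se, n, n_events=None
) -> list[VariantAssociation]:
    out = []
    z = beta / se
    pvals = np.maximum(2 * stats.norm.sf(np.abs(z)), _TINY_P)
    for j, vid in enumerate(ids):
        ea, oa = alleles[j]
        out.append(VariantAssociation(
            variant_id=vid, chrom=chrom, pos=int(positions[j]),
            effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
            beta=float(beta[j]), se=float(se[j]), pval=float(pvals[j]),
            n=float(n), n_events=n_events,
        ))
    return out


def generate_exposure_gwas(
    spec: ScenarioSpec,
) -> tuple[list[VariantAssociation], LDMatrix, dict]:
    """Exposure pQTL summary statistics, LD matrix, and the truth record.

    Marginal true effects on the standardized-genotype scale are
    ``rho @ gamma``; estimates add correlated noise ``(noise_scale/sqrt(n)) *
    chol(rho) z``. Per-allele effects and SEs divide by
    ``sqrt(2 p (1-p))``.
    """
    rng = np.random.default_rng(spec.seed)
    ld = generate_ld_matrix(spec)
    k = spec.k_instruments
    mafs = _resolve_mafs(spec, k, rng)
    gamma = _joint_gamma(spec, ld.rho)
    marginal_std = ld.rho @ gamma
    scale = np.sqrt(2 * mafs * (1 - mafs))
    noise = np.zeros(k)
    if spec.noise_scale > 0:
        chol = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(k))
        noise = spec.noise_scale * (chol @ rng.standard_normal(k)) / np.sqrt(
            spec.n_exposure
        )
    beta_std_hat = marginal_std + noise
    beta = beta_std_hat / scale
    se = 1.0 / (np.sqrt(spec.n_exposure) * scale)
    positions = spec.pos_start + spec.pos_step * np.arange(k)
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]
    records = _records(
        ld.variant_ids, spec.chrom, positions, alleles, mafs, beta, se,
        spec.n_exposure,
    )
    truth = {
        "gamma_std": gamma, "marginal_std": marginal_std, "mafs": mafs,
        "r2": float(gamma @ ld.rho @ gamma), "alleles": alleles,
        "positions": positions, "variant_ids": ld.variant_ids,
    }
    return records, ld, truth


def generate_outcome_gwas(
    exposure_truth: dict, spec: ScenarioSpec
) -> list[VariantAssociation]:
    """Outcome (survival) summary statistics under a true causal effect theta.

    True per-variant marginal log-HRs are ``theta *`` the marginal exposure
    effects, plus any injected direct (pleiotropic) effect LD-propagated from
    its variant. SEs use the event count: ``1/sqrt(2 n_events p (1-p))``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ld = generate_ld_matrix(spec)
    k = spec.k_instruments
    mafs = exposure_truth["mafs"]
    marginal_std = spec.theta * exposure_truth["marginal_std"].copy()
    if spec.pleiotropy is not None:
        idx, effect = spec.pleiotropy
        marginal_std = marginal_std + ld.rho[:, idx] * effect
    scale = np.sqrt(2 * mafs * (1 - mafs))
    se = 1.0 / (np.sqrt(spec.n_events) * scale)
    noise = np.zeros(k)
    if spec.noise_scale > 0:
        chol = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(k))
        noise = spec.noise_scale * (chol @ rng.standard_normal(k)) / np.sqrt(
            spec.n_events
        )
    beta = (marginal_std + noise) / scale
    positions = exposure_truth["positions"]
    alleles = exposure_truth["alleles"]
    return _records(
        exposure_truth["variant_ids"], spec.chrom, positions, alleles, mafs,
        beta, se, spec.n_cases, n_events=spec.n_events,
    )


def generate_coloc_region(
    spec: ScenarioSpec, shared: bool = True, mode: str | None = None
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Full cis-region summary statistics for two traits, for colocalization.

    ``mode`` overrides the boolean: ``shared`` (one causal variant drives both
    traits), ``distinct`` (different causal variants), ``trait1_only``
    (trait 2 null), or ``null`` (both null). Regions are built from
    compound-symmetric LD blocks of 20 variants (rho = 0.6).
    """
    if spec.region_size_variants < 50:
        raise ValueError("coloc regions need at least 50 variants")
    mode = mode or ("shared" if shared else "trait1_only")
    if mode not in ("shared", "distinct", "trait1_only", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    m = spec.region_size_variants
    block = 20
    sizes = [block] * (m // block) + ([m % block] if m % block else [])
    region_spec = replace(
        spec, k_instruments=m, mafs=None,
        ld_blocks=tuple((s, 0.6) for s in sizes),
    )
    rng = np.random.default_rng(spec.seed)
    ld = generate_ld_matrix(region_spec)
    mafs = _resolve_mafs(region_spec, m, rng)
    scale = np.sqrt(2 * mafs * (1 - mafs))
    c1 = m // 2            # causal variant for trait 1
    c2 = m // 4            # distinct causal variant for trait 2
    # Effect sizes giving clear single-variant signals (z ~ 8-12).
    gamma1 = np.zeros(m)
    gamma2 = np.zeros(m)
    if mode != "null":
        gamma1[c1] = 10.0 / np.sqrt(spec.n_exposure)
    if mode == "shared":
        gamma2[c1] = 10.0 / np.sqrt(spec.n_events)
    elif mode == "distinct":
        gamma2[c2] = 10.0 / np.sqrt(spec.n_events)

    chol = np.linalg.cholesky(ld.rho + 1e-10 * np.eye(m))
    positions = spec.pos_start + spec.pos_step * np.arange(m)
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    tables = []
    for gamma, n, tag in (
        (gamma1, spec.n_exposure, 0), (gamma2, spec.n_events, 1)
    ):
        marginal = ld.rho @ gamma
        noise = np.zeros(m)
        if spec.noise_scale > 0:
            noise = spec.noise_scale * (chol @ rng.standard_normal(m)) / np.sqrt(n)
        beta = (marginal + noise) / scale
        se = 1.0 / (np.sqrt(n) * scale)
        ids = [f"rs{1000 + j}" for j in range(m)]
        tables.append(_records(ids, spec.chrom, positions, alleles, mafs,
                               beta, se, n))
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures


@dataclass
class WorkedExample:
    """A synthetic stand-in for a published instrument/outcome table pair.

    The original per-variant tables are distributed as journal supplementary
    material and are not bundled; these fixtures are generated with the
    published design values (instrument count, explained variance, GWAS
    sample size, case/event counts) and a configured true hazard ratio, in
    noise-free mode, so the generalized IVW recovers the configured HR
    exactly and the end-to-end file-to-estimate machinery can be exercised
    deterministically. They are synthetic data, not the published tables.
    """

    name: str
    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    ld: LDMatrix
    spec: ScenarioSpec
    true_hr: float


def make_worked_example(name: str, theta: float | None = None) -> WorkedExample:
    """Noise-free fixture for a named scenario preset (synthetic stand-in)."""
    spec = scenario(name, noise_scale=0.0)
    if theta is not None:
        spec = replace(spec, theta=theta)
    exposure, ld, truth = generate_exposure_gwas(spec)
    outcome = generate_outcome_gwas(truth, spec)
    return WorkedExample(name, exposure, outcome, ld, spec,
                         float(np.exp(spec.theta)))


def make_harmonization_example(seed: int = 0):
    """Synthetic 23-instrument panel of which 19 survive harmonization.

    Mimics a correlated cis panel where two instruments are absent from the
    outcome GWAS and two are strand-ambiguous palindromic variants with
    intermediate allele frequency; harmonization drops all four.
    """
    spec = scenario("IL6ST_decode", noise_scale=0.0, seed=seed)
    spec = replace(
        spec, k_instruments=23,
        ld_blocks=((5, 0.25), (5, 0.25), (5, 0.25), (4, 0.25), (4, 0.0)),
    )
    exposure, ld, truth = generate_exposure_gwas(spec)
    outcome = generate_outcome_gwas(truth, spec)
    # Two palindromic ambiguous exposure variants (dropped by harmonization).
    for idx in (19, 20):
        exposure[idx] = replace(exposure[idx], effect_allele="A",
                                other_allele="T", eaf=0.5)
        outcome[idx] = replace(outcome[idx], effect_allele="A",
                               other_allele="T", eaf=0.5)
    # Two variants missing from the outcome table.
    outcome = outcome[:21]
    return exposure, outcome, ld
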