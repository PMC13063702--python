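"""Cis-instrument selection: window filtering, LD clumping, R², F-statistic.

A cis instrument is a variant within a flanking window around the gene
encoding the protein being instrumented. Selection proceeds: restrict to the
window, keep genome-wide-significant variants (p < 5e-8 by default, strict),
greedily clump by LD, compute the explained variance R² and the overall
instrument F-statistic, and reject sets explaining less than a floor
(default 1%) of the trait variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cismr.sumstats import LDMatrix, VariantAssociation

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
LENIENT_P = 1e-6
DEFAULT_FLANK = 500_000
DEFAULT_R2_FLOOR = 0.01


@dataclass(frozen=True)
class GeneLocus:
    """Gene body coordinates (1-based inclusive) plus a cis flank in bp."""

    gene_name: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.gene_name}: flank must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start - self.flank, self.end + self.flank)


@dataclass
class InstrumentSet:
    """A selected instrument panel with its aligned LD matrix and strength metrics."""

    exposure_name: str
    source_tag: str
    variants: list[VariantAssociation]
    ld: LDMatrix
    r2_total: float
    f_stat: float
    n_gwas: float
    excluded: bool = False
    exclusion_reason: str = ""
    r2_adjusted: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.ld.k != len(self.variants):
            raise ValueError("LD dimension does not match instrument count")
        if not (0.0 <= self.r2_total <= 1.0):
            raise ValueError(f"r2_total outside [0,1]: {self.r2_total}")
        if self.f_stat < 0:
            raise ValueError("f_stat must be >= 0")

    @property
    def k(self) -> int:
        return len(self.variants)


def select_cis_variants(
    sumstats: Sequence[VariantAssociation],
    locus: GeneLocus,
    p_threshold: float = GENOME_WIDE_P,
) -> list[VariantAssociation]:
    """Variants inside the cis window with p strictly below the threshold.

    The window is inclusive at both flank boundaries; the significance test
    is strict (``pval < p_threshold``). An empty result logs a warning and
    returns an empty list — some proteins simply have no usable cis signal.
    """
    lo, hi = locus.window
    kept = [
        v for v in sumstats
        if v.chrom == locus.chrom and lo <= v.pos <= hi and v.pval < p_threshold
    ]
    if not kept:
        logger.warning(
            "no cis variants for %s at p<%g in %s:%d-%d",
            locus.gene_name, p_threshold, locus.chrom, lo, hi,
        )
    return kept


def clump(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant variant, discard its proxies.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken by lexicographic variant_id) and removes every remaining variant
    with squared correlation >= ``r2_threshold`` against it. Output preserves
    the selection order's determinism regardless of input row order.
    """
    missing = [v.variant_id for v in variants if v.variant_id not in ld._index]
    if missing:
        raise KeyError(f"variants missing from LD matrix: {missing}")
    remaining = sorted(variants, key=lambda v: (v.pval, v.variant_id))
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        sub = ld.subset([index.variant_id] + [v.variant_id for v in remaining])
        r2 = sub.rho[0, 1:] ** 2
        remaining = [v for v, r in zip(remaining, r2) if r < r2_threshold]
    return kept


def per_variant_r2(v: VariantAssociation) -> float:
    """Trait variance explained by one variant: 2·p·(1−p)·β² (standardized trait)."""
    return 2.0 * v.eaf * (1.0 - v.eaf) * v.beta ** 2


def total_r2(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix | None = None,
    adjusted: bool = False,
) -> float:
    """Total explained variance of an instrument set.

    Default is the naive sum of per-variant R² (common practice, but an
    overstatement when instruments are correlated). With ``adjusted=True``
    and an LD matrix, returns the joint quadratic-form value
    ``b' D ρ⁻¹ D b`` with ``D = diag(sqrt(2 p (1-p)))`` — i.e. the R² of the
    jointly fitted standardized genotypes. Values are capped at 1 with a
    warning.
    """
    if not variants:
        return 0.0
    if adjusted:
        if ld is None:
            raise ValueError("adjusted total R² requires an LD matrix")
        sub = ld.subset([v.variant_id for v in variants])
        s = np.array([np.sqrt(2 * v.eaf * (1 - v.eaf)) for v in variants])
        b = np.array([v.beta for v in variants]) * s  # standardized-genotype scale
        r2 = float(b @ np.linalg.solve(sub.rho, b))
    else:
        r2 = float(sum(per_variant_r2(v) for v in variants))
    if r2 > 1.0:
        logger.warning("total R² %.4f exceeds 1; capping", r2)
        r2 = 1.0
    return r2


def f_statistic(n: float, k: int, r2_total: float) -> float:
    """Overall instrument strength: ((n−k−1)/k) · (R² / (1−R²)).

    ``n`` is the exposure-GWAS sample size, ``k`` the instrument count and
    ``r2_total`` the explained variance; values above 10 conventionally
    indicate adequate strength.
    """
    if not (0.0 < r2_total < 1.0):
        raise ValueError(f"r2_total must lie strictly in (0,1): {r2_total}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    if k < 1:
        raise ValueError("k must be >= 1")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def apply_r2_floor(
    instrument_set: InstrumentSet, floor: float = DEFAULT_R2_FLOOR
) -> InstrumentSet:
    """Mark an instrument set excluded when it explains less than ``floor`` variance.

    The boundary is retained (``r2_total >= floor`` passes). The set is
    returned either way; callers check ``excluded``.
    """
    if instrument_set.r2_total >= floor:
        return instrument_set
    instrument_set.excluded = True
    instrument_set.exclusion_reason = "insufficient_r2"
    return instrument_set


def build_instrument_set(
    exposure_name: str,
    source_tag: str,
    sumstats: Sequence[VariantAssociation],
    ld: LDMatrix,
    locus: GeneLocus,
    p_threshold: float = GENOME_WIDE_P,
    clump_r2: float = 0.001,
    r2_floor: float = DEFAULT_R2_FLOOR,
    n_gwas: float | None = None,
    r2_override: float | None = None,
) -> InstrumentSet | None:
    """Full selection workflow: window + p filter, clumping, R², F, floor.

    ``r2_override`` substitutes a published total R² for the naive sum (the
    per-variant formula assumes a standardized exposure and the naive sum
    overstates R² for correlated panels). Returns None when no variant
    survives selection.
    """
    cis = select_cis_variants(sumstats, locus, p_threshold)
    if not cis:
        return None
    chosen = clump(cis, ld, clump_r2)
    sub_ld = ld.subset([v.variant_id for v in chosen])
    r2 = r2_override if r2_override is not None else total_r2(chosen)
    r2_adj = total_r2(chosen, sub_ld, adjusted=True) if r2_override is None else None
    n = n_gwas if n_gwas is not None else max(v.n for v in chosen)
    f = f_statistic(n, len(chosen), r2) if 0 < r2 < 1 else 0.0
    iset = InstrumentSet(
        exposure_name=exposure_name, source_tag=source_tag, variants=chosen,
        ld=sub_ld, r2_total=r2, f_stat=f, n_gwas=n, r2_adjusted=r2_adj,
    )
    return apply_r2_floor(iset, r2_floor)
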