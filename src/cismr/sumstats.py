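"""GWAS summary-statistic data model, I/O, and exposure/outcome harmonization.

Summary tables are tab-separated UTF-8 text with a header row. The canonical
columns are ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pval, n`` (outcome tables additionally carry ``n_events``); common
synonyms from public GWAS releases are resolved via :data:`COLUMN_SYNONYMS`.
LD matrices are tab-separated square tables whose first row and first column
hold the variant identifiers, with pairwise genotype correlations signed
relative to each variant's effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Accepted header synonyms, mapped to canonical column names.
COLUMN_SYNONYMS: dict[str, str] = {
    "snp": "variant_id", "rsid": "variant_id", "rs_id": "variant_id",
    "id": "variant_id", "markername": "variant_id",
    "chr": "chrom", "chromosome": "chrom",
    "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "a1": "effect_allele", "ea": "effect_allele", "alt": "effect_allele",
    "a2": "other_allele", "oa": "other_allele", "nea": "other_allele",
    "ref": "other_allele",
    "effect_allele_frequency": "eaf", "freq": "eaf", "af": "eaf",
    "b": "beta", "effect": "beta",
    "standard_error": "se", "stderr": "se",
    "p": "pval", "p_value": "pval", "pvalue": "pval",
    "samplesize": "n", "sample_size": "n",
    "events": "n_events", "n_deaths": "n_events", "ncase_events": "n_events",
}

MANDATORY_COLUMNS = (
    "variant_id", "effect_allele", "other_allele", "eaf", "beta", "se",
    "pval", "n",
)


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file violates the expected format."""


class HarmonizationError(ValueError):
    """Raised when harmonization cannot produce a usable instrument set."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is per effect allele, in SD units of a standardized trait for
    exposures and log hazard-ratio units for survival outcomes.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    chrom: str = ""
    pos: int = 0
    n_events: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf out of range (0,1): {self.eaf}")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0: {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: pval out of range (0,1]: {self.pval}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, where strand is ambiguous."""
        return COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flip_coded_allele(self) -> "VariantAssociation":
        """Return the same association coded on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


class LDMatrix:
    """Square matrix of pairwise genotype correlations, aligned to variant ids.

    Correlations are signed relative to each variant's effect allele; flipping
    the coded allele of variant *j* negates row and column *j*.
    """

    def __init__(self, variant_ids: Sequence[str], rho: np.ndarray):
        rho = np.asarray(rho, dtype=float)
        ids = list(variant_ids)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValueError("rho must be a square matrix")
        if rho.shape[0] != len(ids):
            raise ValueError("variant_ids length must match rho dimension")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if not np.allclose(rho, rho.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have a unit diagonal")
        # Small excursions beyond |1| (rounding in upstream tools) are kept so
        # that regularize_ld can repair them; anything larger is malformed.
        if np.any(np.abs(rho) > 1.0 + 1e-4):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self.variant_ids = ids
        self.rho = 0.5 * (rho + rho.T)
        self._index = {v: i for i, v in enumerate(ids)}

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(variant_ids, np.eye(len(variant_ids)))

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.rho)[0])

    def is_psd(self, tol: float = 1e-8) -> bool:
        return self.min_eigenvalue() >= -tol

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        """Sub-matrix for the given variants, in the given order."""
        try:
            idx = [self._index[v] for v in variant_ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in LD matrix") from None
        return LDMatrix(list(variant_ids), self.rho[np.ix_(idx, idx)])

    def flip_signs(self, variant_ids: Iterable[str]) -> "LDMatrix":
        """Negate rows/columns of variants whose coded allele was flipped."""
        sign = np.ones(self.k)
        for v in variant_ids:
            sign[self._index[v]] = -1.0
        rho = sign[:, None] * self.rho * sign[None, :]
        return LDMatrix(self.variant_ids, rho)


@dataclass
class HarmonizedSet:
    """Exposure/outcome associations aligned to a common effect allele.

    ``table`` has one row per retained variant with columns ``variant_id,
    effect_allele, other_allele, eaf, beta_x, se_x, pval_x, beta_y, se_y,
    pval_y, n_x, n_y, n_events``; ``ld`` is aligned to the same row order.
    ``provenance`` records every input exposure variant with a status in
    ``{kept, flipped, dropped}`` and a machine-readable reason code.
    """

    table: pd.DataFrame
    ld: LDMatrix
    provenance: pd.DataFrame

    @classmethod
    def from_arrays(
        cls,
        variant_ids: Sequence[str],
        bx: np.ndarray,
        se_x: np.ndarray,
        by: np.ndarray,
        se_y: np.ndarray,
        ld: "LDMatrix | None" = None,
        eaf: np.ndarray | None = None,
    ) -> "HarmonizedSet":
        """Assemble an already-aligned set directly from numeric arrays."""
        ids = list(variant_ids)
        k = len(ids)
        bx, se_x = np.broadcast_to(bx, k), np.broadcast_to(se_x, k)
        by, se_y = np.broadcast_to(by, k), np.broadcast_to(se_y, k)
        eaf = np.broadcast_to(0.5 if eaf is None else eaf, k)
        table = pd.DataFrame({
            "variant_id": ids, "effect_allele": "A", "other_allele": "G",
            "eaf": np.asarray(eaf, float),
            "beta_x": np.asarray(bx, float), "se_x": np.asarray(se_x, float),
            "pval_x": 1.0, "n_x": np.nan,
            "beta_y": np.asarray(by, float), "se_y": np.asarray(se_y, float),
            "pval_y": 1.0, "n_y": np.nan, "n_events": np.nan,
        })
        provenance = pd.DataFrame(
            {"variant_id": ids, "status": "kept", "reason": ""}
        )
        return cls(table, ld if ld is not None else LDMatrix.identity(ids),
                   provenance)

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    @property
    def bx(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(float)

    def with_identity_ld(self) -> "HarmonizedSet":
        """Copy treating instruments as independent (identity correlation)."""
        return HarmonizedSet(
            self.table.copy(), LDMatrix.identity(self.variant_ids),
            self.provenance.copy(),
        )

    def drop_variant(self, variant_id: str) -> "HarmonizedSet":
        keep = [v for v in self.variant_ids if v != variant_id]
        if len(keep) == self.k:
            raise KeyError(f"variant {variant_id!r} not in harmonized set")
        tab = self.table[self.table["variant_id"].isin(keep)].reset_index(drop=True)
        return HarmonizedSet(tab, self.ld.subset(keep), self.provenance)

    def exposure_records(self) -> list[VariantAssociation]:
        return _records_from_table(self.table, "x")

    def outcome_records(self) -> list[VariantAssociation]:
        return _records_from_table(self.table, "y")


def _records_from_table(tab: pd.DataFrame, suffix: str) -> list[VariantAssociation]:
    out = []
    for row in tab.itertuples(index=False):
        out.append(VariantAssociation(
            variant_id=row.variant_id,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            eaf=float(row.eaf),
            beta=float(getattr(row, f"beta_{suffix}")),
            se=float(getattr(row, f"se_{suffix}")),
            pval=float(getattr(row, f"pval_{suffix}")),
            n=float(getattr(row, f"n_{suffix}")),
            n_events=(float(row.n_events)
                      if suffix == "y" and not pd.isna(row.n_events) else None),
        ))
    return out


# ---------------------------------------------------------------------------
# I/O


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        mapping[col] = COLUMN_SYNONYMS.get(key, key)
    return mapping


def read_sumstats(
    path: str | Path,
    trait_kind: str = "exposure",
    sep: str = "\t",
    strict: bool = False,
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into association records.

    Rows that violate the record invariants (e.g. ``eaf`` outside (0,1)) are
    rejected with a logged row-level diagnostic; with ``strict=True`` any bad
    row raises instead.
    """
    if trait_kind not in ("exposure", "outcome"):
        raise ValueError(f"trait_kind must be exposure or outcome: {trait_kind!r}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = df.rename(columns=_canonical_columns(df.columns))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = row._asdict()
        try:
            rec = VariantAssociation(
                variant_id=str(d["variant_id"]),
                chrom=str(d.get("chrom", "") or ""),
                pos=int(float(d["pos"])) if d.get("pos") not in (None, "") else 0,
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                eaf=float(d["eaf"]),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                n=float(d["n"]),
                n_events=(float(d["n_events"])
                          if trait_kind == "outcome" and d.get("n_events")
                          not in (None, "") and not pd.isna(d.get("n_events"))
                          else None),
            )
        except (ValueError, TypeError) as exc:
            msg = f"{path} line {i}: row rejected: {exc}"
            if strict:
                raise SumstatsFormatError(msg) from exc
            logger.warning(msg)
            continue
        records.append(rec)
    return records


def write_sumstats(records: Sequence[VariantAssociation], path: str | Path) -> None:
    """Write association records as a tab-separated table (the reader's dialect)."""
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": repr(r.eaf), "beta": repr(r.beta), "se": repr(r.se),
            "pval": repr(r.pval), "n": repr(r.n),
        }
        if r.n_events is not None:
            row["n_events"] = repr(r.n_events)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if ids != [str(i) for i in df.index]:
        raise SumstatsFormatError(f"{path}: LD row and column ids differ")
    return LDMatrix(ids, df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.rho, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# Harmonization


def _match_alleles(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[str, VariantAssociation | None]:
    """Align an outcome record's coding to the exposure's effect allele.

    Returns ``(action, aligned_outcome)`` with action in
    ``{same, flipped, allele_mismatch}``. A strand (complementary-allele)
    flip of the outcome record is attempted before declaring a mismatch;
    this is skipped for palindromic variants, where a strand flip is
    indistinguishable from an allele swap.
    """
    ea_x, oa_x = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea_x, oa_x):
        return "same", out
    if (out.effect_allele, out.other_allele) == (oa_x, ea_x):
        return "flipped", out.flip_coded_allele()
    if not exp.is_palindromic:
        cea = COMPLEMENT.get(out.effect_allele)
        coa = COMPLEMENT.get(out.other_allele)
        if cea and coa:
            stranded = replace(out, effect_allele=cea, other_allele=coa)
            if (cea, coa) == (ea_x, oa_x):
                return "same", stranded
            if (cea, coa) == (oa_x, ea_x):
                return "flipped", stranded.flip_coded_allele()
    return "allele_mismatch", None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LDMatrix | None = None,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Pair exposure and outcome associations on a common effect allele.

    Variants are matched by ``variant_id``. Outcome records coded on the
    opposite allele have their beta sign flipped and EAF complemented.
    Palindromic (A/T, C/G) variants with exposure EAF within
    ``0.5 ± palindrome_eaf_window`` are dropped as strand-ambiguous. The LD
    matrix is subset to the retained variants; correlations stay signed
    relative to the exposure effect alleles, which harmonization never
    re-codes.
    """
    ids = [v.variant_id for v in exposure]
    if len(set(ids)) != len(ids):
        raise HarmonizationError("exposure variants are not unique by variant_id")
    if ld is None:
        ld = LDMatrix.identity(ids)
    missing_ld = [v for v in ids if v not in ld._index]
    if missing_ld:
        raise HarmonizationError(f"LD matrix missing variants: {missing_ld}")

    outcome_by_id = {v.variant_id: v for v in outcome}
    rows, prov = [], []
    for exp in exposure:
        out = outcome_by_id.get(exp.variant_id)
        if out is None:
            prov.append((exp.variant_id, "dropped", "missing_in_outcome"))
            continue
        if exp.is_palindromic and abs(exp.eaf - 0.5) <= palindrome_eaf_window:
            prov.append((exp.variant_id, "dropped", "palindromic_ambiguous"))
            continue
        action, aligned = _match_alleles(exp, out)
        if aligned is None:
            prov.append((exp.variant_id, "dropped", "allele_mismatch"))
            continue
        prov.append((exp.variant_id, "kept" if action == "same" else "flipped", ""))
        rows.append({
            "variant_id": exp.variant_id,
            "effect_allele": exp.effect_allele,
            "other_allele": exp.other_allele,
            "eaf": exp.eaf,
            "beta_x": exp.beta, "se_x": exp.se, "pval_x": exp.pval,
            "n_x": float(exp.n),
            "beta_y": aligned.beta, "se_y": aligned.se, "pval_y": aligned.pval,
            "n_y": float(aligned.n),
            "n_events": aligned.n_events if aligned.n_events is not None else np.nan,
        })
    if not rows:
        raise HarmonizationError("no overlapping instruments after harmonization")
    table = pd.DataFrame(rows)
    provenance = pd.DataFrame(prov, columns=["variant_id", "status", "reason"])
    return HarmonizedSet(table, ld.subset(list(table["variant_id"])), provenance)


def regularize_ld(
    ld: LDMatrix, jitter_max: float = 1e-4, tol: float = 1e-8
) -> tuple[LDMatrix, float]:
    """Repair a near-PSD correlation matrix by minimal diagonal inflation.

    The repaired matrix is ``(rho + d*I) / (1 + d)`` with the smallest
    ``d >= 0`` making the minimum eigenvalue >= -tol, preserving the unit
    diagonal. Returns the (possibly unchanged) matrix and the inflation used.
    """
    lam_min = ld.min_eigenvalue()
    if lam_min >= -tol:
        return ld, 0.0
    d = -lam_min + tol
    if d > jitter_max:
        raise ValueError(
            f"LD matrix not repairable: required inflation {d:.3g} "
            f"exceeds jitter_max {jitter_max:.3g}"
        )
    rho = (ld.rho + d * np.eye(ld.k)) / (1.0 + d)
    return LDMatrix(ld.variant_ids, rho), d
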