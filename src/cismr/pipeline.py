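"""Orchestration: run the full analysis grid from one declarative config file.

One config describes exposures (summary-statistics path, gene locus, clumping
threshold, optional LD matrix and published R² override) and outcome strata
(summary-statistics path, case and event counts). For every exposure x
stratum cell the pipeline selects instruments, harmonizes, runs generalized
IVW + MR-Egger + Cochran's Q (weighted median and PRESSO only for panels
treated as independent), computes the minimally detectable HR, applies
Bonferroni correction across exposures within each source, and writes a
structured JSON bundle plus a method-by-stratum grid of ``HR (95% CI)``
strings shaped like a publication main table. A stage error in one cell is
recorded and the remaining cells continue.

Config example (YAML)::

    output_dir: results/
    seed: 7
    multiple_testing_m: 4
    exploratory_events_floor: 200
    methods: [ivw, egger]
    exposures:
      - name: sIL6RA
        source: decode
        sumstats: sil6ra_decode.tsv
        ld: sil6ra_ld.tsv           # optional; identity if omitted
        gene: {name: IL6R, chrom: "1", start: 154377669,
               end: 154441926, flank: 500000}
        p_threshold: 5.0e-8
        clump_r2: 0.001
        r2_floor: 0.01
        n_gwas: 35559
        independent: true           # identity correlation in estimation
        r2_override: 0.49           # optional published total R²
    outcomes:
      - stratum: overall
        sumstats: outcome_overall.tsv
        n_cases: 16964
        n_events: 4010
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cismr.instruments import GeneLocus, build_instrument_set
from cismr.mr import MRModel, bonferroni_adjust
from cismr.power import PowerSpec, min_detectable_hr
from cismr.presso import presso_test
from cismr.sumstats import (
    HarmonizationError,
    harmonize,
    read_ld_matrix,
    read_sumstats,
)

logger = logging.getLogger(__name__)


@dataclass
class ExposureConfig:
    name: str
    source: str
    sumstats: str
    gene: dict
    ld: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    r2_floor: float = 0.01
    n_gwas: float | None = None
    independent: bool = False
    r2_override: float | None = None

    @property
    def locus(self) -> GeneLocus:
        g = self.gene
        return GeneLocus(
            gene_name=g["name"], chrom=str(g["chrom"]),
            start=int(g["start"]), end=int(g["end"]),
            flank=int(g.get("flank", 500_000)),
        )


@dataclass
class OutcomeConfig:
    stratum: str
    sumstats: str
    n_cases: int
    n_events: int


@dataclass
class AnalysisConfig:
    """Validated configuration for one full analysis run."""

    exposures: list[ExposureConfig]
    outcomes: list[OutcomeConfig]
    output_dir: str = "results"
    seed: int = 0
    multiple_testing_m: int | None = None
    exploratory_events_floor: int = 200
    methods: tuple[str, ...] = ("ivw", "egger")
    palindrome_eaf_window: float = 0.08
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("config needs at least one exposure and one outcome")
        if self.multiple_testing_m is not None and self.multiple_testing_m < 1:
            raise ValueError("multiple_testing_m must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "AnalysisConfig":
        def _resolve(p: str | None) -> str | None:
            if p is None or base_dir is None:
                return p
            q = Path(p)
            return str(q if q.is_absolute() else base_dir / q)

        exposures = [
            ExposureConfig(**{**e, "sumstats": _resolve(e["sumstats"]),
                              "ld": _resolve(e.get("ld"))})
            for e in raw["exposures"]
        ]
        outcomes = [
            OutcomeConfig(**{**o, "sumstats": _resolve(o["sumstats"])})
            for o in raw["outcomes"]
        ]
        kwargs = {
            k: raw[k]
            for k in ("output_dir", "seed", "multiple_testing_m",
                      "exploratory_events_floor", "palindrome_eaf_window",
                      "n_boot")
            if k in raw
        }
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        return cls(exposures=exposures, outcomes=outcomes, **kwargs)


def _analyse_cell(
    exp: ExposureConfig,
    out: OutcomeConfig,
    config: AnalysisConfig,
) -> dict:
    """Instrument selection -> harmonization -> MR suite for one grid cell."""
    exposure_records = read_sumstats(exp.sumstats, "exposure")
    ld = read_ld_matrix(exp.ld) if exp.ld else None
    iset = build_instrument_set(
        exposure_name=exp.name, source_tag=exp.source,
        sumstats=exposure_records,
        ld=ld if ld is not None else _identity_for(exposure_records),
        locus=exp.locus, p_threshold=exp.p_threshold,
        clump_r2=exp.clump_r2, r2_floor=exp.r2_floor,
        n_gwas=exp.n_gwas, r2_override=exp.r2_override,
    )
    if iset is None:
        return {"status": "no_instruments"}
    if iset.excluded:
        return {"status": "excluded", "reason": iset.exclusion_reason,
                "r2_total": iset.r2_total}

    outcome_records = read_sumstats(out.sumstats, "outcome")
    h = harmonize(iset.variants, outcome_records, iset.ld,
                  config.palindrome_eaf_window)
    methods = list(config.methods)
    if exp.independent and "weighted_median" not in methods:
        methods.append("weighted_median")
    model = MRModel(h, correlated=not exp.independent)
    results = model.fit(methods=methods, n_boot=config.n_boot, seed=config.seed)

    cell: dict = {
        "status": "ok",
        "k_selected": iset.k,
        "k_harmonized": h.k,
        "r2_total": iset.r2_total,
        "f_stat": iset.f_stat,
        "dropped_variants": results_dropped(h),
        "estimates": {m: e.to_dict() for m, e in results.estimates.items()},
        "method_errors": results.errors,
        "q_stat": results.q_stat,
        "q_pval": results.q_pval,
        "min_detectable_hr": min_detectable_hr(PowerSpec(
            n_cases=out.n_cases, n_events=out.n_events,
            r2=min(iset.r2_total, 0.999),
        )),
        "exploratory": out.n_events < config.exploratory_events_floor,
    }
    if h.k >= 2:
        cell["leave_one_out"] = results.leave_one_out().to_dict("records")
    if exp.independent and h.k >= 4:
        pres = presso_test(h, seed=config.seed)
        cell["presso"] = {
            "global_pval": pres.global_pval,
            "outlier_ids": pres.outlier_ids,
            "n_sim": pres.n_sim,
        }
    return cell


def _identity_for(records):
    from cismr.sumstats import LDMatrix

    return LDMatrix.identity([v.variant_id for v in records])


def results_dropped(h) -> list[dict]:
    dropped = h.provenance[h.provenance["status"] == "dropped"]
    return dropped.to_dict("records")


def run_analysis(config: AnalysisConfig, write: bool = True) -> dict:
    """Run every exposure x stratum cell; write JSON bundle and a grid TSV.

    Cells that fail record the error and the run continues. Bonferroni
    adjustment is applied to IVW p-values across exposures within each
    source (``multiple_testing_m`` overrides the per-source exposure count).
    Returns the report bundle; with ``write=True`` also emits
    ``results.json`` and ``table_main.tsv`` under ``output_dir``.
    """
    cells: dict[str, dict] = {}
    for exp in config.exposures:
        for out in config.outcomes:
            key = f"{exp.name}|{exp.source}|{out.stratum}"
            try:
                cells[key] = _analyse_cell(exp, out, config)
            except (HarmonizationError, ValueError, KeyError, OSError) as exc:
                logger.error("cell %s failed: %s", key, exc)
                cells[key] = {"status": "error", "error": str(exc)}

    # Bonferroni across exposures within each GWAS source, on overall IVW p.
    sources = sorted({e.source for e in config.exposures})
    for source in sources:
        exp_names = [e.name for e in config.exposures if e.source == source]
        m = config.multiple_testing_m or len(exp_names)
        for out in config.outcomes:
            keys = [f"{n}|{source}|{out.stratum}" for n in exp_names]
            pvals, ok_keys = [], []
            for k in keys:
                est = cells.get(k, {}).get("estimates", {}).get("ivw")
                if est:
                    pvals.append(est["pval"])
                    ok_keys.append(k)
            if pvals:
                for k, adj in zip(ok_keys, bonferroni_adjust(pvals, m)):
                    cells[k]["estimates"]["ivw"]["pval_bonferroni"] = adj
                    cells[k]["estimates"]["ivw"]["significant_adjusted"] = (
                        adj < 0.05
                    )

    bundle = {
        "seed": config.seed,
        "multiple_testing_m": config.multiple_testing_m,
        "cells": cells,
        "grid": _grid_rows(config, cells),
    }
    if write:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=str)
        pd.DataFrame(bundle["grid"]).to_csv(
            out_dir / "table_main.tsv", sep="\t", index=False
        )
    return bundle


def _format_est(est: dict | None, digits: int = 2) -> str:
    if not est:
        return "NA"
    return (f"{est['hr']:.{digits}f} "
            f"({est['hr_ci_low']:.{digits}f}, {est['hr_ci_high']:.{digits}f})")


def _grid_rows(config: AnalysisConfig, cells: dict) -> list[dict]:
    """Main-table-shaped rows: biomarker x stratum with HR (CI) per method."""
    rows = []
    for exp in config.exposures:
        for out in config.outcomes:
            cell = cells.get(f"{exp.name}|{exp.source}|{out.stratum}", {})
            est = cell.get("estimates", {})
            rows.append({
                "biomarker": exp.name,
                "source": exp.source,
                "stratum": out.stratum,
                "IVW": _format_est(est.get("ivw")),
                "MR-Egger": _format_est(est.get("egger_slope")),
                "weighted_median": _format_est(est.get("weighted_median")),
                "nSNP": cell.get("k_harmonized", 0),
                "exploratory": cell.get("exploratory", False),
                "status": cell.get("status", "missing"),
            })
    return rows
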