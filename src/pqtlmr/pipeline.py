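"""Configuration-driven orchestration of the full cis-pQTL MR analysis.

One run covers: per exposure dataset (first = discovery, rest = validation)
and per outcome — cis instrument selection, allele harmonization, Steiger
filtering, causal estimation (gIVW, or Wald ratio for a single instrument)
and Bonferroni control; Bayesian colocalization plus the LD check for every
outcome with a Bonferroni-significant discovery estimate and always for the
positive-control outcome; and the proteome-wide pleiotropy audit when a
protein catalog is configured.  Reports are TSV; a plain-text run log records
every threshold, seed and dropped-variant count so each number in the report
can be reproduced by calling the module operations directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import coloc as coloc_mod
from .instruments import CisLocus, select_cis_instruments, steiger_filter
from .ld import LDMatrix, ld_check, read_ld
from .mr_core import MREstimate, bonferroni, givw
from .pleioscan import ProteinCatalog, run_pleiotropy_audit
from .sumstats import SummaryTable, harmonization_tally, harmonize, read_sumstats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid study configuration."""


@dataclass
class DatasetSpec:
    trait_id: str
    path: str
    trait_type: str = "quantitative"
    positive_control: bool = False
    column_map: dict[str, str] = field(default_factory=dict)


@dataclass
class StudyConfig:
    """All inputs and thresholds of one study run.

    Thresholds default to the standard cis-MR pipeline values: cis window
    +-500 kb, instrument p < 5e-8, F > 10, MAF > 0.05, clump r^2 < 0.2,
    palindromic-MAF cutoff 0.42, colocalization priors (1e-4, 1e-4, 1e-5)
    with conditional-H4 threshold 0.9, LD-check r^2 >= 0.8.
    """

    exposures: list[DatasetSpec]
    outcomes: list[DatasetSpec]
    ld_path: str
    locus: CisLocus
    out_dir: str
    p_max: float = 5e-8
    f_min: float = 10.0
    maf_min: float = 0.05
    clump_r2: float = 0.2
    palindrome_maf_max: float = 0.42
    coloc_priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    conditional_h4_min: float = 0.9
    ld_check_r2: float = 0.8
    window_bp: int = 500_000
    bonferroni_m: int | None = None      # default: number of non-control outcomes
    alpha: float = 0.05
    coloc_all: bool = False              # run colocalization for every outcome
    catalog_manifest: str | None = None
    pleio_p_assoc: float = 5e-8
    pleio_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.exposures:
            raise ConfigError("at least one exposure dataset is required")
        if not self.outcomes:
            raise ConfigError("at least one outcome dataset is required")
        n_tests = sum(1 for o in self.outcomes if not o.positive_control)
        if self.bonferroni_m is None:
            self.bonferroni_m = max(n_tests, 1)
        if self.bonferroni_m < n_tests:
            raise ConfigError(
                f"bonferroni_m ({self.bonferroni_m}) < number of non-control outcomes ({n_tests})")
        for name, val, lo, hi in (("p_max", self.p_max, 0, 1), ("clump_r2", self.clump_r2, 0, 1.0001),
                                  ("palindrome_maf_max", self.palindrome_maf_max, 0, 0.5),
                                  ("ld_check_r2", self.ld_check_r2, 0, 1),
                                  ("conditional_h4_min", self.conditional_h4_min, 0, 1)):
            if not (lo < val <= hi):
                raise ConfigError(f"{name} = {val} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw: dict[str, Any] = yaml.safe_load(path.read_text())
        base = path.parent

        def _ds(d: Mapping[str, Any]) -> DatasetSpec:
            return DatasetSpec(trait_id=d["trait_id"], path=str(base / d["path"]),
                               trait_type=d.get("trait_type", "quantitative"),
                               positive_control=bool(d.get("positive_control", False)),
                               column_map=dict(d.get("column_map", {})))

        locus = CisLocus(chrom=str(raw["locus"]["chrom"]),
                         anchor_pos=int(raw["locus"]["anchor_pos"]),
                         window_bp=int(raw["locus"].get("window_bp", 500_000)))
        priors = coloc_mod.ColocPriors(**raw.get("coloc_priors", {}))
        kwargs = {k: raw[k] for k in (
            "p_max", "f_min", "maf_min", "clump_r2", "palindrome_maf_max",
            "conditional_h4_min", "ld_check_r2", "window_bp", "bonferroni_m",
            "alpha", "coloc_all", "pleio_p_assoc", "pleio_alpha", "seed") if k in raw}
        manifest = raw.get("catalog_manifest")
        return cls(exposures=[_ds(d) for d in raw["exposures"]],
                   outcomes=[_ds(d) for d in raw["outcomes"]],
                   ld_path=str(base / raw["ld_path"]), locus=locus,
                   out_dir=str(base / raw.get("out_dir", "results")),
                   coloc_priors=priors,
                   catalog_manifest=str(base / manifest) if manifest else None,
                   **kwargs)


@dataclass
class StudyReport:
    """Combined per-(exposure, outcome) report plus artifact paths."""

    table: pd.DataFrame
    instrument_counts: dict[str, dict[str, int]]
    paths: dict[str, Path]
    errors: list[str]


def _mr_row(est: MREstimate) -> dict[str, float]:
    return {"n_snps": est.n_snps, "beta": est.beta_xy, "se": est.se,
            "or": est.or_, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval, "q_stat": est.q_stat, "method": est.method}


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the configured study; see the module docstring for stages."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}"]
    for k in ("p_max", "f_min", "maf_min", "clump_r2", "palindrome_maf_max",
              "conditional_h4_min", "ld_check_r2", "window_bp", "bonferroni_m", "alpha"):
        log_lines.append(f"{k}: {getattr(config, k)}")
    errors: list[str] = []

    ld = read_ld(config.ld_path)
    exposures = {d.trait_id: read_sumstats(d.path, d.column_map, d.trait_type, d.trait_id)
                 for d in config.exposures}
    outcomes = {d.trait_id: read_sumstats(d.path, d.column_map, d.trait_type, d.trait_id)
                for d in config.outcomes}
    control_ids = {d.trait_id for d in config.outcomes if d.positive_control}
    discovery_id = config.exposures[0].trait_id

    rows: list[dict] = []
    inst_counts: dict[str, dict[str, int]] = {}
    estimates: dict[tuple[str, str], MREstimate] = {}
    steiger_rows: dict[tuple[str, str], list] = {}

    for exp_id, exposure in exposures.items():
        try:
            selection = select_cis_instruments(
                exposure, config.locus, ld, p_max=config.p_max, f_min=config.f_min,
                clump_r2=config.clump_r2, maf_min=config.maf_min)
        except Exception as err:  # stage-named failure, keep other exposures running
            errors.append(f"select[{exp_id}]: {err}")
            continue
        inst_counts[exp_id] = {"candidates_selected": len(selection.variant_ids)}
        log_lines.append(f"{exp_id}: selected {selection.variant_ids} "
                         f"(total F = {selection.f_total:.2f})")
        if selection.is_empty:
            errors.append(f"select[{exp_id}]: empty selection")
            continue
        for out_id, outcome in outcomes.items():
            try:
                harm = harmonize(selection.table, outcome,
                                 palindrome_maf_max=config.palindrome_maf_max)
                tally = harmonization_tally(harm)
                retained, verdicts = steiger_filter(harm)
                n_steiger_removed = sum(1 for r in harm if r.is_usable) - len(retained)
                if not retained:
                    errors.append(f"mr[{exp_id},{out_id}]: no instruments left "
                                  "after harmonization/Steiger")
                    continue
                est = givw(retained, ld)
                estimates[(exp_id, out_id)] = est
                steiger_rows[(exp_id, out_id)] = retained
                counts = inst_counts.setdefault(exp_id, {})
                counts[f"{out_id}:instruments"] = len(retained)
                counts[f"{out_id}:dropped_palindromic"] = tally["dropped_palindromic"]
                counts[f"{out_id}:dropped_incompatible"] = tally["dropped_incompatible"]
                counts[f"{out_id}:steiger_removed"] = n_steiger_removed
                log_lines.append(
                    f"{exp_id} x {out_id}: {len(retained)} instruments "
                    f"(palindromic {tally['dropped_palindromic']}, "
                    f"incompatible {tally['dropped_incompatible']}, "
                    f"steiger-removed {n_steiger_removed})")
            except Exception as err:
                errors.append(f"mr[{exp_id},{out_id}]: {err}")

    # Bonferroni over non-control outcomes, per exposure
    for exp_id in exposures:
        pvals = {out_id: estimates[(exp_id, out_id)].pval for out_id in outcomes
                 if (exp_id, out_id) in estimates and out_id not in control_ids}
        corrected = bonferroni(pvals, config.bonferroni_m) if pvals else {}
        for out_id, p_adj in corrected.items():
            estimates[(exp_id, out_id)] = estimates[(exp_id, out_id)].with_bonferroni(
                config.bonferroni_m)

    # colocalization + LD check, gated on discovery MR significance
    coloc_results: dict[str, coloc_mod.ColocResult] = {}
    ldcheck_results: dict[str, list] = {}
    for out_id, outcome in outcomes.items():
        est = estimates.get((discovery_id, out_id))
        if est is None:
            continue
        significant = (est.pval_bonferroni is not None
                       and est.pval_bonferroni <= config.alpha)
        if not (significant or out_id in control_ids or config.coloc_all):
            log_lines.append(f"coloc[{out_id}]: skipped (no MR evidence)")
            continue
        try:
            exposure = exposures[discovery_id]
            df = exposure.df
            in_win = (df["chrom"].astype(str) == config.locus.chrom) & \
                     ((df["pos"] - config.locus.anchor_pos).abs() <= config.window_bp)
            region_exp = exposure.subset(df.loc[in_win, "variant_id"])
            pair = coloc_mod.RegionPair.from_tables(region_exp, outcome)
            coloc_results[out_id] = coloc_mod.coloc_abf(
                pair, config.coloc_priors, threshold=config.conditional_h4_min)
            inst_ids = [r.variant_id for r in steiger_rows[(discovery_id, out_id)]]
            ldcheck_results[out_id] = ld_check(
                inst_ids, outcome, ld, window_bp=config.window_bp,
                r2_min=config.ld_check_r2)
        except Exception as err:
            errors.append(f"coloc[{out_id}]: {err}")

    # pleiotropy audit (discovery instruments only)
    pleio_report = None
    if config.catalog_manifest:
        try:
            catalog = ProteinCatalog.from_manifest(config.catalog_manifest)
            first_outcome = {oid: t for oid, t in outcomes.items()}
            inst_ids = list({v for (e, o), rws in steiger_rows.items() if e == discovery_id
                             for v in (r.variant_id for r in rws)})
            pleio_report = run_pleiotropy_audit(
                inst_ids, exposures[discovery_id], catalog, first_outcome, ld,
                p_assoc=config.pleio_p_assoc, alpha_bonf=config.pleio_alpha)
            log_lines.append(f"pleioscan: {len(pleio_report.flagged)} flags, "
                             f"{len(pleio_report.triggered_mvmr)} mvmr adjustments")
        except Exception as err:
            errors.append(f"pleioscan: {err}")

    # combined report shaped like a per-outcome results table
    for out_id in outcomes:
        row: dict[str, Any] = {"outcome_id": out_id,
                               "positive_control": out_id in control_ids}
        for exp_id in exposures:
            est = estimates.get((exp_id, out_id))
            if est is None:
                continue
            prefix = "discovery" if exp_id == discovery_id else exp_id
            for k, v in _mr_row(est).items():
                row[f"{prefix}_{k}"] = v
            row[f"{prefix}_pval_bonferroni"] = est.pval_bonferroni
        cres = coloc_results.get(out_id)
        if cres is not None:
            row.update(coloc_n_snps=cres.n_snps, pp0=cres.pp0, pp1=cres.pp1,
                       pp2=cres.pp2, pp3=cres.pp3, pp4=cres.pp4,
                       conditional_h4=cres.conditional_h4, coloc_decision=cres.decision)
            checks = ldcheck_results.get(out_id, [])
            row["ld_check_pass"] = any(c.passed for c in checks)
        rows.append(row)

    table = pd.DataFrame(rows)
    paths = {"report": out_dir / "mr_report.tsv", "log": out_dir / "run_log.txt"}
    table.to_csv(paths["report"], sep="\t", index=False, float_format="%.10g")
    if pleio_report is not None:
        pleio_df = pd.DataFrame(
            [{"protein_id": p, "outcome_id": o, **_mr_row(est),
              "pval_bonferroni": est.pval_bonferroni}
             for (p, o), est in pleio_report.second_step.items()])
        paths["pleiotropy"] = out_dir / "pleiotropy_report.tsv"
        pleio_df.to_csv(paths["pleiotropy"], sep="\t", index=False, float_format="%.10g")
    for err in errors:
        log_lines.append(f"ERROR {err}")
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return StudyReport(table=table, instrument_counts=inst_counts, paths=paths,
                       errors=errors)


def region_plot(trait1: SummaryTable, trait2: SummaryTable, path: str | Path,
                title: str = "") -> Path:
    """Minimal regional association plot: position vs -log10 p for two traits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for table, marker, color in ((trait1, "o", "tab:blue"), (trait2, "s", "tab:red")):
        ax.scatter(table.df["pos"] / 1e6, -np.log10(table.df["pval"].clip(lower=1e-320)),
                   s=12, marker=marker, alpha=0.7, label=table.trait_id, color=color)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
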