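"""Two-step proteome-wide horizontal-pleiotropy audit of cis instruments.

Step 1 looks up each instrument of the primary exposure across a catalog of
protein GWAS and flags proteins the instruments associate with at genome-wide
significance.  Step 2 runs MR of each flagged protein (using that protein's
own instruments) on each outcome with Bonferroni control; where a flagged
protein shows a robust outcome effect, the primary exposure's estimate is
re-derived by multivariable MR adjusting for that protein, giving its direct
effect net of the pleiotropic path.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ld import LDMatrix
from .mr_core import MREstimate, bonferroni, givw, mvmr
from .sumstats import HarmonizedRow, SummaryTable, harmonize, read_sumstats

logger = logging.getLogger(__name__)


class PleioscanError(ValueError):
    """Invalid pleiotropy-scan input."""


@dataclass
class ProteinCatalog:
    """Local catalog of protein GWAS tables and their instrument lists."""

    sumstats: dict[str, SummaryTable] = field(default_factory=dict)
    instruments: dict[str, list[str]] = field(default_factory=dict)

    def add(self, protein_id: str, table: SummaryTable,
            instrument_ids: Sequence[str] = ()) -> None:
        if protein_id in self.sumstats:
            raise PleioscanError(f"duplicate protein id {protein_id!r}")
        self.sumstats[protein_id] = table
        self.instruments[protein_id] = list(instrument_ids)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.sumstats)

    @classmethod
    def from_manifest(cls, path: str | Path, trait_type: str = "quantitative") -> "ProteinCatalog":
        """Load from a TSV manifest: ``protein_id, sumstats_path, instruments_path``.

        Relative paths resolve against the manifest's directory; the
        instruments file lists one variant id per line (or a ``variant_id``
        column).
        """
        path = Path(path)
        man = pd.read_csv(path, sep="\t")
        for col in ("protein_id", "sumstats_path", "instruments_path"):
            if col not in man.columns:
                raise PleioscanError(f"manifest missing column {col!r}")
        cat = cls()
        for row in man.itertuples(index=False):
            table = read_sumstats(path.parent / row.sumstats_path, trait_type=trait_type,
                                  trait_id=row.protein_id)
            inst_path = path.parent / row.instruments_path
            first = inst_path.read_text().splitlines()
            ids = [ln.split("\t")[0].strip() for ln in first if ln.strip()]
            if ids and ids[0] == "variant_id":
                ids = ids[1:]
            cat.add(row.protein_id, table, ids)
        return cat


@dataclass(frozen=True)
class PleiotropyFlag:
    protein_id: str
    variant_id: str
    pval: float


@dataclass
class PleiotropyReport:
    """Outcome of the two-step audit."""

    flagged: list[PleiotropyFlag]
    second_step: dict[tuple[str, str], MREstimate]
    triggered_mvmr: dict[str, MREstimate]      # outcome_id -> adjusted primary estimate


def scan_instruments(instrument_ids: Sequence[str], catalog: ProteinCatalog,
                     p_assoc: float = 5e-8,
                     exclude: str | None = None) -> list[PleiotropyFlag]:
    """Flag catalog proteins any audited instrument associates with at ``p < p_assoc``.

    The audited exposure itself (``exclude``) is never flagged; instruments
    absent from a protein's table count as no association.
    """
    flags: list[PleiotropyFlag] = []
    for pid, table in catalog.sumstats.items():
        if pid == exclude:
            continue
        for vid in instrument_ids:
            if vid not in table:
                logger.debug("scan: %s absent from %s", vid, pid)
                continue
            p = table.get(vid).pval
            if p < p_assoc:
                flags.append(PleiotropyFlag(pid, vid, p))
    return flags


def second_step_mr(flagged: Sequence[PleiotropyFlag], catalog: ProteinCatalog,
                   outcomes: Mapping[str, SummaryTable], ld: LDMatrix,
                   m_tests: int | None = None,
                   ) -> dict[tuple[str, str], MREstimate]:
    """MR of each flagged protein on each outcome, Bonferroni-corrected.

    Each protein uses its own catalog instruments (gIVW; Wald for a single
    instrument).  ``m_tests`` defaults to the number of (protein, outcome)
    pairs attempted.
    """
    proteins = list(dict.fromkeys(f.protein_id for f in flagged))
    pairs = [(p, o) for p in proteins for o in outcomes]
    if m_tests is None:
        m_tests = len(pairs)
    results: dict[tuple[str, str], MREstimate] = {}
    for pid, oid in pairs:
        inst = catalog.instruments.get(pid, [])
        if not inst:
            logger.info("second_step_mr: %s has no instruments; pair (%s, %s) skipped",
                        pid, pid, oid)
            continue
        rows = [r for r in harmonize(catalog.sumstats[pid].subset(
            [v for v in inst if v in catalog.sumstats[pid]]), outcomes[oid])
            if r.is_usable]
        if not rows:
            logger.info("second_step_mr: no usable instruments for (%s, %s)", pid, oid)
            continue
        est = givw(rows, ld)
        results[(pid, oid)] = est.with_bonferroni(m_tests)
    return results


def adjust_with_mvmr(primary: SummaryTable, pleiotropic: SummaryTable,
                     outcome: SummaryTable, ld: LDMatrix,
                     instrument_ids: Sequence[str]) -> MREstimate:
    """Direct effect of the primary exposure adjusting for one pleiotropic protein.

    ``instrument_ids`` is the union of both exposures' instruments; every id
    must be present in both exposure tables and the outcome.  Returns the
    primary exposure's multivariable estimate.
    """
    missing = [v for v in instrument_ids
               if v not in primary or v not in pleiotropic or v not in outcome]
    if missing:
        raise PleioscanError(f"instruments absent from some table: {missing}")
    rows = [r for r in harmonize(primary.subset(instrument_ids), outcome) if r.is_usable]
    ids = [r.variant_id for r in rows]
    if len(ids) < 2:
        raise PleioscanError("multivariable adjustment needs >= 2 usable instruments")
    # align the covariate exposure to the harmonized (exposure-oriented) rows
    rows_cov = {r.variant_id: r for r in harmonize(pleiotropic.subset(ids), primary.subset(ids))
                if r.is_usable}
    if set(rows_cov) != set(ids):
        raise PleioscanError("could not harmonize the pleiotropic protein onto the instruments")
    blocks = {
        primary.trait_id: [r.beta_exp for r in rows],
        pleiotropic.trait_id: [rows_cov[r.variant_id].beta_exp for r in rows],
    }
    return mvmr(blocks, rows, ld)[primary.trait_id]


def run_pleiotropy_audit(instrument_ids: Sequence[str], primary: SummaryTable,
                         catalog: ProteinCatalog, outcomes: Mapping[str, SummaryTable],
                         ld: LDMatrix, p_assoc: float = 5e-8,
                         alpha_bonf: float = 0.05) -> PleiotropyReport:
    """Full two-step audit; multivariable adjustment is triggered for every
    (protein, outcome) pair whose corrected second-step p passes ``alpha_bonf``."""
    flags = scan_instruments(instrument_ids, catalog, p_assoc, exclude=primary.trait_id)
    second = second_step_mr(flags, catalog, outcomes, ld)
    adjusted: dict[str, MREstimate] = {}
    for (pid, oid), est in second.items():
        if est.pval_bonferroni is not None and est.pval_bonferroni <= alpha_bonf:
            union = list(dict.fromkeys(list(instrument_ids) + catalog.instruments[pid]))
            usable = [v for v in union
                      if v in primary and v in catalog.sumstats[pid] and v in outcomes[oid]]
            try:
                adjusted[oid] = adjust_with_mvmr(primary, catalog.sumstats[pid],
                                                 outcomes[oid], ld, usable)
            except (PleioscanError, ValueError) as err:
                logger.warning("mvmr adjustment failed for outcome %s: %s", oid, err)
    return PleiotropyReport(flags, second, adjusted)
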