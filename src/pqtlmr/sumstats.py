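"""GWAS summary statistics: containers, delimited-text I/O and allele harmonization.

A :class:`SummaryTable` holds one trait's marginal association estimates
(per-allele beta, SE, p-value, effect-allele frequency, sample sizes) backed
by a :class:`pandas.DataFrame` with a canonical column set.  Harmonization
aligns an exposure table and an outcome table to a shared effect-allele
orientation, flipping outcome effect signs where needed and dropping
strand-ambiguous (palindromic) variants whose orientation cannot be inferred
from allele frequency.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical on-disk column order
CANONICAL_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_cases", "n_controls",
)
_REQUIRED = CANONICAL_COLUMNS[:10]
_OPTIONAL = CANONICAL_COLUMNS[10:]
_NUMERIC = ("pos", "eaf", "beta", "se", "pval", "n", "n_cases", "n_controls")

TRAIT_TYPES = ("quantitative", "binary")


class SumstatsError(ValueError):
    """Base error for summary-statistics handling."""


class SchemaError(SumstatsError):
    """A required column is missing from an input file."""


class DuplicateVariantError(SumstatsError):
    """Duplicate variant ids within one table."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's marginal association for one trait.

    ``beta`` is the per-effect-allele coefficient: on the trait's measurement
    scale for quantitative traits and on the log-odds scale for binary traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    n_cases: int | None = None
    n_controls: int | None = None

    def problems(self) -> list[str]:
        """Return invariant violations (empty when the record is valid)."""
        out: list[str] = []
        if not (isinstance(self.pos, (int, np.integer)) and self.pos > 0):
            out.append(f"pos must be a positive integer, got {self.pos!r}")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in NUCLEOTIDES:
                out.append(f"{name} {a!r} is not a single nucleotide (indels/multi-allelics are rejected)")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (0.0 < self.eaf < 1.0):
            out.append(f"eaf {self.eaf!r} outside (0,1)")
        if not (self.se > 0):
            out.append(f"se {self.se!r} not > 0")
        if not (0.0 < self.pval <= 1.0):
            out.append(f"pval {self.pval!r} outside (0,1]")
        if not self.n > 0:
            out.append(f"n {self.n!r} not positive")
        if self.n_cases is not None and self.n_controls is not None:
            if self.n_cases + self.n_controls != self.n:
                out.append(f"n_cases+n_controls ({self.n_cases}+{self.n_controls}) != n ({self.n})")
        if not all(math.isfinite(x) for x in (self.eaf, self.beta, self.se, self.pval)):
            out.append("non-finite numeric field")
        return out

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a row of an input file was rejected."""

    line: int           # 1-based line number in the source file (header = 1)
    variant_id: str
    reason: str


class SummaryTable:
    """Ordered collection of :class:`SummaryRecord` for one trait, keyed by variant id."""

    def __init__(self, trait_id: str, trait_type: str, df: pd.DataFrame,
                 diagnostics: Sequence[RowDiagnostic] = ()):
        if trait_type not in TRAIT_TYPES:
            raise SumstatsError(f"trait_type must be one of {TRAIT_TYPES}, got {trait_type!r}")
        dup = df["variant_id"][df["variant_id"].duplicated()].tolist()
        if dup:
            raise DuplicateVariantError(f"duplicate variant_id values: {sorted(set(dup))}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.df = df.reset_index(drop=True)
        self.diagnostics = list(diagnostics)
        self._loc = {v: i for i, v in enumerate(self.df["variant_id"])}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._loc

    def __iter__(self) -> Iterator[SummaryRecord]:
        for row in self.df.itertuples(index=False):
            yield self._to_record(row)

    @staticmethod
    def _to_record(row) -> SummaryRecord:
        def _opt(x):
            return None if x is None or (isinstance(x, float) and math.isnan(x)) else int(x)
        return SummaryRecord(
            variant_id=row.variant_id, chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=row.effect_allele, other_allele=row.other_allele,
            eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
            pval=float(row.pval), n=int(row.n),
            n_cases=_opt(getattr(row, "n_cases", None)),
            n_controls=_opt(getattr(row, "n_controls", None)),
        )

    def get(self, variant_id: str) -> SummaryRecord:
        return self._to_record(next(self.df.iloc[[self._loc[variant_id]]].itertuples(index=False)))

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def subset(self, variant_ids: Iterable[str]) -> "SummaryTable":
        """Row subset in the given order; ids absent from the table raise ``KeyError``."""
        idx = [self._loc[v] for v in variant_ids]
        return SummaryTable(self.trait_id, self.trait_type, self.df.iloc[idx])

    @classmethod
    def from_records(cls, trait_id: str, trait_type: str,
                     records: Iterable[SummaryRecord]) -> "SummaryTable":
        rows = []
        for r in records:
            probs = r.problems()
            if probs:
                raise SumstatsError(f"invalid record {r.variant_id}: {'; '.join(probs)}")
            rows.append({c: getattr(r, c) for c in CANONICAL_COLUMNS})
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(trait_id, trait_type, df)


def read_sumstats(path: str | Path, column_map: Mapping[str, str] | None = None,
                  trait_type: str = "quantitative", trait_id: str | None = None,
                  sep: str | None = None) -> SummaryTable:
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row; ``.gz`` is
        transparent.
    column_map
        Mapping from standard field name (see ``CANONICAL_COLUMNS``) to the
        column name used in the file.  Fields absent from the map are assumed
        to use their canonical name.
    trait_type
        ``"quantitative"`` or ``"binary"``.
    trait_id
        Defaults to the file stem.

    Rows violating :class:`SummaryRecord` invariants (or with unparseable
    numeric cells) are dropped and reported in ``SummaryTable.diagnostics``,
    one entry per offending row with its source line number.
    """
    path = Path(path)
    if sep is None:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                          keep_default_na=False, comment=None)
    else:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {column_map.get(std, std): std for std in CANONICAL_COLUMNS
              if column_map.get(std, std) in raw.columns}
    missing = [column_map.get(std, std) for std in _REQUIRED
               if column_map.get(std, std) not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) in {path.name}: {missing}")
    df = raw.rename(columns=rename)[[c for c in CANONICAL_COLUMNS if c in rename.values()]].copy()
    for c in _OPTIONAL:
        if c not in df.columns:
            df[c] = ""

    diagnostics: list[RowDiagnostic] = []
    keep = np.ones(len(df), dtype=bool)
    numeric: dict[str, pd.Series] = {}
    for c in _NUMERIC:
        col = df[c].replace({"": None, "NA": None, "nan": None, ".": None})
        num = pd.to_numeric(col, errors="coerce")
        if c in _REQUIRED:
            bad = num.isna()
            for i in np.flatnonzero(bad.to_numpy() & keep):
                diagnostics.append(RowDiagnostic(
                    line=i + 2, variant_id=df["variant_id"].iat[i],
                    reason=f"unparseable numeric cell in column {c!r}: {df[c].iat[i]!r}"))
            keep &= ~bad.to_numpy()
        numeric[c] = num
    for c in _NUMERIC:
        df[c] = numeric[c]
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].str.upper()

    # per-row invariant screen on the rows that parsed
    for i in np.flatnonzero(keep):
        row = df.iloc[i]
        rec = SummaryRecord(
            variant_id=row["variant_id"], chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            eaf=row["eaf"], beta=row["beta"], se=row["se"], pval=row["pval"],
            n=int(row["n"]),
            n_cases=None if pd.isna(row["n_cases"]) else int(row["n_cases"]),
            n_controls=None if pd.isna(row["n_controls"]) else int(row["n_controls"]),
        )
        probs = rec.problems()
        if probs:
            keep[i] = False
            diagnostics.append(RowDiagnostic(line=i + 2, variant_id=rec.variant_id,
                                             reason="; ".join(probs)))
    out = df.loc[keep].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out["n"] = out["n"].astype(int)
    if diagnostics:
        logger.info("read_sumstats(%s): rejected %d of %d rows", path.name,
                    len(diagnostics), len(df))
    return SummaryTable(trait_id or path.stem, trait_type, out, diagnostics)


def write_sumstats(table: SummaryTable, path: str | Path, sep: str = "\t") -> Path:
    """Write the canonical delimited format; ``read_sumstats`` inverts it exactly."""
    if len(table) == 0:
        raise SumstatsError("refusing to write an empty SummaryTable")
    path = Path(path)
    df = table.df.copy()
    for c in ("n_cases", "n_controls"):
        df[c] = df[c].map(lambda x: "" if pd.isna(x) else str(int(x)))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


# --------------------------------------------------------------------------
# harmonization
# --------------------------------------------------------------------------

ACTIONS = ("kept", "flipped", "dropped_palindromic", "dropped_incompatible")


@dataclass(frozen=True)
class HarmonizedRow:
    """Exposure-outcome pair for one variant after orientation to the exposure's effect allele.

    For dropped rows (``action`` starting with ``dropped_``) the outcome-side
    estimates are set to NaN so they cannot leak into downstream estimators.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    pval_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    eaf_out: float
    pval_out: float
    n_out: int
    action: str

    @property
    def is_usable(self) -> bool:
        return self.action in ("kept", "flipped")


def _pair(rec: SummaryRecord) -> tuple[str, str]:
    return (rec.effect_allele, rec.other_allele)


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              palindrome_maf_max: float = 0.42) -> list[HarmonizedRow]:
    """Align outcome effects to the exposure's effect-allele orientation.

    Only variants present in both tables are considered (absentees are counted
    in a log message).  Rules, per shared variant:

    * same allele pair, same orientation -> ``kept``;
    * same pair, swapped orientation (directly or after strand complement) ->
      ``flipped``: outcome beta negated, outcome EAF complemented;
    * palindromic pair (A/T or C/G) with MAF > ``palindrome_maf_max`` in either
      table -> ``dropped_palindromic`` (strand unresolvable near MAF 0.5);
    * palindromic pair with informative MAF -> oriented by matching the
      outcome EAF against the exposure EAF and its complement;
    * irreconcilable allele pairs -> ``dropped_incompatible``.
    """
    shared = [v for v in exposure.variant_ids if v in outcome]
    n_only = (len(exposure) - len(shared)) + (len(outcome) - len(shared))
    if n_only:
        logger.info("harmonize: %d variants present in only one table were skipped", n_only)

    rows: list[HarmonizedRow] = []
    for vid in shared:
        e = exposure.get(vid)
        o = outcome.get(vid)
        action = None
        beta_o, eaf_o = o.beta, o.eaf
        if e.is_palindromic:
            if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
                action = "dropped_incompatible"
            elif e.maf > palindrome_maf_max or o.maf > palindrome_maf_max:
                action = "dropped_palindromic"
            else:
                # allele labels carry no strand information here; orient by EAF
                if abs(e.eaf - o.eaf) <= abs(e.eaf - (1.0 - o.eaf)):
                    action = "kept"
                else:
                    action, beta_o, eaf_o = "flipped", -o.beta, 1.0 - o.eaf
        else:
            po = _pair(o)
            pc = (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele])
            if po == _pair(e) or pc == _pair(e):
                action = "kept"
            elif po == _pair(e)[::-1] or pc == _pair(e)[::-1]:
                action, beta_o, eaf_o = "flipped", -o.beta, 1.0 - o.eaf
            else:
                action = "dropped_incompatible"
        dropped = action.startswith("dropped")
        rows.append(HarmonizedRow(
            variant_id=vid, chrom=e.chrom, pos=e.pos,
            effect_allele=e.effect_allele, other_allele=e.other_allele,
            beta_exp=e.beta, se_exp=e.se, eaf_exp=e.eaf, pval_exp=e.pval, n_exp=e.n,
            beta_out=math.nan if dropped else beta_o,
            se_out=math.nan if dropped else o.se,
            eaf_out=math.nan if dropped else eaf_o,
            pval_out=math.nan if dropped else o.pval,
            n_out=o.n, action=action,
        ))
    return rows


def harmonization_tally(rows: Sequence[HarmonizedRow]) -> dict[str, int]:
    """Count rows per action; values sum to the size of the variant intersection."""
    tally = {a: 0 for a in ACTIONS}
    for r in rows:
        tally[r.action] += 1
    return tally


def rows_to_tables(rows: Sequence[HarmonizedRow], exposure: SummaryTable,
                   outcome: SummaryTable) -> tuple[SummaryTable, SummaryTable]:
    """Rebuild (exposure, outcome) tables from usable harmonized rows.

    Useful for idempotence checks and for feeding harmonized pairs back into
    table-level operations; the outcome table inherits the exposure's allele
    orientation.
    """
    usable = [r for r in rows if r.is_usable]
    exp_recs, out_recs = [], []
    for r in usable:
        e = exposure.get(r.variant_id)
        o = outcome.get(r.variant_id)
        exp_recs.append(e)
        out_recs.append(replace(
            o, effect_allele=r.effect_allele, other_allele=r.other_allele,
            beta=r.beta_out, eaf=r.eaf_out))
    return (SummaryTable.from_records(exposure.trait_id, exposure.trait_type, exp_recs),
            SummaryTable.from_records(outcome.trait_id, outcome.trait_type, out_recs))
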