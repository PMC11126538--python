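"""Signed LD correlation matrices, greedy clumping, and the LD-check heuristic.

The matrix stores the signed correlation ``r`` between variant dosages:
generalized IVW needs the sign to build the outcome covariance, while
clumping and the LD check threshold only its square.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import SummaryTable


class LDError(ValueError):
    """Invalid LD matrix or id mismatch."""


@dataclass(frozen=True)
class LDMatrix:
    """Signed pairwise correlation among an ordered set of variants."""

    variant_ids: tuple[str, ...]
    r: np.ndarray  # (M, M), symmetric, unit diagonal, |r| <= 1

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "_loc", {v: i for i, v in enumerate(self.variant_ids)})

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._loc

    def index(self, variant_id: str) -> int:
        return self._loc[variant_id]

    def r_of(self, id1: str, id2: str) -> float:
        return float(self.r[self._loc[id1], self._loc[id2]])

    def r2(self, id1: str, id2: str) -> float:
        return self.r_of(id1, id2) ** 2

    def subset(self, ids: Iterable[str]) -> "LDMatrix":
        ids = list(ids)
        missing = [v for v in ids if v not in self._loc]
        if missing:
            raise LDError(f"variant ids absent from LD matrix: {missing}")
        idx = [self._loc[v] for v in ids]
        return LDMatrix(tuple(ids), self.r[np.ix_(idx, idx)])


def validate_ld(ids: Sequence[str], r: np.ndarray, tol: float = 1e-8) -> LDMatrix:
    """Validate and symmetrize a correlation array into an :class:`LDMatrix`.

    Asymmetries within ``tol`` are averaged away; larger ones, off-unit
    diagonals, out-of-range entries or duplicate ids raise :class:`LDError`
    naming the offending entries.
    """
    r = np.asarray(r, dtype=float)
    ids = list(ids)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise LDError(f"LD array must be square, got shape {r.shape}")
    if len(ids) != r.shape[0]:
        raise LDError(f"{len(ids)} ids for a {r.shape[0]}x{r.shape[1]} matrix")
    if len(set(ids)) != len(ids):
        dup = sorted({v for v in ids if ids.count(v) > 1})
        raise LDError(f"duplicate variant ids: {dup}")
    asym = np.abs(r - r.T)
    if asym.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise LDError(f"asymmetry beyond tolerance at ({ids[i]}, {ids[j]}): "
                      f"{r[i, j]!r} vs {r[j, i]!r}")
    r = 0.5 * (r + r.T)
    bad_diag = np.flatnonzero(np.abs(np.diag(r) - 1.0) > tol)
    if bad_diag.size:
        raise LDError(f"non-unit diagonal at {[ids[i] for i in bad_diag]}")
    np.fill_diagonal(r, 1.0)
    over = np.abs(r) > 1.0 + tol
    if over.any():
        i, j = np.argwhere(over)[0]
        raise LDError(f"|r| > 1 at ({ids[i]}, {ids[j]}): {r[i, j]!r}")
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(tuple(ids), r)


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD matrix from text.

    Two layouts are accepted: *wide* (header row of variant ids followed by
    the numeric matrix) and *long* (three columns ``id1, id2, r``; missing
    pairs default to 0).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    fields = header.split(sep)
    if [f.strip().lower() for f in fields[:3]] == ["id1", "id2", "r"]:
        df = pd.read_csv(path, sep=sep)
        ids = list(dict.fromkeys(pd.concat([df["id1"], df["id2"]]).astype(str)))
        loc = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for a, b, v in zip(df["id1"].astype(str), df["id2"].astype(str), df["r"].astype(float)):
            r[loc[a], loc[b]] = v
            r[loc[b], loc[a]] = v
        return validate_ld(ids, r)
    mat = pd.read_csv(path, sep=sep, header=0)
    return validate_ld([str(c) for c in mat.columns], mat.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path: str | Path, sep: str = "\t") -> Path:
    """Write the wide text layout read back by :func:`read_ld`."""
    path = Path(path)
    pd.DataFrame(ld.r, columns=list(ld.variant_ids)).to_csv(
        path, sep=sep, index=False, float_format="%.17g")
    return path


def clump(records: SummaryTable, ld: LDMatrix, r2_max: float = 0.2) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Candidates are ranked by ascending p-value (ties: ascending position,
    then lexicographic variant id).  The best remaining candidate is accepted
    and every remaining candidate with ``r^2 >= r2_max`` against ANY accepted
    variant is discarded; the retained set is therefore pairwise ``r^2 < r2_max``.
    Returns accepted ids in acceptance order.
    """
    missing = [v for v in records.variant_ids if v not in ld]
    if missing:
        raise LDError(f"variant ids absent from LD matrix: {missing}")
    order = records.df.sort_values(
        ["pval", "pos", "variant_id"], kind="mergesort")["variant_id"].tolist()
    accepted: list[str] = []
    for vid in order:
        if all(ld.r2(vid, a) < r2_max for a in accepted):
            accepted.append(vid)
    return accepted


@dataclass(frozen=True)
class LDCheckResult:
    """LD between one instrument and the outcome's lead variant near it."""

    instrument_id: str
    outcome_lead_id: str | None
    r2: float
    passed: bool
    empty_window: bool = False


def ld_check(instrument_ids: Sequence[str], outcome_region: SummaryTable,
             ld: LDMatrix, window_bp: int = 500_000, r2_min: float = 0.8,
             instrument_positions: dict[str, int] | None = None) -> list[LDCheckResult]:
    """Check each instrument against the outcome's lead variant within +-window_bp.

    The lead is the smallest outcome p-value inside the closed window around
    the instrument (ties broken by position then id, as in clumping).  A pass
    (``r^2 >= r2_min``) corroborates a colocalization signal; an empty window
    yields ``passed=False`` with ``empty_window=True``.
    """
    results = []
    df = outcome_region.df
    for vid in instrument_ids:
        if instrument_positions and vid in instrument_positions:
            pos = instrument_positions[vid]
        elif vid in outcome_region:
            pos = outcome_region.get(vid).pos
        else:
            raise LDError(f"position of instrument {vid!r} unknown: supply instrument_positions")
        win = df[(df["pos"] >= pos - window_bp) & (df["pos"] <= pos + window_bp)]
        if win.empty:
            results.append(LDCheckResult(vid, None, 0.0, False, empty_window=True))
            continue
        lead = win.sort_values(["pval", "pos", "variant_id"], kind="mergesort").iloc[0]
        lead_id = lead["variant_id"]
        r2 = ld.r2(vid, lead_id)
        results.append(LDCheckResult(vid, lead_id, r2, r2 >= r2_min))
    return results
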