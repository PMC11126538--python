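"""cis-window instrument selection, instrument strength, and Steiger directionality filtering.

Selection applies the joint criteria for a valid cis-pQTL instrument: within
+-``window_bp`` of the leading pQTL (closed interval), genome-wide significant
(p < 5e-8), strong (per-SNP F > 10), common (MAF > 0.05), and approximately
independent after greedy LD clumping at r^2 < 0.2.  Steiger filtering then
removes instruments that explain more variance of the outcome than of the
exposure, the signature of reverse causation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ld import LDError, LDMatrix, clump
from .sumstats import HarmonizedRow, SummaryTable

logger = logging.getLogger(__name__)


class InstrumentError(ValueError):
    """Invalid instrument-selection input."""


@dataclass(frozen=True)
class CisLocus:
    """cis region: closed +-window around the leading pQTL position."""

    chrom: str
    anchor_pos: int
    window_bp: int = 500_000

    def __post_init__(self):
        if self.window_bp <= 0:
            raise InstrumentError("window_bp must be positive")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and abs(pos - self.anchor_pos) <= self.window_bp


@dataclass(frozen=True)
class SteigerResult:
    """Variance explained on each trait and the implied causal direction."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool


@dataclass
class InstrumentSet:
    """Selected instruments with strength statistics and (optionally) Steiger verdicts."""

    variant_ids: list[str]
    table: SummaryTable            # exposure records of the selected instruments
    f_per_snp: dict[str, float]
    f_total: float
    ld_sub: LDMatrix
    steiger: dict[str, SteigerResult] = field(default_factory=dict)
    status: str = "ok"             # "ok" or "empty_selection"

    @property
    def is_empty(self) -> bool:
        return len(self.variant_ids) == 0


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength F = (beta/se)^2, the squared Wald z."""
    if not se > 0:
        raise InstrumentError(f"se must be positive, got {se!r}")
    return (beta / se) ** 2


def total_f(f_per_snp: Mapping[str, float]) -> float:
    """Combined instrument strength: mean of the per-SNP F statistics."""
    if not f_per_snp:
        raise InstrumentError("empty F mapping")
    return float(np.mean(list(f_per_snp.values())))


def total_f_regression(r2_sum: float, n: int, k: int) -> float:
    """Alternative combined F from summed variance explained.

    The k-instrument regression F: ``(n - k - 1)/k * R^2/(1 - R^2)`` with
    ``R^2`` approximated by the sum of per-SNP variances explained (valid for
    independent instruments).
    """
    if not (0 <= r2_sum < 1):
        raise InstrumentError("r2_sum must lie in [0, 1)")
    if n <= k + 1 or k < 1:
        raise InstrumentError("need n > k+1 and k >= 1")
    return (n - k - 1) / k * r2_sum / (1 - r2_sum)


def select_cis_instruments(exposure: SummaryTable, locus: CisLocus, ld: LDMatrix,
                           p_max: float = 5e-8, f_min: float = 10.0,
                           clump_r2: float = 0.2, maf_min: float = 0.05) -> InstrumentSet:
    """Apply the cis-instrument criteria and LD clumping to an exposure table.

    Candidates must lie in the closed cis window, reach ``p < p_max``, have
    per-SNP ``F > f_min`` and ``MAF > maf_min``; greedy clumping at
    ``r^2 < clump_r2`` then enforces approximate independence.  An empty
    survivor set is a valid outcome (``status='empty_selection'``), but a
    locus anchor position absent from the table is an error.
    """
    df = exposure.df
    on_anchor = (df["chrom"].astype(str) == locus.chrom) & (df["pos"] == locus.anchor_pos)
    if not on_anchor.any():
        raise InstrumentError(
            f"no variant at locus anchor {locus.chrom}:{locus.anchor_pos} in {exposure.trait_id}")
    in_cis = (df["chrom"].astype(str) == locus.chrom) & \
             ((df["pos"] - locus.anchor_pos).abs() <= locus.window_bp)
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    fstat = (df["beta"] / df["se"]) ** 2
    mask = in_cis & (df["pval"] < p_max) & (fstat > f_min) & (maf > maf_min)
    candidates = exposure.subset(df.loc[mask, "variant_id"])
    logger.info("select_cis_instruments(%s): %d/%d candidates pass cis/p/F/MAF filters",
                exposure.trait_id, len(candidates), len(exposure))
    if len(candidates) == 0:
        return InstrumentSet([], candidates, {}, float("nan"),
                             LDMatrix((), np.empty((0, 0))), status="empty_selection")
    kept = clump(candidates, ld, r2_max=clump_r2)
    table = exposure.subset(kept)
    f_per = {r.variant_id: f_statistic(r.beta, r.se) for r in table}
    return InstrumentSet(kept, table, f_per, total_f(f_per), ld.subset(kept))


def steiger_r2(z: float, n: int) -> float:
    """Variance explained implied by a Wald z at sample size n: z^2/(z^2 + n - 2)."""
    if n < 3:
        raise InstrumentError("sample size must be >= 3")
    return z * z / (z * z + n - 2)


def steiger_filter(rows: Sequence[HarmonizedRow], n_exp: int | None = None,
                   n_out: int | None = None
                   ) -> tuple[list[HarmonizedRow], dict[str, SteigerResult]]:
    """Remove instruments whose variance explained is larger on the outcome.

    Per instrument, r^2 on each trait is computed from the Wald z on that
    trait's analysis scale, ``r^2 = z^2/(z^2 + n - 2)``; the instrument is
    retained iff ``r2_exposure > r2_outcome`` (strict — ties are removed as a
    conservative choice).  Sample sizes default to the per-row ``n_exp`` /
    ``n_out`` carried through harmonization.
    """
    retained: list[HarmonizedRow] = []
    verdicts: dict[str, SteigerResult] = {}
    for row in rows:
        if not row.is_usable:
            continue
        ne = n_exp if n_exp is not None else row.n_exp
        no = n_out if n_out is not None else row.n_out
        if not ne or not no:
            raise InstrumentError(
                f"sample size missing for {row.variant_id}: supply n_exp/n_out")
        r2e = steiger_r2(row.beta_exp / row.se_exp, ne)
        r2o = steiger_r2(row.beta_out / row.se_out, no)
        ok = r2e > r2o
        verdicts[row.variant_id] = SteigerResult(r2e, r2o, ok)
        if ok:
            retained.append(row)
    return retained, verdicts
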