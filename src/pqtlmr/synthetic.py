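"""LD-structured synthetic GWAS summary statistics with known ground truth.

Generates the marginal association estimates a GWAS would report for a cis
region under a chosen causal configuration: null, a causal variant shared by
two traits, distinct causal variants, instrument-level pleiotropy, or reverse
causation.  Genotypes are parameterized on the standardized (per-SD) scale so
standard errors have closed form, and observed effect estimates are drawn
jointly from a multivariate normal whose correlation equals the LD matrix —
the sampling covariance structure of marginal GWAS estimates from one cohort.

Seeds are explicit everywhere; identical seeds give identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ld import LDMatrix, validate_ld
from .sumstats import CANONICAL_COLUMNS, SummaryTable
from scipy import stats

LD_FAMILIES = ("ar1", "block", "identity")


class SyntheticError(ValueError):
    """Invalid simulation request."""


@dataclass(frozen=True)
class RegionTemplate:
    """A cis region: variant grid, allele frequencies and LD structure."""

    M: int
    chrom: str
    positions: np.ndarray          # strictly increasing, 1-based bp
    mafs: np.ndarray               # in (0.01, 0.5)
    ld: LDMatrix
    ld_family: str
    ld_param: float

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return self.ld.variant_ids


@dataclass
class TruthRecord:
    """Ground truth behind a simulated study (known only to the simulator)."""

    causal_config: str                         # none|shared|distinct|trait1_only|trait2_only
    causal_idx1: list[int] = field(default_factory=list)
    causal_idx2: list[int] = field(default_factory=list)
    joint_effects1: np.ndarray | None = None   # standardized joint effects, length M
    joint_effects2: np.ndarray | None = None
    beta_xy_true: float = 0.0
    pleiotropy: np.ndarray | None = None       # per-instrument direct outcome effects
    reverse_flags: np.ndarray | None = None    # True where the instrument acts outcome-first


def make_region(M: int, ld_family: str = "ar1", ld_param: float = 0.9,
                seed: int = 0, chrom: str = "9", span_bp: int = 1_000_000,
                start_pos: int = 1_000_000, block_size: int = 10) -> RegionTemplate:
    """Build a deterministic region template.

    ``ar1`` gives ``r_ij = ld_param**|i-j|``; ``block`` gives within-block
    correlation ``ld_param`` (blocks of ``block_size``) and zero between;
    ``identity`` gives independent variants.  Positions are drawn uniformly
    over ``span_bp`` (sorted, made strictly increasing); MAFs uniform on
    (0.05, 0.5).  Non-positive-definite requests are jittered on the diagonal.
    """
    if M < 1:
        raise SyntheticError("M must be >= 1")
    if ld_family not in LD_FAMILIES:
        raise SyntheticError(f"ld_family must be one of {LD_FAMILIES}")
    if ld_family == "ar1" and not abs(ld_param) < 1:
        raise SyntheticError("ar1 requires |ld_param| < 1")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.choice(span_bp, size=M, replace=False)) if M <= span_bp else None
    if offsets is None:
        raise SyntheticError("span too small for M distinct positions")
    positions = start_pos + offsets
    mafs = rng.uniform(0.05, 0.5, size=M)
    if ld_family == "identity":
        r = np.eye(M)
    elif ld_family == "ar1":
        idx = np.arange(M)
        r = ld_param ** np.abs(idx[:, None] - idx[None, :])
    else:
        r = np.eye(M)
        for start in range(0, M, block_size):
            sl = slice(start, min(start + block_size, M))
            r[sl, sl] = ld_param
        np.fill_diagonal(r, 1.0)
    # guard: jitter if the smallest eigenvalue is not safely positive
    if np.linalg.eigvalsh(r).min() < 1e-8:
        r = (r + 1e-6 * np.eye(M)) / (1 + 1e-6)
        np.fill_diagonal(r, 1.0)
    ids = tuple(f"rs{seed % 1000}_{i:04d}" for i in range(M))
    return RegionTemplate(M=M, chrom=chrom, positions=positions, mafs=mafs,
                          ld=validate_ld(ids, r), ld_family=ld_family,
                          ld_param=float(ld_param))


def _se_vector(region: RegionTemplate, trait_type: str, n: int,
               case_fraction: float | None) -> np.ndarray:
    if trait_type == "quantitative":
        return np.full(region.M, 1.0 / np.sqrt(n))
    if case_fraction is None or not (0 < case_fraction < 1):
        raise SyntheticError("binary traits need case_fraction in (0,1)")
    geno_var = 2.0 * region.mafs * (1.0 - region.mafs)
    return 1.0 / np.sqrt(n * case_fraction * (1 - case_fraction) * geno_var)


def simulate_trait(region: RegionTemplate, joint_effects: np.ndarray | Sequence[float],
                   trait_type: str, n: int, case_fraction: float | None = None,
                   seed: int = 0, trait_id: str = "trait", noise: bool = True,
                   n_cases: bool = True) -> SummaryTable:
    """Simulate one trait's marginal summary statistics over the region.

    ``joint_effects`` are the true joint (conditional) standardized effects
    ``b``; the true marginal effects are ``R b``.  Standard errors are
    ``1/sqrt(n)`` for quantitative traits (standardized scale) and
    ``1/sqrt(n*phi*(1-phi)*2*maf*(1-maf))`` on the log-odds scale for binary
    traits with case fraction ``phi``.  Observed estimates are drawn from
    ``MVN(R b, D R D)`` with ``D = diag(se)``; ``noise=False`` emits the
    exact expected marginals for deterministic oracle checks.
    """
    if n < 100:
        raise SyntheticError("n must be >= 100")
    b = np.asarray(joint_effects, float)
    if b.shape != (region.M,):
        raise SyntheticError(f"joint_effects must have length {region.M}")
    R = region.ld.r
    se = _se_vector(region, trait_type, n, case_fraction)
    mean = R @ b
    if noise:
        rng = np.random.default_rng(seed)
        chol = np.linalg.cholesky(R)
        beta = mean + se * (chol @ rng.standard_normal(region.M))
    else:
        beta = mean.copy()
    z = beta / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 5e-324, 1.0)
    df = pd.DataFrame({
        "variant_id": list(region.variant_ids),
        "chrom": region.chrom,
        "pos": region.positions.astype(int),
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": region.mafs,       # ancestral orientation: effect allele = minor
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": int(n),
        "n_cases": np.nan,
        "n_controls": np.nan,
    }, columns=list(CANONICAL_COLUMNS))
    if trait_type == "binary" and case_fraction is not None and n_cases:
        df["n_cases"] = float(round(n * case_fraction))
        df["n_controls"] = float(n - round(n * case_fraction))
    return SummaryTable(trait_id, trait_type, df)


def simulate_mr_study(region: RegionTemplate, beta_xy_true: float,
                      k_instruments: int, pleiotropy_sd: float = 0.0,
                      reverse_fraction: float = 0.0, n_exp: int = 35_000,
                      n_out: int = 100_000, seed: int = 0,
                      instrument_effect: float = 0.1, leak_coef: float = 0.5,
                      outcome_type: str = "binary", case_fraction: float = 0.3,
                      ) -> tuple[SummaryTable, SummaryTable, TruthRecord]:
    """Simulate an exposure-outcome pair with a known causal effect.

    ``k_instruments`` causal variants, evenly spread over the region, receive
    standardized exposure effect ``instrument_effect``.  Outcome joint effects
    are ``beta_xy_true * (exposure effects)`` plus per-instrument direct
    (pleiotropic) effects drawn with SD ``pleiotropy_sd``.  A
    ``reverse_fraction`` share of instruments is instead made outcome-first:
    the variant gets ``instrument_effect`` on the outcome and only the leaked
    share ``leak_coef * instrument_effect`` on the exposure, the configuration
    Steiger filtering must detect and remove.
    """
    if k_instruments < 1 or k_instruments > region.M:
        raise SyntheticError("need 1 <= k_instruments <= M")
    if not 0.0 <= reverse_fraction <= 1.0:
        raise SyntheticError("reverse_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    idx = np.unique(np.linspace(0, region.M - 1, k_instruments).round().astype(int))
    n_rev = int(round(reverse_fraction * idx.size))
    rev = np.zeros(idx.size, dtype=bool)
    rev[:n_rev] = True

    b_exp = np.zeros(region.M)
    b_out = np.zeros(region.M)
    pleio = rng.normal(0.0, pleiotropy_sd, size=idx.size) if pleiotropy_sd > 0 \
        else np.zeros(idx.size)
    for j, i in enumerate(idx):
        if rev[j]:
            b_out[i] = instrument_effect
            b_exp[i] = leak_coef * instrument_effect
        else:
            b_exp[i] = instrument_effect
            b_out[i] = beta_xy_true * instrument_effect + pleio[j]

    exp_seed, out_seed = rng.integers(0, 2**31 - 1, size=2)
    exposure = simulate_trait(region, b_exp, "quantitative", n_exp,
                              seed=int(exp_seed), trait_id="exposure")
    outcome = simulate_trait(region, b_out, outcome_type, n_out,
                             case_fraction=case_fraction if outcome_type == "binary" else None,
                             seed=int(out_seed), trait_id="outcome")
    truth = TruthRecord(
        causal_config="none" if beta_xy_true == 0 and pleiotropy_sd == 0 and n_rev == 0
        else "shared",
        causal_idx1=list(idx), causal_idx2=list(idx),
        joint_effects1=b_exp, joint_effects2=b_out,
        beta_xy_true=float(beta_xy_true), pleiotropy=pleio, reverse_flags=rev)
    return exposure, outcome, truth


def simulate_coloc_pair(region: RegionTemplate, scenario: str, seed: int = 0,
                        effect: float = 0.1, n1: int = 50_000, n2: int = 50_000,
                        causal_idx: tuple[int, int] | None = None,
                        ) -> tuple[SummaryTable, SummaryTable, TruthRecord]:
    """Simulate a two-trait region under a named colocalization scenario.

    Scenarios: ``none`` (both null), ``shared`` (one causal variant for both
    traits), ``distinct`` (separate causal variants), ``trait1_only`` /
    ``trait2_only``.  ``causal_idx`` pins the causal variant index per trait;
    defaults put the shared variant at the region center and distinct
    variants at the 1/4 and 3/4 points.
    """
    if scenario not in ("none", "shared", "distinct", "trait1_only", "trait2_only"):
        raise SyntheticError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    M = region.M
    if causal_idx is None:
        causal_idx = (M // 2, M // 2) if scenario != "distinct" else (M // 4, (3 * M) // 4)
    c1, c2 = causal_idx
    b1 = np.zeros(M)
    b2 = np.zeros(M)
    if scenario in ("shared", "trait1_only", "distinct"):
        b1[c1] = effect
    if scenario == "shared":
        b2[c1] = effect
    elif scenario in ("distinct", "trait2_only"):
        b2[c2] = effect
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    t1 = simulate_trait(region, b1, "quantitative", n1, seed=int(s1), trait_id="trait1")
    t2 = simulate_trait(region, b2, "quantitative", n2, seed=int(s2), trait_id="trait2")
    truth = TruthRecord(causal_config=scenario,
                        causal_idx1=[c1] if b1.any() else [],
                        causal_idx2=[c1 if scenario == "shared" else c2] if b2.any() else [],
                        joint_effects1=b1, joint_effects2=b2)
    return t1, t2, truth
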