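"""Causal-effect estimators for two-sample MR with summary statistics.

Implements the Wald ratio for a single instrument, generalized IVW (gIVW)
for multiple instruments correlated through LD, multivariable MR for joint
exposures, and Bonferroni multiple-testing control.

gIVW is generalized least squares of the outcome associations on the exposure
associations without intercept, with weighting covariance
``Omega_ij = se_gy_i * se_gy_j * r_ij`` built from the signed LD correlation.
A multiplicative random-effects model inflates the naive SE by
``max(1, sqrt(Q/(k-1)))`` where Q is the residual heterogeneity statistic;
the inflation never deflates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats

from .ld import LDMatrix
from .sumstats import HarmonizedRow

Z_95 = 1.959964  # two-sided 95% normal quantile


class MRError(ValueError):
    """Invalid estimator input."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with OR-scale interval and heterogeneity diagnostics."""

    beta_xy: float
    se: float
    pval: float
    n_snps: int
    q_stat: float
    re_inflation: float
    method: str  # wald | givw | mvmr
    pval_bonferroni: float | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta_xy)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta_xy - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta_xy + Z_95 * self.se)

    def with_bonferroni(self, m: int) -> "MREstimate":
        from dataclasses import replace
        return replace(self, pval_bonferroni=min(1.0, self.pval * m))


def _estimate(beta: float, se: float, n_snps: int, q_stat: float,
              inflation: float, method: str) -> MREstimate:
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MREstimate(beta_xy=float(beta), se=float(se), pval=max(p, 5e-324),
                      n_snps=n_snps, q_stat=float(q_stat),
                      re_inflation=float(inflation), method=method)


def wald_ratio(beta_gx: float, se_gx: float, beta_gy: float, se_gy: float,
               second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate ``beta_gy / beta_gx``.

    The default SE is the first-order delta approximation ``se_gy/|beta_gx|``
    (exposure-side uncertainty ignored — appropriate for strong instruments);
    ``second_order=True`` adds the exposure-variance term
    ``beta_gy^2 se_gx^2 / beta_gx^4``.
    """
    if not (se_gx > 0 and se_gy > 0):
        raise MRError("standard errors must be positive")
    if beta_gx == 0:
        raise MRError("Wald ratio undefined for beta_gx = 0")
    beta = beta_gy / beta_gx
    var = (se_gy / beta_gx) ** 2
    if second_order:
        var += beta_gy ** 2 * se_gx ** 2 / beta_gx ** 4
    return _estimate(beta, math.sqrt(var), 1, 0.0, 1.0, "wald")


def _outcome_cov(se_gy: np.ndarray, ld_r: np.ndarray) -> np.ndarray:
    return np.outer(se_gy, se_gy) * ld_r


def _chol(omega: np.ndarray, context: str):
    try:
        c, low = linalg.cho_factor(omega)
    except linalg.LinAlgError as err:
        raise MRError(
            f"{context}: outcome covariance is not positive definite "
            "(instruments too correlated? try a stricter clumping r^2)") from err
    return c, low


def givw_arrays(beta_gx: np.ndarray, beta_gy: np.ndarray, se_gy: np.ndarray,
                ld_r: np.ndarray) -> MREstimate:
    """gIVW from aligned arrays (see module docstring for the model)."""
    x = np.asarray(beta_gx, float)
    y = np.asarray(beta_gy, float)
    s = np.asarray(se_gy, float)
    k = x.size
    if k == 0:
        raise MRError("no instruments")
    if (s <= 0).any():
        raise MRError("outcome standard errors must be positive")
    omega = _outcome_cov(s, np.asarray(ld_r, float))
    cf = _chol(omega, "givw")
    oi_x = linalg.cho_solve(cf, x)
    oi_y = linalg.cho_solve(cf, y)
    xtox = float(x @ oi_x)
    if xtox <= 0:
        raise MRError("degenerate design: x' Omega^-1 x <= 0")
    beta = float(x @ oi_y) / xtox
    se_naive = math.sqrt(1.0 / xtox)
    resid = y - x * beta
    q = float(resid @ linalg.cho_solve(cf, resid))
    inflation = max(1.0, math.sqrt(q / (k - 1))) if k > 1 else 1.0
    return _estimate(beta, se_naive * inflation, k, q, inflation, "givw")


def givw(rows: Sequence[HarmonizedRow], ld_sub: LDMatrix) -> MREstimate:
    """gIVW over harmonized instrument rows; reduces to the Wald ratio for k=1."""
    usable = [r for r in rows if r.is_usable]
    if not usable:
        raise MRError("no usable instruments after harmonization")
    ids = [r.variant_id for r in usable]
    r_mat = ld_sub.subset(ids).r
    est = givw_arrays(np.array([r.beta_exp for r in usable]),
                      np.array([r.beta_out for r in usable]),
                      np.array([r.se_out for r in usable]), r_mat)
    return est


def mvmr_arrays(design_gx: np.ndarray, beta_gy: np.ndarray, se_gy: np.ndarray,
                ld_r: np.ndarray, exposure_ids: Sequence[str]) -> dict[str, MREstimate]:
    """Multivariable MR: weighted multiple regression of outcome on exposure betas.

    ``design_gx`` has one column per exposure.  Direct effects come from
    ``b = (X' Omega^-1 X)^-1 X' Omega^-1 y`` with the gIVW weighting
    covariance; per-exposure SEs from the diagonal of ``(X' Omega^-1 X)^-1``,
    jointly inflated by ``max(1, sqrt(Q/(k - p)))``.
    """
    X = np.atleast_2d(np.asarray(design_gx, float))
    y = np.asarray(beta_gy, float)
    s = np.asarray(se_gy, float)
    k, p = X.shape
    if len(exposure_ids) != p:
        raise MRError("exposure_ids length must match design columns")
    if k <= p:
        raise MRError(f"need more instruments ({k}) than exposures ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise MRError(f"rank-deficient design: collinear exposures among {list(exposure_ids)}")
    omega = _outcome_cov(s, np.asarray(ld_r, float))
    cf = _chol(omega, "mvmr")
    oi_X = linalg.cho_solve(cf, X)
    xtx = X.T @ oi_X
    xtx_inv = np.linalg.inv(xtx)
    b = xtx_inv @ (X.T @ linalg.cho_solve(cf, y))
    resid = y - X @ b
    q = float(resid @ linalg.cho_solve(cf, resid))
    inflation = max(1.0, math.sqrt(q / (k - p)))
    out = {}
    for j, eid in enumerate(exposure_ids):
        se = math.sqrt(xtx_inv[j, j]) * inflation
        out[eid] = _estimate(b[j], se, k, q, inflation, "mvmr")
    return out


def mvmr(exposure_blocks: Mapping[str, Sequence[float]], outcome_rows: Sequence[HarmonizedRow],
         ld_sub: LDMatrix) -> dict[str, MREstimate]:
    """Multivariable MR from per-exposure beta vectors aligned to the outcome rows.

    ``exposure_blocks`` maps exposure id -> instrument-aligned beta vector
    (same order as ``outcome_rows``).  With a single exposure this reduces to
    :func:`givw`.
    """
    usable = [r for r in outcome_rows if r.is_usable]
    ids = [r.variant_id for r in usable]
    if not exposure_blocks:
        raise MRError("no exposures")
    X = np.column_stack([np.asarray(exposure_blocks[e], float) for e in exposure_blocks])
    if X.shape[0] != len(usable):
        raise MRError("exposure beta vectors must align with outcome rows")
    if X.shape[1] == 1:
        eid = next(iter(exposure_blocks))
        est = givw_arrays(X[:, 0], np.array([r.beta_out for r in usable]),
                          np.array([r.se_out for r in usable]), ld_sub.subset(ids).r)
        return {eid: est}
    return mvmr_arrays(X, np.array([r.beta_out for r in usable]),
                       np.array([r.se_out for r in usable]), ld_sub.subset(ids).r,
                       list(exposure_blocks))


def bonferroni(pvals: Mapping[str, float], m: int) -> dict[str, float]:
    """Bonferroni correction: ``min(1, p*m)`` per outcome; requires ``m >= len(pvals)``."""
    if m < len(pvals):
        raise MRError(f"m ({m}) smaller than number of tests ({len(pvals)})")
    out = {}
    for key, p in pvals.items():
        if not (0.0 < p <= 1.0):
            raise MRError(f"p-value for {key!r} outside (0,1]: {p!r}")
        out[key] = min(1.0, p * m)
    return out
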