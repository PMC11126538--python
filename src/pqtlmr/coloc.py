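"""Single-causal-variant Bayesian colocalization from summary statistics.

Per-SNP evidence uses the Wakefield approximate Bayes factor computed from
the estimate, its standard error and a prior effect-size standard deviation.
The region-level posteriors weigh five hypotheses: no association (H0),
association with trait 1 only (H1), trait 2 only (H2), both traits via two
distinct causal variants (H3), and both traits via one shared causal variant
(H4).  The decision statistic is the conditional probability of a shared
variant given any joint signal, ``PP4/(PP3+PP4)``, thresholded at 0.9.

All evidence arithmetic is carried in log space with max-shift so the
computation is stable for |z| well beyond 50.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import SummaryTable

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}


class ColocError(ValueError):
    """Invalid colocalization input."""


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association with trait 1, trait 2, or both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ColocError("require 0 < p12 <= min(p1, p2)")

    def check_region(self, m: int) -> None:
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            raise ColocError(f"priors too large for a region of {m} variants")


@dataclass(frozen=True)
class ColocResult:
    """Posterior hypothesis probabilities and the conditional-H4 decision."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    conditional_h4: float
    n_snps: int
    decision: bool
    threshold: float = 0.9

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


@dataclass(frozen=True)
class RegionPair:
    """Aligned per-variant estimates for two traits over one genomic region."""

    variant_ids: tuple[str, ...]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    type1: str = "quantitative"
    type2: str = "binary"
    prior_sd1: float | None = None
    prior_sd2: float | None = None

    def __post_init__(self):
        m = len(self.variant_ids)
        for name in ("beta1", "se1", "beta2", "se2"):
            v = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, v)
            if v.shape != (m,):
                raise ColocError(f"{name} has length {v.size}, expected {m}")
        if m < 1:
            raise ColocError("region must contain at least one variant")

    @classmethod
    def from_tables(cls, t1: SummaryTable, t2: SummaryTable,
                    prior_sd1: float | None = None,
                    prior_sd2: float | None = None) -> "RegionPair":
        """Pair two tables on their shared variants (dropped ids are logged)."""
        shared = [v for v in t1.variant_ids if v in t2]
        n_dropped = (len(t1) - len(shared)) + (len(t2) - len(shared))
        if n_dropped:
            logger.info("RegionPair: %d variants missing from one trait were dropped", n_dropped)
        if not shared:
            raise ColocError("no shared variants between the two traits")
        d1 = t1.subset(shared).df
        d2 = t2.subset(shared).df
        return cls(tuple(shared), d1["beta"].to_numpy(), d1["se"].to_numpy(),
                   d2["beta"].to_numpy(), d2["se"].to_numpy(),
                   t1.trait_type, t2.trait_type, prior_sd1, prior_sd2)


def prior_sd_for(trait_type: str, user_value: float | None = None) -> float:
    """Prior SD of the true effect: user override, else 0.15 (quantitative, per-SD
    units) or 0.2 (binary, log-odds units)."""
    if user_value is not None:
        if user_value <= 0:
            raise ColocError("prior sd must be positive")
        return float(user_value)
    try:
        return DEFAULT_PRIOR_SD[trait_type]
    except KeyError:
        raise ColocError(f"unknown trait_type {trait_type!r}") from None


def log_abf(beta, se, prior_sd: float):
    """Log Wakefield approximate Bayes factor for association at one variant.

    With ``V = se^2``, ``W = prior_sd^2``, ``z = beta/se`` and
    ``r = W/(V+W)``: ``log ABF = 0.5*log(1-r) + z^2*r/2``.  Accepts scalars
    or aligned arrays.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ColocError("se and prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z * z * r
    return float(out) if out.ndim == 0 else out


def _log_h3(l1: np.ndarray, l2: np.ndarray, s1: float, s2: float, s12: float) -> float:
    """log sum_{i != j} BF1_i * BF2_j, stable against cancellation."""
    m = l1.size
    if m == 1:
        return -math.inf
    total = s1 + s2               # log sum_{i,j} BF1_i BF2_j
    diff = s12 - total            # <= 0 always
    if diff < -1e-10:
        return total + math.log1p(-math.exp(diff))
    # near-total cancellation (mass concentrated on the diagonal): sum pairs directly
    pair = l1[:, None] + l2[None, :]
    np.fill_diagonal(pair, -np.inf)
    return float(logsumexp(pair))


def coloc_abf(pair: RegionPair, priors: ColocPriors = ColocPriors(),
              threshold: float = 0.9) -> ColocResult:
    """Posterior colocalization probabilities under a single causal variant per trait.

    Per-SNP log-ABFs for the two traits are combined into log evidence for
    each hypothesis (H0 carries evidence 1 by convention; H1/H2 sum BFs over
    candidate causal variants; H3 sums over ordered distinct pairs; H4 over
    the shared variant), weighted by the per-SNP priors, and normalized.
    """
    m = len(pair.variant_ids)
    priors.check_region(m)
    sd1 = prior_sd_for(pair.type1, pair.prior_sd1)
    sd2 = prior_sd_for(pair.type2, pair.prior_sd2)
    l1 = np.atleast_1d(log_abf(pair.beta1, pair.se1, sd1))
    l2 = np.atleast_1d(log_abf(pair.beta2, pair.se2, sd2))
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    log_ev = np.array([
        0.0,
        math.log(priors.p1) + s1,
        math.log(priors.p2) + s2,
        math.log(priors.p1) + math.log(priors.p2) + _log_h3(l1, l2, s1, s2, s12),
        math.log(priors.p12) + s12,
    ])
    pp = np.exp(log_ev - logsumexp(log_ev))
    pp /= pp.sum()
    joint = pp[3] + pp[4]
    cond_h4 = float(pp[4] / joint) if joint > 0 else 0.0
    return ColocResult(*map(float, pp), conditional_h4=cond_h4, n_snps=m,
                       decision=cond_h4 >= threshold, threshold=threshold)
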