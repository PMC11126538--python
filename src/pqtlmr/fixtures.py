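"""A hand-constructed 10-SNP toy cis region exercising every selection rule.

Synthetic data (no real cohort measurements).  The region is built so that
rule application is unambiguous:

========  =========  ======================================================
variant   position   fate under the instrument-selection criteria
========  =========  ======================================================
rs001     1,000,000  lead pQTL (z=10) — selected
rs002     1,050,000  strong but r=0.9 with rs001 -> clumped out (r^2=0.81)
rs003       900,000  z=7, r=0.3 with rs001 (r^2=0.09) — selected
rs004     1,501,000  501 kb from the anchor -> outside the closed cis window
rs005     1,100,000  z=4 -> fails p < 5e-8
rs006       950,000  z=8 but EAF 0.03 -> fails MAF > 0.05
rs007     1,200,000  A/T at MAF 0.45 -> dropped as palindromic at harmonization
rs008       800,000  null (z=0.5)
rs009       905,000  z=6 but r=0.8 with rs003 -> clumped out (r^2=0.64)
rs010     1,400,000  null (z=1)
========  =========  ======================================================

Exactly two instruments (rs001, rs003) survive; both have outcome Wald ratio
0.2, so the combined causal estimate is 0.2 with zero heterogeneity.  The LD
matrix follows the correlation chain rs002 - rs001 - rs003 - rs009 (edge
correlations 0.9, 0.3, 0.8, implied products elsewhere), which is positive
definite by construction.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .instruments import CisLocus
from .ld import LDMatrix, validate_ld
from .sumstats import SummaryRecord, SummaryTable

N_EXP = 35_559
N_OUT = 100_000

_IDS = tuple(f"rs{i:03d}" for i in range(1, 11))
_POS = (1_000_000, 1_050_000, 900_000, 1_501_000, 1_100_000,
        950_000, 1_200_000, 800_000, 905_000, 1_400_000)
# (effect_allele, other_allele, eaf, z) for the exposure
_EXP = (("A", "G", 0.30, 10.0), ("C", "T", 0.40, 9.0), ("C", "T", 0.25, 7.0),
        ("A", "G", 0.40, 10.0), ("A", "C", 0.35, 4.0), ("G", "T", 0.03, 8.0),
        ("A", "T", 0.45, 6.5), ("A", "G", 0.20, 0.5), ("G", "A", 0.28, 6.0),
        ("C", "G", 0.33, 1.0))
_SE_EXP = 0.05
# outcome z-scores chosen so the usable instruments share Wald ratio 0.2
_OUT_Z = (10.0, 8.0, 7.0, 9.0, 1.0, 2.0, 3.0, 0.3, 5.0, 0.8)
_SE_OUT = 0.01


def _record(vid, chrom, pos, ea, oa, eaf, z, se, n, n_cases=None, n_controls=None):
    beta = z * se
    pval = float(np.clip(2.0 * stats.norm.sf(abs(z)), 5e-324, 1.0))
    return SummaryRecord(vid, chrom, pos, ea, oa, eaf, beta, se, pval, n,
                         n_cases, n_controls)


def toy_exposure() -> SummaryTable:
    recs = [_record(vid, "9", pos, ea, oa, eaf, z, _SE_EXP, N_EXP)
            for vid, pos, (ea, oa, eaf, z) in zip(_IDS, _POS, _EXP)]
    return SummaryTable.from_records("BGAT_toy", "quantitative", recs)


def toy_outcome() -> SummaryTable:
    """Binary outcome with rs003 on the swapped orientation (exercises flipping)
    and rs007 on the complementary palindromic labels."""
    recs = []
    for vid, pos, (ea, oa, eaf, z_exp), z in zip(_IDS, _POS, _EXP, _OUT_Z):
        if vid == "rs003":     # swapped alleles: beta and eaf complemented
            recs.append(_record(vid, "9", pos, oa, ea, 1 - eaf, -z, _SE_OUT,
                                N_OUT, 30_000, 70_000))
        elif vid == "rs007":   # palindromic, reported on the other strand label
            recs.append(_record(vid, "9", pos, oa, ea, 1 - eaf, z, _SE_OUT,
                                N_OUT, 30_000, 70_000))
        else:
            recs.append(_record(vid, "9", pos, ea, oa, eaf, z, _SE_OUT,
                                N_OUT, 30_000, 70_000))
    return SummaryTable.from_records("VH_toy", "binary", recs)


def toy_ld() -> LDMatrix:
    edges = {("rs002", "rs001"): 0.9, ("rs001", "rs003"): 0.3, ("rs003", "rs009"): 0.8}
    chain = ["rs002", "rs001", "rs003", "rs009"]
    r = np.eye(10)
    loc = {v: i for i, v in enumerate(_IDS)}
    for i, a in enumerate(chain):
        prod = 1.0
        for j in range(i + 1, len(chain)):
            prod *= edges[(chain[j - 1], chain[j])]
            r[loc[a], loc[chain[j]]] = r[loc[chain[j]], loc[a]] = prod
    return validate_ld(list(_IDS), r)


def toy_locus() -> CisLocus:
    return CisLocus(chrom="9", anchor_pos=1_000_000, window_bp=500_000)
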