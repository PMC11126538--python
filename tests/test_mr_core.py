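"""Wald ratio, generalized IVW, multivariable MR and Bonferroni control."""
import math

import numpy as np
import pytest

from pqtlmr import mr_core as mr
from pqtlmr.ld import validate_ld
from pqtlmr.sumstats import HarmonizedRow


def _row(vid, bx, sx, by, sy):
    return HarmonizedRow(vid, "9", 1, "A", "G", bx, sx, 0.3, 1e-10, 35_000,
                         by, sy, 0.3, 1e-4, 100_000, "kept")


# ---------------------------------------------------------------- Wald ratio

def test_wald_ratio_arithmetic():
    est = mr.wald_ratio(0.5, 0.05, 0.1, 0.02)
    assert est.beta_xy == pytest.approx(0.2)
    assert est.se == pytest.approx(0.04)
    assert est.n_snps == 1 and est.method == "wald"
    assert est.or_ == pytest.approx(math.exp(0.2))
    assert est.ci_low == pytest.approx(math.exp(0.2 - 1.959964 * 0.04))
    assert est.ci_high == pytest.approx(math.exp(0.2 + 1.959964 * 0.04))


def test_wald_ratio_sign_antisymmetry():
    plus = mr.wald_ratio(0.5, 0.05, 0.1, 0.02)
    minus = mr.wald_ratio(-0.5, 0.05, 0.1, 0.02)
    assert minus.beta_xy == pytest.approx(-plus.beta_xy)
    assert minus.se == pytest.approx(plus.se)


def test_wald_ratio_zero_exposure_errors():
    with pytest.raises(mr.MRError):
        mr.wald_ratio(0.0, 0.05, 0.1, 0.02)


def test_wald_first_order_close_to_second_order_for_strong_instruments(rng):
    """With relative exposure uncertainty < 5%, the first-order delta SE is
    within 5% of the second-order formula (independent oracle)."""
    for _ in range(200):
        bx = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
        sx = abs(bx) * rng.uniform(0.001, 0.05)
        sy = rng.uniform(0.005, 0.05)
        by = rng.uniform(-4, 4) * sy   # moderate outcome z: first-order regime
        first = mr.wald_ratio(bx, sx, by, sy)
        second_se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert first.se == pytest.approx(second_se, rel=0.05)
        second = mr.wald_ratio(bx, sx, by, sy, second_order=True)
        assert second.se == pytest.approx(second_se, rel=1e-12)


# ---------------------------------------------------------------- gIVW

def test_givw_single_instrument_equals_wald():
    row = _row("s1", 0.5, 0.05, 0.1, 0.02)
    ld = validate_ld(["s1"], np.eye(1))
    g = mr.givw([row], ld)
    w = mr.wald_ratio(0.5, 0.05, 0.1, 0.02)
    assert g.beta_xy == pytest.approx(w.beta_xy, abs=1e-12)
    assert g.se == pytest.approx(w.se, abs=1e-12)


def test_givw_perfect_fit_two_instruments():
    rows = [_row("s1", 0.5, 0.05, 0.1, 0.02), _row("s2", 0.3, 0.05, 0.06, 0.02)]
    ld = validate_ld(["s1", "s2"], np.eye(2))
    est = mr.givw(rows, ld)
    assert est.beta_xy == pytest.approx(0.2, abs=1e-12)
    assert est.q_stat == pytest.approx(0.0, abs=1e-18)
    assert est.re_inflation == 1.0


def _gls_oracle(x, y, s, r):
    """Explicit-inverse generalized least squares, no shared code with givw."""
    omega = np.diag(s) @ r @ np.diag(s)
    oinv = np.linalg.inv(omega)
    var = 1.0 / (x @ oinv @ x)
    beta = var * (x @ oinv @ y)
    resid = y - x * beta
    q = resid @ oinv @ resid
    return beta, math.sqrt(var), q


@pytest.mark.parametrize("seed", range(20))
def test_givw_matches_gls_oracle(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 11)
    rho = rng.uniform(-0.6, 0.6)
    idx = np.arange(k)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    x = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
    y = rng.normal(0.2 * x, 0.02)
    s = rng.uniform(0.01, 0.05, k)
    rows = [_row(f"s{i}", x[i], 0.01, y[i], s[i]) for i in range(k)]
    est = mr.givw(rows, validate_ld([f"s{i}" for i in range(k)], r))
    beta, se_naive, q = _gls_oracle(x, y, s, r)
    assert est.beta_xy == pytest.approx(beta, abs=1e-10)
    assert est.q_stat == pytest.approx(q, abs=1e-8)
    infl = max(1.0, math.sqrt(q / (k - 1)))
    assert est.se == pytest.approx(se_naive * infl, abs=1e-10)
    assert est.re_inflation == pytest.approx(infl, abs=1e-12)


def test_givw_identity_ld_equals_textbook_ivw(rng):
    """With identity LD the pre-inflation estimate equals fixed-effect IVW
    with weights beta_gx^2/se_gy^2."""
    k = 6
    x = rng.uniform(0.1, 0.5, k)
    y = rng.normal(0.15 * x, 0.03)
    s = rng.uniform(0.01, 0.05, k)
    rows = [_row(f"s{i}", x[i], 0.01, y[i], s[i]) for i in range(k)]
    est = mr.givw(rows, validate_ld([f"s{i}" for i in range(k)], np.eye(k)))
    w = x**2 / s**2
    ratios = y / x
    assert est.beta_xy == pytest.approx(np.sum(w * ratios) / np.sum(w), rel=1e-12)


def test_givw_scale_equivariance(rng):
    k = 4
    x = rng.uniform(0.1, 0.5, k)
    y = rng.normal(0.15 * x, 0.03)
    s = rng.uniform(0.01, 0.05, k)
    ld = validate_ld([f"s{i}" for i in range(k)], np.eye(k))
    a = mr.givw([_row(f"s{i}", x[i], 0.01, y[i], s[i]) for i in range(k)], ld)
    c = 3.0
    b = mr.givw([_row(f"s{i}", c * x[i], 0.01, y[i], s[i]) for i in range(k)], ld)
    assert b.beta_xy == pytest.approx(a.beta_xy / c, rel=1e-12)


def test_givw_singular_ld_rejected():
    rows = [_row("s1", 0.5, 0.05, 0.1, 0.02), _row("s2", 0.5, 0.05, 0.1, 0.02)]
    r = np.ones((2, 2))  # perfectly correlated instruments
    with pytest.raises(mr.MRError, match="positive definite"):
        mr.givw(rows, validate_ld(["s1", "s2"], r))


# ---------------------------------------------------------------- MVMR

def test_mvmr_single_exposure_reduces_to_givw(rng):
    k = 5
    x = rng.uniform(0.1, 0.5, k)
    y = rng.normal(0.2 * x, 0.02)
    s = rng.uniform(0.01, 0.05, k)
    rows = [_row(f"s{i}", x[i], 0.01, y[i], s[i]) for i in range(k)]
    ld = validate_ld([f"s{i}" for i in range(k)], np.eye(k))
    g = mr.givw(rows, ld)
    m = mr.mvmr({"expA": x}, rows, ld)["expA"]
    assert m.beta_xy == pytest.approx(g.beta_xy, abs=1e-10)
    assert m.se == pytest.approx(g.se, abs=1e-10)


def test_mvmr_orthogonal_blocks_match_per_exposure_givw(rng):
    """Two exposures with disjoint instrument support: direct effects equal
    the per-exposure gIVW estimates (block-diagonal GLS oracle)."""
    k = 8
    xa = np.concatenate([rng.uniform(0.2, 0.5, 4), np.zeros(4)])
    xb = np.concatenate([np.zeros(4), rng.uniform(0.2, 0.5, 4)])
    y = 0.3 * xa - 0.1 * xb + rng.normal(0, 0.005, k)
    s = np.full(k, 0.02)
    ids = [f"s{i}" for i in range(k)]
    rows = [_row(ids[i], xa[i] + xb[i], 0.01, y[i], s[i]) for i in range(k)]
    ld = validate_ld(ids, np.eye(k))
    res = mr.mvmr({"A": xa, "B": xb}, rows, ld)
    # oracle: explicit block GLS on each support
    for name, xcol, sl in (("A", xa, slice(0, 4)), ("B", xb, slice(4, 8))):
        beta_o, _, _ = _gls_oracle(xcol[sl], y[sl], s[sl], np.eye(4))
        assert res[name].beta_xy == pytest.approx(beta_o, abs=1e-10)


def test_mvmr_rank_deficiency_and_df_errors(rng):
    x = rng.uniform(0.1, 0.5, 4)
    rows = [_row(f"s{i}", x[i], 0.01, 0.2 * x[i], 0.02) for i in range(4)]
    ld = validate_ld([f"s{i}" for i in range(4)], np.eye(4))
    with pytest.raises(mr.MRError, match="collinear"):
        mr.mvmr({"A": x, "B": 2 * x}, rows, ld)
    with pytest.raises(mr.MRError, match="more instruments"):
        mr.mvmr({"A": x[:2], "B": [0.1, 0.2]}, rows[:2], ld.subset(["s0", "s1"]))


def test_mvmr_recovers_direct_effects_in_confounded_pair():
    """Exposure A causal (0.2), exposure B null but sharing correlated
    instruments: A's direct effect recovers 0.2 and B's covers 0."""
    rng = np.random.default_rng(42)
    n_rep = 300
    est_a, est_b, cover_b = [], [], 0
    k = 6
    ids = [f"s{i}" for i in range(k)]
    ld = validate_ld(ids, np.eye(k))
    for _ in range(n_rep):
        xa = rng.uniform(0.1, 0.4, k)
        xb = 0.6 * xa + rng.uniform(0.05, 0.2, k)   # correlated with A's effects
        se_y = np.full(k, 0.02)
        y = 0.2 * xa + rng.normal(0, se_y)
        rows = [_row(ids[i], xa[i], 0.01, y[i], se_y[i]) for i in range(k)]
        res = mr.mvmr({"A": xa, "B": xb}, rows, ld)
        est_a.append(res["A"].beta_xy)
        est_b.append(res["B"].beta_xy)
        lo = res["B"].beta_xy - 1.959964 * res["B"].se
        hi = res["B"].beta_xy + 1.959964 * res["B"].se
        cover_b += int(lo <= 0.0 <= hi)
    assert np.mean(est_a) == pytest.approx(0.2, abs=0.02)
    assert abs(np.mean(est_b)) < 0.02
    assert cover_b / n_rep > 0.90


# ---------------------------------------------------------------- Bonferroni

def test_bonferroni_values_and_cap():
    out = mr.bonferroni({"a": 0.003, "b": 0.2, "c": 1e-7}, 10)
    assert out["a"] == pytest.approx(0.03)
    assert out["b"] == 1.0
    assert out["c"] == pytest.approx(1e-6)


def test_bonferroni_input_validation():
    with pytest.raises(mr.MRError):
        mr.bonferroni({"a": 0.0}, 10)
    with pytest.raises(mr.MRError):
        mr.bonferroni({"a": 0.1, "b": 0.2}, 1)
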