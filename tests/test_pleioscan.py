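"""Two-step proteome-wide pleiotropy audit."""
import numpy as np
import pytest

from pqtlmr import pleioscan as ps
from pqtlmr.mr_core import MRError
from pqtlmr.synthetic import make_region, simulate_trait
from pqtlmr.sumstats import write_sumstats

from conftest import make_record, make_table


def _protein_table(pid, instrument_pval, rng, region=None, share_signal=False):
    """A small protein GWAS over 5 variants; v0 is the audited instrument."""
    recs = []
    for i in range(5):
        if i == 0:
            p = instrument_pval
            z = 7.0 if p < 5e-8 else 0.5
        else:
            p = float(rng.uniform(0.1, 1.0))
            z = 0.5
        recs.append(make_record(f"v{i}", "9", 1_000_000 + i * 1000, "A", "G",
                                0.3, z * 0.02, 0.02, p, 30_000))
    return make_table(recs, pid)


def _catalog(rng, n_proteins=20, n_signal=3):
    cat = ps.ProteinCatalog()
    for j in range(n_proteins):
        pid = f"prot{j:02d}"
        share = j < n_signal
        table = _protein_table(pid, 1e-9 if share else 0.3, rng)
        cat.add(pid, table, ["v0"])
    return cat


def test_empty_catalog_no_flags():
    assert ps.scan_instruments(["v0"], ps.ProteinCatalog()) == []


def test_single_protein_flagged(rng):
    cat = ps.ProteinCatalog()
    cat.add("protA", _protein_table("protA", 1e-9, rng), ["v0"])
    flags = ps.scan_instruments(["v0"], cat)
    assert [f.protein_id for f in flags] == ["protA"]


def test_exactly_constructed_proteins_flagged(rng):
    cat = _catalog(rng)
    flags = ps.scan_instruments(["v0"], cat)
    assert sorted({f.protein_id for f in flags}) == ["prot00", "prot01", "prot02"]


def test_exposure_excluded_and_missing_instrument_tolerated(rng):
    cat = _catalog(rng, n_proteins=3, n_signal=3)
    flags = ps.scan_instruments(["v0", "missing_rs"], cat, exclude="prot00")
    assert "prot00" not in {f.protein_id for f in flags}


def test_scan_threshold_zero_reduces_to_univariable(rng):
    cat = _catalog(rng)
    assert ps.scan_instruments(["v0"], cat, p_assoc=0.0) == []


# ------------------------------------------------------------- second step

def _outcome_table(rng, z0=0.0):
    recs = []
    for i in range(5):
        z = z0 if i == 0 else float(rng.normal(0, 1))
        recs.append(make_record(f"v{i}", "9", 1_000_000 + i * 1000, "A", "G",
                                0.3, z * 0.01, 0.01,
                                float(min(1.0, max(2 * 0.5 * np.exp(-z*z/2), 1e-300))),
                                100_000))
    return make_table(recs, "out", "binary")


def _ld5():
    from pqtlmr.ld import validate_ld
    return validate_ld([f"v{i}" for i in range(5)], np.eye(5))


def test_second_step_null_protein_nonsignificant(rng):
    cat = ps.ProteinCatalog()
    cat.add("protA", _protein_table("protA", 1e-9, rng), ["v0"])
    outcomes = {"out": _outcome_table(rng, z0=0.5)}
    flags = ps.scan_instruments(["v0"], cat)
    res = ps.second_step_mr(flags, cat, outcomes, _ld5(), m_tests=10)
    est = res[("protA", "out")]
    assert est.pval_bonferroni > 0.05


def test_second_step_m1_corrected_equals_raw(rng):
    cat = ps.ProteinCatalog()
    cat.add("protA", _protein_table("protA", 1e-9, rng), ["v0"])
    outcomes = {"out": _outcome_table(rng, z0=2.0)}
    flags = ps.scan_instruments(["v0"], cat)
    res = ps.second_step_mr(flags, cat, outcomes, _ld5(), m_tests=1)
    est = res[("protA", "out")]
    assert est.pval_bonferroni == pytest.approx(est.pval)


def test_second_step_true_effect_detected_with_power(rng):
    """A protein with true effect 0.3 on the outcome passes Bonferroni in
    >= 90% of replicates."""
    hits = 0
    n_rep = 100
    region = make_region(5, "identity", 0.0, seed=30)
    for rep in range(n_rep):
        prot = simulate_trait(region, np.array([0.1, 0, 0, 0, 0.0]),
                              "quantitative", 30_000, seed=rep, trait_id="protA")
        out = simulate_trait(region, 0.3 * np.array([0.1, 0, 0, 0, 0.0]),
                             "quantitative", 200_000, seed=10_000 + rep,
                             trait_id="out")
        cat = ps.ProteinCatalog()
        cat.add("protA", prot, [region.variant_ids[0]])
        res = ps.second_step_mr([ps.PleiotropyFlag("protA", region.variant_ids[0], 1e-9)],
                                cat, {"out": out}, region.ld, m_tests=10)
        est = res[("protA", "out")]
        hits += int(est.pval_bonferroni <= 0.05)
    assert hits / n_rep >= 0.9


def test_protein_without_instruments_skipped(rng):
    cat = ps.ProteinCatalog()
    cat.add("protA", _protein_table("protA", 1e-9, rng), [])
    res = ps.second_step_mr([ps.PleiotropyFlag("protA", "v0", 1e-9)], cat,
                            {"out": _outcome_table(rng)}, _ld5(), m_tests=1)
    assert res == {}


# ------------------------------------------------------------- MVMR adjustment

def _mvmr_setup(seed, pleio_effect):
    """Primary exposure with 3 instruments; covariate protein shares them."""
    rng = np.random.default_rng(seed)
    region = make_region(6, "identity", 0.0, seed=31)
    b_primary = np.array([0.1, 0.12, 0.09, 0, 0, 0])
    b_cov = np.array([0.05, 0.02, 0.08, 0, 0, 0])
    primary = simulate_trait(region, b_primary, "quantitative", 50_000,
                             seed=int(rng.integers(2**31)), trait_id="primary")
    cov = simulate_trait(region, b_cov, "quantitative", 50_000,
                         seed=int(rng.integers(2**31)), trait_id="cov")
    b_out = 0.2 * b_primary + pleio_effect * b_cov
    out = simulate_trait(region, b_out, "quantitative", 200_000,
                         seed=int(rng.integers(2**31)), trait_id="out")
    ids = list(region.variant_ids[:3])
    return primary, cov, out, region.ld, ids


def test_adjusted_close_to_unadjusted_when_covariate_null():
    diffs = []
    for seed in range(30):
        primary, cov, out, ld, ids = _mvmr_setup(seed, pleio_effect=0.0)
        from pqtlmr.mr_core import givw
        from pqtlmr.sumstats import harmonize
        rows = [r for r in harmonize(primary.subset(ids), out) if r.is_usable]
        unadj = givw(rows, ld)
        adj = ps.adjust_with_mvmr(primary, cov, out, ld, ids)
        diffs.append(adj.beta_xy - unadj.beta_xy)
    assert abs(np.mean(diffs)) < 0.02


def test_mediated_pleiotropy_adjusted_away():
    """Primary null, outcome driven through the covariate protein: the
    adjusted primary estimate covers zero."""
    rng = np.random.default_rng(5)
    region = make_region(6, "identity", 0.0, seed=32)
    cover = 0
    n_rep = 100
    for rep in range(n_rep):
        b_shared = np.array([0.1, 0.12, 0.09, 0, 0, 0])
        primary = simulate_trait(region, b_shared, "quantitative", 50_000,
                                 seed=3 * rep, trait_id="primary")
        cov = simulate_trait(region, b_shared * 0.8, "quantitative", 50_000,
                             seed=3 * rep + 1, trait_id="cov")
        out = simulate_trait(region, 0.25 * (b_shared * 0.8), "quantitative",
                             200_000, seed=3 * rep + 2, trait_id="out")
        ids = list(region.variant_ids[:3])
        try:
            adj = ps.adjust_with_mvmr(primary, cov, out, region.ld, ids)
        except (ps.PleioscanError, MRError):
            continue
        lo = adj.beta_xy - 1.959964 * adj.se
        hi = adj.beta_xy + 1.959964 * adj.se
        cover += int(lo <= 0.0 <= hi)
    assert cover / n_rep >= 0.85


def test_collinear_exposures_surface_rank_error():
    region = make_region(6, "identity", 0.0, seed=33)
    b = np.array([0.1, 0.12, 0.09, 0, 0, 0])
    primary = simulate_trait(region, b, "quantitative", 50_000, seed=1,
                             trait_id="primary", noise=False)
    clone = simulate_trait(region, b, "quantitative", 50_000, seed=1,
                           trait_id="clone", noise=False)
    out = simulate_trait(region, 0.2 * b, "quantitative", 200_000, seed=2,
                         trait_id="out")
    ids = list(region.variant_ids[:3])
    with pytest.raises(MRError, match="collinear"):
        ps.adjust_with_mvmr(primary, clone, out, region.ld, ids)


def test_manifest_round_trip(tmp_path, rng):
    region = make_region(5, "identity", 0.0, seed=34)
    table = simulate_trait(region, np.zeros(5), "quantitative", 30_000, seed=35,
                           trait_id="protA")
    write_sumstats(table, tmp_path / "protA.tsv")
    (tmp_path / "protA_instruments.txt").write_text(
        region.variant_ids[0] + "\n")
    (tmp_path / "manifest.tsv").write_text(
        "protein_id\tsumstats_path\tinstruments_path\n"
        "protA\tprotA.tsv\tprotA_instruments.txt\n")
    cat = ps.ProteinCatalog.from_manifest(tmp_path / "manifest.tsv")
    assert cat.protein_ids == ["protA"]
    assert cat.instruments["protA"] == [region.variant_ids[0]]
    assert len(cat.sumstats["protA"]) == 5
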