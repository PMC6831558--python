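import numpy as np
import pytest

from jawstrain.synth import make_invivo
from jawstrain.validation import (InVivoSample, arc_contains, covering_arc,
                                  read_invivo, validate_gauge, whisker_bounds,
                                  write_invivo)


def make_sample(e1, e_min=None, theta=None, gauge="ULAT"):
    e1 = np.asarray(e1, dtype=float)
    if e_min is None:
        e_min = -e1
    if theta is None:
        theta = np.linspace(40, 80, e1.size)
    return InVivoSample(gauge=gauge, e1=e1, e_min=np.asarray(e_min, dtype=float),
                        orientation_deg=np.asarray(theta, dtype=float))


def test_whisker_bounds_1_to_8():
    # linear-interpolation quartiles of {1..8}: Q1=2.75, Q3=6.25, IQR=3.5
    q1, q3, lo, hi = whisker_bounds(np.arange(1.0, 9.0))
    assert q1 == pytest.approx(2.75)
    assert q3 == pytest.approx(6.25)
    assert lo == pytest.approx(-2.5)
    assert hi == pytest.approx(11.5)


def test_whisker_bounds_constant_sample():
    q1, q3, lo, hi = whisker_bounds(np.full(6, 42.0))
    assert q1 == q3 == lo == hi == 42.0


def test_whisker_bounds_needs_4():
    with pytest.raises(ValueError, match=">= 4"):
        whisker_bounds(np.array([1.0, 2.0, 3.0]))


def test_planted_quartiles_recovered_at_large_n():
    s = make_invivo("LLAT", 40_000,
                    e1_plant=dict(median=103.0, iqr=60.0, min=10.0, max=208.0),
                    emin_plant=dict(median=-84.0, iqr=50.0, min=-168.0, max=-4.0),
                    orientation_arc=(250.0, 80.0), seed=3)
    assert np.median(s.e1) == pytest.approx(103.0, rel=0.02)
    q1, q3, _, _ = whisker_bounds(s.e1)
    assert q3 - q1 == pytest.approx(60.0, rel=0.02)
    assert s.e1.min() >= 10.0 - 1e-9 and s.e1.max() <= 208.0 + 1e-9
    start, width = covering_arc(s.orientation_deg)
    assert arc_contains((250.0, 80.0), (start, width))


def test_invivo_minimal_and_deterministic():
    kw = dict(e1_plant=dict(median=100.0, iqr=40.0, min=20.0, max=200.0),
              emin_plant=dict(median=-90.0, iqr=30.0, min=-180.0, max=-10.0),
              orientation_arc=(10.0, 30.0))
    a = make_invivo("MED", 4, seed=9, **kw)
    b = make_invivo("MED", 4, seed=9, **kw)
    np.testing.assert_array_equal(a.e1, b.e1)
    with pytest.raises(ValueError, match="n >= 4"):
        make_invivo("MED", 3, seed=0, **kw)


def test_infeasible_plant_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        make_invivo("MED", 10,
                    e1_plant=dict(median=100.0, iqr=80.0, min=90.0, max=120.0),
                    emin_plant=dict(median=-90.0, iqr=30.0, min=-180.0, max=-10.0),
                    orientation_arc=(0.0, 10.0), seed=0)


# ---------------------------------------------------------------------------
# verdict designs
# ---------------------------------------------------------------------------

def test_verdict_pass_when_median_matches():
    vivo = make_sample(np.arange(10.0, 90.0, 10.0))
    med = float(np.median(vivo.e1))
    verdicts, orient = validate_gauge(np.full(5, med * 1.0), np.full(5, -med),
                                      np.full(5, 60.0), vivo)
    v_e1 = next(v for v in verdicts if v.quantity == "e1")
    assert v_e1.within_whiskers and v_e1.within_range
    assert orient.within_range


def test_verdict_fail_whiskers_pass_range():
    """A heavy-tailed in-vivo sample puts its max beyond the whisker: an FEM
    median between the two passes the range check but not the whisker check."""
    vivo = make_sample(np.array([10.0, 10.0, 11.0, 11.0, 12.0, 12.0, 300.0]))
    _, _, _, hi = whisker_bounds(vivo.e1)
    assert hi < 300.0
    fem = np.full(5, (hi + 300.0) / 2.0)
    verdicts, _ = validate_gauge(fem, -fem, np.full(5, 60.0), vivo)
    v_e1 = next(v for v in verdicts if v.quantity == "e1")
    assert not v_e1.within_whiskers
    assert v_e1.within_range


def test_verdict_boundary_median_on_whisker_passes():
    vivo = make_sample(np.arange(1.0, 9.0))
    _, _, _, hi = whisker_bounds(vivo.e1)
    verdicts, _ = validate_gauge(np.full(3, hi), np.full(3, -1.0), np.full(3, 50.0), vivo)
    assert next(v for v in verdicts if v.quantity == "e1").within_whiskers


def test_verdict_fail_both_beyond_range():
    vivo = make_sample(np.arange(1.0, 9.0))
    verdicts, _ = validate_gauge(np.full(3, 1e4), np.full(3, -2.0), np.full(3, 50.0), vivo)
    v_e1 = next(v for v in verdicts if v.quantity == "e1")
    assert not v_e1.within_whiskers and not v_e1.within_range


def test_orientation_verdicts_on_circle():
    # in-vivo arc straddling 0: {350..20}; FEM inside vs outside
    vivo = make_sample(np.arange(1.0, 9.0), theta=np.array([350.0, 355.0, 5.0, 10.0,
                                                            15.0, 20.0, 0.0, 358.0]))
    _, orient = validate_gauge(np.full(4, 4.0), np.full(4, -4.0),
                               np.array([355.0, 2.0, 8.0, 12.0]), vivo)
    assert orient.within_range
    _, orient2 = validate_gauge(np.full(4, 4.0), np.full(4, -4.0),
                                np.array([100.0, 120.0]), vivo)
    assert not orient2.within_range


def test_covering_arc_wraparound():
    start, width = covering_arc(np.array([350.0, 10.0]))
    assert start == pytest.approx(350.0) and width == pytest.approx(20.0)
    assert arc_contains((340.0, 40.0), (start, width))
    assert not arc_contains((start, width), (340.0, 40.0))


def test_verdicts_invariant_to_order_and_scale(rng):
    vivo_vals = rng.uniform(50, 150, size=30)
    theta = rng.uniform(30, 90, size=30)
    fem = rng.uniform(80, 120, size=12)
    base = make_sample(vivo_vals, theta=theta)
    shuffled = make_sample(rng.permutation(vivo_vals), theta=rng.permutation(theta))
    for scale in (1.0, 2.5):
        va, oa = validate_gauge(fem * scale, -fem * scale, np.full(12, 60.0),
                                make_sample(vivo_vals * scale, theta=theta))
        vb, ob = validate_gauge(fem * scale, -fem * scale, np.full(12, 60.0),
                                make_sample(rng.permutation(vivo_vals) * scale, theta=theta))
        assert [v.within_whiskers for v in va] == [v.within_whiskers for v in vb]
        assert oa.within_range == ob.within_range
    del base, shuffled


def test_whiskers_imply_range_when_whiskers_inside():
    vivo = make_sample(np.array([1.0, 40.0, 50.0, 60.0, 100.0]))
    q1, q3, lo, hi = whisker_bounds(vivo.e1)
    if lo >= vivo.e1.min() and hi <= vivo.e1.max():
        fem = np.full(3, (lo + hi) / 2)
        verdicts, _ = validate_gauge(fem, -fem, np.full(3, 10.0), vivo)
        for v in verdicts:
            if v.within_whiskers:
                assert v.within_range


def test_gauge_name_mismatch_rejected():
    vivo = make_sample(np.arange(1.0, 9.0), gauge="MED")
    with pytest.raises(ValueError, match="mismatch"):
        validate_gauge(np.ones(3), -np.ones(3), np.ones(3), vivo, gauge="ULAT")


def test_invivo_csv_roundtrip(tmp_path):
    samples = {
        "ULAT": make_sample(np.arange(10.0, 18.0)),
        "MED": make_sample(np.arange(5.0, 13.0), gauge="MED"),
    }
    path = tmp_path / "invivo.csv"
    write_invivo(samples, path)
    back = read_invivo(path)
    assert set(back) == {"ULAT", "MED"}
    np.testing.assert_allclose(back["ULAT"].e1, samples["ULAT"].e1)
    np.testing.assert_allclose(back["MED"].orientation_deg,
                               samples["MED"].orientation_deg)
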