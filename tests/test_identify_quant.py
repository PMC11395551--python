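"""Retention indices, quantitation arithmetic, rOAV and class totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aromakey as ak
from aromakey import identify_quant as iq


# ---------------------------------------------------------------------------
# retention index
# ---------------------------------------------------------------------------

def test_ri_equals_100n_at_every_alkane(simple_ladder):
    for n, rt in simple_ladder.entries:
        ri = iq.compute_retention_index(rt, simple_ladder)
        assert ri.value == pytest.approx(100.0 * n, abs=1e-9)
        assert not ri.extrapolated


def test_ri_linear_midpoint(simple_ladder):
    rts = dict(simple_ladder.entries)
    mid = (rts[10] + rts[11]) / 2
    assert iq.compute_retention_index(mid, simple_ladder).value == \
        pytest.approx(1050.0)


def test_ri_hand_case_between_c7_and_c8():
    # rt 6.5 min sits half way along the C7(5.0)–C8(8.0) segment
    ladder = ak.AlkaneLadder(entries=((7, 5.0), (8, 8.0)))
    assert iq.compute_retention_index(6.5, ladder).value == pytest.approx(750.0)


def test_ri_brute_force_interpolation_oracle(simple_ladder):
    # independent oracle: numpy interp over the (rt, 100*carbon) nodes
    rng = np.random.default_rng(11)
    rts = np.array(simple_ladder.retention_times)
    ris = 100.0 * np.array(simple_ladder.carbons)
    for rt in rng.uniform(rts[0], rts[-1], size=200):
        expected = float(np.interp(rt, rts, ris))
        got = iq.compute_retention_index(float(rt), simple_ladder)
        assert got.value == pytest.approx(expected, abs=1e-9)
        assert not got.extrapolated


def test_ri_extrapolation_flagged(simple_ladder):
    lo = simple_ladder.retention_times[0]
    hi = simple_ladder.retention_times[-1]
    assert iq.compute_retention_index(lo - 1.0, simple_ladder).extrapolated
    assert iq.compute_retention_index(hi + 1.0, simple_ladder).extrapolated
    # nearest-segment slope: ladder is affine, so extension stays exact
    assert iq.compute_retention_index(lo - 3.0, simple_ladder).value == \
        pytest.approx(600.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=60.0),
       st.floats(min_value=0.001, max_value=5.0))
def test_ri_strictly_monotone(rt, delta):
    ladder = ak.AlkaneLadder(entries=tuple(
        (n, 5.0 + 3.0 * (n - 7)) for n in range(7, 21)))
    a = iq.compute_retention_index(rt, ladder).value
    b = iq.compute_retention_index(rt + delta, ladder).value
    assert b > a


def test_ri_inversion_round_trip(simple_ladder):
    for ri in (700.0, 912.3, 1555.5, 2000.0):
        rt = iq.invert_retention_index(ri, simple_ladder)
        assert iq.compute_retention_index(rt, simple_ladder).value == \
            pytest.approx(ri, abs=1e-9)


# ---------------------------------------------------------------------------
# library matching
# ---------------------------------------------------------------------------

def test_match_exact_single(tiny_library):
    hits = iq.match_library(1860.0, tiny_library, tolerance=15.0)
    assert [h[0].name for h in hits] == ["guaiacol"]


def test_match_nothing_within_tolerance(tiny_library):
    assert iq.match_library(1000.0, tiny_library, tolerance=15.0) == []


def test_match_tie_breaks_lexicographically():
    lib = [
        ak.CompoundLibraryEntry("zeta", "other", ref_ri=1010.0),
        ak.CompoundLibraryEntry("alpha", "other", ref_ri=990.0),
    ]
    hits = iq.match_library(1000.0, lib, tolerance=15.0)
    assert [h[0].name for h in hits] == ["alpha", "zeta"]
    assert hits[0][1] == hits[1][1] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# quantitation
# ---------------------------------------------------------------------------

SPEC = ak.InternalStandardSpec()  # 5 µL × 180 µg/mL into 3 g


def _peak(area, name="x"):
    return ak.PeakRecord("S1", 1, name, 10.0, area)


def test_quantify_equal_areas_gives_0p3():
    q = iq.quantify_peak(_peak(1e6), 1e6, SPEC)
    assert q.concentration == pytest.approx(0.3)


def test_quantify_zero_area_is_zero():
    assert iq.quantify_peak(_peak(0.0), 1e6, SPEC).concentration == 0.0


def test_quantify_ratio_2p5():
    q = iq.quantify_peak(_peak(2.5e6), 1e6, SPEC)
    assert q.concentration == pytest.approx(0.75)


def test_quantify_rejects_nonpositive_is_area():
    with pytest.raises(iq.QuantitationError):
        iq.quantify_peak(_peak(1.0), 0.0, SPEC)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-3, max_value=1e9),
       st.floats(min_value=1e-3, max_value=1e9))
def test_quantify_linearity(ax, as_area):
    base = iq.quantify_peak(_peak(ax), as_area, SPEC).concentration
    doubled = iq.quantify_peak(_peak(2 * ax), as_area, SPEC).concentration
    assert doubled == pytest.approx(2 * base, rel=1e-12)
    heavy = ak.InternalStandardSpec(Cs=SPEC.Cs, Vs=SPEC.Vs, mx=2 * SPEC.mx)
    halved = iq.quantify_peak(_peak(ax), as_area, heavy).concentration
    assert halved == pytest.approx(base / 2, rel=1e-12)


# ---------------------------------------------------------------------------
# rOAV
# ---------------------------------------------------------------------------

def test_roav_threshold_identity():
    # Ci = 0.0015 µg/g = 1.5 µg/kg against OT 1.5 µg/kg
    assert iq.roav(0.0015, 1.5) == pytest.approx(1.0)


def test_roav_zero_and_hand_case():
    assert iq.roav(0.0, 1.5) == 0.0
    assert iq.roav(0.003, 1.5) == pytest.approx(2.0)


def test_roav_undefined_without_threshold():
    assert iq.roav(1.0, None) is None


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1e3),
       st.floats(min_value=1e-6, max_value=1e6),
       st.floats(min_value=1e-3, max_value=1e3))
def test_roav_scale_invariance(ci, oti, factor):
    a = iq.roav(ci, oti)
    b = iq.roav(ci * factor, oti * factor)
    assert b == pytest.approx(a, rel=1e-9)


# ---------------------------------------------------------------------------
# class aggregation
# ---------------------------------------------------------------------------

def _quant_frame(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "replicate", "compound_name", "concentration"])


def test_aggregate_hand_case_25_percent():
    lib = [ak.CompoundLibraryEntry("a1", "acid", odor_threshold=1.0),
           ak.CompoundLibraryEntry("a2", "acid", odor_threshold=1.0)]
    quant = _quant_frame([
        ("S1", 1, "a1", 1.0), ("S1", 1, "a2", 1.4),
        ("S4", 1, "a1", 1.0), ("S4", 1, "a2", 2.0),
    ])
    agg = iq.aggregate_classes(quant, lib, "S1")
    acid_s4 = agg[(agg.sample_id == "S4") & (agg.chem_class == "acid")]
    assert acid_s4["total"].iloc[0] == pytest.approx(3000.0)  # µg/kg
    assert acid_s4["pct_change_vs_reference"].iloc[0] == pytest.approx(25.0)


def test_aggregate_same_totals_zero_change():
    lib = [ak.CompoundLibraryEntry("k", "ketone")]
    quant = _quant_frame([("S1", 1, "k", 2.0), ("S2", 1, "k", 2.0)])
    agg = iq.aggregate_classes(quant, lib, "S1")
    assert (agg["pct_change_vs_reference"].abs() < 1e-12).all()


def test_aggregate_empty_class_is_minus_100():
    lib = [ak.CompoundLibraryEntry("k", "ketone"),
           ak.CompoundLibraryEntry("p", "phenol")]
    quant = _quant_frame([
        ("S1", 1, "k", 2.0), ("S1", 1, "p", 1.0), ("S2", 1, "k", 2.0)])
    agg = iq.aggregate_classes(quant, lib, "S1")
    phenol_s2 = agg[(agg.sample_id == "S2") & (agg.chem_class == "phenol")]
    assert phenol_s2["total"].iloc[0] == 0.0
    assert phenol_s2["pct_change_vs_reference"].iloc[0] == pytest.approx(-100.0)


def test_aggregate_missing_reference_errors():
    lib = [ak.CompoundLibraryEntry("k", "ketone")]
    quant = _quant_frame([("S1", 1, "k", 2.0)])
    with pytest.raises(ValueError, match="reference"):
        iq.aggregate_classes(quant, lib, "S9")


def test_class_totals_conserve_grand_total(fixture_bundle, fixture_result):
    agg = fixture_result.class_totals
    for s, sub in agg.groupby("sample_id"):
        grand = sub.loc[sub.chem_class == "grand_total", "total"].iloc[0]
        parts = sub.loc[sub.chem_class != "grand_total", "total"].sum()
        assert parts == pytest.approx(grand, rel=1e-9)


# ---------------------------------------------------------------------------
# full quantitation table
# ---------------------------------------------------------------------------

def test_quantify_table_excludes_internal_standard(fixture_bundle,
                                                   fixture_result):
    names = set(fixture_result.quantified["compound_name"])
    assert fixture_bundle.is_spec.compound_name not in names
    assert len(names) == 99
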