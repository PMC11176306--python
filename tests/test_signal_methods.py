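"""Analytical-signal transforms: worked examples, guards, algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from padquant import (
    METHOD_IDS,
    METHODS,
    BlankReference,
    ZoneMeasurement,
    compute_all_signals,
    compute_signal,
    multi_zone_ed,
    rgb_to_hsv,
)
from padquant.exceptions import (
    ConfigurationError,
    DivisionGuardError,
    DomainError,
    PairingError,
)
from padquant.signal_methods import HSVTriple, MethodSpec, hsv_to_rgb


def zone(r, g, b, zid="z", conc=None):
    return ZoneMeasurement(zid, conc, float(r), float(g), float(b))


BLANK = BlankReference(200.0, 200.0, 200.0)


class TestComputeSignal:
    @pytest.mark.parametrize(
        "method_id, rgb, blank, expected",
        [
            (1, (100, 150, 200), None, 100.0),
            (4, (100, 150, 200), None, 150.0),
            (18, (200, 200, 200), BLANK, 0.0),                      # zone == blank
            (6, (50, 100, 50), BLANK, math.log10(2.0)),             # G0/G = 200/100
            (19, (100, 100, 100), BLANK, math.log10(8.0)),          # product ratio 1/8
            (12, (90, 120, 90), None, 300.0 / 90.0),
            (8, (150, 150, 150), BLANK, 50.0),
            (11, (150, 140, 130), BLANK, 50.0 + 60.0 + 70.0),
            (15, (90, 120, 90), None, 0.75),
        ],
    )
    def test_worked_examples(self, method_id, rgb, blank, expected):
        value = compute_signal(method_id, zone(*rgb), blank).value
        assert value == pytest.approx(expected, abs=1e-12)

    def test_missing_blank_raises(self):
        with pytest.raises(ConfigurationError, match="blank"):
            compute_signal(18, zone(1, 2, 3))

    @pytest.mark.parametrize("method_id", [14, 16])
    def test_zero_denominator_guard(self, method_id):
        with pytest.raises(DivisionGuardError, match="B"):
            compute_signal(method_id, zone(100, 100, 0))

    def test_log_domain_guard(self):
        with pytest.raises(DomainError):
            compute_signal(5, zone(0, 100, 100), BLANK)

    def test_clamp_option(self):
        v = compute_signal(5, zone(0, 100, 100), BLANK, clamp=True).value
        assert v == pytest.approx(math.log10(200.0))

    def test_gamma_scales_log_product(self):
        spec = MethodSpec(19, "-log(RGB/R0G0B0)", "m19_logprod", True, gamma=2.0)
        v1 = compute_signal(19, zone(100, 100, 100), BLANK).value
        v2 = compute_signal(spec, zone(100, 100, 100), BLANK).value
        assert v2 == pytest.approx(2.0 * v1)

    def test_configurable_log_base(self):
        v = compute_signal(6, zone(50, 100, 50), BLANK, log_base=math.e).value
        assert v == pytest.approx(math.log(2.0))


class TestComputeAllSignals:
    def test_complete_table(self):
        zones = [zone(150, 160, 170, f"z{i}", conc=10.0 * i) for i in range(3)]
        table = compute_all_signals(zones, BLANK)
        method_cols = [METHODS[i].column for i in METHOD_IDS]
        assert list(table.columns[:3]) == ["zone_id", "concentration", "replicate"]
        assert table[method_cols].notna().all().all()
        assert table[method_cols].size == 57

    def test_guard_failures_become_nan(self):
        zones = [zone(100, 100, 0, "bad"), zone(100, 100, 100, "ok")]
        table = compute_all_signals(zones, BLANK)
        bad = table.set_index("zone_id").loc["bad"]
        assert np.isnan(bad["m14_sumoverB"]) and np.isnan(bad["m16_GoverB"])
        # every transform with B in a denominator or a logarithm fails too
        assert np.isnan(bad["m17_RoverB"])
        assert np.isnan(bad["m07_logB"]) and np.isnan(bad["m19_logprod"])
        others = [
            METHODS[i].column for i in METHOD_IDS if i not in (7, 14, 16, 17, 19)
        ]
        assert bad[others].notna().all()
        ok = table.set_index("zone_id").loc["ok"]
        assert ok[[METHODS[i].column for i in METHOD_IDS]].notna().all()

    def test_matches_single_calls(self):
        rng = np.random.default_rng(3)
        zones = [zone(*rng.uniform(50, 250, 3), f"z{i}") for i in range(4)]
        table = compute_all_signals(zones, BLANK).set_index("zone_id")
        for z in zones:
            for mid in METHOD_IDS:
                expected = compute_signal(mid, z, BLANK).value
                assert table.loc[z.zone_id, METHODS[mid].column] == expected

    def test_hsv_columns_optional(self):
        table = compute_all_signals([zone(255, 0, 0)], BLANK, include_hsv=True)
        assert table.loc[0, "hue_deg"] == 0.0
        assert table.loc[0, "sat_pct"] == 100.0


class TestMultiZoneED:
    def test_three_four_five(self):
        v = multi_zone_ed([zone(10, 20, 30)], [BlankReference(13, 24, 30)])
        assert v.value == pytest.approx(5.0)

    def test_two_identical_pairs(self):
        zones = [zone(10, 20, 30)] * 2
        blanks = [BlankReference(13, 24, 30)] * 2
        assert multi_zone_ed(zones, blanks).value == pytest.approx(math.sqrt(50.0))

    def test_zero_when_zones_equal_blanks(self):
        zones = [zone(10, 20, 30), zone(40, 50, 60)]
        blanks = [BlankReference(10, 20, 30), BlankReference(40, 50, 60)]
        assert multi_zone_ed(zones, blanks).value == 0.0

    def test_single_pair_equals_method_18(self):
        z = zone(140, 150, 160)
        assert multi_zone_ed([z], [BLANK]).value == compute_signal(18, z, BLANK).value

    def test_pairing_mismatch(self):
        with pytest.raises(PairingError):
            multi_zone_ed([zone(1, 2, 3)], [])


class TestRgbToHsv:
    def test_pure_red(self):
        hsv = rgb_to_hsv((255.0, 0.0, 0.0))
        assert (hsv.H, hsv.S, hsv.V) == (0.0, 100.0, 100.0)

    def test_grey_axis(self):
        hsv = rgb_to_hsv((128.0, 128.0, 128.0))
        assert hsv.H == 0.0 and hsv.S == 0.0
        assert hsv.V == pytest.approx(100.0 * 128.0 / 255.0, abs=1e-9)

    def test_matches_independent_implementation(self):
        from skimage.color import rgb2hsv

        rng = np.random.default_rng(19)
        for rgb in rng.uniform(0, 255, size=(50, 3)):
            ours = rgb_to_hsv(tuple(rgb))
            h, s, v = rgb2hsv(rgb[None, None, :] / 255.0)[0, 0]
            assert ours.H == pytest.approx((h * 360.0) % 360.0, abs=1e-6)
            assert ours.S == pytest.approx(s * 100.0, abs=1e-6)
            assert ours.V == pytest.approx(v * 100.0, abs=1e-6)


channels = st.floats(min_value=1.0, max_value=255.0, allow_nan=False)
triple = st.tuples(channels, channels, channels)


@settings(max_examples=200, derandomize=True)
@given(rgb=triple, blank_rgb=triple)
def test_method_identities(rgb, blank_rgb):
    """The averaged, summed and log-product transforms decompose exactly
    into their per-channel constituents."""
    z = zone(*rgb)
    blank = BlankReference(*blank_rgb)
    v = {m: compute_signal(m, z, blank).value for m in METHOD_IDS}
    assert v[4] == (v[1] + v[2] + v[3]) / 3.0
    assert v[11] == v[8] + v[9] + v[10]
    assert v[19] == pytest.approx(v[5] + v[6] + v[7], abs=1e-12)
    assert v[18] ** 2 == pytest.approx(v[8] ** 2 + v[9] ** 2 + v[10] ** 2, abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(rgb=triple, blank_rgb=triple)
def test_euclidean_distance_nonnegative(rgb, blank_rgb):
    """ED is a metric distance: non-negative, zero only at the blank itself."""
    z = zone(*rgb)
    blank = BlankReference(*blank_rgb)
    v = compute_signal(18, z, blank).value
    assert v >= 0.0
    if v == 0.0:
        assert rgb == blank_rgb


@settings(max_examples=200, derandomize=True)
@given(rgb=st.tuples(
    st.floats(min_value=0.0, max_value=255.0),
    st.floats(min_value=0.0, max_value=255.0),
    st.floats(min_value=0.0, max_value=255.0),
))
def test_hsv_roundtrip(rgb):
    """Hexcone conversion followed by its inverse recovers the channels."""
    back = hsv_to_rgb(rgb_to_hsv(rgb))
    assert all(abs(a - b) <= 0.5 for a, b in zip(back, rgb))
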