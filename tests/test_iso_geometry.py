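import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from doseresp.iso_geometry import (
    ROT_ANGLES,
    ZenithBand,
    band_weight,
    default_band_set,
    iso_response,
    iso_response_per_dosemeter,
    printed_weights,
)
from doseresp.response import ResponseValue
from doseresp.util import round_display


def quadrature_weight(lo, hi):
    """Independent oracle: numerically integrate the solid-angle density sin(t)/2."""
    val, _ = quad(lambda t: math.sin(t) / 2.0, math.radians(lo), math.radians(hi))
    return val


class TestBandWeight:
    @pytest.mark.parametrize(
        "lo,hi,printed",
        [(0, 45, 0.146), (45, 75, 0.224), (75, 105, 0.259), (105, 135, 0.224), (135, 180, 0.146)],
    )
    def test_printed_three_decimal_coefficients(self, lo, hi, printed):
        assert round(band_weight(lo, hi), 3) == printed

    @pytest.mark.parametrize("lo,hi", [(0, 45), (45, 75), (75, 105), (0, 180), (10, 17)])
    def test_closed_form_matches_quadrature(self, lo, hi):
        assert band_weight(lo, hi) == pytest.approx(quadrature_weight(lo, hi), abs=1e-9)

    def test_full_sphere_band(self):
        assert band_weight(0, 180) == pytest.approx(1.0)

    @pytest.mark.parametrize("lo,hi", [(45, 45), (60, 30), (-5, 45), (170, 190)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            band_weight(lo, hi)

    @given(
        cut=st.floats(1, 179),
    )
    @settings(max_examples=50, derandomize=True)
    def test_weights_additive_over_adjacent_bands(self, cut):
        assert band_weight(0, cut) + band_weight(cut, 180) == pytest.approx(1.0, abs=1e-12)


class TestDefaultBandSet:
    def test_partitions_the_sphere(self):
        bands = default_band_set()
        assert sum(b.weight for b in bands) == pytest.approx(1.0, abs=1e-12)
        edges = sorted((b.theta_lo, b.theta_hi) for b in bands)
        assert edges[0][0] == 0 and edges[-1][1] == 180
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            assert hi == lo

    def test_symmetric_pairs_equal(self):
        w = {b.representative_angle: b.weight for b in default_band_set()}
        assert w[30] == pytest.approx(w[150], abs=1e-15)
        assert w[60] == pytest.approx(w[120], abs=1e-15)

    def test_printed_weights_sum_to_0_999(self):
        pw = printed_weights()
        assert list(pw.values()) == [0.146, 0.224, 0.259, 0.224, 0.146]
        assert sum(pw.values()) == pytest.approx(0.999)

    def test_representative_angle_must_lie_in_band(self):
        with pytest.raises(ValueError, match="outside band"):
            ZenithBand(50, 0, 45)


def _rot(values, k=1.0):
    return {
        a: ResponseValue(v, 0.01, math.exp(1.96 * 0.01), 4)
        for a, v in zip(ROT_ANGLES, values)
    }


class TestIsoResponse:
    def test_epd_662_printed_weights(self):
        values = [0.87, 0.86, 0.87, 0.83, 0.64]
        weights = [0.146, 0.224, 0.259, 0.224, 0.146]
        rv = iso_response(_rot(values), weight_mode="printed")
        assert rv.mean_B == pytest.approx(
            sum(w * v for w, v in zip(weights, values)), rel=1e-12
        )
        assert round_display(rv.mean_B) == 0.82

    def test_gb_119_dot_product_oracle(self):
        values = [0.65, 0.80, 0.83, 0.82, 0.80]
        weights = [0.146, 0.224, 0.259, 0.224, 0.146]
        expected = sum(w * v for w, v in zip(weights, values))
        rv = iso_response(_rot(values), weight_mode="printed")
        assert rv.mean_B == pytest.approx(expected, rel=1e-12)
        assert round_display(rv.mean_B) == 0.79

    def test_constant_field_is_identity_with_exact_weights(self):
        rv = iso_response(_rot([0.9] * 5), weight_mode="exact")
        assert rv.mean_B == pytest.approx(0.9, rel=1e-12)

    def test_exact_weights_bounded_by_rot_extremes(self):
        values = [0.87, 0.86, 0.87, 0.83, 0.64]
        rv = iso_response(_rot(values), weight_mode="exact")
        assert min(values) <= rv.mean_B <= max(values)

    def test_angle_symmetric_field_invariant_under_reversal(self):
        values = [0.7, 0.8, 0.9, 0.8, 0.7]
        fwd = iso_response(_rot(values))
        rev = iso_response(_rot(values[::-1]))
        assert fwd.mean_B == pytest.approx(rev.mean_B, rel=1e-12)

    def test_missing_angle_named_in_error(self):
        rot = _rot([0.87, 0.86, 0.87, 0.83, 0.64])
        del rot[120.0]
        with pytest.raises(ValueError, match="120"):
            iso_response(rot)

    def test_all_nine_published_iso_cells(self, printed_responses, printed_rot_map):
        iso_printed = printed_responses[printed_responses["geometry"] == "ISO"]
        for row in iso_printed.itertuples():
            rot = printed_rot_map[(row.dosemeter_type, float(row.mean_energy_keV))]
            rv = iso_response(rot, weight_mode="printed")
            assert abs(round_display(rv.mean_B) - row.mean_B) <= 0.01 + 1e-12


class TestIsoPerDosemeter:
    def test_uniform_dosemeters_match_mean_level_synthesis(self):
        per = {a: {"d1": v, "d2": v} for a, v in zip(ROT_ANGLES, [0.8, 0.9, 1.0, 0.9, 0.8])}
        rv = iso_response_per_dosemeter(per)
        mean_level = iso_response(_rot([0.8, 0.9, 1.0, 0.9, 0.8]))
        assert rv.mean_B == pytest.approx(mean_level.mean_B, rel=1e-12)
        assert rv.K == 1.0  # identical dosemeters -> no spread after synthesis

    def test_angle_averaging_shrinks_k_below_single_angle(self):
        # dosemeter 2 reads high at 30 deg and low at 150 deg: averaging cancels
        per = {
            30.0: {"d1": 0.80, "d2": 0.90},
            60.0: {"d1": 0.85, "d2": 0.85},
            90.0: {"d1": 0.90, "d2": 0.90},
            120.0: {"d1": 0.85, "d2": 0.85},
            150.0: {"d1": 0.90, "d2": 0.80},
        }
        rv = iso_response_per_dosemeter(per)
        single_angle_k = math.exp(
            1.96 * abs(math.log(0.90) - math.log(0.80)) / math.sqrt(2)
        )
        assert rv.K < single_angle_k

    def test_requires_common_dosemeter(self):
        per = {a: {f"only-{a}": 1.0} for a in ROT_ANGLES}
        with pytest.raises(ValueError, match="dosemeter"):
            iso_response_per_dosemeter(per)
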