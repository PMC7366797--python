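import math

import pytest

from doseresp.datasets import load_facility_profiles, printed_response_map
from doseresp.response import ResponseValue
from doseresp.util import round_display
from doseresp.workenv import (
    DEFAULT_BAND_MIXES,
    FacilityProfile,
    band_response,
    facility_response,
)

# Published facility-level factors (type, facility) -> B
PUBLISHED_FACTORS = {
    ("EPD", "NPP"): 1.00, ("EPD", "MA"): 1.01,
    ("GB", "NPP"): 1.02, ("GB", "MA"): 1.02,
    ("LB", "NPP"): 1.06, ("LB", "MA"): 1.08,
}


def _rv(b, sd=0.01):
    return ResponseValue(b, sd, math.exp(1.96 * sd), 4)


class TestBandResponse:
    def test_arithmetic_mix_hand_computed(self):
        responses = {119.0: _rv(1.38), 207.0: _rv(1.35)}
        rv = band_response(DEFAULT_BAND_MIXES["band_100_300"], responses, "arithmetic")
        assert rv.mean_B == pytest.approx(0.25 * 1.38 + 0.75 * 1.35, rel=1e-12)

    def test_single_component_band_passes_through(self):
        rv = band_response(((662.0, 1.0),), {662.0: _rv(1.20)}, "log_scale")
        assert rv.mean_B == pytest.approx(1.20, rel=1e-12)

    def test_log_scale_equals_arithmetic_for_equal_components(self):
        responses = {119.0: _rv(0.9), 207.0: _rv(0.9)}
        mix = DEFAULT_BAND_MIXES["band_100_300"]
        a = band_response(mix, responses, "arithmetic")
        g = band_response(mix, responses, "log_scale")
        assert a.mean_B == pytest.approx(g.mean_B, rel=1e-12)

    def test_missing_energy_rejected(self):
        with pytest.raises(ValueError, match="207"):
            band_response(DEFAULT_BAND_MIXES["band_100_300"], {119.0: _rv(1.0)})


class TestFacilityResponse:
    @pytest.mark.parametrize("dtype,facility", sorted(PUBLISHED_FACTORS))
    def test_log_scale_reproduces_published_factors(self, dtype, facility):
        profile = load_facility_profiles()[facility]
        result = facility_response(profile, printed_response_map(dtype), dtype)
        published = PUBLISHED_FACTORS[(dtype, facility)]
        assert abs(round_display(result.B_workenv) - published) <= 0.01 + 1e-12

    @pytest.mark.parametrize(
        "dtype,facility", [("EPD", "NPP"), ("LB", "MA")]
    )
    def test_exact_cells(self, dtype, facility):
        profile = load_facility_profiles()[facility]
        result = facility_response(profile, printed_response_map(dtype), dtype)
        assert round_display(result.B_workenv) == PUBLISHED_FACTORS[(dtype, facility)]

    def test_arithmetic_overshoots_log_scale_slightly(self):
        # AM-GM: arithmetic >= geometric; on these inputs by ~0.02
        profile = load_facility_profiles()["NPP"]
        cells = printed_response_map("EPD")
        log_r = facility_response(profile, cells, "EPD", method="log_scale")
        ari_r = facility_response(profile, cells, "EPD", method="arithmetic")
        # flat arithmetic oracle: band mix, then energy and geometry weights
        band_ap = 0.25 * 1.38 + 0.75 * 1.35
        band_iso = 0.25 * 0.77 + 0.75 * 0.92
        expected = 0.5 * (0.1 * band_ap + 0.9 * 1.20) + 0.5 * (0.1 * band_iso + 0.9 * 0.82)
        assert ari_r.B_workenv == pytest.approx(expected, rel=1e-12)
        assert log_r.B_workenv < ari_r.B_workenv
        assert 0.01 < ari_r.B_workenv - log_r.B_workenv < 0.04

    def test_degenerate_profile_returns_single_cell(self):
        profile = FacilityProfile(
            "point",
            {"band_0_100": 0.0, "band_100_300": 0.0, "band_300_3000": 1.0},
            {"AP": 1.0, "ISO": 0.0, "ROT": 0.0},
        )
        cells = printed_response_map("EPD")
        for method in ("log_scale", "arithmetic"):
            r = facility_response(profile, cells, "EPD", method=method)
            assert r.B_workenv == pytest.approx(cells[(662.0, "AP")].mean_B, rel=1e-12)

    def test_result_bounded_by_used_cells(self):
        profile = load_facility_profiles()["MA"]
        cells = printed_response_map("LB")
        values = [rv.mean_B for rv in cells.values()]
        for method in ("log_scale", "arithmetic"):
            r = facility_response(profile, cells, "LB", method=method)
            assert min(values) <= r.B_workenv <= max(values)

    def test_missing_cell_named_in_error(self):
        profile = load_facility_profiles()["NPP"]
        cells = printed_response_map("EPD")
        del cells[(662.0, "ISO")]
        with pytest.raises(ValueError, match=r"662 keV, ISO"):
            facility_response(profile, cells, "EPD")

    def test_zero_band_weight_needs_no_mix(self):
        # the 0-100 keV band has zero weight in both presets and no measured cell
        profile = load_facility_profiles()["NPP"]
        r = facility_response(profile, printed_response_map("GB"), "GB")
        assert r.B_workenv > 0

    def test_nonzero_weight_on_unmapped_band_rejected(self):
        profile = FacilityProfile(
            "low-energy",
            {"band_0_100": 0.5, "band_100_300": 0.5, "band_300_3000": 0.0},
            {"AP": 1.0, "ISO": 0.0, "ROT": 0.0},
        )
        with pytest.raises(ValueError, match="band_0_100"):
            facility_response(profile, printed_response_map("GB"), "GB")

    def test_k_propagation_matches_published_uncertainties(self):
        # informative: independent-cell log-scale propagation lands on the
        # published facility-level K values to 3 decimals
        published_k = {
            ("EPD", "NPP"): 1.004, ("EPD", "MA"): 1.003,
            ("GB", "NPP"): 1.011, ("GB", "MA"): 1.011,
            ("LB", "NPP"): 1.037, ("LB", "MA"): 1.033,
        }
        profiles = load_facility_profiles()
        for (dtype, facility), k in published_k.items():
            r = facility_response(profiles[facility], printed_response_map(dtype), dtype)
            assert abs(round_display(r.K_workenv, 3) - k) <= 0.01

    def test_profile_fraction_validation(self):
        with pytest.raises(ValueError, match="sum"):
            FacilityProfile("bad", {"band_0_100": 0.5, "band_100_300": 0.1,
                                    "band_300_3000": 0.1},
                            {"AP": 0.5, "ISO": 0.5, "ROT": 0.0})
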