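import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arid14c.sic import (SICPartition, adjust_delta14c_for_sic,
                         f_sic_from_d13c, partition_site, screen_site,
                         sic_equilibrium_d13c)


class TestEquilibriumOffset:
    @pytest.mark.parametrize("d13c,expected", [
        (0.0, -9.6),     # calcite–CO₂ fractionation at 20 °C
        (9.6, 0.0),
        (-5.0, -14.6),
    ])
    def test_offset(self, d13c, expected):
        assert sic_equilibrium_d13c(d13c) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sic_equilibrium_d13c(float("nan"))


class TestFSic:
    def test_hand_arithmetic(self):
        est = f_sic_from_d13c(-20.0, -8.0, -24.0)
        assert est.value == pytest.approx(0.25)
        assert not est.clamped

    def test_pure_soc_endmember(self):
        assert f_sic_from_d13c(-24.0, -8.0, -24.0).value == 0.0

    def test_degenerate_endmembers_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            f_sic_from_d13c(-20.0, -24.0, -24.0)

    def test_clamping_flags(self):
        assert f_sic_from_d13c(-30.0, -8.0, -24.0) == (0.0, True)
        assert f_sic_from_d13c(-4.0, -8.0, -24.0) == (1.0, True)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_mixture_round_trip(self, data):
        d_soc = data.draw(st.floats(-30.0, -20.0))
        d_sic_eq = data.draw(st.floats(-15.0, 0.0))
        f = data.draw(st.floats(0.0, 1.0))
        if abs(d_sic_eq - d_soc) < 2.0:
            return
        mixture = f * d_sic_eq + (1.0 - f) * d_soc
        assert f_sic_from_d13c(mixture, d_sic_eq, d_soc).value == \
            pytest.approx(f, abs=1e-9)


class TestAdjustDelta14C:
    def test_hand_arithmetic(self):
        assert adjust_delta14c_for_sic(-100.0, 0.25, -600.0) == \
            pytest.approx(66.6667, abs=1e-3)

    def test_zero_fraction_identity_and_fixed_point(self):
        assert adjust_delta14c_for_sic(-123.4, 0.0, -1000.0) == -123.4
        # when total CO₂ equals the SIC endmember, the SOC value is the same
        assert adjust_delta14c_for_sic(-600.0, 0.3, -600.0) == \
            pytest.approx(-600.0)

    def test_inverts_mixing_exactly(self, rng):
        for _ in range(50):
            f = rng.uniform(0.0, 0.95)
            soc, sic = rng.uniform(-900, 100, 2)
            total = f * sic + (1 - f) * soc
            assert adjust_delta14c_for_sic(total, f, sic) == \
                pytest.approx(soc, abs=1e-9)

    def test_all_sic_rejected(self):
        with pytest.raises(ValueError, match="no SOC"):
            adjust_delta14c_for_sic(-500.0, 1.0, -1000.0)


class TestScreening:
    @pytest.mark.parametrize("sic,f_sic,region,expected", [
        (0.05, None, None, "assumed_zero_sic"),
        (1.0, 0.20, None, "excluded_high_fsic"),
        (1.0, 0.10, None, "included_original"),
        (1.0, 0.10, "China Loess Plateau", "included_original"),
    ])
    def test_rules(self, sic, f_sic, region, expected):
        assert screen_site(sic, f_sic, region) == expected

    def test_region_exclusion_list(self):
        cfg = {"excluded_regions": ("China Loess Plateau",)}
        assert screen_site(1.0, 0.10, "China Loess Plateau", cfg) == \
            "excluded_region"
        assert screen_site(1.0, 0.10, "Spain", cfg) == "included_original"

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError):
            screen_site(-0.1, None, None)


class TestPartitionSite:
    def test_low_carbonate_short_circuits(self):
        part = partition_site(d13c_co2=None, d13c_soc=None, d13c_sic=None,
                              sic_content=0.05, delta14c_co2=-40.0)
        assert part.status == "assumed_zero_sic"
        assert part.f_sic == 0.0 and part.f_soc == 1.0
        assert part.delta14c_co2_soc == -40.0

    def test_full_partition_included(self):
        part = partition_site(d13c_co2=-22.0, d13c_soc=-24.0, d13c_sic=0.0,
                              sic_content=1.0, delta14c_co2=-40.0,
                              region="Spain")
        # f_sic = (−22 + 24)/(−9.6 + 24) = 0.1389
        assert part.f_sic == pytest.approx(2.0 / 14.4, abs=1e-9)
        assert part.status == "included_original"
        assert part.f_sic + part.f_soc == 1.0
        # audit adjustment uses the −1000‰ default endmember
        expected = (-40.0 - part.f_sic * -1000.0) / (1 - part.f_sic)
        assert part.delta14c_co2_soc == pytest.approx(expected)

    def test_high_fsic_excluded(self):
        part = partition_site(d13c_co2=-20.0, d13c_soc=-24.0, d13c_sic=0.0,
                              sic_content=1.0, delta14c_co2=-40.0)
        assert part.f_sic == pytest.approx(4.0 / 14.4)
        assert part.status == "excluded_high_fsic"

    def test_missing_d13c_above_floor_rejected(self):
        with pytest.raises(ValueError, match="δ¹³C"):
            partition_site(d13c_co2=None, d13c_soc=-24.0, d13c_sic=0.0,
                           sic_content=1.0, delta14c_co2=-40.0)

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            SICPartition(d13c_sic_eq=None, f_sic=0.3, f_soc=0.6,
                         delta14c_co2_soc=None, status="included_original")
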