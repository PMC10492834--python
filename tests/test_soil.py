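"""Soil carbon accounting: pedotransfer bulk density, stoniness, layer
stocks, peat extrapolation and the truncation rules."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealcarbon.errors import InvalidArgumentError, InvalidStateError, MissingDataError
from borealcarbon.records import SoilProfileRecord
from borealcarbon.soil import (
    StoninessTransfer,
    bulk_density,
    mineral_layer_stock,
    mineral_profile_stock,
    organic_layer_stock,
    peat_extrapolated_stock,
    stone_volume,
    total_soc,
)


def make_profile(thickness=5.0, mass=300.0, c_org=45.0, area=78.5, layers=None, pens=None):
    if layers is None:
        layers = [(0.0, 10.0, 2.0), (10.0, 20.0, 1.0), (55.0, 65.0, 0.4)]
    if pens is None:
        pens = (30.0,) * 12
    return SoilProfileRecord(
        plot_id="t1",
        organic_thickness=thickness,
        organic_core_dry_mass=mass,
        organic_core_c_conc=c_org,
        organic_sampled_area=area,
        mineral_layers=layers,
        penetration_depths=pens,
    )


class TestBulkDensity:
    @pytest.mark.parametrize(
        "c, depth, expected, tol",
        [
            (0.0, 0.0, 1.5463, 1e-12),  # exp(0) = 1
            (50.0, 0.0, 0.16910, 1e-4),
            (2.0, 15.0, 1.0329, 1e-3),
        ],
    )
    def test_hand_values(self, c, depth, expected, tol):
        assert bulk_density(c, depth) == pytest.approx(expected, abs=tol)

    def test_rejects_negative(self):
        with pytest.raises(InvalidArgumentError):
            bulk_density(-1, 0)
        with pytest.raises(InvalidArgumentError):
            bulk_density(0, -1)

    @given(
        c=st.floats(0.01, 60), dc=st.floats(0.01, 10), d=st.floats(0, 100), dd=st.floats(0.01, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, c, dc, d, dd):
        """Strictly decreasing in C, strictly increasing in depth, and never
        below the depth term alone."""
        assert bulk_density(c + dc, d) < bulk_density(c, d)
        assert bulk_density(c, d + dd) > bulk_density(c, d)
        assert bulk_density(c, d) > 0.0027 * d


class TestStoneVolume:
    def test_rod_never_stopped(self):
        assert stone_volume([30.0] * 12) == pytest.approx(44.3 - 1.44 * 30, abs=1e-9)

    def test_fully_obstructed(self):
        assert stone_volume([0.0] * 12) == pytest.approx(44.3)

    def test_degenerate_transfer_is_constant(self):
        flat = StoninessTransfer(a=20.0, b=0.0)
        assert stone_volume([5.0] * 12, flat) == stone_volume([25.0] * 12, flat) == 20.0

    def test_out_of_range_depth_rejected(self):
        with pytest.raises(InvalidArgumentError):
            stone_volume([31.0] + [10.0] * 11)


class TestLayerStocks:
    def test_mineral_unit_factor(self):
        # 2 % C, 1 g/cm3, 10 cm, 20 % stones -> 0.16 g/cm2 = 16 Mg/ha
        assert mineral_layer_stock(2.0, 1.0, 10.0, 20.0) == pytest.approx(16.0)

    def test_mineral_zero_cases(self):
        assert mineral_layer_stock(0.0, 1.0, 10.0, 0.0) == 0.0
        assert mineral_layer_stock(5.0, 1.0, 10.0, 100.0) == 0.0

    def test_mineral_stone_vol_over_100_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mineral_layer_stock(2.0, 1.0, 10.0, 101.0)

    def test_organic_hand_value(self):
        assert organic_layer_stock(300.0, 45.0, 78.5) == pytest.approx(171.97, abs=0.01)

    def test_organic_zero_mass(self):
        assert organic_layer_stock(0.0, 45.0, 78.5) == 0.0

    def test_organic_intensive(self):
        """Doubling both core mass and sampled area leaves the stock unchanged."""
        assert organic_layer_stock(600.0, 45.0, 157.0) == pytest.approx(
            organic_layer_stock(300.0, 45.0, 78.5)
        )

    def test_organic_zero_area_rejected(self):
        with pytest.raises(InvalidArgumentError):
            organic_layer_stock(300.0, 45.0, 0.0)

    @given(
        c=st.floats(0.1, 20),
        rho=st.floats(0.1, 2.0),
        th=st.floats(0.1, 30),
        sv=st.floats(0, 99),
        k=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_mineral_linear_in_conc_and_thickness(self, c, rho, th, sv, k):
        base = mineral_layer_stock(c, rho, th, sv)
        assert mineral_layer_stock(k * c, rho, th, sv) == pytest.approx(k * base, rel=1e-9)
        assert mineral_layer_stock(c, rho, k * th, sv) == pytest.approx(k * base, rel=1e-9)


class TestPeatExtrapolation:
    def test_doubling_rule(self):
        # 0-30 cm stock of 150 extrapolated to 60 cm -> 300
        prof = make_profile(thickness=60.0, mass=150 * 78.5 / 45.0, c_org=45.0, area=78.5)
        assert peat_extrapolated_stock(prof) == pytest.approx(300.0, rel=1e-9)

    def test_capped_at_one_metre(self):
        deep = make_profile(thickness=150.0)
        capped = make_profile(thickness=100.0 + 1e-9)
        assert peat_extrapolated_stock(deep) == pytest.approx(
            peat_extrapolated_stock(capped), rel=1e-6
        )

    def test_requires_peat(self):
        with pytest.raises(InvalidStateError):
            peat_extrapolated_stock(make_profile(thickness=30.0))


class TestMineralProfile:
    def test_uniform_column_is_five_layers(self):
        """Equal C density in every sampled layer gives 5x one layer over
        the 50 cm column (0-10, 10-20, and 3 x the deep stand-in)."""
        prof = make_profile(thickness=0.0, layers=[(0.0, 10.0, 2.0), (10.0, 20.0, 2.0), (55.0, 65.0, 2.0)])
        sv = stone_volume(prof.penetration_depths)
        per_layer = {
            5.0: mineral_layer_stock(2.0, bulk_density(2.0, 5.0), 10.0, sv),
            15.0: mineral_layer_stock(2.0, bulk_density(2.0, 15.0), 10.0, sv),
            60.0: mineral_layer_stock(2.0, bulk_density(2.0, 60.0), 10.0, sv),
        }
        expected = per_layer[5.0] + per_layer[15.0] + 3 * per_layer[60.0]
        assert mineral_profile_stock(prof) == pytest.approx(expected, rel=1e-12)

    def test_weighting_rule_hand_value(self):
        """Layer stocks 20/10/4 Mg/ha combine as 20 + 10 + 3*4 = 42."""
        prof = make_profile(thickness=0.0)
        sv = stone_volume(prof.penetration_depths)

        def conc_for(target, depth):
            # invert the linear-in-c approximation numerically
            from scipy.optimize import brentq

            return brentq(
                lambda c: mineral_layer_stock(c, bulk_density(c, depth), 10.0, sv) - target,
                1e-6,
                60.0,
            )

        layers = [
            (0.0, 10.0, conc_for(20.0, 5.0)),
            (10.0, 20.0, conc_for(10.0, 15.0)),
            (55.0, 65.0, conc_for(4.0, 60.0)),
        ]
        prof = make_profile(thickness=0.0, layers=layers)
        assert mineral_profile_stock(prof) == pytest.approx(42.0, rel=1e-9)

    def test_fully_displaced_by_organic(self):
        assert mineral_profile_stock(make_profile(thickness=100.0)) == 0.0

    def test_missing_layer_flags_plot(self):
        prof = make_profile(layers=[(0.0, 10.0, 2.0), (10.0, 20.0, 1.0)])
        with pytest.raises(MissingDataError) as err:
            mineral_profile_stock(prof)
        assert err.value.plot_id == "t1"


class TestTotalSoc:
    def test_zero_carbon_profile(self):
        prof = make_profile(mass=0.0, layers=[(0.0, 10.0, 0.0), (10.0, 20.0, 0.0), (55.0, 65.0, 0.0)])
        pools = total_soc(prof)
        assert pools.organic == pools.mineral == pools.total_soc == 0.0

    def test_continuity_across_peat_threshold(self):
        lo = total_soc(make_profile(thickness=30.0)).total_soc
        hi = total_soc(make_profile(thickness=30.0 + 1e-7)).total_soc
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_continuity_across_depth_cap(self):
        lo = total_soc(make_profile(thickness=100.0 - 1e-7)).total_soc
        hi = total_soc(make_profile(thickness=100.0 + 1e-7)).total_soc
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_peat_profile_is_organic_dominated(self):
        pools = total_soc(make_profile(thickness=80.0))
        assert pools.is_peat
        assert pools.organic > pools.mineral

    def test_si_unit_oracle(self):
        """Independent dimensional-analysis check: one plot computed fully in
        SI units (kg, m) must agree with the pipeline to 1e-9 relative."""
        prof = make_profile(thickness=6.0)
        pools = total_soc(prof)

        # organic: kg C / m2 -> Mg/ha is *10
        kg_c_per_m2 = (prof.organic_core_c_conc / 100.0) * (
            prof.organic_core_dry_mass / 1000.0
        ) / (prof.organic_sampled_area * 1e-4)
        assert pools.organic == pytest.approx(kg_c_per_m2 * 10.0, rel=1e-9)

        # mineral: per layer, concentration * density(kg/m3) * thickness(m)
        sv = stone_volume(prof.penetration_depths)
        total_kg_m2 = 0.0
        for (top, bottom, c), weight in zip(prof.mineral_layers, (1.0, 1.0, 3.0)):
            rho_si = bulk_density(c, 0.5 * (top + bottom)) * 1000.0  # kg/m3
            thick_m = (bottom - top) / 100.0
            total_kg_m2 += weight * (c / 100.0) * rho_si * thick_m * (100.0 - sv) / 100.0
        assert pools.mineral == pytest.approx(total_kg_m2 * 10.0, rel=1e-9)
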