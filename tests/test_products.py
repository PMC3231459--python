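"""Derived products: footprint, reflectances, NDVI/EVI2, LAI, VPD."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosense import products, synth
from phenosense.products import FootprintParams, LaiParams
from phenosense.types import QUANTUM_UMOL_PER_W, PhenosenseError


class TestFootprint:
    def test_zero_height_zero_radius(self):
        assert products.footprint_radius(0.0) == 0.0

    def test_five_metres_at_85_degrees(self):
        # tan(85 deg) = 11.4301: a 5 m mast sees a ~57 m disc,
        # comfortably above the 50 m design requirement
        r = products.footprint_radius(FootprintParams(h=5.0, view_half_angle=85.0))
        assert r == pytest.approx(5.0 * math.tan(math.radians(85.0)))
        assert r == pytest.approx(57.15, abs=0.01)
        assert r >= 50.0

    def test_invalid_view_angle_rejected(self):
        for angle in (0.0, 90.0, 120.0):
            with pytest.raises(PhenosenseError):
                FootprintParams(h=5.0, view_half_angle=angle)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(h=st.floats(0.01, 50.0), scale=st.floats(1.1, 10.0))
    def test_linear_in_height(self, h, scale):
        r1 = products.footprint_radius(h)
        r2 = products.footprint_radius(h * scale)
        assert r2 == pytest.approx(r1 * scale, rel=1e-9)

    def test_strictly_increasing_in_view_angle(self):
        radii = [products.footprint_radius(FootprintParams(5.0, a))
                 for a in (30.0, 60.0, 85.0, 89.0)]
        assert all(a < b for a, b in zip(radii, radii[1:]))


def quad_from_reflectances(rho_par, rho_nir, par_in=1500.0, sw_in=800.0):
    """Inverse construction: channels that encode the given reflectances."""
    par_out = rho_par * par_in
    sw_out = par_out / QUANTUM_UMOL_PER_W + rho_nir * (
        sw_in - par_in / QUANTUM_UMOL_PER_W
    )
    return pd.DataFrame(
        {"par_in": [par_in], "par_out": [par_out],
         "sw_in": [sw_in], "sw_out": [sw_out]},
        index=pd.DatetimeIndex([pd.Timestamp("2021-05-01 12:00")]),
    )


class TestReflectances:
    def test_inverse_construction_recovered_exactly(self):
        refl = products.broadband_reflectances(quad_from_reflectances(0.03, 0.36))
        assert refl.defined[0]
        assert refl.rho_par[0] == pytest.approx(0.03, abs=1e-12)
        assert refl.rho_nir[0] == pytest.approx(0.36, abs=1e-12)

    def test_black_surface_gives_zero_reflectances(self):
        refl = products.broadband_reflectances(quad_from_reflectances(0.0, 0.0))
        assert refl.rho_par[0] == 0.0 and refl.rho_nir[0] == 0.0

    def test_undefined_below_incoming_floor(self):
        refl = products.broadband_reflectances(
            quad_from_reflectances(0.03, 0.36, par_in=50.0, sw_in=30.0)
        )
        assert not refl.defined[0]
        assert "floor" in refl.reason[0]

    def test_undefined_when_shortwave_equals_par_energy(self):
        # all energy in the PAR band: the NIR denominator vanishes
        par_in = 1500.0
        quad = quad_from_reflectances(0.03, 0.0, par_in=par_in,
                                      sw_in=par_in / QUANTUM_UMOL_PER_W)
        refl = products.broadband_reflectances(quad)
        assert not refl.defined[0]
        assert "NIR" in refl.reason[0]

    def test_out_of_unit_interval_flagged_not_dropped(self):
        refl = products.broadband_reflectances(quad_from_reflectances(0.03, 1.4))
        assert refl.defined[0]
        assert "outside" in refl.reason[0]
        assert refl.rho_nir[0] == pytest.approx(1.4)


class TestIndexes:
    def test_ndvi_symmetry_and_boundaries(self):
        assert products.ndvi(0.2, 0.2) == 0.0
        assert products.ndvi(0.0, 0.5) == 1.0
        assert np.isnan(products.ndvi(0.0, 0.0))

    def test_ndvi_worked_example(self):
        assert products.ndvi(0.03, 0.36) == pytest.approx(0.33 / 0.39)
        assert products.ndvi(0.03, 0.36) == pytest.approx(0.8462, abs=1e-4)

    def test_evi2_worked_examples(self):
        assert products.evi2(0.2, 0.2) == 0.0
        assert products.evi2(0.03, 0.36) == pytest.approx(2.5 * 0.33 / 1.432)
        assert products.evi2(0.0, 1.0) == pytest.approx(1.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rho_par=st.floats(0.0, 1.0),
        rho_nir=st.floats(0.0, 1.0),
    )
    def test_ndvi_bounded_and_evi2_same_sign(self, rho_par, rho_nir):
        if rho_par + rho_nir == 0:
            return
        n = products.ndvi(rho_par, rho_nir)
        e = products.evi2(rho_par, rho_nir)
        assert -1.0 <= n <= 1.0
        assert np.sign(n) == np.sign(e)


class TestLai:
    def test_linear_mode(self):
        p = LaiParams(mode="linear", c=5.0)
        assert products.lai_from_ndvi(0.0, p) == 0.0
        assert products.lai_from_ndvi(0.8, p) == pytest.approx(4.0)
        assert products.lai_from_ndvi(-0.2, p) == 0.0  # negative NDVI floors at 0

    def test_saturating_mode_zero_at_ndvi_min_and_monotone(self):
        p = LaiParams(mode="saturating", ndvi_min=0.1, ndvi_max=0.9, k=0.6)
        assert products.lai_from_ndvi(0.1, p) == pytest.approx(0.0, abs=1e-9)
        vals = [products.lai_from_ndvi(v, p) for v in (0.2, 0.5, 0.8, 0.89)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_saturating_mode_clips_at_ndvi_max(self):
        p = LaiParams(mode="saturating", ndvi_min=0.1, ndvi_max=0.9, k=0.6)
        clipped = products.lai_from_ndvi(0.95, p)
        assert np.isfinite(clipped)
        assert clipped == products.lai_from_ndvi(2.0, p)

    def test_invalid_params_rejected(self):
        with pytest.raises(PhenosenseError):
            LaiParams(mode="linear", c=-1.0)
        with pytest.raises(PhenosenseError):
            LaiParams(mode="saturating", ndvi_min=0.9, ndvi_max=0.1)


class TestVpd:
    def test_saturated_air_has_zero_deficit(self):
        assert products.vpd(25.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_magnus_worked_example(self):
        # es(25 degC) = 0.6108 exp(17.27*25/262.3) ~ 3.168 kPa; half-dry air
        # leaves half the deficit
        assert products.vpd(25.0, 50.0) == pytest.approx(1.584, abs=2e-3)

    def test_monotone_decreasing_in_humidity(self):
        vals = [products.vpd(25.0, rh) for rh in (20.0, 50.0, 80.0, 100.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_humidity_rejected(self):
        with pytest.raises(PhenosenseError):
            products.vpd(25.0, 120.0)

    def test_vpd_series_pairs_channels_per_node(self, clean_table):
        out = products.vpd_series(clean_table)
        assert set(out["node_id"].unique()) == {"t01", "t02"}
        assert (out["vpd_kpa"] >= 0).all()


class TestDailyNdviPipeline:
    def test_noise_free_round_trip_to_1e6(self, clean_week):
        table, truth = clean_week
        daily = products.daily_ndvi(table)
        assert len(daily) == 7
        for _, row in daily.iterrows():
            expected = truth.ndvi_by_date[str(row["date"].date())]
            assert row["value"] == pytest.approx(expected, abs=1e-6)

    def test_noisy_round_trip_within_three_sd(self, small_geom):
        cfg = synth.SynthConfig(
            random_seed=17, n_days=7,
            noise_sd={c: 0.02 for c in ("par_in", "par_out", "sw_in", "sw_out")},
        )
        table, truth = synth.make_deployment_series(small_geom, cfg)
        daily = products.daily_ndvi(table)
        # compare against 3x the standard error of each daily mean, estimated
        # from the spread of the instantaneous values that fed it
        from phenosense import series_ops

        t = series_ops.cloud_filter(series_ops.window_filter(table))
        quad = products.radiation_quad(t, node_id="t00")
        refl = products.broadband_reflectances(quad)
        inst = pd.DataFrame(
            {"ts": quad.index,
             "v": np.where(refl.defined,
                           products.ndvi(refl.rho_par, refl.rho_nir), np.nan)}
        ).dropna()
        sd = inst.groupby(inst["ts"].dt.normalize())["v"].agg(["std", "size"])
        for _, row in daily.iterrows():
            expected = truth.ndvi_by_date[str(row["date"].date())]
            se = sd.loc[pd.Timestamp(row["date"]), "std"] / np.sqrt(
                sd.loc[pd.Timestamp(row["date"]), "size"]
            )
            assert abs(row["value"] - expected) <= 3.0 * se
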