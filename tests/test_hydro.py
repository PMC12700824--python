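"""Perrin/rod hydrodynamics and SEC calibration against closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ffstools import hydro
from ffstools.exceptions import ValidationError


class TestPerrinFactor:
    def test_sphere_is_exactly_one(self):
        assert hydro.perrin_factor(1.0) == 1.0

    def test_direct_formula_evaluation(self):
        p = 2.0
        xi = math.sqrt(3.0)
        expected = 2.0 ** (-1.0 / 3.0) * xi / math.log(2.0 + xi)
        assert hydro.perrin_factor(2.0) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        grid = np.concatenate([[1.0], np.geomspace(1.1, 50.0, 40)])
        vals = [hydro.perrin_factor(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v >= 1.0 for v in vals)

    def test_series_limit_continuous(self):
        assert hydro.perrin_factor(1.0 + 5e-8) == pytest.approx(
            hydro.perrin_factor(1.0 + 2e-7), abs=1e-9
        )

    def test_oblate_rejected(self):
        with pytest.raises(ValidationError):
            hydro.perrin_factor(0.5)


class TestDiffusionCoefficient:
    def test_stokes_einstein_sphere(self):
        """10 nm sphere in water at 293 K: D = kT/(3 pi eta d) ~ 42.9 µm²/s."""
        shape = hydro.HydroShape("sphere", 1, L0=10.0, d0=10.0)
        assert shape.equivalent_diameter == pytest.approx(10.0, rel=1e-12)
        D = hydro.diffusion_coefficient(shape)
        expected = 1.380649e-23 * 293.15 / (3 * math.pi * 1.0016e-3 * 10e-9) * 1e12
        assert D == pytest.approx(expected, rel=1e-12)
        assert D == pytest.approx(42.9, rel=2e-3)

    def test_near_spherical_prolate_matches_sphere(self):
        sph = hydro.diffusion_coefficient(hydro.HydroShape("sphere", 1, L0=6, d0=5))
        pro = hydro.diffusion_coefficient(hydro.HydroShape("prolate", 1, L0=6, d0=5))
        assert pro == pytest.approx(sph, rel=0.02)

    def test_rod_friction_scales_with_length_over_log(self):
        ns = np.arange(2, 51)
        Ds = np.array([
            hydro.diffusion_coefficient(hydro.HydroShape("rod", int(n), L0=6, d0=5))
            for n in ns
        ])
        assert (np.diff(Ds) < 0).all()  # D strictly decreasing in n
        # friction f = kT/D obeys f*(ln p + nu)/L = const exactly for a rod
        p = ns * 6.0 / 5.0
        nu = 0.312 + 0.565 / p - 0.100 / p**2
        f = 1.0 / Ds
        const = f * (np.log(p) + nu) / ns
        assert const.max() / const.min() == pytest.approx(1.0, rel=1e-9)
        # drag grows with length but slower than linearly (the log factor)
        assert (np.diff(f) > 0).all()
        assert (np.diff(f / ns) < 0).all()

    def test_rod_below_validity_warns(self):
        with pytest.warns(UserWarning):
            hydro.diffusion_coefficient(hydro.HydroShape("rod", 1, L0=6, d0=5))

    def test_all_models_finite_positive(self):
        for model in ("sphere", "prolate", "rod"):
            for n in (2, 5, 20):
                D = hydro.diffusion_coefficient(hydro.HydroShape(model, n, L0=6, d0=5))
                assert np.isfinite(D) and D > 0


class TestDiffusionRatios:
    def test_globular_ratios_analytic(self):
        assert hydro.predicted_diffusion_ratio(1, 5, "globule") == pytest.approx(
            5 ** (1 / 3), rel=1e-12
        )
        assert hydro.predicted_diffusion_ratio(2, 10, "globule") == pytest.approx(
            5 ** (1 / 3), rel=1e-12
        )

    def test_rod_exceeds_globule_for_protomer_geometry(self):
        glob = hydro.predicted_diffusion_ratio(2, 10, "globule")
        for model in ("rod", "prolate"):
            assert hydro.predicted_diffusion_ratio(2, 10, model) > glob

    def test_order_enforced(self):
        with pytest.raises(ValidationError):
            hydro.predicted_diffusion_ratio(10, 2, "rod")


class TestHydrodynamicDiameter:
    def test_round_trip(self):
        D = hydro.diffusion_from_diameter(35.0)
        assert hydro.hydrodynamic_diameter(D) == pytest.approx(35.0, rel=1e-12)

    def test_prolate_diameter_monotone_in_subunits(self):
        dhs = []
        for n in range(1, 30):
            shape = hydro.HydroShape("prolate", n, L0=6, d0=5)
            dhs.append(
                hydro.hydrodynamic_diameter(hydro.diffusion_coefficient(shape))
            )
        assert (np.diff(dhs) > 0).all()
        # consistency: prolate Dh equals d_eq * Perrin factor
        shape = hydro.HydroShape("prolate", 8, L0=6, d0=5)
        expected = shape.equivalent_diameter * hydro.perrin_factor(shape.aspect_ratio)
        assert dhs[7] == pytest.approx(expected, rel=1e-9)

    def test_root_finding_inverts_forward_model(self):
        n = hydro.subunits_for_diameter(35.0, "rod")
        shape = hydro.HydroShape("rod", 1, L0=n * 6.0, d0=5.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dh = hydro.hydrodynamic_diameter(hydro.diffusion_coefficient(shape))
        assert dh == pytest.approx(35.0, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            hydro.hydrodynamic_diameter(-1.0)


class TestSECCalibration:
    def test_matches_closed_form_least_squares(self):
        """OLS on the six non-void standards equals the normal equations."""
        cal = hydro.sec_calibrate()
        pts = [(mw, ev) for _, mw, ev in hydro.DEFAULT_SEC_STANDARDS[1:]]
        x = np.log10([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        n = x.size
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x**2).sum() - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        assert cal.slope == pytest.approx(slope, rel=1e-12)
        assert cal.intercept == pytest.approx(intercept, rel=1e-12)
        assert cal.r2 > 0.98
        assert cal.void_volume == 8.7

    def test_void_marker_excluded_by_default(self):
        cal = hydro.sec_calibrate()
        incl = hydro.sec_calibrate(exclude_void=False)
        assert cal.void_volume == 8.7
        assert incl.void_volume is None
        assert incl.slope != cal.slope

    def test_three_collinear_standards_interpolate_exactly(self):
        stds = [("a", 100.0, 10.0), ("b", 10.0, 14.0), ("c", 1.0, 18.0)]
        cal = hydro.sec_calibrate(stds, exclude_void=False)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)
        assert cal.predict_ev(10.0) == pytest.approx(14.0, abs=1e-9)

    def test_two_fitted_standards_interpolate_exactly(self):
        # void marker excluded, two remaining points: exact interpolation
        stds = [("void", 2000.0, 8.7), ("b", 100.0, 12.0), ("c", 10.0, 16.0)]
        cal = hydro.sec_calibrate(stds)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)
        assert cal.predict_ev(100.0) == pytest.approx(12.0, abs=1e-9)

    def test_round_trip_mw(self):
        cal = hydro.sec_calibrate()
        for mw in (13.7, 66.0, 440.0):
            assert cal.invert_mw(cal.predict_ev(mw)) == pytest.approx(mw, rel=1e-9)

    def test_duplicate_mw_rejected(self):
        with pytest.raises(ValidationError):
            hydro.sec_calibrate([("a", 10.0, 1.0), ("b", 10.0, 2.0), ("c", 1.0, 3.0)])


class TestSECPredict:
    def test_monomer_equals_direct_prediction(self):
        cal = hydro.sec_calibrate()
        tab = hydro.sec_predict(cal, 35.0, 5)
        assert tab.loc[0, "ev_ml"] == pytest.approx(cal.predict_ev(35.0))

    def test_strictly_decreasing_and_void_flagged(self):
        cal = hydro.sec_calibrate()
        tab = hydro.sec_predict(cal, 35.0, 20)
        assert (np.diff(tab["ev_ml"]) < 0).all()
        flagged = tab[tab["flag"] != ""]
        # threshold crossing: first multimer whose EV falls below the void
        n_cross = int(flagged["n"].min())
        assert tab.loc[n_cross - 2, "ev_ml"] >= cal.void_volume
        assert tab.loc[n_cross - 1, "ev_ml"] < cal.void_volume

    @given(mw=st.floats(5.0, 500.0))
    def test_predictions_monotone_in_mw(self, mw):
        cal = hydro.sec_calibrate()
        assert cal.predict_ev(mw) > cal.predict_ev(mw * 2.0)
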