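"""Detrending, correlation estimators, diffusion fits and FCCS arithmetic."""

import numpy as np
import pytest

from ffstools import fcs
from ffstools.exceptions import UndeterminedError, ValidationError
from ffstools.fcs import CorrelationCurve, diffusion_model
from ffstools.simulate import (
    DEFAULT_VOLUME,
    PhotonTrace,
    SimulationConfig,
    SpeciesSpec,
    simulate_trace,
)

from conftest import poisson_trace


class TestDetrend:
    def test_ramp_flattened(self):
        """A 10% linear intensity ramp leaves a flat moving-average profile."""
        rng = np.random.default_rng(2)
        n = 100_000
        lam = 5.0 * (1.0 + 0.1 * np.arange(n) / n)
        tr = PhotonTrace(1e-4, rng.poisson(lam), np.zeros(n, dtype=int))
        det = fcs.detrend(tr, window=1.0)
        w = 10_000
        ma = np.convolve(det.counts_g, np.ones(w) / w, mode="valid")
        assert np.abs(ma / det.counts_g.mean() - 1.0).max() < 0.01

    def test_total_count_preserved(self, trace_fcs):
        _, tr = trace_fcs
        det = fcs.detrend(tr, window=1.0)
        assert abs(det.counts_g.sum() - tr.counts_g.sum()) <= 0.001 * tr.counts_g.sum()

    def test_stationary_trace_correlation_unchanged(self, trace_fcs):
        _, tr = trace_fcs
        det = fcs.detrend(tr, window=1.0)
        c_raw = fcs.correlate(tr, "g", "g")
        c_det = fcs.correlate(det, "g", "g")
        # distortion well below the statistical error of the curve itself
        tol = 3.0 * np.maximum(c_raw.se, 0.01 * abs(c_raw.G[0]))
        assert (np.abs(c_raw.G - c_det.G) <= tol).all()

    def test_idempotent_within_requantization(self, trace_fcs):
        _, tr = trace_fcs
        once = fcs.detrend(tr, window=1.0)
        twice = fcs.detrend(once, window=1.0)
        assert np.abs(twice.counts_g - once.counts_g).mean() < 0.05

    def test_window_bounds_enforced(self, trace_fcs):
        _, tr = trace_fcs
        with pytest.raises(ValidationError):
            fcs.detrend(tr, window=tr.duration)
        with pytest.raises(ValidationError):
            fcs.detrend(tr, window=50 * tr.bin_width)

    def test_improves_amplitude_accuracy_under_drift(self):
        """Across the drift grid, detrending brings the measured amplitude
        (first-lag G, where the slow-drift plateau shows undiluted) closer
        to the known single-species value."""
        tau_d = DEFAULT_VOLUME.w_xy**2 / (4.0 * 25.0)
        g1_true = 0.5 * fcs.diffusion_model(np.array([1e-4]), 1.0, tau_d)[0]
        for amp in (0.4, 0.5):
            for seed in (1, 2):
                cfg = SimulationConfig(
                    species=(SpeciesSpec(eps_g=1e4, mean_occupancy=2.0, D=25.0),),
                    duration=8.0,
                    drift_amplitude=amp,
                    seed=seed,
                )
                tr = simulate_trace(cfg)
                det = fcs.detrend(tr, window=1.0)
                g_raw = fcs.correlate(tr, "g", "g").G[0]
                g_det = fcs.correlate(det, "g", "g").G[0]
                assert abs(g_det - g1_true) <= abs(g_raw - g1_true)


class TestCorrelate:
    def test_independent_channels_uncorrelated(self):
        tr = poisson_trace(1.0, 200_000, lam_r=1.0, seed=3)
        c = fcs.correlate(tr, "g", "r")
        z = np.abs(c.G) / np.maximum(c.se, 1e-12)
        assert (z < 3).mean() > 0.9
        assert abs(np.median(c.G)) < 3.0 * np.median(c.se)

    def test_multitau_equals_direct_on_native_lags(self, trace_fcs):
        _, tr = trace_fcs
        mt = fcs.correlate(tr, "g", "g", scheme="multi_tau")
        dr = fcs.correlate(tr, "g", "g", scheme="direct", lag_bins=list(range(1, 17)))
        assert np.abs(mt.G[:16] - dr.G).max() <= 1e-3 * abs(mt.G[0])

    def test_multitau_equals_direct_on_rebinned_trace(self, trace_fcs):
        """Coarser multi-tau stages reproduce the direct estimator applied
        to the correspondingly rebinned trace."""
        _, tr = trace_fcs
        mt = fcs.correlate(tr, "g", "g", scheme="multi_tau")
        lag_bins = np.round(mt.lags / tr.bin_width).astype(int)
        for f in (2, 4):
            n = (len(tr) // f) * f
            reb = PhotonTrace(
                tr.bin_width * f,
                tr.counts_g[:n].reshape(-1, f).sum(axis=1),
                tr.counts_r[:n].reshape(-1, f).sum(axis=1),
            )
            sel = [i for i, (lb, _) in enumerate(zip(lag_bins, mt.lags))
                   if lb % f == 0 and 9 * f <= lb <= 16 * f]
            dr = fcs.correlate(reb, "g", "g", scheme="direct",
                               lag_bins=[lag_bins[i] // f for i in sel])
            assert np.abs(mt.G[sel] - dr.G).max() <= 1e-3 * abs(mt.G[0])

    def test_amplitude_is_reciprocal_occupancy(self, trace_n5):
        cfg, tr = trace_n5
        c = fcs.correlate(tr, "g", "g")
        assert c.G[0] == pytest.approx(1.0 / 5.0, rel=0.15)

    def test_cross_correlation_symmetry(self):
        cfg = SimulationConfig(
            species=(SpeciesSpec(eps_g=1e4, eps_r=1e4, mean_occupancy=0.5),),
            duration=5.0,
            seed=21,
        )
        tr = simulate_trace(cfg)
        gr = fcs.correlate(tr, "g", "r")
        rg = fcs.correlate(tr, "r", "g")
        tol = 4.0 * np.maximum(gr.se + rg.se, 0.01 * abs(gr.G[0]))
        assert (np.abs(gr.G - rg.G) <= tol).all()

    def test_zero_mean_channel_rejected(self):
        tr = poisson_trace(1.0, 10_000, lam_r=0.0, seed=4)
        with pytest.raises(ValidationError):
            fcs.correlate(tr, "g", "r")


class TestFitDiffusion:
    def _model_curve(self, G0, tau_D, S=6.0):
        lags = np.geomspace(1e-5, 1.0, 60)
        return CorrelationCurve(
            lags=lags, G=diffusion_model(lags, G0, tau_D, S),
            se=np.zeros(60), kind="auto_g",
        )

    def test_noise_free_fixed_point(self):
        fit = fcs.fit_diffusion(self._model_curve(0.1, 1e-3))
        assert fit.N == pytest.approx(10.0, rel=1e-6)
        assert fit.tau_D == pytest.approx(1e-3, rel=1e-6)
        assert fit.G0 * fit.N == pytest.approx(1.0, abs=1e-9)

    def test_large_shape_factor_reduces_to_2d_model(self):
        lags = np.geomspace(1e-5, 1.0, 60)
        g3d = diffusion_model(lags, 0.2, 1e-3, S=1e6)
        g2d = 0.2 / (1.0 + lags / 1e-3)
        assert np.abs(g3d - g2d).max() < 1e-6 * 0.2

    def test_recovers_simulated_diffusion_time(self, trace_n5):
        cfg, tr = trace_n5
        fit = fcs.fit_diffusion(fcs.correlate(tr, "g", "g"))
        tau_true = cfg.volume.w_xy**2 / (4.0 * cfg.species[0].D)
        assert fit.tau_D == pytest.approx(tau_true, rel=0.15)

    def test_stokes_einstein_scaling_of_ratio(self):
        """Spheres n=1 vs n=5 with D ~ n^(-1/3): ratio 5^(1/3)."""
        f1 = fcs.fit_diffusion(self._model_curve(1.0, 1e-3))
        f5 = fcs.fit_diffusion(self._model_curve(1.0, 1e-3 * 5 ** (1 / 3)))
        assert fcs.diffusion_ratio(f1, f5) == pytest.approx(5 ** (1 / 3), rel=1e-6)

    def test_identical_fits_give_unit_ratio(self):
        f = fcs.fit_diffusion(self._model_curve(0.5, 2e-3))
        assert fcs.diffusion_ratio(f, f) == 1.0


class TestFCCS:
    def _curves(self, n_g, n_r, n_x, mean_g=0.5, mean_r=0.4, bleed=0.0):
        """Analytic curve triple for occupancies (n_g, n_r, complex n_x),
        optionally with green->red bleedthrough mixed in."""
        lags = np.geomspace(1e-4, 0.1, 40)
        shape = diffusion_model(lags, 1.0, 1e-3)
        cov_gg = (1.0 / n_g) * shape * mean_g**2
        cov_rr = (1.0 / n_r) * shape * mean_r**2
        cov_gr = (n_x / (n_g * n_r)) * shape * mean_g * mean_r
        mg = mean_g
        mr = mean_r + bleed * mean_g
        m_rr = cov_rr + 2 * bleed * cov_gr + bleed**2 * cov_gg
        m_gr = cov_gr + bleed * cov_gg
        mk = lambda G, kind, ma, mb: CorrelationCurve(
            lags=lags, G=G, se=np.zeros(40), kind=kind, mean_a=ma, mean_b=mb,
            bin_width=1e-4,
        )
        return (
            mk(cov_gg / mg**2, "auto_g", mg, mg),
            mk(m_rr / mr**2, "auto_r", mr, mr),
            mk(m_gr / (mg * mr), "cross", mg, mr),
        )

    def test_full_binding_equal_concentrations(self):
        g, r, x = self._curves(1.0, 1.0, 1.0)
        res = fcs.fccs_bound_fraction(g, r, x)
        assert res.bound_fraction == pytest.approx(1.0, abs=1e-6)

    def test_half_binding_of_less_concentrated_green(self):
        g, r, x = self._curves(1.0, 1.5, 0.5)
        res = fcs.fccs_bound_fraction(g, r, x)
        assert res.less_concentrated == "g"
        assert res.bound_fraction == pytest.approx(0.5, abs=1e-6)

    def test_bleedthrough_unmixing_restores_fraction(self):
        g, r, x = self._curves(1.0, 1.5, 0.5, bleed=0.08)
        biased = fcs.fccs_bound_fraction(g, r, x)
        corrected = fcs.fccs_bound_fraction(g, r, x, bleed=0.08)
        assert corrected.bound_fraction == pytest.approx(0.5, abs=1e-6)
        assert abs(biased.bound_fraction - 0.5) > abs(corrected.bound_fraction - 0.5)

    def test_invariant_under_brightness_rescaling(self):
        res1 = fcs.fccs_bound_fraction(*self._curves(1.0, 1.5, 0.5, mean_g=0.5, mean_r=0.4))
        res2 = fcs.fccs_bound_fraction(*self._curves(1.0, 1.5, 0.5, mean_g=1.5, mean_r=1.2))
        assert res1.bound_fraction == pytest.approx(res2.bound_fraction, abs=1e-9)

    def test_overlap_factor_correction_and_clamping(self):
        g, r, x = self._curves(1.0, 1.5, 0.4)
        res = fcs.fccs_bound_fraction(g, r, x, positive_control_ratio=0.5)
        assert res.bound_fraction == pytest.approx(0.8, abs=1e-6)
        over = fcs.fccs_bound_fraction(g, r, x, positive_control_ratio=0.2)
        assert over.clamped and over.bound_fraction == 1.0
        with pytest.raises(ValidationError):
            fcs.fccs_bound_fraction(g, r, x, positive_control_ratio=0.0)

    def test_bleedthrough_coefficient_zero_without_bleed(self):
        cfg = SimulationConfig(
            species=(SpeciesSpec(eps_g=1e4, mean_occupancy=0.3),),
            duration=2.0, seed=31,
        )
        assert fcs.bleedthrough_coefficient(simulate_trace(cfg)) == pytest.approx(0.0, abs=1e-3)

    def test_bleedthrough_undetermined_at_background_level(self):
        tr = poisson_trace(0.05, 10_000, lam_r=0.05, seed=33)
        with pytest.raises(UndeterminedError):
            # all green signal explained by the quoted background rate
            fcs.bleedthrough_coefficient(tr, background_g=500.0, background_r=0.0)

    def test_bleedthrough_coefficient_recovers_simulated_value(self):
        cfg = SimulationConfig(
            species=(SpeciesSpec(eps_g=1e4, mean_occupancy=0.5),),
            duration=5.0, bleed_g_to_r=0.05, seed=32,
        )
        coeff = fcs.bleedthrough_coefficient(simulate_trace(cfg))
        assert coeff == pytest.approx(0.05, rel=0.05)
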