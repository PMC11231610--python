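"""Forward lineshape model: resonance positions, widths, spectra, mixtures."""

import numpy as np
import pytest
import scipy.signal as ss
from hypothesis import given, settings, strategies as st

from spinbind.errors import (FastRegimeError, InvalidParameterError,
                             SpectralWindowError, WeightSumError)
from spinbind.forward import (SpinComponent, double_integral,
                              fast_motion_linewidths, mhz_to_mt,
                              resonance_positions_fast, simulate_component,
                              simulate_mixture, default_field_axis)
from conftest import count_zero_crossings

G = (2.0083, 2.0061, 2.0022)


def make(label="free", aiso=44.1, tau_c=0.1, **kw):
    return SpinComponent(label, G, (16.0, 16.0, 3 * aiso - 32.0), tau_c, **kw)


class TestResonancePositions:
    def test_zero_hyperfine_collapses_to_center(self):
        pos = resonance_positions_fast(2.0060, 0.0, 9.4)
        assert np.allclose(pos, 334.79995, atol=1e-4)

    def test_hyperfine_spacing_matches_field_conversion(self):
        pos = resonance_positions_fast(2.0060, 44.1, 9.4)
        assert pos[1] - pos[0] == pytest.approx(1.5707, abs=2e-3)
        assert np.all(np.diff(pos) > 0)

    @given(g=st.floats(1.9, 2.1), a=st.floats(0.0, 120.0))
    @settings(max_examples=50, deadline=None)
    def test_first_order_spacing_is_symmetric(self, g, a):
        pos = resonance_positions_fast(g, a, 9.47)
        assert (pos[1] - pos[0]) == pytest.approx(pos[2] - pos[1], rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            resonance_positions_fast(-2.0, 44.0, 9.4)
        with pytest.raises(InvalidParameterError):
            resonance_positions_fast(2.0, 44.0, 0.0)


class TestFastMotionLinewidths:
    def test_isotropic_tensors_give_equal_widths(self):
        comp = SpinComponent("free", (2.006,) * 3, (44.0,) * 3, 0.1,
                             lw_lorentz=0.05)
        w = fast_motion_linewidths(comp, 335.0)
        assert np.allclose(w, 0.05)

    def test_high_field_line_broadest(self):
        w = fast_motion_linewidths(make(tau_c=0.1), 335.0)
        assert np.all(w > 0)
        assert w[2] > w[0]  # mI=-1 (high field) wider than mI=+1

    def test_motional_part_linear_in_tau(self):
        base = fast_motion_linewidths(make(tau_c=0.1, lw_lorentz=0.02), 335.0)
        dbl = fast_motion_linewidths(make(tau_c=0.2, lw_lorentz=0.02), 335.0)
        assert np.allclose(dbl - 0.02, 2 * (base - 0.02), rtol=1e-9)

    def test_slow_tumbling_flagged(self):
        with pytest.raises(FastRegimeError):
            fast_motion_linewidths(make(tau_c=5.0), 335.0)


class TestSimulateComponent:
    def test_free_probe_has_three_sharp_lines(self, wide_axis, mw_freq):
        y = simulate_component(make(lw_gauss=0.135), wide_axis, mw_freq)
        thr = 0.05 * np.abs(y).max()
        peaks, _ = ss.find_peaks(y, height=thr)
        dips, _ = ss.find_peaks(-y, height=thr)
        assert len(peaks) == 3 and len(dips) == 3
        # derivative triplet: one crossing per line + one between lines
        assert count_zero_crossings(y) == 5

    def test_unit_spins_double_integral(self, wide_axis, mw_freq, library):
        for comp in library:
            y = simulate_component(comp, wide_axis, mw_freq)
            assert double_integral(wide_axis, y) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_limit_outer_splitting(self, mw_freq):
        comp = SpinComponent("strong", G, (16.0, 16.0, 90.0), 1e3,
                             lw_gauss=0.13)
        ax = default_field_axis(328.0, 346.0, 4096)
        y = simulate_component(comp, ax, mw_freq)
        thr = 0.02 * np.abs(y).max()
        pk, _ = ss.find_peaks(y, height=thr)
        tr, _ = ss.find_peaks(-y, height=thr)
        sep = ax[tr[-1]] - ax[pk[0]]
        expected = 2 * mhz_to_mt(90.0, G[2])
        assert sep == pytest.approx(expected, rel=0.02)

    def test_gaussian_broadening_conserves_area(self, wide_axis, mw_freq):
        base = make(tau_c=2.0)
        y0 = simulate_component(base, wide_axis, mw_freq, normalization="none")
        y1 = simulate_component(base.with_params(lw_gauss=0.3), wide_axis,
                                mw_freq, normalization="none")
        d0 = double_integral(wide_axis, y0)
        d1 = double_integral(wide_axis, y1)
        assert d1 == pytest.approx(d0, rel=5e-3)

    @pytest.mark.parametrize("param", [
        dict(tau_c=5.0), dict(lw_lorentz=0.2), dict(exchange_freq=5.0)])
    def test_area_invariant_under_broadening_changes(self, wide_axis, mw_freq,
                                                     param):
        y0 = simulate_component(make(tau_c=1.0), wide_axis, mw_freq,
                                normalization="none")
        y1 = simulate_component(make(tau_c=1.0).with_params(**param),
                                wide_axis, mw_freq, normalization="none")
        assert double_integral(wide_axis, y1) == pytest.approx(
            double_integral(wide_axis, y0), rel=5e-3)

    def test_truncated_window_raises(self, mw_freq):
        comp = SpinComponent("strong", G, (16.0, 16.0, 90.0), 1e3)
        narrow = default_field_axis(334.0, 340.0, 512)
        with pytest.raises(SpectralWindowError):
            simulate_component(comp, narrow, mw_freq)

    def test_engine_consistency_in_fast_regime(self, wide_axis, mw_freq):
        comp = make(tau_c=0.3, lw_gauss=0.135)
        y_fast = simulate_component(comp, wide_axis, mw_freq, engine="fast")
        y_slow = simulate_component(comp, wide_axis, mw_freq, engine="slow")
        rms = np.sqrt(np.mean((y_fast - y_slow) ** 2)) / np.ptp(y_fast)
        assert rms <= 0.05

    def test_central_broadening_monotone_in_tau(self, mw_freq):
        ax = default_field_axis(330.0, 345.0, 2048)
        comp = make(lw_gauss=0.135)
        pos = resonance_positions_fast(comp.giso, comp.aiso, mw_freq)
        sel = (ax > pos[0] + 0.6) & (ax < pos[2] - 0.6)

        def central_ppw(y):
            seg, axm = y[sel], ax[sel]
            thr = 0.2 * np.abs(seg).max()
            pk, _ = ss.find_peaks(seg, height=thr)
            tr, _ = ss.find_peaks(-seg, height=thr)
            return axm[tr[-1]] - axm[pk[0]]

        widths = [central_ppw(simulate_component(comp.with_params(tau_c=tc),
                                                 ax, mw_freq))
                  for tc in (0.1, 0.3, 1.0, 2.0, 3.0, 5.0, 10.0, 30.0)]
        assert np.all(np.diff(widths) >= -1e-9)


class TestSimulateMixture:
    def test_single_component_identity(self, wide_axis, mw_freq, library):
        y_single = simulate_component(library[0], wide_axis, mw_freq)
        trace = simulate_mixture(library, (1.0, 0.0, 0.0), wide_axis, mw_freq)
        assert np.allclose(trace.intensity, y_single)

    def test_linearity_in_weights(self, wide_axis, mw_freq, library):
        y0 = simulate_component(library[0], wide_axis, mw_freq)
        y1 = simulate_component(library[1], wide_axis, mw_freq)
        mix = simulate_mixture(library[:2], (0.5, 0.5), wide_axis, mw_freq)
        assert np.allclose(mix.intensity, 0.5 * y0 + 0.5 * y1)

    def test_double_integral_shares_recover_weights(self, wide_axis, mw_freq,
                                                    library):
        w = np.array([0.27, 0.55, 0.18])
        parts = [wi * simulate_component(c, wide_axis, mw_freq)
                 for wi, c in zip(w, library)]
        dis = np.array([double_integral(wide_axis, p) for p in parts])
        assert np.allclose(dis / dis.sum(), w, atol=1e-6)

    def test_weight_sum_violation_reports_sum(self, wide_axis, mw_freq, library):
        with pytest.raises(WeightSumError, match="0.9"):
            simulate_mixture(library, (0.5, 0.3, 0.1), wide_axis, mw_freq)
        with pytest.raises(WeightSumError):
            simulate_mixture(library, (1.2, -0.1, -0.1), wide_axis, mw_freq)


class TestSpinComponentValidation:
    def test_derived_isotropic_means(self):
        comp = make(aiso=44.1)
        assert comp.giso == pytest.approx(np.mean(G))
        assert comp.aiso == pytest.approx(44.1)

    @pytest.mark.parametrize("kw", [
        dict(tau_c=-1.0), dict(tau_c=0.0), dict(lw_gauss=-0.1),
        dict(exchange_freq=-2.0)])
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            make(**{"tau_c": 0.1, **kw})
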