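"""Spectral decomposition: weight recovery, double-integral fractions,
uncertainty rule."""

import itertools
import warnings

import numpy as np
import pytest

from spinbind.decompose import (DecompositionResult, fit_weights,
                                fractions_from_double_integrals,
                                phi_uncertainty)
from spinbind.errors import DegeneracyWarning, EmptySpectrumError
from spinbind.forward import SpectrumTrace, simulate_component, simulate_mixture


def _noisy(trace, snr, seed):
    rng = np.random.default_rng(seed)
    y = trace.intensity + rng.normal(0, np.ptp(trace.intensity) / snr,
                                     trace.intensity.size)
    return SpectrumTrace(field_mT=trace.field_mT, intensity=y,
                         mw_freq_GHz=trace.mw_freq_GHz)


class TestFitWeights:
    def test_noiseless_mixture_recovered_exactly(self, std_axis, mw_freq, library):
        truth = (0.2, 0.5, 0.3)
        trace = simulate_mixture(library, truth, std_axis, mw_freq)
        res = fit_weights(trace, library)
        assert np.allclose(res.phi, truth, atol=1e-4)
        assert res.rmsd_pct < 1e-6

    def test_noisy_mixture_recovered_within_tolerance(self, std_axis, mw_freq,
                                                      library):
        truth = np.array([0.2, 0.5, 0.3])
        trace = simulate_mixture(library, truth, std_axis, mw_freq)
        res = fit_weights(_noisy(trace, snr=50, seed=7), library)
        assert np.all(np.abs(res.phi - truth) <= 0.03)

    def test_pure_free_spectrum_has_little_bound_leakage(self, std_axis,
                                                         mw_freq, library):
        trace = simulate_mixture(library, (1.0, 0.0, 0.0), std_axis, mw_freq)
        res = fit_weights(_noisy(trace, snr=200, seed=3), library)
        assert res.weights["intermediate"] + res.weights["strong"] <= 0.02

    def test_component_order_does_not_matter(self, std_axis, mw_freq, library):
        truth = {"free": 0.3, "intermediate": 0.45, "strong": 0.25}
        trace = simulate_mixture(library, [truth[c.label] for c in library],
                                 std_axis, mw_freq)
        noisy = _noisy(trace, snr=100, seed=1)
        base = fit_weights(noisy, library).weights
        for perm in itertools.permutations(library):
            w = fit_weights(noisy, list(perm)).weights
            for lab in truth:
                assert w[lab] == pytest.approx(base[lab], abs=1e-9)

    def test_grid_search_oracle_agrees_on_tiny_axis(self, mw_freq, library):
        """Exhaustive 0.01-step weight grid against the solver optimum."""
        axis = np.linspace(330.0, 345.0, 65)
        comps = library[:2]
        c_mat = np.column_stack([simulate_component(c, axis, mw_freq)
                                 for c in comps])
        truth = np.array([0.37, 0.63])
        rng = np.random.default_rng(11)
        y = c_mat @ truth + rng.normal(0, np.ptp(c_mat @ truth) / 60, axis.size)

        grid = np.arange(0.0, 1.0 + 1e-12, 0.01)
        rss = [np.sum((c_mat @ np.array([w, 1 - w]) * s - y) ** 2)
               for w in grid
               for s in [float(np.linalg.lstsq(
                   (c_mat @ np.array([w, 1 - w]))[:, None], y, rcond=None)[0][0])]]
        w_oracle = grid[int(np.argmin(rss))]

        res = fit_weights(SpectrumTrace(field_mT=axis, intensity=y,
                                        mw_freq_GHz=mw_freq), comps)
        assert abs(res.weights["free"] - w_oracle) <= 0.011

    def test_parameter_recovery_statistics(self, std_axis, mw_freq, library):
        """Median/95th-percentile error over seeded mixtures and SNR levels."""
        c_mat = np.column_stack([simulate_component(c, std_axis, mw_freq)
                                 for c in library])
        rng = np.random.default_rng(2024)
        errs = []
        for snr in (20, 50, 200):
            for _ in range(34):
                w = rng.dirichlet((1.0, 1.0, 1.0))
                mix = c_mat @ w
                y = mix + rng.normal(0, np.ptp(mix) / snr, std_axis.size)
                res = fit_weights(SpectrumTrace(field_mT=std_axis, intensity=y,
                                                mw_freq_GHz=mw_freq), library)
                errs.extend(np.abs(res.phi - w))
        errs = np.array(errs)
        assert np.median(errs) <= 0.02
        assert np.percentile(errs, 95) <= 0.06

    def test_duplicate_components_flagged_degenerate(self, std_axis, mw_freq,
                                                     library):
        twin = library[1].with_params(label="strong")
        trace = simulate_mixture([library[0], library[1]], (0.4, 0.6),
                                 std_axis, mw_freq)
        with pytest.warns(DegeneracyWarning):
            res = fit_weights(trace, [library[0], library[1], twin])
        # ambiguous weight assigned to the smaller-tau_c member
        assert res.weights["intermediate"] >= res.weights["strong"]

    def test_refinement_recovers_perturbed_tau(self, std_axis, mw_freq, library):
        perturbed = [library[0],
                     library[1].with_params(tau_c=library[1].tau_c * 1.10),
                     library[2]]
        trace = simulate_mixture(perturbed, (0.3, 0.5, 0.2), std_axis, mw_freq)
        res = fit_weights(trace, library, refine="tau_c")
        fitted_tau = res.refined_params["intermediate"]["tau_c"]
        assert fitted_tau == pytest.approx(library[1].tau_c * 1.10, rel=0.05)
        assert np.allclose(res.phi, (0.3, 0.5, 0.2), atol=0.02)


class TestDoubleIntegralFractions:
    def test_unit_components_give_weights(self, std_axis, mw_freq, library):
        w = (0.6, 0.4, 0.0)
        traces = [wi * simulate_component(c, std_axis, mw_freq)
                  for wi, c in zip(w, library)]
        assert np.allclose(
            fractions_from_double_integrals(std_axis, traces), w, atol=1e-9)

    def test_common_rescaling_invariance(self, std_axis, mw_freq, library):
        w = np.array([0.3, 0.5, 0.2])
        traces = [wi * simulate_component(c, std_axis, mw_freq)
                  for wi, c in zip(w, library)]
        scaled = [7.3 * t for t in traces]
        assert np.allclose(fractions_from_double_integrals(std_axis, scaled),
                           fractions_from_double_integrals(std_axis, traces))

    def test_zero_total_integral_raises(self, std_axis):
        with pytest.raises(EmptySpectrumError):
            fractions_from_double_integrals(std_axis,
                                            [np.zeros_like(std_axis)] * 3)


class TestPhiUncertainty:
    def _result(self, weights, rmsd):
        return DecompositionResult(weights=weights,
                                   weight_errors={}, rmsd_pct=rmsd,
                                   fitted_trace=np.zeros(4))

    def test_rmsd_rule(self):
        out = phi_uncertainty(self._result({"free": 0.722}, 2.0))
        phi, lo, hi = out["free"]
        assert (phi, lo, hi) == pytest.approx((0.722, 0.02, 0.02))

    def test_clipping_at_domain_bounds(self):
        out = phi_uncertainty(self._result({"strong": 0.01}, 5.0))
        _, lo, hi = out["strong"]
        assert lo == pytest.approx(0.01)   # lower bound clipped at zero
        assert hi == pytest.approx(0.05)

    def test_noiseless_fit_has_zero_error(self):
        out = phi_uncertainty(self._result({"free": 0.5}, 0.0))
        assert out["free"][1] == out["free"][2] == 0.0
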