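"""Forward simulation of first-derivative CW EPR spectra of nitroxide radicals.

The model treats one unpaired electron (S = 1/2) coupled to a single ¹⁴N
nucleus (I = 1).  Each spectral species is described by a
:class:`SpinComponent` carrying principal g- and hyperfine-tensor values,
an isotropic rotational correlation time ``tau_c`` and residual broadenings.

Motional regimes
----------------
Fast isotropic tumbling averages the tensors to their isotropic means and
leaves three Lorentzian lines whose mI-dependent widths follow the standard
motional-narrowing (Redfield/Kivelson) expansion ``ΔB(mI) = A + B·mI + C·mI²``.
In the rigid limit the spectrum converges to the static powder pattern with
outer splitting 2·A'zz.  Between the two, this module uses a documented
partial-averaging interpolation: the anisotropic part of each tensor is
scaled by an order parameter

    S(tau_c) = tau_c² / (tau_c² + tau_0²),    tau_0 = 3 ns,

the orientation average is taken over the partially averaged tensors, and the
residual (motionally modulated) anisotropy ``(1 - S)`` feeds the fast-motion
linewidth formulas.  ``S -> 0`` reproduces the fast-motion engine exactly and
``S -> 1`` the rigid powder limit, so a single code path serves both engines;
``engine="fast"`` simply forces ``S = 0``.  This is an approximate slow-motion
lineshape, not a stochastic-Liouville solution: it honours area conservation,
the rigid-limit splitting, fast/slow consistency and monotone broadening,
which is the fidelity contract the rest of the package relies on.

Heisenberg spin exchange is applied as a uniform extra Lorentzian broadening
of the exchange frequency converted to field units (valid in the low-exchange
regime).  Field modulation is not convolved by default; a pseudo-modulation
flag approximates the 0.1 mT modulation amplitude when requested.

Units: magnetic field in mT, hyperfine couplings in MHz, correlation times in
ns, microwave frequency in GHz.  Linewidths are peak-to-peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import (
    FastRegimeError,
    InvalidParameterError,
    SpectralWindowError,
    WeightSumError,
)

__all__ = [
    "SpinComponent",
    "SpectrumTrace",
    "resonance_positions_fast",
    "fast_motion_linewidths",
    "simulate_component",
    "simulate_mixture",
    "double_integral",
    "mhz_to_mt",
    "default_field_axis",
]

PLANCK = 6.62607015e-34          # J s
BOHR_MAGNETON = 9.2740100783e-24  # J/T
HBAR = PLANCK / (2.0 * np.pi)
GAMMA_E_OVER_G = BOHR_MAGNETON / HBAR  # rad s^-1 T^-1 per unit g

#: correlation time (ns) marking the fast/slow engine hand-over in auto mode
FAST_SLOW_THRESHOLD_NS = 0.5
#: crossover time (ns) of the partial-averaging order parameter
TAU_CROSSOVER_NS = 3.0
#: relative absorption amplitude allowed at the window edges
EDGE_TOLERANCE = 0.05

Engine = Literal["auto", "fast", "slow"]


def mhz_to_mt(freq_mhz: float | np.ndarray, g: float) -> float | np.ndarray:
    """Convert a frequency in MHz to a magnetic-field interval in mT at g."""
    return np.asarray(freq_mhz) * PLANCK * 1e6 / (g * BOHR_MAGNETON) * 1e3


@dataclass(frozen=True)
class SpinComponent:
    """One nitroxide spectral species.

    Parameters
    ----------
    label : {"free", "intermediate", "strong"}
    g_tensor : principal g values (gxx, gyy, gzz), dimensionless
    A_tensor : principal hyperfine values (A'xx, A'yy, A'zz) in MHz
    tau_c : isotropic rotational correlation time in ns (> 0)
    lw_gauss, lw_lorentz : residual Gaussian / Lorentzian peak-to-peak
        broadenings in mT
    exchange_freq : Heisenberg exchange frequency in MHz
    euler_deg : (alpha, beta, gamma) tilt of the hyperfine frame relative to
        the g frame, degrees
    """

    label: str
    g_tensor: tuple[float, float, float]
    A_tensor: tuple[float, float, float]
    tau_c: float
    lw_gauss: float = 0.0
    lw_lorentz: float = 0.0
    exchange_freq: float = 0.0
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.label not in ("free", "intermediate", "strong"):
            raise InvalidParameterError(f"unknown component label {self.label!r}")
        g = np.asarray(self.g_tensor, float)
        a = np.asarray(self.A_tensor, float)
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(a))):
            raise InvalidParameterError("tensor values must be finite")
        if np.any(g <= 0):
            raise InvalidParameterError("g principal values must be positive")
        if not self.tau_c > 0:
            raise InvalidParameterError("tau_c must be > 0")
        if self.lw_gauss < 0 or self.lw_lorentz < 0:
            raise InvalidParameterError("linewidths must be >= 0")
        if self.exchange_freq < 0:
            raise InvalidParameterError("exchange frequency must be >= 0")

    @property
    def giso(self) -> float:
        return float(np.mean(self.g_tensor))

    @property
    def aiso(self) -> float:
        """Isotropic hyperfine coupling in MHz."""
        return float(np.mean(self.A_tensor))

    def with_params(self, **kwargs) -> "SpinComponent":
        return replace(self, **kwargs)


@dataclass
class SpectrumTrace:
    """A first-derivative CW EPR spectrum with acquisition metadata."""

    field_mT: np.ndarray
    intensity: np.ndarray
    mw_freq_GHz: float
    temperature_K: float = 310.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.field_mT = np.asarray(self.field_mT, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.field_mT.size < 64:
            raise InvalidParameterError("spectrum needs at least 64 field points")
        if self.field_mT.shape != self.intensity.shape:
            raise InvalidParameterError("field and intensity arrays differ in length")
        if np.any(np.diff(self.field_mT) <= 0):
            raise InvalidParameterError("field axis must be strictly increasing")
        if not (np.all(np.isfinite(self.field_mT)) and np.all(np.isfinite(self.intensity))):
            raise InvalidParameterError("spectrum contains non-finite values")


def default_field_axis(start: float = 332.5, stop: float = 342.5,
                       n: int = 4096) -> np.ndarray:
    """Uniform field axis over the standard 10 mT sweep window."""
    return np.linspace(start, stop, n)


def resonance_positions_fast(giso: float, aiso: float, mw_freq: float) -> np.ndarray:
    """First-order resonance fields (mT) of the ¹⁴N triplet in the fast limit.

    The centre (mI = 0) line sits at B0 = h·nu / (giso·muB); the mI = ±1 lines
    are displaced by ∓aiso (converted to field units).  Returned sorted
    ascending.
    """
    if giso <= 0 or mw_freq <= 0:
        raise InvalidParameterError("giso and mw_freq must be positive")
    b0 = PLANCK * mw_freq * 1e9 / (giso * BOHR_MAGNETON) * 1e3
    a_mt = mhz_to_mt(aiso, giso)
    return np.sort(np.array([b0 - a_mt, b0, b0 + a_mt]))


def _anisotropy_terms(component: SpinComponent, b0_mt: float):
    """Angular-frequency anisotropy measures (rad/s) used by the width model.

    Returns (axial g-shift Δω, rhombic g-shift δω, axial hyperfine b,
    rhombic hyperfine δb).
    """
    gx, gy, gz = component.g_tensor
    ax, ay, az = component.A_tensor
    giso = component.giso
    b0_t = b0_mt * 1e-3
    dg = gz - 0.5 * (gx + gy)
    rg = 0.5 * (gx - gy)
    d_omega = dg * BOHR_MAGNETON * b0_t / HBAR
    r_omega = rg * BOHR_MAGNETON * b0_t / HBAR
    b = 2.0 * np.pi * (az - 0.5 * (ax + ay)) * 1e6
    rb = 2.0 * np.pi * 0.5 * (ax - ay) * 1e6
    return d_omega, r_omega, b, rb, giso


def _motional_pp_widths(component: SpinComponent, b0_mt: float,
                        tau_c_ns: float) -> np.ndarray:
    """Motional Lorentzian peak-to-peak widths (mT) for mI = (+1, 0, -1).

    Second-moment (secular + pseudosecular) motional-narrowing expressions
    for coaxial axial + rhombic tensor parts:

        T2^-1(mI) = tau_c * [ (1/5)(Δω + b·mI)² + (3/5)(δω + δb·mI)²
                              + (3/50)·b²·(I(I+1) - mI²) ]

    All terms are non-negative, vanish for isotropic tensors and are linear
    in tau_c, which is the contract the rest of the package relies on.
    """
    d_omega, r_omega, b, rb, giso = _anisotropy_terms(component, b0_mt)
    tau = tau_c_ns * 1e-9
    mi = np.array([1.0, 0.0, -1.0])
    ii1 = 2.0  # I(I+1) for I = 1
    t2inv = tau * ((d_omega + b * mi) ** 2 / 5.0
                   + 3.0 * (r_omega + rb * mi) ** 2 / 5.0
                   + 0.06 * b ** 2 * (ii1 - mi ** 2))
    gamma = giso * GAMMA_E_OVER_G
    return (2.0 / np.sqrt(3.0)) * t2inv / gamma * 1e3  # T -> mT


def fast_motion_linewidths(component: SpinComponent, B0: float) -> np.ndarray:
    """Peak-to-peak Lorentzian widths (mT) for mI = (+1, 0, -1) at field B0.

    Valid only in the fast regime (tau_c below the auto-engine threshold);
    larger correlation times raise :class:`FastRegimeError` so the caller can
    switch to the slow engine.  The residual ``lw_lorentz`` is included, so
    widths collapse to it as tau_c -> 0.
    """
    if component.tau_c > FAST_SLOW_THRESHOLD_NS:
        raise FastRegimeError(
            f"tau_c = {component.tau_c} ns exceeds the fast-motion validity "
            f"threshold ({FAST_SLOW_THRESHOLD_NS} ns); use the slow engine")
    return component.lw_lorentz + _motional_pp_widths(component, B0, component.tau_c)


def _order_parameter(tau_c_ns: float) -> float:
    t2 = tau_c_ns ** 2
    return t2 / (t2 + TAU_CROSSOVER_NS ** 2)


def _width_tau_eff(tau_c_ns: float, s_order: float) -> float:
    """Effective correlation time feeding the motional width formulas.

    Only the residual, motionally modulated anisotropy fraction (1 - S)
    broadens the lines (the statically expressed part S is already in the
    resonance-position spread), and the Redfield growth saturates once
    tau_c leaves the motional-narrowing regime.
    """
    sat = tau_c_ns / (1.0 + (tau_c_ns / TAU_CROSSOVER_NS) ** 2)
    return (1.0 - s_order) ** 2 * sat


def _euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active z-y-z rotation matrix for Euler angles in radians."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def _orientation_grid(n_theta: int = 192, n_phi: int = 96):
    """Gauss-Legendre grid over the unit sphere (direction cosines, weights)."""
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = (np.arange(n_phi) + 0.5) * np.pi / n_phi   # half sphere suffices
    ct = np.repeat(x, n_phi)
    st = np.sqrt(np.clip(1.0 - ct ** 2, 0.0, None))
    cp = np.tile(np.cos(phi), n_theta)
    sp = np.tile(np.sin(phi), n_theta)
    weights = np.repeat(w, n_phi) / n_phi
    n = np.stack([st * cp, st * sp, ct], axis=1)
    return n, weights


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _cached_grid(n_theta=192, n_phi=96):
    key = (n_theta, n_phi)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = _orientation_grid(n_theta, n_phi)
    return _GRID_CACHE[key]


def _deposit(field_axis: np.ndarray, positions: np.ndarray,
             weights: np.ndarray) -> np.ndarray:
    """Linearly deposit weighted sticks onto a uniform field grid."""
    out = np.zeros_like(field_axis)
    step = field_axis[1] - field_axis[0]
    pos = (positions - field_axis[0]) / step
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    ok = (lo >= 0) & (lo < field_axis.size - 1)
    if not np.all(ok):
        lost = float(np.sum(weights[~ok]) / np.sum(weights))
        raise SpectralWindowError(
            f"{lost:.1%} of resonance positions fall outside the field window")
    np.add.at(out, lo[ok], weights[ok] * (1.0 - frac[ok]))
    np.add.at(out, lo[ok] + 1, weights[ok] * frac[ok])
    return out


def _lorentzian_abs_kernel(field_axis: np.ndarray, fwhm: float) -> np.ndarray:
    n = field_axis.size
    step = field_axis[1] - field_axis[0]
    x = (np.arange(n) - n // 2) * step
    g = max(fwhm, 1e-6) / 2.0
    k = g / (np.pi * (x ** 2 + g ** 2))
    # compact support (±4 FWHM, ~1.5% relative amplitude at the cut): caps
    # the slow 1/x² tails so the window area is conserved exactly for lines
    # well inside the sweep; discrete unit sum conserves the double integral
    k[np.abs(x) > 8.0 * g] = 0.0
    return k / k.sum()


def _gaussian_kernel(field_axis: np.ndarray, sigma: float) -> np.ndarray:
    n = field_axis.size
    step = field_axis[1] - field_axis[0]
    x = (np.arange(n) - n // 2) * step
    k = np.exp(-0.5 * np.clip(x / sigma, -30, 30) ** 2)
    return k / k.sum()


def _convolve_same(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # circular convolution: the (sub-edge-tolerance) tail mass wraps around
    # instead of being cropped, so the absorption sum — and with it the
    # double integral — is conserved exactly under width changes
    from scipy.fft import irfft, rfft
    n = y.size
    return irfft(rfft(y) * rfft(np.roll(kernel, -(n // 2))), n=n)


def _check_uniform_axis(field_axis: np.ndarray) -> None:
    steps = np.diff(field_axis)
    if steps.size == 0 or np.any(steps <= 0):
        raise InvalidParameterError("field axis must be strictly increasing")
    if np.ptp(steps) > 1e-6 * steps.mean():
        raise InvalidParameterError("field axis must be uniformly spaced")


def simulate_component(component: SpinComponent, field_axis: np.ndarray,
                       mw_freq: float, engine: Engine = "auto",
                       normalization: str = "unit-spins",
                       pseudo_modulation_mT: float = 0.0) -> np.ndarray:
    """Simulate the first-derivative spectrum of a single component.

    Parameters
    ----------
    field_axis : uniform, strictly increasing array of field values (mT)
    mw_freq : microwave frequency in GHz
    engine : "fast" forces the motionally averaged three-line model,
        "slow" the partial-averaging powder model, "auto" picks by tau_c.
    normalization : "unit-spins" scales the double integral (absorption area)
        to one; "none" leaves raw convolution amplitudes.

    Returns the intensity array on ``field_axis``.
    """
    field_axis = np.asarray(field_axis, float)
    _check_uniform_axis(field_axis)
    if mw_freq <= 0:
        raise InvalidParameterError("mw_freq must be positive")
    if engine not in ("auto", "fast", "slow"):
        raise InvalidParameterError(f"unknown engine {engine!r}")
    if engine == "auto":
        engine = "fast" if component.tau_c <= FAST_SLOW_THRESHOLD_NS else "slow"

    s_order = 0.0 if engine == "fast" else _order_parameter(component.tau_c)
    giso, aiso = component.giso, component.aiso
    b0 = PLANCK * mw_freq * 1e9 / (giso * BOHR_MAGNETON) * 1e3

    widths_pp = component.lw_lorentz + _motional_pp_widths(
        component, b0, _width_tau_eff(component.tau_c, s_order))
    if component.exchange_freq > 0:
        # low-exchange regime: uniform Lorentzian broadening, FWHM = nu_ex in
        # field units, i.e. pp width nu_ex/sqrt(3)
        widths_pp = widths_pp + mhz_to_mt(component.exchange_freq, giso) / np.sqrt(3.0)

    absorption = np.zeros_like(field_axis)
    if s_order < 1e-9:
        a_mt = mhz_to_mt(aiso, giso)
        for mi_idx, mi in enumerate((1.0, 0.0, -1.0)):
            sticks = _deposit(field_axis, np.array([b0 - mi * a_mt]), np.array([1.0]))
            absorption += _convolve_same(
                sticks, _lorentzian_abs_kernel(field_axis, np.sqrt(3.0) * widths_pp[mi_idx]))
    else:
        g_eff = giso + s_order * (np.asarray(component.g_tensor) - giso)
        a_eff = aiso + s_order * (np.asarray(component.A_tensor) - aiso)
        n, w = _cached_grid()
        rot = _euler_matrix(*np.deg2rad(component.euler_deg))
        n_a = n @ rot  # field direction expressed in the hyperfine frame
        g_orient = n ** 2 @ g_eff
        a_orient = np.sqrt(n_a ** 2 @ a_eff ** 2)  # MHz
        b_center = PLANCK * mw_freq * 1e9 / (g_orient * BOHR_MAGNETON) * 1e3
        a_field = mhz_to_mt(a_orient, giso)
        for mi_idx, mi in enumerate((1.0, 0.0, -1.0)):
            sticks = _deposit(field_axis, b_center - mi * a_field, w)
            absorption += _convolve_same(
                sticks, _lorentzian_abs_kernel(field_axis, np.sqrt(3.0) * widths_pp[mi_idx]))

    if component.lw_gauss > 0:
        absorption = _convolve_same(
            absorption, _gaussian_kernel(field_axis, component.lw_gauss / 2.0))
    if pseudo_modulation_mT > 0:
        absorption = _convolve_same(
            absorption, _gaussian_kernel(field_axis, pseudo_modulation_mT / 2.0))

    edge = max(absorption[0], absorption[-1])
    if edge > EDGE_TOLERANCE * absorption.max():
        raise SpectralWindowError(
            "field window truncates the spectrum (edge amplitude "
            f"{edge / absorption.max():.2%} of maximum)")

    derivative = np.gradient(absorption, field_axis)
    if normalization == "unit-spins":
        derivative = derivative / double_integral(field_axis, derivative)
    elif normalization != "none":
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    return derivative


def simulate_mixture(components: Sequence[SpinComponent],
                     weights: Sequence[float], field_axis: np.ndarray,
                     mw_freq: float, engine: Engine = "auto",
                     temperature_K: float = 310.15,
                     meta: dict | None = None) -> SpectrumTrace:
    """Weighted superposition of unit-spin-normalized component spectra."""
    weights = np.asarray(weights, float)
    if weights.size != len(components):
        raise WeightSumError("one weight per component required")
    if np.any(weights < 0):
        raise WeightSumError("weights must be non-negative")
    total = float(weights.sum())
    if abs(total - 1.0) > 1e-9:
        raise WeightSumError(f"weights must sum to 1 (got {total!r})")
    field_axis = np.asarray(field_axis, float)
    intensity = np.zeros_like(field_axis)
    for comp, w in zip(components, weights):
        if w > 0:
            intensity += w * simulate_component(comp, field_axis, mw_freq, engine)
    return SpectrumTrace(field_mT=field_axis, intensity=intensity,
                         mw_freq_GHz=mw_freq, temperature_K=temperature_K,
                         meta=dict(meta or {}))


def double_integral(field_mT: np.ndarray, intensity: np.ndarray) -> float:
    """Double integral of a first-derivative spectrum (∝ number of spins)."""
    absorption = cumulative_trapezoid(intensity, field_mT, initial=0.0)
    return float(np.trapezoid(absorption, field_mT))
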