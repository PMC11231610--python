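# Methods

This note documents the models behind `spinbind`, the parameters that
matter, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## Spin system and forward lineshape model

All spectra are first-derivative CW EPR lineshapes of a nitroxide radical:
one unpaired electron (S = 1/2) hyperfine-coupled to a single ¹⁴N nucleus
(I = 1).  A spectral species (`SpinComponent`) is parameterized by three
principal g values, three principal hyperfine values A′ (MHz), an isotropic
rotational correlation time τc (ns), residual Gaussian and Lorentzian
peak-to-peak broadenings (mT), a Heisenberg exchange frequency (MHz), and
Euler angles tilting the hyperfine frame against the g frame.  Isotropic
means giso and aiso are always derived from the tensors, never stored.

**Fast motion.**  Rapid tumbling averages the tensors; the spectrum is
three Lorentzian derivative lines at first-order resonance fields
B(mI) = h·ν/(giso·μB) − mI·aiso (in field units).  The mI-dependent widths
follow the second-moment motional-narrowing (Redfield/Kivelson) form

    T2⁻¹(mI) = τc·[ (1/5)(Δω + b·mI)² + (3/5)(δω + δb·mI)²
                    + (3/50)·b²·(I(I+1) − mI²) ],

where Δω, δω are the axial and rhombic g-shift frequencies at the working
field and b, δb the corresponding hyperfine anisotropies (rad/s).  These
terms are manifestly non-negative, vanish for isotropic tensors, are linear
in τc, and make the high-field (mI = −1) line broadest for nitroxide-sign
anisotropies — the qualitative signatures downstream code relies on.

**Slow motion.**  Instead of solving the stochastic Liouville equation, the
package uses a documented partial-averaging interpolation.  An order
parameter

    S(τc) = τc² / (τc² + τ0²),    τ0 = 3 ns,

scales the anisotropic part of both tensors; the spectrum is the powder
average (Gauss–Legendre grid, 192 polar × 96 azimuthal orientations) over
the partially averaged tensors, with first-order resonance fields per
orientation.  The motional Lorentzian width uses an effective correlation
time

    τ_eff = (1 − S)² · τc / (1 + (τc/τ0)²):

only the residual, still-fluctuating anisotropy fraction (1 − S) broadens
the lines (the statically expressed part S is already present as the
resonance-position spread), and the Redfield growth saturates outside the
motional-narrowing regime.  S → 0 reproduces the fast engine exactly (the
fast engine is literally the S = 0 branch of the same code path) and S → 1
converges to the rigid powder pattern with outer splitting 2·A′zz.

This model satisfies the fidelity contract the rest of the package needs —
unit-area conservation, fast/slow consistency (RMS deviation ≪ 5% of
peak-to-peak at τc ≤ 0.3 ns), rigid-limit splitting within 2%, and central
broadening monotone in τc — but it is *not* a stochastic-Liouville
solution; absolute lineshapes in the deep slow-motional crossover
(τc ≈ 3–10 ns) are approximate.  Because the generator and the
decomposition fitter share this forward model, downstream statistics are
engine-consistent by construction.

**Broadenings.**  Residual Lorentzian and Gaussian widths are peak-to-peak
(pp) quantities; FWHM = √3·pp for Lorentzian and pp = 2σ for Gaussian
lines.  Heisenberg exchange is applied as a uniform extra Lorentzian
broadening with FWHM equal to the exchange frequency converted to field
units (low-exchange regime; no line-mixing operator).  Field modulation is
not convolved by default — 0.1 mT is small against the narrowest lines — a
pseudo-modulation flag adds an equivalent Gaussian smoothing on request.

**Numerics.**  Spectra live on uniform field axes (default
332.5–342.5 mT, 4096 points — the resolution class of modern benchtop
sweeps).  Orientation sticks are deposited with linear weight splitting
between neighbouring bins; line kernels are applied by circular FFT
convolution with discretely unit-normalized kernels, so the absorption sum
(and hence the double integral) is conserved exactly under width changes.
Lorentzian kernels are truncated at ±4 FWHM (≈1.5% relative amplitude) and
renormalized: the slow 1/ΔB² tails would otherwise leak a percent-level
fraction of the area out of any finite window.  A spectrum whose
absorption amplitude at the window edge exceeds 5% of its maximum raises a
window error.  The default microwave frequency is 9.47 GHz: at X-band with
g ≈ 2.006 this centres the nitroxide triplet in the standard 10 mT window
so that even rigid-limit wings (A′zz ≈ 90 MHz) fit inside it.

## Spectral decomposition

A spectrum is modelled as scale·ΣΦx·Cx(B) + a + b·B with Φx ≥ 0 and
ΣΦx = 1.  Components are unit-double-integral normalized, so the bounded
linear least-squares amplitudes (scipy `lsq_linear`, BVLS) are exactly the
double-integral shares; the sum-to-one constraint is applied by
normalizing the non-negative amplitudes, absorbing the experimental
amplitude into one scale factor.  A linear baseline is fitted jointly —
measured spectra rarely come perfectly baselined.

The fit RMSD, as a percentage of the spectrum's peak-to-peak amplitude, is
reported and doubles as the absolute uncertainty of every fraction
(Φ ± RMSD%), clipped so Φ ± error stays within [0, 1].  A component design
with condition number above 10⁴ triggers a degeneracy warning; a pair of
components correlated above 1 − 10⁻⁷ has its combined weight assigned to
the smaller-τc member — the conservative choice with respect to claiming
strong binding.  Optional refinement of per-component τc and/or A′zz is
bounded to ±15% around the library values to keep the problem
identifiable; it wraps the linear solve in an L-BFGS-B loop.

The fitted-model spin count (`scale`) is the preferred total-intensity
estimate for noisy data: double-integrating a noisy derivative trace
accumulates a random-walk error that the model-based estimate avoids.

## Binding thermodynamics

With ligand fixed at cL (20 μM by default) and protein at cP, fractions
convert to concentrations [x] = Φx·cL.  Every transition uses the same 1:1
mass-action form, KD = (cP − [PL])(cL − [PL])/[PL] with [PL] = Φbound·cL,
KA = 1/KD, and ΔG = −R·T·ln KA with R = 8.314 J·mol⁻¹·K⁻¹.  The F→T row
uses Φ_I + Φ_S, F→I uses Φ_I alone, F→S uses Φ_S alone; I→S is the
dimensionless ratio [S]/[I].  Applying the same bimolecular model to every
pool is a deliberate simplification (surface attachment is probably not a
simple 1:1 event); its main observable consequence is that ΔG(I→S) formed
directly from the population ratio differs from ΔG(F→S) − ΔG(F→I) formed
from the two bimolecular constants.  The package computes **both** routes
(`is_transition_routes`) and reports the discrepancy instead of
reconciling it.

Uncertainties propagate to first order: σ_KD = |∂KD/∂Φ|·σ_Φ (analytic
derivative, verified against central finite differences),
σ_lnKA = σ_KD/KD, σ_ΔG = R·T·σ_lnKA.  Errors of combined pools add in
quadrature.

Temperatures: EPR-derived quantities use 310.15 K (37 °C).
Thermophoresis-derived Gibbs energies use 295.15 K — back-calculating the
published KA → ΔG chains confirms 295.15 K even though the titrations are
measured at 25 °C; users converting their own MST data at a different
temperature should pass it explicitly.

## Binding curves and apparent affinities

Four sigmoid families (Hill, Bi-Hill, Bi-Dose-Response, Double-Boltzmann)
are fitted by weighted least squares with five seeded multi-starts; the
exact parameterizations are frozen in the `curves` module docstring
because the model names alone are ambiguous across plotting software.
Apparent K′D values are read off the fitted curve at **absolute** bound
fractions 0.50 and 0.75 of total ligand (not fractions of the fitted
plateau), by log-spaced bracketing plus Brent root-finding; a curve whose
plateau lies below the requested level raises an unattainable-level error
rather than extrapolating.  The Double-Boltzmann form does not pass
exactly through zero at c = 0; it is kept as the conventional form.

## Temperature series

Per-temperature decompositions are assembled into a Φx(T) table; duplicate
temperatures are averaged, rows below 0 °C (frozen solution, powder
spectra) are flagged and excluded from analysis, and the total spin count
is normalized to the lowest non-frozen temperature.  The intermediate-state
maximum is located by quadratic interpolation through the grid peak (edge
maxima and exact ties are flagged, lower temperature wins a tie).

High-temperature classification uses two ratio rules on the non-frozen
table: **release** if the free fraction rises ≥ 0.15 between 50 °C and the
series end while ≥ 70% of the spin count survives; **trap_destroy** if the
spin count falls below 50% while the free fraction rises < 0.10;
**dynamics_only** otherwise.  The thresholds are package defaults chosen
to separate the generator presets cleanly — the underlying phenomena are
described qualitatively, not operationally, in the literature — and all
four are exposed in the configuration.  Classification depends only on
double-integral *ratios*, so it is invariant to uniform intensity
rescaling.

## MST isotherm

F_norm is the ratio of mean fluorescence in a cold window (the last 1 s
before the IR laser fires, heating onset at t = 0) to a 0.2 s hot window
centred at the evaluation time (1.5 s).  Bound fractions follow the exact
1:1 ligand-depletion quadratic with the labelled ligand at 80 nM; baseline
and amplitude of the raw signal are nuisance parameters of the fit, making
the KD estimate invariant to affine transformations of the signal.
Replicate-based per-point standard deviations are pooled into one
homoscedastic error bar — SD estimates from duplicates are far too noisy
to use as individual weights.  The 68% confidence range is the ±1σ
interval from the parameter covariance (lmfit/leastsq); titrations whose
top concentration is below the fitted KD get a plateau warning.

## Synthetic-data generator

The generator (`spinbind.synth`) is the package's stand-in for raw
spectrometer output.  Ground truth: total binding is a single 1:1
equilibrium with effective dissociation constant K_eff = K_I/(1 + K_IS);
the bound pool splits between intermediate and strong states in the fixed
ratio K_IS = [S]/[I]; an optional plateau caps the total bound fraction
(emulating isoforms that saturate below 100%).  Presets `fabp3_like`,
`fabp4_like`, `fabp5_like` echo the isoform narratives (heart-type:
highest affinity, full saturation; adipocyte-type: weakest; epidermal:
plateau at 94.8%).

Temperature dependence is two-state van't Hoff weighting,
ΔG_x(T) = ΔH_x − T·ΔS_x, with entropies anchored so the 37 °C constants
equal the preset values.  The default effective enthalpies
(ΔH_I = −120 kJ/mol for binding, ΔH_IS = −40 kJ/mol for the I→S step) were
chosen once so that the intermediate population peaks near physiological
temperature (verified 308–318 K for the default preset at 100/20 μM) and
the free fraction rises substantially by 90 °C; they are *effective*
generator parameters that concentrate the qualitative physiology into the
measured window, not claimed calorimetric values.  The `destroy` preset
uses a mild binding enthalpy (−15 kJ/mol, so little free probe appears)
plus a sigmoidal spin-count decay to ~30% above ~55 °C; `release` keeps
the spin count and uses the steep enthalpy; `flat` has zero enthalpies and
is exactly temperature-independent.

Spectra are three-component mixtures built with the shared forward model
from a library with the hallmark parameters of DOXYL-stearic-acid probes
on lipid-transport proteins at 37 °C (aiso 44.1 / 42.9 / 41.3 MHz,
τc 0.1 / 4.8 / 17.9 ns, 2.7 MHz exchange on the intermediate component,
50° hyperfine tilt on bound components; nitroxide-typical g tensor
(2.0083, 2.0061, 2.0022) and A′xx = A′yy = 16 MHz).  Noise is additive
white Gaussian with SNR defined as peak-to-peak amplitude over noise SD
(default 50).  Everything is seeded: identical parameters and seed give
identical datasets.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: baseline drift and field offsets, microwave
phase errors, temperature-dependent τc and A′zz of the components
(real spectra need per-temperature refinement), aggregation-induced
affinity shifts, a possible fourth spectral component, saturation and
modulation distortions, and correlated (non-white) noise.  Recovery
statistics on synthetic data are therefore best-case bounds.

## Problem sizes in the shipped checks

The test-suite and the acceptance script size their Monte-Carlo loops as:
100 noise seeds for fraction recovery at SNR 50 and for the Hill
cooperativity sign and MST recovery rates; 34 random mixtures at each of
SNR 20/50/200 for the pooled recovery statistics; 10 seeds per preset (20
total) for the temperature classifier; full 19-temperature grids per
series.  These sizes give stable pass/fail statistics while keeping a full
run in the tens of seconds on one CPU.

## Known limitations

* The slow-motion lineshape is an interpolation, not a stochastic-Liouville
  solution; component *shapes* in the 3–10 ns crossover are approximate
  even though all contracted invariants hold.
* Anisotropic rotational diffusion, ordering potentials (MOMD/SRLS) and
  microwave saturation are out of scope.
* Only three components are fitted; model selection between two- and
  three-component descriptions is reported via rank diagnostics only.
* The mass-action treatment of the intermediate pool ignores possible
  multi-ligand surface attachment and cooperativity; the dual-route I→S
  report quantifies the resulting internal tension rather than resolving
  it.
* Whole-protein hydropathy figures follow the windowed-profile-sum
  convention (window 9); the raw residue sum is also provided and differs
  by the sliding window's edge under-coverage.
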