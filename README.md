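# spinbind

Ligand's-perspective analysis of fatty-acid binding to lipid-transport
proteins (FABP3/4/5) by continuous-wave EPR of nitroxide spin probes, with
supporting thermophoresis and sequence-hydropathy tools.

## The problem

Fatty acid binding proteins are small β-barrel transporters that solubilize
long-chain fatty acids in the cytosol.  When the fatty acid carries a DOXYL
nitroxide (5-DSA / 16-DSA), its CW EPR spectrum reports the ligand's
rotational mobility and local polarity, so a single spectrum resolves
**three ligand states**: freely tumbling (τc ≈ 0.1 ns), intermediately
bound at the protein surface or portal region (τc ≈ 5 ns, with slight
Heisenberg exchange broadening), and strongly bound inside the β-barrel
(τc ≈ 18 ns, lower hyperfine coupling).  `spinbind` simulates these
three-component derivative spectra, decomposes measured spectra into state
fractions Φx by double-integral weighting, and converts the fractions into
binding thermodynamics.

## The model

* **Lineshapes.** S = 1/2 electron coupled to one ¹⁴N (I = 1).  Fast
  motion: three Lorentzian lines with motional-narrowing widths
  ΔB(mI) = A + B·mI + C·mI².  Slow motion: a partial-averaging powder model
  — the tensor anisotropy is scaled by S(τc) = τc²/(τc² + τ0²) (τ0 = 3 ns)
  and orientation-averaged, converging to the rigid powder pattern with
  outer splitting 2·A′zz.  See `docs/methods.md` for the fidelity contract.
* **Decomposition.** Spectrum ≈ scale · Σx Φx·Cx(B) + linear baseline, with
  Φx ≥ 0, ΣΦx = 1; unit-spin normalization makes the solver amplitudes
  equal to double-integral shares.  Uncertainty: Φ ± RMSD% of the fit.
* **Thermodynamics.** [x] = Φx·cL; each transition (free→total, free→
  intermediate, free→strong, intermediate→strong) is treated with the 1:1
  mass-action form KD = [P]·[L]/[PL], KA = 1/KD, and the van't Hoff
  relation ΔG = −R·T·ln KA (EPR at 310.15 K, MST at 295.15 K).
* **Binding curves.** Hill, Bi-Hill, Bi-Dose-Response and Double-Boltzmann
  fits of Φbound(cP), with apparent K′D read at absolute bound levels of
  50% and 75%.
* **MST.** F_norm from cold/hot trace windows and the exact 1:1
  ligand-depletion isotherm for KD with a 68% confidence range.
* **Sequences.** Kyte–Doolittle hydropathy and Zimmermann polarity, per
  residue, windowed (ProtScale convention) and whole-protein.

A seeded synthetic-data generator (`spinbind.synth`) produces ground-truth
fractions, spectra, concentration/temperature series and MST titrations so
the entire pipeline is testable end to end.

## Worked example

```python
from spinbind import (TruthParams, component_library, fit_weights,
                      kd_from_mass_action, thermo_chain)
from spinbind.synth import synth_concentration_series
from spinbind.thermo import T_EPR

params = TruthParams.from_preset("fabp3_like", noise_snr=50, seed=1)
series = synth_concentration_series(params)   # 20 uM probe, cP = 0..200 uM
library = component_library()

point, trace = series[2]                      # the 100/20 uM sample
res = fit_weights(trace, library)
print("fractions:", {k: round(v, 3) for k, v in res.weights.items()},
      f"(RMSD {res.rmsd_pct:.1f}%)")

phi_bound = res.weights["intermediate"] + res.weights["strong"]
kd = kd_from_mass_action(100.0, 20.0, phi_bound)
chain = thermo_chain(kd, T_EPR)
print(f"KD = {kd:.2f} uM,  dG(F->T, 37 C) = {chain['dG_kJ_mol']:.1f} kJ/mol")
```

prints

```
fractions: {'free': 0.027, 'intermediate': 0.721, 'strong': 0.252} (RMSD 1.9%)
KD = 2.24 uM,  dG(F->T, 37 C) = -33.5 kJ/mol
```

At 100 μM protein and 20 μM probe, 97% of the ligand is bound — mostly in
the intermediate state, as expected at body temperature — and the
mass-action KD recovered from the noisy spectrum (2.24 μM) sits within the
fit uncertainty of the generator's effective truth (2.22 μM).  The
corresponding association Gibbs energy, −33.5 kJ/mol, is strongly
exergonic, typical for micromolar fatty-acid binding.

## Command line

```bash
spinbind synth --out run1 --seed 1     # synthetic concentration series
spinbind fit --out run1                # decompose into fractions
spinbind thermo --out run1             # KD / KA / dG per transition
spinbind bindcurve --out run1          # Hill-family fits + apparent K'D
spinbind tempseries --out run2         # temperature series + classification
spinbind hydropathy --out run3         # FABP sequence hydropathy/polarity
spinbind mst --out run4 points.csv     # 1:1 MST isotherm fit
```

All commands accept `--config <yaml>`, `--seed N` and `-v`; every run
writes a `run.json` with the package version, seed and config hash.

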