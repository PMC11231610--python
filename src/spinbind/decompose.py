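"""Multi-component decomposition of CW EPR spectra.

A measured (or synthetic) derivative spectrum is modelled as a weighted sum
of unit-spin-normalized component spectra plus a linear baseline,

    y(B) ≈ s · Σx Φx · Cx(B) + a + b·B,

with Φx ≥ 0 and Σ Φx = 1.  Because every component is normalized to unit
double integral, the non-negative least-squares amplitudes are proportional
to the double-integral shares, so the reported fractions are exactly the
double-integral proportions of the fitted components.  The fit RMSD,
expressed as a percentage of the spectrum's peak-to-peak amplitude, doubles
as the absolute uncertainty of each fraction (Φ ± RMSD%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .errors import DegeneracyWarning, EmptySpectrumError, FitError
from .forward import SpectrumTrace, SpinComponent, double_integral, simulate_component

__all__ = [
    "DecompositionResult",
    "fit_weights",
    "fractions_from_double_integrals",
    "phi_uncertainty",
]

#: condition number of the component design above which degeneracy is flagged
DEGENERACY_CONDITION = 1e4
#: pairwise correlation above which two components are treated as one
DEGENERACY_CORRELATION = 1.0 - 1e-7
#: bounded refinement range around the library values
REFINE_FRACTION = 0.15

RefineMode = Literal["none", "tau_c", "Azz", "both"]


@dataclass
class DecompositionResult:
    """Component fractions fitted to one spectrum."""

    weights: dict[str, float]
    weight_errors: dict[str, float]
    rmsd_pct: float
    fitted_trace: np.ndarray
    refined_params: dict[str, dict[str, float]] = field(default_factory=dict)
    condition_number: float = np.nan
    scale: float = np.nan
    baseline: tuple[float, float] = (0.0, 0.0)

    @property
    def phi(self) -> np.ndarray:
        return np.array(list(self.weights.values()))

    def as_dict(self) -> dict:
        return {
            "weights": self.weights,
            "weight_errors": self.weight_errors,
            "rmsd_pct": self.rmsd_pct,
            "refined_params": self.refined_params,
            "condition_number": self.condition_number,
        }


def _component_matrix(components: Sequence[SpinComponent], field_axis: np.ndarray,
                      mw_freq: float, engine: str) -> np.ndarray:
    return np.column_stack([
        simulate_component(c, field_axis, mw_freq, engine=engine)
        for c in components])


def _solve_linear(design: np.ndarray, y: np.ndarray, n_comp: int):
    """Non-negative component amplitudes + free linear baseline."""
    lb = np.r_[np.zeros(n_comp), -np.inf, -np.inf]
    ub = np.full(n_comp + 2, np.inf)
    res = lsq_linear(design, y, bounds=(lb, ub), method="bvls")
    return res.x, y - design @ res.x


def fit_weights(spectrum: SpectrumTrace, components: Sequence[SpinComponent],
                refine: RefineMode = "none", engine: str = "auto") -> DecompositionResult:
    """Fit component fractions Φx to a spectrum.

    Weights minimize the residual sum of squares under non-negativity; the
    sum-to-one constraint is enforced by normalizing the non-negative
    amplitudes (the overall experimental amplitude is one global scale
    factor).  ``refine`` optionally performs a bounded (±15%) nonlinear
    refinement of per-component tau_c and/or A'zz around the library values,
    wrapping the linear solve.

    A near-rank-deficient component design triggers a
    :class:`DegeneracyWarning` carrying the condition number; in that case
    the weight shared by an indistinguishable pair is assigned to the
    smaller-tau_c member (conservative with respect to claiming strong
    binding).
    """
    if len(components) == 0:
        raise ValueError("component library is empty")
    axis = spectrum.field_mT
    y = spectrum.intensity
    nu = spectrum.mw_freq_GHz
    labels = [c.label for c in components]

    def build(comps):
        mat = _component_matrix(comps, axis, nu, engine)
        return np.column_stack([mat, np.ones_like(axis), axis - axis.mean()])

    current = list(components)

    def objective(theta):
        comps = _apply_refinement(components, theta, refine)
        _, resid = _solve_linear(build(comps), y, len(comps))
        return float(resid @ resid)

    if refine != "none":
        theta0, bounds = _refinement_vector(components, refine)
        opt = minimize(objective, theta0, bounds=bounds, method="L-BFGS-B",
                       options={"maxiter": 60, "eps": 1e-3})
        if not opt.success and not np.isfinite(opt.fun):
            raise FitError("refinement did not converge", best=opt)
        current = _apply_refinement(components, opt.x, refine)

    design = build(current)
    comp_cols = design[:, :len(current)]
    norm_cols = comp_cols / np.linalg.norm(comp_cols, axis=0)
    cond = float(np.linalg.cond(norm_cols))

    amp, resid = _solve_linear(design, y, len(current))
    raw = amp[:len(current)].copy()
    total = raw.sum()
    if total <= 0:
        raise EmptySpectrumError("all component amplitudes vanished")

    if cond > DEGENERACY_CONDITION:
        warnings.warn(DegeneracyWarning(
            f"component design is ill-conditioned (cond = {cond:.3g})"))
        corr = np.corrcoef(norm_cols.T)
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                if corr[i, j] > DEGENERACY_CORRELATION:
                    keep, drop = ((i, j) if current[i].tau_c <= current[j].tau_c
                                  else (j, i))
                    raw[keep] += raw[drop]
                    raw[drop] = 0.0

    phi = raw / raw.sum()
    rmsd_pct = 100.0 * float(np.sqrt(np.mean(resid ** 2)) / np.ptp(y)) if np.ptp(y) > 0 else 0.0
    fitted = design @ amp

    refined_params = {}
    if refine != "none":
        for c0, c1 in zip(components, current):
            entry = {}
            if refine in ("tau_c", "both"):
                entry["tau_c"] = c1.tau_c
            if refine in ("Azz", "both"):
                entry["Azz"] = c1.A_tensor[2]
            refined_params[c0.label] = entry

    errors = {lab: min(rmsd_pct / 100.0, 1.0) for lab in labels}
    return DecompositionResult(
        weights=dict(zip(labels, map(float, phi))),
        weight_errors=errors,
        rmsd_pct=rmsd_pct,
        fitted_trace=fitted,
        refined_params=refined_params,
        condition_number=cond,
        scale=float(total),
        baseline=(float(amp[-2]), float(amp[-1])),
    )


def _refinement_vector(components, refine):
    theta0, bounds = [], []
    for c in components:
        if refine in ("tau_c", "both"):
            theta0.append(c.tau_c)
            bounds.append((c.tau_c * (1 - REFINE_FRACTION), c.tau_c * (1 + REFINE_FRACTION)))
        if refine in ("Azz", "both"):
            azz = c.A_tensor[2]
            bounds.append(tuple(sorted((azz * (1 - REFINE_FRACTION),
                                        azz * (1 + REFINE_FRACTION)))))
            theta0.append(azz)
    return np.array(theta0), bounds


def _apply_refinement(components, theta, refine):
    out, k = [], 0
    for c in components:
        kwargs = {}
        if refine in ("tau_c", "both"):
            kwargs["tau_c"] = float(theta[k]); k += 1
        if refine in ("Azz", "both"):
            ax, ay, _ = c.A_tensor
            kwargs["A_tensor"] = (ax, ay, float(theta[k])); k += 1
        out.append(c.with_params(**kwargs))
    return out


def fractions_from_double_integrals(field_mT: np.ndarray,
                                    traces: Sequence[np.ndarray]) -> np.ndarray:
    """Fractions of each fitted component trace by double-integral share.

    ``fraction_x = DI_x / Σ DI``; equals the solver weights when components
    are unit-spins normalized, and is invariant to a common rescaling.
    """
    dis = np.array([double_integral(field_mT, t) for t in traces])
    total = dis.sum()
    if total <= 0:
        raise EmptySpectrumError("total double integral is zero")
    return dis / total


def phi_uncertainty(result: DecompositionResult) -> dict[str, tuple[float, float, float]]:
    """Φ ± absolute error per component, clipped so Φ ± err stays in [0, 1].

    Returns ``{label: (phi, err_low, err_high)}`` where the errors are the
    fit RMSD% applied as an absolute fraction error.
    """
    err = result.rmsd_pct / 100.0
    out = {}
    for lab, phi in result.weights.items():
        lo = min(err, phi)        # clip so phi - err_low >= 0
        hi = min(err, 1.0 - phi)  # clip so phi + err_high <= 1
        out[lab] = (phi, lo, hi)
    return out
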