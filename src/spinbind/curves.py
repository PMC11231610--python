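"""Binding-curve models and apparent-affinity readout.

Four sigmoid families are fitted to bound-fraction-versus-protein-
concentration data.  The exact parameterizations (frozen here because the
names alone are ambiguous across plotting packages) are, with c ≥ 0 in μM:

hill
    θ(c) = θmax · cⁿ / (Kⁿ + cⁿ)
    params: theta_max, K (μM), n

bihill
    θ(c) = θmax · [ f·c^n1/(K1^n1 + c^n1) + (1−f)·c^n2/(K2^n2 + c^n2) ]
    params: theta_max, frac f ∈ [0,1], K1, n1, K2, n2

bidoseresp  (two logistic transitions in log10-concentration)
    θ(c) = θmax · [ f / (1 + 10^{h1·(logK1 − log10 c)})
                    + (1−f) / (1 + 10^{h2·(logK2 − log10 c)}) ]
    params: theta_max, frac, logK1, h1, logK2, h2;  θ(0) = 0 by continuity

double_boltzmann  (two logistic transitions in linear concentration)
    θ(c) = θmax · [ f / (1 + exp((c1 − c)/s1)) + (1−f) / (1 + exp((c2 − c)/s2)) ]
    params: theta_max, frac, c1, s1, c2, s2

All are non-decreasing in c for positive slopes/coefficients.  Apparent
affinities K′D are read off the fitted curve as the smallest concentration
at which it crosses an absolute bound-fraction level (0.50 or 0.75 of the
total ligand, not of the fitted plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import FitError, PlateauWarning, UnattainableLevelError

__all__ = ["CurveFit", "evaluate_binding_curve", "fit_binding_curve", "apparent_kd",
           "MODELS"]

MODELS = ("hill", "bihill", "bidoseresp", "double_boltzmann")

_PARAM_NAMES = {
    "hill": ("theta_max", "K", "n"),
    "bihill": ("theta_max", "frac", "K1", "n1", "K2", "n2"),
    "bidoseresp": ("theta_max", "frac", "logK1", "h1", "logK2", "h2"),
    "double_boltzmann": ("theta_max", "frac", "c1", "s1", "c2", "s2"),
}


@dataclass
class CurveFit:
    model: str
    params: dict[str, float]
    param_errors: dict[str, float]
    covariance: np.ndarray
    rss: float
    r_squared: float
    x_units: str = "uM"
    c_range: tuple[float, float] = (0.0, np.inf)
    n_points: int = 0
    warnings: list[str] = field(default_factory=list)

    def __call__(self, c):
        return evaluate_binding_curve(self.model, self.params, c)


def _hill(c, theta_max, k, n):
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.power(c, n)
        out = theta_max * cn / (k ** n + cn)
    return np.where(c == 0, 0.0, out)


def evaluate_binding_curve(model: str, params: dict[str, float], c) -> np.ndarray:
    """Bound fraction θ(c) for one of the four frozen model forms."""
    c = np.asarray(c, float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    p = params
    if model == "hill":
        out = _hill(c, p["theta_max"], p["K"], p["n"])
    elif model == "bihill":
        out = p["theta_max"] * (
            p["frac"] * _hill(c, 1.0, p["K1"], p["n1"])
            + (1 - p["frac"]) * _hill(c, 1.0, p["K2"], p["n2"]))
    elif model == "bidoseresp":
        with np.errstate(divide="ignore"):
            logc = np.log10(np.where(c > 0, c, np.nan))
        t1 = 1.0 / (1.0 + 10 ** (p["h1"] * (p["logK1"] - logc)))
        t2 = 1.0 / (1.0 + 10 ** (p["h2"] * (p["logK2"] - logc)))
        out = p["theta_max"] * (p["frac"] * t1 + (1 - p["frac"]) * t2)
        out = np.where(c == 0, 0.0, out)
    elif model == "double_boltzmann":
        t1 = 1.0 / (1.0 + np.exp((p["c1"] - c) / p["s1"]))
        t2 = 1.0 / (1.0 + np.exp((p["c2"] - c) / p["s2"]))
        out = p["theta_max"] * (p["frac"] * t1 + (1 - p["frac"]) * t2)
    else:
        raise ValueError(f"unknown model {model!r}")
    return out if out.shape else float(out)


def _initial_guesses(model, c, y, rng):
    cmax = float(c.max())
    ymax = float(max(y.max(), 0.05))
    half = float(np.interp(0.5 * ymax, y, c)) if y.max() > 0 else cmax / 4
    half = min(max(half, 1e-3), cmax)
    base = {
        "hill": [ymax, half, 1.5],
        "bihill": [ymax, 0.6, half * 0.7, 1.5, half * 2.0, 1.5],
        "bidoseresp": [ymax, 0.6, np.log10(half * 0.7), 1.0, np.log10(half * 2.0), 1.0],
        "double_boltzmann": [ymax, 0.6, half * 0.7, half / 4, half * 2.0, half / 2],
    }[model]
    theta = np.array(base, float)
    jitter = 1.0 + 0.3 * rng.standard_normal(theta.size)
    return theta * np.abs(jitter)


def _bounds(model, c):
    cmax = float(c.max())
    big = 50 * cmax
    if model == "hill":
        lo, hi = [1e-3, 1e-4, 0.05], [1.05, big, 10.0]
    elif model == "bihill":
        lo = [1e-3, 0.0, 1e-4, 0.05, 1e-4, 0.05]
        hi = [1.05, 1.0, big, 10.0, big, 10.0]
    elif model == "bidoseresp":
        lo = [1e-3, 0.0, -4.0, 0.05, -4.0, 0.05]
        hi = [1.05, 1.0, np.log10(big), 10.0, np.log10(big), 10.0]
    else:
        lo = [1e-3, 0.0, -big, 1e-3, -big, 1e-3]
        hi = [1.05, 1.0, big, big, big, big]
    return np.array(lo), np.array(hi)


def fit_binding_curve(points: Sequence[tuple], model: str = "hill") -> CurveFit:
    """Weighted least-squares fit of a binding-curve model.

    ``points`` is a sequence of ``(c, phi_bound)`` or ``(c, phi_bound,
    sigma)`` tuples.  Five seeded starts (seeds 0–4) guard against local
    minima; the best solution by residual sum of squares wins.  Parameter
    standard errors come from the Jacobian-based covariance.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    pts = [tuple(p) for p in points]
    c = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    sig = np.array([p[2] if len(p) > 2 and p[2] > 0 else 1.0 for p in pts], float)
    names = _PARAM_NAMES[model]
    if c.size < max(4, len(names)):
        raise ValueError(f"need at least {max(4, len(names))} points for {model}")
    order = np.argsort(c)
    c, y, sig = c[order], y[order], sig[order]
    lo, hi = _bounds(model, c)

    def resid(theta):
        pred = evaluate_binding_curve(model, dict(zip(names, theta)), c)
        return (np.asarray(pred) - y) / sig

    best = None
    for seed in range(5):
        rng = np.random.default_rng(seed)
        theta0 = np.clip(_initial_guesses(model, c, y, rng), lo, hi)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                max_nfev=4000)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(f"{model} fit failed to converge from all starts")

    theta = best.x
    params = dict(zip(names, theta))
    rss = float(2 * best.cost)
    dof = max(c.size - len(names), 1)
    jac = best.jac
    jtj = jac.T @ jac
    try:
        cov = np.linalg.pinv(jtj) * rss / dof
        perr = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
    except np.linalg.LinAlgError:
        cov = np.full((len(names), len(names)), np.nan)
        perr = dict.fromkeys(names, np.nan)
    ss_tot = float(np.sum(((y - y.mean()) / sig) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else np.nan

    fit = CurveFit(model=model, params=params, param_errors=perr, covariance=cov,
                   rss=rss, r_squared=r2, c_range=(float(c.min()), float(c.max())),
                   n_points=c.size)
    k_est = params.get("K", params.get("K1", 10 ** params.get("logK1", np.nan)
                                       if "logK1" in params else np.nan))
    if np.isfinite(k_est) and c.max() < k_est:
        msg = (f"plateau not identifiable: max concentration {c.max():g} uM is "
               f"below the affinity estimate {k_est:g} uM")
        fit.warnings.append(msg)
        warnings.warn(PlateauWarning(msg))
    return fit


def apparent_kd(fit: CurveFit, level: float) -> float:
    """Smallest concentration (μM) at which the fitted curve reaches ``level``.

    ``level`` is an absolute bound fraction (typically 0.50 or 0.75).  Found
    by log-spaced bracketing followed by root bisection on the fitted curve;
    raises :class:`UnattainableLevelError` when the curve never reaches the
    level within the admissible range.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    c_hi = max(fit.c_range[1], 1.0) * 1e3
    grid = np.concatenate([[0.0], np.geomspace(1e-6, c_hi, 600)])
    vals = np.asarray(evaluate_binding_curve(fit.model, fit.params, grid))
    above = np.nonzero(vals >= level)[0]
    if above.size == 0:
        raise UnattainableLevelError(
            f"curve maximum {vals.max():.3f} never reaches level {level}")
    i = above[0]
    if i == 0:
        return 0.0
    f = lambda c: float(evaluate_binding_curve(fit.model, fit.params, c)) - level
    return float(brentq(f, grid[i - 1], grid[i], xtol=1e-10, rtol=1e-12))


def plot_binding_curve(points, fits, path=None):
    """Bound fraction vs concentration with fitted curves and error bars.

    ``fits`` is a mapping label -> :class:`CurveFit`.  Requires matplotlib
    (optional dependency); returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [tuple(p) for p in points]
    c = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    err = np.array([p[2] if len(p) > 2 else 0.0 for p in pts], float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(c, y, yerr=err, fmt="o", ms=4, capsize=2, color="k",
                label="data")
    grid = np.geomspace(max(c.min(), 1e-3), c.max() * 1.2, 300)
    for label, fit in fits.items():
        ax.plot(grid, evaluate_binding_curve(fit.model, fit.params, grid),
                label=label)
    ax.set_xscale("log")
    ax.set_xlabel("protein concentration (uM)")
    ax.set_ylabel("bound fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
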