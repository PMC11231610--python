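"""Microscale-thermophoresis (MST) signal extraction and 1:1 isotherm fit.

MST tracks the fluorescence of a labelled ligand while an IR laser heats the
capillary.  The signal F_norm is the ratio of the mean fluorescence in a
"cold" window just before heating to the mean in a "hot" window at a fixed
evaluation time after heating starts (1.5 s by default, with the heating
onset at t = 0).  Against titrated protein, F_norm follows the bound
fraction of the 1:1 equilibrium

    f(cP) = (cP + L0 + KD − sqrt((cP + L0 + KD)² − 4·cP·L0)) / (2·L0),

the exact ligand-depletion solution with labelled-ligand concentration L0
(80 nM by default).  Baseline and amplitude of the raw signal are nuisance
parameters absorbed by the fit, which reports KD with a 68% confidence
range from the parameter covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .errors import FitError, PlateauWarning, TraceFormatError

__all__ = ["MstSeries", "MstFitResult", "fnorm_from_trace",
           "bound_fraction_1to1", "fit_kd_mst"]

COLD_WINDOW_S = 1.0   # width of the pre-heating window ending at t = 0
HOT_WINDOW_S = 0.2    # width of the window centred at t_end


@dataclass
class MstSeries:
    """Dose-response points of one MST titration.

    ``points`` holds ``(c_protein_uM, signal, replicate_id)`` triples; the
    signal may be raw F_norm or an already-normalized bound fraction —
    baseline and amplitude are fitted either way.
    """

    points: list[tuple[float, float, int]]
    ligand_conc_nM: float = 80.0
    t_end_s: float = 1.5

    def __post_init__(self):
        if self.ligand_conc_nM <= 0:
            raise ValueError("ligand concentration must be positive")
        if len({round(p[0], 12) for p in self.points}) < 6:
            raise ValueError("need >= 6 distinct concentrations for fitting")


@dataclass
class MstFitResult:
    kd_uM: float
    kd_stderr_uM: float
    confidence_68_uM: tuple[float, float]
    confidence_pct: float
    baseline: float
    amplitude: float
    rss: float
    warnings: list[str] = field(default_factory=list)


def fnorm_from_trace(time_s: np.ndarray, fluorescence: np.ndarray,
                     t_end: float = 1.5) -> float:
    """F_norm = mean(cold window) / mean(hot window at ``t_end``).

    The heating onset defines t = 0; the trace must span the cold window
    [−1 s, 0] and the hot window of 0.2 s centred at ``t_end``.
    """
    time_s = np.asarray(time_s, float)
    fl = np.asarray(fluorescence, float)
    cold = (time_s >= -COLD_WINDOW_S) & (time_s <= 0.0)
    hot = np.abs(time_s - t_end) <= HOT_WINDOW_S / 2.0
    if not (cold.any() and hot.any()):
        raise TraceFormatError(
            "trace must cover the pre-heating baseline and the evaluation "
            f"window at t = {t_end} s")
    return float(np.mean(fl[cold]) / np.mean(fl[hot]))


def bound_fraction_1to1(c_protein: float | np.ndarray, kd: float,
                        ligand_total: float) -> float | np.ndarray:
    """Exact 1:1 bound-ligand fraction with ligand depletion.

    All concentrations in the same units (μM here).  ``ligand_total = 0``
    degenerates to the hyperbolic limit cP/(cP + KD).
    """
    c_p = np.asarray(c_protein, float)
    if np.any(c_p < 0) or kd < 0 or ligand_total < 0:
        raise ValueError("concentrations and KD must be >= 0")
    if ligand_total == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(c_p + kd > 0, c_p / (c_p + kd), 0.0)
        return out if out.shape else float(out)
    s = c_p + ligand_total + kd
    disc = s * s - 4.0 * c_p * ligand_total
    f = (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * ligand_total)
    f = np.clip(f, 0.0, 1.0)
    return f if f.shape else float(f)


def fit_kd_mst(series: MstSeries) -> MstFitResult:
    """Weighted least-squares 1:1 isotherm fit of an MST titration.

    Replicates are averaged per concentration with their standard deviation
    as the error bar; baseline and amplitude are nuisance parameters.  The
    68% confidence range comes from the KD standard error (1σ) of the
    parameter covariance.  A titration that never approaches its plateau
    triggers a :class:`PlateauWarning`.
    """
    pts = np.array([(p[0], p[1]) for p in series.points], float)
    l0 = series.ligand_conc_nM * 1e-3  # nM -> uM
    concs = np.unique(pts[:, 0])
    means = np.array([pts[pts[:, 0] == c, 1].mean() for c in concs])
    sds = np.array([pts[pts[:, 0] == c, 1].std(ddof=1)
                    if (pts[:, 0] == c).sum() > 1 else np.nan for c in concs])
    # duplicate-based SD estimates are too noisy to weight point-by-point;
    # pool them into one homoscedastic error bar
    med = np.nanmedian(sds)
    sds = np.full_like(means, med if np.isfinite(med) and med > 0 else 1.0)

    span = means.max() - means.min()
    params = Parameters()
    params.add("kd", value=max(np.median(concs), 1e-3), min=1e-6, max=1e5)
    params.add("baseline", value=float(means[np.argmin(concs)]))
    params.add("amplitude", value=float(span if span > 0 else 1.0),
               min=-10 * abs(span or 1.0), max=10 * abs(span or 1.0))

    def residual(p):
        model = p["baseline"] + p["amplitude"] * bound_fraction_1to1(
            concs, p["kd"].value, l0)
        return (model - means) / sds

    out = lm_minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError("MST isotherm fit did not converge", best=out)
    kd = float(out.params["kd"].value)
    stderr = out.params["kd"].stderr
    stderr = float(stderr) if stderr is not None else np.inf

    result = MstFitResult(
        kd_uM=kd, kd_stderr_uM=stderr,
        confidence_68_uM=(kd - stderr, kd + stderr),
        confidence_pct=100.0 * stderr / kd if kd > 0 else np.inf,
        baseline=float(out.params["baseline"].value),
        amplitude=float(out.params["amplitude"].value),
        rss=float(np.sum(out.residual ** 2)),
    )
    if concs.max() < kd:
        msg = (f"no plateau: max protein concentration {concs.max():g} uM is "
               f"below the fitted KD {kd:g} uM; interval is wide")
        result.warnings.append(msg)
        warnings.warn(PlateauWarning(msg))
    return result
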