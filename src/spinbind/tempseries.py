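"""Temperature-resolved binding-state analysis.

Per-temperature spectral decompositions are assembled into a Φx(T) table,
the interior maximum of the intermediately bound population is located, and
the high-temperature fate of the ligand is classified:

release
    the free fraction rises markedly above ~50 °C while the total double
    integral (spin count) is retained — the protein gradually lets go of an
    intact radical;
trap_destroy
    the spin count collapses with little gain in free ligand — the probe
    stays trapped inside the (denaturing) protein and its nitroxide is
    chemically destroyed;
dynamics_only
    neither signature — only rotational-dynamics changes with temperature.

Rows below 0 °C (frozen solution, powder-type spectra) are kept in the raw
table but flagged and excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decompose import DecompositionResult
from .errors import EdgeMaximumWarning, InsufficientSeriesError

__all__ = ["ClassifierThresholds", "TempSeriesResult", "build_series",
           "intermediate_maximum", "classify_high_T"]

FREEZE_T = 273.15
HIGH_T_START = 323.15   # 50 degC: start of the high-temperature comparison
HIGH_T_REQUIRED = 333.15  # 60 degC: minimum series end for classification


@dataclass(frozen=True)
class ClassifierThresholds:
    """Package defaults separating the release / trap-destroy presets."""

    release_free_rise: float = 0.15   # min rise of phi_free above 50 degC
    destroy_free_rise: float = 0.10   # max rise compatible with trap/destroy
    release_integral_keep: float = 0.70  # min retained double-integral share
    destroy_integral_drop: float = 0.50  # max retained share for trap/destroy


@dataclass
class TempSeriesResult:
    table: pd.DataFrame
    classification: str | None = None
    T_intermediate_max: float | None = None
    evidence: dict = field(default_factory=dict)


def build_series(decompositions: Sequence[tuple[float, DecompositionResult, float]]
                 ) -> TempSeriesResult:
    """Assemble a sorted Φx(T) table from per-temperature decompositions.

    ``decompositions`` holds ``(T_K, result, raw_double_integral)`` triples.
    Duplicate temperatures are averaged.  The total double integral is
    normalized to its value at the lowest analyzed (non-frozen)
    temperature.
    """
    rows = []
    for t, res, di in decompositions:
        w = res.weights
        rows.append({"T_K": float(t), "phi_free": w.get("free", 0.0),
                     "phi_intermediate": w.get("intermediate", 0.0),
                     "phi_strong": w.get("strong", 0.0),
                     "double_integral": float(di)})
    df = pd.DataFrame(rows).groupby("T_K", as_index=False).mean().sort_values("T_K")
    df["frozen"] = df["T_K"] < FREEZE_T
    usable = df[~df["frozen"]]
    if len(usable) < 4:
        raise InsufficientSeriesError(
            f"need >= 4 non-frozen temperatures, got {len(usable)}")
    ref = usable["double_integral"].iloc[0]
    df["di_rel"] = df["double_integral"] / ref
    return TempSeriesResult(table=df.reset_index(drop=True))


def intermediate_maximum(series: TempSeriesResult) -> tuple[float, tuple[float, float]]:
    """Temperature of the intermediate-population maximum.

    Quadratic interpolation through the grid maximum and its neighbours;
    returns ``(T_max, (T_left, T_right))`` with the bracketing grid window.
    An edge maximum is returned uninterpolated with an
    :class:`EdgeMaximumWarning`; an exact tie returns the lower temperature
    and flags the tie.
    """
    df = series.table[~series.table["frozen"]].reset_index(drop=True)
    phi = df["phi_intermediate"].to_numpy()
    t = df["T_K"].to_numpy()
    if np.ptp(phi) == 0:
        raise ValueError("intermediate fraction is constant; no maximum")
    peak = phi.max()
    idxs = np.nonzero(phi == peak)[0]
    if idxs.size > 1:
        warnings.warn(EdgeMaximumWarning(
            f"tie between {idxs.size} equal maxima; lower temperature returned"))
    i = int(idxs[0])
    if i == 0 or i == phi.size - 1:
        warnings.warn(EdgeMaximumWarning(
            "intermediate maximum at the series edge; no interpolation"))
        series.T_intermediate_max = float(t[i])
        return float(t[i]), (float(t[max(i - 1, 0)]), float(t[min(i + 1, t.size - 1)]))
    y0, y1, y2 = phi[i - 1], phi[i], phi[i + 1]
    denom = (y0 - 2 * y1 + y2)
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    step_l, step_r = t[i] - t[i - 1], t[i + 1] - t[i]
    t_max = t[i] + shift * (step_r if shift > 0 else step_l)
    series.T_intermediate_max = float(t_max)
    return float(t_max), (float(t[i - 1]), float(t[i + 1]))


def classify_high_T(series: TempSeriesResult,
                    thresholds: ClassifierThresholds | None = None) -> str:
    """Classify the high-temperature behaviour of the series.

    Always returns a label and stores the triggering statistics in
    ``series.evidence``.  Requires the series to reach at least 60 °C.
    """
    th = thresholds or ClassifierThresholds()
    df = series.table[~series.table["frozen"]]
    if df["T_K"].max() < HIGH_T_REQUIRED:
        raise InsufficientSeriesError("series must reach 333.15 K (60 degC)")
    base = df[df["T_K"] <= HIGH_T_START]
    ref_free = base["phi_free"].iloc[-1] if len(base) else df["phi_free"].iloc[0]
    free_rise = float(df["phi_free"].iloc[-1] - ref_free)
    di_end = float(df["di_rel"].iloc[-1])
    evidence = {"free_rise_above_50C": free_rise, "di_retained": di_end,
                "thresholds": th.__dict__}
    if free_rise >= th.release_free_rise and di_end >= th.release_integral_keep:
        label = "release"
    elif di_end < th.destroy_integral_drop and free_rise < th.destroy_free_rise:
        label = "trap_destroy"
    else:
        label = "dynamics_only"
    series.classification = label
    series.evidence = evidence
    return label
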