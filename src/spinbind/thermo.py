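"""Mass-action binding thermodynamics from spectral component fractions.

Three ligand states are distinguished: free (F), intermediately bound (I)
and strongly bound (S); T denotes the totally bound pool I + S.  With the
ligand fixed at total concentration cL and protein at cP, the component
fractions Φx convert to concentrations [x] = Φx·cL.  Each binding transition
is described by the same 1:1 mass-action model of two interacting partners:

    KD = [P]free·[L]free / [PL],   [PL] = Φbound·cL,  [P]free = cP − [PL],

with KA = 1/KD and the van't Hoff relation ΔG = −R·T·ln KA (R = 8.314
J·mol⁻¹·K⁻¹).  The I→S interconversion is a unimolecular ratio
K_IS = [S]/[I] (dimensionless), so its ΔG can be formed two ways: directly
from K_IS, or as ΔG(F→S) − ΔG(F→I) from the two bimolecular constants.  The
two routes do not generally coincide under this simple scheme — both are
reported (see :func:`is_transition_routes`).

EPR-derived quantities default to 310.15 K (37 °C); thermophoresis-derived
affinities use 295.15 K (22 °C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import NoBindingError, StoichiometryError, UndefinedTransitionError

__all__ = [
    "R_GAS",
    "T_EPR",
    "T_MST",
    "BindingPoint",
    "ThermoRow",
    "concentrations_from_fractions",
    "kd_from_mass_action",
    "phi_from_kd",
    "gibbs_from_k",
    "equilibrium_constants_threestate",
    "propagate_errors",
    "thermo_chain",
    "is_transition_routes",
]

R_GAS = 8.314      # J mol^-1 K^-1
T_EPR = 310.15     # K, EPR series temperature (37 degC)
T_MST = 295.15     # K, thermophoresis Gibbs-energy reference (22 degC)

STATES = ("free", "intermediate", "strong")
TRANSITIONS = ("F-T", "F-I", "F-S", "I-S")


@dataclass
class BindingPoint:
    """Component fractions at one protein/ligand concentration pair."""

    c_protein_total: float          # uM
    c_ligand_total: float           # uM
    phi: tuple[float, float, float]  # (free, intermediate, strong)
    temperature_K: float = T_EPR
    phi_errors: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.c_protein_total < 0 or self.c_ligand_total < 0:
            raise ValueError("concentrations must be >= 0")
        phi = np.asarray(self.phi, float)
        if np.any(phi < -1e-12) or abs(phi.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must be >= 0 and sum to 1")

    @property
    def phi_bound(self) -> float:
        return self.phi[1] + self.phi[2]


@dataclass
class ThermoRow:
    """Equilibrium constants and Gibbs energy for one transition."""

    transition: str
    KD: float | None          # uM, None for the dimensionless I-S row
    KA: float | None          # M^-1 (or dimensionless [S]/[I] ratio)
    lnKA: float | None
    dG_kJ_mol: float | None
    dimensionless: bool = False
    defined: bool = True
    reason: str = ""
    errors: dict[str, float] = field(default_factory=dict)


def concentrations_from_fractions(point: BindingPoint) -> dict[str, float]:
    """Per-state ligand concentrations [x] = Φx · cL in uM."""
    return {s: p * point.c_ligand_total for s, p in zip(STATES, point.phi)}


def kd_from_mass_action(c_protein_total: float, c_ligand_total: float,
                        phi_bound: float) -> float:
    """1:1 mass-action dissociation constant in uM from a bound fraction."""
    if phi_bound <= 0:
        raise NoBindingError("bound fraction is zero; KD is undefined (infinite)")
    pl = phi_bound * c_ligand_total
    if phi_bound >= 1.0 or pl >= c_protein_total:
        raise StoichiometryError(
            f"bound ligand {pl:.4g} uM is not below min(cL, cP) = "
            f"{min(c_ligand_total, c_protein_total):.4g} uM")
    p_free = c_protein_total - pl
    l_free = c_ligand_total - pl
    return p_free * l_free / pl


def phi_from_kd(c_protein_total: float, c_ligand_total: float, kd: float) -> float:
    """Bound ligand fraction for a 1:1 equilibrium (exact quadratic root)."""
    if kd < 0:
        raise ValueError("KD must be >= 0")
    s = c_protein_total + c_ligand_total + kd
    disc = s * s - 4.0 * c_protein_total * c_ligand_total
    pl = 0.5 * (s - np.sqrt(max(disc, 0.0)))
    return pl / c_ligand_total


def gibbs_from_k(ka: float, temperature_K: float) -> float:
    """van't Hoff Gibbs energy ΔG = −R·T·ln(KA) in kJ/mol.

    ``ka`` is the association constant in M⁻¹ (or a dimensionless ratio for
    unimolecular steps).  Strictly decreasing in KA, zero at KA = 1.
    """
    if ka <= 0 or temperature_K <= 0:
        raise ValueError("KA and T must be positive")
    return -R_GAS * temperature_K * np.log(ka) / 1000.0


def thermo_chain(kd_uM: float, temperature_K: float) -> dict[str, float]:
    """KD (uM) → KA (M⁻¹), lnKA, ΔG (kJ/mol) at the given temperature."""
    if kd_uM <= 0:
        raise ValueError("KD must be positive")
    ka = 1.0 / (kd_uM * 1e-6)
    lnka = float(np.log(ka))
    return {"KD_uM": kd_uM, "KA_Minv": ka, "lnKA": lnka,
            "dG_kJ_mol": gibbs_from_k(ka, temperature_K)}


def _bimolecular_row(transition: str, point: BindingPoint, phi_b: float) -> ThermoRow:
    t = point.temperature_K
    try:
        kd = kd_from_mass_action(point.c_protein_total, point.c_ligand_total, phi_b)
    except NoBindingError:
        return ThermoRow(transition, None, None, None, None, defined=False,
                         reason="component absent")
    chain = thermo_chain(kd, t)
    return ThermoRow(transition, kd, chain["KA_Minv"], chain["lnKA"],
                     chain["dG_kJ_mol"])


def equilibrium_constants_threestate(point: BindingPoint) -> dict[str, ThermoRow]:
    """Thermo rows for the transitions F-T, F-I, F-S and I-S.

    F-T uses Φ_I + Φ_S, F-I uses Φ_I alone, F-S uses Φ_S alone — each with
    the same 1:1 mass-action form.  I-S is the dimensionless population
    ratio [S]/[I].  Rows whose component is absent are marked undefined,
    mirroring empty report-table fields.
    """
    phi_f, phi_i, phi_s = point.phi
    rows = {
        "F-T": _bimolecular_row("F-T", point, phi_i + phi_s),
        "F-I": _bimolecular_row("F-I", point, phi_i),
        "F-S": _bimolecular_row("F-S", point, phi_s),
    }
    if phi_i <= 0:
        if phi_s > 0:
            raise UndefinedTransitionError(
                "K_IS undefined: strong component present with no intermediate")
        rows["I-S"] = ThermoRow("I-S", None, None, None, None, dimensionless=True,
                                defined=False, reason="no bound components")
    else:
        k_is = phi_s / phi_i
        if k_is == 0:
            rows["I-S"] = ThermoRow("I-S", None, 0.0, None, None,
                                    dimensionless=True, defined=False,
                                    reason="strong component absent")
        else:
            rows["I-S"] = ThermoRow("I-S", None, k_is, float(np.log(k_is)),
                                    gibbs_from_k(k_is, point.temperature_K),
                                    dimensionless=True)
    return rows


def is_transition_routes(rows: Mapping[str, ThermoRow]) -> dict[str, float | None]:
    """Both computation routes for ΔG of the I→S step, and their discrepancy.

    ``direct`` is −RT·ln([S]/[I]); ``difference`` is ΔG(F-S) − ΔG(F-I) from
    the two bimolecular 1:1 constants.  Under the shared simple binding
    model these disagree in general; the gap is reported, not hidden.
    """
    direct = rows["I-S"].dG_kJ_mol if rows["I-S"].defined else None
    fs, fi = rows["F-S"], rows["F-I"]
    diff = (fs.dG_kJ_mol - fi.dG_kJ_mol) if (fs.defined and fi.defined) else None
    gap = (direct - diff) if (direct is not None and diff is not None) else None
    return {"direct": direct, "difference": diff, "discrepancy": gap}


def _dkd_dphi(c_p: float, c_l: float, phi: float) -> float:
    """Analytic derivative of the 1:1 KD with respect to the bound fraction."""
    # KD(phi) = (cP - phi*cL) * (1 - phi) / phi
    return (-c_l * (1 - phi) / phi
            - (c_p - phi * c_l) / phi
            - (c_p - phi * c_l) * (1 - phi) / phi ** 2)


def propagate_errors(point: BindingPoint) -> dict[str, ThermoRow]:
    """Thermo rows with first-order propagated uncertainties.

    σ_KD = |∂KD/∂Φ|·σ_Φ, σ_lnKA = σ_KD/KD, σ_ΔG = R·T·σ_lnKA/1000.  For the
    totally bound pool the fraction errors combine in quadrature; for the
    I-S ratio both population errors propagate through ln([S]/[I]).
    """
    rows = equilibrium_constants_threestate(point)
    c_p, c_l = point.c_protein_total, point.c_ligand_total
    t = point.temperature_K
    e_f, e_i, e_s = point.phi_errors
    phi_f, phi_i, phi_s = point.phi
    sigma = {
        "F-T": (phi_i + phi_s, float(np.hypot(e_i, e_s))),
        "F-I": (phi_i, e_i),
        "F-S": (phi_s, e_s),
    }
    for name, (phi_b, s_phi) in sigma.items():
        row = rows[name]
        if not row.defined:
            continue
        s_kd = abs(_dkd_dphi(c_p, c_l, phi_b)) * s_phi
        s_ln = s_kd / row.KD
        row.errors = {"KD": s_kd, "lnKA": s_ln,
                      "dG_kJ_mol": R_GAS * t * s_ln / 1000.0}
    row = rows["I-S"]
    if row.defined and phi_i > 0 and phi_s > 0:
        s_ln = float(np.hypot(e_i / phi_i, e_s / phi_s))
        row.errors = {"lnKA": s_ln, "dG_kJ_mol": R_GAS * t * s_ln / 1000.0}
    return rows
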