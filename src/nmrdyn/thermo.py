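"""Exchange thermodynamics: Van't Hoff and Eyring analysis.

The temperature dependence of the two-state equilibrium constant
Ke = pB/pA follows

    ln(Ke) = dS_BA/R - (dH_BA/R) (1/T),

and the forward rate constant k_AB follows transition-state theory,

    ln(k_AB/T) - ln(kappa kB/h) = dS*/R - (dH*/R) (1/T),

with a transmission coefficient kappa (default 1.6e-7) absorbing the
fraction of transition-state molecules that proceed to product.  Both are
weighted or unweighted linear regressions on 1/T.  Energies are carried in
J/mol internally; reporting is in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import H_PLANCK, K_BOLTZMANN, KAPPA_DEFAULT, R_GAS

__all__ = [
    "ThermoResult",
    "vant_hoff_fit",
    "eyring_fit",
    "delta_g_from_population",
    "reaction_coordinate_diagram",
    "ke_from_thermo",
    "kab_from_eyring",
]


def ke_from_thermo(dh_ba: float, ds_ba: float, temp_k: float) -> float:
    """Equilibrium constant Ke = pB/pA from dH_BA, dS_BA (J/mol, J/mol/K)."""
    return float(np.exp(ds_ba / R_GAS - dh_ba / (R_GAS * temp_k)))


def kab_from_eyring(
    dh_act: float, ds_act: float, temp_k: float, kappa: float = KAPPA_DEFAULT
) -> float:
    """Forward rate k_AB (s^-1) from activation parameters (J/mol, J/mol/K)."""
    prefactor = kappa * K_BOLTZMANN * temp_k / H_PLANCK
    return float(prefactor * np.exp(ds_act / R_GAS - dh_act / (R_GAS * temp_k)))


@dataclass
class LinearFitDiagnostics:
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    r_squared: float


@dataclass
class ThermoResult:
    """Excited-state (BA) and transition-state (act) thermodynamics."""

    dh_ba: float                    # J/mol
    ds_ba: float                    # J/(mol K)
    dh_act: float                   # J/mol
    ds_act: float                   # J/(mol K)
    kappa: float = KAPPA_DEFAULT
    vant_hoff_diagnostics: LinearFitDiagnostics | None = None
    eyring_diagnostics: LinearFitDiagnostics | None = None

    def dg_ba(self, temp_k: float) -> float:
        return self.dh_ba - temp_k * self.ds_ba

    def dg_act(self, temp_k: float) -> float:
        return self.dh_act - temp_k * self.ds_act

    # standard errors propagated from the regression coefficients
    def dh_ba_err(self) -> float:
        d = self.vant_hoff_diagnostics
        return R_GAS * d.slope_stderr if d else float("nan")

    def ds_ba_err(self) -> float:
        d = self.vant_hoff_diagnostics
        return R_GAS * d.intercept_stderr if d else float("nan")

    def dh_act_err(self) -> float:
        d = self.eyring_diagnostics
        return R_GAS * d.slope_stderr if d else float("nan")

    def ds_act_err(self) -> float:
        d = self.eyring_diagnostics
        return R_GAS * d.intercept_stderr if d else float("nan")


def _weighted_linfit(x, y, weights=None) -> LinearFitDiagnostics:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if weights is None:
        res = stats.linregress(x, y)
        return LinearFitDiagnostics(
            res.slope, res.intercept, res.stderr, res.intercept_stderr,
            res.rvalue**2,
        )
    w = np.asarray(weights, float)
    coeffs, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
    yhat = np.polyval(coeffs, x)
    ss_res = np.sum(w * (y - yhat) ** 2)
    ss_tot = np.sum(w * (y - np.average(y, weights=w)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearFitDiagnostics(
        coeffs[0], coeffs[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), r2
    )


def vant_hoff_fit(
    ke_by_temperature, weights=None
) -> tuple[float, float, LinearFitDiagnostics]:
    """Fit ln(Ke) vs 1/T; returns (dH_BA, dS_BA, diagnostics) in J units.

    ``ke_by_temperature`` is a sequence of (temperature K, Ke) pairs with
    Ke > 0; at least three temperatures are required (no two-point
    extrapolation).  slope = -dH_BA/R, intercept = dS_BA/R.
    """
    pairs = sorted((float(t), float(k)) for t, k in ke_by_temperature)
    if len(pairs) < 3:
        raise ValueError("Van't Hoff fit needs at least 3 temperatures")
    temps = np.array([t for t, _ in pairs])
    kes = np.array([k for _, k in pairs])
    if np.any(kes <= 0):
        raise ValueError("equilibrium constants must be positive")
    diag = _weighted_linfit(1.0 / temps, np.log(kes), weights)
    dh = -diag.slope * R_GAS
    ds = diag.intercept * R_GAS
    return dh, ds, diag


def eyring_fit(
    kab_by_temperature, kappa: float = KAPPA_DEFAULT, weights=None
) -> tuple[float, float, LinearFitDiagnostics]:
    """Fit ln(k_AB/T) - ln(kappa kB/h) vs 1/T; returns (dH*, dS*, diagnostics).

    slope = -dH*/R, intercept = dS*/R.  Doubling kappa lowers dS* by
    R ln(2) and leaves dH* untouched (pure intercept effect).
    """
    pairs = sorted((float(t), float(k)) for t, k in kab_by_temperature)
    if len(pairs) < 3:
        raise ValueError("Eyring fit needs at least 3 temperatures")
    temps = np.array([t for t, _ in pairs])
    kabs = np.array([k for _, k in pairs])
    if np.any(kabs <= 0):
        raise ValueError("rate constants must be positive")
    y = np.log(kabs / temps) - np.log(kappa * K_BOLTZMANN / H_PLANCK)
    diag = _weighted_linfit(1.0 / temps, y, weights)
    dh = -diag.slope * R_GAS
    ds = diag.intercept * R_GAS
    return dh, ds, diag


def delta_g_from_population(p_b: float, temp_k: float) -> float:
    """Free-energy gap dG_BA = -R T ln(pB/pA) in J/mol from the excited-state
    population."""
    if not 0.0 < p_b < 1.0:
        raise ValueError("p_B must lie in (0, 1)")
    return float(-R_GAS * temp_k * np.log(p_b / (1.0 - p_b)))


def fit_thermo(
    per_temperature_kinetics, kappa: float = KAPPA_DEFAULT, weights=None
) -> ThermoResult:
    """Run both fits on (temperature, k_AB, k_BA) triples."""
    kin = [(float(t), float(kab), float(kba)) for t, kab, kba in per_temperature_kinetics]
    ke = [(t, kab / kba) for t, kab, kba in kin]
    kab = [(t, k) for t, k, _ in kin]
    dh_ba, ds_ba, d1 = vant_hoff_fit(ke, weights)
    dh_act, ds_act, d2 = eyring_fit(kab, kappa, weights)
    return ThermoResult(
        dh_ba=dh_ba, ds_ba=ds_ba, dh_act=dh_act, ds_act=ds_act, kappa=kappa,
        vant_hoff_diagnostics=d1, eyring_diagnostics=d2,
    )


def reaction_coordinate_diagram(thermo: ThermoResult, temp_k: float) -> dict:
    """Three-level reaction-coordinate data (ground A, transition state, B).

    Level energies are relative to the ground state; dG = dH - T dS holds
    identically for each level.  Energies in kJ/mol.
    """
    levels = []
    for label, dh, ds in (
        ("A", 0.0, 0.0),
        ("transition", thermo.dh_act, thermo.ds_act),
        ("B", thermo.dh_ba, thermo.ds_ba),
    ):
        dg = dh - temp_k * ds
        levels.append({
            "state": label,
            "dG_kJ_mol": dg / 1000.0,
            "dH_kJ_mol": dh / 1000.0,
            "TdS_kJ_mol": temp_k * ds / 1000.0,
        })
    return {"temperature_K": temp_k, "levels": levels}
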