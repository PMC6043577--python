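"""Chemical-shift analyses: temperature coefficients, CSP mapping, and
single-site binding (KD) fits from titration shift changes.

The amide-proton temperature coefficient (TCI, ppb/K) is the slope of the
1H shift versus temperature; values more positive than -5 ppb/K indicate an
intramolecular hydrogen bond.  Ligand titrations in fast exchange displace
peaks by

    dw_obs = dw_max * ((KD + L0 + P0) - sqrt((KD + L0 + P0)^2 - 4 P0 L0))
             / (2 P0),

the single-site quadratic binding isotherm, fitted per residue for
(KD, dw_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .constants import CSP_ALPHA, TCI_HBOND_CUT

__all__ = [
    "ShiftSeries",
    "TitrationSeries",
    "BindingFit",
    "binding_isotherm",
    "temperature_coefficient",
    "csp_index",
    "fit_binding_quadratic",
    "compare_dw",
]


@dataclass
class ShiftSeries:
    """Per-residue 1H/15N shifts along an axis (temperature or ligand)."""

    residue_id: int
    axis: str                    # "temperature_K" or "ligand_M"
    axis_values: np.ndarray
    h_ppm: np.ndarray
    n_ppm: np.ndarray

    def __post_init__(self):
        self.axis_values = np.asarray(self.axis_values, float)
        self.h_ppm = np.asarray(self.h_ppm, float)
        self.n_ppm = np.asarray(self.n_ppm, float)
        if not np.all(np.diff(self.axis_values) > 0):
            raise ValueError("axis values must be strictly increasing")


@dataclass
class TitrationSeries:
    """15N shift changes of one residue versus total ligand concentration."""

    residue_id: int
    p_total: float               # M
    ligand_concs: np.ndarray     # M
    dw_obs_ppm: np.ndarray
    disappeared: bool = False    # peak lost to exchange broadening

    def __post_init__(self):
        self.ligand_concs = np.asarray(self.ligand_concs, float)
        self.dw_obs_ppm = np.asarray(self.dw_obs_ppm, float)
        if self.p_total <= 0:
            raise ValueError("protein concentration must be positive")
        if np.any(self.ligand_concs < 0):
            raise ValueError("ligand concentrations must be non-negative")


@dataclass
class BindingFit:
    residue_id: int
    kd: float                    # M
    kd_err: float
    dw_max: float                # ppm
    dw_max_err: float
    well_determined: bool = True


def binding_isotherm(
    l0: np.ndarray, kd: float, dw_max: float, p_total: float
) -> np.ndarray:
    """Quadratic single-site binding isotherm (exact bound fraction)."""
    l0 = np.asarray(l0, float)
    s = kd + l0 + p_total
    bound = (s - np.sqrt(s * s - 4.0 * p_total * l0)) / (2.0 * p_total)
    return dw_max * bound


def temperature_coefficient(series: ShiftSeries) -> tuple[float, float, bool]:
    """Amide-proton temperature coefficient and hydrogen-bond classification.

    Returns (slope ppb/K, slope stderr ppb/K, h_bonded).  Classification is
    ``slope > -5 ppb/K`` (strict: exactly -5 is not classified H-bonded).
    Adding a constant to every shift does not change the slope.
    """
    if series.axis != "temperature_K":
        raise ValueError("series axis must be temperature_K")
    if series.axis_values.size < 3:
        raise ValueError("need at least 3 temperatures")
    res = stats.linregress(series.axis_values, series.h_ppm * 1000.0)  # ppb
    h_bonded = res.slope > TCI_HBOND_CUT
    return float(res.slope), float(res.stderr), bool(h_bonded)


def csp_index(
    free_shifts: pd.DataFrame,
    bound_shifts: pd.DataFrame,
    alpha: float = CSP_ALPHA,
) -> pd.DataFrame:
    """Combined chemical-shift perturbation per residue.

    Inputs are DataFrames with columns ``residue_id, h_ppm, n_ppm`` for the
    free and bound forms.  CSP = sqrt(ddH^2 + (alpha*ddN)^2); residues with
    CSP above mean + 1 SD are flagged significant.
    """
    merged = free_shifts.merge(
        bound_shifts, on="residue_id", suffixes=("_free", "_bound")
    )
    if merged.empty:
        raise ValueError("no residues common to free and bound shift sets")
    ddh = merged["h_ppm_bound"] - merged["h_ppm_free"]
    ddn = merged["n_ppm_bound"] - merged["n_ppm_free"]
    csp = np.sqrt(ddh**2 + (alpha * ddn) ** 2)
    threshold = float(csp.mean() + csp.std(ddof=1)) if len(csp) > 1 else float(csp.mean())
    return pd.DataFrame({
        "residue_id": merged["residue_id"],
        "csp_ppm": csp,
        "significant": csp > threshold,
        "threshold_ppm": threshold,
    })


def fit_binding_quadratic(series: TitrationSeries) -> BindingFit:
    """Fit the quadratic binding isotherm for (KD, dw_max).

    Requires at least 4 concentration points.  When the highest ligand
    concentration does not exceed the fitted KD the data do not constrain
    the plateau and the fit is flagged poorly determined.
    """
    if series.disappeared:
        raise ValueError(
            f"residue {series.residue_id}: peak disappeared during titration; "
            "excluded from fitting"
        )
    mask = series.ligand_concs > 0
    l0 = series.ligand_concs[mask]
    dw = series.dw_obs_ppm[mask]
    if l0.size < 4:
        raise ValueError("need at least 4 non-zero concentration points")

    model = lmfit.Model(
        lambda l, kd, dw_max: binding_isotherm(l, kd, dw_max, series.p_total),
        independent_vars=["l"],
    )
    params = model.make_params(
        kd={"value": np.median(l0), "min": 1e-12},
        dw_max={"value": float(np.max(np.abs(dw))) or 1.0},
    )
    result = model.fit(dw, params, l=l0)
    kd = float(result.params["kd"].value)
    dw_max = float(result.params["dw_max"].value)
    kd_err = float(result.params["kd"].stderr or np.nan)
    dw_err = float(result.params["dw_max"].stderr or np.nan)
    return BindingFit(
        residue_id=series.residue_id,
        kd=kd, kd_err=kd_err, dw_max=dw_max, dw_max_err=dw_err,
        well_determined=bool(np.max(l0) >= kd),
    )


def compare_dw(
    titration_dw: dict[int, float],
    dispersion_dw: dict[int, float],
    outlier_cutoff: float = 0.5,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-residue comparison of |dw 15N| from titration versus dispersion.

    Residues whose absolute difference exceeds ``outlier_cutoff`` (ppm) are
    flagged; the Pearson correlation over the common set is reported in the
    table attributes.
    """
    common = sorted(set(titration_dw) & set(dispersion_dw))
    if not common:
        raise ValueError("no residues common to both dw sets")
    rows = []
    for res in common:
        a, b = abs(titration_dw[res]), abs(dispersion_dw[res])
        rows.append({
            "residue_id": res,
            "titration_dw_ppm": a,
            "dispersion_dw_ppm": b,
            "abs_difference_ppm": abs(a - b),
            "outlier": abs(a - b) > outlier_cutoff,
        })
    table = pd.DataFrame(rows)
    if len(common) > 2:
        corr = float(np.corrcoef(
            table["titration_dw_ppm"], table["dispersion_dw_ppm"]
        )[0, 1])
    else:
        corr = float("nan")
    table.attrs["pearson_r"] = corr
    outliers = table.loc[table["outlier"], "residue_id"].astype(int).tolist()
    return table, outliers
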