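"""CSV/JSON readers and writers for the pipeline's tabular interfaces.

All CSV files use comma separators, '.' decimals, UTF-8 and a header row.
Readers validate row by row and report offending line numbers (1-based,
header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import PEAK_TABLE_COLUMNS, DispersionCurve
from .globalfit import GlobalFitResult
from .shifts import BindingFit, ShiftSeries
from .thermo import ThermoResult

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_shift_table",
    "write_shift_table",
    "write_dispersion_curves",
    "read_dispersion_curves",
    "write_fit_result",
    "write_thermo_result",
    "write_binding_fits",
]

SHIFT_TABLE_COLUMNS = ("residue_id", "axis_value", "h_ppm", "n_ppm")


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a peak-intensity table.

    Rows with non-finite or negative intensities, or negative CPMG
    frequencies, are reported with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PEAK_TABLE_COLUMNS, path)
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not np.isfinite(row["intensity"]):
            errors.append(f"line {line}: non-finite intensity")
        elif row["intensity"] < 0:
            errors.append(f"line {line}: negative intensity "
                          f"({row['intensity']})")
        if not np.isfinite(row["nu_cpmg_hz"]) or row["nu_cpmg_hz"] < 0:
            errors.append(f"line {line}: invalid nu_cpmg_hz")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return df[list(PEAK_TABLE_COLUMNS)]


def write_peak_table(df: pd.DataFrame, path) -> None:
    df[list(PEAK_TABLE_COLUMNS)].to_csv(path, index=False)


def read_shift_table(path) -> list[ShiftSeries]:
    """Read a shift table (one series per residue) from CSV.

    The axis kind is stored in an ``axis`` column when present (default
    ``temperature_K``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SHIFT_TABLE_COLUMNS, path)
    axis = df["axis"].iloc[0] if "axis" in df.columns else "temperature_K"
    out = []
    for res, grp in df.groupby("residue_id"):
        grp = grp.sort_values("axis_value")
        out.append(ShiftSeries(
            residue_id=int(res),
            axis=str(axis),
            axis_values=grp["axis_value"].to_numpy(),
            h_ppm=grp["h_ppm"].to_numpy(),
            n_ppm=grp["n_ppm"].to_numpy(),
        ))
    return out


def write_shift_table(series_list: list[ShiftSeries], path) -> None:
    rows = []
    for s in series_list:
        for x, h, n in zip(s.axis_values, s.h_ppm, s.n_ppm):
            rows.append({
                "residue_id": s.residue_id, "axis_value": x,
                "h_ppm": h, "n_ppm": n, "axis": s.axis,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dispersion_curves(curves: list[DispersionCurve], path) -> None:
    rows = []
    for c in curves:
        for v, r, e in zip(c.nu_cpmg_hz, c.r2eff, c.r2eff_err):
            rows.append({
                "residue_id": c.residue_id, "field_mhz": c.field_mhz,
                "temp_k": c.temp_k, "nu_cpmg_hz": v,
                "r2eff": r, "r2eff_err": e,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dispersion_curves(path) -> list[DispersionCurve]:
    df = pd.read_csv(path)
    _require_columns(
        df, ("residue_id", "field_mhz", "temp_k", "nu_cpmg_hz",
             "r2eff", "r2eff_err"), path,
    )
    curves = []
    for (res, fld, tmp), grp in df.groupby(["residue_id", "field_mhz", "temp_k"]):
        grp = grp.sort_values("nu_cpmg_hz")
        curves.append(DispersionCurve(
            int(res), float(fld), float(tmp),
            grp["nu_cpmg_hz"].to_numpy(), grp["r2eff"].to_numpy(),
            grp["r2eff_err"].to_numpy(),
        ))
    return curves


def write_fit_result(result: GlobalFitResult, csv_path, json_path) -> None:
    """Flat parameter CSV plus a JSON summary of the global fit."""
    rows = []
    unc = result.uncertainties
    for t, p_b, k_ab in result.params.per_temperature:
        s_pb = s_kab = float("nan")
        if unc is not None:
            for tt, sp, sk in unc.per_temperature:
                if abs(tt - t) < 1e-9:
                    s_pb, s_kab = sp, sk
        rows.append({"parameter": f"p_B({t:g}K)", "value": p_b,
                     "uncertainty": s_pb})
        rows.append({"parameter": f"k_AB({t:g}K)", "value": k_ab,
                     "uncertainty": s_kab})
        rows.append({"parameter": f"k_ex({t:g}K)",
                     "value": result.params.kex_at(t),
                     "uncertainty": float("nan")})
    for r, dw in sorted(result.params.per_residue_dw_ppm.items()):
        s = unc.per_residue_dw_ppm.get(r, float("nan")) if unc else float("nan")
        rows.append({"parameter": f"dw_ppm(res{r})", "value": dw,
                     "uncertainty": s})
    for (r, f), r20 in sorted(result.params.per_residue_per_field_r20.items()):
        s = (unc.per_residue_per_field_r20.get((r, f), float("nan"))
             if unc else float("nan"))
        rows.append({"parameter": f"R2_0(res{r},{f:g}MHz)", "value": r20,
                     "uncertainty": s})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    summary = {
        "chi2": result.chi2,
        "reduced_chi2": result.reduced_chi2,
        "n_data": result.n_data,
        "n_par": result.n_par,
        "converged": result.converged,
        "n_starts": result.n_starts,
        "seed": result.seed,
        "identifiability_warning": result.identifiability_warning,
    }
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def write_thermo_result(thermo: ThermoResult, diagram: dict,
                        csv_path, json_path) -> None:
    rows = [
        {"quantity": "dH_BA_kJ_mol", "value": thermo.dh_ba / 1000.0,
         "uncertainty": thermo.dh_ba_err() / 1000.0},
        {"quantity": "dS_BA_J_mol_K", "value": thermo.ds_ba,
         "uncertainty": thermo.ds_ba_err()},
        {"quantity": "dH_act_kJ_mol", "value": thermo.dh_act / 1000.0,
         "uncertainty": thermo.dh_act_err() / 1000.0},
        {"quantity": "dS_act_J_mol_K", "value": thermo.ds_act,
         "uncertainty": thermo.ds_act_err()},
        {"quantity": "kappa", "value": thermo.kappa, "uncertainty": 0.0},
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(diagram, indent=2) + "\n")


def write_binding_fits(fits: list[BindingFit], path) -> None:
    pd.DataFrame([
        {
            "residue_id": f.residue_id,
            "kd_m": f.kd, "kd_err": f.kd_err,
            "dwmax_ppm": f.dw_max, "dwmax_err": f.dw_max_err,
            "well_determined": f.well_determined,
        }
        for f in fits
    ]).to_csv(path, index=False)
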