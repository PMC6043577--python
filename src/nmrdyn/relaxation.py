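"""Fast-timescale (ps-ns) backbone dynamics from 15N relaxation.

R1 and R2 come from single-exponential fits of peak-intensity decays, the
steady-state heteronuclear NOE from saturated/reference intensity ratios,
and the overall rotational correlation time tau_c from the trimmed-mean
R2/R1 ratio of rigid residues, numerically inverting the isotropic-rotor
spectral densities

    J(w) = (2/5) tau_c / (1 + (w tau_c)^2)

for an amide 15N relaxed by 1H dipolar coupling (r_NH = 1.02 A) and CSA
(-160 ppm).  Residues with Het-NOE below 0.65 are flagged flexible and left
out of the tau_c estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import (
    CSA_N15,
    GAMMA_H,
    GAMMA_N,
    HBAR,
    HETNOE_FLEXIBLE_CUT,
    MU0_OVER_4PI,
    NH_BOND_LENGTH,
)

__all__ = [
    "RelaxationRecord",
    "fit_exponential_decay",
    "het_noe",
    "r1_r2_from_tau_c",
    "estimate_tau_c",
]


@dataclass
class RelaxationRecord:
    residue_id: int
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    het_noe: float
    het_noe_err: float

    @property
    def flexible(self) -> bool:
        return self.het_noe < HETNOE_FLEXIBLE_CUT


def fit_exponential_decay(
    delays_s: np.ndarray,
    intensities: np.ndarray,
    errors: np.ndarray | None = None,
) -> tuple[float, float]:
    """Fit I(t) = I0 exp(-R t); returns (rate s^-1, stderr).

    Requires at least 4 delay points.  When per-point intensity errors are
    supplied the fit is inverse-variance weighted (the usual treatment when
    peak uncertainties are known from the spectral noise); otherwise it is
    unweighted.  A series that does not decay (non-positive fitted rate) is
    rejected.
    """
    delays = np.asarray(delays_s, float)
    inten = np.asarray(intensities, float)
    if delays.size < 4:
        raise ValueError("need at least 4 delay points for an exponential fit")
    if np.any(inten <= 0):
        raise ValueError("intensities must be positive")
    weights = None
    if errors is not None:
        errors = np.asarray(errors, float)
        if np.any(errors <= 0):
            raise ValueError("intensity errors must be positive")
        weights = 1.0 / errors
    # log-linear seed, then nonlinear refinement
    slope, intercept, *_ = stats.linregress(delays, np.log(inten))
    model = lmfit.Model(lambda t, i0, rate: i0 * np.exp(-rate * t))
    params = model.make_params(
        i0={"value": float(np.exp(intercept)), "min": 0.0},
        rate={"value": max(-slope, 1e-3)},
    )
    result = model.fit(inten, params, t=delays, weights=weights)
    rate = float(result.params["rate"].value)
    err = float(result.params["rate"].stderr or np.nan)
    if rate <= 0:
        raise ValueError("series does not decay: fitted rate is non-positive")
    return rate, err


def het_noe(
    i_saturated: float, i_reference: float, noise_sd: float = 0.0
) -> tuple[float, float, bool]:
    """Heteronuclear NOE ratio, its propagated error and the flexibility flag.

    ratio = I_sat/I_ref; sigma_ratio = |ratio| sqrt((s/I_sat)^2 + (s/I_ref)^2);
    flexible when ratio < 0.65.
    """
    if i_reference <= 0:
        raise ValueError("reference intensity must be positive")
    ratio = i_saturated / i_reference
    if i_saturated != 0:
        err = abs(ratio) * np.hypot(noise_sd / i_saturated, noise_sd / i_reference)
    else:
        err = noise_sd / i_reference
    return float(ratio), float(err), bool(ratio < HETNOE_FLEXIBLE_CUT)


# ---------------------------------------------------------------------------
# isotropic-rotor 15N relaxation model
# ---------------------------------------------------------------------------

def _jw(omega: float, tau_c: float) -> float:
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def r1_r2_from_tau_c(
    tau_c_s: float, field_mhz: float,
    csa: float = CSA_N15, r_nh: float = NH_BOND_LENGTH,
) -> tuple[float, float]:
    """Forward 15N R1/R2 (s^-1) for a rigid isotropic rotor.

    Dipolar (1H-15N) plus CSA relaxation with the standard spectral-density
    combinations; ``field_mhz`` is the 1H Larmor frequency.
    """
    b0 = 2.0 * np.pi * field_mhz * 1e6 / GAMMA_H
    omega_h = GAMMA_H * b0
    omega_n = GAMMA_N * b0
    d = MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_N / r_nh**3
    c = omega_n * csa / np.sqrt(3.0)
    j = lambda w: _jw(w, tau_c_s)
    r1 = (d**2 / 4.0) * (
        j(omega_h - omega_n) + 3.0 * j(omega_n) + 6.0 * j(omega_h + omega_n)
    ) + c**2 * j(omega_n)
    r2 = (d**2 / 8.0) * (
        4.0 * j(0.0) + j(omega_h - omega_n) + 3.0 * j(omega_n)
        + 6.0 * j(omega_h) + 6.0 * j(omega_h + omega_n)
    ) + (c**2 / 6.0) * (4.0 * j(0.0) + 3.0 * j(omega_n))
    return float(r1), float(r2)


def estimate_tau_c(
    records: list[RelaxationRecord],
    field_mhz: float,
    trim_fraction: float = 0.1,
    exclude_residues: set[int] | None = None,
    tau_bounds_ns: tuple[float, float] = (0.5, 50.0),
) -> tuple[float, list[int]]:
    """Overall rotational correlation time (ns) from the R2/R1 ratio.

    Rigid residues (Het-NOE >= 0.65, not in ``exclude_residues``) contribute
    their R2/R1 ratio; a trimmed mean suppresses residues with residual
    exchange contributions; the isotropic-rotor ratio is then inverted
    numerically.  Returns (tau_c in ns, residues used).
    """
    exclude = exclude_residues or set()
    rigid = [
        r for r in records
        if not r.flexible and r.residue_id not in exclude
    ]
    if len(rigid) < 5:
        raise ValueError(
            f"tau_c estimation needs >= 5 rigid residues, found {len(rigid)}"
        )
    ratios = np.array([r.r2 / r.r1 for r in rigid])
    target = float(stats.trim_mean(ratios, trim_fraction))

    def ratio_minus_target(tau_ns: float) -> float:
        r1, r2 = r1_r2_from_tau_c(tau_ns * 1e-9, field_mhz)
        return r2 / r1 - target

    lo, hi = tau_bounds_ns
    if ratio_minus_target(lo) * ratio_minus_target(hi) > 0:
        raise ValueError(
            f"R2/R1 ratio {target:.2f} outside the invertible range for "
            f"tau_c in [{lo}, {hi}] ns at {field_mhz} MHz"
        )
    tau_ns = optimize.brentq(ratio_minus_target, lo, hi, xtol=1e-6)
    return float(tau_ns), sorted(r.residue_id for r in rigid)


def records_to_frame(records: list[RelaxationRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "residue_id": r.residue_id,
            "r1": r.r1, "r1_err": r.r1_err,
            "r2": r.r2, "r2_err": r.r2_err,
            "het_noe": r.het_noe, "het_noe_err": r.het_noe_err,
            "flexible": r.flexible,
        }
        for r in records
    ])
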