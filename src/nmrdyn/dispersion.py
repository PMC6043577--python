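"""CPMG relaxation dispersion: R2,eff extraction, errors, exchange models.

The experimental side converts constant-time CPMG peak intensities into
effective transverse relaxation rates,

    R2,eff = -(1/T_relax) * ln(I_CPMG / I0),

with uncertainties from the spectral noise floor.  The model side provides
the forward two-state Bloch-McConnell propagator (numerical, the model that
is fitted) and the Carver-Richards closed form (an independent analytic
oracle used for cross-validation, never for fitting).

Conventions
-----------
* A CPMG element is tau - 180 - tau with tau = 1/(4 nu_CPMG); the number of
  elements in T_relax is n = 2 * nu_CPMG * T_relax and must be an integer.
* Chemical-shift differences are stored in ppm (field independent) and
  converted to rad/s per field; the two-state single-quantum dispersion
  depends only on |dw|.
* Intrinsic rates R2,0 are shared between the ground (A) and excited (B)
  states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    DELTA_R2EFF_THRESHOLD,
    ERROR_FLOOR_FRACTION,
    NU_CPMG_REFERENCE_HZ,
    NU_HIGH_DEFAULT_HZ,
    NU_LOW_DEFAULT_HZ,
    T_RELAX_DEFAULT,
)

__all__ = [
    "DispersionCurve",
    "DispersionDataset",
    "echo_count",
    "r2eff_from_intensities",
    "r2eff_error",
    "bm_r2eff",
    "bm_r2eff_batch",
    "carver_richards_r2eff",
    "luz_meiboom_rex",
    "select_exchange_residues",
]

#: column schema of a peak-intensity table; nu_cpmg_hz == 0 marks the
#: T_relax = 0 reference row (I0).
PEAK_TABLE_COLUMNS = (
    "residue_id", "field_mhz", "temp_k", "condition", "nu_cpmg_hz", "intensity",
)


@dataclass
class DispersionCurve:
    """R2,eff versus CPMG frequency for one residue at one field/temperature."""

    residue_id: int
    field_mhz: float
    temp_k: float
    nu_cpmg_hz: np.ndarray
    r2eff: np.ndarray
    r2eff_err: np.ndarray

    def __post_init__(self):
        self.nu_cpmg_hz = np.asarray(self.nu_cpmg_hz, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.r2eff_err = np.asarray(self.r2eff_err, dtype=float)
        if not np.all(np.diff(self.nu_cpmg_hz) > 0):
            raise ValueError(
                f"residue {self.residue_id}: nu_CPMG must be strictly increasing"
            )
        if np.any(self.r2eff_err <= 0):
            raise ValueError(f"residue {self.residue_id}: errors must be positive")


@dataclass
class DispersionDataset:
    """Collection of dispersion curves plus the residues excluded from analysis."""

    curves: list[DispersionCurve]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def residue_ids(self) -> list[int]:
        return sorted({c.residue_id for c in self.curves})

    @property
    def n_r(self) -> int:
        return len(self.residue_ids)

    @property
    def n_t(self) -> int:
        return len({c.temp_k for c in self.curves})

    @property
    def n_b(self) -> int:
        return len({c.field_mhz for c in self.curves})

    @property
    def n_points(self) -> int:
        return sum(c.nu_cpmg_hz.size for c in self.curves)

    def subset(self, residue_ids) -> "DispersionDataset":
        keep = set(residue_ids)
        return DispersionDataset(
            curves=[c for c in self.curves if c.residue_id in keep],
            excluded=list(self.excluded),
        )


def echo_count(nu_cpmg_hz: float, t_relax: float, rel_tol: float = 0.01) -> int:
    """Number of CPMG elements (tau-180-tau blocks) fitting in ``t_relax``.

    ``n = 2 * nu * T`` must be an integer; nominal frequencies quoted with a
    rounded decimal (e.g. 66.7 Hz for 66.667 Hz at T = 30 ms) are accepted
    when within ``rel_tol`` of an integer block count.
    """
    n_exact = 2.0 * nu_cpmg_hz * t_relax
    n = int(round(n_exact))
    if n < 1 or abs(n_exact - n) > rel_tol * max(n, 1):
        nearest = max(n, 1) / (2.0 * t_relax)
        raise ValueError(
            f"nu_CPMG = {nu_cpmg_hz} Hz incompatible with an integer number of "
            f"echo blocks in T_relax = {t_relax} s; closest valid value is "
            f"{nearest:.4f} Hz"
        )
    return n


def r2eff_from_intensities(
    table: pd.DataFrame,
    t_relax: float = T_RELAX_DEFAULT,
    noise_sd: float | None = None,
) -> list[DispersionCurve]:
    """Convert a peak-intensity table into dispersion curves.

    Parameters
    ----------
    table
        DataFrame with columns ``residue_id, field_mhz, temp_k, condition,
        nu_cpmg_hz, intensity``; one reference row (``nu_cpmg_hz == 0``,
        intensity I0) per residue/field/temperature group.
    t_relax
        Constant-time relaxation delay in seconds.
    noise_sd
        Spectral noise standard deviation (intensity units).  When given, the
        point error is ``max(noise_sd / (T * I(500 Hz)), 0.03 * R2eff)``;
        otherwise the 3% floor alone is used.

    Raises
    ------
    ValueError
        If a group lacks its reference row or a CPMG intensity is
        non-positive (log undefined).
    """
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    curves = []
    problems = []
    for (res, fld, tmp), grp in table.groupby(
        ["residue_id", "field_mhz", "temp_k"], sort=True
    ):
        ref = grp[grp["nu_cpmg_hz"] == 0.0]
        if len(ref) != 1:
            problems.append(
                f"residue {res}, field {fld}, T {tmp}: "
                f"{len(ref)} reference rows (need exactly 1)"
            )
            continue
        i0 = float(ref["intensity"].iloc[0])
        if i0 <= 0:
            problems.append(f"residue {res}, field {fld}, T {tmp}: I0 <= 0")
            continue
        pts = grp[grp["nu_cpmg_hz"] > 0.0].sort_values("nu_cpmg_hz")
        inten = pts["intensity"].to_numpy(dtype=float)
        if np.any(inten <= 0):
            bad = pts["nu_cpmg_hz"].to_numpy()[inten <= 0]
            problems.append(
                f"residue {res}, field {fld}, T {tmp}: non-positive intensity "
                f"at nu_CPMG = {bad.tolist()} (log undefined)"
            )
            continue
        nu = pts["nu_cpmg_hz"].to_numpy(dtype=float)
        r2eff = -np.log(inten / i0) / t_relax
        # error per point: noise term evaluated at the 500 Hz spectrum
        if noise_sd is not None:
            idx500 = int(np.argmin(np.abs(nu - NU_CPMG_REFERENCE_HZ)))
            errs = np.array([
                r2eff_error(noise_sd, inten[idx500], t_relax, r)
                for r in r2eff
            ])
        else:
            errs = np.maximum(ERROR_FLOOR_FRACTION * np.abs(r2eff), 1e-6)
        curves.append(DispersionCurve(int(res), float(fld), float(tmp), nu, r2eff, errs))
    if problems:
        raise ValueError("peak table problems: " + "; ".join(problems))
    return curves


def r2eff_error(
    noise_sd: float,
    i_ref500: float,
    t_relax: float,
    r2eff: float,
) -> float:
    """Uncertainty of one R2,eff point.

    The noise term is ``sigma / (T_relax * I_CPMG(500 Hz))``; a floor of 3%
    of the R2,eff value is imposed when the noise term falls below it.
    """
    if i_ref500 <= 0:
        raise ValueError("reference intensity must be positive")
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    noise_term = noise_sd / (t_relax * i_ref500)
    return max(noise_term, ERROR_FLOOR_FRACTION * abs(r2eff), 1e-6)


# ---------------------------------------------------------------------------
# forward two-state models
# ---------------------------------------------------------------------------

def _expm2x2(mat: np.ndarray) -> np.ndarray:
    """Closed-form matrix exponential of a batch of complex 2x2 matrices.

    Uses exp(A) = e^m [cosh(d) I + sinh(d)/d (A - m I)] with m = tr(A)/2 and
    d^2 = (a-d)^2/4 + bc; the d -> 0 limit is taken analytically.
    """
    a = mat[..., 0, 0]
    b = mat[..., 0, 1]
    c = mat[..., 1, 0]
    d = mat[..., 1, 1]
    m = 0.5 * (a + d)
    delta = np.sqrt(0.25 * (a - d) ** 2 + b * c + 0j)
    small = np.abs(delta) < 1e-12
    safe = np.where(small, 1.0, delta)
    sinch = np.where(small, 1.0 + delta**2 / 6.0, np.sinh(safe) / safe)
    cosh = np.cosh(delta)
    em = np.exp(m)
    out = np.empty(mat.shape, dtype=complex)
    out[..., 0, 0] = em * (cosh + sinch * (a - m))
    out[..., 0, 1] = em * sinch * b
    out[..., 1, 0] = em * sinch * c
    out[..., 1, 1] = em * (cosh + sinch * (d - m))
    return out


def bm_r2eff(
    k_ab: float,
    k_ba: float,
    dw_rad: float,
    r20: float,
    nu_cpmg_hz: float,
    t_relax: float = T_RELAX_DEFAULT,
) -> float:
    """R2,eff from numerical propagation of the two-state Bloch-McConnell
    equations through an ideal constant-time CPMG element train.

    Transverse magnetization (complex, one component per state) evolves under

        d/dt [MA, MB] = [[-R20 - kAB,          kBA     ],
                         [      kAB,  -R20 - kBA + i dw]] [MA, MB]

    during free precession; each ideal 180 pulse conjugates the magnetization.
    Starting from equilibrium populations, the observed ground-state peak
    decays as |MA(T_relax)| and R2,eff = -(1/T) ln(|MA(T)| / pA).
    """
    if k_ab < 0 or k_ba < 0 or (k_ab + k_ba) <= 0:
        raise ValueError("exchange rates must be positive")
    n = echo_count(nu_cpmg_hz, t_relax)
    tau = t_relax / (4.0 * n)   # quarter of one echo element
    kex = k_ab + k_ba
    p_a = k_ba / kex
    p_b = k_ab / kex
    kmat = np.array(
        [
            [-r20 - k_ab, k_ba],
            [k_ab, -r20 - k_ba + 1j * dw_rad],
        ],
        dtype=complex,
    )
    prop = _expm2x2(kmat * (2.0 * tau))  # half-element propagator (tau..tau)
    m = np.array([p_a, p_b], dtype=complex)
    for _ in range(n):
        m = prop @ m
        m = np.conj(m)
        m = prop @ m
    mag = abs(m[0])
    if not np.isfinite(mag) or mag <= 0:
        raise FloatingPointError(
            f"Bloch-McConnell propagation overflow/underflow at kex={kex}, "
            f"dw={dw_rad} rad/s, r20={r20}, nu={nu_cpmg_hz} Hz"
        )
    return float(-np.log(mag / p_a) / t_relax)


def bm_r2eff_batch(
    k_ab: np.ndarray,
    k_ba: np.ndarray,
    dw_rad: np.ndarray,
    r20: np.ndarray,
    n_echo: np.ndarray,
    t_relax: float = T_RELAX_DEFAULT,
) -> np.ndarray:
    """Vectorised Bloch-McConnell R2,eff over N data points.

    All inputs broadcast to shape (N,); ``n_echo`` is the per-point integer
    CPMG element count (must be even, as in the constant-time designs used
    here).  Equivalent to :func:`bm_r2eff` point by point; the pairwise echo
    propagator ``P conj(P) conj(P) P`` is raised to ``n_echo/2`` by binary
    exponentiation so the cost is logarithmic in the pulse count.
    """
    k_ab, k_ba, dw_rad, r20, n_echo = np.broadcast_arrays(
        np.asarray(k_ab, float), np.asarray(k_ba, float),
        np.asarray(dw_rad, float), np.asarray(r20, float),
        np.asarray(n_echo),
    )
    if np.any(n_echo % 2 != 0):
        raise ValueError("bm_r2eff_batch requires even echo counts")
    npts = k_ab.shape[0]
    kex = k_ab + k_ba
    p_a = k_ba / kex
    tau = t_relax / (4.0 * n_echo.astype(float))
    kmat = np.zeros((npts, 2, 2), dtype=complex)
    kmat[:, 0, 0] = -r20 - k_ab
    kmat[:, 0, 1] = k_ba
    kmat[:, 1, 0] = k_ab
    kmat[:, 1, 1] = -r20 - k_ba + 1j * dw_rad
    prop = _expm2x2(kmat * (2.0 * tau)[:, None, None])
    pc = np.conj(prop)
    # propagator of two consecutive echo elements
    pair = prop @ pc @ pc @ prop
    m_pairs = (n_echo // 2).astype(int)
    result = np.tile(np.eye(2, dtype=complex), (npts, 1, 1))
    base = pair
    mvals = m_pairs.copy()
    while np.any(mvals > 0):
        odd = (mvals & 1) == 1
        if np.any(odd):
            result[odd] = result[odd] @ base[odd]
        mvals >>= 1
        if np.any(mvals > 0):
            base = base @ base
    m0 = np.stack([p_a, 1.0 - p_a], axis=-1).astype(complex)
    m_final = np.einsum("nij,nj->ni", result, m0)
    mag = np.abs(m_final[:, 0])
    with np.errstate(divide="raise", invalid="raise"):
        return -np.log(mag / p_a) / t_relax


def carver_richards_r2eff(
    k_ab: float,
    k_ba: float,
    dw_rad: float,
    r20: float,
    nu_cpmg_hz: float,
    t_relax: float = T_RELAX_DEFAULT,
    asymptotic: bool = False,
) -> float:
    """Carver-Richards closed-form R2,eff for two-state single-quantum CPMG.

    Analytic oracle for :func:`bm_r2eff`, assuming equal intrinsic rates in
    the two states and ideal 180 pulses.  The default evaluates the full
    closed-form solution of the echo-train problem by scalar complex algebra
    (free-precession propagator entries in closed form, eigenvalues and
    spectral projectors of the two-echo propagator, finite train length
    ``n = 2 nu T``), including the intensity prefactor of the slowly decaying
    mode.  No matrix exponential or repeated matrix multiplication is used,
    so the route is independent of the numerical propagation in
    :func:`bm_r2eff`.

    With ``asymptotic=True`` the widely quoted simplification is returned:
    the decay rate of the dominant eigenvalue alone,

        R2,eff = R2,0 + kex/2 - (1/tcp) acosh(D+ cosh(eta+) - D- cos(eta-)),

    which neglects the finite-train prefactor.  The two forms agree in fast
    exchange; the asymptotic one overestimates R2,eff by up to ~10% in
    slow-intermediate exchange (kex below ~|dw|) with appreciable excited-
    state population at low CPMG frequencies, where only a handful of echoes
    fit into the relaxation delay.
    """
    kex = k_ab + k_ba
    if kex <= 0:
        raise ValueError("exchange rates must be positive")
    p_a = k_ba / kex
    p_b = k_ab / kex
    dw = abs(dw_rad)
    if dw == 0.0:
        return float(r20)

    tcp = 1.0 / (2.0 * nu_cpmg_hz)  # spacing between successive 180 pulses
    psi = kex**2 - dw**2
    zeta = -2.0 * dw * kex * (p_a - p_b)
    root = np.sqrt(psi**2 + zeta**2)
    if asymptotic:
        eta_p = (tcp / np.sqrt(2.0)) * np.sqrt(max(psi + root, 0.0))
        eta_m = (tcp / np.sqrt(2.0)) * np.sqrt(max(-psi + root, 0.0))
        d_p = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
        d_m = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
        arg = d_p * np.cosh(eta_p) - d_m * np.cos(eta_m)
        arg = max(arg, 1.0)  # numerical guard; acosh domain
        return float(r20 + 0.5 * (kex - np.arccosh(arg) / tcp))

    n = echo_count(nu_cpmg_hz, t_relax)
    if n % 2 != 0:
        raise ValueError("closed-form oracle requires an even echo count")
    delta = tcp / 2.0  # free precession on either side of each 180

    # closed-form half-element propagator F = exp(E delta) with the intrinsic
    # rate factored out; E = [[-kAB, kBA], [kAB, -kBA + i dw]]
    g = 0.5 * (-kex + 1j * dw)          # tr(E)/2
    u = 0.5 * (k_ba - k_ab - 1j * dw)   # E11 - g = -(E22 - g)
    fsq = u * u + k_ab * k_ba
    f = np.sqrt(fsq)
    if abs(f) * delta < 1e-8:
        cc, ss = 1.0 + 0.5 * fsq * delta**2, delta * (1.0 + fsq * delta**2 / 6.0)
    else:
        cc, ss = np.cosh(f * delta), np.sinh(f * delta) / f
    eg = np.exp(g * delta)
    f11, f12 = eg * (cc + ss * u), eg * ss * k_ba
    f21, f22 = eg * ss * k_ab, eg * (cc - ss * u)

    # one echo pair: V = conj(H) H with H = conj(F) F
    h11 = np.conj(f11) * f11 + np.conj(f12) * f21
    h12 = np.conj(f11) * f12 + np.conj(f12) * f22
    h21 = np.conj(f21) * f11 + np.conj(f22) * f21
    h22 = np.conj(f21) * f12 + np.conj(f22) * f22
    v11 = np.conj(h11) * h11 + np.conj(h12) * h21
    v12 = np.conj(h11) * h12 + np.conj(h12) * h22
    v21 = np.conj(h21) * h11 + np.conj(h22) * h21
    v22 = np.conj(h21) * h12 + np.conj(h22) * h22

    # ground-state magnetization after m = n/2 echo pairs, by spectral
    # decomposition of V applied to the equilibrium state (pA, pB)
    m = n // 2
    tr = v11 + v22
    det = v11 * v22 - v12 * v21
    disc = np.sqrt(0.25 * tr * tr - det)
    lam_p = 0.5 * tr + disc
    lam_m = 0.5 * tr - disc
    if abs(lam_p - lam_m) < 1e-14 * max(abs(lam_p), 1.0):
        # defective/degenerate pair propagator: V = lam I + N with N^2 = 0
        lam = 0.5 * tr
        n11 = v11 - lam
        ma = lam**m * p_a + m * lam ** (m - 1) * (n11 * p_a + v12 * p_b)
    else:
        w_p = ((v11 - lam_m) * p_a + v12 * p_b) / (lam_p - lam_m)
        w_m = ((v11 - lam_p) * p_a + v12 * p_b) / (lam_m - lam_p)
        ma = lam_p**m * w_p + lam_m**m * w_m
    mag = abs(ma)
    if not np.isfinite(mag) or mag <= 0:
        raise FloatingPointError("closed-form evaluation underflow")
    return float(r20 - np.log(mag / p_a) / t_relax)


def luz_meiboom_rex(
    p_a: float, p_b: float, dw_rad: float, kex: float, nu_cpmg_hz: float
) -> float:
    """Fast-exchange (Luz-Meiboom) exchange contribution to R2,eff.

    Valid for kex >> |dw|:  Rex = pA pB dw^2 / kex *
    [1 - (4 nu / kex) tanh(kex / (4 nu))].
    """
    x = kex / (4.0 * nu_cpmg_hz)
    return p_a * p_b * dw_rad**2 / kex * (1.0 - np.tanh(x) / x)


# ---------------------------------------------------------------------------
# exchange-residue selection
# ---------------------------------------------------------------------------

def select_exchange_residues(
    dataset: DispersionDataset,
    threshold: float = DELTA_R2EFF_THRESHOLD,
    nu_low: float = NU_LOW_DEFAULT_HZ,
    nu_high: float = NU_HIGH_DEFAULT_HZ,
) -> tuple[list[int], pd.DataFrame]:
    """Identify residues undergoing conformational exchange.

    A residue is retained when the dispersion amplitude
    ``dR2,eff = R2,eff(nu_low) - R2,eff(nu_high)`` exceeds ``threshold`` in at
    least one field/temperature condition.  Residues carrying an exclusion tag
    (peak overlap, low quality) are dropped regardless of amplitude.

    Returns the retained residue ids and a per-curve table of dR2,eff values.
    """
    tagged = {res for res, _ in dataset.excluded}
    rows = []
    for c in dataset.curves:
        ilow = int(np.argmin(np.abs(c.nu_cpmg_hz - nu_low)))
        ihigh = int(np.argmin(np.abs(c.nu_cpmg_hz - nu_high)))
        rows.append({
            "residue_id": c.residue_id,
            "field_mhz": c.field_mhz,
            "temp_k": c.temp_k,
            "delta_r2eff": c.r2eff[ilow] - c.r2eff[ihigh],
        })
    table = pd.DataFrame(rows)
    selected = []
    for res, grp in table.groupby("residue_id"):
        if res in tagged:
            continue
        if (grp["delta_r2eff"] > threshold).any():
            selected.append(int(res))
    if tagged & set(table["residue_id"]):
        warnings.warn(
            f"residues {sorted(tagged & set(table['residue_id']))} excluded by "
            "quality tags despite having curves", stacklevel=2,
        )
    return sorted(selected), table
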