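"""Global two-state fit of CPMG dispersion data across residues, fields and
temperatures.

The model couples all curves through a single exchange process: one
(p_B, k_AB) pair per temperature, one |dw| per residue (in ppm, hence field
independent), and one intrinsic rate R2,0 per residue and field (shared by
the two exchanging states and across temperatures).  The target function is

    chi^2 = sum_points ((R2eff_calc - R2eff_exp) / dR2eff_exp)^2

with R2eff_calc from numerical Bloch-McConnell propagation.  Internally the
fit runs on log-transformed rates and logit-transformed populations so all
parameters are unconstrained while the physical ones stay positive and
p_B stays inside (0, 1); the 0.5 boundary (state relabelling ambiguity) is
reported as an identifiability warning when approached.

A strict per-temperature mode (each temperature fitted independently, dw
free per temperature) is available for comparison with the joint fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares

from .constants import T_RELAX_DEFAULT, n15_omega_rad_per_ppm
from .dispersion import DispersionDataset, bm_r2eff_batch, echo_count

__all__ = [
    "TwoStateGlobalParams",
    "GlobalFitResult",
    "FitConfig",
    "chi_square",
    "fit_global",
    "estimate_uncertainties",
]


@dataclass
class TwoStateGlobalParams:
    """Parameters of the shared two-state exchange model."""

    per_temperature: list[tuple[float, float, float]]  # (T K, p_B, k_AB s^-1)
    per_residue_dw_ppm: dict[int, float]
    per_residue_per_field_r20: dict[tuple[int, float], float]

    def __post_init__(self):
        for t, p_b, k_ab in self.per_temperature:
            if not 0.0 < p_b < 0.5:
                raise ValueError(f"p_B = {p_b} at {t} K outside (0, 0.5)")
            if k_ab <= 0:
                raise ValueError(f"k_AB must be positive at {t} K")

    def kinetics_at(self, temp_k: float) -> tuple[float, float]:
        """(k_AB, k_BA) at a fitted temperature."""
        for t, p_b, k_ab in self.per_temperature:
            if abs(t - temp_k) < 1e-9:
                return k_ab, k_ab * (1.0 - p_b) / p_b
        raise KeyError(f"no parameters at T = {temp_k} K")

    def kex_at(self, temp_k: float) -> float:
        k_ab, k_ba = self.kinetics_at(temp_k)
        return k_ab + k_ba

    def p_b_at(self, temp_k: float) -> float:
        for t, p_b, _ in self.per_temperature:
            if abs(t - temp_k) < 1e-9:
                return p_b
        raise KeyError(f"no parameters at T = {temp_k} K")

    def ke_at(self, temp_k: float) -> float:
        p_b = self.p_b_at(temp_k)
        return p_b / (1.0 - p_b)


@dataclass
class GlobalFitResult:
    params: TwoStateGlobalParams
    chi2: float
    n_data: int
    n_par: int
    converged: bool
    seed: int | None = None
    n_starts: int = 1
    identifiability_warning: bool = False
    uncertainties: TwoStateGlobalParams | None = None
    _jac: np.ndarray | None = field(default=None, repr=False)
    _x_opt: np.ndarray | None = field(default=None, repr=False)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_data - self.n_par, 1)


@dataclass
class FitConfig:
    mode: str = "joint"            # "joint" or "per_temperature"
    n_starts: int = 5
    ftol: float = 1e-8
    max_nfev: int = 10000
    seed: int = 0
    t_relax: float = T_RELAX_DEFAULT


# ---------------------------------------------------------------------------
# design flattening and parameter packing
# ---------------------------------------------------------------------------

class _Design:
    """Flat array view of a dispersion dataset for vectorised evaluation."""

    def __init__(self, dataset: DispersionDataset, t_relax: float):
        self.t_relax = t_relax
        self.temps = sorted({c.temp_k for c in dataset.curves})
        self.fields = sorted({c.field_mhz for c in dataset.curves})
        self.residues = sorted({c.residue_id for c in dataset.curves})
        t_idx = {t: i for i, t in enumerate(self.temps)}
        f_idx = {f: i for i, f in enumerate(self.fields)}
        r_idx = {r: i for i, r in enumerate(self.residues)}
        ti, fi, ri, nu, r2, err = [], [], [], [], [], []
        for c in dataset.curves:
            for v, y, e in zip(c.nu_cpmg_hz, c.r2eff, c.r2eff_err):
                ti.append(t_idx[c.temp_k])
                fi.append(f_idx[c.field_mhz])
                ri.append(r_idx[c.residue_id])
                nu.append(v)
                r2.append(y)
                err.append(e)
        self.t_i = np.array(ti)
        self.f_i = np.array(fi)
        self.r_i = np.array(ri)
        self.nu = np.array(nu)
        self.n_echo = np.array([echo_count(v, t_relax) for v in self.nu])
        self.r2exp = np.array(r2)
        self.err = np.array(err)
        self.omega_per_ppm = np.array(
            [n15_omega_rad_per_ppm(f) for f in self.fields]
        )
        self.n_t = len(self.temps)
        self.n_f = len(self.fields)
        self.n_r = len(self.residues)
        self.n_par = 2 * self.n_t + self.n_r + self.n_r * self.n_f
        self.n_data = self.nu.size

    # parameter vector layout:
    #   [log kex (n_t)] [logit pB (n_t)] [log dw_ppm (n_r)] [log r20 (n_r*n_f)]
    def pack(self, params: TwoStateGlobalParams) -> np.ndarray:
        x = np.empty(self.n_par)
        for i, t in enumerate(self.temps):
            p_b = params.p_b_at(t)
            x[i] = np.log(params.kex_at(t))
            x[self.n_t + i] = np.log(p_b / (1.0 - p_b))
        for j, r in enumerate(self.residues):
            x[2 * self.n_t + j] = np.log(params.per_residue_dw_ppm[r])
        base = 2 * self.n_t + self.n_r
        for j, r in enumerate(self.residues):
            for k, f in enumerate(self.fields):
                x[base + j * self.n_f + k] = np.log(
                    params.per_residue_per_field_r20[(r, f)]
                )
        return x

    def unpack(self, x: np.ndarray) -> TwoStateGlobalParams:
        kex = np.exp(x[: self.n_t])
        p_b = 1.0 / (1.0 + np.exp(-x[self.n_t: 2 * self.n_t]))
        dw = np.exp(x[2 * self.n_t: 2 * self.n_t + self.n_r])
        r20 = np.exp(x[2 * self.n_t + self.n_r:])
        per_temp = [
            (t, float(p_b[i]), float(p_b[i] * kex[i]))
            for i, t in enumerate(self.temps)
        ]
        dw_map = {r: float(dw[j]) for j, r in enumerate(self.residues)}
        r20_map = {
            (r, f): float(r20[j * self.n_f + k])
            for j, r in enumerate(self.residues)
            for k, f in enumerate(self.fields)
        }
        return TwoStateGlobalParams(per_temp, dw_map, r20_map)

    def model_r2eff(self, x: np.ndarray) -> np.ndarray:
        kex = np.exp(x[: self.n_t])[self.t_i]
        p_b = 1.0 / (1.0 + np.exp(-x[self.n_t: 2 * self.n_t]))[self.t_i]
        dw_ppm = np.exp(x[2 * self.n_t: 2 * self.n_t + self.n_r])[self.r_i]
        r20_flat = np.exp(x[2 * self.n_t + self.n_r:])
        r20 = r20_flat[self.r_i * self.n_f + self.f_i]
        dw_rad = dw_ppm * self.omega_per_ppm[self.f_i]
        k_ab = p_b * kex
        k_ba = (1.0 - p_b) * kex
        return bm_r2eff_batch(k_ab, k_ba, dw_rad, r20, self.n_echo, self.t_relax)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return (self.model_r2eff(x) - self.r2exp) / self.err

    def jac_sparsity(self) -> sparse.lil_matrix:
        s = sparse.lil_matrix((self.n_data, self.n_par), dtype=bool)
        rows = np.arange(self.n_data)
        s[rows, self.t_i] = True
        s[rows, self.n_t + self.t_i] = True
        s[rows, 2 * self.n_t + self.r_i] = True
        s[rows, 2 * self.n_t + self.n_r + self.r_i * self.n_f + self.f_i] = True
        return s


def chi_square(params: TwoStateGlobalParams, dataset: DispersionDataset,
               t_relax: float = T_RELAX_DEFAULT) -> float:
    """Target function: weighted sum of squared deviations over all points."""
    _check_coverage(params, dataset)
    design = _Design(dataset, t_relax)
    return float(np.sum(design.residuals(design.pack(params)) ** 2))


def _check_coverage(params: TwoStateGlobalParams, dataset: DispersionDataset):
    for c in dataset.curves:
        if c.residue_id not in params.per_residue_dw_ppm:
            raise KeyError(f"no dw entry for residue {c.residue_id}")
        if (c.residue_id, c.field_mhz) not in params.per_residue_per_field_r20:
            raise KeyError(
                f"no R2,0 entry for residue {c.residue_id} at "
                f"{c.field_mhz} MHz"
            )
        try:
            params.p_b_at(c.temp_k)
        except KeyError:
            raise KeyError(f"no exchange parameters at T = {c.temp_k} K")


# ---------------------------------------------------------------------------
# initialisation and fitting
# ---------------------------------------------------------------------------

def auto_init(dataset: DispersionDataset,
              kex0: float = 1000.0, p_b0: float = 0.05) -> TwoStateGlobalParams:
    """Heuristic starting point.

    R2,0 from the high-frequency plateau of each curve; dw from the observed
    dispersion amplitude through the fast-exchange relation
    Rex(nu->0) = pA pB dw^2 / kex evaluated at the initial kinetics.
    """
    temps = sorted({c.temp_k for c in dataset.curves})
    fields = sorted({c.field_mhz for c in dataset.curves})
    residues = sorted({c.residue_id for c in dataset.curves})
    r20_map, rex_map = {}, {}
    for c in dataset.curves:
        r20_map.setdefault((c.residue_id, c.field_mhz), []).append(c.r2eff[-1])
        rex_map.setdefault(c.residue_id, []).append(
            max(c.r2eff[0] - c.r2eff[-1], 0.0)
        )
    dw_map = {}
    omega500 = n15_omega_rad_per_ppm(min(fields))
    for r in residues:
        rex = float(np.median(rex_map[r]))
        dw_rad = np.sqrt(max(rex, 0.25) * kex0 / ((1.0 - p_b0) * p_b0))
        dw_map[r] = float(np.clip(dw_rad / omega500, 0.05, 15.0))
    return TwoStateGlobalParams(
        per_temperature=[(t, p_b0, p_b0 * kex0) for t in temps],
        per_residue_dw_ppm=dw_map,
        per_residue_per_field_r20={
            k: float(max(np.median(v), 0.5)) for k, v in r20_map.items()
        },
    )


def _perturb(design: _Design, x: np.ndarray, rng) -> np.ndarray:
    """Randomised restart: scatter kinetics broadly, nuisance mildly."""
    x = x.copy()
    x[: design.n_t] += rng.normal(0.0, 0.7, design.n_t)          # kex factor ~2
    x[design.n_t: 2 * design.n_t] += rng.normal(0.0, 0.7, design.n_t)
    x[2 * design.n_t: 2 * design.n_t + design.n_r] += rng.normal(
        0.0, 0.3, design.n_r
    )
    return x


def fit_global(
    dataset: DispersionDataset,
    init: TwoStateGlobalParams | str = "auto",
    config: FitConfig | None = None,
) -> GlobalFitResult | dict[float, GlobalFitResult]:
    """Least-squares minimisation of the global target function.

    ``config.n_starts`` initialisations are tried (the supplied or automatic
    one plus randomised restarts) and the best chi^2 kept.  In
    ``per_temperature`` mode each temperature is fitted independently and a
    mapping temperature -> result is returned.
    """
    config = config or FitConfig()
    if config.mode == "per_temperature":
        results = {}
        joint_cfg = replace(config, mode="joint")
        for t in sorted({c.temp_k for c in dataset.curves}):
            sub = DispersionDataset(
                [c for c in dataset.curves if c.temp_k == t], dataset.excluded
            )
            results[t] = fit_global(sub, init="auto", config=joint_cfg)
        return results
    if config.mode != "joint":
        raise ValueError(f"unknown fit mode {config.mode!r}")
    if not dataset.curves:
        raise ValueError("dataset is empty")

    design = _Design(dataset, config.t_relax)
    if design.n_data <= design.n_par:
        raise ValueError(
            f"underdetermined fit: {design.n_data} points for "
            f"{design.n_par} parameters"
        )
    if init == "auto":
        init_params = auto_init(dataset)
    else:
        _check_coverage(init, dataset)
        init_params = init
    x0 = design.pack(init_params)
    sparsity = design.jac_sparsity()
    rng = np.random.default_rng(config.seed)

    best = None
    for start in range(max(config.n_starts, 1)):
        x_start = x0 if start == 0 else _perturb(design, x0, rng)
        try:
            sol = least_squares(
                design.residuals, x_start, jac_sparsity=sparsity,
                method="trf", ftol=config.ftol, xtol=1e-10,
                max_nfev=config.max_nfev,
            )
        except (FloatingPointError, ValueError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    params = design.unpack(best.x)
    chi2 = float(2.0 * best.cost)
    converged = bool(best.status > 0)
    ident = any(p_b > 0.45 for _, p_b, _ in params.per_temperature)
    if ident:
        warnings.warn(
            "p_B approaches the 0.5 identifiability bound; the two states "
            "are nearly interchangeable", stacklevel=2,
        )
    if not converged:
        warnings.warn("fit did not converge; best-so-far returned", stacklevel=2)
    return GlobalFitResult(
        params=params, chi2=chi2, n_data=design.n_data, n_par=design.n_par,
        converged=converged, seed=config.seed,
        n_starts=max(config.n_starts, 1), identifiability_warning=ident,
        _jac=best.jac.toarray() if sparse.issparse(best.jac) else best.jac,
        _x_opt=best.x,
    )


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------

def _params_from_sigma(design: _Design, x: np.ndarray,
                       sigma_x: np.ndarray) -> TwoStateGlobalParams:
    """Map parameter-vector standard errors to physical-scale errors.

    kex, dw and R2,0 are log-parametrised (sigma_phys = phys * sigma_log);
    p_B is logit-parametrised (sigma = pB (1-pB) sigma_logit).  The k_AB
    error combines the kex and p_B contributions in quadrature.
    """
    kex = np.exp(x[: design.n_t])
    p_b = 1.0 / (1.0 + np.exp(-x[design.n_t: 2 * design.n_t]))
    s_kex = kex * sigma_x[: design.n_t]
    s_pb = p_b * (1.0 - p_b) * sigma_x[design.n_t: 2 * design.n_t]
    s_kab = np.sqrt((p_b * s_kex) ** 2 + (kex * s_pb) ** 2)
    dw = np.exp(x[2 * design.n_t: 2 * design.n_t + design.n_r])
    s_dw = dw * sigma_x[2 * design.n_t: 2 * design.n_t + design.n_r]
    r20 = np.exp(x[2 * design.n_t + design.n_r:])
    s_r20 = r20 * sigma_x[2 * design.n_t + design.n_r:]
    per_temp = [
        (t, float(s_pb[i]), float(s_kab[i]))
        for i, t in enumerate(design.temps)
    ]
    dw_map = {r: float(s_dw[j]) for j, r in enumerate(design.residues)}
    r20_map = {
        (r, f): float(s_r20[j * design.n_f + k])
        for j, r in enumerate(design.residues)
        for k, f in enumerate(design.fields)
    }
    out = TwoStateGlobalParams.__new__(TwoStateGlobalParams)
    out.per_temperature = per_temp
    out.per_residue_dw_ppm = dw_map
    out.per_residue_per_field_r20 = r20_map
    return out


def estimate_uncertainties(
    result: GlobalFitResult,
    dataset: DispersionDataset,
    method: str = "covariance",
    n_boot: int = 200,
    seed: int = 0,
    t_relax: float = T_RELAX_DEFAULT,
) -> TwoStateGlobalParams:
    """Parameter uncertainties at the optimum.

    ``covariance`` inverts the Gauss-Newton normal matrix J^T J of the
    weighted residuals and scales by the reduced chi^2, so exactly fitting
    (noise-free) data yields vanishing uncertainties.  ``bootstrap``
    resamples weighted residuals with replacement, refits from the optimum,
    and reports the standard deviation over replicates.
    """
    if method == "covariance":
        if result._jac is None or result._x_opt is None:
            raise ValueError("result carries no Jacobian; refit first")
        jtj = result._jac.T @ result._jac
        cov = np.linalg.pinv(jtj) * result.reduced_chi2
        sigma_x = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        design = _Design(dataset, t_relax)
        return _params_from_sigma(design, result._x_opt, sigma_x)
    if method != "bootstrap":
        raise ValueError("method must be 'covariance' or 'bootstrap'")

    design = _Design(dataset, t_relax)
    x_opt = result._x_opt
    if x_opt is None:
        x_opt = design.pack(result.params)
    r2_calc = design.model_r2eff(x_opt)
    resid = design.r2exp - r2_calc
    rng = np.random.default_rng(seed)
    sparsity = design.jac_sparsity()
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, resid.size, resid.size)
        boot = _Design.__new__(_Design)
        boot.__dict__.update(design.__dict__)
        boot.r2exp = r2_calc + resid[idx]
        sol = least_squares(
            boot.residuals, x_opt, jac_sparsity=sparsity, method="trf",
            ftol=1e-6, xtol=1e-8, max_nfev=2000,
        )
        draws.append(sol.x)
    sigma_x = np.std(np.array(draws), axis=0, ddof=1)
    return _params_from_sigma(design, x_opt, sigma_x)
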