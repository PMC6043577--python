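"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators reproduce the statistical structure the analysis assumes:
two-state Bloch-McConnell dispersion curves across fields and temperatures,
single-exponential relaxation decays, linear amide-shift temperature series,
quadratic single-site binding titrations, and hollow atomic shells with an
analytically known cavity volume.  Every generator takes a seed and is
bit-reproducible.

The default study design mirrors the reference experiment: 22 residues, two
fields (500/700 MHz), five temperatures (298.0-308.0 K), twelve CPMG
frequencies (66.7-1000 Hz), 30 ms relaxation delay, 3% intensity noise.
The default kinetic truth is thermodynamically consistent by construction:
per-temperature (k_AB, k_BA) pairs are derived from (dH_BA, dS_BA) via the
Van't Hoff relation and from (dH*, dS*, kappa) via the Eyring relation, so
ln(Ke) and ln(k_AB/T) are exactly linear in 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cavity import StructureCoords, _excluded_volume_mask, _occupancy_grid
from .constants import (
    FIELDS_DEFAULT_MHZ,
    KAPPA_DEFAULT,
    N_RESIDUES_DEFAULT,
    NU_CPMG_DEFAULT_HZ,
    R_GAS,
    T_RELAX_DEFAULT,
    TEMPERATURES_DEFAULT_K,
    n15_omega_rad_per_ppm,
)
from .dispersion import bm_r2eff_batch, echo_count
from .relaxation import RelaxationRecord, r1_r2_from_tau_c
from .shifts import ShiftSeries, TitrationSeries, binding_isotherm
from .thermo import delta_g_from_population, kab_from_eyring, ke_from_thermo

__all__ = [
    "ThermoTruth",
    "SyntheticTruth",
    "reference_thermo_truth",
    "generate_two_state_system",
    "generate_dispersion_intensities",
    "generate_relaxation_series",
    "generate_titration_shifts",
    "generate_temp_shift_series",
    "generate_hollow_structure",
    "generate_backbone_records",
    "HollowShellFixture",
]

I0_DEFAULT = 100.0


@dataclass(frozen=True)
class ThermoTruth:
    """Generating thermodynamic parameters (J/mol and J/(mol K))."""

    dh_ba: float
    ds_ba: float
    dh_act: float
    ds_act: float
    kappa: float = KAPPA_DEFAULT

    def kinetics_at(self, temp_k: float) -> tuple[float, float]:
        """(k_AB, k_BA) at one temperature, exactly on both linear laws."""
        ke = ke_from_thermo(self.dh_ba, self.ds_ba, temp_k)
        k_ab = kab_from_eyring(self.dh_act, self.ds_act, temp_k, self.kappa)
        return k_ab, k_ab / ke


def reference_thermo_truth(
    p_b_298: float = 0.085,
    kex_298: float = 812.0,
    dh_ba: float = -37e3,
    dh_act: float = 40e3,
    kappa: float = KAPPA_DEFAULT,
) -> ThermoTruth:
    """Thermodynamic truth anchored at the reference kinetics.

    dS_BA is fixed by the excited-state population at 298 K together with
    dH_BA; dS* is fixed by k_AB(298 K) = p_B * kex together with dH*.  The
    defaults place p_B = 8.5% and kex = 812 1/s at 298 K with an
    enthalpically favourable, entropically penalised excited state
    (dH_BA = -37 kJ/mol).
    """
    t0 = 298.0
    dg_ba = delta_g_from_population(p_b_298, t0)
    ds_ba = (dh_ba - dg_ba) / t0
    k_ab = p_b_298 * kex_298
    prefactor = kappa * 1.380649e-23 * t0 / 6.62607015e-34
    dg_act = -R_GAS * t0 * np.log(k_ab / prefactor)
    ds_act = (dh_act - dg_act) / t0
    return ThermoTruth(dh_ba, ds_ba, dh_act, ds_act, kappa)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dispersion dataset."""

    per_temperature_kinetics: list[tuple[float, float, float]]  # (T, kAB, kBA)
    per_residue_dw_ppm: dict[int, float]
    per_residue_per_field_r20: dict[tuple[int, float], float]
    thermo_truth: ThermoTruth | None = None
    noise_fraction: float = 0.03
    seed: int = 0
    fields_mhz: tuple[float, ...] = FIELDS_DEFAULT_MHZ

    def __post_init__(self):
        temps = [t for t, _, _ in self.per_temperature_kinetics]
        if not all(b > a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        for t, kab, kba in self.per_temperature_kinetics:
            if kab <= 0 or kba <= 0:
                raise ValueError(f"rates must be positive at T = {t} K")
            p_b = kab / (kab + kba)
            if not 0.0 < p_b < 0.5:
                raise ValueError(
                    f"p_B = {p_b:.3f} at T = {t} K outside (0, 0.5); the "
                    "minor state must stay minor for identifiability"
                )
        if any(dw <= 0 for dw in self.per_residue_dw_ppm.values()):
            raise ValueError("dw values must be positive (sign is not modelled)")
        if any(r <= 0 for r in self.per_residue_per_field_r20.values()):
            raise ValueError("intrinsic rates must be positive")

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self.per_residue_dw_ppm)

    @property
    def temperatures(self) -> list[float]:
        return [t for t, _, _ in self.per_temperature_kinetics]

    def p_b_at(self, temp_k: float) -> float:
        for t, kab, kba in self.per_temperature_kinetics:
            if abs(t - temp_k) < 1e-9:
                return kab / (kab + kba)
        raise KeyError(f"no kinetics at T = {temp_k} K")

    def kex_at(self, temp_k: float) -> float:
        for t, kab, kba in self.per_temperature_kinetics:
            if abs(t - temp_k) < 1e-9:
                return kab + kba
        raise KeyError(f"no kinetics at T = {temp_k} K")


def generate_two_state_system(
    n_residues: int = N_RESIDUES_DEFAULT,
    thermo_truth: ThermoTruth | None = None,
    temperatures=TEMPERATURES_DEFAULT_K,
    fields=FIELDS_DEFAULT_MHZ,
    dw_range: tuple[float, float] = (0.8, 3.5),
    r20_range: tuple[float, float] = (8.0, 20.0),
    noise_fraction: float = 0.03,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a thermodynamically consistent two-state exchange system.

    Per-temperature kinetics follow exactly from ``thermo_truth`` (defaults
    to :func:`reference_thermo_truth`); per-residue dw and per-residue-per-
    field intrinsic rates are drawn uniformly from the given ranges.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    temperatures = [float(t) for t in temperatures]
    fields = [float(f) for f in fields]
    if not temperatures or not fields:
        raise ValueError("temperature and field lists must be non-empty")
    if any(not 250.0 <= t <= 350.0 for t in temperatures):
        raise ValueError("temperatures outside the physically sensible "
                         "250-350 K range")
    if thermo_truth is None:
        thermo_truth = reference_thermo_truth()
    kinetics = []
    for t in sorted(temperatures):
        k_ab, k_ba = thermo_truth.kinetics_at(t)
        p_b = k_ab / (k_ab + k_ba)
        if p_b >= 0.5:
            raise ValueError(
                f"thermo truth implies p_B = {p_b:.3f} >= 0.5 at {t} K"
            )
        kinetics.append((t, k_ab, k_ba))
    rng = np.random.default_rng(seed)
    dw = {
        res: float(rng.uniform(*dw_range)) if dw_range[0] < dw_range[1]
        else float(dw_range[0])
        for res in range(1, n_residues + 1)
    }
    r20 = {
        (res, f): (
            float(rng.uniform(*r20_range)) if r20_range[0] < r20_range[1]
            else float(r20_range[0])
        )
        for res in range(1, n_residues + 1)
        for f in fields
    }
    return SyntheticTruth(
        per_temperature_kinetics=kinetics,
        per_residue_dw_ppm=dw,
        per_residue_per_field_r20=r20,
        thermo_truth=thermo_truth,
        noise_fraction=noise_fraction,
        seed=seed,
        fields_mhz=tuple(fields),
    )


def truth_r2eff(
    truth: SyntheticTruth, nu_cpmg, t_relax: float = T_RELAX_DEFAULT
) -> pd.DataFrame:
    """Noise-free forward R2,eff for every residue/field/temperature/nu."""
    nu = np.asarray(nu_cpmg, float)
    n_echo = np.array([echo_count(v, t_relax) for v in nu])
    rows = []
    for t, k_ab, k_ba in truth.per_temperature_kinetics:
        for f in truth.fields_mhz:
            for res in truth.residue_ids:
                dw_rad = truth.per_residue_dw_ppm[res] * n15_omega_rad_per_ppm(f)
                r20 = truth.per_residue_per_field_r20[(res, f)]
                r2 = bm_r2eff_batch(
                    np.full(nu.size, k_ab), np.full(nu.size, k_ba),
                    np.full(nu.size, dw_rad), np.full(nu.size, r20),
                    n_echo, t_relax,
                )
                for v, r in zip(nu, r2):
                    rows.append({
                        "residue_id": res, "field_mhz": f, "temp_k": t,
                        "nu_cpmg_hz": v, "r2eff": r,
                    })
    return pd.DataFrame(rows)


def generate_dispersion_intensities(
    truth: SyntheticTruth,
    nu_cpmg=NU_CPMG_DEFAULT_HZ,
    t_relax: float = T_RELAX_DEFAULT,
    seed: int | None = None,
    i0: float = I0_DEFAULT,
) -> pd.DataFrame:
    """Peak-intensity table for the CPMG experiment defined by ``truth``.

    Intensities are ``I0 exp(-R2eff T_relax)`` plus Gaussian noise of
    standard deviation ``noise_fraction * I0`` (also applied to the
    reference rows).  Frequencies must accommodate an integer number of
    echo elements within ``t_relax``.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    clean = truth_r2eff(truth, nu_cpmg, t_relax)
    sigma = truth.noise_fraction * i0
    rows = []
    for (res, f, t), grp in clean.groupby(
        ["residue_id", "field_mhz", "temp_k"], sort=True
    ):
        rows.append({
            "residue_id": res, "field_mhz": f, "temp_k": t,
            "condition": "reference", "nu_cpmg_hz": 0.0,
            "intensity": i0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0),
        })
        for _, point in grp.iterrows():
            inten = i0 * np.exp(-point["r2eff"] * t_relax)
            if sigma > 0:
                inten += rng.normal(0.0, sigma)
            rows.append({
                "residue_id": res, "field_mhz": f, "temp_k": t,
                "condition": "cpmg", "nu_cpmg_hz": point["nu_cpmg_hz"],
                "intensity": inten,
            })
    return pd.DataFrame(rows)


def generate_relaxation_series(
    rate: float,
    delays,
    i0: float = I0_DEFAULT,
    noise_fraction: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
) -> pd.DataFrame:
    """Single-exponential decay table: I(t) = I0 exp(-rate t) plus noise.

    Noise is proportional to the decaying intensity (standard deviation
    ``noise_fraction * I(t)``), matching the per-peak relative precision of
    well-resolved intensity measurements across a delay series.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    delays = np.asarray(delays, float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-rate * delays)
    sigma = noise_fraction * clean
    inten = clean
    if noise_fraction > 0:
        inten = clean + rng.normal(0.0, 1.0, size=delays.size) * sigma
    return pd.DataFrame({
        "residue_id": residue_id,
        "delay_s": delays,
        "intensity": inten,
        "intensity_err": sigma,
    })


def generate_titration_shifts(
    kd: float,
    dw_max: float,
    p_total: float,
    ligand_concs,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
) -> TitrationSeries:
    """Titration shift changes following the quadratic binding isotherm."""
    if kd <= 0 or p_total <= 0:
        raise ValueError("kd and p_total must be positive")
    l0 = np.asarray(ligand_concs, float)
    if np.any(l0 < 0):
        raise ValueError("ligand concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    dw = binding_isotherm(l0, kd, dw_max, p_total)
    if noise_sd > 0:
        dw = dw + rng.normal(0.0, noise_sd, size=l0.size)
        dw[l0 == 0] = 0.0  # the reference point defines zero shift change
    return TitrationSeries(
        residue_id=residue_id, p_total=p_total,
        ligand_concs=l0, dw_obs_ppm=dw,
    )


def generate_temp_shift_series(
    slope_ppb_per_k: float,
    temperatures,
    intercept_ppb: float = 8500.0,
    noise_sd_ppb: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
    n_ppm: float = 120.0,
) -> ShiftSeries:
    """Linear 1H shift-versus-temperature series (fixture for TCI analysis)."""
    temps = np.asarray(sorted(float(t) for t in temperatures))
    if temps.size < 3:
        raise ValueError("need at least 3 temperatures")
    rng = np.random.default_rng(seed)
    h_ppb = intercept_ppb + slope_ppb_per_k * temps
    if noise_sd_ppb > 0:
        h_ppb = h_ppb + rng.normal(0.0, noise_sd_ppb, size=temps.size)
    return ShiftSeries(
        residue_id=residue_id, axis="temperature_K", axis_values=temps,
        h_ppm=h_ppb / 1000.0, n_ppm=np.full(temps.size, n_ppm),
    )


@dataclass
class HollowShellFixture:
    coords: StructureCoords
    analytic_cavity_volume: float    # A^3


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n points approximately uniformly distributed on a sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return radius * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])


def generate_hollow_structure(
    inner_radius: float,
    outer_radius: float,
    atom_radius: float = 1.5,
    packing_spacing: float = 1.0,
    check_leaks: bool = True,
) -> HollowShellFixture:
    """Atomic shell enclosing an empty sphere of analytically known volume.

    Atom centres populate spherical layers (Fibonacci lattices, which stay
    leak-free at coarser atom counts than cubic packings) from
    ``inner_radius + atom_radius`` to ``outer_radius - atom_radius``.  The
    ground-truth cavity volume is ``4/3 pi inner_radius^3``.  A solvent
    flood-fill with a 1.3 A probe verifies the shell is tight; leaky shells
    are rejected.
    """
    if inner_radius < 0:
        raise ValueError("inner_radius must be non-negative")
    if outer_radius <= inner_radius + 2.0 * atom_radius:
        raise ValueError("need outer_radius > inner_radius + 2*atom_radius")
    r_lo = inner_radius + atom_radius
    r_hi = outer_radius - atom_radius
    n_layers = max(int(np.floor((r_hi - r_lo) / packing_spacing)) + 1, 1)
    layer_radii = np.linspace(r_lo, r_hi, n_layers)
    centers = []
    for r in layer_radii:
        n = max(int(np.ceil(4.0 * np.pi * r**2 / packing_spacing**2)), 12)
        centers.append(_fibonacci_sphere(n, r))
    coords = np.vstack(centers)
    struct = StructureCoords(
        elements=["C"] * len(coords),
        coords=coords,
        radii=np.full(len(coords), atom_radius),
        source="synthetic-hollow-shell",
    )
    volume = 4.0 / 3.0 * np.pi * inner_radius**3
    if check_leaks and inner_radius > 1.3:
        spacing = 0.5
        occ, origin = _occupancy_grid(struct, spacing, margin=1.3 + atom_radius + 2.0)
        excluded = _excluded_volume_mask(occ, spacing, 1.3, from_outside=True)
        center_idx = tuple(np.round(-origin / spacing).astype(int))
        if not excluded[center_idx]:
            raise ValueError(
                "shell is leaky: a 1.3 A probe reaches the centre from "
                "outside; decrease packing_spacing"
            )
    return HollowShellFixture(coords=struct, analytic_cavity_volume=volume)


def generate_backbone_records(
    tau_c_ns: float,
    field_mhz: float,
    n_residues: int = 20,
    n_flexible: int = 0,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> list[RelaxationRecord]:
    """Relaxation records for a rigid isotropic rotor, optionally with a few
    flexible residues (Het-NOE below the 0.65 cut)."""
    rng = np.random.default_rng(seed)
    r1, r2 = r1_r2_from_tau_c(tau_c_ns * 1e-9, field_mhz)
    records = []
    for res in range(1, n_residues + 1):
        noise1 = rng.normal(0.0, noise_fraction * r1) if noise_fraction else 0.0
        noise2 = rng.normal(0.0, noise_fraction * r2) if noise_fraction else 0.0
        flexible = res > n_residues - n_flexible
        noe = 0.45 if flexible else 0.82
        records.append(RelaxationRecord(
            residue_id=res,
            r1=r1 + noise1, r1_err=max(abs(noise_fraction * r1), 1e-3),
            r2=r2 + noise2, r2_err=max(abs(noise_fraction * r2), 1e-3),
            het_noe=noe, het_noe_err=0.02,
        ))
    return records
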