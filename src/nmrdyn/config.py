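"""Run configuration: one place for every tunable constant of the pipeline.

Configs load from a YAML file with sections mirroring the dataclass fields;
unknown keys are rejected so typos fail loudly.  Precedence is
CLI flag > config file > defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import constants as C

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # stage toggles
    run_dispersion: bool = True
    run_thermo: bool = True
    run_relaxation: bool = True
    run_tempcoeff: bool = True
    run_titration: bool = True
    run_cavity: bool = True

    # CPMG analysis
    t_relax_s: float = C.T_RELAX_DEFAULT
    error_floor: float = C.ERROR_FLOOR_FRACTION
    delta_r2eff_threshold: float = C.DELTA_R2EFF_THRESHOLD
    nu_low_hz: float = C.NU_LOW_DEFAULT_HZ
    nu_high_hz: float = C.NU_HIGH_DEFAULT_HZ
    fit_mode: str = "joint"
    n_fit_starts: int = 5

    # thermodynamics
    kappa: float = C.KAPPA_DEFAULT

    # backbone relaxation
    hetnoe_cut: float = C.HETNOE_FLEXIBLE_CUT
    relax_field_mhz: float = 500.0

    # shift analyses
    tci_cut_ppb_per_k: float = C.TCI_HBOND_CUT
    csp_alpha: float = C.CSP_ALPHA
    dw_outlier_cutoff_ppm: float = 0.5

    # cavity
    probe_small: float = C.PROBE_SMALL_DEFAULT
    probe_large: float = C.PROBE_LARGE_DEFAULT
    grid_spacing: float = C.GRID_SPACING_DEFAULT

    # simulation / reproducibility
    seed: int = 0
    noise_fraction: float = 0.03
    n_residues: int = C.N_RESIDUES_DEFAULT
    temperatures_k: tuple = C.TEMPERATURES_DEFAULT_K
    fields_mhz: tuple = C.FIELDS_DEFAULT_MHZ
    nu_cpmg_hz: tuple = C.NU_CPMG_DEFAULT_HZ

    # paths (None = simulate inputs)
    peak_table: str | None = None
    shift_table: str | None = None
    pdb_file: str | None = None
    output_dir: str = "nmrdyn_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("temperatures_k", "fields_mhz", "nu_cpmg_hz"):
            d[key] = list(d[key])
        return d


_SECTIONS = {
    "stages": {"run_dispersion", "run_thermo", "run_relaxation",
               "run_tempcoeff", "run_titration", "run_cavity"},
    "dispersion": {"t_relax_s", "error_floor", "delta_r2eff_threshold",
                   "nu_low_hz", "nu_high_hz", "fit_mode", "n_fit_starts"},
    "thermo": {"kappa"},
    "relaxation": {"hetnoe_cut", "relax_field_mhz"},
    "shifts": {"tci_cut_ppb_per_k", "csp_alpha", "dw_outlier_cutoff_ppm"},
    "cavity": {"probe_small", "probe_large", "grid_spacing"},
    "simulation": {"seed", "noise_fraction", "n_residues", "temperatures_k",
                   "fields_mhz", "nu_cpmg_hz"},
    "paths": {"peak_table", "shift_table", "pdb_file", "output_dir"},
}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    The YAML layout uses the sections in ``_SECTIONS``; flat top-level keys
    are also accepted.  Unknown sections or keys raise with a listing of the
    valid schema.
    """
    valid = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key, val in raw.items():
            if isinstance(val, dict):
                if key not in _SECTIONS:
                    raise ValueError(
                        f"{path}: unknown section {key!r}; valid sections: "
                        f"{sorted(_SECTIONS)}"
                    )
                for k, v in val.items():
                    if k not in _SECTIONS[key]:
                        raise ValueError(
                            f"{path}: unknown key {k!r} in section {key!r}; "
                            f"valid keys: {sorted(_SECTIONS[key])}"
                        )
                    values[k] = v
            elif key in valid:
                values[key] = val
            else:
                raise ValueError(
                    f"{path}: unknown key {key!r}; valid keys: {sorted(valid)}"
                )
    if overrides:
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown override(s) {sorted(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("temperatures_k", "fields_mhz", "nu_cpmg_hz"):
        if key in values:
            values[key] = tuple(values[key])
    return RunConfig(**values)
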