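"""Internal-cavity volume by the two-probe rolling-probe difference method.

A small probe (default 1.3 A, water-sized) and a large probe (default
3.0 A) each define a solvent-excluded volume on a regular grid.  The large
probe rolls on the outside of the structure and defines the molecular
envelope: every point it cannot reach from the surrounding solvent —
protein matter, channels and enclosed voids alike — counts as excluded.
The small probe defines the fine-grained excluded volume: any point that a
small probe sphere can occupy without clashing into an atom counts as
solvent, whether or not that pocket connects to the outside.  The
difference between the two excluded volumes therefore isolates interior
cavities and channels too narrow for the large probe, which is how the
large-probe/small-probe difference recovers the full volume of an enclosed
cavity (e.g. the analytic hollow-shell fixture).

All distances in Angstrom; volumes in cubic Angstrom.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import (
    GRID_SPACING_DEFAULT,
    PROBE_LARGE_DEFAULT,
    PROBE_SMALL_DEFAULT,
    VDW_FALLBACK,
    VDW_RADII,
)

__all__ = [
    "StructureCoords",
    "CavityResult",
    "read_structure",
    "rolling_probe_volume",
]


@dataclass
class StructureCoords:
    """Atom positions and van der Waals radii for volume calculations."""

    elements: list[str]
    coords: np.ndarray           # (n_atoms, 3), Angstrom
    radii: np.ndarray            # (n_atoms,), Angstrom
    model_id: int = 1
    source: str = "unknown"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.radii = np.asarray(self.radii, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.coords) < 1:
            raise ValueError("structure must contain at least one atom")
        if np.any(~np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    def to_pdb(self) -> str:
        """Minimal PDB representation (ATOM records, default occupancy/B)."""
        lines = []
        for i, (el, (x, y, z)) in enumerate(zip(self.elements, self.coords), 1):
            name = el.upper().rjust(2)
            lines.append(
                f"ATOM  {i % 100000:5d} {name:>4s} DUM A{(i - 1) % 9999 + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {el.upper():>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


@dataclass
class CavityResult:
    cavity_volume: float                 # A^3
    small_probe: float
    large_probe: float
    grid_spacing: float
    component_volumes: list[float] = field(default_factory=list)
    cavity_points: np.ndarray | None = None   # (n, 3) grid points, optional


def read_structure(
    pdb_text: str,
    model: int = 1,
    include_hetero: bool = False,
) -> StructureCoords:
    """Parse PDB content into coordinates with element-based vdW radii.

    Waters and hetero-ligands are excluded by default; hydrogens are kept
    when present.  Unknown elements fall back to a 1.70 A radius with a
    warning.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("structure", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ValueError("no models found in PDB content")
    chosen = None
    for m in models:
        if m.id + 1 == model or m.id == model:
            chosen = m
            break
    if chosen is None:
        chosen = models[0]
        warnings.warn(
            f"model {model} not found; using first model (id {chosen.id})",
            stacklevel=2,
        )
    elements, coords, radii = [], [], []
    unknown = set()
    for residue in chosen.get_residues():
        hetflag = residue.id[0].strip()
        if hetflag and not include_hetero:
            continue  # waters (W) and hetero-ligands (H_*)
        for atom in residue.get_atoms():
            el = (atom.element or "").strip().capitalize()
            if el not in VDW_RADII:
                unknown.add(el or "?")
                radius = VDW_FALLBACK
            else:
                radius = VDW_RADII[el]
            elements.append(el or "X")
            coords.append(atom.coord)
            radii.append(radius)
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}: using fallback radius "
            f"{VDW_FALLBACK} A", stacklevel=2,
        )
    if not coords:
        raise ValueError("no atoms selected from PDB content")
    return StructureCoords(
        elements=elements, coords=np.array(coords), radii=np.array(radii),
        model_id=model, source="pdb",
    )


# ---------------------------------------------------------------------------
# grid machinery
# ---------------------------------------------------------------------------

def _occupancy_grid(coords: StructureCoords, spacing: float, margin: float):
    """Boolean grid of points inside any vdW sphere, plus the grid origin."""
    lo = coords.coords.min(axis=0) - margin
    hi = coords.coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    for pos, rad in zip(coords.coords, coords.radii):
        r_vox = rad / spacing
        center = (pos - lo) / spacing
        lo_idx = np.maximum(np.floor(center - r_vox).astype(int), 0)
        hi_idx = np.minimum(np.ceil(center + r_vox).astype(int) + 1, shape)
        sl = tuple(slice(a, b) for a, b in zip(lo_idx, hi_idx))
        axes = [np.arange(a, b) for a, b in zip(lo_idx, hi_idx)]
        dist2 = (
            (axes[0][:, None, None] - center[0]) ** 2
            + (axes[1][None, :, None] - center[1]) ** 2
            + (axes[2][None, None, :] - center[2]) ** 2
        )
        occ[sl] |= dist2 <= r_vox**2
    return occ, lo


def _excluded_volume_mask(
    occ: np.ndarray, spacing: float, probe: float, from_outside: bool
) -> np.ndarray:
    """Excluded-volume mask for one probe radius.

    ``from_outside=True`` keeps only probe positions connected to the box
    boundary (rolling from solvent); otherwise any clash-free probe position
    counts as solvent.
    """
    dist_to_atoms = ndimage.distance_transform_edt(~occ, sampling=spacing)
    fit = dist_to_atoms >= probe
    if from_outside:
        labels, _ = ndimage.label(fit, structure=_SIX_CONN)
        boundary_labels = set()
        for axis in range(3):
            for idx in (0, -1):
                face = np.take(labels, idx, axis=axis)
                boundary_labels.update(np.unique(face[face > 0]).tolist())
        fit = np.isin(labels, sorted(boundary_labels))
    dist_to_fit = ndimage.distance_transform_edt(~fit, sampling=spacing)
    solvent = dist_to_fit <= probe
    return ~solvent


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def rolling_probe_volume(
    coords: StructureCoords,
    small_probe: float = PROBE_SMALL_DEFAULT,
    large_probe: float = PROBE_LARGE_DEFAULT,
    grid_spacing: float = GRID_SPACING_DEFAULT,
    keep_points: bool = False,
) -> CavityResult:
    """Cavity volume as the difference of large- and small-probe excluded
    volumes.

    Parameters follow the two-probe convention: the large probe defines the
    envelope by rolling from the outside, the small probe carves out every
    pocket it fits into.  Connected cavity components are reported
    individually (6-neighbourhood); components touching the box boundary are
    solvent and discarded.
    """
    if small_probe <= 0 or large_probe <= small_probe:
        raise ValueError("need 0 < small_probe < large_probe")
    if grid_spacing > small_probe / 2.0:
        raise ValueError(
            f"grid spacing {grid_spacing} A too coarse; must be <= "
            f"small_probe/2 = {small_probe / 2.0} A"
        )
    extent = coords.coords.max(axis=0) - coords.coords.min(axis=0)
    if np.all(extent + 2 * coords.radii.max() < 2 * large_probe):
        warnings.warn(
            "structure smaller than the large probe; cavity volume is zero",
            stacklevel=2,
        )
        return CavityResult(0.0, small_probe, large_probe, grid_spacing, [])

    margin = large_probe + float(coords.radii.max()) + 3.0 * grid_spacing
    occ, origin = _occupancy_grid(coords, grid_spacing, margin)
    excluded_large = _excluded_volume_mask(
        occ, grid_spacing, large_probe, from_outside=True
    )
    excluded_small = _excluded_volume_mask(
        occ, grid_spacing, small_probe, from_outside=False
    )
    cavity = excluded_large & ~excluded_small

    voxel = grid_spacing**3
    labels, n_comp = ndimage.label(cavity, structure=_SIX_CONN)
    comp_volumes = []
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        touches_boundary = (
            mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()
            or mask[:, :, 0].any() or mask[:, :, -1].any()
        )
        if touches_boundary:
            cavity[mask] = False
            continue
        comp_volumes.append(float(mask.sum() * voxel))
    comp_volumes.sort(reverse=True)
    points = None
    if keep_points:
        idx = np.argwhere(cavity)
        points = origin + idx * grid_spacing
    return CavityResult(
        cavity_volume=float(sum(comp_volumes)),
        small_probe=small_probe,
        large_probe=large_probe,
        grid_spacing=grid_spacing,
        component_volumes=comp_volumes,
        cavity_points=points,
    )
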