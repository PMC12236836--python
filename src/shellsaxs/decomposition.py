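"""Contrast decomposition into bare-protein and hydration-shell terms.

The forward scattering of a buffer-subtracted curve obeys I0 = (Delta Ne)^2,
where Delta Ne is the total solute-plus-shell contrast in electrons.  It
splits additively,

    Delta Ne = Delta Ne_prot + Delta Ne_hs,
    Delta Ne_prot = Ne_prot - rho_solv * V_prot,

with Ne_prot the protein electron count (sum of form factors at zero
angle), V_prot the solvent-excluded protein volume (rolling-probe, grid
based) and rho_solv the bulk solvent electron density at the given
temperature.  The shell term Delta Ne_hs is whatever the total contrast
carries beyond the bare protein; divided by 10 e per water it converts to a
water-molecule count.  The split depends on the V_prot convention only
through a temperature-independent constant, so temperature *trends* of
Delta Ne_hs are convention-free.

The hydration-shell size indicator Delta Rg = Rg - Rg_prot compares the
Guinier radius of gyration (which sees the shell) with the electron-
weighted Rg of the bare solute.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .model_io import ConfigurationEnsemble
from .synthetic import ELECTRONS_PER_WATER

__all__ = [
    "ContrastDecomposition",
    "TemperatureSeries",
    "protein_volume",
    "electron_count",
    "decompose_contrast",
    "waters_relative",
    "solute_rg",
    "delta_rg",
]


@dataclasses.dataclass
class ContrastDecomposition:
    """Contrast bookkeeping at one temperature (all electron units)."""

    T: float
    delta_Ne: float
    delta_Ne_prot: float
    delta_Ne_hs: float
    Ne_prot: float
    V_prot: float  # A^3
    rho_solv: float  # e/A^3

    def __post_init__(self) -> None:
        # additivity must hold to machine precision by construction
        assert abs(self.delta_Ne - (self.delta_Ne_prot + self.delta_Ne_hs)) <= 1e-9 * max(
            1.0, abs(self.delta_Ne)
        )


@dataclasses.dataclass
class TemperatureSeries:
    """Per-temperature results table with a designated reference row."""

    table: pd.DataFrame  # indexed by temperature
    T_ref: float

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate temperature rows")
        if self.T_ref not in self.table.index:
            raise ValueError(f"reference temperature {self.T_ref} K not in series")

    def to_tsv(self, path) -> None:
        df = self.table.reset_index()
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def protein_volume(
    solute: ConfigurationEnsemble,
    grid_spacing: float = 0.1,
    probe_radius: float = 1.4,
    frame: int = 0,
) -> float:
    """Solvent-excluded volume of the solute by rolling-probe grid closure.

    Voxels within (r_vdw + probe) of any atom form the probe-inflated
    region; eroding it back by the probe radius (Euclidean distance
    transform) leaves the volume a spherical probe of that radius cannot
    enter — vdW spheres plus re-entrant crevices.  With probe 0 this is the
    plain union of vdW spheres.  Returns voxel count x spacing^3 in A^3.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if probe_radius > 0 and grid_spacing > probe_radius:
        raise ValueError("grid too coarse: spacing must not exceed the probe radius")
    at = solute.atoms
    mask_solute = at.solute
    if not np.any(mask_solute):
        raise ValueError("no solute atoms")
    xyz = solute.frames[frame][mask_solute]
    vdw = at.vdw_radius[mask_solute]

    pad = float(np.max(vdw) + probe_radius + 2 * grid_spacing)
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    inflated = np.zeros(shape, dtype=bool)
    # mark voxels within (r_vdw + probe) of each atom on a local subgrid
    for pos, r in zip(xyz, vdw):
        reach = r + probe_radius
        ijk0 = np.floor((pos - reach - lo) / grid_spacing).astype(int)
        ijk1 = np.ceil((pos + reach - lo) / grid_spacing).astype(int) + 1
        ijk0 = np.maximum(ijk0, 0)
        ijk1 = np.minimum(ijk1, shape)
        axes = [
            lo[d] + grid_spacing * np.arange(ijk0[d], ijk1[d]) - pos[d]
            for d in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        inflated[ijk0[0]:ijk1[0], ijk0[1]:ijk1[1], ijk0[2]:ijk1[2]] |= d2 <= reach**2
    if probe_radius == 0:
        return float(inflated.sum()) * grid_spacing**3
    # erode by the probe: keep voxels deeper than probe_radius from the outside
    dist_in = ndimage.distance_transform_edt(inflated, sampling=grid_spacing)
    excluded = dist_in > probe_radius
    return float(excluded.sum()) * grid_spacing**3


def electron_count(solute: ConfigurationEnsemble) -> float:
    """Ne_prot: sum of solute form factors at zero scattering angle."""
    at = solute.atoms
    ne = float(at.electrons[at.solute].sum())
    if ne <= 0:
        raise ValueError("solute carries no electrons (DUMMY-only?)")
    return ne


def decompose_contrast(
    I0: float,
    Ne_prot: float,
    V_prot: float,
    rho_solv: float,
    T: float = 300.0,
) -> ContrastDecomposition:
    """Split the total contrast sqrt(I0) into protein and shell terms.

    ``rho_solv`` in e/A^3.  The positive square-root branch is taken, valid
    for electron-dense solutes in water; a warning is attached when the bare
    protein contrast is non-positive and the branch choice becomes ambiguous.
    """
    if I0 < 0:
        raise ValueError("I0 must be non-negative")
    delta_Ne = float(np.sqrt(I0))
    delta_Ne_prot = float(Ne_prot - rho_solv * V_prot)
    if delta_Ne_prot <= 0:
        import warnings

        warnings.warn(
            "bare-protein contrast <= 0: the positive sqrt branch of I0 may "
            "pick the wrong sign for Delta Ne"
        )
    return ContrastDecomposition(
        T=T,
        delta_Ne=delta_Ne,
        delta_Ne_prot=delta_Ne_prot,
        delta_Ne_hs=delta_Ne - delta_Ne_prot,
        Ne_prot=float(Ne_prot),
        V_prot=float(V_prot),
        rho_solv=float(rho_solv),
    )


def waters_relative(series: TemperatureSeries, T_ref: float | None = None) -> pd.Series:
    """Shell contrast change versus the reference, in water molecules.

    Delta N_water(T) = [Delta Ne_hs(T) - Delta Ne_hs(T_ref)] / 10 e; negative
    values mean the shell has lost water relative to the reference.
    """
    T_ref = series.T_ref if T_ref is None else T_ref
    if T_ref not in series.table.index:
        raise ValueError(f"reference temperature {T_ref} K not in series")
    hs = series.table["delta_Ne_hs"]
    return (hs - hs.loc[T_ref]) / ELECTRONS_PER_WATER


def solute_rg(solute: ConfigurationEnsemble, frame: int = 0) -> float:
    """Electron-weighted radius of gyration of the bare solute (A)."""
    at = solute.atoms
    mask = at.solute
    w = at.electrons[mask]
    if w.sum() <= 0:
        raise ValueError("solute carries no electrons")
    xyz = solute.frames[frame][mask]
    com = np.average(xyz, axis=0, weights=w)
    r2 = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt(np.average(r2, weights=w)))


def delta_rg(guinier_Rg: float, solute: ConfigurationEnsemble, frame: int = 0) -> float:
    """Delta Rg = Rg(Guinier, with shell) - Rg_prot(bare solute)."""
    return float(guinier_Rg) - solute_rg(solute, frame)
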