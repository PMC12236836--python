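"""Spatial and energetic diagnostics of the hydration shell.

Covers: 3D solvent electron-density grids and difference maps (written as
OpenDX scalar fields for molecular viewers), 1D density as a function of
distance from the solute van der Waals surface, water-water radial
distribution functions restricted to shell-selected oxygens, geometric
hydrogen-bond counting (donor-acceptor distance <= 3.5 A and
H-donor-acceptor angle <= 30 deg, the standard criterion of trajectory
analysis tools), and pairwise protein-water Lennard-Jones plus short-range
Coulomb interaction energies.

All analyses assume the envelope/shell regions lie wholly inside the
primary box; no minimum-image convention is applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import surface_distance
from .model_io import ConfigurationEnsemble

__all__ = [
    "DensityGrid",
    "RadialProfile",
    "density_grid",
    "grid_difference",
    "write_dx",
    "read_dx",
    "distance_profile",
    "shell_rdf",
    "count_hbonds",
    "interaction_energy",
    "NonbondedParams",
]

#: Coulomb constant in kJ/mol * nm / e^2 (MD convention)
KE_KJ_MOL_NM = 138.935458


@dataclasses.dataclass
class DensityGrid:
    """Frame-averaged scalar field on a regular grid (electron density, e/A^3)."""

    origin: np.ndarray  # (3,) A, position of voxel (0,0,0) corner
    spacing: float  # A
    data: np.ndarray  # (nx, ny, nz)
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.data = np.asarray(self.data, dtype=float)

    def same_geometry(self, other: "DensityGrid") -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin)
        )


@dataclasses.dataclass
class RadialProfile:
    """Binned radial quantity: density (e/A^3) or g(r) (dimensionless)."""

    edges: np.ndarray  # (n_bins + 1,) A
    values: np.ndarray  # (n_bins,), NaN where the stratum volume vanishes
    counts: np.ndarray  # raw per-bin counts (electrons or pairs)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def density_grid(
    ensemble: ConfigurationEnsemble,
    spacing: float = 0.5,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    solvent_only: bool = True,
) -> DensityGrid:
    """Frame-averaged electron density on a regular grid.

    Atom electrons are deposited to the voxel containing the atom
    (nearest-voxel binning), averaged over frames, and divided by the voxel
    volume.  The grid defaults to covering the whole box.  Frames must be
    aligned (the rigid-solute generator contract).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(np.ceil((ensemble.box - origin) / spacing).astype(int))
    at = ensemble.atoms
    sel = ~at.solute if solvent_only else np.ones(len(at), dtype=bool)
    electrons = at.electrons[sel]
    grid = np.zeros(shape)
    for t in range(ensemble.n_frames):
        ijk = np.floor((ensemble.frames[t][sel] - origin) / spacing).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
        np.add.at(grid, tuple(ijk[ok].T), electrons[ok])
    grid /= ensemble.n_frames * spacing**3
    return DensityGrid(origin=origin, spacing=spacing, data=grid, n_frames=ensemble.n_frames)


def grid_difference(grid_T: DensityGrid, grid_ref: DensityGrid) -> DensityGrid:
    """Pointwise difference map (may be negative); geometries must match."""
    if not grid_T.same_geometry(grid_ref):
        raise ValueError("grid geometries differ; difference maps need matched grids")
    return DensityGrid(
        origin=grid_T.origin.copy(),
        spacing=grid_T.spacing,
        data=grid_T.data - grid_ref.data,
        n_frames=min(grid_T.n_frames, grid_ref.n_frames),
    )


def write_dx(grid: DensityGrid, path: str | Path, comment: str = "") -> None:
    """Write the grid as an OpenDX scalar field (plain text)."""
    nx, ny, nz = grid.data.shape
    d = grid.spacing
    lines = [f"# shellsaxs electron density grid (e/A^3) {comment}".rstrip()]
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6f} {:.6f} {:.6f}".format(*grid.origin))
    lines.append(f"delta {d:.6f} 0 0")
    lines.append(f"delta 0 {d:.6f} 0")
    lines.append(f"delta 0 0 {d:.6f}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"
    )
    flat = grid.data.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`write_dx`."""
    counts = None
    origin = None
    deltas = []
    values: list[float] = []
    in_data = False
    n_items = 0
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("object") and "gridpositions" in s:
            counts = tuple(int(x) for x in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(x) for x in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append([float(x) for x in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split()[-3])
            in_data = True
        elif in_data and len(values) < n_items:
            values.extend(float(x) for x in s.split())
        elif s.startswith(("attribute", "object")):
            in_data = False
    if counts is None or origin is None or len(values) < n_items:
        raise ValueError(f"{path}: not a parseable OpenDX scalar field")
    spacing = float(deltas[0][0])
    data = np.array(values[:n_items]).reshape(counts, order="C")
    return DensityGrid(origin=origin, spacing=spacing, data=data)


def distance_profile(
    ensemble: ConfigurationEnsemble,
    solute: ConfigurationEnsemble | None = None,
    bin_width: float = 0.1,
    r_max: float = 12.0,
    n_mc: int = 200_000,
    seed: int = 0,
) -> RadialProfile:
    """Solvent electron density versus distance from the solute vdW surface.

    Solvent-atom electrons are binned by d = min_j(|r - r_j| - r_vdw,j) and
    each bin is normalised by the Monte-Carlo volume of its distance stratum
    within the box.  Bins whose stratum volume estimate is zero are NaN
    (geometrically unreachable), not zero density.
    """
    src = solute if solute is not None else ensemble
    at_s = src.atoms
    if not np.any(at_s.solute):
        raise ValueError("no solute atoms for the vdW surface")
    sol_xyz = src.frames[0][at_s.solute]
    sol_vdw = at_s.vdw_radius[at_s.solute]

    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    electron_sum = np.zeros(n_bins)
    at = ensemble.atoms
    solvent = ~at.solute
    electrons = at.electrons[solvent]
    for t in range(ensemble.n_frames):
        d = surface_distance(ensemble.frames[t][solvent], sol_xyz, sol_vdw)
        ok = (d >= 0) & (d < r_max)
        idx = np.minimum((d[ok] / bin_width).astype(int), n_bins - 1)
        np.add.at(electron_sum, idx, electrons[ok])
    electron_sum /= ensemble.n_frames

    rng = np.random.default_rng(seed)
    pts = rng.random((n_mc, 3)) * ensemble.box
    d_mc = surface_distance(pts, sol_xyz, sol_vdw)
    ok = (d_mc >= 0) & (d_mc < r_max)
    hist, _ = np.histogram(d_mc[ok], bins=edges)
    stratum_vol = hist / n_mc * float(np.prod(ensemble.box))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(stratum_vol > 0, electron_sum / stratum_vol, np.nan)
    return RadialProfile(edges=edges, values=values, counts=electron_sum)


def _select_shell_oxygens(
    frame_xyz: np.ndarray,
    atoms,
    sol_xyz: np.ndarray,
    sol_vdw: np.ndarray,
    shell_max: float,
) -> np.ndarray:
    """Water-oxygen coordinates with 0 <= d(vdW surface) <= shell_max."""
    is_o = (~atoms.solute) & (atoms.elements == "O")
    xyz = frame_xyz[is_o]
    if len(xyz) == 0:
        return xyz
    d = surface_distance(xyz, sol_xyz, sol_vdw)
    return xyz[(d >= 0) & (d <= shell_max)]


def shell_rdf(
    ensemble: ConfigurationEnsemble,
    solute: ConfigurationEnsemble | None = None,
    shell_max: float = 7.0,
    dr: float = 0.1,
    r_max: float = 10.0,
    n_mc: int = 30_000,
    seed: int = 0,
) -> RadialProfile:
    """g(r) between water oxygens selected within a shell of the solute.

    Oxygens with vdW-surface distance in [0, shell_max] are selected per
    frame.  Normalisation uses ideal-gas pair counts obtained by Monte-Carlo
    sampling of the *selected shell geometry* (not the whole box): uniform
    points in the shell region provide the pair-distance distribution an
    uncorrelated fluid with the same boundaries would show.
    """
    if shell_max <= 0:
        raise ValueError("shell_max must be positive")
    src = solute if solute is not None else ensemble
    at_s = src.atoms
    if not np.any(at_s.solute):
        raise ValueError("no solute atoms")
    sol_xyz = src.frames[0][at_s.solute]
    sol_vdw = at_s.vdw_radius[at_s.solute]

    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    pair_hist = np.zeros(n_bins)
    total_pairs = 0.0
    any_selected = False
    for t in range(ensemble.n_frames):
        sel = _select_shell_oxygens(
            ensemble.frames[t], ensemble.atoms, sol_xyz, sol_vdw, shell_max
        )
        n = len(sel)
        if n < 2:
            continue
        any_selected = True
        tree = cKDTree(sel)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs):
            dists = np.linalg.norm(sel[pairs[:, 0]] - sel[pairs[:, 1]], axis=1)
            h, _ = np.histogram(dists, bins=edges)
            pair_hist += h
        total_pairs += n * (n - 1) / 2.0
    if not any_selected:
        raise ValueError("fewer than 2 shell oxygens in every frame")

    # ideal-gas reference: uniform points in the same shell region
    rng = np.random.default_rng(seed)
    shell_pts = []
    target = n_mc
    lo = np.maximum(sol_xyz.min(axis=0) - np.max(sol_vdw) - shell_max, 0.0)
    hi = np.minimum(sol_xyz.max(axis=0) + np.max(sol_vdw) + shell_max, ensemble.box)
    while sum(len(p) for p in shell_pts) < target:
        cand = lo + rng.random((target, 3)) * (hi - lo)
        d = surface_distance(cand, sol_xyz, sol_vdw)
        shell_pts.append(cand[(d >= 0) & (d <= shell_max)])
    pts = np.concatenate(shell_pts)[:target]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    dists = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    ref_hist, _ = np.histogram(dists, bins=edges)
    n_ref_pairs = len(pts) * (len(pts) - 1) / 2.0
    p_ref = ref_hist / n_ref_pairs  # P(pair distance in bin | uniform shell)

    expected = total_pairs * p_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, pair_hist / expected, np.nan)
    return RadialProfile(edges=edges, values=g, counts=pair_hist)


def _water_topology(atoms) -> tuple[np.ndarray, np.ndarray]:
    """(oxygen indices, hydrogen indices grouped (n_waters, 2)) of solvent waters."""
    solvent = ~atoms.solute
    o_idx = np.flatnonzero(solvent & (atoms.elements == "O"))
    h_by_mol: dict[int, list[int]] = {}
    for j in np.flatnonzero(solvent & (atoms.elements == "H")):
        h_by_mol.setdefault(int(atoms.mol_id[j]), []).append(j)
    h_idx = np.array([h_by_mol.get(int(atoms.mol_id[o]), [-1, -1])[:2] for o in o_idx])
    return o_idx, h_idx


def count_hbonds(
    ensemble: ConfigurationEnsemble,
    r_cut: float = 3.5,
    angle_cut: float = 30.0,
    selection: str = "water-water",
    surface_max: float | None = None,
    solute: ConfigurationEnsemble | None = None,
) -> tuple[float, float]:
    """Mean geometric hydrogen-bond count per frame, with standard error.

    A bond exists when the donor-acceptor oxygen distance is <= ``r_cut``
    and the H-donor-acceptor angle is <= ``angle_cut`` degrees.  Selections:
    ``water-water`` (optionally restricted to waters whose oxygen lies
    within ``surface_max`` of the solute vdW surface) or ``protein-water``
    (donor water, acceptor any solute N/O atom, and vice versa via water
    acceptors of solute-bound hydrogens is not modelled — solute hydrogens
    are included as donors when present).
    """
    at = ensemble.atoms
    o_idx, h_idx = _water_topology(at)
    if len(o_idx) == 0:
        raise ValueError("no water molecules in ensemble")
    if np.any(h_idx < 0):
        raise ValueError("water hydrogens missing; cannot evaluate donors")
    cos_cut = np.cos(np.deg2rad(angle_cut))

    if selection not in {"water-water", "protein-water"}:
        raise ValueError(f"unknown selection {selection!r}")
    src = solute if solute is not None else ensemble
    need_surface = surface_max is not None or selection == "protein-water"
    if need_surface and not np.any(src.atoms.solute):
        raise ValueError("selection requires solute atoms")

    counts = []
    for t in range(ensemble.n_frames):
        xyz = ensemble.frames[t]
        o_pos = xyz[o_idx]
        keep = np.ones(len(o_idx), dtype=bool)
        if surface_max is not None:
            sol_xyz = src.frames[0][src.atoms.solute]
            sol_vdw = src.atoms.vdw_radius[src.atoms.solute]
            d = surface_distance(o_pos, sol_xyz, sol_vdw)
            keep = d <= surface_max
        n_bonds = 0
        if selection == "water-water":
            sel_o = np.flatnonzero(keep)
            if len(sel_o) >= 2:
                tree = cKDTree(o_pos[sel_o])
                pairs = tree.query_pairs(r_cut, output_type="ndarray")
                for a, b in pairs:
                    i, j = sel_o[a], sel_o[b]
                    n_bonds += _pair_hbond(xyz, o_idx, h_idx, i, j, cos_cut)
                    n_bonds += _pair_hbond(xyz, o_idx, h_idx, j, i, cos_cut)
        else:  # protein-water
            sol_mask = ensemble.atoms.solute
            acc_mask = sol_mask & np.isin(at.elements, ["N", "O"])
            acc_pos = xyz[acc_mask]
            if len(acc_pos) == 0:
                raise ValueError("no solute N/O acceptors")
            tree = cKDTree(acc_pos)
            # water donors to solute acceptors
            near = tree.query_ball_point(o_pos, r_cut)
            for wi, neigh in enumerate(near):
                if not neigh:
                    continue
                d_pos = o_pos[wi]
                for h in h_idx[wi]:
                    hv = xyz[h] - d_pos
                    hv /= np.linalg.norm(hv)
                    for aj in neigh:
                        av = acc_pos[aj] - d_pos
                        r = np.linalg.norm(av)
                        if r < 1e-6:
                            continue
                        if hv @ (av / r) >= cos_cut:
                            n_bonds += 1
        counts.append(n_bonds)
    counts = np.asarray(counts, dtype=float)
    se = counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else 0.0
    return float(counts.mean()), float(se)


def _pair_hbond(xyz, o_idx, h_idx, donor_i, acceptor_j, cos_cut) -> int:
    """1 if water ``donor_i`` donates an H-bond to water ``acceptor_j``."""
    d_pos = xyz[o_idx[donor_i]]
    a_vec = xyz[o_idx[acceptor_j]] - d_pos
    r = np.linalg.norm(a_vec)
    if r < 1e-6:
        return 0
    a_vec = a_vec / r
    for h in h_idx[donor_i]:
        hv = xyz[h] - d_pos
        hv = hv / np.linalg.norm(hv)
        if hv @ a_vec >= cos_cut:
            return 1
    return 0


@dataclasses.dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters aligned with an ensemble's atom order."""

    charge: np.ndarray  # e
    sigma: np.ndarray  # A
    epsilon: np.ndarray  # kJ/mol

    def __post_init__(self) -> None:
        n = len(self.charge)
        if len(self.sigma) != n or len(self.epsilon) != n:
            raise ValueError("parameter arrays must have equal length")


def interaction_energy(
    ensemble: ConfigurationEnsemble,
    params: NonbondedParams,
    cutoff: float = 10.0,
) -> tuple[float, float]:
    """Mean protein-water (E_LJ, E_Coulomb) per frame in kJ/mol.

    Pairwise sums over solute-solvent pairs within ``cutoff`` (A):
    LJ 4 eps [ (sigma/r)^12 - (sigma/r)^6 ] with Lorentz-Berthelot
    combination (arithmetic sigma, geometric epsilon) and Coulomb
    k_e q_i q_j / r with k_e = 138.935458 kJ/mol nm e^-2.  No mesh or
    long-range correction — short-range terms only.
    """
    at = ensemble.atoms
    if len(params.charge) != len(at):
        raise ValueError(
            f"parameter table covers {len(params.charge)} atoms, ensemble has {len(at)}"
        )
    sol = np.flatnonzero(at.solute)
    wat = np.flatnonzero(~at.solute)
    if len(sol) == 0 or len(wat) == 0:
        raise ValueError("need both solute and solvent atoms")
    e_lj_frames = []
    e_coul_frames = []
    for t in range(ensemble.frames.shape[0]):
        xyz = ensemble.frames[t]
        tree_w = cKDTree(xyz[wat])
        e_lj = 0.0
        e_coul = 0.0
        for i in sol:
            neigh = tree_w.query_ball_point(xyz[i], cutoff)
            if not neigh:
                continue
            j = wat[np.asarray(neigh)]
            r = np.linalg.norm(xyz[j] - xyz[i], axis=1)
            ok = r > 1e-6
            j, r = j[ok], r[ok]
            sig = 0.5 * (params.sigma[i] + params.sigma[j])
            eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
            sr6 = (sig / r) ** 6
            e_lj += float(np.sum(4.0 * eps * (sr6**2 - sr6)))
            # r in A -> nm for the MD-convention Coulomb constant
            e_coul += float(
                np.sum(KE_KJ_MOL_NM * params.charge[i] * params.charge[j] / (r / 10.0))
            )
        e_lj_frames.append(e_lj)
        e_coul_frames.append(e_coul)
    return float(np.mean(e_lj_frames)), float(np.mean(e_coul_frames))
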