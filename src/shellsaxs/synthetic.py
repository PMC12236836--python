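"""Synthetic solute+solvent ensembles with a controllable hydration shell.

This module stands in for restrained-protein MD output so that the whole
SAXS / Guinier / contrast-decomposition pipeline can be validated against
known ground truth.  Solvent frames are independent ideal-gas-like draws of
rigid 3-site waters at bulk number density rho_bulk/10 per A^3 (10
electrons per water), boosted by a factor (1 + epsilon) inside the
first-shell region — within ``shell_width`` of the solute van der Waals
surface — and excluded inside the solute.  Each frame carries a fixed water
count matched to the integral of that shaped density (canonical-ensemble
boxes, as restrained NVT/NPT simulations provide), so sample and buffer
share identical bulk statistics; positions within a frame are independent
draws, making sub-region occupancies Poisson-like.  The imposed shell
excess in electrons is

    N_excess = epsilon * rho_bulk * V_shell,

with V_shell estimated by Monte Carlo, which downstream contrast
decomposition must recover.  Matched pure-solvent (buffer) boxes use the
same statistics with no solute and no shell.  Everything is deterministic
for a fixed seed.

Water-water correlations of real water (oxygen-oxygen RDF structure,
hydrogen-bond networks) are deliberately absent except for an optional
minimum O-O exclusion distance; the generator validates contrast and size
bookkeeping, not liquid structure.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import surface_distance
from .model_io import DUMMY, Atoms, BONDI_RADII, ConfigurationEnsemble, FORM_FACTORS

__all__ = [
    "ShellSpec",
    "ELECTRONS_PER_WATER",
    "make_toy_solute",
    "make_solvated_system",
    "make_uniform_sphere",
    "make_hbond_fixture",
    "shell_volume_mc",
    "epsilon_of_temperature",
]

#: electrons in one H2O molecule (exact)
ELECTRONS_PER_WATER = 10.0

# rigid 3-site water geometry (gas-phase-like, standard for simple models)
_OH_BOND = 0.9572  # Angstrom
_HOH_ANGLE = np.deg2rad(104.52)
_OM_DIST = 0.15  # optional virtual-site offset along the HOH bisector


@dataclasses.dataclass
class ShellSpec:
    """Hydration-shell perturbation parameters.

    epsilon : fractional first-shell density excess (e.g. +0.06 = 6% denser).
    shell_width : radial extent of the perturbed shell from the vdW surface (A).
    rho_bulk : bulk solvent electron density (e/A^3); waters are placed at
        number density rho_bulk / 10.
    seed : RNG seed for all placement randomness.
    """

    epsilon: float = 0.0
    shell_width: float = 3.0
    rho_bulk: float = 0.334
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_width <= 0:
            raise ValueError("shell_width must be positive")
        if self.rho_bulk <= 0:
            raise ValueError("rho_bulk must be positive")
        if 1.0 + self.epsilon <= 0:
            raise ValueError("1 + epsilon must be positive")


def epsilon_of_temperature(
    T: float, T_ref: float = 300.0, slope: float = 0.002
) -> float:
    """Temperature-like shell perturbation: linear, zero at T_ref.

    Positive slope makes the shell deplete on heating (epsilon < 0 for
    T > T_ref), mirroring the experimentally observed loss of shell water.
    """
    return slope * (T_ref - T)


def make_toy_solute(
    n_atoms: int,
    radius: float,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    temperature: float = 300.0,
) -> ConfigurationEnsemble:
    """Quasi-uniform random packing of atoms in a ball: a protein stand-in.

    ``composition`` maps element symbols to relative frequencies (default all
    carbon).  Atom counts per element are largest-remainder rounded so they
    sum to ``n_atoms`` exactly.  Coordinates are centred on the origin and
    deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    composition = composition or {"C": 1.0}
    rng = np.random.default_rng(seed)
    # uniform in ball via radius ~ U^(1/3)
    u = rng.random(n_atoms)
    r = radius * np.cbrt(u)
    v = rng.normal(size=(n_atoms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    xyz = r[:, None] * v
    xyz -= xyz.mean(axis=0)
    max_norm = np.max(np.linalg.norm(xyz, axis=1))
    if max_norm > radius:  # recentring can push points just past the ball
        xyz *= radius / max_norm

    total = sum(composition.values())
    quotas = {el: n_atoms * w / total for el, w in composition.items()}
    counts = {el: int(np.floor(q)) for el, q in quotas.items()}
    remainder = n_atoms - sum(counts.values())
    for el, _ in sorted(
        quotas.items(), key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True
    )[:remainder]:
        counts[el] += 1
    elements = [el for el, c in counts.items() for _ in range(c)]
    atoms = Atoms.from_lists(
        names=[f"{el}{i + 1}" for i, el in enumerate(elements)],
        elements=elements,
        solute=[True] * n_atoms,
        residues=["MOL"] * n_atoms,
    )
    box = np.full(3, 2 * radius + 10.0)
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=xyz[None, :, :],
        box=box,
        temperature=temperature,
        label=f"toy-solute-n{n_atoms}",
    )


def _water_sites(o_xyz: np.ndarray, rng: np.random.Generator, virtual_site: bool):
    """Rigid-water H (and optional virtual) site positions for given oxygens."""
    n = len(o_xyz)
    # random orthonormal frames via QR of Gaussian matrices
    m = rng.normal(size=(n, 3, 3))
    q, _ = np.linalg.qr(m)
    half = _HOH_ANGLE / 2.0
    local_h1 = _OH_BOND * np.array([np.sin(half), 0.0, np.cos(half)])
    local_h2 = _OH_BOND * np.array([-np.sin(half), 0.0, np.cos(half)])
    h1 = o_xyz + np.einsum("nij,j->ni", q, local_h1)
    h2 = o_xyz + np.einsum("nij,j->ni", q, local_h2)
    sites = [o_xyz, h1, h2]
    if virtual_site:
        local_m = _OM_DIST * np.array([0.0, 0.0, 1.0])
        sites.append(o_xyz + np.einsum("nij,j->ni", q, local_m))
    return sites


def _acceptance_probability(
    cand: np.ndarray,
    solute_xyz: np.ndarray | None,
    solute_vdw: np.ndarray | None,
    shell_width: float,
    epsilon: float,
) -> np.ndarray:
    """Relative acceptance density (normalised to max 1) at candidate points."""
    if solute_xyz is None:
        return np.ones(len(cand))
    boost = max(1.0, 1.0 + epsilon)
    d = surface_distance(cand, solute_xyz, solute_vdw)
    p = np.where(d <= shell_width, (1.0 + epsilon) / boost, 1.0 / boost)
    p[d < 0] = 0.0  # inside the solute vdW region
    return p


def _place_oxygens(
    rng: np.random.Generator,
    box: np.ndarray,
    n_target: int,
    solute_xyz: np.ndarray | None,
    solute_vdw: np.ndarray | None,
    shell_width: float,
    epsilon: float,
    min_oo_distance: float | None,
) -> np.ndarray:
    """Exactly ``n_target`` oxygen positions drawn from the shaped density.

    Rejection sampling from the piecewise-constant density (zero inside the
    solute vdW region, boosted by 1+epsilon in the shell, bulk elsewhere);
    conditioning on the frame total emulates a canonical-ensemble (fixed-N)
    solvent box.  With ``min_oo_distance`` candidates too close to an
    already-accepted oxygen are discarded (hard-core packing).
    """
    accepted: list[np.ndarray] = []
    n_have = 0
    for _ in range(500):
        if n_have >= n_target:
            break
        batch = max(1024, 2 * (n_target - n_have))
        cand = rng.random((batch, 3)) * box
        p = _acceptance_probability(cand, solute_xyz, solute_vdw, shell_width, epsilon)
        keep = cand[rng.random(batch) < p]
        if min_oo_distance is not None and len(keep):
            from scipy.spatial import cKDTree

            pool = np.vstack(accepted) if accepted else np.empty((0, 3))
            if len(pool):
                d, _ = cKDTree(pool).query(keep, k=1)
                keep = keep[d >= min_oo_distance]
            if len(keep) > 1:  # greedy within-batch thinning
                mask = np.ones(len(keep), dtype=bool)
                for i, j in sorted(cKDTree(keep).query_pairs(min_oo_distance)):
                    if mask[i] and mask[j]:
                        mask[j] = False
                keep = keep[mask]
        accepted.append(keep)
        n_have += len(keep)
    else:
        raise ValueError("could not place the requested number of waters")
    return np.concatenate(accepted)[:n_target]


def make_solvated_system(
    solute: ConfigurationEnsemble,
    box: np.ndarray | tuple[float, float, float],
    shell: ShellSpec,
    n_frames: int,
    n_waters_per_frame: int | None = None,
    virtual_site: bool = False,
    min_oo_distance: float | None = None,
    margin: float = 0.0,
) -> tuple[ConfigurationEnsemble, ConfigurationEnsemble]:
    """Build matched (sample, buffer) ensembles around a rigid solute.

    The solute (frame 0 of ``solute``) is centred in the box and held fixed
    in every frame; waters are redrawn independently per frame.  If
    ``n_waters_per_frame`` is given, the bulk density is derived from it
    (10 e per water over the box volume), overriding ``shell.rho_bulk``.
    ``margin`` asserts that solute + shell + margin fit inside the box.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be 3 positive edge lengths")
    sol_at = solute.atoms
    if not np.any(sol_at.solute):
        raise ValueError("solute ensemble has no solute-flagged atoms")
    sol_xyz = solute.solute_coordinates(frame=0)
    sol_xyz = sol_xyz - sol_xyz.mean(axis=0) + box / 2.0
    sol_vdw = sol_at.vdw_radius[sol_at.solute]
    extent = np.max(np.abs(sol_xyz - box / 2.0)) + np.max(sol_vdw)
    if extent + shell.shell_width + margin > np.min(box) / 2.0:
        raise ValueError(
            f"box too small: solute extent {extent:.1f} A + shell "
            f"{shell.shell_width:.1f} A + margin {margin:.1f} A exceeds "
            f"half the smallest box edge {np.min(box) / 2.0:.1f} A"
        )
    rho_bulk = shell.rho_bulk
    if n_waters_per_frame is not None:
        rho_bulk = ELECTRONS_PER_WATER * n_waters_per_frame / float(np.prod(box))
    rho_number = rho_bulk / ELECTRONS_PER_WATER
    v_box = float(np.prod(box))

    # fixed per-frame totals matched to the shaped density's own integral
    # (canonical-ensemble-like solvent boxes, as restrained MD provides);
    # the excluded and shell volumes are estimated by seeded Monte Carlo
    rng_geom = np.random.default_rng(shell.seed + 777_001)
    pts = rng_geom.random((200_000, 3)) * box
    d = surface_distance(pts, sol_xyz, sol_vdw)
    v_excl = v_box * float(np.mean(d < 0))
    v_shell = v_box * float(np.mean((d >= 0) & (d <= shell.shell_width)))
    n_sample = int(round(rho_number * (v_box - v_excl + shell.epsilon * v_shell)))
    n_buffer = int(round(rho_number * v_box))
    if n_sample < 1 or n_buffer < 1:
        raise ValueError("no waters placed; box or density too small")

    rng_sample = np.random.default_rng(shell.seed)
    rng_buffer = np.random.default_rng(shell.seed + 1_000_003)

    sample = _assemble(
        rng_sample, box, n_sample, sol_xyz, sol_vdw, shell, n_frames,
        solute, virtual_site, min_oo_distance,
    )
    buffer = _assemble(
        rng_buffer, box, n_buffer, None, None, shell, n_frames,
        None, virtual_site, min_oo_distance,
    )
    sample.temperature = buffer.temperature = solute.temperature
    sample.label = f"{solute.label}:solvated"
    buffer.label = "buffer"
    return sample, buffer


def _assemble(
    rng, box, n_waters, sol_xyz, sol_vdw, shell, n_frames,
    solute, virtual_site, min_oo_distance,
) -> ConfigurationEnsemble:
    per_water = 4 if virtual_site else 3
    frames_waters = []
    for _ in range(n_frames):
        o_xyz = _place_oxygens(
            rng, box, n_waters, sol_xyz, sol_vdw,
            shell.shell_width, shell.epsilon, min_oo_distance,
        )
        sites = _water_sites(o_xyz, rng, virtual_site)
        frames_waters.append(np.stack(sites, axis=1).reshape(-1, 3))

    names = ["OW", "HW1", "HW2"] + (["MW"] if virtual_site else [])
    elements = ["O", "H", "H"] + ([DUMMY] if virtual_site else [])
    wat_names = names * n_waters
    wat_elements = elements * n_waters
    wat_mol = np.repeat(np.arange(n_waters), per_water)

    if solute is not None:
        sol_at = solute.atoms
        n_sol = len(sol_at)
        all_names = list(sol_at.names) + wat_names
        all_elements = list(sol_at.elements) + wat_elements
        all_solute = [True] * n_sol + [False] * (n_waters * per_water)
        all_mol = np.concatenate([sol_at.mol_id, wat_mol + sol_at.mol_id.max() + 1])
        all_res = list(
            sol_at.residues if sol_at.residues is not None else ["MOL"] * n_sol
        ) + ["SOL"] * (n_waters * per_water)
        frames = np.array(
            [np.vstack([sol_xyz, fw]) for fw in frames_waters], dtype=float
        )
    else:
        all_names = wat_names
        all_elements = wat_elements
        all_solute = [False] * (n_waters * per_water)
        all_mol = wat_mol
        all_res = ["SOL"] * (n_waters * per_water)
        frames = np.array(frames_waters, dtype=float)

    atoms = Atoms.from_lists(
        names=all_names, elements=all_elements, solute=all_solute,
        mol_id=all_mol, residues=all_res,
    )
    return ConfigurationEnsemble(
        atoms=atoms, frames=frames, box=box.copy(), temperature=300.0, label=""
    )


def make_uniform_sphere(
    R: float,
    n_points: int,
    electrons_per_point: float = 1.0,
    seed: int = 0,
    n_frames: int = 1,
) -> ConfigurationEnsemble:
    """Point scatterers uniform in a ball: the analytic SAXS/Guinier fixture.

    Each point carries a constant (q-independent) form factor of
    ``electrons_per_point``, tagged with the pseudo-element ``POINT`` which
    scattering code treats as flat.  The analytic references are
    Rg = sqrt(3/5) R and the sphere form factor
    [3 (sin qR - qR cos qR) / (qR)^3]^2.
    """
    if n_points < 10:
        raise ValueError("need at least 10 points")
    if R <= 0:
        raise ValueError("R must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        r = R * np.cbrt(rng.random(n_points))
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frames.append(r[:, None] * v)
    atoms = Atoms(
        names=np.array([f"P{i}" for i in range(n_points)], dtype=object),
        elements=np.array(["POINT"] * n_points, dtype=object),
        electrons=np.full(n_points, float(electrons_per_point)),
        vdw_radius=np.full(n_points, 1.0),
        solute=np.ones(n_points, dtype=bool),
        mol_id=np.arange(n_points),
        residues=np.array(["SPH"] * n_points, dtype=object),
    )
    box = np.full(3, 4 * R + 20.0)
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=np.asarray(frames) + box / 2.0,
        box=box,
        temperature=300.0,
        label=f"uniform-sphere-R{R:g}",
    )


def make_hbond_fixture(d_OO: float, angle_deg: float) -> ConfigurationEnsemble:
    """Two rigid waters with a prescribed O-O distance and donor angle.

    The first water donates: its H1 points along +x; the acceptor oxygen sits
    at distance ``d_OO`` in a direction making ``angle_deg`` with the O-H1
    bond, so the hydrogen-bond angle criterion (H-donor-acceptor angle) sees
    exactly ``angle_deg``.
    """
    if d_OO <= 0:
        raise ValueError("d_OO must be positive")
    theta = np.deg2rad(angle_deg)
    o1 = np.zeros(3)
    h1 = np.array([_OH_BOND, 0.0, 0.0])
    h2 = np.array(
        [_OH_BOND * np.cos(_HOH_ANGLE), _OH_BOND * np.sin(_HOH_ANGLE), 0.0]
    )
    o2 = d_OO * np.array([np.cos(theta), 0.0, np.sin(theta)])
    # acceptor H atoms point away from the donor
    away = np.array([1.0, 0.0, 0.0])
    h3 = o2 + _OH_BOND * (away * np.cos(np.pi / 3) + np.array([0, 1, 0]) * np.sin(np.pi / 3))
    h4 = o2 + _OH_BOND * (away * np.cos(np.pi / 3) - np.array([0, 1, 0]) * np.sin(np.pi / 3))
    xyz = np.vstack([o1, h1, h2, o2, h3, h4])
    center_shift = 25.0 - xyz.mean(axis=0)
    xyz = xyz + center_shift
    atoms = Atoms.from_lists(
        names=["OW", "HW1", "HW2", "OW", "HW1", "HW2"],
        elements=["O", "H", "H", "O", "H", "H"],
        solute=[False] * 6,
        mol_id=[0, 0, 0, 1, 1, 1],
        residues=["SOL"] * 6,
    )
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=xyz[None, :, :],
        box=np.full(3, 50.0),
        temperature=300.0,
        label=f"hbond-fixture-d{d_OO:g}-a{angle_deg:g}",
    )


def shell_volume_mc(
    solute: ConfigurationEnsemble,
    shell_width: float,
    box: np.ndarray,
    n_mc: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo volume of the shell region 0 <= d(vdW surface) <= width.

    Returns (volume, standard error) in A^3; sampling is over the full box
    with the solute centred, matching the generator's placement geometry.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    sol_at = solute.atoms
    sol_xyz = solute.solute_coordinates(frame=0)
    sol_xyz = sol_xyz - sol_xyz.mean(axis=0) + box / 2.0
    sol_vdw = sol_at.vdw_radius[sol_at.solute]
    pts = rng.random((n_mc, 3)) * box
    d = surface_distance(pts, sol_xyz, sol_vdw)
    inside = (d >= 0) & (d <= shell_width)
    frac = inside.mean()
    volume = float(np.prod(box))
    se = volume * np.sqrt(max(frac * (1 - frac), 1e-300) / n_mc)
    return volume * frac, se
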