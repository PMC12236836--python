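"""Atomistic configuration I/O, element inference, and atomic form factors.

The central container is :class:`ConfigurationEnsemble`: a set of frames of
identical atom content in an orthorhombic periodic box at a stated
temperature.  Atom metadata (element, electron count, van der Waals radius,
solute/solvent flag, molecule id) is shared across frames.

Atomic X-ray form factors use the four-Gaussian Cromer-Mann parametrisation

    f(q) = sum_i a_i * exp(-b_i * (q / 4 pi)^2) + c

with coefficients from the International Tables for Crystallography Vol. C
(as tabulated by gemmi).  The momentum-transfer convention is
q = 4 pi sin(theta) / lambda, so f(0) equals the atomic electron number Z.
Massless virtual sites (e.g. the charge site of 4-site water models) carry
the pseudo-element ``DUMMY`` with zero electrons and do not scatter.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "DUMMY",
    "Atoms",
    "ConfigurationEnsemble",
    "FormFactorTable",
    "FORM_FACTORS",
    "BONDI_RADII",
    "SOLVENT_RESIDUES",
    "SaxsCurve",
    "infer_element",
    "read_configurations",
    "write_pdb",
    "read_saxs_curve",
    "write_saxs_curve",
]

#: pseudo-element for massless virtual interaction sites (no electrons)
DUMMY = "DUMMY"

#: Bondi van der Waals radii (Angstrom); the default radius set for the
#: solute vdW surface.  Configurable per call where it matters.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Na": 2.27,
    "Cl": 1.75,
    "K": 2.75,
    "Mg": 1.73,
    "Ca": 2.31,
    DUMMY: 0.0,
}

#: residue names treated as solvent when partitioning solute/solvent
SOLVENT_RESIDUES: frozenset[str] = frozenset(
    {"SOL", "WAT", "HOH", "TIP3", "TIP4", "T4P", "SPC", "NA", "CL", "NA+", "CL-", "ION"}
)

_WATER_RESIDUES = frozenset({"SOL", "WAT", "HOH", "TIP3", "TIP4", "T4P", "SPC"})

# elements resolvable by the name heuristics below
_KNOWN_ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Na", "Cl", "K", "Mg", "Ca")


class FormFactorTable:
    """Cromer-Mann form factors for a set of elements.

    Coefficients (a1..a4, b1..b4, c) are pulled from gemmi's International
    Tables (IT92) data and evaluated here in float64.  ``DUMMY`` is a valid
    element with f identically zero.
    """

    def __init__(self, elements: Iterable[str] = _KNOWN_ELEMENTS) -> None:
        self._coeffs: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
        for el in elements:
            self.add_element(el)
        self._coeffs[DUMMY] = (np.zeros(4), np.zeros(4), 0.0)

    def add_element(self, element: str) -> None:
        g = gemmi.Element(element)
        if g.name == "X" or not g.it92:
            raise KeyError(f"no Cromer-Mann coefficients for element {element!r}")
        it = g.it92
        self._coeffs[element] = (
            np.asarray(it.a, dtype=float),
            np.asarray(it.b, dtype=float),
            float(it.c),
        )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._coeffs)

    def coefficients(self, element: str) -> tuple[np.ndarray, np.ndarray, float]:
        try:
            return self._coeffs[element]
        except KeyError:
            raise KeyError(f"element {element!r} not in form-factor table") from None

    def __call__(self, element: str, q: float | np.ndarray) -> np.ndarray | float:
        """f(q) in electrons; ``q`` in 1/Angstrom, scalar or array."""
        a, b, c = self.coefficients(element)
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be non-negative")
        s2 = (q / (4.0 * math.pi)) ** 2
        f = np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + c
        return float(f) if f.ndim == 0 else f

    def electrons(self, element: str) -> float:
        """f(0): the atomic electron number carried into scattering sums."""
        a, _, c = self.coefficients(element)
        return float(np.sum(a) + c)


#: module-level default table
FORM_FACTORS = FormFactorTable()


def form_factor(element: str, q: float | np.ndarray) -> np.ndarray | float:
    """Cromer-Mann form factor f(q) for ``element`` (convenience wrapper)."""
    return FORM_FACTORS(element, q)


def infer_element(atom_name: str, residue_name: str) -> tuple[str, float]:
    """Map a PDB/GRO-style atom name to (element, electron count).

    PDB naming conventions are assumed: in amino-acid and water residues a
    leading ``C``/``N``/``O``/``H``/``S`` names the element ("CA" in ALA is an
    alpha-carbon, not calcium); virtual sites of 4-site waters (``MW``,
    ``EPW``, ``EP``) map to ``DUMMY`` with zero electrons.  Two-letter ion
    elements are recognised through ion residue names (``NA``, ``CL`` ...).

    Raises ``ValueError`` for an irresolvable name — never a silent guess.
    """
    name = atom_name.strip()
    res = residue_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    upper = name.upper()

    if res in _WATER_RESIDUES:
        if upper.startswith(("MW", "EP", "M", "LP")) and not upper.startswith("MG"):
            return DUMMY, 0.0
        if upper.startswith(("OW", "O")):
            return "O", FORM_FACTORS.electrons("O")
        if upper.startswith(("HW", "H")):
            return "H", FORM_FACTORS.electrons("H")
        raise ValueError(f"cannot infer element for water atom name {atom_name!r}")

    ion_map = {"NA": "Na", "CL": "Cl", "K": "K", "MG": "Mg", "CA": "Ca"}
    if res in {"NA", "CL", "K", "MG", "CA", "NA+", "CL-", "ION"}:
        key = upper.rstrip("+-0123456789")
        if key in ion_map:
            el = ion_map[key]
            return el, FORM_FACTORS.electrons(el)

    if upper in {"MW", "EP", "EPW", "DUM", "MCH3"}:
        return DUMMY, 0.0

    # strip leading digits (e.g. "1HB2"), then the first letter names the
    # element in standard biopolymer nomenclature
    stripped = upper.lstrip("0123456789")
    if stripped and stripped[0] in {"H", "C", "N", "O", "S", "P", "F"}:
        el = stripped[0]
        return el, FORM_FACTORS.electrons(el)
    raise ValueError(
        f"cannot infer element for atom name {atom_name!r} in residue {residue_name!r}"
    )


@dataclasses.dataclass
class Atoms:
    """Per-atom metadata shared by all frames of an ensemble (column store)."""

    names: np.ndarray  # str
    elements: np.ndarray  # str, 'DUMMY' allowed
    electrons: np.ndarray  # float, e
    vdw_radius: np.ndarray  # float, Angstrom
    solute: np.ndarray  # bool
    mol_id: np.ndarray  # int, molecule grouping (water O + H sites share an id)
    residues: np.ndarray | None = None  # str, optional

    def __post_init__(self) -> None:
        n = len(self.names)
        for field in ("elements", "electrons", "vdw_radius", "solute", "mol_id"):
            if len(getattr(self, field)) != n:
                raise ValueError(f"Atoms field {field!r} length mismatch")
        dummy = self.elements == DUMMY
        if np.any(self.electrons[dummy] != 0):
            raise ValueError("DUMMY atoms must carry zero electrons")
        if np.any((self.electrons == 0) & ~dummy):
            raise ValueError("zero electrons only allowed for DUMMY atoms")
        if np.any(self.vdw_radius[~dummy] <= 0):
            raise ValueError("vdW radius must be positive for non-DUMMY atoms")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_lists(
        cls,
        names: Sequence[str],
        elements: Sequence[str],
        solute: Sequence[bool],
        mol_id: Sequence[int] | None = None,
        residues: Sequence[str] | None = None,
        vdw_radii: Mapping[str, float] = BONDI_RADII,
        form_factors: FormFactorTable = FORM_FACTORS,
    ) -> "Atoms":
        elements = np.asarray(elements, dtype=object)
        electrons = np.array([form_factors.electrons(el) for el in elements])
        vdw = np.array([vdw_radii.get(el, 1.5) for el in elements])
        n = len(elements)
        return cls(
            names=np.asarray(names, dtype=object),
            elements=elements,
            electrons=electrons,
            vdw_radius=vdw,
            solute=np.asarray(solute, dtype=bool),
            mol_id=np.arange(n) if mol_id is None else np.asarray(mol_id, dtype=int),
            residues=None if residues is None else np.asarray(residues, dtype=object),
        )


@dataclasses.dataclass
class ConfigurationEnsemble:
    """Frames of a solute+solvent (or pure-solvent) system in a periodic box.

    Parameters
    ----------
    atoms : Atoms
        Shared per-atom metadata; ordering identical in every frame.
    frames : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom.
    box : ndarray, shape (3,)
        Orthorhombic box edge lengths (Angstrom).
    temperature : float
        Thermodynamic temperature in kelvin.
    """

    atoms: Atoms
    frames: np.ndarray
    box: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] == 0:
            raise ValueError("ensemble contains zero frames")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match atom metadata")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def solute_coordinates(self, frame: int | None = None) -> np.ndarray:
        """Coordinates of solute atoms; all frames pooled when frame is None."""
        mask = self.atoms.solute
        if frame is not None:
            return self.frames[frame][mask]
        return self.frames[:, mask, :].reshape(-1, 3)

    def solute_only(self, frame: int = 0) -> "ConfigurationEnsemble":
        """Single-frame ensemble of the solute atoms only."""
        mask = self.atoms.solute
        if not np.any(mask):
            raise ValueError("ensemble has no solute atoms")
        at = self.atoms
        sub = Atoms(
            names=at.names[mask],
            elements=at.elements[mask],
            electrons=at.electrons[mask],
            vdw_radius=at.vdw_radius[mask],
            solute=at.solute[mask],
            mol_id=at.mol_id[mask],
            residues=None if at.residues is None else at.residues[mask],
        )
        return ConfigurationEnsemble(
            atoms=sub,
            frames=self.frames[frame : frame + 1, mask, :].copy(),
            box=self.box.copy(),
            temperature=self.temperature,
            label=self.label + ":solute",
        )


# ---------------------------------------------------------------------------
# configuration readers / writers
# ---------------------------------------------------------------------------


def _partition_and_infer(
    names: Sequence[str], residues: Sequence[str], solvent_residues: frozenset[str]
) -> tuple[list[str], list[bool]]:
    elements: list[str] = []
    solute: list[bool] = []
    for name, res in zip(names, residues):
        el, _ = infer_element(name, res)
        elements.append(el)
        solute.append(res.strip().upper() not in solvent_residues)
    return elements, solute


def read_configurations(
    path: str | Path,
    format: str | None = None,
    trajectory: str | Path | None = None,
    temperature: float = 300.0,
    solvent_residues: frozenset[str] = SOLVENT_RESIDUES,
) -> ConfigurationEnsemble:
    """Read an ensemble from a multi-model PDB or a GRO file plus trajectory.

    ``format`` is inferred from the suffix when omitted (``.pdb`` /
    ``.gro``).  The solute/solvent partition is assigned from residue names;
    elements are inferred through :func:`infer_element`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in {"pdb", "multi-model-pdb"}:
        return _read_pdb(path, temperature, solvent_residues)
    if fmt in {"gro", "gro+trajectory"}:
        return _read_gro(path, trajectory, temperature, solvent_residues)
    raise ValueError(f"unknown configuration format {fmt!r}")


def _read_pdb(
    path: Path, temperature: float, solvent_residues: frozenset[str]
) -> ConfigurationEnsemble:
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    names: list[str] = []
    residues: list[str] = []
    mol_id: list[int] = []
    coords = []
    for imodel, model in enumerate(st):
        xyz = []
        mid = 0
        for chain in model:
            for residue in chain:
                mid += 1
                for atom in residue:
                    if imodel == 0:
                        names.append(atom.name)
                        residues.append(residue.name)
                        mol_id.append(mid)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if imodel > 0 and len(xyz) != len(names):
            raise ValueError(f"{path}: model {imodel + 1} atom count differs")
        coords.append(xyz)
    if not names:
        raise ValueError(f"{path}: no atoms found")
    elements, solute = _partition_and_infer(names, residues, solvent_residues)
    atoms = Atoms.from_lists(names, elements, solute, mol_id=mol_id, residues=residues)
    cell = st.cell
    box = np.array([cell.a, cell.b, cell.c])
    if np.any(box <= 1.0):  # no meaningful CRYST1 record
        span = np.ptp(np.asarray(coords[0]), axis=0)
        box = span + 20.0
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=np.asarray(coords, dtype=float),
        box=box,
        temperature=temperature,
        label=path.stem,
    )


def _read_gro(
    path: Path,
    trajectory: str | Path | None,
    temperature: float,
    solvent_residues: frozenset[str],
) -> ConfigurationEnsemble:
    import MDAnalysis as mda  # deferred: heavy import

    if trajectory is not None:
        u = mda.Universe(str(path), str(trajectory))
    else:
        u = mda.Universe(str(path))
    names = [a.name for a in u.atoms]
    residues = [a.resname for a in u.atoms]
    mol_id = [a.resindex for a in u.atoms]
    elements, solute = _partition_and_infer(names, residues, solvent_residues)
    atoms = Atoms.from_lists(names, elements, solute, mol_id=mol_id, residues=residues)
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if frames.shape[0] == 0:
        raise ValueError(f"{path}: trajectory contains zero frames")
    box = np.asarray(u.dimensions[:3], dtype=float)
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=frames,
        box=box,
        temperature=temperature,
        label=path.stem,
    )


def write_pdb(ensemble: ConfigurationEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    path = Path(path)
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*ensemble.box, 90, 90, 90)
    at = ensemble.atoms
    residues = at.residues
    for iframe in range(ensemble.n_frames):
        model = gemmi.Model(iframe + 1)
        chain = gemmi.Chain("A")
        prev_mid = None
        residue = None
        for j in range(ensemble.n_atoms):
            mid = int(at.mol_id[j])
            if mid != prev_mid:
                residue = gemmi.Residue()
                residue.name = (
                    str(residues[j]) if residues is not None
                    else ("MOL" if at.solute[j] else "SOL")
                )
                residue.seqid = gemmi.SeqId(mid % 10000, " ")
                chain.add_residue(residue)
                prev_mid = mid
            atom = gemmi.Atom()
            atom.name = str(at.names[j])
            el = str(at.elements[j])
            atom.element = gemmi.Element(el if el != DUMMY else "X")
            x, y, z = ensemble.frames[iframe, j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            chain[-1].add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    path.write_text(doc)


# ---------------------------------------------------------------------------
# SAXS curve container and ASCII I/O
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SaxsCurve:
    """A scattering curve I(q) with optional pointwise uncertainties.

    q in 1/Angstrom (strictly ascending), I in e^2 for computed curves or
    arbitrary units for experimental data.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have identical shape")
        if len(self.q) > 1 and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("non-finite intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma shape mismatch")

    def __len__(self) -> int:
        return len(self.q)

    def same_grid(self, other: "SaxsCurve", rtol: float = 1e-10) -> bool:
        return self.q.shape == other.q.shape and np.allclose(
            self.q, other.q, rtol=rtol, atol=0
        )


def write_saxs_curve(curve: SaxsCurve, path: str | Path) -> None:
    """Write a curve as whitespace-delimited ``q I sigma`` ASCII."""
    path = Path(path)
    lines = ["# shellsaxs SAXS curve", "# q [1/A]  I [e^2 or a.u.]  sigma"]
    for key, val in sorted(curve.meta.items()):
        lines.append(f"# {key} = {val}")
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    for q, i, s in zip(curve.q, curve.I, sigma):
        lines.append(f"{q:.8e} {i:.8e} {s:.8e}")
    path.write_text("\n".join(lines) + "\n")


def read_saxs_curve(path: str | Path) -> SaxsCurve:
    """Read a 3-column (or 2-column) ASCII curve; '#' lines are comments."""
    path = Path(path)
    meta: dict = {}
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "=" in stripped:
                key, _, val = stripped.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = stripped.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable number") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array([r + [0.0] * (3 - len(r)) for r in rows])
    sigma = arr[:, 2] if np.any(arr[:, 2] != 0) else None
    return SaxsCurve(q=arr[:, 0], I=arr[:, 1], sigma=sigma, meta=meta)
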