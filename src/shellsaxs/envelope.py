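"""Scattering envelope: a fixed closed region around the solute.

The envelope is the union of spheres of radius D centred on the pooled
solute atom positions of all frames, so every hydration-shell water lies
inside it at the default offset D = 12 A.  Membership is a nearest-pooled-
atom distance test (closed boundary: distance <= D counts as inside), and
the identical region is applied to the matched pure-solvent buffer so that
sample and buffer amplitudes are evaluated over the same volume.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .model_io import ConfigurationEnsemble

__all__ = ["Envelope", "build_envelope", "classify_solvent", "envelope_volume"]

DEFAULT_DISTANCE = 12.0  # A; guarantees the full hydration shell is enclosed


@dataclasses.dataclass
class Envelope:
    """Union-of-spheres region at offset ``distance`` around pooled points."""

    points: np.ndarray  # pooled solute positions, (n, 3)
    distance: float
    _tree: cKDTree = dataclasses.field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] == 0:
            raise ValueError("envelope needs at least one solute point")
        if self.distance <= 0:
            raise ValueError("envelope distance must be positive")
        self._tree = cKDTree(self.points)

    def nearest_distance(self, xyz: np.ndarray) -> np.ndarray:
        """Distance from each query point to the nearest pooled solute atom."""
        d, _ = self._tree.query(np.atleast_2d(xyz), k=1)
        return d

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask: inside iff nearest-atom distance <= D (closed)."""
        return self.nearest_distance(xyz) <= self.distance

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.points.min(axis=0) - self.distance
        hi = self.points.max(axis=0) + self.distance
        return lo, hi


def build_envelope(
    ensemble: ConfigurationEnsemble, distance: float = DEFAULT_DISTANCE
) -> Envelope:
    """Envelope around the solute atoms pooled over all frames."""
    if not np.any(ensemble.atoms.solute):
        raise ValueError("cannot build an envelope: ensemble has no solute atoms")
    pooled = ensemble.solute_coordinates(frame=None)
    lo, hi = pooled.min(axis=0) - distance, pooled.max(axis=0) + distance
    if np.any(lo < -1e-9) or np.any(hi > ensemble.box + 1e-9):
        raise ValueError(
            "envelope extends outside the primary box; increase the box or "
            "re-wrap coordinates (periodic images are not evaluated)"
        )
    return Envelope(points=pooled, distance=distance)


def classify_solvent(
    envelope: Envelope,
    ensemble: ConfigurationEnsemble,
    frame: int,
    whole_molecule: bool = True,
) -> np.ndarray:
    """Per-atom inside/outside mask for one frame.

    Solute atoms are always inside.  With ``whole_molecule`` (default) a
    solvent molecule is assigned as a unit by the position of its first
    atom — the oxygen for waters — so a molecule's electrons are never split
    across the envelope boundary.
    """
    xyz = ensemble.frames[frame]
    at = ensemble.atoms
    mask = np.zeros(len(at), dtype=bool)
    mask[at.solute] = True
    solvent = ~at.solute
    if not np.any(solvent):
        return mask
    if whole_molecule:
        mol = at.mol_id[solvent]
        first_of_mol = np.concatenate([[True], mol[1:] != mol[:-1]])
        solvent_idx = np.flatnonzero(solvent)
        head_idx = solvent_idx[first_of_mol]
        head_inside = envelope.contains(xyz[head_idx])
        inside_by_mol = dict(zip(mol[first_of_mol], head_inside))
        mask[solvent_idx] = np.array([inside_by_mol[m] for m in mol])
    else:
        mask[solvent] = envelope.contains(xyz[solvent])
    return mask


def envelope_volume(
    envelope: Envelope, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo envelope volume with its binomial standard error (A^3)."""
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    rng = np.random.default_rng(seed)
    lo, hi = envelope.bounding_box
    span = hi - lo
    pts = lo + rng.random((n_mc, 3)) * span
    frac = envelope.contains(pts).mean()
    v_bound = float(np.prod(span))
    volume = v_bound * frac
    se = v_bound * np.sqrt(max(frac * (1 - frac), 1e-300) / n_mc)
    return volume, se
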