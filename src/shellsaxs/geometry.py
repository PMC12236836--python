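"""Small geometric helpers shared by the generator and shell diagnostics."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["surface_distance", "fibonacci_sphere"]


def surface_distance(
    points: np.ndarray, solute_xyz: np.ndarray, solute_vdw: np.ndarray
) -> np.ndarray:
    """Signed distance from each point to the solute van der Waals surface.

    d(r) = min_j ( |r - r_j| - r_vdw,j ); negative inside some vdW sphere.
    Evaluated in chunks so the (n_points x n_solute) distance block stays
    bounded in memory.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    solute_xyz = np.asarray(solute_xyz, dtype=float)
    solute_vdw = np.asarray(solute_vdw, dtype=float)
    if solute_xyz.shape[0] == 0:
        raise ValueError("no solute atoms")
    if np.ptp(solute_vdw) < 1e-12:
        # uniform radii: a KD-tree nearest-neighbour query suffices
        tree = cKDTree(solute_xyz)
        d, _ = tree.query(points, k=1)
        return d - solute_vdw[0]
    out = np.empty(len(points))
    chunk = max(1, int(4e6 / max(1, solute_xyz.shape[0])))
    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        dists = np.linalg.norm(block[:, None, :] - solute_xyz[None, :, :], axis=2)
        out[start : start + chunk] = np.min(dists - solute_vdw[None, :], axis=1)
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, quasi-uniform unit vectors (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    vecs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
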