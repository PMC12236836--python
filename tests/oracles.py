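"""Independent reference computations for validating the scattering code.

These deliberately avoid the package's amplitude/orientational-average path:
the Debye formula is an exact closed-form orientational average over the
pair distances, evaluated as a brute-force double sum.
"""

from __future__ import annotations

import numpy as np


def debye_intensity(xyz: np.ndarray, f_of_q, q: np.ndarray) -> np.ndarray:
    """Brute-force Debye double sum for a rigid set of atoms.

    I(q) = sum_jk f_j(q) f_k(q) sinc(q r_jk); ``f_of_q(q_scalar)`` returns
    the per-atom form-factor vector at one q magnitude.
    """
    xyz = np.asarray(xyz, dtype=float)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    out = np.empty(len(q))
    for k, qk in enumerate(np.asarray(q, dtype=float)):
        f = np.asarray(f_of_q(qk), dtype=float)
        qd = qk * d
        with np.errstate(invalid="ignore"):
            sinc = np.where(qd > 1e-12, np.sin(qd) / np.where(qd > 0, qd, 1.0), 1.0)
        out[k] = float(np.sum(np.outer(f, f) * sinc))
    return out


def sphere_form_factor_sq(qR: np.ndarray) -> np.ndarray:
    """|F(q)|^2 of a homogeneous ball: [3 (sin x - x cos x)/x^3]^2, x = qR."""
    x = np.asarray(qR, dtype=float)
    return np.where(
        x > 1e-8, (3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300) ** 3) ** 2, 1.0
    )


def mc_union_volume(
    centers: np.ndarray, radii: np.ndarray, n_mc: int = 400_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo volume of a union of spheres, with standard error."""
    rng = np.random.default_rng(seed)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    pts = lo + rng.random((n_mc, 3)) * (hi - lo)
    inside = np.zeros(n_mc, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    frac = inside.mean()
    vbox = float(np.prod(hi - lo))
    se = vbox * np.sqrt(max(frac * (1 - frac), 1e-300) / n_mc)
    return vbox * frac, se
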