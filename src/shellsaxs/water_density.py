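"""Temperature-dependent electron density of liquid water.

Mass densities of liquid water at 1 bar / saturation (CRC-style tables,
supercooled branch included) converted to electron densities with 10
electrons per 18.015 g/mol, giving rho_e [e/nm^3] = rho_mass [g/cm^3] *
334.27.  Linear interpolation between tabulated temperatures; values
outside 250-378 K raise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["water_electron_density"]

# electrons per nm^3 per (g/cm^3): 10 * N_A / 18.015 g/mol / 1e21
_E_PER_G_CM3 = 10.0 * 6.02214076e23 / 18.015 / 1.0e21

# (T in K, mass density in g/cm^3); supercooled branch from laboratory
# measurements of metastable liquid water, >= 273 K from standard tables
_TABLE = np.array(
    [
        (243.15, 0.9767),
        (248.15, 0.98365),
        (253.15, 0.98980),
        (258.15, 0.99362),
        (263.15, 0.99659),
        (268.15, 0.99817),
        (273.15, 0.99984),
        (277.15, 0.99997),
        (283.15, 0.99970),
        (288.15, 0.99910),
        (293.15, 0.99821),
        (298.15, 0.99705),
        (303.15, 0.99565),
        (308.15, 0.99403),
        (313.15, 0.99222),
        (318.15, 0.99021),
        (323.15, 0.98804),
        (328.15, 0.98570),
        (333.15, 0.98320),
        (338.15, 0.98056),
        (343.15, 0.97778),
        (348.15, 0.97486),
        (353.15, 0.97182),
        (358.15, 0.96865),
        (363.15, 0.96535),
        (368.15, 0.96192),
        (373.15, 0.95840),
        (378.15, 0.95475),
    ]
)


def water_electron_density(T: float | np.ndarray, units: str = "e/nm3"):
    """Electron density of liquid water at temperature T (kelvin).

    ``units``: "e/nm3" (default) or "e/A3".  Roughly 333 e/nm^3 at
    298.15 K, with the well-known density maximum near 277 K.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = _TABLE[0, 0], _TABLE[-1, 0]
    if np.any(T < lo) or np.any(T > hi):
        raise ValueError(f"temperature outside tabulated range [{lo:.1f}, {hi:.1f}] K")
    rho_mass = np.interp(T, _TABLE[:, 0], _TABLE[:, 1])
    rho_e = rho_mass * _E_PER_G_CM3
    if units == "e/nm3":
        out = rho_e
    elif units == "e/A3":
        out = rho_e / 1000.0
    else:
        raise ValueError("units must be 'e/nm3' or 'e/A3'")
    return float(out) if out.ndim == 0 else out
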