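"""Guinier analysis and experimental-style curve reduction.

In the Guinier regime ln[I(q)/I0] = -q^2 Rg^2 / 3, so a weighted linear fit
of ln I against q^2 yields the forward scattering I0 = exp(intercept) and
the radius of gyration Rg = sqrt(-3 * slope).  The fit window is made
self-consistent by iterating: fit, recompute Rg, truncate to
q <= qRg_max / Rg, refit, until the window stops changing (the conventional
q Rg <= 1.3 bound by default).

Curve reduction for multi-concentration, multi-temperature measurements:
pointwise averaging of repeat curves and linear extrapolation of I/c to the
infinite-dilution limit c -> 0.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .model_io import SaxsCurve

__all__ = [
    "GuinierResult",
    "GuinierError",
    "guinier_fit",
    "average_curves",
    "extrapolate_infinite_dilution",
]


class GuinierError(ValueError):
    """No valid Guinier regime (non-negative slope) or no convergence."""


@dataclasses.dataclass
class GuinierResult:
    I0: float
    Rg: float
    q_min: float
    q_max: float
    qRg_max: float
    n_points: int
    n_iterations: int
    covariance: np.ndarray  # 2x2 covariance of (ln I0, slope)
    residuals: np.ndarray

    @property
    def I0_err(self) -> float:
        return self.I0 * float(np.sqrt(self.covariance[0, 0]))

    @property
    def Rg_err(self) -> float:
        # Rg = sqrt(-3 s): dRg/ds = -3 / (2 Rg)
        return float(3.0 / (2.0 * self.Rg) * np.sqrt(self.covariance[1, 1]))


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns (a, b, cov)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise GuinierError("degenerate q^2 values in fit window")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    cov = np.array([[1.0 / W + xm**2 / sxx, -xm / sxx], [-xm / sxx, 1.0 / sxx]])
    # scale covariance by reduced chi^2 when unweighted or overdispersed
    resid = y - (a + b * x)
    dof = max(1, len(x) - 2)
    chi2 = np.sum(w * resid**2) / dof
    return a, b, cov * chi2, resid


def guinier_fit(
    curve: SaxsCurve,
    qRg_max: float = 1.3,
    min_points: int = 5,
    max_iterations: int = 50,
) -> GuinierResult:
    """Self-consistent Guinier fit of the low-q window of ``curve``.

    Weights are 1/sigma_lnI^2 with sigma_lnI = sigma/I when uncertainties
    are available, unweighted otherwise.  Points with I <= 0 are excluded
    up front.  Raises :class:`GuinierError` when the low-q slope is not
    negative (no Guinier regime) or the window iteration does not converge.
    """
    positive = curve.I > 0
    q = curve.q[positive]
    I = curve.I[positive]
    sigma = curve.sigma[positive] if curve.sigma is not None else None
    if len(q) < min_points:
        raise GuinierError(f"need >= {min_points} positive-intensity points")

    x_all = q**2
    y_all = np.log(I)
    if sigma is not None and np.all(sigma > 0):
        w_all = (I / sigma) ** 2
    else:
        w_all = np.ones_like(I)

    window = np.arange(len(q))
    seen: set[tuple[int, int]] = set()
    trace = []
    for iteration in range(1, max_iterations + 1):
        a, b, cov, resid = _wls_line(x_all[window], y_all[window], w_all[window])
        if -3.0 * b <= 1e-12:  # non-negative or vanishing slope
            raise GuinierError(
                f"no Guinier regime: non-negative slope {b:.3g} at iteration {iteration}"
            )
        Rg = float(np.sqrt(-3.0 * b))
        new_window = np.flatnonzero(q * Rg <= qRg_max)
        if len(new_window) < min_points:
            new_window = np.arange(min_points)
        trace.append((Rg, len(new_window)))
        signature = (int(new_window[0]), int(new_window[-1]))
        # fixed point, or a limit cycle between near-identical windows:
        # either way the current fit is self-consistent to within one point
        if np.array_equal(new_window, window) or signature in seen:
            return GuinierResult(
                I0=float(np.exp(a)),
                Rg=Rg,
                q_min=float(q[window[0]]),
                q_max=float(q[window[-1]]),
                qRg_max=qRg_max,
                n_points=len(window),
                n_iterations=iteration,
                covariance=cov,
                residuals=resid,
            )
        seen.add((int(window[0]), int(window[-1])))
        window = new_window
    raise GuinierError(f"fit window did not converge in {max_iterations} iterations; trace={trace}")


def average_curves(curves: list[SaxsCurve]) -> SaxsCurve:
    """Pointwise mean of repeat curves; sigma = standard error over curves."""
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    if len(curves) == 1:
        warnings.warn("average_curves called with a single curve; returned unchanged")
        return first
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("average_curves: q grids differ")
    stack = np.vstack([c.I for c in curves])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return SaxsCurve(q=first.q.copy(), I=mean, sigma=se, meta={"n_averaged": len(curves)})


def extrapolate_infinite_dilution(
    curves: list[SaxsCurve], concentrations: list[float]
) -> SaxsCurve:
    """Extrapolate concentration-normalised intensities to c -> 0.

    Per q point, I/c is regressed linearly on c (weighted by sigma/c when
    available) and the intercept — the infinite-dilution curve — is returned
    with its standard error.  Curves at duplicate concentrations are
    averaged first.
    """
    if len(curves) != len(concentrations):
        raise ValueError("need one concentration per curve")
    if not curves:
        raise ValueError("no curves given")
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("extrapolate_infinite_dilution: q grids differ")

    # pool duplicate concentrations
    by_conc: dict[float, list[SaxsCurve]] = {}
    for curve, conc in zip(curves, concentrations):
        if conc <= 0:
            raise ValueError("concentrations must be positive")
        by_conc.setdefault(float(conc), []).append(curve)
    concs = np.array(sorted(by_conc))
    pooled = [
        by_conc[c][0] if len(by_conc[c]) == 1 else average_curves(by_conc[c])
        for c in concs
    ]

    if len(concs) == 1:
        warnings.warn("single concentration: returning I/c without extrapolation")
        c0 = concs[0]
        cur = pooled[0]
        sig = cur.sigma / c0 if cur.sigma is not None else None
        return SaxsCurve(q=cur.q.copy(), I=cur.I / c0, sigma=sig,
                         meta={"concentration_mg_ml": c0})

    Y = np.vstack([cur.I / c for cur, c in zip(pooled, concs)])  # (n_c, n_q)
    if all(cur.sigma is not None for cur in pooled):
        W = np.vstack([(c / cur.sigma) ** 2 for cur, c in zip(pooled, concs)])
        W[~np.isfinite(W)] = 1.0
    else:
        W = np.ones_like(Y)
    intercept = np.empty(Y.shape[1])
    se = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        a, b, cov, _ = _wls_line(concs, Y[:, j], W[:, j])
        intercept[j] = a
        se[j] = np.sqrt(max(cov[0, 0], 0.0))
    return SaxsCurve(
        q=first.q.copy(), I=intercept, sigma=se,
        meta={"concentrations_mg_ml": ", ".join(f"{c:g}" for c in concs)},
    )
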