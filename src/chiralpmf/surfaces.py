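"""Parametric 1-D model free-energy surfaces with landmark control.

A :class:`ModelSurface` is a sum of Gaussians plus a linear term (plus a constant),

    G(x) = sum_j a_j exp(-(x - c_j)^2 / (2 w_j^2)) + s*x + c0,

smooth with an analytic gradient, so it can serve both as the "true" free energy
driving the synthetic Langevin sampler and as ground truth when checking the WHAM
reconstruction.  :func:`surface_from_landmarks` builds a surface whose reactant
minimum, transition-state maximum and product minimum sit at prescribed reaction
coordinates with a prescribed barrier height and overall reaction free energy —
the shape of a single-step nucleophilic-substitution profile with no intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["ModelSurface", "SurfaceConstructionError", "surface_from_landmarks"]


class SurfaceConstructionError(RuntimeError):
    """Raised when no surface satisfying the requested landmarks can be built."""


@dataclass(frozen=True)
class ModelSurface:
    """Sum-of-Gaussians free-energy surface G(x) on a finite domain.

    ``gaussians`` is a tuple of (amplitude kcal/mol, center A, width A) triples;
    ``linear_slope`` is in kcal/mol/A and ``offset`` in kcal/mol.
    """

    gaussians: tuple[tuple[float, float, float], ...]
    linear_slope: float = 0.0
    offset: float = 0.0
    domain: tuple[float, float] = (-5.0, 4.0)

    def __post_init__(self) -> None:
        for a, c, w in self.gaussians:
            if w <= 0:
                raise ValueError(f"gaussian width must be > 0, got {w}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"domain must satisfy lo < hi, got {self.domain}")

    # Parameter arrays in the layout the Langevin kernel consumes.
    def _params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.gaussians:
            g = np.asarray(self.gaussians, dtype=float)
            return g[:, 0].copy(), g[:, 1].copy(), g[:, 2].copy()
        z = np.zeros(0)
        return z, z.copy(), z.copy()

    def energy(self, x):
        """G(x) in kcal/mol; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        out = self.linear_slope * x + self.offset
        for a, c, w in self.gaussians:
            d = (x - c) / w
            out = out + a * np.exp(-0.5 * d * d)
        return out

    def gradient(self, x):
        """dG/dx in kcal/mol/A; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.linear_slope, dtype=float)
        for a, c, w in self.gaussians:
            d = (x - c) / w
            out = out - (a / w) * d * np.exp(-0.5 * d * d)
        return out


def _grid_landmarks(surface: ModelSurface, reactant_rc, ts_rc, product_rc, resolution=1e-3):
    """Locate the reactant/product minima and the barrier maximum on a dense grid."""
    lo, hi = surface.domain
    x = np.arange(lo, hi + resolution / 2, resolution)
    g = surface.energy(x)
    mid_rt = 0.5 * (reactant_rc + ts_rc)
    mid_tp = 0.5 * (ts_rc + product_rc)
    r_mask = x <= mid_rt
    t_mask = (x > mid_rt) & (x < mid_tp)
    p_mask = x >= mid_tp
    i_r = np.flatnonzero(r_mask)[np.argmin(g[r_mask])]
    i_t = np.flatnonzero(t_mask)[np.argmax(g[t_mask])]
    i_p = np.flatnonzero(p_mask)[np.argmin(g[p_mask])]
    return (x[i_r], g[i_r]), (x[i_t], g[i_t]), (x[i_p], g[i_p])


def surface_from_landmarks(
    reactant_rc: float,
    ts_rc: float,
    barrier: float,
    product_rc: float,
    overall_dg: float,
    *,
    domain: tuple[float, float] | None = None,
    tolerance: float = 0.05,
) -> ModelSurface:
    """Build a surface with prescribed stationary points.

    Parameters
    ----------
    reactant_rc, ts_rc, product_rc:
        Reaction-coordinate positions (A) of the reactant minimum, barrier top and
        product minimum; must be strictly increasing.
    barrier:
        Barrier height G(ts) - G(reactant) in kcal/mol; must exceed
        ``max(0, overall_dg)`` or no single-barrier profile exists.
    overall_dg:
        Overall reaction free energy G(product) - G(reactant), kcal/mol.
    tolerance:
        Maximum allowed deviation, in kcal/mol for energies and A for positions,
        between requested and grid-verified landmarks.

    One Gaussian is centred at each landmark; amplitudes, slope and offset are
    solved by linear least squares against the three value and three
    zero-derivative constraints, and the widths are then refined by a derivative
    free minimisation of the residual.  The result is verified on a dense grid.
    """
    if not (reactant_rc < ts_rc < product_rc):
        raise ValueError("landmarks must satisfy reactant_rc < ts_rc < product_rc")
    if barrier <= max(0.0, overall_dg):
        raise ValueError(
            f"barrier ({barrier}) must exceed max(0, overall_dg) = {max(0.0, overall_dg)}"
        )
    if domain is None:
        domain = (reactant_rc - 2.0, product_rc + 2.0)

    centers = np.array([reactant_rc, ts_rc, product_rc])
    targets = np.array([0.0, barrier, overall_dg, 0.0, 0.0, 0.0])  # values then derivatives
    gap = np.array(
        [
            ts_rc - reactant_rc,
            min(ts_rc - reactant_rc, product_rc - ts_rc),
            product_rc - ts_rc,
        ]
    )

    def solve_linear(widths: np.ndarray):
        # Rows: G at 3 landmarks, then G' at 3 landmarks. Columns: a1 a2 a3 s c0.
        A = np.zeros((6, 5))
        for row, xv in enumerate(centers):
            d = (xv - centers) / widths
            phi = np.exp(-0.5 * d * d)
            A[row, :3] = phi
            A[row, 3] = xv
            A[row, 4] = 1.0
            A[row + 3, :3] = -(d / widths) * phi
            A[row + 3, 3] = 1.0
        coef, *_ = np.linalg.lstsq(A, targets, rcond=None)
        resid = A @ coef - targets
        return coef, float(resid @ resid)

    def objective(log_scale: np.ndarray) -> float:
        widths = gap * 0.5 * np.exp(log_scale)
        return solve_linear(widths)[1]

    res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    widths = gap * 0.5 * np.exp(res.x)
    coef, _ = solve_linear(widths)
    amps, slope, offset = coef[:3], coef[3], coef[4]

    surface = ModelSurface(
        gaussians=tuple((float(a), float(c), float(w)) for a, c, w in zip(amps, centers, widths)),
        linear_slope=float(slope),
        offset=float(offset),
        domain=domain,
    )

    # Re-anchor so the grid-located reactant minimum sits exactly at zero.
    (xr, gr), (xt, gt), (xp, gp) = _grid_landmarks(surface, reactant_rc, ts_rc, product_rc)
    surface = ModelSurface(
        gaussians=surface.gaussians,
        linear_slope=surface.linear_slope,
        offset=float(surface.offset - gr),
        domain=domain,
    )
    gt, gp = gt - gr, gp - gr

    errs = {
        "reactant position": abs(xr - reactant_rc),
        "barrier position": abs(xt - ts_rc),
        "product position": abs(xp - product_rc),
        "barrier height": abs(gt - barrier),
        "overall dG": abs(gp - overall_dg),
    }
    bad = {k: v for k, v in errs.items() if v > tolerance}
    if bad:
        raise SurfaceConstructionError(
            "landmark fit failed: " + ", ".join(f"{k} off by {v:.3g}" for k, v in bad.items())
        )
    return surface
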