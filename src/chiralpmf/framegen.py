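"""Synthetic reaction-site coordinate frames realizing prescribed observable schedules.

Builds labeled 8-atom frames whose Burgi-Dunitz angle, Flippin-Lodge angle, key
distances and backbone torsion follow configurable piecewise-linear functions of
the reaction coordinate, with optional Gaussian noise applied in observable space.
Together with the Langevin sampler this replaces the MD engine: the geometry
analyzer can be validated by exact roundtrip (zero noise) and by recovering the
scheduled means and SDs (with noise).

Construction, per frame (all in a canonical body frame; add a rigid motion
afterwards if desired):

* Ccarb at the origin, Ocarb on +x (C=O bond 1.23 A);
* Calpha and Ob in the xy-plane completing the trigonal carbonyl center
  (bond lengths 1.52 / 1.36 A, in-plane angles 121 / -123 degrees), so the
  carbonyl plane is exactly z = 0 with Ob on the -y side;
* O3' at the scheduled d(Ccarb...O3') and BD angle, tilted off the xz reference
  plane by the scheduled FL angle (toward Ob = positive);
* H3' on the Ccarb->O3' ray beyond O3' at the scheduled d(H3'...O3');
* N by internal coordinates from (Ob, Ccarb, Calpha): bond 1.47 A, torsion
  tau(Ob-Ccarb-Calpha-N) as scheduled, and the Ccarb-Calpha-N bond angle solved
  numerically so that d(N...O3') matches its schedule;
* P5' on the Calpha->N ray beyond N at the scheduled d(N...P5').

The default L-like and D-like schedules emulate the window-averaged trajectories
of the two enantiomeric aminoacylation systems: both share the BD ramp to 105
degrees and an FL angle fluctuating about 0, while the D-like schedule carries
the abrupt cis->trans flip of tau near RC = -2.2 A with the coupled d(N...O3')
drop and d(N...P5') jump (5.1 A at the barrier, 6.3 A after it), versus the
L-like gradual tau rotation to 60 degrees and d(N...P5') ~ 4.0 A at the barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import GeometryFrame

__all__ = [
    "PiecewiseLinear",
    "GeometrySchedule",
    "GeometryConstructionError",
    "generate_geometry_frames",
    "l_ala_like_schedule",
    "d_ala_like_schedule",
]

# Fixed internal geometry of the carbonyl center (A, degrees).
_D_C_OCARB = 1.23
_D_C_CALPHA = 1.52
_D_C_OB = 1.36
_D_CALPHA_N = 1.47
_ANG_OCARB_C_CALPHA = 121.0   # Calpha on the +y side
_ANG_OCARB_C_OB = -123.0      # Ob on the -y side


class GeometryConstructionError(RuntimeError):
    """Raised when a frame satisfying the scheduled targets cannot be built."""


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear function of the reaction coordinate, defined by knots."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 1:
            raise ValueError("knot arrays must be non-empty and equal length")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("knot positions must be strictly increasing")

    def __call__(self, rc):
        return np.interp(rc, self.x, self.y)

    @property
    def domain(self) -> tuple[float, float]:
        return (self.x[0], self.x[-1])


#: Observable names a schedule must provide.
SCHEDULED_OBSERVABLES = ("bd_angle", "fl_angle", "d_n_o3", "d_n_p5", "tau", "d_c_o3", "d_h_o3")


@dataclass(frozen=True)
class GeometrySchedule:
    """Scheduled observable targets and per-observable Gaussian noise SDs."""

    bd_angle: PiecewiseLinear
    fl_angle: PiecewiseLinear
    d_n_o3: PiecewiseLinear
    d_n_p5: PiecewiseLinear
    tau: PiecewiseLinear
    d_c_o3: PiecewiseLinear
    d_h_o3: PiecewiseLinear
    noise_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("d_n_o3", "d_n_p5", "d_c_o3", "d_h_o3"):
            if min(getattr(self, name).y) <= 0:
                raise ValueError(f"{name} targets must be positive")
        if not all(0 < v < 180 for v in self.bd_angle.y):
            raise ValueError("bd_angle targets must lie in (0, 180)")
        if not all(-90 <= v <= 90 for v in self.fl_angle.y):
            raise ValueError("fl_angle targets must lie in [-90, 90]")
        if not all(-180 <= v <= 180 for v in self.tau.y):
            raise ValueError("tau targets must lie in [-180, 180]")
        for k, v in self.noise_sd.items():
            if k not in SCHEDULED_OBSERVABLES:
                raise ValueError(f"unknown observable {k!r} in noise_sd")
            if v < 0:
                raise ValueError("noise SDs must be >= 0")

    @property
    def domain(self) -> tuple[float, float]:
        los, his = zip(*(getattr(self, n).domain for n in SCHEDULED_OBSERVABLES))
        return (max(los), min(his))

    def targets(self, rc: float) -> dict[str, float]:
        return {n: float(getattr(self, n)(rc)) for n in SCHEDULED_OBSERVABLES}


#: Window-average noise levels loosely matching the error bars of window-averaged
#: trajectories: a few degrees on the approach angles, ~10 degrees on the
#: torsion, fractions of an angstrom on distances.
_DEFAULT_NOISE = {
    "bd_angle": 5.0,
    "fl_angle": 5.0,
    "tau": 10.0,
    "d_n_o3": 0.15,
    "d_n_p5": 0.15,
    "d_c_o3": 0.05,
    "d_h_o3": 0.05,
}


def _shared_rc_distance_knots() -> dict[str, PiecewiseLinear]:
    # The O3'-H3' bond stays near its 0.96 A equilibrium length until the proton
    # transfers, so early RC progress is almost entirely the nucleophile closing
    # in: d(Ccarb...O3') falls from 4.96 A at RC -4 through ~3.2 A at RC -2.2
    # toward a forming C-O bond.  Both schedules share knot positions so that
    # d(H3'...O3') - d(Ccarb...O3') equals the RC exactly at every point.
    knots = (-4.0, -1.2, 0.0)
    d_c = PiecewiseLinear(knots, (4.96, 2.2, 1.45))
    d_h = PiecewiseLinear(knots, (0.96, 1.0, 1.45))
    return {"d_c_o3": d_c, "d_h_o3": d_h}


def l_ala_like_schedule(noise_sd: Mapping[str, float] | None = None) -> GeometrySchedule:
    """Schedule emulating the L-enantiomer pathway over RC in [-4, 0] A."""
    return GeometrySchedule(
        bd_angle=PiecewiseLinear((-4.0, -1.0, 0.0), (75.0, 105.0, 105.0)),
        fl_angle=PiecewiseLinear((-4.0, 0.0), (0.0, 0.0)),
        d_n_o3=PiecewiseLinear((-4.0, -2.5, -0.75, 0.0), (5.2, 4.2, 3.0, 2.9)),
        d_n_p5=PiecewiseLinear((-4.0, -1.1, -0.5, 0.0), (4.25, 4.25, 4.0, 4.0)),
        tau=PiecewiseLinear((-4.0, -2.2, -0.5, 0.0), (0.0, 0.0, 60.0, 60.0)),
        noise_sd=dict(_DEFAULT_NOISE if noise_sd is None else noise_sd),
        **_shared_rc_distance_knots(),
    )


def d_ala_like_schedule(noise_sd: Mapping[str, float] | None = None) -> GeometrySchedule:
    """Schedule emulating the D-enantiomer pathway, with the cis->trans tau flip
    near RC = -2.2 A and the coupled distance rearrangements."""
    return GeometrySchedule(
        bd_angle=PiecewiseLinear((-4.0, -1.0, 0.0), (75.0, 105.0, 105.0)),
        fl_angle=PiecewiseLinear((-4.0, 0.0), (0.0, 0.0)),
        d_n_o3=PiecewiseLinear(
            (-4.0, -2.5, -2.2, -1.6, 0.0), (5.2, 4.3, 3.3, 3.2, 3.05)
        ),
        d_n_p5=PiecewiseLinear(
            (-4.0, -2.5, -2.2, -0.55, -0.4, 0.0), (4.25, 4.3, 5.1, 5.1, 6.3, 6.3)
        ),
        tau=PiecewiseLinear((-4.0, -2.5, -2.2, 0.0), (0.0, 0.0, 180.0, 180.0)),
        noise_sd=dict(_DEFAULT_NOISE if noise_sd is None else noise_sd),
        **_shared_rc_distance_knots(),
    )


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _place_by_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                       bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom D from internal coordinates relative to chain a-b-c.

    ``angle_deg`` is the b-c-D bond angle, ``torsion_deg`` the a-b-c-D torsion in
    the same handed convention as :func:`chiralpmf.geometry.dihedral`.
    """
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise GeometryConstructionError("reference chain atoms are collinear")
    n_u = n / n_norm
    m_u = np.cross(n_u, bc_u)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def _build_frame(targets: Mapping[str, float], rc: float, *, clamp_unreachable: bool = False) -> GeometryFrame:
    ccarb = np.zeros(3)
    ocarb = np.array([_D_C_OCARB, 0.0, 0.0])
    calpha = _D_C_CALPHA * np.array(
        [np.cos(np.radians(_ANG_OCARB_C_CALPHA)), np.sin(np.radians(_ANG_OCARB_C_CALPHA)), 0.0]
    )
    ob = _D_C_OB * np.array(
        [np.cos(np.radians(_ANG_OCARB_C_OB)), np.sin(np.radians(_ANG_OCARB_C_OB)), 0.0]
    )

    theta = np.radians(targets["bd_angle"])
    phi = np.radians(targets["fl_angle"])
    d_co = targets["d_c_o3"]
    # O3' above the carbonyl plane (+z); positive FL tilts toward Ob (-y side).
    o3 = d_co * np.array(
        [np.cos(theta), -np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
    )
    h3 = o3 * (1.0 + targets["d_h_o3"] / d_co)

    # N: torsion fixed by the schedule, Ccarb-Calpha-N angle solved so that
    # d(N...O3') hits its target.
    def n_at(alpha: float) -> np.ndarray:
        return _place_by_internal(ob, ccarb, calpha, _D_CALPHA_N, alpha, targets["tau"])

    def resid(alpha: float) -> float:
        return float(np.linalg.norm(n_at(alpha) - o3)) - targets["d_n_o3"]

    grid = np.linspace(5.0, 175.0, 69)
    vals = np.array([resid(a) for a in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)
    if sign_change.size == 0:
        if clamp_unreachable:
            # Noisy target outside the reachable band: take the closest distance.
            alpha = float(grid[np.argmin(np.abs(vals))])
        else:
            raise GeometryConstructionError(
                f"d(N...O3') target {targets['d_n_o3']:.3f} A unreachable at rc={rc:.3f} "
                f"(reachable range [{vals.min() + targets['d_n_o3']:.3f}, "
                f"{vals.max() + targets['d_n_o3']:.3f}] A)"
            )
    else:
        # Prefer the solution closest to a tetrahedral angle.
        best = min(sign_change, key=lambda i: abs(0.5 * (grid[i] + grid[i + 1]) - 109.5))
        alpha = brentq(resid, grid[best], grid[best + 1], xtol=1e-13)
    n_pos = n_at(alpha)

    p5 = n_pos + targets["d_n_p5"] * (n_pos - calpha) / np.linalg.norm(n_pos - calpha)

    return GeometryFrame.from_dict(
        {
            "O3'": o3, "H3'": h3, "Ccarb": ccarb, "Ocarb": ocarb,
            "Calpha": calpha, "Ob": ob, "N": n_pos, "P5'": p5,
        },
        rc=rc,
    )


def generate_geometry_frames(
    schedule: GeometrySchedule,
    rc_values: Sequence[float],
    seed: int = 0,
    *,
    noise: bool = True,
) -> list[GeometryFrame]:
    """One frame per RC value, targets interpolated from the schedule.

    With ``noise=True``, each observable target is perturbed by Gaussian noise of
    the schedule's per-observable SD before the frame is constructed, so the
    noise statistics are exactly known in observable space.  Pass the same RC
    value repeatedly to populate an umbrella window.  Deterministic given seed.
    """
    lo, hi = schedule.domain
    rng = np.random.default_rng(seed)
    frames: list[GeometryFrame] = []
    for rc in rc_values:
        if not lo <= rc <= hi:
            raise ValueError(f"rc={rc} outside schedule domain [{lo}, {hi}]")
        targets = schedule.targets(rc)
        if noise:
            for name in SCHEDULED_OBSERVABLES:
                sd = schedule.noise_sd.get(name, 0.0)
                if sd > 0:
                    targets[name] += sd * rng.standard_normal()
            # Keep perturbed targets in their physical ranges.
            targets["bd_angle"] = float(np.clip(targets["bd_angle"], 1.0, 179.0))
            targets["fl_angle"] = float(np.clip(targets["fl_angle"], -89.0, 89.0))
            targets["tau"] = float((targets["tau"] + 180.0) % 360.0 - 180.0)
            for name in ("d_n_o3", "d_n_p5", "d_c_o3", "d_h_o3"):
                targets[name] = max(targets[name], 0.2)
        frames.append(_build_frame(targets, rc=float(rc), clamp_unreachable=noise))
    return frames
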