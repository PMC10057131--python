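"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written by a different route than the library
code it validates: per-sample loops instead of vectorised binning, explicit
rotation matrices instead of cross-product identities, and an unbinned
MBAR-style self-consistent estimator instead of binned WHAM.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def naive_histogram(values, edges):
    """Per-sample half-open [lo, hi) binning by linear scan."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_out = 0
    for v in values:
        placed = False
        for b in range(len(edges) - 1):
            if edges[b] <= v < edges[b + 1]:
                counts[b] += 1
                placed = True
                break
        if not placed:
            n_out += 1
    return counts, n_out


def angle_deg(p1, p2, p3):
    """Planar angle at p2 via explicit normalised dot product."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(max(-1.0, min(1.0, cosang)))))


def _rotation_onto_z(v):
    """Rotation matrix sending unit vector v onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(v @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def torsion_deg(p1, p2, p3, p4):
    """Signed torsion by rotating the central bond onto +z and reading off the
    azimuthal angles of the flanking bonds (clockwise-positive convention)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    R = _rotation_onto_z(p3 - p2)
    a = R @ (p1 - p2)
    d = R @ (p4 - p3)
    phi_a = np.arctan2(a[1], a[0])
    phi_d = np.arctan2(d[1], d[0])
    ang = np.degrees(phi_d - phi_a)  # clockwise-positive viewed along the central bond
    ang = (ang + 180.0) % 360.0 - 180.0
    return 180.0 if ang == -180.0 else float(ang)


def mbar_pmf(series_values, bias_fns, kbt, edges):
    """Unbinned MBAR-style estimator: window free energies by direct minimisation
    of the convex MBAR objective over the pooled samples, then a weighted
    histogram of unbiased sample weights.  Returns (bin centers, anchored PMF
    with NaN for empty bins, window free energies)."""
    from scipy.optimize import minimize

    xs = np.concatenate(series_values)
    N = np.array([len(v) for v in series_values], dtype=float)
    n_tot = N.sum()
    # u[i, n] = bias of window i at sample n, in kBT units
    u = np.array([fn(xs) / kbt for fn in bias_fns])

    def objective(f):
        log_denom = logsumexp(f[:, None] - u, b=N[:, None], axis=0)
        val = log_denom.sum() - N @ f
        # gradient: N_i * (sum_n W_in - 1) with W_in the normalised weights
        W = np.exp(f[:, None] - u - log_denom[None, :])
        grad = N * (W.sum(axis=1)) - N
        return val, grad

    res = minimize(objective, np.zeros(len(N)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    f = res.x - res.x[0]
    log_w = -logsumexp(f[:, None] - u, b=N[:, None], axis=0)
    w = np.exp(log_w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pmf = np.full(len(centers), np.nan)
    idx = np.digitize(xs, edges) - 1
    for b in range(len(centers)):
        m = idx == b
        if m.any():
            pmf[b] = -kbt * np.log(w[m].sum())
    pmf -= np.nanmin(pmf)
    return centers, pmf, f * kbt


def place_by_internal_reference(a, b, c, bond, angle_deg_, torsion_deg_):
    """Internal-coordinate atom placement via explicit rotations (reference for
    torsion fixtures): positions atom D with given bond length from c, bond
    angle b-c-D and torsion a-b-c-D in the clockwise-positive convention."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    R = _rotation_onto_z(c - b)
    a_loc = R @ (a - b)
    phi_a = np.arctan2(a_loc[1], a_loc[0])
    phi_d = phi_a + np.radians(torsion_deg_)
    theta = np.radians(180.0 - angle_deg_)  # polar angle from +z at c
    d_loc = np.array(
        [
            bond * np.sin(theta) * np.cos(phi_d),
            bond * np.sin(theta) * np.sin(phi_d),
            np.linalg.norm(c - b) + bond * np.cos(theta),
        ]
    )
    return np.linalg.inv(R) @ d_loc + b


def random_rotation(rng):
    """Haar-ish random rotation from QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
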