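"""Reaction-site approach geometry: Burgi-Dunitz / Flippin-Lodge angles, key
distances and the amino-backbone dihedral, with per-window aggregation.

The eight labeled atoms of the acyl-transfer reaction site are, in canonical
order: O3' (attacking 3'-hydroxyl oxygen), H3' (its proton), Ccarb and Ocarb
(carbonyl carbon and oxygen), Calpha (amino-acid alpha carbon), Ob (bridging
phosphate oxygen), N (amino nitrogen) and P5' (5'-phosphate phosphorus).

Observables:

* Burgi-Dunitz (BD) angle — the O3'...Ccarb=Ocarb angle describing the
  out-of-plane approach of the nucleophile to the carbonyl (canonically ~105
  degrees near a transition state).
* Flippin-Lodge (FL) angle — the in-carbonyl-plane offset of the approach,
  measured as the signed angle between the plane (O3', Ccarb, Ocarb) and the
  reference plane through the C=O axis perpendicular to the carbonyl plane;
  positive when the nucleophile tilts toward the bridging oxygen Ob.
* tau(Ob-Ccarb-Calpha-N) — signed torsion distinguishing cis (~0 deg) from trans
  (~±180 deg) conformations of the aminoacyl backbone.
* d(N...O3'), d(N...P5'), d(Ccarb...O3'), d(H3'...O3') — the electrostatic-contact
  and reaction-coordinate distances; RC = d(H3'...O3') - d(Ccarb...O3').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import circmean, circstd

from .core import reaction_coordinate_value

__all__ = [
    "ATOM_LABELS",
    "GeometryFrame",
    "KeyDistances",
    "WindowedObservable",
    "bd_angle",
    "fl_angle",
    "dihedral",
    "key_distances",
    "window_statistics",
    "OBSERVABLES",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
]

#: Canonical atom order for frames and XYZ files.
ATOM_LABELS: tuple[str, ...] = ("O3'", "H3'", "Ccarb", "Ocarb", "Calpha", "Ob", "N", "P5'")
_INDEX = {label: i for i, label in enumerate(ATOM_LABELS)}


@dataclass(frozen=True)
class GeometryFrame:
    """One labeled snapshot of the eight reaction-site atoms (coordinates in A)."""

    coords: np.ndarray                 # shape (8, 3), rows in ATOM_LABELS order
    rc: float | None = None            # reaction-coordinate tag, else derived

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(ATOM_LABELS), 3):
            raise ValueError(f"coords must have shape {(len(ATOM_LABELS), 3)}, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        diff = c[:, None, :] - c[None, :, :]
        d = np.sqrt((diff * diff).sum(axis=-1))
        iu = np.triu_indices(len(ATOM_LABELS), k=1)
        if np.any(d[iu] <= 1e-6):
            i, j = iu[0][d[iu] <= 1e-6][0], iu[1][d[iu] <= 1e-6][0]
            raise ValueError(f"atoms {ATOM_LABELS[i]} and {ATOM_LABELS[j]} coincide")
        object.__setattr__(self, "coords", c)

    @classmethod
    def from_dict(cls, atoms: Mapping[str, Sequence[float]], rc: float | None = None):
        missing = [label for label in ATOM_LABELS if label not in atoms]
        if missing:
            raise ValueError(f"missing atom label(s): {', '.join(missing)}")
        return cls(np.array([atoms[label] for label in ATOM_LABELS], dtype=float), rc=rc)

    def position(self, label: str) -> np.ndarray:
        try:
            return self.coords[_INDEX[label]]
        except KeyError:
            raise ValueError(f"unknown atom label {label!r}") from None

    @property
    def reaction_coordinate(self) -> float:
        if self.rc is not None:
            return self.rc
        return key_distances(self).rc


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-10:
        raise ValueError(f"degenerate geometry: {what} has zero length")
    return v / n


def bd_angle(frame: GeometryFrame) -> float:
    """Burgi-Dunitz angle O3'...Ccarb=Ocarb in degrees, range [0, 180]."""
    c = frame.position("Ccarb")
    u = _unit(frame.position("O3'") - c, "Ccarb->O3' vector")
    v = _unit(frame.position("Ocarb") - c, "Ccarb->Ocarb vector")
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def _carbonyl_normal(frame: GeometryFrame) -> np.ndarray:
    """Unit normal of the least-squares plane through Ccarb, Ocarb, Calpha, Ob."""
    pts = np.array([frame.position(a) for a in ("Ccarb", "Ocarb", "Calpha", "Ob")])
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise ValueError("carbonyl-plane atoms are collinear; plane undefined")
    return vt[2]


def fl_angle(frame: GeometryFrame) -> float:
    """Flippin-Lodge angle in signed degrees, principal range [-90, 90].

    The magnitude is the angle between the plane (O3', Ccarb, Ocarb) and the
    reference plane through the C=O axis perpendicular to the carbonyl plane
    (least-squares plane of Ccarb, Ocarb, Calpha, Ob), i.e. the lateral tilt of
    the nucleophile's approach; 0 means a symmetric approach above the carbonyl,
    90 an in-carbonyl-plane approach.

    The sign is handed: measured about the directed Ccarb->Ocarb axis by the
    right-hand rule, starting from the carbonyl normal taken on the nucleophile's
    side.  On the approach face these reaction systems (and the synthetic frame
    generator) realise, this handed sign coincides with the chemical convention
    "positive when O3' tilts toward the bridging oxygen Ob" — while, being a
    triple product, it flips under mirror reflection of the frame, which is what
    makes the observable sensitive to the chirality of the reaction site.
    """
    c = frame.position("Ccarb")
    axis = _unit(frame.position("Ocarb") - c, "C=O axis")
    n = _carbonyl_normal(frame)
    n = n - (n @ axis) * axis
    n = _unit(n, "carbonyl normal after removing the C=O axis component")

    u = frame.position("O3'") - c
    p = u - (u @ axis) * axis
    p_norm = float(np.linalg.norm(p))
    if p_norm < 1e-10:
        return 0.0  # O3' exactly on the C=O axis: no lateral tilt
    comp_n = float(p @ n)
    if abs(comp_n) < 1e-12 * p_norm:
        # O3' exactly in the carbonyl plane: boundary case, signed toward Ob.
        ob = frame.position("Ob") - c
        ob_perp = ob - (ob @ axis) * axis
        return 90.0 if float(p @ ob_perp) > 0 else -90.0
    n_side = n if comp_n > 0 else -n
    y = float(np.cross(n_side, p) @ axis)
    x = float(p @ n_side)
    return float(np.degrees(np.arctan2(y, x)))


def dihedral(
    frame: GeometryFrame,
    atoms: tuple[str, str, str, str] = ("Ob", "Ccarb", "Calpha", "N"),
) -> float:
    """Signed torsion angle of ``atoms`` in degrees, principal range (-180, 180].

    Standard polymer convention: viewed along the central bond (second toward
    third atom), the angle is positive when the far bond is rotated clockwise
    from the near bond.  0 is cis (eclipsed), ±180 is trans.
    """
    a, b, c, d = (frame.position(x) for x in atoms)
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("three consecutive dihedral atoms are collinear")
    y = float(np.cross(n1, n2) @ _unit(b2, "central bond"))
    x = float(n1 @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass(frozen=True)
class KeyDistances:
    d_n_o3: float
    d_n_p5: float
    d_c_o3: float
    d_h_o3: float

    @property
    def rc(self) -> float:
        return reaction_coordinate_value(self.d_h_o3, self.d_c_o3)


def key_distances(frame: GeometryFrame) -> KeyDistances:
    """The four monitored distances, with the frame RC derived from two of them."""
    def d(a: str, b: str) -> float:
        return float(np.linalg.norm(frame.position(a) - frame.position(b)))

    return KeyDistances(
        d_n_o3=d("N", "O3'"),
        d_n_p5=d("N", "P5'"),
        d_c_o3=d("Ccarb", "O3'"),
        d_h_o3=d("H3'", "O3'"),
    )


#: Named observable extractors usable with :func:`window_statistics`.
OBSERVABLES: dict[str, Callable[[GeometryFrame], float]] = {
    "bd_angle": bd_angle,
    "fl_angle": fl_angle,
    "tau": dihedral,
    "d_n_o3": lambda f: key_distances(f).d_n_o3,
    "d_n_p5": lambda f: key_distances(f).d_n_p5,
    "d_c_o3": lambda f: key_distances(f).d_c_o3,
    "d_h_o3": lambda f: key_distances(f).d_h_o3,
}

#: Observables that live on a circle and need circular statistics near the
#: wrap-around at ±180 degrees.
CIRCULAR_OBSERVABLES = {"tau"}


@dataclass(frozen=True)
class WindowedObservable:
    """Per-window mean and spread of one observable."""

    center: float
    mean: float
    sd: float
    n: int
    circular: bool = False


def window_statistics(
    groups: Mapping[float, Sequence[GeometryFrame]],
    observable: str | Callable[[GeometryFrame], float],
    *,
    circular: bool = False,
    rc_range: tuple[float, float] = (-4.0, 0.0),
) -> list[WindowedObservable]:
    """Aggregate an observable over frames grouped by umbrella-window center.

    ``observable`` is a name from :data:`OBSERVABLES` or any callable mapping a
    frame to a float.  With ``circular=True`` the mean is the vector (circular)
    mean on (-180, 180] degrees and the spread the circular standard deviation —
    required for torsions that hop between +179 and -179.  Only windows whose
    center falls inside ``rc_range`` are reported; empty groups are skipped with
    a warning.
    """
    func = OBSERVABLES[observable] if isinstance(observable, str) else observable
    lo, hi = rc_range
    out: list[WindowedObservable] = []
    for center in sorted(groups):
        if not lo <= center <= hi:
            continue
        frames = groups[center]
        if len(frames) == 0:
            warnings.warn(f"window {center}: no frames, skipped", stacklevel=2)
            continue
        vals = np.array([func(f) for f in frames], dtype=float)
        if circular:
            mean = float(circmean(vals, low=-180.0, high=180.0))
            if mean <= -180.0:
                mean += 360.0
            sd = float(circstd(vals, low=-180.0, high=180.0))
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(WindowedObservable(center=center, mean=mean, sd=sd, n=len(vals), circular=circular))
    return out


# ---------------------------------------------------------------------------
# Frame I/O: multi-frame XYZ (canonical atom order) and minimal PDB
# ---------------------------------------------------------------------------

def write_xyz(frames: Sequence[GeometryFrame], path) -> None:
    """Multi-frame XYZ with the canonical 8-atom order; RC tagged in the comment."""
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{len(ATOM_LABELS)}\n")
            fh.write(f"rc= {f.reaction_coordinate:.6f}\n" if f.rc is not None else "\n")
            for label, xyz in zip(ATOM_LABELS, f.coords):
                fh.write(f"{label:8s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n")


def read_xyz(path) -> list[GeometryFrame]:
    frames: list[GeometryFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        rc = None
        if "rc=" in comment:
            rc = float(comment.split("rc=")[1].split()[0])
        atoms: dict[str, list[float]] = {}
        for j in range(n):
            parts = lines[i + 2 + j].split()
            atoms[parts[0]] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(GeometryFrame.from_dict(atoms, rc=rc))
        i += 2 + n
    return frames


#: Default PDB atom-name mapping (PDB name -> canonical label).
DEFAULT_PDB_NAME_MAP: dict[str, str] = {
    "O3'": "O3'",
    "H3'": "H3'",
    "C": "Ccarb",
    "O": "Ocarb",
    "CA": "Calpha",
    "OB": "Ob",
    "N": "N",
    "P": "P5'",
}
_PDB_WRITE_NAMES = {v: k for k, v in DEFAULT_PDB_NAME_MAP.items()}


def write_pdb(frames: Sequence[GeometryFrame], path) -> None:
    """Minimal multi-MODEL PDB with one 8-atom residue per frame."""
    with open(path, "w") as fh:
        for m, f in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for serial, label in enumerate(ATOM_LABELS, start=1):
                x, y, z = f.position(label)
                name = _PDB_WRITE_NAMES[label]
                element = label[0]
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} RXN A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path, name_map: Mapping[str, str] | None = None) -> list[GeometryFrame]:
    """Read frames from a (multi-MODEL) PDB, selecting atoms via ``name_map``."""
    name_map = dict(DEFAULT_PDB_NAME_MAP if name_map is None else name_map)
    frames: list[GeometryFrame] = []
    atoms: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                pdb_name = line[12:16].strip()
                label = name_map.get(pdb_name)
                if label is not None:
                    atoms[label] = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            elif rec == "ENDMDL" and atoms:
                frames.append(GeometryFrame.from_dict(atoms))
                atoms = {}
    if atoms:
        frames.append(GeometryFrame.from_dict(atoms))
    return frames
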