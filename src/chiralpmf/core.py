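"""Shared domain types for umbrella sampling along an aminoacylation reaction coordinate.

The reaction coordinate (RC) for the acyl-transfer reaction is a difference of two
distances at the reaction site,

    RC = d(H3'...O3') - d(Ccarb...O3')   [angstrom],

negative in the reactant state (hydroxyl intact, carbonyl carbon far) and positive
once the aminoacyl group has transferred.  Umbrella windows restrain the RC with a
harmonic bias; this module holds the window schedule, the bias potential, physical
constants and a small ion-neutralisation utility.

Units are fixed package-wide: angstrom, kcal/mol, kelvin, femtosecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "KB_KCAL_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "kt",
    "WindowSpec",
    "ScheduleSegment",
    "IonInventory",
    "ScheduleError",
    "build_window_schedule",
    "bias_energy",
    "reaction_coordinate_value",
    "required_anions_for_neutrality",
    "write_schedule_tsv",
    "read_schedule_tsv",
    "write_wham_metadata",
    "read_wham_metadata",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K: float = 0.0019872041

#: Simulation temperature used throughout unless overridden.
DEFAULT_TEMPERATURE_K: float = 300.0


def kt(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in kcal/mol (0.59616 kcal/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature


class ScheduleError(ValueError):
    """Raised when umbrella-window segments overlap or are otherwise inconsistent."""


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: harmonic restraint centred at ``center``.

    Parameters
    ----------
    index:
        Position of the window in the schedule, 0-based.
    center:
        Restraint target RC value (angstrom).
    force_constant:
        Harmonic force constant k in kcal/mol/A^2.  The bias is
        ``0.5 * k * (rc - center)**2`` by default (see :func:`bias_energy`).
    n_equil_samples, n_prod_samples:
        Samples discarded as equilibration / retained as production.
    sample_interval:
        Time between collected samples, fs.
    """

    index: int
    center: float
    force_constant: float = 500.0
    n_equil_samples: int = 2000
    n_prod_samples: int = 4000
    sample_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"window index must be >= 0, got {self.index}")
        if self.force_constant <= 0:
            raise ValueError(f"force_constant must be > 0, got {self.force_constant}")
        if self.n_equil_samples < 0:
            raise ValueError("n_equil_samples must be >= 0")
        if self.n_prod_samples <= 0:
            raise ValueError("n_prod_samples must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")


@dataclass(frozen=True)
class ScheduleSegment:
    """A uniformly spaced run of window centers, ``start`` to ``stop`` by ``step``.

    Boundary ownership is explicit: ``include_start``/``include_stop`` decide
    whether the exact endpoints generate windows, which is how two segments can
    share a boundary value without duplicating it.
    """

    start: float
    stop: float
    step: float
    include_start: bool = True
    include_stop: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if not self.start < self.stop:
            raise ValueError(f"start ({self.start}) must be < stop ({self.stop})")

    def centers(self) -> list[float]:
        """Window centers by integer stepping, rounded to 3 decimals.

        Integer stepping (center = start + i*step) followed by rounding makes the
        schedule immune to floating-point drift: a boundary shared between two
        segments resolves to the same 3-decimal value in both.
        """
        out: list[float] = []
        n = int(round((self.stop - self.start) / self.step))
        for i in range(n + 1):
            c = round(self.start + i * self.step, 3)
            if c < round(self.start, 3) or c > round(self.stop, 3):
                continue
            if c == round(self.start, 3) and not self.include_start:
                continue
            if c == round(self.stop, 3) and not self.include_stop:
                continue
            out.append(c)
        return out


# Default segment layout of the umbrella campaign: coarse 0.1 A spacing on the flanks,
# fine 0.05 A spacing through the barrier region [-1.5, 1.5], 101 windows total.
DEFAULT_SEGMENTS: tuple[ScheduleSegment, ...] = (
    ScheduleSegment(-4.0, -1.5, 0.1, include_start=True, include_stop=False),
    ScheduleSegment(-1.5, 1.5, 0.05, include_start=True, include_stop=True),
    ScheduleSegment(1.5, 3.0, 0.1, include_start=False, include_stop=True),
)


def build_window_schedule(
    segments: Iterable[ScheduleSegment],
    *,
    force_constant: float = 500.0,
    n_equil_samples: int = 2000,
    n_prod_samples: int = 4000,
    sample_interval: float = 5.0,
) -> list[WindowSpec]:
    """Expand schedule segments into an ordered list of umbrella windows.

    Raises
    ------
    ScheduleError
        If, after applying the boundary-inclusion flags, any two segments produce
        the same center or centers out of order.
    """
    centers: list[float] = []
    for seg in segments:
        centers.extend(seg.centers())
    if not centers:
        raise ScheduleError("segments produced no window centers")
    for a, b in zip(centers, centers[1:]):
        if b == a:
            raise ScheduleError(f"duplicate window center {a} after boundary resolution")
        if b < a:
            raise ScheduleError(f"window centers not increasing: {a} then {b}")
    return [
        WindowSpec(
            index=i,
            center=c,
            force_constant=force_constant,
            n_equil_samples=n_equil_samples,
            n_prod_samples=n_prod_samples,
            sample_interval=sample_interval,
        )
        for i, c in enumerate(centers)
    ]


def bias_energy(rc: float, window: WindowSpec, *, half_prefactor: bool = True) -> float:
    """Harmonic umbrella bias at RC value ``rc``, kcal/mol.

    Default convention is ``0.5 * k * (rc - center)**2``.  ``half_prefactor=False``
    switches to ``k * (rc - center)**2`` (the AMBER NMR-restraint convention); both
    appear in the umbrella-sampling literature and published force constants are
    ambiguous between them, so the choice is explicit and propagates to WHAM.
    """
    d = rc - window.center
    e = window.force_constant * d * d
    return 0.5 * e if half_prefactor else e


def reaction_coordinate_value(d_ho: float, d_co: float) -> float:
    """RC = d(H3'...O3') - d(Ccarb...O3'), both distances in angstrom."""
    if d_ho < 0 or d_co < 0:
        raise ValueError(f"distances must be non-negative, got {d_ho}, {d_co}")
    return d_ho - d_co


@dataclass(frozen=True)
class IonInventory:
    """Ion bookkeeping for neutralising a charged solute (charges in units of e)."""

    solute_charge: int
    n_divalent_cations: int = 0
    n_monovalent_cations: int = 0
    n_monovalent_anions: int = 0

    def __post_init__(self) -> None:
        for name in ("n_divalent_cations", "n_monovalent_cations", "n_monovalent_anions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def net_charge(self) -> int:
        return (
            self.solute_charge
            + 2 * self.n_divalent_cations
            + self.n_monovalent_cations
            - self.n_monovalent_anions
        )


def required_anions_for_neutrality(inventory: IonInventory) -> int:
    """Number of monovalent anions needed to bring the system to zero net charge.

    Ignores any anions already present in ``inventory``.
    """
    n = inventory.solute_charge + 2 * inventory.n_divalent_cations + inventory.n_monovalent_cations
    if n < 0:
        raise ValueError(
            f"system has net negative charge {n}; cannot be neutralised by anions alone"
        )
    return n


# ---------------------------------------------------------------------------
# Schedule serialisation
# ---------------------------------------------------------------------------

def write_schedule_tsv(windows: Sequence[WindowSpec], path) -> None:
    """Write the schedule as TSV: index, center, force_constant."""
    with open(path, "w") as fh:
        fh.write("index\tcenter\tforce_constant\n")
        for w in windows:
            fh.write(f"{w.index}\t{w.center:.3f}\t{w.force_constant:g}\n")


def read_schedule_tsv(path, **kwargs) -> list[WindowSpec]:
    windows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("index"):
            raise ValueError(f"{path}: expected TSV header starting with 'index'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            windows.append(
                WindowSpec(
                    index=int(parts[0]),
                    center=float(parts[1]),
                    force_constant=float(parts[2]),
                    **kwargs,
                )
            )
    return windows


def write_wham_metadata(windows: Sequence[WindowSpec], series_paths: Sequence[str], path) -> None:
    """Write a Grossfield-style metadata file: one ``path center k`` line per window."""
    if len(windows) != len(series_paths):
        raise ValueError("need exactly one series path per window")
    with open(path, "w") as fh:
        for w, sp in zip(windows, series_paths):
            fh.write(f"{sp} {w.center:.3f} {w.force_constant:g}\n")


def read_wham_metadata(path, **kwargs) -> tuple[list[WindowSpec], list[str]]:
    """Read a Grossfield-style metadata file; returns (windows, series paths)."""
    windows: list[WindowSpec] = []
    paths: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'path center force-constant', got {stripped!r}"
                )
            paths.append(parts[0])
            windows.append(
                WindowSpec(
                    index=len(windows),
                    center=float(parts[1]),
                    force_constant=float(parts[2]),
                    **kwargs,
                )
            )
    return windows, paths
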