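"""Overdamped Langevin sampling of biased umbrella windows on a model surface.

The synthetic stand-in for the MD engine: a single reaction coordinate x evolves
by Euler-Maruyama integration of the overdamped (Brownian) Langevin equation

    dx = -(1/gamma) * d(G + w)/dx * dt + sqrt(2 kB T dt / gamma) * N(0, 1)

under the model free energy G(x) plus the window's harmonic bias w(x).  Inertia is
deliberately absent: WHAM only consumes the stationary distribution, which for
this dynamics is exactly proportional to exp(-(G + w)/kB T), so the generator's
fidelity target — the sampling measure — is analytically characterisable.

The friction gamma (kcal/mol * fs / A^2) and the time step dt (fs) are integrator
knobs, not physical parameters: dt is chosen small enough that the Euler-Maruyama
variance bias in a k = 500 kcal/mol/A^2 window stays well under 2% (the discrete
stationary variance exceeds kB T/k by a factor 1/(1 - k dt / 2 gamma)), and gamma
so that the relaxation time gamma/k is comparable to the 5 fs sampling cadence,
keeping consecutive samples close to independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .core import WindowSpec, kt, write_wham_metadata
from .surfaces import ModelSurface
from .wham import BiasedSeries, write_series_file

__all__ = ["LangevinParams", "simulate_window", "generate_campaign", "window_seed"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings for the overdamped sampler (units: fs, K, kcal/mol, A)."""

    dt: float = 0.05
    friction: float = 1000.0
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def window_seed(master_seed: int, window_index: int) -> int:
    """Deterministic, well-separated per-window seed derived from a master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(window_index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@njit(cache=True)
def _integrate(amps, centers, widths, slope,
               k_eff, bias_center,
               dt, gamma, kbt, lo, hi,
               x0, n_equil_steps, n_samples, n_sub, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    sigma = np.sqrt(2.0 * kbt * dt / gamma)
    inv_gamma = dt / gamma
    x = x0
    n_reflect = 0
    out = np.empty(n_samples)
    total = n_equil_steps + n_samples * n_sub
    j_out = 0
    for step in range(total):
        g = slope + k_eff * (x - bias_center)
        for j in range(amps.size):
            d = (x - centers[j]) / widths[j]
            g -= (amps[j] / widths[j]) * d * np.exp(-0.5 * d * d)
        x = x - g * inv_gamma + sigma * np.random.normal()
        if x < lo:
            x = 2.0 * lo - x
            n_reflect += 1
        elif x > hi:
            x = 2.0 * hi - x
            n_reflect += 1
        if step >= n_equil_steps and (step - n_equil_steps + 1) % n_sub == 0:
            out[j_out] = x
            j_out += 1
    return out, x, n_reflect


def simulate_window(
    surface: ModelSurface,
    window: WindowSpec,
    params: LangevinParams,
    *,
    x0: float | None = None,
    half_prefactor: bool = True,
    seed: int | None = None,
) -> tuple[BiasedSeries, float]:
    """Sample one umbrella window; returns (series, final coordinate).

    The trajectory starts at ``x0`` (default: the window center, clipped into the
    surface domain), runs ``n_equil_samples * sample_interval`` of discarded
    equilibration, then records ``n_prod_samples`` values every
    ``sample_interval`` fs.  Excursions beyond the surface domain are reflected
    and counted; more than 1% reflected steps logs a warning.
    """
    lo, hi = surface.domain
    if not lo <= window.center <= hi:
        raise ValueError(
            f"window center {window.center} outside surface domain [{lo}, {hi}]"
        )
    if x0 is None:
        x0 = float(np.clip(window.center, lo, hi))
    n_sub = max(1, int(round(window.sample_interval / params.dt)))
    n_equil_steps = window.n_equil_samples * n_sub
    k_eff = window.force_constant if half_prefactor else 2.0 * window.force_constant
    amps, centers, widths = surface._params()
    use_seed = params.seed if seed is None else seed
    values, x_final, n_reflect = _integrate(
        amps, centers, widths, surface.linear_slope,
        k_eff, window.center,
        params.dt, params.friction, kt(params.temperature), lo, hi,
        x0, n_equil_steps, window.n_prod_samples, n_sub, use_seed,
    )
    total_steps = n_equil_steps + window.n_prod_samples * n_sub
    if n_reflect > 0.01 * total_steps:
        logger.warning(
            "window %d: %.1f%% of steps reflected at the domain boundary",
            window.index, 100.0 * n_reflect / total_steps,
        )
    series = BiasedSeries(
        window_index=window.index,
        values=values,
        sample_interval=window.sample_interval,
        n_reflections=int(n_reflect),
    )
    return series, float(x_final)


def generate_campaign(
    surface: ModelSurface,
    schedule: Sequence[WindowSpec],
    params: LangevinParams,
    *,
    half_prefactor: bool = True,
    out_dir: str | Path | None = None,
    series_name: str = "window_{index:03d}.dat",
    metadata_name: str = "wham_metadata.txt",
) -> list[BiasedSeries]:
    """Run every window of an umbrella schedule on one surface.

    Windows run in schedule order and each one starts from the final coordinate of
    the previous window (the first starts at its own center), mimicking how
    umbrella campaigns are seeded from the neighbouring window's equilibrated
    state.  Per-window seeds derive deterministically from ``params.seed``, so the
    campaign is reproducible and individual windows are statistically independent.

    If ``out_dir`` is given, writes one two-column series file per window plus a
    Grossfield-style metadata file, and returns the series as well.
    """
    all_series: list[BiasedSeries] = []
    x_prev: float | None = None
    for w in schedule:
        try:
            series, x_prev = simulate_window(
                surface, w, params,
                x0=x_prev, half_prefactor=half_prefactor,
                seed=window_seed(params.seed, w.index),
            )
        except Exception as exc:
            raise RuntimeError(f"window {w.index} (center {w.center}): {exc}") from exc
        all_series.append(series)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for w, s in zip(schedule, all_series):
            name = series_name.format(index=w.index)
            write_series_file(s, out / name)
            paths.append(name)
        write_wham_metadata(schedule, paths, out / metadata_name)
    return all_series
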