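"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Combines biased reaction-coordinate histograms from many umbrella windows into one
unbiased potential of mean force (PMF) by self-consistent iteration of the WHAM
equations

    P(b) = sum_i n_i(b) / sum_i N_i exp((f_i - w_i(x_b)) / kB T)
    f_i  = -kB T ln sum_b P(b) exp(-w_i(x_b) / kB T)

where n_i(b) are per-window bin counts, N_i the window totals, w_i the harmonic
bias evaluated at the bin center and f_i the window free energies.  Convergence is
monitored as the maximum absolute change of any f_i per iteration, in kcal/mol
(default tolerance 1e-7).  Per-bin statistical uncertainties come from a Monte
Carlo bootstrap: each window's sample set is resampled with replacement and the
whole WHAM solve repeated per replicate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .core import WindowSpec, DEFAULT_TEMPERATURE_K, kt

__all__ = [
    "BiasedSeries",
    "WHAMConfig",
    "HistogramSet",
    "PMFProfile",
    "BootstrapResult",
    "WHAMError",
    "histogram_windows",
    "solve_wham",
    "bootstrap_pmf",
    "read_series_file",
    "write_series_file",
    "write_pmf_tsv",
    "read_pmf_tsv",
    "write_pmf_sidecar",
]


class WHAMError(RuntimeError):
    pass


@dataclass(frozen=True)
class BiasedSeries:
    """Reaction-coordinate samples collected in one umbrella window."""

    window_index: int
    values: np.ndarray
    sample_interval: float = 5.0
    n_reflections: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must all be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WHAMConfig:
    """Estimator settings.

    ``rc_range`` of None means: data min/max padded by one bin.  ``tolerance`` is
    on max |delta f_i| per iteration in kcal/mol.  ``anchor_rc_max`` bounds the
    reactant region used to zero the PMF (the profile minimum at RC below this
    value is shifted to zero; if no defined bin lies there, the global minimum is
    used instead).  ``half_prefactor`` selects the bias convention and must match
    the one used during sampling.
    """

    bin_width: float = 0.02
    rc_range: tuple[float, float] | None = None
    tolerance: float = 1e-7
    max_iterations: int = 100_000
    temperature: float = DEFAULT_TEMPERATURE_K
    half_prefactor: bool = True
    anchor_rc_max: float = -2.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class HistogramSet:
    """Per-window counts on a shared binning; ``n_out`` counts out-of-range samples."""

    bin_edges: np.ndarray
    counts: np.ndarray          # shape (n_windows, n_bins)
    n_in: np.ndarray            # per-window in-range totals
    n_out: np.ndarray           # per-window out-of-range totals

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PMFProfile:
    """Binned PMF with window free energies and optional bootstrap uncertainty.

    Bins never visited by any window carry NaN in ``free_energy`` and False in
    ``defined``; they are not numbers and must not be treated as such.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    window_free_energies: np.ndarray
    counts: np.ndarray
    n_iterations: int
    converged: bool
    temperature: float = DEFAULT_TEMPERATURE_K
    bootstrap_sd: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def histogram_windows(series: Sequence[BiasedSeries], cfg: WHAMConfig) -> HistogramSet:
    """Histogram every window's samples on a shared half-open [lo, hi) binning.

    A value exactly on an interior bin edge belongs to the bin on its right.
    Raises :class:`WHAMError` if any window has no samples inside the range.
    """
    if not series:
        raise WHAMError("no series supplied")
    bw = cfg.bin_width
    if cfg.rc_range is None:
        vmin = min(float(s.values.min()) for s in series)
        vmax = max(float(s.values.max()) for s in series)
        lo, hi = vmin - bw, vmax + bw
    else:
        lo, hi = cfg.rc_range
        if not lo < hi:
            raise ValueError("rc_range must satisfy lo < hi")
    n_bins = int(np.ceil((hi - lo) / bw - 1e-9))
    edges = lo + bw * np.arange(n_bins + 1)

    counts = np.zeros((len(series), n_bins), dtype=np.int64)
    n_in = np.zeros(len(series), dtype=np.int64)
    n_out = np.zeros(len(series), dtype=np.int64)
    for row, s in enumerate(series):
        idx = np.floor((s.values - lo) / bw).astype(np.int64)
        ok = (idx >= 0) & (idx < n_bins) & (s.values < edges[-1])
        np.add.at(counts[row], idx[ok], 1)
        n_in[row] = int(ok.sum())
        n_out[row] = int(s.values.size - ok.sum())
        if n_in[row] == 0:
            raise WHAMError(
                f"window {s.window_index}: no samples fall inside the histogram range "
                f"[{lo:g}, {hi:g})"
            )
    return HistogramSet(bin_edges=edges, counts=counts, n_in=n_in, n_out=n_out)


def _bias_matrix(centers: np.ndarray, windows: Sequence[WindowSpec], half: bool) -> np.ndarray:
    k = np.array([w.force_constant for w in windows])
    x0 = np.array([w.center for w in windows])
    d = centers[None, :] - x0[:, None]
    w = k[:, None] * d * d
    return 0.5 * w if half else w


def solve_wham(
    hists: HistogramSet,
    windows: Sequence[WindowSpec],
    cfg: WHAMConfig,
    *,
    f_init: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solve on pre-binned data.

    Window free energies start at zero (or ``f_init`` for warm starts, e.g. in the
    bootstrap) and iterate until the largest |delta f_i| drops below the
    configured tolerance.  The step is halved only when successive increment
    vectors point in opposite directions (oscillation), which leaves the fixpoint
    untouched.  Non-convergence returns an honest ``converged=False`` profile and
    a warning rather than raising.
    """
    if len(windows) != hists.counts.shape[0]:
        raise ValueError("number of windows must match histogram rows")
    if len(windows) == 0:
        raise WHAMError("need at least one window")
    total = hists.counts.sum(axis=0).astype(float)
    if not np.any(total > 0):
        raise WHAMError("all histograms are empty")

    centers = hists.bin_centers
    kbt = kt(cfg.temperature)
    W = _bias_matrix(centers, windows, cfg.half_prefactor)  # (n_win, n_bins)
    if len(windows) > 1:
        occupied = hists.counts > 0
        for i in range(len(windows) - 1):
            if not np.any(occupied[i] & occupied[i + 1]):
                warnings.warn(
                    f"windows {windows[i].index} and {windows[i + 1].index} share no "
                    "occupied histogram bin; the PMF may be disconnected",
                    stacklevel=2,
                )
    boltz = np.exp(-W / kbt)                                # underflows cleanly to 0
    N = hists.n_in.astype(float)

    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    prev_delta = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        # P(b) up to normalisation; empty bins stay exactly zero.
        denom = (N[:, None] * np.exp(f[:, None] / kbt) * boltz).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, total / denom, 0.0)
        z = boltz @ p
        f_new = -kbt * np.log(z)
        f_new -= f_new[0]
        delta = f_new - f
        if prev_delta is not None and float(delta @ prev_delta) < 0:
            delta = 0.5 * delta
        f = f + delta
        prev_delta = delta
        if float(np.max(np.abs(delta))) < cfg.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {cfg.max_iterations} iterations "
            f"(last max |delta f| = {float(np.max(np.abs(delta))):.3g})",
            stacklevel=2,
        )

    denom = (N[:, None] * np.exp(f[:, None] / kbt) * boltz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, total / denom, np.nan)
        pmf = -kbt * np.log(p)

    defined = np.isfinite(pmf)
    anchor_mask = defined & (centers <= cfg.anchor_rc_max)
    if not np.any(anchor_mask):
        anchor_mask = defined
    pmf = pmf - np.nanmin(pmf[anchor_mask])

    return PMFProfile(
        bin_centers=centers,
        free_energy=pmf,
        window_free_energies=f,
        counts=total,
        n_iterations=it,
        converged=converged,
        temperature=cfg.temperature,
    )


@dataclass(frozen=True)
class BootstrapResult:
    bin_sd: np.ndarray
    window_free_energy_sd: np.ndarray
    n_replicates: int
    n_dropped: int


def bootstrap_pmf(
    series: Sequence[BiasedSeries],
    windows: Sequence[WindowSpec],
    cfg: WHAMConfig,
    n_boot: int,
    seed: int,
    *,
    block_length: int | None = None,
) -> BootstrapResult:
    """Monte Carlo bootstrap of the PMF.

    Each replicate resamples every window's value set with replacement (contiguous
    blocks of ``block_length`` if given, to respect autocorrelation) and reruns
    the full WHAM solve, warm-started from the reference solution.  Replicates
    that fail to converge are dropped and counted; more than 20% dropped is an
    error.  Deterministic for a given seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if block_length is not None and block_length < 1:
        raise ValueError("block_length must be >= 1")
    rng = np.random.default_rng(seed)

    ref_hists = histogram_windows(series, cfg)
    # Freeze the binning so all replicates share it.
    frozen = replace(cfg, rc_range=(float(ref_hists.bin_edges[0]), float(ref_hists.bin_edges[-1])))
    ref = solve_wham(ref_hists, windows, frozen)

    pmfs, fs = [], []
    n_dropped = 0
    for _ in range(n_boot):
        resampled = []
        for s in series:
            n = len(s)
            if block_length is None or block_length >= n:
                vals = rng.choice(s.values, size=n, replace=True)
            else:
                n_blocks = int(np.ceil(n / block_length))
                starts = rng.integers(0, n - block_length + 1, size=n_blocks)
                vals = np.concatenate(
                    [s.values[st : st + block_length] for st in starts]
                )[:n]
            resampled.append(replace(s, values=vals))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = solve_wham(
                    histogram_windows(resampled, frozen), windows, frozen,
                    f_init=ref.window_free_energies,
                )
        except WHAMError:
            n_dropped += 1
            continue
        if not prof.converged:
            n_dropped += 1
            continue
        pmfs.append(prof.free_energy)
        fs.append(prof.window_free_energies)

    if n_dropped > 0.2 * n_boot:
        raise WHAMError(
            f"{n_dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    pmf_arr = np.asarray(pmfs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bins defined in only some replicates
        bin_sd = np.nanstd(pmf_arr, axis=0, ddof=1)
    f_sd = np.std(np.asarray(fs), axis=0, ddof=1)
    return BootstrapResult(
        bin_sd=bin_sd,
        window_free_energy_sd=f_sd,
        n_replicates=len(pmfs),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# File formats: two-column series files, PMF TSV, JSON sidecar
# ---------------------------------------------------------------------------

def write_series_file(series: BiasedSeries, path) -> None:
    """Two-column whitespace text: time (fs), RC value (A)."""
    t = series.sample_interval * np.arange(1, len(series) + 1)
    np.savetxt(path, np.column_stack([t, series.values]), fmt="%.4f %.6f")


def read_series_file(path, window_index: int = 0, sample_interval: float | None = None) -> BiasedSeries:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    if sample_interval is None:
        t = data[:, 0]
        sample_interval = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return BiasedSeries(
        window_index=window_index, values=data[:, 1], sample_interval=sample_interval
    )


def write_pmf_tsv(profile: PMFProfile, path, bootstrap: BootstrapResult | None = None) -> None:
    """TSV columns: bin_center, pmf (empty for undefined bins), bootstrap_sd, counts."""
    sd = bootstrap.bin_sd if bootstrap is not None else profile.bootstrap_sd
    with open(path, "w") as fh:
        fh.write("bin_center\tpmf\tbootstrap_sd\tcounts\n")
        for b in range(len(profile.bin_centers)):
            pmf = "" if not np.isfinite(profile.free_energy[b]) else f"{profile.free_energy[b]:.6f}"
            s = ""
            if sd is not None and np.isfinite(sd[b]):
                s = f"{sd[b]:.6f}"
            fh.write(f"{profile.bin_centers[b]:.4f}\t{pmf}\t{s}\t{int(profile.counts[b])}\n")


def read_pmf_tsv(path, temperature: float = DEFAULT_TEMPERATURE_K) -> PMFProfile:
    centers, pmf, sd, counts = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bin_center"):
            raise ValueError(f"{path}: not a PMF TSV (missing header)")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            centers.append(float(parts[0]))
            pmf.append(float(parts[1]) if parts[1] else np.nan)
            sd.append(float(parts[2]) if parts[2] else np.nan)
            counts.append(float(parts[3]))
    sd_arr = np.asarray(sd)
    return PMFProfile(
        bin_centers=np.asarray(centers),
        free_energy=np.asarray(pmf),
        window_free_energies=np.zeros(0),
        counts=np.asarray(counts),
        n_iterations=0,
        converged=True,
        temperature=temperature,
        bootstrap_sd=None if np.all(np.isnan(sd_arr)) else sd_arr,
    )


def write_pmf_sidecar(profile: PMFProfile, cfg: WHAMConfig, path,
                      bootstrap: BootstrapResult | None = None,
                      warnings_list: Sequence[str] = ()) -> None:
    """JSON sidecar: window free energies, iteration count, convergence, config echo."""
    payload = {
        "window_free_energies": [float(v) for v in profile.window_free_energies],
        "n_iterations": profile.n_iterations,
        "converged": bool(profile.converged),
        "config": asdict(cfg),
        "warnings": list(warnings_list),
    }
    if bootstrap is not None:
        payload["bootstrap"] = {
            "n_replicates": bootstrap.n_replicates,
            "n_dropped": bootstrap.n_dropped,
            "window_free_energy_sd": [float(v) for v in bootstrap.window_free_energy_sd],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
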