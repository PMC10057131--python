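#!/usr/bin/env python
"""Sample both enantiomer systems by Langevin umbrella campaigns and estimate
their free-energy profiles by WHAM with bootstrap errors.

The two model surfaces encode the landmark parameters of the L- and D-alanine
aminoacylation profiles: barriers of 17.0 and 26.2 kcal/mol at RC -0.5 / -0.55 A
with overall reaction free energies of -7.0 and -1.0 kcal/mol.  Each system is
sampled over the full 101-window schedule at 4000 production samples per window,
and WHAM (1e-7 convergence tolerance, 0.02 A bins) reconstructs the PMF.
Writes pmf TSV + JSON sidecars under results/<system>/ and prints the maximum
pointwise deviation from the known true surface.
"""

from pathlib import Path

import numpy as np

from chiralpmf.core import DEFAULT_SEGMENTS, build_window_schedule
from chiralpmf.langevin import LangevinParams, generate_campaign
from chiralpmf.surfaces import surface_from_landmarks
from chiralpmf.wham import (
    WHAMConfig,
    bootstrap_pmf,
    histogram_windows,
    solve_wham,
    write_pmf_sidecar,
    write_pmf_tsv,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

SYSTEMS = {
    "l_ala": (-3.0, -0.5, 17.0, 2.0, -7.0),
    "d_ala": (-3.0, -0.55, 26.2, 2.0, -1.0),
}


def main() -> None:
    windows = build_window_schedule(DEFAULT_SEGMENTS)
    cfg = WHAMConfig()
    for offset, (name, landmarks) in enumerate(SYSTEMS.items()):
        surface = surface_from_landmarks(*landmarks)
        series = generate_campaign(surface, windows, LangevinParams(seed=SEED + offset))
        profile = solve_wham(histogram_windows(series, cfg), windows, cfg)
        boot = bootstrap_pmf(series, windows, cfg, n_boot=20, seed=SEED + offset + 10)

        sysdir = OUT / name
        sysdir.mkdir(parents=True, exist_ok=True)
        write_pmf_tsv(profile, sysdir / "pmf.tsv", bootstrap=boot)
        write_pmf_sidecar(profile, cfg, sysdir / "pmf.json", bootstrap=boot)

        mask = profile.defined & (profile.bin_centers >= -4) & (profile.bin_centers <= 3)
        truth = surface.energy(profile.bin_centers[mask])
        truth -= truth[profile.bin_centers[mask] <= -2].min()
        max_err = np.max(np.abs(profile.free_energy[mask] - truth))
        med_sd = np.nanmedian(boot.bin_sd)
        print(
            f"{name}: WHAM converged in {profile.n_iterations} iterations over "
            f"{int(mask.sum())} bins; max |PMF - truth| = {max_err:.3f} kcal/mol; "
            f"median bootstrap SD = {med_sd:.3f} kcal/mol"
        )


if __name__ == "__main__":
    main()
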