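# chiralpmf

Free-energy and approach-geometry analysis for chiral-selective RNA
aminoacylation: umbrella sampling along the acyl-transfer reaction coordinate,
WHAM reconstruction of the potential of mean force (PMF) with Monte Carlo
bootstrap errors, transition-state/barrier extraction, Boltzmann selectivity
ratios, and the Bürgi–Dunitz / Flippin–Lodge reaction-site observables — with a
synthetic overdamped-Langevin engine standing in for the QM/MM molecular
dynamics, so that every estimator can be validated against exactly known ground
truth.

## Who this is for

Anyone building or auditing an umbrella-sampling free-energy analysis of the
minihelix aminoacylation reaction (or a structurally similar 1-D PMF problem):
the package separates the *estimators* (WHAM, bootstrap, transition-state
analysis, geometry) — which are exactly what a real campaign needs — from the
*sampler*, which here is a controllable synthetic surrogate.

## The model

The reaction coordinate is RC = d(H3'…O3') − d(Ccarb…O3') in Å: ≈ −4 in the
reactant (intact 0.96 Å O3'–H3' bond, distant carbonyl carbon), positive after
acyl transfer.  Umbrella windows apply harmonic biases w_i(ξ) = ½k(ξ − ξ0,i)²
(k = 500 kcal/mol/Å², 101 windows from −4 to 3 Å).  WHAM combines the biased
histograms by self-consistent iteration of

    P(b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − w_i(ξ_b))/k_BT]
    f_i  = −k_BT ln Σ_b P(b) exp[−w_i(ξ_b)/k_BT]

to tolerance 10⁻⁷ kcal/mol on max|Δf_i|, giving PMF(ξ_b) = −k_BT ln P(ξ_b)
anchored to the reactant basin.  The barrier gap between the two enantiomer
profiles converts to a rate preference exp(ΔΔG‡/k_BT); RT·ln 4 ≈ 0.83 kcal/mol
(< 1 kcal/mol) suffices for a fourfold L/D selectivity at 300 K.

## Worked example

```python
from chiralpmf import (
    DEFAULT_SEGMENTS, build_window_schedule, surface_from_landmarks,
    LangevinParams, generate_campaign, WHAMConfig,
    histogram_windows, solve_wham, locate_transition_state,
)

windows = build_window_schedule(DEFAULT_SEGMENTS)          # 101 umbrella windows
surface = surface_from_landmarks(-3.0, -0.5, 17.0, 2.0, -7.0)  # L-like profile
series = generate_campaign(surface, windows, LangevinParams(seed=1))
cfg = WHAMConfig()
pmf = solve_wham(histogram_windows(series, cfg), windows, cfg)
ts = locate_transition_state(pmf)
print(f"barrier {ts.barrier:.2f} kcal/mol at RC {ts.ts_rc:+.2f} A, "
      f"overall dG {ts.overall_dg:+.2f} kcal/mol")
```

prints (seed 1):

```
barrier 17.07 kcal/mol at RC -0.51 A, overall dG -6.81 kcal/mol
```

i.e. the estimator recovers the surface's true 17.0 kcal/mol barrier at
RC −0.5 Å and ΔG −7.0 kcal/mol to within the campaign's statistical resolution
(~0.1–0.3 kcal/mol, quantified by `bootstrap_pmf`).  Doing the same for the
high-barrier D-like surface (26.2 kcal/mol at −0.55 Å, ΔG −1.0) and comparing
— as `analysis/03_transition_states_and_selectivity.py` does — prints:

```
barrier gap (D - L): 9.24 kcal/mol -> Boltzmann ratio 5.4e+06 at 300 K
gap sufficient for the observed fourfold preference: 0.826 kcal/mol (under 1 kcal/mol)
```

## Analysis drivers

The study itself is laid out as numbered scripts under `analysis/`, each a thin
narrative over the library, writing tables to `results/`:

1. `01_make_windows.py` — the 101-window schedule (TSV + WHAM metadata).
2. `02_sample_and_estimate_pmfs.py` — Langevin campaigns on both enantiomer
   surfaces, WHAM + 20-replicate bootstrap, PMF tables.
3. `03_transition_states_and_selectivity.py` — barriers, TS positions, overall
   ΔG, the D−L gap and its Boltzmann ratio.
4. `04_geometry_observables.py` — per-window BD/FL angles, τ(Ob-Ccarb-Cα-N) and
   key distances from synthetic reaction-site frames (L: gradual τ → 60°,
   d(N…P5') ≈ 4.0 Å at the barrier; D: cis→trans flip at RC ≈ −2.2 Å,
   d(N…P5') ≈ 5.1 Å at the barrier jumping to 6.3 Å past it).

A `chiralpmf` CLI (`make-windows`, `simulate`, `wham`, `analyze`, `geometry`,
`report`) exposes the same pipeline over on-disk files (Grossfield-style
metadata, two-column series, XYZ/PDB frames, TSV/JSON outputs) for ad-hoc runs;
every command echoes its configuration and is byte-reproducible given a seed.

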