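# Methods

## The problem this package models

Aminoacylation of an RNA minihelix — transfer of an amino acid from an acyl
phosphate donor to the 3'-hydroxyl of the terminal adenosine — proceeds with a
marked preference for L- over D-amino acids even without enzymes, a candidate
mechanism for the origin of protein homochirality.  The kinetic question reduces
to free-energy profiles along a single reaction coordinate,

RC = d(H3'…O3') − d(Ccarb…O3')  (Å),

which is ≈ −4 Å in the reactant state (intact 0.96 Å O–H bond, distant carbonyl
carbon) and positive once the acyl group has transferred.  The enantiomer whose
transition state (the PMF maximum) lies lower reacts faster; the barrier gap
ΔΔG‡ maps to a rate ratio exp(ΔΔG‡/kBT), so a gap of only RT·ln 4 ≈ 0.83
kcal/mol at 300 K already explains a fourfold preference.

This package implements the full estimation pipeline — umbrella sampling
bookkeeping, WHAM, bootstrap errors, transition-state and selectivity analysis,
and the reaction-site approach-geometry observables — with a synthetic sampling
engine in place of a QM/MM molecular-dynamics engine.
Everything downstream of the sampler is the estimator a real campaign would use.

## Umbrella sampling model

Windows restrain the RC with a harmonic bias w_i(ξ) = ½k(ξ − ξ0,i)².  Defaults
follow the production campaign design: k = 500 kcal/mol/Å², 101 windows from
−4.0 to 3.0 Å (Δ = 0.1 Å on the flanks, 0.05 Å through [−1.5, 1.5]), 10 ps
equilibration and 20 ps production per window sampled every 5 fs → 4000
production samples/window (the cadence fixes the count).  Published force
constants are
ambiguous between the ½k(ξ−ξ0)² and k(ξ−ξ0)² conventions; both are supported
(`half_prefactor`), default ½k, and the choice propagates consistently from the
sampler to WHAM.

Boundary ownership in the mixed-spacing schedule: the shared centers −1.5 and
1.5 belong to the fine segment, the coarse segments are half-open — the only
assignment that yields 101 distinct windows.  Centers are computed by integer
stepping and rounded to 3 decimals so no floating-point drift can duplicate a
boundary.

## Synthetic sampling engine

**Surfaces.**  G(ξ) is a sum of three Gaussians plus a linear term and constant
offset.  `surface_from_landmarks` places one Gaussian at each requested
stationary point (reactant minimum at G = 0, barrier top, product minimum),
solves amplitudes/slope/offset by linear least squares against the three value
and three zero-derivative constraints, refines the widths by Nelder–Mead on the
residual, and verifies the result on a 10⁻³ Å grid to within 0.05 kcal/mol and
0.05 Å.  The two study surfaces use landmarks (−3.0, −0.5, 17.0, 2.0, −7.0) and
(−3.0, −0.55, 26.2, 2.0, −1.0) — barrier and ΔG of the L- and D-alanine
profiles.

**Dynamics.**  Overdamped (Brownian) Euler–Maruyama integration,
dξ = −G′(ξ)dt/γ + √(2kBT dt/γ)·N(0,1), rather than inertial Langevin: WHAM
consumes only the stationary distribution, which for this dynamics is exactly
∝ exp(−(G + w)/kBT), so every fidelity test has a closed form.  dt = 0.05 fs and
γ = 1000 kcal·fs/mol/Å² are integrator knobs, not physics: the discrete
stationary variance exceeds kBT/k by 1/(1 − k·dt/2γ) ≈ 1.3% (calibrated well
under the 2% band on the flat-surface variance test), and the bias-well
relaxation time γ/k = 2 fs is below the 5 fs cadence, so consecutive samples are
near-independent (lag-1 correlation e^(−2.5) ≈ 0.08).  Trajectories reflect at
the surface-domain boundary; reflections are counted and >1% triggers a warning.
Each window starts from the previous window's final coordinate (the first at its
own center), mimicking sequential campaign seeding; per-window seeds derive from
the master seed via `SeedSequence(master, spawn_key=(index,))`, making campaigns
bit-reproducible while windows stay statistically independent.

**Geometry frames.**  Labeled 8-atom frames (O3', H3', Ccarb, Ocarb, Cα, Ob, N,
P5') realize scheduled observables exactly: carbonyl center fixed in a canonical
plane, O3' placed by the scheduled Bürgi–Dunitz angle, Flippin–Lodge angle and
d(Ccarb…O3'), H3' on the Ccarb→O3' ray, N by internal coordinates with the
scheduled torsion τ(Ob-Ccarb-Cα-N) and the Ccarb-Cα-N angle solved (Brent) to
hit d(N…O3'), P5' on the Cα→N ray at d(N…P5').  Noise is Gaussian in observable
space, applied to the targets before construction, so recovered means and SDs
have exactly known statistics.  The default L-like and D-like schedules are
piecewise-linear reconstructions of the window-averaged trajectories of the two
enantiomer systems: a shared BD ramp to 105°, FL ≈ 0°, and the distinguishing
pathway — gradual τ rotation 0→60° (L) versus an abrupt cis→trans flip near
RC = −2.2 Å (D) coupled to a d(N…O3') drop and the d(N…P5') jump 4.3 → 5.1 Å
(held to the barrier) → 6.3 Å beyond it, versus ≈ 4.0 Å at the L transition
state.  The d(N…O3') *absolute* values are adjusted to remain jointly realizable
with the closing d(Ccarb…O3') in this single-fragment rigid construction (the
real system relaxes many more degrees of freedom); the qualitative contrasts —
drop timing, L/D ordering reversal at RC ≈ −1.6 Å, flip coupling — are
preserved, and that is what the generator is for.

What the generator does *not* emulate: solvent and ions, multidimensional
coupling between the RC and orthogonal slow modes, kinetics (the friction is not
physical), and QM energetics.  Passing tests therefore demonstrate correctness
of the estimators under a known sampling measure, not fidelity of any MD engine.

## WHAM estimator

Standard self-consistent iteration on binned data (default 0.02 Å bins,
configurable; range = data min/max padded by one bin):

P(b) = Σᵢnᵢ(b) / Σᵢ Nᵢ e^{(fᵢ − wᵢ(ξ_b))/kBT},  fᵢ = −kBT ln Σ_b P(b) e^{−wᵢ(ξ_b)/kBT}

iterated until max |Δfᵢ| < 10⁻⁷ kcal/mol on the fᵢ increments (the standard
monitored quantity).  fᵢ start at 0; the step is halved only when
successive increment vectors oppose (oscillation guard), which cannot move the
fixpoint.  Empty bins are excluded from fᵢ sums and carry NaN, never a number.
Non-convergence returns `converged=False` with a warning instead of raising.
The PMF is anchored so its minimum over the reactant region (RC ≤ −2 by default,
falling back to the global minimum) is zero, matching how barrier heights are
quoted relative to the reactant basin.

Bootstrap: each window's sample set is resampled with replacement (optionally in
contiguous blocks to respect autocorrelation), the entire WHAM solve repeated
per replicate warm-started from the reference fᵢ, and per-bin/per-fᵢ SDs taken
over replicates; non-converged replicates are dropped and counted, >20% dropped
is an error.  20 replicates by default.

Exact invariances tested: gauge shifts of all wᵢ by a constant; duplication of
the entire window set (a pure multiplicity rescaling).  Duplicating a *single*
window with its data is not an exact invariance of the WHAM fixpoint — it
reweights that window's data and shifts the estimate by an amount of the order
of the window's histogram-vs-model residual — so the suite asserts the exact
version and bounds the estimator against an independent unbinned MBAR-style
oracle (0.1 kcal/mol on well-populated bins) instead.

## Transition-state and selectivity analysis

The transition state is the PMF argmax over defined bins strictly inside the
search range (default (−2, 1), bracketing both systems' barrier tops while
excluding the end plateaus), ties toward smaller RC; reactant/product minima are
the profile minima left and right of it.  Extrema sit on bin centers — no
interpolation by default, so the reported resolution is the histogram's; a
quadratic-interpolation refinement is reported separately when requested.
Boundary maxima and monotone profiles raise a "no barrier" error rather than
returning a fabricated TS.  Selectivity: ratio = exp(ΔΔG‡/kBT) and its inverse
ΔΔG‡ = kBT·ln(ratio), kB = 0.0019872041 kcal/(mol·K), T = 300 K default.

## Geometry observables

BD angle: planar angle O3'…Ccarb=Ocarb.  Carbonyl plane: least-squares (SVD)
plane of {Ccarb, Ocarb, Cα, Ob} — a fit, not a single cross product, because the
four atoms need not be exactly coplanar in noisy frames.  FL angle: the tilt of
the O3' approach out of the reference plane through the C=O axis perpendicular
to the carbonyl plane, signed by the right-hand rule about the Ccarb→Ocarb axis
with the normal taken on the nucleophile's side.  Being a triple product, this
sign flips under reflection — the chirality sensitivity the mechanism rests
on — and on the approach face realized here it coincides with the chemical
reading "positive toward the bridging oxygen Ob".  τ(Ob-Ccarb-Cα-N): standard
signed torsion, clockwise-positive viewed along the central bond (0 cis, ±180
trans), fixed by an independently constructed −60° internal-coordinate fixture.
Window statistics offer both linear and circular (vector-mean/circular-SD)
aggregation; circular is the honest choice for τ hopping between +179° and
−179°; both modes are provided and labeled in the output.  Principal ranges: BD [0, 180], FL
[−90, 90], τ (−180, 180].

## Problem sizes and numerical defaults

Full-scale runs (analysis drivers, acceptance script) use the complete
101-window × 4000-sample campaigns — the study conditions — for both surfaces,
plus 20 bootstrap replicates and 200 geometry frames per window over RC ∈
[−4, 0].  The test suite exercises the same code paths on a reduced 36-window ×
800-sample campaign for the invariance/bootstrap checks and at full scale for
the parameter-recovery checks.  At the study conditions the accumulated
statistical uncertainty of the reconstructed PMF (a random walk of window
free-energy increments across 101 windows) has a typical worst-bin deviation of
≈ 0.15–0.3 kcal/mol from the true surface, which the recovery tests bound at
0.3 kcal/mol pointwise, 0.5 kcal/mol on barriers and 0.1 Å on the TS bin.

## Known limitations

- The sampler is 1-D and memoryless; it cannot exhibit hysteresis between
  forward and backward window sweeps, a common failure mode of real campaigns.
- The WHAM implementation is 1-D, aperiodic, with fixed-width bins; no
  autocorrelation-time estimation beyond optional fixed-length block bootstrap.
- The geometry generator fixes the carbonyl fragment's internal coordinates;
  only scheduled observables (plus noise) vary, so covariances between
  observables are those implied by the construction, not by any force field.
- Transition-state uncertainty is the bootstrap SD of the PMF at the TS bin; no
  uncertainty is propagated onto the TS *position*.
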