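#!/usr/bin/env python
"""Per-window reaction-site geometry along the approach (RC -4 to 0 A).

Generates noisy synthetic coordinate frames for the L-like and D-like observable
schedules, aggregates every observable per umbrella window (circular statistics
for the backbone torsion), writes TSV tables under results/<system>/geometry/,
and prints the headline geometric contrasts: the Burgi-Dunitz angle reaching
~105 degrees before the transition state, the Flippin-Lodge angle fluctuating
about 0, and the d(N...P5') separation — ~4.0 A at the L transition state versus
~5.1 A (jumping to ~6.3 A past the barrier) for D, the electrostatic signature
coupled to the cis->trans flip of tau(Ob-Ccarb-Calpha-N).
"""

from pathlib import Path

import numpy as np

from chiralpmf.framegen import d_ala_like_schedule, generate_geometry_frames, l_ala_like_schedule
from chiralpmf.geometry import CIRCULAR_OBSERVABLES, OBSERVABLES, window_statistics

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11
FRAMES_PER_WINDOW = 200


def main() -> None:
    for offset, (name, schedule) in enumerate(
        (("l_ala", l_ala_like_schedule()), ("d_ala", d_ala_like_schedule()))
    ):
        centers = [round(c, 3) for c in np.arange(-4.0, 0.0001, 0.1)]
        frames = generate_geometry_frames(
            schedule, np.repeat(centers, FRAMES_PER_WINDOW), seed=SEED + offset
        )
        groups: dict[float, list] = {c: [] for c in centers}
        for f in frames:
            groups[round(f.rc, 3)].append(f)

        geodir = OUT / name / "geometry"
        geodir.mkdir(parents=True, exist_ok=True)
        tables = {}
        for obs in OBSERVABLES:
            stats = window_statistics(groups, obs, circular=obs in CIRCULAR_OBSERVABLES)
            tables[obs] = {s.center: s for s in stats}
            with open(geodir / f"{obs}.tsv", "w") as fh:
                fh.write("window_center\tmean\tsd\tn\n")
                for s in stats:
                    fh.write(f"{s.center:.3f}\t{s.mean:.4f}\t{s.sd:.4f}\t{s.n}\n")

        bd = tables["bd_angle"][-1.0]
        fl = tables["fl_angle"][-1.5]
        tau = tables["tau"][-1.0]
        print(
            f"{name}: BD = {bd.mean:.1f} +/- {bd.sd:.1f} deg at RC -1.0; "
            f"FL = {fl.mean:+.1f} +/- {fl.sd:.1f} deg at RC -1.5; "
            f"tau = {tau.mean:+.0f} deg at RC -1.0 "
            f"({'trans' if abs(tau.mean) > 90 else 'cis-to-gauche pathway'})"
        )
    print(f"per-window observable tables written under {OUT}/<system>/geometry/")


if __name__ == "__main__":
    main()
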