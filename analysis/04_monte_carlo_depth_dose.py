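#!/usr/bin/env python
"""Monte Carlo depth-dose profiles for the two reference tumor radii.

Runs 10^5 straight-line CSDA histories from a uniform surface source on
the 0.25 cm and 0.5 cm tumors, scores shell tallies at the standard
depths (0.3, 0.8, ... mm) and converts to dose with the closed-form
activity.  Writes results/depth_dose_r{radius}.csv and prints the two
structural findings: the profile falls monotonically with depth, and
beyond the ~3.7 mm beta range of Au-198 the dose is identically zero —
deep shells of the 0.5 cm tumor receive nothing.
"""
import pathlib

import numpy as np

from aunp_radiodose import (
    ShellTally,
    TumorModel,
    depth_dose_profile,
    load_au198,
    run_tally,
    surface_activity,
)
from aunp_radiodose.pipeline import Scenario, default_depths_mm

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
N_HISTORIES = 100_000


def main() -> None:
    nuc = load_au198()
    for radius, seed in ((0.25, 1025), (0.5, 1050)):
        tumor = TumorModel(radius)
        tally = ShellTally.from_depths(tumor, default_depths_mm(radius))
        res = run_tally(tumor, tally, N_HISTORIES, seed, nuclide=nuc)
        loading = Scenario(name="ref", tumor_radius_cm=radius).loading()
        activity = surface_activity(loading, radius, nuc)
        profile = depth_dose_profile(res, activity, nuc)
        path = OUT / f"depth_dose_r{radius:g}cm.csv"
        profile.to_csv(path)

        print(f"\ntumor r = {radius} cm  (A = {activity:.1f} mCi, "
              f"{N_HISTORIES} histories, seed {seed})")
        for d, t, dose in zip(profile.depth_mm, profile.t_mev_per_g,
                              profile.dose_gy):
            print(f"  depth {d:>4.1f} mm   T = {t:.3e} MeV/g   "
                  f"D = {dose:.4g} Gy")
        mono = np.all(np.diff(profile.dose_gy) <= 0)
        print(f"  monotone falloff: {mono}")
        if radius == 0.5:
            deep = profile.dose_gy[profile.depth_mm >= 4.3]
            print(f"  dose at 4.3/4.8 mm (beyond the beta range): {deep}")
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
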