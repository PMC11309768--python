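#!/usr/bin/env python
"""Constant-time CPMG R2,eff profiles: flat apo/bound vs a dispersive control.

Generates R2,eff profiles over the printed CPMG frequency list for
exchange-free residues (flat, as observed for both apo and RNA-bound
states) and one synthetic dispersive control, then applies the
amplitude + F-test dispersion assessment.

Writes results/04_cpmg.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dsrbd_dynamics.io import ResidueID
from dsrbd_dynamics.rates import CpmgSeries, assess_dispersion
from dsrbd_dynamics.synth import gen_cpmg_profile, stage_seed

RESULTS = Path(__file__).resolve().parents[1] / "results"

NU_CPMG = np.array([25, 50, 75, 125, 175, 275, 375, 525, 675, 825, 1000.0])
TRELAX = 0.040


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2024)
    args = parser.parse_args()
    seed = stage_seed(args.seed, "cpmg")

    cases = {
        "flat_apo": dict(r20=11.0),
        "flat_bound": dict(r20=20.0),
        "dispersive_control": dict(r20=11.0, pb=0.05, kex=1500.0, dw=800.0),
    }
    rows = []
    for k, (name, kwargs) in enumerate(cases.items()):
        r2eff, sig = gen_cpmg_profile(NU_CPMG, sigma=0.3, seed=seed + k,
                                      **kwargs)
        series = CpmgSeries(ResidueID(200), NU_CPMG, r2eff, TRELAX,
                            sigma=sig)
        verdict = assess_dispersion(series)
        rows.append({"case": name, **verdict,
                     **{f"r2eff_{int(nu)}": v
                        for nu, v in zip(NU_CPMG, r2eff)}})
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "04_cpmg.csv", index=False)
    for row in rows:
        print(f"{row['case']}: dispersive={row['dispersive']} "
              f"(amplitude {row['amplitude']:.2f} s^-1, "
              f"p={row['p_value']:.3g})")


if __name__ == "__main__":
    main()
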