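#!/usr/bin/env python
"""Adiabatic (HSn) dispersion: apo vs RNA-bound exchange maps.

Simulates HSn R1rho/R2rho rows for a small panel of residues in two
states — apo (mostly slow/no exchange) and bound (exchange induced in
RNA-binding regions, quenched elsewhere) — fits the two-state model per
residue, classifies the exchange regime, and emits the delta-kex table
with the >10,000 s^-1 induced/quenched flags.

Writes results/03_hard_fits.csv and results/03_delta_kex.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dsrbd_dynamics.hard import (ExchangeParams, build_hs_pulse,
                                 classify_exchange, delta_kex,
                                 dw_ppm_to_rad, fit_two_state)
from dsrbd_dynamics.io import SpectrometerContext
from dsrbd_dynamics.synth import gen_hard_dataset, stage_seed

RESULTS = Path(__file__).resolve().parents[1] / "results"

R1RHO_DELAYS = np.array([0, 16, 32, 64, 96, 128]) * 1e-3
R2RHO_DELAYS = np.array([0, 16, 32, 64]) * 1e-3
DW_PPM = 2.0


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2024)
    args = parser.parse_args()
    seed = stage_seed(args.seed, "hard")
    context = SpectrometerContext(600.0)
    pulses = [build_hs_pulse(n) for n in (1, 2, 4, 6, 8)]
    dw = dw_ppm_to_rad(DW_PPM, context)

    def ex(pb, kex):
        return ExchangeParams(pb=pb, kex=kex, dw=dw, r1g=1.5, r2g=11.0)

    # apo: slow exchange at three sites, none elsewhere; bound: induced
    # exchange at binding-region residues, quenched at one site
    truth_apo = {200: ex(0.12, 3000.0), 212: ex(0.15, 20000.0),
                 224: ex(0.12, 15000.0), 170: None, 190: None}
    truth_bound = {200: ex(0.12, 3000.0), 212: ex(0.15, 2500.0),
                   224: ex(0.12, 15000.0), 170: ex(0.15, 18000.0),
                   190: None}

    fits = {}
    rows_out = []
    for state, truth in (("apo", truth_apo), ("bound", truth_bound)):
        rows, _ = gen_hard_dataset(truth, pulses, R1RHO_DELAYS,
                                   R2RHO_DELAYS, sigma=0.02,
                                   seed=seed + (0 if state == "apo" else 1),
                                   state=state)
        fits[state] = {}
        for num, row in rows.items():
            fit = fit_two_state(row, pulses, context, sigma=0.02,
                                grid_shape=(8, 6, 1), fix_dw_ppm=DW_PPM)
            fits[state][num] = fit
            cls = classify_exchange(fit)
            rec = {"state": state, "residue": num,
                   "detected": fit.detected, **cls,
                   "truth_kex": truth[num].kex if truth[num] else 0.0}
            if fit.detected:
                rec.update(kex=fit.params.kex, pb=fit.params.pb,
                           r2g=fit.params.r2g, chi2=fit.chi2)
            rows_out.append(rec)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows_out).to_csv(RESULTS / "03_hard_fits.csv",
                                  index=False)
    delta = delta_kex(fits["apo"], fits["bound"])
    delta.to_csv(RESULTS / "03_delta_kex.csv", index=False)

    print(pd.DataFrame(rows_out)[["state", "residue", "truth_kex",
                                  "detected", "kex_class"]]
          .to_string(index=False))
    flagged = delta[delta["flag"].isin(["induced", "quenched"])]
    print("\ndelta-kex flags (|delta| > 10,000 s^-1):")
    print(flagged.to_string(index=False) if len(flagged) else "  none")


if __name__ == "__main__":
    main()
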