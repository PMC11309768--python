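#!/usr/bin/env python
"""Per-residue relaxation rates from synthetic peak-intensity decays.

Generates apo-like inversion-recovery decays for the 68-residue core at
the printed delay schedule (duplicates included), estimates the noise
from the duplicate delays, fits mono-exponential rates with Monte-Carlo
uncertainties, and reports the core-window mean +/- SEM.

Writes results/01_rates.csv and results/01_core_summary.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dsrbd_dynamics.io import read_delay_schedule
from dsrbd_dynamics.rates import (aggregate_region_stats,
                                  estimate_noise_from_duplicates,
                                  fit_monoexponential,
                                  monte_carlo_uncertainty)
from dsrbd_dynamics.io import RateTable
from dsrbd_dynamics.synth import gen_decay_dataset, stage_seed

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2024)
    parser.add_argument("--mc", type=int, default=100)
    args = parser.parse_args()

    schedule = read_delay_schedule("10, 30*, 50, 100, 200, 300, 450*, 600")
    rng = np.random.default_rng(stage_seed(args.seed, "rates"))
    truth = {n: float(r) for n, r in zip(
        range(159, 228), rng.normal(1.43, 0.10, 69))}
    truth.pop(186)                      # proline gap
    series, _ = gen_decay_dataset(truth, schedule, sigma=0.02,
                                  seed=stage_seed(args.seed, "rates"))
    sigmas = estimate_noise_from_duplicates(series)

    records = []
    for k, s in enumerate(series):
        est = fit_monoexponential(s)
        est.rate_sigma = monte_carlo_uncertainty(
            fit_monoexponential, s, sigmas[s.residue.number], n=args.mc,
            seed=stage_seed(args.seed, "rates") + k)
        records.append({"residue": s.residue.number, "resname": "",
                        "kind": "R1", "condition": "", "value": est.rate,
                        "sigma": est.rate_sigma, "field_mhz": 600.0,
                        "state": "apo"})
    table = RateTable.from_records(records)
    RESULTS.mkdir(exist_ok=True)
    table.df.to_csv(RESULTS / "01_rates.csv", index=False)

    stats = aggregate_region_stats(table, (159, 227), "R1",
                                   field_mhz=600.0, state="apo")
    recov = np.array([(r["value"], truth[r["residue"]])
                      for r in records]).T
    summary = {
        "core_mean_r1": stats["mean"], "core_sem_r1": stats["sem"],
        "n_residues": stats["n"],
        "median_abs_rate_error": float(np.median(
            np.abs(recov[0] - recov[1]))),
        "median_mc_sigma": float(np.median(table.df["sigma"])),
    }
    (RESULTS / "01_core_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"core R1 = {stats['mean']:.3f} +/- {stats['sem']:.3f} s^-1 "
          f"over {stats['n']} residues "
          f"(median |fit - truth| = {summary['median_abs_rate_error']:.4f})")


if __name__ == "__main__":
    main()
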