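# dsrbd-dynamics

NMR spin-relaxation, relaxation-dispersion and RNA-binding analysis for
tandem double-stranded RNA-binding domains (dsRBDs), built around the
comparison of TRBP2-dsRBD1/dsRBD2 in their apo and 12-bp-duplex (D12)
bound states. It is aimed at protein-NMR practitioners who want the
quantitative steps of such a study — rates, model-free parameters,
exchange maps, binding thermodynamics — as reproducible, testable code
rather than a chain of vendor tools.

The package covers five stages:

1. **Rates** — mono-exponential R1/R2/R1ρ/R2ρ fits of peak-height decays
   I(t) = I0·e^(−Rt), duplicate-delay noise estimation
   σ = √(Σdᵢ²/2m), Monte-Carlo rate errors (n = 500), heteronuclear nOe
   ratios, constant-time CPMG R2,eff = −ln(I_ν/I_ref)/T_relax, and
   core-window mean ± SEM aggregation.
2. **Model-free** — extended Lipari–Szabo spectral densities
   J(ω) = (2/5)Σₖ Aₖ[S²τₖ/(1+(ωτₖ)²) + …], forward prediction of
   R1/R2/nOe at 600/800 MHz, R2/R1-based and global correlation-time
   (τc) fitting, AIC model selection over the m0–m8 ladder, and Rex maps.
3. **Adiabatic dispersion (HSn)** — hyperbolic-secant spin-lock
   waveforms, direct two-state Bloch–McConnell propagation (6×6 matrix
   exponentials, 4th-order Magnus), R1ρ/R2ρ dispersion across HS1–HS8,
   two-state fits of (pB, kex, Δω), exchange-regime classification, and
   apo-vs-bound Δkex tables.
4. **Binding** — the quadratic two-state complex solver, the one-site
   NMR-titration isotherm, chemical-shift perturbations, and single-site
   ITC simulation/fitting (Kd, ΔH, n, derived ΔG/ΔS).
5. **Synthetic data** — seeded generators for every input above with
   embedded ground truth, plus an RNA-duplex Watson–Crick/wobble pairing
   utility.

## Worked example

Simulate the dsRBD2–D12 ITC titration at its reported average
thermodynamics and refit it:

```python
import numpy as np
from dsrbd_dynamics.binding import BindingModel, fit_itc_single_site
from dsrbd_dynamics.synth import gen_itc_dataset

truth = BindingModel(kd=1.18e-6, dh=-10.12, n=1.0)   # Kd in M, dH kcal/mol
experiment, _ = gen_itc_dataset(truth, sigma=0.05, seed=7)
fit = fit_itc_single_site(experiment)
print(f"Kd = {fit['kd']*1e6:.2f} uM, dH = {fit['dh']:.2f} kcal/mol, "
      f"n = {fit['n']:.2f}, dS = {fit['ds']*1e3:.1f} cal/mol/K")
```

```
Kd = 0.98 uM, dH = -9.69 kcal/mol, n = 0.99, dS = -5.0 cal/mol/K
```

The fitted dissociation constant and enthalpy recover the generating
values within the noise; the negative ΔS says the binding is enthalpy
driven, with ΔG (−8.1 kcal/mol at 298 K) less negative than ΔH. Running
`python analysis/05_binding.py` repeats this 100 times and also prints
the weak-binding fraction-bound check (9.64% of protein bound at Kd
1.7 μM, 50 μM protein, 5 μM RNA) and the D12 duplex pairing count
(11 Watson–Crick + 1 G·U wobble = 12 bp).

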