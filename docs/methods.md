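# Methods

This package re-implements, as a tested library plus a set of analysis
drivers, the quantitative backbone-dynamics and RNA-binding analysis used
to compare the two N-terminal double-stranded RNA-binding domains
(dsRBD1, dsRBD2) of TRBP2 in their apo and 12-bp-duplex (D12) bound
states. The deposited raw spectra are not shipped; every pipeline stage
is instead exercised on synthetic data generated by `synth` with known
ground truth, which is what the tests and the acceptance script measure.

## Relaxation-rate extraction (`rates`)

Peak heights versus relaxation delay are fit to I(t) = I0·exp(−R·t) by
unweighted least squares. The initial guess is deterministic and
scale-free (I0 from the maximum height; R from the first/last height
ratio, clipped to [1e−3, 1e3] s⁻¹), so fits are reproducible without a
global optimizer. Duplicate-delay points enter as separate observations
rather than being averaged, preserving the error model the duplicates
imply. Negative fitted rates are reported with a warning, not clamped —
they are diagnostic of baseline problems.

Noise is estimated from duplicate delays as σ = sqrt(Σdᵢ²/2m) over the m
paired height differences, per residue by default with a pooled mode as
fallback (whether the original analysis pooled across residues is not
recorded; both are provided). Rate uncertainties come from Monte-Carlo
refitting (default n = 500) of the best-fit curve plus Gaussian noise,
seeded. The steady-state heteronuclear nOe is the saturated/unsaturated
height ratio with the error propagated from the baseline-noise RMSDs.

Constant-time CPMG effective rates are R2,eff = −ln(I_ν/I_ref)/T_relax
with T_relax = 40 ms. A profile is called dispersive only when the
low-ν minus high-ν amplitude exceeds k·(pooled σ) (default k = 2) *and*
an F-test at α = 0.05 prefers a two-parameter monotone surrogate
(offset + amplitude·exp(−ν/ν₀), ν₀ fixed at the median frequency) over a
constant. The study observed no CPMG dispersion in either state; the
surrogate exists to make that a falsifiable decision rather than a
visual one.

Region statistics (e.g. the 68-residue core window 159–227 used for all
core averages) are unweighted means with SEM = sd/√n. Core windows are
configuration, not code constants.

## Model-free analysis (`modelfree`)

The spectral density is the extended Lipari–Szabo form with both a fast
(τf, Sf²) and slow (τs) internal process, reducing to the original
two-parameter form at Sf² = 1 and supporting isotropic or axially
symmetric (three-term Woessner) global diffusion. R1, R2 and the nOe
follow the standard dipolar + CSA expressions with constants
r(N–H) = 1.02 Å, Δσ(¹⁵N) = −172 ppm, γH = 2.6752×10⁸,
γN = −2.7126×10⁷ rad s⁻¹ T⁻¹ (all configurable; the original analysis
defers to its software's defaults without printing them). Rex is
referenced to 600 MHz and scaled by (B/B_ref)².

Per-residue model selection runs the conventional ladder m0–m8 with
five deterministic starting points per model and selects by
AIC = χ² + 2k, breaking ties toward fewer parameters. On noiseless
nested data this never prefers a super-model (the χ² gain is zero and
the 2k penalty decides).

The global correlation time is initialized from the trimmed-mean R2/R1
ratio of rigid-candidate residues (nOe > 0.65) via a 1-D root solve of
the rigid-limit ratio, then refined by alternating (a) per-residue
internal-parameter fits at fixed diffusion and (b) global diffusion
optimization at fixed internal parameters, until tc moves < 0.01%
(relative 1e−4). The axial case additionally optimizes the ratio
D∥/D⊥ and the symmetry-axis orientation; per-residue N–H unit vectors
are an input table, never extracted from structures here. The fully
anisotropic (ellipsoid) tensor used in the original analysis is out of
scope: the axially symmetric model is the ceiling, so correlation-time
comparisons are recovery-style (generate at the reported tc, recover it)
rather than re-analysis-exact. On the synthetic two-field dataset used
for acceptance (60 rigid residues, S² = 0.85, τe = 50 ps, 2% relative
noise) the recovered tc is within a fraction of a percent of the 7.3 ns
truth.

One caveat the forward model makes explicit: at the bound-state tc of
10.9 ns an isotropic rigid residue has *lower* R1 at 600 MHz (~1.14 s⁻¹)
than the measured bound-state core average (~1.37 s⁻¹), and the measured
bound R2 average (~20 s⁻¹) contains substantial exchange broadening on
top of the pure tumbling contribution (~13.8 s⁻¹). The core-average
acceptance checks therefore target the apo state, where the rigid-core
forward model reproduces the reported averages within 15%, and assert
only the direction of the apo→bound R2 increase.

## Adiabatic relaxation dispersion (`hard`)

Dispersion is generated by stretching hyperbolic-secant spin-lock pulses:
A(t) = ω1max·sech(β((2t/Tp)−1)ⁿ) with β = asech(0.01), carrier offset
sweeping [−bw/2, +bw/2] as the normalized cumulative integral of A²
(constant adiabaticity). Defaults, none printed in the source study:
Tp = 16 ms (the relaxation delays are multiples of 16 ms),
ω1max/2π = 2.5 kHz, bw/2π = 5 kHz, 1024 steps per pulse.

Propagation is direct: the 6×6 two-state Bloch–McConnell generator
(states A/B × components x,y,z; kAB = pB·kex, kBA = pA·kex; intrinsic
rates assumed equal in both states as the standard identifiability
constraint; the thermal-equilibrium return term is omitted since only
decay rates are measured) is exponentiated per piecewise-constant step
using a fourth-order Magnus scheme (two Gauss–Legendre waveform nodes
per step, exponent (h/2)(L1+L2) + (√3h²/12)[L2,L1], batched
eigendecomposition with a scipy `expm` fallback). Doubling the step
count changes the final magnetization by < 1e−7 at the default
discretization, and a coarse-grid step-doubling check can be requested
at propagation time. R1ρ starts from +z, R2ρ from +x; rates come from
mono-exponential fits (the same fitter as the laboratory-frame rates) of
the magnetization projected on (R1ρ) or perpendicular to (R2ρ) the
end-of-sweep effective-field axis. Against the closed-form rotating-frame
oracle R = R1cos²θ + R2sin²θ (no exchange, constant lock) and the
Laguerre/asymptotic two-state R1ρ expression, the propagator agrees to
better than 1% and 5% respectively over the tested (pB ≤ 0.2,
kex ∈ [500, 5×10⁴] s⁻¹) grid — in practice to ~0.1%.

Two physical points that shape the fitter:

- **Exchange-free profiles are monotone, not flat.** The time-average
  ⟨sin²θ⟩ of the effective-field tilt grows with the stretching factor,
  so R1ρ rises and R2ρ falls from HS1 to HS8 even without exchange —
  exactly the trend the measurements show for both domains, with
  exchange only amplifying its extent. The "no detectable exchange"
  sentinel therefore compares the data against the *fitted exchange-free
  geometric baseline* (reduced χ² < 2), not against a constant.
- **Fast-exchange identifiability.** When kex ≫ Δω only kex and
  φex = pB(1−pB)Δω² are determined; pB and Δω individually lie on a
  ridge, and on a substantial fraction of 2%-noise draws an alternative
  (low-pB, higher-R2g) basin fits strictly better than the generating
  parameters. The fit therefore works in (log10 kex, logit pB, Δω, R2g),
  seeds a bounded local refinement from the best points of a coarse
  12×10×8 grid, and optionally pins Δω (`fix_dw_ppm`) when an
  independent shift difference is available, which makes pB well
  determined. Recovery tests assert replicate medians (kex within ×1.5,
  pB within ±0.05 at the tested conditions); per-draw recovery at those
  thresholds is not attainable and is not claimed. Similarly, when
  kex ≫ ω1 the exchange contribution averages to a nearly lock-
  independent R2 addition, so a very fast process of moderate φex is
  absorbed by the baseline and classified as "none" — consistently
  across seeds — rather than producing unstable parameters.

Fitted processes are binned by kex (slow < 5000, fast 5000–50,000,
very fast > 50,000 s⁻¹; lower edges exclusive) and pB (<10%, 10–20%,
20–40%, >40%). Δkex = kex(bound) − kex(apo) is flagged above
10,000 s⁻¹ (sign recorded as induced/quenched); residues fitted in one
state only are emitted with a missing-state marker. The cited
"geometric approximation" acceleration is not implemented; the direct
propagator is fast enough at these problem sizes (a per-residue fit
takes seconds with a reduced in-fit discretization of 64–96 steps,
which changes the rates by < 0.1%).

## Binding (`binding`)

The two-state complex concentration is the exact quadratic root
[PL] = ((Pt+Lt+Kd) − sqrt((Pt+Lt+Kd)² − 4PtLt))/2. The NMR titration
isotherm fits (Kd, Δδmax) through Δδobs = Δδmax·{(Pt+Lt+Kd) −
sqrt(...)}/(2Pt); the response may be a peak-intensity change (as in the
source study) or a chemical shift — both are accepted and labelled, with
no claim they are interchangeable. An under-sampling warning fires when
the fitted curve reaches < 90% of saturation at the last titration point
(or max [L]t < Kd) — the situation the study hit when line broadening
removed the inflection-point data. CSP = sqrt(ΔδH² + (0.14·ΔδN)²), the
weight being convention, configurable.

ITC uses the single-site Wiseman model: cumulative heat
Q = n·Θ·Mt·ΔH·V0 with Θ from the binding quadratic, perfusion dilution
of both cell and syringe species, per-injection heats with the
displaced-volume correction dQ(i) = Q(i) − Q(i−1) + (dVi/V0)(Q(i)+Q(i−1))/2,
an optional constant dilution offset (fitted by default), and the
instrument's injection scheme (one discarded 0.4 μl injection, then
eighteen 2 μl injections). Cell/syringe volumes are not printed in the
source; defaults (V0 = 200 μl, cell 10 μM duplex, syringe 130 μM
protein) follow the instrument class and the stated concentration
ratios, and give half-saturation near the eighth injection as reported.
Kd and n are fitted in log space; ΔS derives from ΔG = ΔH − TΔS at the
experiment temperature. Fitting the simulated dsRBD2–D12 run (Kd
1.18 μM, ΔH −10.12 kcal/mol, n 1) at zero noise reproduces the truth to
1e−6 relative; with 2% heat noise the 100-replicate means land within a
few percent, with negative ΔS as observed.

## Synthetic data (`synth`)

Every generator is a deterministic function of (truth, seed) and returns
a ground-truth sidecar; one global seed fans out to per-stage child
seeds by fixed offsets. Noise is Gaussian and relative (σ as a fraction
of the signal) by default — the study reports no noise distribution —
with absolute-σ modes where units demand it (ITC heats). The default
synthetic protein is a 68-residue rigid core numbered 159–227 (S² 0.85,
τe 50 ps; one proline gap at 186 so the count matches a realistic
assignment map) plus six flexible residues at each terminus (S² 0.3).
What the generators do *not* emulate: heteroscedastic, line-broadening-
dependent noise; residue-to-residue variation in Δω and intrinsic rates;
cross-correlated relaxation; anisotropic tumbling in the default truth.
Passing tests therefore demonstrate estimator correctness and
self-consistency at realistic signal-to-noise, not robustness to every
pathology of real spectra.

The RNA-duplex utility counts Watson–Crick (A:U, G:C) and G·U wobble
pairs over the literal antiparallel register (guide position i against
passenger position L+1−i), with overhangs reported for unequal strands;
no secondary-structure prediction is attempted. The printed D12
guide/passenger pair gives 11 WC + 1 wobble = 12 paired positions.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen for desk-scale runs: ITC
recovery uses 100 replicates (seconds); the correlation-time recovery
uses 60 residues at two fields (seconds); HARD recovery studies use 4–8
replicates per condition with a reduced 8×6 grid and Δω pinned, each fit
a few seconds. Optimizers are scipy least-squares (LM for unconstrained,
TRF with bounds elsewhere) with deterministic multi-starts; all
Monte-Carlo paths take explicit seeds and are bitwise reproducible.
Degenerate inputs (zero noise, zero heats, flat dispersion, Δω = 0,
empty selections) return exact values, sentinels, or typed errors as
documented per function rather than NaNs.
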