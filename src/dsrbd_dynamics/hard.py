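"""Adiabatic rotating-frame relaxation dispersion (HSn spin-lock trains).

Simulates and fits the dispersion produced by stretching hyperbolic-secant
(HSn) adiabatic pulses used as spin locks: waveform construction, direct
two-state Bloch-McConnell propagation through the pulse train, R1rho/R2rho
extraction across the HSn family, least-squares fitting of (pB, kex,
delta-omega, R2g), exchange-regime classification, and apo-vs-bound
delta-kex tables.

The propagator treats each pulse as piecewise constant over ``npoints``
steps and takes the exact matrix exponential of the 6x6 two-state
generator on each step (states A/B x components x,y,z; decay toward zero,
i.e. the thermal-equilibrium return term is omitted, as usual when only
decay rates are measured).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .io import IntensitySeries, DelaySchedule, ResidueID, SpectrometerContext
from .rates import fit_monoexponential

__all__ = [
    "AdiabaticPulse",
    "ExchangeParams",
    "NO_EXCHANGE",
    "build_hs_pulse",
    "pulse_propagator",
    "bm_propagate",
    "simulate_hard_rates",
    "fit_two_state",
    "classify_exchange",
    "delta_kex",
    "dw_ppm_to_rad",
]

#: sech(beta) = 1% amplitude truncation at the pulse edges
BETA = float(np.arccosh(100.0))


@dataclass(frozen=True)
class AdiabaticPulse:
    """A hyperbolic-secant HSn adiabatic pulse, piecewise-constant sampled.

    Amplitude A(t) = w1max * sech(beta * ((2t/Tp) - 1)^n); the carrier
    offset sweeps [-bw/2, +bw/2] as the normalized cumulative integral of
    A^2 (constant-adiabaticity sweep).  ``amplitude`` and ``offset`` hold
    the step-midpoint values in rad/s.
    """

    n: int
    tp: float
    w1max: float
    bandwidth: float
    npoints: int = 1024

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("stretching factor n must be >= 1")
        if self.tp <= 0 or self.w1max <= 0 or self.bandwidth <= 0:
            raise ValueError("Tp, w1max and bandwidth must be positive")
        if self.npoints < 64:
            raise ValueError("npoints must be >= 64")

    @property
    def dt(self) -> float:
        return self.tp / self.npoints

    def amplitude_at(self, t: np.ndarray) -> np.ndarray:
        x = 2.0 * np.asarray(t, dtype=float) / self.tp - 1.0
        return self.w1max / np.cosh(BETA * np.sign(x) * np.abs(x) ** self.n)

    @property
    def times(self) -> np.ndarray:
        """Step-midpoint times."""
        return (np.arange(self.npoints) + 0.5) * self.dt

    @property
    def amplitude(self) -> np.ndarray:
        return self.amplitude_at(self.times)

    def offset_at(self, t: np.ndarray) -> np.ndarray:
        """Carrier offset at arbitrary times via a dense cumulative grid."""
        grid = np.linspace(0.0, self.tp, 16385)
        a2 = self.amplitude_at(grid) ** 2
        cum = np.concatenate([[0.0], np.cumsum((a2[1:] + a2[:-1]) / 2.0)])
        frac = cum / cum[-1]
        return self.bandwidth * (np.interp(t, grid, frac) - 0.5)

    @property
    def offset(self) -> np.ndarray:
        return self.offset_at(self.times)

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.amplitude_at(t), self.offset_at(t)


@dataclass(frozen=True)
class ConstantLock:
    """A constant-amplitude, constant-offset spin lock.

    Interface-compatible with :class:`AdiabaticPulse` for propagation;
    used for closed-form rotating-frame oracles (tilt angle
    theta = atan2(w1, offset); decay rate R1 cos^2 theta + R2 sin^2 theta
    in the absence of exchange).
    """

    w1: float
    offset_value: float
    tp: float = 16e-3
    npoints: int = 64
    n: int = 0

    @property
    def dt(self) -> float:
        return self.tp / self.npoints

    @property
    def amplitude(self) -> np.ndarray:
        return np.full(self.npoints, self.w1)

    @property
    def offset(self) -> np.ndarray:
        return np.full(self.npoints, self.offset_value)

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t)
        return np.full(t.shape, self.w1), np.full(t.shape, self.offset_value)


def build_hs_pulse(n: int, tp: float = 16e-3,
                   w1max: float = 2 * np.pi * 2500.0,
                   bandwidth: float = 2 * np.pi * 5000.0,
                   npoints: int = 1024) -> AdiabaticPulse:
    """Construct an HSn pulse (defaults: Tp 16 ms, w1max/2pi 2.5 kHz,
    bandwidth/2pi 5 kHz, 1024 steps)."""
    return AdiabaticPulse(n=n, tp=tp, w1max=w1max, bandwidth=bandwidth,
                          npoints=npoints)


@dataclass(frozen=True)
class ExchangeParams:
    """Two-state exchange: ground A and excited B with pA + pB = 1.

    kex = kAB + kBA with kAB = pB kex and kBA = pA kex (detailed balance
    pA kAB = pB kBA).  dw is the B-minus-A 15N shift difference in rad/s;
    r1g/r2g are the intrinsic rates, assumed equal in both states.
    """

    pb: float
    kex: float
    dw: float
    r1g: float = 1.5
    r2g: float = 11.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pb <= 0.5):
            raise ValueError("pB must lie in (0, 0.5]")
        if self.kex < 0:
            raise ValueError("kex must be >= 0")
        if self.r1g < 0 or self.r2g < 0:
            raise ValueError("intrinsic rates must be >= 0")

    @property
    def pa(self) -> float:
        return 1.0 - self.pb

    @property
    def kab(self) -> float:
        return self.pb * self.kex

    @property
    def kba(self) -> float:
        return self.pa * self.kex


#: Sentinel returned by the fitter when the data carry no detectable dispersion.
NO_EXCHANGE = "no detectable exchange"


def dw_ppm_to_rad(dw_ppm: float, context: SpectrometerContext) -> float:
    """15N shift difference, ppm -> rad/s at the context's field."""
    return dw_ppm * 1e-6 * context.omega_n


def _batch_generators(amp: np.ndarray, off: np.ndarray,
                      p: ExchangeParams) -> np.ndarray:
    """Stack of per-step generators; carrier offset sweeps both states."""
    n = len(amp)
    ls = np.zeros((n, 6, 6))
    off_a = -off          # ground state on resonance with the sweep centre
    off_b = p.dw - off
    r2, r1 = p.r2g, p.r1g
    for base, o in ((0, off_a), (3, off_b)):
        x, y, z = base, base + 1, base + 2
        ls[:, x, x] = -r2
        ls[:, x, y] = o
        ls[:, y, x] = -o
        ls[:, y, y] = -r2
        ls[:, y, z] = amp
        ls[:, z, y] = -amp
        ls[:, z, z] = -r1
    eye = np.eye(3)
    ls[:, :3, :3] += -p.kab * eye
    ls[:, :3, 3:] += p.kba * eye
    ls[:, 3:, :3] += p.kab * eye
    ls[:, 3:, 3:] += -p.kba * eye
    return ls


def _expm_batch(ls: np.ndarray, dt: float) -> np.ndarray:
    """exp(L dt) for a stack of 6x6 generators via batched eigendecomposition,
    falling back to scipy expm for (near-)defective steps."""
    w, v = np.linalg.eig(ls)
    with np.errstate(all="ignore"):
        try:
            vinv = np.linalg.inv(v)
            props = np.real(v @ (np.exp(w * dt)[:, :, None] * vinv))
            # reconstruction check against one scipy expm as a spot guard
            check = np.einsum("nij,njk->nik", v, w[:, :, None] * vinv
                              ).real - ls
            bad = ~np.isfinite(props).all(axis=(1, 2))
            bad |= np.abs(check).max(axis=(1, 2)) > 1e-6 * max(
                1.0, np.abs(ls).max())
        except np.linalg.LinAlgError:
            props = np.empty_like(ls)
            bad = np.ones(len(ls), dtype=bool)
    for i in np.nonzero(bad)[0]:
        props[i] = expm(ls[i] * dt)
    return props


_GAUSS_OFFSET = np.sqrt(3.0) / 6.0

_NODE_CACHE: dict = {}


def _node_samples(pulse) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                  np.ndarray]:
    """Waveform values at the two Gauss nodes of every step (cached:
    they do not depend on the exchange parameters)."""
    key = pulse
    if key not in _NODE_CACHE:
        h = pulse.dt
        starts = np.arange(pulse.npoints) * h
        t1 = starts + (0.5 - _GAUSS_OFFSET) * h
        t2 = starts + (0.5 + _GAUSS_OFFSET) * h
        a1, o1 = pulse.sample(t1)
        a2, o2 = pulse.sample(t2)
        if len(_NODE_CACHE) > 256:
            _NODE_CACHE.clear()
        _NODE_CACHE[key] = (a1, o1, a2, o2)
    return _NODE_CACHE[key]


def pulse_propagator(params: ExchangeParams, pulse: AdiabaticPulse,
                     ) -> np.ndarray:
    """Propagator of the full pulse: fourth-order Magnus per step.

    Each of the ``npoints`` steps samples the waveform at the two
    Gauss-Legendre nodes; the step exponent is
    Omega = (h/2)(L1 + L2) + (sqrt(3) h^2 / 12)[L2, L1], which is exact
    for constant generators and fourth-order accurate for smooth sweeps.
    """
    h = pulse.dt
    a1, o1, a2, o2 = _node_samples(pulse)
    l1 = _batch_generators(a1, o1, params)
    l2 = _batch_generators(a2, o2, params)
    omega = (h / 2.0) * (l1 + l2) \
        + (np.sqrt(3.0) * h * h / 12.0) * (l2 @ l1 - l1 @ l2)
    props = _expm_batch(omega, 1.0)
    total = np.eye(6)
    for p in props:            # time ordering: earliest step applied first
        total = p @ total
    return total


def bm_propagate(params: ExchangeParams, pulse: AdiabaticPulse,
                 m0: np.ndarray, duration: float,
                 convergence_check: bool = False,
                 convergence_tol: float = 1e-6) -> np.ndarray:
    """Magnetization trajectory at pulse boundaries over ``duration``.

    ``duration`` must be an integer number of pulses.  Returns an array of
    shape (n_pulses + 1, 6) starting at ``m0``.  With
    ``convergence_check`` the per-pulse propagator is re-computed at twice
    the discretization and the trajectory must agree to
    ``convergence_tol`` (relative), otherwise an error advises a finer
    ``npoints``.
    """
    m0 = np.asarray(m0, dtype=float)
    if m0.shape != (6,):
        raise ValueError("m0 must be a 6-vector (A then B, components x,y,z)")
    n_pulses = duration / pulse.tp
    if abs(n_pulses - round(n_pulses)) > 1e-9:
        raise ValueError(
            f"duration {duration} s is not an integer multiple of the pulse "
            f"length {pulse.tp} s")
    n_pulses = int(round(n_pulses))
    prop = pulse_propagator(params, pulse)
    if convergence_check:
        fine = pulse_propagator(params, replace(pulse,
                                                npoints=2 * pulse.npoints))
        m_coarse = np.linalg.matrix_power(prop, max(n_pulses, 1)) @ m0
        m_fine = np.linalg.matrix_power(fine, max(n_pulses, 1)) @ m0
        scale = max(np.linalg.norm(m_fine), 1e-30)
        if np.linalg.norm(m_coarse - m_fine) / scale > convergence_tol:
            raise ValueError(
                f"pulse discretization not converged at npoints="
                f"{pulse.npoints}; increase npoints")
    traj = np.empty((n_pulses + 1, 6))
    traj[0] = m0
    m = m0
    for k in range(n_pulses):
        m = prop @ m
        traj[k + 1] = m
    return traj


def _rate_from_signal(delays: np.ndarray, signal: np.ndarray,
                      residue: ResidueID) -> float:
    schedule = DelaySchedule(tuple(delays), (False,) * len(delays))
    series = IntensitySeries(residue, schedule, signal)
    return fit_monoexponential(series).rate


def simulate_hard_rates(params: ExchangeParams,
                        pulses: Sequence[AdiabaticPulse],
                        delays_r1rho: Sequence[float],
                        delays_r2rho: Sequence[float],
                        residue: ResidueID = ResidueID(1),
                        ) -> dict:
    """Forward-simulate R1rho(HSn)/R2rho(HSn) and R1 for one residue.

    Delays must be integer multiples of the pulse length.  R1rho starts
    with magnetization along +z, R2rho along +x; the decaying signal is
    the projection onto (R1rho) or perpendicular to (R2rho) the
    end-of-train effective-field axis, which for a full sweep lies along
    z, and rates come from the same mono-exponential fitter as the
    laboratory-frame data.  R1 is the free (no spin lock) decay of z
    magnetization, which in this two-state model relaxes at r1g exactly.
    """
    delays_r1rho = np.asarray(sorted(delays_r1rho), dtype=float)
    delays_r2rho = np.asarray(sorted(delays_r2rho), dtype=float)
    out: dict = {"R1": params.r1g, "R1rho": {}, "R2rho": {}}
    mz0 = np.array([0.0, 0.0, params.pa, 0.0, 0.0, params.pb])
    mx0 = np.array([params.pa, 0.0, 0.0, params.pb, 0.0, 0.0])
    for pulse in pulses:
        for d in np.concatenate([delays_r1rho, delays_r2rho]):
            if abs(d / pulse.tp - round(d / pulse.tp)) > 1e-9:
                raise ValueError(
                    f"delay {d} s is not a multiple of Tp={pulse.tp} s")
        prop = pulse_propagator(params, pulse)
        max_k = int(round(max(delays_r1rho.max(), delays_r2rho.max())
                          / pulse.tp))
        powers = [np.eye(6)]
        for _ in range(max_k):
            powers.append(prop @ powers[-1])

        def signal(m0: np.ndarray, delays: np.ndarray,
                   transverse: bool) -> np.ndarray:
            s = np.empty(len(delays))
            for i, d in enumerate(delays):
                m = powers[int(round(d / pulse.tp))] @ m0
                tot = m[:3] + m[3:]
                if transverse:
                    s[i] = np.hypot(tot[0], tot[1])
                else:
                    s[i] = abs(tot[2])
            return s

        label = f"HS{pulse.n}"
        out["R1rho"][label] = _rate_from_signal(
            delays_r1rho, signal(mz0, delays_r1rho, transverse=False), residue)
        out["R2rho"][label] = _rate_from_signal(
            delays_r2rho, signal(mx0, delays_r2rho, transverse=True), residue)
    return out


# -- fitting -----------------------------------------------------------------

_GRID_LOG10_KEX = np.linspace(2.0, 6.0, 12)
_GRID_PB = np.geomspace(0.01, 0.5, 10)
_GRID_DW_PPM = np.geomspace(0.2, 6.0, 8)


@dataclass
class ExchangeFit:
    """Result of a two-state dispersion fit (or the no-exchange sentinel)."""

    detected: bool
    params: ExchangeParams | None = None
    chi2: float = np.nan
    kex_sigma: float = np.nan
    pb_sigma: float = np.nan

    @property
    def sentinel(self) -> str | None:
        return None if self.detected else NO_EXCHANGE


def _collect(row: dict, hsn: Sequence[str]) -> np.ndarray:
    return np.array([row["R1rho"][h] for h in hsn]
                    + [row["R2rho"][h] for h in hsn])


def fit_two_state(row: dict,
                  pulses: Sequence[AdiabaticPulse],
                  context: SpectrometerContext,
                  sigma: float = 0.02,
                  mc: int = 0,
                  seed: int | None = None,
                  fit_npoints: int = 96,
                  grid_npoints: int = 64,
                  grid_shape: tuple[int, int, int] | None = None,
                  fix_dw_ppm: float | None = None,
                  ) -> ExchangeFit:
    """Fit (pB, kex, dw, R2g) to one residue's HSn R1rho/R2rho dispersion.

    ``row`` is the structure returned by :func:`simulate_hard_rates`
    (R1, plus R1rho/R2rho per HSn); R1 fixes r1g.  A coarse grid in
    (log10 kex, pB, dw/ppm) with a data-driven R2g seeds a bounded local
    least-squares refinement in (log10 kex, logit pB, dw, R2g).
    ``sigma`` is the relative rate uncertainty used for chi2 scaling and
    the no-exchange test.  ``mc`` > 0 adds seeded Monte-Carlo spreads for
    kex and pB.

    In fast exchange (kex >> dw) only kex and the product
    pB (1-pB) dw^2 are identifiable, so a free dw leaves pB on a flat
    ridge; ``fix_dw_ppm`` pins dw (e.g. to an independently known shift
    difference) and makes pB well determined.
    """
    if len(pulses) < 3:
        raise ValueError("need >= 3 HSn conditions")
    hsn = [f"HS{p.n}" for p in pulses]
    observed = _collect(row, hsn)
    nh = len(hsn)
    r1g = float(row["R1"])
    sig_abs = np.maximum(sigma * np.abs(observed), 1e-6)

    delays_r1 = np.arange(0, 9) * pulses[0].tp
    delays_r2 = np.arange(0, 5) * pulses[0].tp

    def forward(pb: float, kex: float, dw: float, r2g: float,
                npoints: int) -> np.ndarray:
        p = ExchangeParams(pb=pb, kex=kex, dw=dw, r1g=r1g, r2g=max(r2g, 0.0))
        sim = simulate_hard_rates(
            p, [replace(pl, npoints=npoints) for pl in pulses],
            delays_r1, delays_r2)
        return _collect(sim, hsn)

    # Even without exchange the HSn rates are not flat: the effective-field
    # geometry mixes R1 and R2 differently per stretching factor.  The
    # no-exchange sentinel therefore tests the data against the fitted
    # exchange-free baseline, not against a constant.
    def noex_chi2(r2g: float) -> float:
        pred = forward(1e-3, 0.0, 0.0, r2g, grid_npoints)
        return float(np.sum(((pred - observed) / sig_abs) ** 2))

    from scipy.optimize import minimize_scalar

    res0 = minimize_scalar(noex_chi2, bounds=(0.0, 2.0 * max(observed)),
                           method="bounded", options={"xatol": 1e-3})
    if res0.fun / (2 * nh) < 2.0:
        return ExchangeFit(detected=False, chi2=float(res0.fun))

    # data-driven R2g for the grid stage: the strongest lock (largest n)
    # suppresses exchange the most, so R2rho(HS_max) bounds r2g from above
    r2g0 = float(min(observed[nh:]))
    if grid_shape is not None:
        g_kex = np.linspace(2.0, 6.0, grid_shape[0])
        g_pb = np.geomspace(0.01, 0.5, grid_shape[1])
        g_dw = np.geomspace(0.2, 6.0, grid_shape[2])
    else:
        g_kex, g_pb, g_dw = _GRID_LOG10_KEX, _GRID_PB, _GRID_DW_PPM
    if fix_dw_ppm is not None:
        g_dw = np.array([fix_dw_ppm])

    scored = []
    for lk in g_kex:
        for pb in g_pb:
            for dwp in g_dw:
                pred = forward(pb, 10.0**lk, dw_ppm_to_rad(dwp, context),
                               r2g0, grid_npoints)
                chi2 = float(np.sum(((pred - observed) / sig_abs) ** 2))
                scored.append((chi2, lk, pb, dwp))
    scored.sort(key=lambda s: s[0])

    def logit(p: float) -> float:
        return np.log(p / (1.0 - p))

    def expit(x: float) -> float:
        return 1.0 / (1.0 + np.exp(-x))

    def unpack(x: np.ndarray) -> tuple[float, float, float, float]:
        if fix_dw_ppm is None:
            lk, lp, dwp, r2g = x
        else:
            lk, lp, r2g = x
            dwp = fix_dw_ppm
        pb = 0.5 * expit(lp)          # maps R -> (0, 0.5)
        return float(np.clip(pb, 1e-4, 0.5)), 10.0**lk, \
            dw_ppm_to_rad(dwp, context), r2g

    def residuals(x: np.ndarray) -> np.ndarray:
        pb, kex, dw, r2g = unpack(x)
        return (forward(pb, kex, dw, r2g, fit_npoints) - observed) / sig_abs

    # refine from the best few grid points: the (pB, dw, kex) surface is
    # multimodal because pB (1-pB) dw^2 trades against kex in fast exchange
    sol = None
    for chi2_g, lk0, pb0, dw0 in scored[:3]:
        lp0 = logit(min(pb0 / 0.5, 1 - 1e-6))
        if fix_dw_ppm is None:
            x0 = np.array([lk0, lp0, dw0, r2g0])
        else:
            x0 = np.array([lk0, lp0, r2g0])
        cand = optimize_least_squares(residuals, x0, max_nfev=60)
        if sol is None or float(np.sum(cand.fun**2)) < float(np.sum(sol.fun**2)):
            sol = cand
    pb, kex, dw, r2g = unpack(sol.x)
    fitted = ExchangeParams(pb=pb, kex=kex, dw=dw, r1g=r1g, r2g=max(r2g, 0.0))
    fit = ExchangeFit(detected=True, params=fitted,
                      chi2=float(np.sum(sol.fun**2)))

    if mc > 0:
        rng = np.random.default_rng(seed)
        kexs, pbs = [], []
        base_pred = forward(pb, kex, dw, r2g, fit_npoints)
        for _ in range(mc):
            noisy = base_pred + rng.normal(0.0, sig_abs)
            sol_k = optimize_least_squares(
                lambda x: (forward(*unpack(x), fit_npoints) - noisy) / sig_abs,
                sol.x, max_nfev=25)
            pb_k, kex_k, _, _ = unpack(sol_k.x)
            kexs.append(kex_k)
            pbs.append(pb_k)
        fit.kex_sigma = float(np.std(kexs, ddof=1))
        fit.pb_sigma = float(np.std(pbs, ddof=1))
    return fit


def optimize_least_squares(fun, x0, max_nfev: int | None = None):
    from scipy.optimize import least_squares

    return least_squares(fun, x0, method="lm", xtol=1e-8, ftol=1e-8,
                         max_nfev=max_nfev)


KEX_BINS = (5000.0, 50000.0)
PB_BINS = (0.10, 0.20, 0.40)


def classify_exchange(fit: ExchangeFit | ExchangeParams | str) -> dict:
    """Bin a fitted exchange process by kex and pB.

    kex: slow < 5000, fast 5000-50,000, very_fast > 50,000 s^-1 (lower
    edge exclusive: kex = 4999 is slow).  pB bins: <10%, 10-20%, 20-40%,
    >40%.  The no-exchange sentinel maps to category 'none'.
    """
    if isinstance(fit, str):
        if fit == NO_EXCHANGE:
            return {"kex_class": "none", "pb_class": "none"}
        raise ValueError(f"unknown sentinel {fit!r}")
    if isinstance(fit, ExchangeFit):
        if not fit.detected:
            return {"kex_class": "none", "pb_class": "none"}
        params = fit.params
    else:
        params = fit
    kex, pb = params.kex, params.pb
    if kex > KEX_BINS[1]:
        kc = "very_fast"
    elif kex > KEX_BINS[0]:
        kc = "fast"
    else:
        kc = "slow"
    if pb > PB_BINS[2]:
        pc = ">40%"
    elif pb > PB_BINS[1]:
        pc = "20-40%"
    elif pb > PB_BINS[0]:
        pc = "10-20%"
    else:
        pc = "<10%"
    return {"kex_class": kc, "pb_class": pc}


def delta_kex(apo_fits: dict[int, ExchangeFit],
              bound_fits: dict[int, ExchangeFit],
              threshold: float = 10000.0) -> pd.DataFrame:
    """Per-residue delta-kex = kex(bound) - kex(apo) with significance flags.

    |delta| strictly greater than ``threshold`` is flagged, with the sign
    recorded as induced (bound faster) or quenched.  Residues fitted in
    only one state get a missing-state marker instead of a delta.
    """
    rows = []
    for num in sorted(set(apo_fits) | set(bound_fits)):
        a, b = apo_fits.get(num), bound_fits.get(num)

        def kex_of(f: ExchangeFit | None) -> float | None:
            if f is None or not f.detected:
                return None
            return f.params.kex

        ka, kb = kex_of(a), kex_of(b)
        if num not in apo_fits or num not in bound_fits:
            rows.append({"residue": num, "kex_apo": ka, "kex_bound": kb,
                         "delta_kex": np.nan, "flag": "missing-state"})
            continue
        ka = ka if ka is not None else 0.0
        kb = kb if kb is not None else 0.0
        delta = kb - ka
        if abs(delta) > threshold:
            flag = "induced" if delta > 0 else "quenched"
        else:
            flag = ""
        rows.append({"residue": num, "kex_apo": ka, "kex_bound": kb,
                     "delta_kex": delta, "flag": flag})
    return pd.DataFrame(rows,
                        columns=["residue", "kex_apo", "kex_bound",
                                 "delta_kex", "flag"])
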