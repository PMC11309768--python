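"""Equilibrium protein-RNA binding: titration isotherms and single-site ITC.

Concentrations are molar internally (micromolar only at the I/O edges);
injection heats are in microcalories and enthalpies in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import optimize

__all__ = [
    "BindingModel",
    "TitrationCurve",
    "ItcExperiment",
    "solve_fraction_bound",
    "fit_titration",
    "compute_csp",
    "simulate_itc",
    "fit_itc_single_site",
    "UnderSampledWarning",
    "WideConfidenceWarning",
]

R_GAS_KCAL = 1.98720425864083e-3  # kcal mol^-1 K^-1
KCAL_TO_UCAL = 1e9


class UnderSampledWarning(UserWarning):
    """Titration stops well short of the isotherm inflection point."""


class WideConfidenceWarning(UserWarning):
    """Non-saturating or heat-free data: fitted parameters poorly bounded."""


@dataclass(frozen=True)
class BindingModel:
    """Single-site binding: Kd (M), dH (kcal/mol), stoichiometry n
    (sites per cell-side macromolecule), and the titration response
    amplitude ddmax (peak-intensity change or ppm at saturation)."""

    kd: float
    dh: float = 0.0
    n: float = 1.0
    ddmax: float = 1.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry must be positive")

    def dg(self, temperature: float = 298.15) -> float:
        """Binding free energy, kcal/mol (negative for Kd < 1 M)."""
        return R_GAS_KCAL * temperature * np.log(self.kd)

    def ds(self, temperature: float = 298.15) -> float:
        """Binding entropy, kcal mol^-1 K^-1, from dG = dH - T dS."""
        return (self.dh - self.dg(temperature)) / temperature


@dataclass
class TitrationCurve:
    """Response vs total ligand at fixed total protein.

    ``response_type`` labels whether ddobs is a peak-intensity change or a
    chemical-shift change; the isotherm treats both identically but the
    label is carried through.
    """

    pt: float
    lt: np.ndarray
    ddobs: np.ndarray
    sigma: np.ndarray | None = None
    response_type: str = "intensity"

    def __post_init__(self) -> None:
        self.lt = np.asarray(self.lt, dtype=float)
        self.ddobs = np.asarray(self.ddobs, dtype=float)
        if np.any(self.lt < 0):
            raise ValueError("total ligand concentrations must be >= 0")
        if np.any(np.diff(self.lt) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class ItcExperiment:
    """Injection-heat record of one calorimetric titration.

    The first (discardable) small injection is not part of ``heats``:
    ``injection_volumes`` lists the retained injections only, and
    ``predelivered`` the volume already displaced by discarded
    injection(s).
    """

    v0: float
    cell_concentration: float
    syringe_concentration: float
    injection_volumes: np.ndarray
    heats: np.ndarray
    predelivered: float = 0.4e-6
    temperature: float = 298.15

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.v0 <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if len(self.heats) != len(self.injection_volumes):
            raise ValueError(
                "heats list length must equal the number of retained injections")


def solve_fraction_bound(pt: float, lt: float, kd: float) -> dict:
    """Exact two-state complex concentration from the quadratic equilibrium.

    [PL] = ((Pt + Lt + Kd) - sqrt((Pt + Lt + Kd)^2 - 4 Pt Lt)) / 2.
    """
    if pt < 0 or lt < 0:
        raise ValueError("totals must be >= 0")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    s = pt + lt + kd
    disc = s * s - 4.0 * pt * lt
    complex_ = (s - np.sqrt(max(disc, 0.0))) / 2.0
    complex_ = float(min(complex_, min(pt, lt)))
    return {
        "complex": complex_,
        "fraction_P": complex_ / pt if pt > 0 else 0.0,
        "fraction_L": complex_ / lt if lt > 0 else 0.0,
    }


def _isotherm(lt: np.ndarray, pt: float, kd: float, ddmax: float) -> np.ndarray:
    s = pt + lt + kd
    return ddmax * (s - np.sqrt(s * s - 4.0 * pt * lt)) / (2.0 * pt)


def fit_titration(curve: TitrationCurve, mc: int = 0,
                  seed: int | None = None) -> dict:
    """Least-squares (Kd, ddmax) fit of the one-site titration isotherm.

    Warns (:class:`UnderSampledWarning`) when the titration never reaches
    the Kd scale, i.e. max [L]t < Kd, where the inflection is unsampled
    and the parameters are poorly determined.  Monte-Carlo parameter
    spreads are produced when ``mc`` > 0 and per-point sigmas exist.
    """
    if len(curve.lt) < 4:
        raise ValueError("need >= 4 titration points")
    lt, dd = curve.lt, curve.ddobs
    sig = curve.sigma if curve.sigma is not None else np.ones_like(dd)
    sig = np.where(sig > 0, sig, 1.0)

    span = max(dd.max() - dd.min(), 1e-12)

    def residuals(x: np.ndarray) -> np.ndarray:
        kd, ddmax = np.exp(np.clip(x[0], -60.0, 5.0)), x[1]
        return (_isotherm(lt, curve.pt, kd, ddmax) - dd) / sig

    best = None
    for kd0 in (0.1 * curve.pt, curve.pt, 10.0 * curve.pt):
        sol = optimize.least_squares(residuals, x0=[np.log(kd0), span],
                                     method="lm", xtol=1e-14, ftol=1e-14)
        chi2 = float(np.sum(sol.fun**2))
        if best is None or chi2 < best[1]:
            best = (sol, chi2)
    sol, chi2 = best
    kd, ddmax = float(np.exp(np.clip(sol.x[0], -60.0, 5.0))), float(sol.x[1])
    # under-sampling diagnostics: the titration never reaches the Kd scale,
    # or the fitted curve is still far from its saturation plateau at the
    # last point (no data at the inflection)
    final_frac = _isotherm(np.array([lt.max()]), curve.pt, kd, 1.0)[0]
    if lt.max() < kd or final_frac < 0.9:
        warnings.warn(
            f"titration under-sampled: fitted response reaches only "
            f"{100 * final_frac:.0f}% of saturation at max [L]t = "
            f"{lt.max():.3g} M (Kd = {kd:.3g} M); no data at the "
            f"inflection point", UnderSampledWarning, stacklevel=2)
    out = {"kd": kd, "ddmax": ddmax, "chi2": chi2}
    if mc > 0 and curve.sigma is not None:
        rng = np.random.default_rng(seed)
        model = _isotherm(lt, curve.pt, kd, ddmax)
        kds, dms = [], []
        for _ in range(mc):
            noisy = model + rng.normal(0.0, sig)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol_k = optimize.least_squares(
                    lambda x: (_isotherm(lt, curve.pt, np.exp(x[0]), x[1])
                               - noisy) / sig,
                    x0=sol.x, method="lm")
            kds.append(np.exp(sol_k.x[0]))
            dms.append(sol_k.x[1])
        out["kd_sigma"] = float(np.std(kds, ddof=1))
        out["ddmax_sigma"] = float(np.std(dms, ddof=1))
    return out


def compute_csp(ddh: float, ddn: float, alpha_n: float = 0.14) -> float:
    """Combined 1H/15N chemical-shift perturbation, ppm:
    sqrt(ddH^2 + (alpha_N ddN)^2)."""
    if not (0.0 < alpha_n <= 1.0):
        raise ValueError("alpha_n must lie in (0, 1]")
    return float(np.hypot(ddh, alpha_n * ddn))


def _itc_cumulative_heat(model: BindingModel, v0: float, cell0: float,
                         syringe: float, delivered: np.ndarray) -> np.ndarray:
    """Cumulative heat content Q (ucal) after each cumulative delivered
    volume, with the standard perfusion dilution of both species."""
    frac = delivered / v0
    mt = cell0 * (1.0 - frac / 2.0) / (1.0 + frac / 2.0)
    xt = syringe * frac * (1.0 - frac / 2.0)
    # fraction of sites occupied from the quadratic binding polynomial
    with np.errstate(invalid="ignore"):
        b = 1.0 + xt / (model.n * mt) + model.kd / (model.n * mt)
        theta = (b - np.sqrt(b * b - 4.0 * xt / (model.n * mt))) / 2.0
    theta = np.where(mt > 0, theta, 0.0)
    return model.n * theta * mt * model.dh * v0 * KCAL_TO_UCAL


def simulate_itc(model: BindingModel, v0: float = 200e-6,
                 cell_concentration: float = 10e-6,
                 syringe_concentration: float = 130e-6,
                 n_injections: int = 18,
                 injection_volume: float = 2e-6,
                 first_injection_volume: float = 0.4e-6,
                 noise_sigma: float = 0.0,
                 seed: int | None = None,
                 dilution_offset: float = 0.0,
                 temperature: float = 298.15) -> ItcExperiment:
    """Simulate a single-site ITC run with the instrument's injection scheme.

    One small first injection (volume ``first_injection_volume``) is
    delivered and discarded, followed by ``n_injections`` retained
    injections.  Per-injection heats include the displaced-volume
    correction dQ(i) = Q(i) + (dVi/V0) (Q(i) + Q(i-1))/2 - Q(i-1), an
    optional constant dilution offset, and Gaussian noise of
    ``noise_sigma`` ucal.
    """
    if syringe_concentration <= 0:
        raise ValueError("syringe concentration must be positive")
    volumes = np.full(n_injections, injection_volume)
    delivered = first_injection_volume + np.cumsum(volumes)
    all_delivered = np.concatenate([[first_injection_volume], delivered])
    q = _itc_cumulative_heat(model, v0, cell_concentration,
                             syringe_concentration, all_delivered)
    dq = q[1:] - q[:-1] + (volumes / v0) * (q[1:] + q[:-1]) / 2.0
    dq = dq + dilution_offset
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dq = dq + rng.normal(0.0, noise_sigma, size=dq.shape)
    return ItcExperiment(
        v0=v0, cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=volumes, heats=dq,
        predelivered=first_injection_volume, temperature=temperature)


def fit_itc_single_site(experiment: ItcExperiment, mc: int = 0,
                        seed: int | None = None,
                        fit_dilution: bool = True) -> dict:
    """Least-squares (Kd, dH, n[, dilution offset]) single-site ITC fit.

    Uses the same forward model as :func:`simulate_itc`; dS is derived via
    dG = dH - T dS at the experiment temperature.  Warns
    (:class:`WideConfidenceWarning`) when the data never approach
    saturation or carry no heat, in which case Kd is unbounded above.
    """
    if len(experiment.heats) < 8:
        raise ValueError("need >= 8 retained injections")
    volumes = experiment.injection_volumes
    delivered = experiment.predelivered + np.cumsum(volumes)
    all_delivered = np.concatenate([[experiment.predelivered], delivered])
    heats = experiment.heats

    def model_heats(kd: float, dh: float, n: float, offset: float) -> np.ndarray:
        m = BindingModel(kd=kd, dh=dh, n=n)
        q = _itc_cumulative_heat(m, experiment.v0,
                                 experiment.cell_concentration,
                                 experiment.syringe_concentration,
                                 all_delivered)
        return q[1:] - q[:-1] + (volumes / experiment.v0) * (q[1:] + q[:-1]) \
            / 2.0 + offset

    scale = max(np.max(np.abs(heats)), 1e-9)
    dh0 = heats[0] / (experiment.syringe_concentration * volumes[0]
                      * KCAL_TO_UCAL)

    def residuals(x: np.ndarray) -> np.ndarray:
        kd = np.exp(np.clip(x[0], -60.0, 5.0))
        dh, n = x[1], np.exp(np.clip(x[2], -10.0, 10.0))
        offset = x[3] if fit_dilution else 0.0
        return (model_heats(kd, dh, n, offset) - heats) / scale

    best = None
    for kd0 in (0.1e-6, 1e-6, 10e-6):
        x0 = [np.log(kd0), dh0 if np.isfinite(dh0) and dh0 != 0 else -5.0,
              0.0, 0.0]
        if not fit_dilution:
            x0 = x0[:3] + [0.0]
        try:
            sol = optimize.least_squares(residuals, x0=x0, method="lm",
                                         xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun**2))
        if best is None or chi2 < best[1]:
            best = (sol, chi2)
    if best is None:
        raise RuntimeError("single-site ITC fit failed from all starts")
    sol, chi2 = best
    kd, dh, n = float(np.exp(sol.x[0])), float(sol.x[1]), float(np.exp(sol.x[2]))
    offset = float(sol.x[3]) if fit_dilution else 0.0
    model = BindingModel(kd=kd, dh=dh, n=n)

    # saturation diagnostic: occupancy reached in the last injection
    final = solve_fraction_bound(
        experiment.cell_concentration * n,
        experiment.syringe_concentration * all_delivered[-1] / experiment.v0,
        kd)["fraction_P"]
    noise_floor = float(np.std(np.diff(heats)) / np.sqrt(2.0)) \
        if len(heats) > 2 else 0.0
    if final < 0.8 or np.max(np.abs(heats)) < 4.0 * max(noise_floor, 1e-12):
        warnings.warn(
            "titration does not approach saturation (or carries no heat); "
            "fitted Kd/n have wide confidence intervals",
            WideConfidenceWarning, stacklevel=2)

    out = {"kd": kd, "dh": dh, "n": n, "dilution_offset": offset,
           "chi2": chi2, "dg": model.dg(experiment.temperature),
           "ds": model.ds(experiment.temperature)}
    if mc > 0:
        rng = np.random.default_rng(seed)
        base = model_heats(kd, dh, n, offset)
        resid_sd = float(np.std(heats - base, ddof=1))
        kds, dhs, ns = [], [], []
        for _ in range(mc):
            noisy = base + rng.normal(0.0, resid_sd, size=base.shape)
            sol_k = optimize.least_squares(
                lambda x: (model_heats(np.exp(x[0]), x[1], np.exp(x[2]),
                                       x[3] if fit_dilution else 0.0)
                           - noisy) / scale,
                x0=sol.x, method="lm")
            kds.append(np.exp(sol_k.x[0]))
            dhs.append(sol_k.x[1])
            ns.append(np.exp(sol_k.x[2]))
        out["kd_sigma"] = float(np.std(kds, ddof=1))
        out["dh_sigma"] = float(np.std(dhs, ddof=1))
        out["n_sigma"] = float(np.std(ns, ddof=1))
    return out
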