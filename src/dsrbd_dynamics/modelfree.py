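"""Extended Lipari-Szabo model-free analysis of 15N backbone relaxation.

Spectral densities (isotropic or axially symmetric global diffusion, with
fast/slow internal motions), forward prediction of R1/R2/nOe at multiple
static fields, R2/R1-based and global correlation-time estimation,
per-residue model selection over the conventional m0-m8 ladder, and Rex
extraction.

The spectral density is

    J(w) = (2/5) sum_k A_k [ S2 tk/(1+(w tk)^2)
                             + (1-Sf2) tf'_k/(1+(w tf'_k)^2)
                             + (Sf2-S2) ts'_k/(1+(w ts'_k)^2) ]

with tx'_k = tx tk/(tx + tk).  For isotropic tumbling there is a single
global time tk = tc (A = 1); for axially symmetric diffusion the three
Woessner terms are weighted by the N-H vector's angle to the unique axis.
Setting Sf2 = 1 recovers the original two-parameter form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import GAMMA_H, GAMMA_N, RateTable, SpectrometerContext

__all__ = [
    "PhysicalConstants",
    "ModelFreeParams",
    "DiffusionModel",
    "Observation",
    "spectral_density",
    "predict_relaxation",
    "estimate_tc_from_r2r1",
    "fit_modelfree_residue",
    "fit_global_diffusion",
    "extract_rex_map",
    "MODEL_LADDER",
]

MU0 = 4.0e-7 * np.pi
HBAR = 1.054571817e-34


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the dipolar/CSA relaxation mechanism.

    Defaults: r(N-H) = 1.02 A, 15N CSA = -172 ppm, and the 1H/15N
    gyromagnetic ratios.  The dipolar constant d and CSA constant c are
    derived per field, never stored.
    """

    r_nh: float = 1.02e-10
    csa_ppm: float = -172.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    def __post_init__(self) -> None:
        if self.r_nh <= 0:
            raise ValueError("N-H bond length must be positive")

    def dipolar(self) -> float:
        """d = (mu0/4pi) hbar gammaH gammaN / r^3, rad/s (magnitude)."""
        return (MU0 / (4 * np.pi)) * HBAR * self.gamma_h * abs(self.gamma_n) \
            / self.r_nh**3

    def csa(self, omega_n: float) -> float:
        """c = omegaN * |CSA| / sqrt(3), rad/s."""
        return omega_n * abs(self.csa_ppm) * 1e-6 / np.sqrt(3.0)


@dataclass(frozen=True)
class ModelFreeParams:
    """Internal-motion parameters of one residue.

    s2 is the generalized order parameter (S2 = Sf2 * Ss2), sf2 the
    fast-motion order parameter, tau_f / tau_s the fast and slow internal
    correlation times (s), and rex the exchange broadening (s^-1) at the
    reference field.
    """

    s2: float
    sf2: float = 1.0
    tau_s: float = 0.0
    tau_f: float = 0.0
    rex: float = 0.0
    model_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2 <= self.sf2 <= 1.0 + 1e-12):
            raise ValueError(
                f"require 0 <= S2 <= Sf2 <= 1, got S2={self.s2}, Sf2={self.sf2}"
            )
        if self.tau_s < 0 or self.tau_f < 0:
            raise ValueError("internal correlation times must be >= 0")
        if self.rex < 0:
            raise ValueError("Rex must be >= 0")


@dataclass(frozen=True)
class DiffusionModel:
    """Global rotational diffusion: isotropic or axially symmetric.

    tc is the isotropic correlation time 1/(6 D_iso) in seconds.  For the
    axial kind, ratio = D_par/D_perp and (theta, phi) orient the unique
    axis; per-residue N-H orientations enter through the angle alpha
    between the N-H vector and that axis.
    """

    kind: str = "isotropic"
    tc: float = 7.3e-9
    ratio: float = 1.0
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "axially_symmetric"):
            raise ValueError(f"unknown diffusion kind {self.kind!r}")
        if self.tc <= 0:
            raise ValueError("tc must be positive")
        if self.ratio <= 0:
            raise ValueError("anisotropy ratio must be positive")

    def axis(self) -> np.ndarray:
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return np.array([st * np.cos(self.phi), st * np.sin(self.phi), ct])

    def components(self, alpha: float | None) -> tuple[np.ndarray, np.ndarray]:
        """Woessner weights A_k and correlation times t_k for one residue."""
        if self.kind == "isotropic":
            return np.array([1.0]), np.array([self.tc])
        if alpha is None:
            raise ValueError(
                "axially symmetric diffusion needs a per-residue N-H angle"
            )
        d_iso = 1.0 / (6.0 * self.tc)
        d_perp = 3.0 * d_iso / (2.0 + self.ratio)
        d_par = self.ratio * d_perp
        taus = np.array([
            1.0 / (6.0 * d_perp),
            1.0 / (5.0 * d_perp + d_par),
            1.0 / (2.0 * d_perp + 4.0 * d_par),
        ])
        c, s = np.cos(alpha), np.sin(alpha)
        weights = np.array([
            (1.5 * c * c - 0.5) ** 2,
            3.0 * s * s * c * c,
            0.75 * s**4,
        ])
        return weights, taus


def _lorentzian_mix(tau_global: np.ndarray, tau_int: float,
                    omega: np.ndarray) -> np.ndarray:
    """sum over k of tau'_k / (1 + (w tau'_k)^2) with tau' = t ti/(t+ti)."""
    if tau_int <= 0:
        return np.zeros((len(tau_global), len(omega)))
    tp = tau_global * tau_int / (tau_global + tau_int)
    return tp[:, None] / (1.0 + (omega[None, :] * tp[:, None]) ** 2)


def spectral_density(params: ModelFreeParams, diffusion: DiffusionModel,
                     omega: float | np.ndarray,
                     alpha: float | None = None) -> float | np.ndarray:
    """Extended model-free J(omega) in s/rad; omega in rad/s, >= 0."""
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(w < 0):
        raise ValueError("omega must be >= 0")
    weights, taus = diffusion.components(alpha)
    core = taus[:, None] / (1.0 + (w[None, :] * taus[:, None]) ** 2)
    total = params.s2 * core
    if params.sf2 < 1.0:
        total = total + (1.0 - params.sf2) * _lorentzian_mix(taus, params.tau_f, w)
    if params.sf2 - params.s2 > 0.0:
        total = total + (params.sf2 - params.s2) * _lorentzian_mix(
            taus, params.tau_s, w)
    j = 0.4 * np.einsum("k,kw->w", weights, total)
    return float(j[0]) if np.isscalar(omega) else j


def predict_relaxation(params: ModelFreeParams, diffusion: DiffusionModel,
                       context: SpectrometerContext,
                       constants: PhysicalConstants = PhysicalConstants(),
                       alpha: float | None = None,
                       reference_field_mhz: float = 600.0,
                       ) -> tuple[float, float, float]:
    """Forward-predict (R1, R2, nOe) from model-free parameters.

    Rex is referenced to ``reference_field_mhz`` and scales with the
    square of the field when predicting elsewhere.
    """
    wh, wn = context.omega_h, context.omega_n
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    j0, jn, jhmn, jh, jhpn = spectral_density(params, diffusion, freqs, alpha)
    d = constants.dipolar()
    c = constants.csa(wn)
    d2, c2 = d * d, c * c

    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    rex = params.rex * (context.proton_frequency / reference_field_mhz) ** 2
    r2 = (d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + rex
    gamma_ratio = constants.gamma_h / constants.gamma_n
    noe = 1.0 + (d2 / 4.0) * gamma_ratio * (6.0 * jhpn - jhmn) / r1
    return float(r1), float(r2), float(noe)


def estimate_tc_from_r2r1(table: RateTable, window: Sequence[int],
                          field_mhz: float, state: str | None = None,
                          constants: PhysicalConstants = PhysicalConstants(),
                          noe_cutoff: float = 0.65,
                          trim: float = 0.1,
                          min_residues: int = 5) -> float:
    """Global tc from the trimmed-mean R2/R1 ratio of rigid-candidate residues.

    Residues inside ``window`` with nOe above ``noe_cutoff`` are treated as
    rigid; tc solves the rigid-limit (S2 = 1, no Rex) ratio equation by a
    1-D root search.  This is the standard initializer for the global
    diffusion fit.
    """
    lo, hi = int(window[0]), int(window[1])
    r1 = table.select("R1", field_mhz=field_mhz, state=state, window=(lo, hi))
    r2 = table.select("R2", field_mhz=field_mhz, state=state, window=(lo, hi))
    noe = table.select("noe", field_mhz=field_mhz, state=state, window=(lo, hi))
    rigid = set(noe.loc[noe["value"] > noe_cutoff, "residue"])
    merged = r1.merge(r2, on="residue", suffixes=("_r1", "_r2"))
    merged = merged[merged["residue"].isin(rigid)]
    if len(merged) < min_residues:
        raise ValueError(
            f"need >= {min_residues} rigid-candidate residues "
            f"(nOe > {noe_cutoff}); found {len(merged)}"
        )
    ratios = (merged["value_r2"] / merged["value_r1"]).to_numpy(float)
    ratios = np.sort(ratios)
    k = int(np.floor(trim * len(ratios)))
    if k > 0 and len(ratios) - 2 * k >= 3:
        ratios = ratios[k:len(ratios) - k]
    target = float(np.mean(ratios))

    context = SpectrometerContext(field_mhz)
    rigid_params = ModelFreeParams(s2=1.0)

    def f(tc: float) -> float:
        diff = DiffusionModel("isotropic", tc=tc)
        pr1, pr2, _ = predict_relaxation(rigid_params, diff, context, constants)
        return pr2 / pr1 - target

    lo_tc, hi_tc = 0.5e-9, 60e-9
    if f(lo_tc) > 0:
        raise ValueError("R2/R1 ratio below the rigid-limit range")
    return float(optimize.brentq(f, lo_tc, hi_tc, xtol=1e-14))


@dataclass(frozen=True)
class Observation:
    """One relaxation observable of one residue at one field."""

    kind: str  # R1 | R2 | noe
    field_mhz: float
    value: float
    sigma: float


#: Conventional model ladder: free parameters per model id.
MODEL_LADDER: dict[str, tuple[str, ...]] = {
    "m0": (),
    "m1": ("s2",),
    "m2": ("s2", "tau_s"),
    "m3": ("s2", "rex"),
    "m4": ("s2", "tau_s", "rex"),
    "m5": ("sf2", "ss2", "tau_s"),
    "m6": ("sf2", "ss2", "tau_s", "rex"),
    "m7": ("sf2", "ss2", "tau_f", "tau_s"),
    "m8": ("sf2", "ss2", "tau_f", "tau_s", "rex"),
}

_BOUNDS = {
    "s2": (0.0, 1.0),
    "sf2": (0.0, 1.0),
    "ss2": (0.0, 1.0),
    "tau_s": (0.0, 3e-9),
    "tau_f": (0.0, 3e-10),
    "rex": (0.0, 30.0),
}

_STARTS = {
    "s2": (0.9, 0.8, 0.6, 0.95, 0.4),
    "sf2": (0.95, 0.85, 0.9, 0.99, 0.7),
    "ss2": (0.9, 0.85, 0.7, 0.95, 0.5),
    "tau_s": (5e-11, 2e-10, 1e-9, 2e-11, 5e-10),
    "tau_f": (1e-11, 5e-11, 2e-11, 8e-11, 3e-11),
    "rex": (0.5, 2.0, 5.0, 0.1, 10.0),
}


def _params_from_vector(model_id: str, names: tuple[str, ...],
                        x: np.ndarray) -> ModelFreeParams:
    vals = dict(zip(names, x))
    if "sf2" in vals:
        sf2 = float(np.clip(vals["sf2"], 0.0, 1.0))
        s2 = sf2 * float(np.clip(vals.get("ss2", 1.0), 0.0, 1.0))
    else:
        sf2 = 1.0
        s2 = float(np.clip(vals.get("s2", 1.0), 0.0, 1.0))
    return ModelFreeParams(
        s2=s2, sf2=sf2,
        tau_s=float(max(vals.get("tau_s", 0.0), 0.0)),
        tau_f=float(max(vals.get("tau_f", 0.0), 0.0)),
        rex=float(max(vals.get("rex", 0.0), 0.0)),
        model_id=model_id,
    )


def _residuals(params: ModelFreeParams, diffusion: DiffusionModel,
               observations: Sequence[Observation],
               constants: PhysicalConstants, alpha: float | None,
               reference_field_mhz: float) -> np.ndarray:
    preds: dict[float, tuple[float, float, float]] = {}
    out = np.empty(len(observations))
    for i, obs in enumerate(observations):
        if obs.field_mhz not in preds:
            preds[obs.field_mhz] = predict_relaxation(
                params, diffusion, SpectrometerContext(obs.field_mhz),
                constants, alpha, reference_field_mhz)
        r1, r2, noe = preds[obs.field_mhz]
        model = {"R1": r1, "R2": r2, "noe": noe}[obs.kind]
        sigma = obs.sigma if obs.sigma > 0 else 1.0
        out[i] = (model - obs.value) / sigma
    return out


def _fit_single_model(model_id: str, observations: Sequence[Observation],
                      diffusion: DiffusionModel,
                      constants: PhysicalConstants, alpha: float | None,
                      reference_field_mhz: float,
                      n_starts: int = 5) -> tuple[ModelFreeParams, float]:
    names = MODEL_LADDER[model_id]
    if not names:
        params = ModelFreeParams(s2=1.0, model_id="m0")
        chi2 = float(np.sum(_residuals(params, diffusion, observations,
                                       constants, alpha,
                                       reference_field_mhz) ** 2))
        return params, chi2
    lb = np.array([_BOUNDS[n][0] for n in names])
    ub = np.array([_BOUNDS[n][1] for n in names])
    best: tuple[ModelFreeParams, float] | None = None
    for k in range(n_starts):
        x0 = np.array([_STARTS[n][k % len(_STARTS[n])] for n in names])
        try:
            sol = optimize.least_squares(
                lambda x: _residuals(
                    _params_from_vector(model_id, names, x), diffusion,
                    observations, constants, alpha, reference_field_mhz),
                x0=x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun**2))
        if best is None or chi2 < best[1] - 1e-12:
            best = (_params_from_vector(model_id, names, sol.x), chi2)
    if best is None:
        raise RuntimeError(f"optimizer failed for model {model_id}")
    return best


def fit_modelfree_residue(observations: Sequence[Observation],
                          diffusion: DiffusionModel,
                          constants: PhysicalConstants = PhysicalConstants(),
                          alpha: float | None = None,
                          models: Iterable[str] | None = None,
                          reference_field_mhz: float = 600.0,
                          ) -> tuple[ModelFreeParams, pd.DataFrame]:
    """Fit the model ladder to one residue's observables; select by AIC.

    Diffusion is held fixed.  AIC = chi2 + 2k with k free parameters;
    ties break toward the model with fewer parameters.  Returns the
    selected parameters and the per-model table (chi2, AIC).
    """
    if len(observations) < 3:
        raise ValueError("need >= 3 observables per residue")
    model_ids = list(models) if models is not None else list(MODEL_LADDER)
    rows = []
    failures = {}
    for mid in sorted(model_ids, key=lambda m: len(MODEL_LADDER[m])):
        try:
            params, chi2 = _fit_single_model(
                mid, observations, diffusion, constants, alpha,
                reference_field_mhz)
        except Exception as exc:  # keep per-model diagnostics
            failures[mid] = str(exc)
            continue
        k = len(MODEL_LADDER[mid])
        rows.append({"model": mid, "k": k, "chi2": chi2,
                     "aic": chi2 + 2.0 * k, "params": params})
    if not rows:
        raise RuntimeError(f"all model fits failed: {failures}")
    table = pd.DataFrame(rows)
    # strict '<' over the k-sorted rows implements the fewer-parameter tie-break
    best_row = None
    for _, row in table.sort_values(["k", "model"]).iterrows():
        if best_row is None or row["aic"] < best_row["aic"] - 1e-9:
            best_row = row
    selected: ModelFreeParams = best_row["params"]
    return selected, table.drop(columns=["params"]).assign(
        selected=table["model"] == selected.model_id)


def fit_global_diffusion(residue_observations: dict[int, Sequence[Observation]],
                         kind: str = "isotropic",
                         vectors: dict[int, np.ndarray] | None = None,
                         constants: PhysicalConstants = PhysicalConstants(),
                         tc0: float | None = None,
                         residue_model: str = "m2",
                         max_alternations: int = 30,
                         tol: float = 1e-4,
                         reference_field_mhz: float = 600.0,
                         ) -> tuple[DiffusionModel, dict[int, ModelFreeParams]]:
    """Global diffusion fit by alternating per-residue / global optimization.

    Per-residue internal parameters (model ``residue_model``, default
    S2 + tau_s) are re-fit at the current diffusion tensor, then the
    global parameters are optimized with internal parameters held fixed,
    until tc moves by less than ``tol`` (relative).
    """
    residues = sorted(residue_observations)
    if len(residues) < 10:
        raise ValueError("need >= 10 residues for a global diffusion fit")
    if kind == "axially_symmetric" and vectors is None:
        raise ValueError("axially symmetric fit needs per-residue N-H vectors")

    if tc0 is None:
        tc0 = 8e-9
    diffusion = DiffusionModel(kind, tc=tc0)

    def residue_alpha(num: int, diff: DiffusionModel) -> float | None:
        if kind == "isotropic":
            return None
        v = np.asarray(vectors[num], dtype=float)
        v = v / np.linalg.norm(v)
        return float(np.arccos(np.clip(np.dot(v, diff.axis()), -1.0, 1.0)))

    def fit_residues(diff: DiffusionModel) -> dict[int, ModelFreeParams]:
        out = {}
        for num in residues:
            params, _ = _fit_single_model(
                residue_model, residue_observations[num], diff, constants,
                residue_alpha(num, diff), reference_field_mhz, n_starts=2)
            out[num] = params
        return out

    def total_chi2(diff: DiffusionModel,
                   per_residue: dict[int, ModelFreeParams]) -> float:
        return sum(
            float(np.sum(_residuals(per_residue[num], diff,
                                    residue_observations[num], constants,
                                    residue_alpha(num, diff),
                                    reference_field_mhz) ** 2))
            for num in residues)

    per_residue = fit_residues(diffusion)
    converged = False
    for _ in range(max_alternations):
        if kind == "isotropic":
            res = optimize.minimize_scalar(
                lambda tc: total_chi2(DiffusionModel(kind, tc=tc), per_residue),
                bounds=(1e-9, 40e-9), method="bounded",
                options={"xatol": 1e-13})
            new_diff = DiffusionModel(kind, tc=float(res.x))
        else:
            x0 = np.array([diffusion.tc * 1e9, diffusion.ratio,
                           diffusion.theta, diffusion.phi])

            def objective(x: np.ndarray) -> float:
                tc_ns, ratio, theta, phi = x
                if tc_ns <= 0.1 or ratio <= 0.05:
                    return 1e12
                return total_chi2(
                    DiffusionModel(kind, tc=tc_ns * 1e-9, ratio=ratio,
                                   theta=theta, phi=phi), per_residue)

            res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-10,
                                             "maxiter": 2000})
            tc_ns, ratio, theta, phi = res.x
            new_diff = DiffusionModel(kind, tc=float(tc_ns) * 1e-9,
                                      ratio=float(ratio), theta=float(theta),
                                      phi=float(phi))
        shift = abs(new_diff.tc - diffusion.tc) / diffusion.tc
        diffusion = new_diff
        per_residue = fit_residues(diffusion)
        if shift < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"global diffusion fit did not converge in {max_alternations} "
            f"alternations; last tc = {diffusion.tc * 1e9:.3f} ns"
        )
    return diffusion, per_residue


def extract_rex_map(fits: dict[int, ModelFreeParams],
                    thresholds: Sequence[float] = (1.0, 2.0)) -> pd.DataFrame:
    """Per-residue Rex table with exceedance flags at each threshold."""
    thresholds = sorted(thresholds)
    rows = []
    for num in sorted(fits):
        p = fits[num]
        row = {"residue": num, "model": p.model_id, "rex": p.rex}
        for thr in thresholds:
            row[f"rex_gt_{thr:g}"] = bool(p.rex > thr)
        rows.append(row)
    columns = ["residue", "model", "rex"] + [f"rex_gt_{t:g}" for t in thresholds]
    return pd.DataFrame(rows, columns=columns)
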