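"""Relaxation-rate extraction from peak-intensity decays.

Mono-exponential R1/R2/R1rho/R2rho fits, duplicate-based noise estimation,
Monte-Carlo rate uncertainties, steady-state heteronuclear nOe ratios,
constant-time CPMG R2,eff, dispersion assessment, and core-region
aggregation (mean +/- SEM over a residue window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .io import IntensitySeries, RateTable, ResidueID

__all__ = [
    "RateEstimate",
    "NoeEstimate",
    "CpmgSeries",
    "fit_monoexponential",
    "estimate_noise_from_duplicates",
    "monte_carlo_uncertainty",
    "compute_noe",
    "compute_r2eff",
    "assess_dispersion",
    "aggregate_region_stats",
]


@dataclass
class RateEstimate:
    """Result of a mono-exponential decay fit I(t) = I0 exp(-R t)."""

    residue: ResidueID
    rate: float
    amplitude: float
    rate_sigma: float
    fit_rss: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("fitted rate is not finite")
        if self.rate_sigma < 0:
            raise ValueError("rate_sigma must be >= 0")


@dataclass
class NoeEstimate:
    """Steady-state [1H]-15N nOe: saturated/unsaturated peak-height ratio."""

    residue: ResidueID
    noe: float
    noe_sigma: float

    def __post_init__(self) -> None:
        if self.noe_sigma < 0:
            raise ValueError("noe_sigma must be >= 0")


@dataclass
class CpmgSeries:
    """R2,eff versus CPMG frequency at constant relaxation time Trelax."""

    residue: ResidueID
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    trelax: float
    i_ref: float = 1.0
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("all nu_cpmg must be > 0")
        if self.trelax <= 0:
            raise ValueError("Trelax must be > 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


def _initial_guess(t: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    # Deterministic, scale-free: I0 from the max height; R from the
    # first/last height ratio, clipped to [1e-3, 1e3] s^-1.
    i0 = float(np.max(h))
    ratio = h[0] / h[-1] if h[-1] != 0 else np.nan
    span = t[-1] - t[0]
    if ratio is not None and ratio > 0 and span > 0:
        r = float(np.log(ratio) / span)
    else:
        r = 1.0
    r = float(np.clip(r, 1e-3, 1e3))
    return i0, r


def fit_monoexponential(series: IntensitySeries) -> RateEstimate:
    """Least-squares fit of I(t) = I0 exp(-R t) against acquired delays.

    Duplicate points enter as separate observations.  Negative fitted
    rates are allowed (reported with a warning) rather than clamped.
    """
    t = np.asarray(series.schedule.acquired_delays, dtype=float)
    h = series.heights
    if len(np.unique(t)) < 3:
        raise ValueError(
            f"residue {series.residue.number}: need >= 3 distinct delays "
            f"for a mono-exponential fit, got {len(np.unique(t))}"
        )
    i0_guess, r_guess = _initial_guess(t, h)

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-p[1] * t) - h

    sol = optimize.least_squares(resid, x0=[i0_guess, r_guess],
                                 method="lm", xtol=1e-14, ftol=1e-14)
    i0, rate = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    if i0 <= 0:
        warnings.warn(
            f"residue {series.residue.number}: non-positive fitted amplitude "
            f"({i0:.3g})", stacklevel=2)
    if rate < 0:
        warnings.warn(
            f"residue {series.residue.number}: negative fitted rate "
            f"({rate:.3g} s^-1)", stacklevel=2)
    # covariance-based sigma as a starting point; Monte-Carlo refines it
    dof = max(len(t) - 2, 1)
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * rss / dof
        rate_sigma = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        rate_sigma = 0.0
    return RateEstimate(series.residue, rate, i0, rate_sigma, rss)


def estimate_noise_from_duplicates(
    series_collection: Iterable[IntensitySeries],
    pooled: bool = False,
) -> dict[int, float]:
    """Per-residue noise sigma from duplicate-delay height differences.

    sigma = sqrt(sum(d_i^2) / (2 m)) over the m duplicate pairs of a
    residue.  With ``pooled=True`` the pairs of all residues are pooled and
    every residue receives the common sigma.
    """
    diffs: dict[int, list[float]] = {}
    for series in series_collection:
        pairs = series.schedule.duplicate_pairs(series.heights)
        if not pairs:
            raise ValueError(
                "schedule has no duplicate-flagged delays; supply "
                "noise_sigma explicitly"
            )
        diffs[series.residue.number] = [a - b for a, b in pairs]
    if pooled:
        alld = np.concatenate([np.asarray(v) for v in diffs.values()])
        sigma = float(np.sqrt(np.sum(alld**2) / (2 * len(alld))))
        return {num: sigma for num in diffs}
    return {
        num: float(np.sqrt(np.sum(np.asarray(d) ** 2) / (2 * len(d))))
        for num, d in diffs.items()
    }


def monte_carlo_uncertainty(
    fit_op: Callable[[IntensitySeries], RateEstimate],
    series: IntensitySeries,
    sigma: float,
    n: int = 500,
    seed: int | None = None,
) -> float:
    """Rate uncertainty as the SD of refit rates over n synthetic replicates.

    Replicates are the best-fit curve plus Gaussian noise of the given
    sigma (absolute intensity units).  sigma = 0 short-circuits to 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 0.0
    if n < 2:
        raise ValueError("need n >= 2 Monte-Carlo replicates")
    base = fit_op(series)
    t = np.asarray(series.schedule.acquired_delays, dtype=float)
    model = base.amplitude * np.exp(-base.rate * t)
    rng = np.random.default_rng(seed)
    rates = np.empty(n)
    for k in range(n):
        synthetic = IntensitySeries(
            series.residue, series.schedule,
            model + rng.normal(0.0, sigma, size=model.shape),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates[k] = fit_op(synthetic).rate
    return float(np.std(rates, ddof=1))


def compute_noe(sat_height: float, unsat_height: float,
                rmsd_sat: float, rmsd_unsat: float,
                residue: ResidueID | None = None) -> NoeEstimate:
    """nOe = I(sat)/I(unsat); error propagated from baseline-noise RMSDs."""
    if unsat_height == 0:
        raise ValueError("unsaturated peak height must be non-zero")
    noe = sat_height / unsat_height
    if sat_height == 0:
        sigma = abs(rmsd_sat / unsat_height)
    else:
        sigma = abs(noe) * np.sqrt(
            (rmsd_sat / sat_height) ** 2 + (rmsd_unsat / unsat_height) ** 2
        )
    return NoeEstimate(residue or ResidueID(1), noe, float(sigma))


def compute_r2eff(i_nu: float, i_ref: float, trelax: float) -> float:
    """Constant-time CPMG effective rate: -(1/Trelax) ln(I_nu / I_ref)."""
    if i_nu <= 0 or i_ref <= 0:
        raise ValueError("intensities must be positive")
    if trelax <= 0:
        raise ValueError("Trelax must be > 0")
    return float(-np.log(i_nu / i_ref) / trelax)


def assess_dispersion(series: CpmgSeries, k_sigma: float = 2.0,
                      alpha: float = 0.05) -> dict:
    """Decide whether an R2,eff profile shows CPMG dispersion.

    amplitude = R2,eff at the lowest nu minus at the highest nu.  The
    profile is called dispersive when the amplitude exceeds ``k_sigma``
    pooled sigmas AND an F-test at ``alpha`` prefers a two-parameter
    monotone-dispersion surrogate (offset + amplitude with a fixed decay
    scale) over a constant.
    """
    nu, r2 = series.nu_cpmg, series.r2eff
    if len(nu) < 4:
        raise ValueError("need >= 4 CPMG points to assess dispersion")
    order = np.argsort(nu)
    nu, r2 = nu[order], r2[order]
    amplitude = float(r2[0] - r2[-1])
    sigma = series.sigma
    pooled = float(np.sqrt(np.mean(sigma**2))) if sigma is not None else 0.0

    # constant model (1 parameter)
    rss0 = float(np.sum((r2 - r2.mean()) ** 2))
    # monotone surrogate: a + b exp(-nu/nu0), nu0 fixed at the median nu
    nu0 = float(np.median(nu))
    basis = np.exp(-nu / nu0)
    design = np.column_stack([np.ones_like(nu), basis])
    coef, *_ = np.linalg.lstsq(design, r2, rcond=None)
    rss1 = float(np.sum((design @ coef - r2) ** 2))
    dof1 = len(nu) - 2
    if rss1 <= 0 or dof1 <= 0:
        p_value = 0.0 if rss0 > rss1 else 1.0
    else:
        f = (rss0 - rss1) / 1 / (rss1 / dof1)
        p_value = float(stats.f.sf(max(f, 0.0), 1, dof1))
    dispersive = (amplitude > k_sigma * pooled) and (p_value < alpha)
    return {"dispersive": bool(dispersive), "amplitude": amplitude,
            "p_value": p_value}


def aggregate_region_stats(table: RateTable, residue_window: Sequence[int],
                           kind: str, field_mhz: float | None = None,
                           state: str | None = None,
                           condition: str | None = None) -> dict:
    """Unweighted mean and SEM (sd/sqrt(n)) over residues in a window."""
    lo, hi = int(residue_window[0]), int(residue_window[1])
    df = table.select(kind, field_mhz=field_mhz, state=state,
                      condition=condition, window=(lo, hi))
    values = df["value"].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValueError(
            f"need >= 2 residues in window {lo}-{hi} for kind={kind!r} "
            f"(found {n})"
        )
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    return {"mean": mean, "sem": sem, "n": n}
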