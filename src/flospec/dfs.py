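"""Dynamic-force-spectroscopy statistics.

Per loading rate, the empirical cumulative distribution of rupture forces
is fitted with the Bell–Evans cumulative form to extract the landscape
parameters (k_off, ΔX), from which the most probable rupture force F* at
that rate follows.  Across loading rates, F* is linear in ln Ḟ:

    F* = (k_B T/ΔX)·ln Ḟ + (k_B T/ΔX)·ln[ΔX/(N·k_B T·k_off)],

so an ordinary least-squares fit of F* against ln Ḟ gives ΔX from the
slope and k_off from the intercept (with the serial-bond count N declared
by the user, not inferred).  Subgroup statistics follow the convention of
randomly splitting each rupture population into three disjoint subgroups
and reporting the mean ± SD of the three F* estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import evans
from .core import EnergyLandscape, Environment, LoadingRate

__all__ = [
    "RuptureDataset",
    "RateFit",
    "SubgroupResult",
    "GlobalFit",
    "DFSFitResult",
    "empirical_cdf",
    "fit_cdf_points",
    "fit_rupture_cdf",
    "subgroup_statistics",
    "fit_force_vs_loading_rate",
    "project_single_bond",
    "analyze_rupture_datasets",
]

#: Default minimum number of rupture forces required for a CDF fit.
DEFAULT_MIN_N = 20

_BOUNDS_LOG10_KOFF = (-12.0, 3.0)
_BOUNDS_DELTA_X = (0.01, 100.0)


@dataclass
class RuptureDataset:
    """Rupture forces (pN) measured at one loading rate."""

    rupture_forces: np.ndarray
    loading_rate: LoadingRate
    label: str = ""
    channel: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.rupture_forces, dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("rupture forces must be finite and > 0")
        self.rupture_forces = f

    @property
    def n(self) -> int:
        return int(self.rupture_forces.size)


@dataclass(frozen=True)
class RateFit:
    """Per-loading-rate CDF fit."""

    landscape: EnergyLandscape
    f_star: float
    loading_rate: LoadingRate
    rss: float
    boundary_pinned: bool = False


@dataclass(frozen=True)
class SubgroupResult:
    f_star_mean: float
    f_star_sd: float
    fits: tuple[RateFit, ...]


@dataclass(frozen=True)
class GlobalFit:
    landscape: EnergyLandscape
    k_off_sd: float
    delta_x_sd: float
    slope: float
    intercept: float
    covariance: np.ndarray
    n_serial: int


@dataclass(frozen=True)
class DFSFitResult:
    per_rate: tuple[RateFit, ...]
    subgroups: tuple[SubgroupResult, ...]
    global_fit: GlobalFit
    n_serial: int


def empirical_cdf(forces) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF at the sorted sample points.

    Returns the sorted forces and plotting positions i/n; tied values all
    carry the last-of-ties (highest) position.
    """
    f = np.sort(np.asarray(forces, dtype=float))
    if f.size < 2:
        raise ValueError("need at least 2 forces for an empirical CDF")
    n = f.size
    probs = np.searchsorted(f, f, side="right") / n
    return f, probs


def fit_cdf_points(forces, probs, rate: LoadingRate, env: Environment,
                   method: str = "exact", n_terms: int = 50) -> RateFit:
    """Least-squares fit of the rupture CDF to (force, probability) points.

    Optimises (log10 k_off, ΔX) within bounds k_off ∈ [1e-12, 1e3] s⁻¹ and
    ΔX ∈ [0.01, 100] nm.  Initial ΔX is k_B T / SD(forces) (the width of
    the Bell-Evans density is ≈ k_B T/ΔX); initial k_off inverts the
    most-probable-force relation at a histogram estimate of the mode.
    """
    f = np.asarray(forces, dtype=float)
    p = np.asarray(probs, dtype=float)
    if f.shape != p.shape or f.ndim != 1:
        raise ValueError("forces and probs must be matching 1-D arrays")
    kbt = env.thermal_energy

    sd = float(np.std(f, ddof=1))
    dx0 = float(np.clip(kbt / max(sd, 1e-9), *_BOUNDS_DELTA_X))
    hist, edges = np.histogram(f, bins="auto")
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    # invert F* = (kbt/dx)·ln[f_dot·dx/(kbt·k_off)] at the mode estimate
    k0 = rate.f_dot * dx0 / kbt * np.exp(-mode * dx0 / kbt)
    log_k0 = float(np.clip(np.log10(max(k0, 1e-300)), *_BOUNDS_LOG10_KOFF))

    def residuals(theta):
        landscape = EnergyLandscape(k_off=10.0 ** theta[0], delta_x=theta[1])
        return evans.rupture_cdf(f, landscape, rate, env,
                                 method=method, n_terms=n_terms) - p

    lo = np.array([_BOUNDS_LOG10_KOFF[0], _BOUNDS_DELTA_X[0]])
    hi = np.array([_BOUNDS_LOG10_KOFF[1], _BOUNDS_DELTA_X[1]])
    res = optimize.least_squares(residuals, [log_k0, dx0], bounds=(lo, hi),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError(f"rupture CDF fit did not converge: {res.message}")
    pinned = bool(np.any(np.isclose(res.x, lo, rtol=1e-6))
                  or np.any(np.isclose(res.x, hi, rtol=1e-6)))
    if pinned:
        warnings.warn("rupture CDF fit is pinned at a parameter bound",
                      UserWarning, stacklevel=2)
    landscape = EnergyLandscape(k_off=10.0 ** res.x[0], delta_x=res.x[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", evans.NearEquilibriumWarning)
        f_star = evans.most_probable_force(landscape, rate, env)
    return RateFit(landscape=landscape, f_star=f_star, loading_rate=rate,
                   rss=float(2.0 * res.cost), boundary_pinned=pinned)


def fit_rupture_cdf(data: RuptureDataset, env: Environment,
                    method: str = "exact", n_terms: int = 50,
                    min_n: int = DEFAULT_MIN_N) -> RateFit:
    """Fit the cumulative rupture-force distribution of one dataset."""
    if data.n < min_n:
        raise ValueError(f"need at least {min_n} rupture forces, got {data.n}")
    grid, probs = empirical_cdf(data.rupture_forces)
    return fit_cdf_points(grid, probs, data.loading_rate, env,
                          method=method, n_terms=n_terms)


def random_partition(n: int, n_groups: int, seed=None) -> list[np.ndarray]:
    """Disjoint, exhaustive random split of range(n) into near-equal groups."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_groups)]


def subgroup_statistics(data: RuptureDataset, env: Environment,
                        n_groups: int = 3, seed=None, method: str = "exact",
                        min_n: int = DEFAULT_MIN_N) -> SubgroupResult:
    """Mean ± SD of F* over a random split into ``n_groups`` subgroups.

    The population is divided by random selection without replacement into
    disjoint subgroups whose sizes differ by at most one; each subgroup's
    CDF is fitted independently.
    """
    if data.n < n_groups * min_n:
        raise ValueError(
            f"need at least {n_groups * min_n} forces for {n_groups} subgroups")
    parts = random_partition(data.n, n_groups, seed=seed)
    fits = []
    for idx in parts:
        sub = RuptureDataset(rupture_forces=data.rupture_forces[idx],
                             loading_rate=data.loading_rate,
                             label=data.label, channel=data.channel)
        fits.append(fit_rupture_cdf(sub, env, method=method, min_n=min_n))
    f_stars = np.array([fit.f_star for fit in fits])
    return SubgroupResult(f_star_mean=float(np.mean(f_stars)),
                          f_star_sd=float(np.std(f_stars, ddof=1)),
                          fits=tuple(fits))


def fit_force_vs_loading_rate(points, env: Environment,
                              n_serial: int = 1) -> GlobalFit:
    """Global landscape fit from (Ḟ, F*) pairs.

    Unweighted OLS of F* on ln Ḟ; the slope s gives ΔX = k_B T/s and the
    intercept b gives k_off = ΔX/(n_serial·k_B T)·exp(−b/s).  Parameter
    uncertainties are propagated from the regression covariance by the
    delta method.
    """
    pts = [(float(fd), float(fs)) for fd, fs in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (loading rate, F*) points")
    f_dot = np.array([p[0] for p in pts])
    f_star = np.array([p[1] for p in pts])
    if np.any(f_dot <= 0):
        raise ValueError("loading rates must be > 0")
    if np.unique(f_dot).size < 2:
        raise ValueError("need at least 2 distinct loading rates")
    x = np.log(f_dot)
    if len(pts) == 2:
        slope = (f_star[1] - f_star[0]) / (x[1] - x[0])
        intercept = f_star[0] - slope * x[0]
        cov = np.zeros((2, 2))
    else:
        (slope, intercept), cov = np.polyfit(x, f_star, 1, cov=True)
    if slope <= 0:
        raise ValueError("non-positive slope of F* vs ln(loading rate): "
                         "the single-barrier rupture model is violated")
    kbt = env.thermal_energy
    delta_x = kbt / slope
    k_off = delta_x / (n_serial * kbt) * np.exp(-intercept / slope)
    # delta method: gradients of (delta_x, k_off) wrt (slope, intercept)
    d_dx = np.array([-kbt / slope ** 2, 0.0])
    dlnk_dslope = -1.0 / slope + intercept / slope ** 2
    dlnk_dint = -1.0 / slope
    d_k = k_off * np.array([dlnk_dslope, dlnk_dint])
    delta_x_sd = float(np.sqrt(d_dx @ cov @ d_dx))
    k_off_sd = float(np.sqrt(d_k @ cov @ d_k))
    return GlobalFit(landscape=EnergyLandscape(k_off=float(k_off),
                                               delta_x=float(delta_x)),
                     k_off_sd=k_off_sd, delta_x_sd=delta_x_sd,
                     slope=float(slope), intercept=float(intercept),
                     covariance=np.asarray(cov), n_serial=n_serial)


def project_single_bond(landscape: EnergyLandscape, env: Environment,
                        rate_grid) -> np.ndarray:
    """F*(Ḟ) for a single bond (N = 1) over a grid of loading rates."""
    rates = np.asarray(rate_grid, dtype=float)
    out = np.empty_like(rates)
    for i, fd in np.ndenumerate(rates):
        out[i] = evans.most_probable_force(landscape, LoadingRate(f_dot=fd), env,
                                           n_serial=1)
    return out


def analyze_rupture_datasets(datasets, env: Environment, n_serial: int = 1,
                             n_groups: int = 3, seed=None,
                             method: str = "exact",
                             min_n: int = DEFAULT_MIN_N) -> DFSFitResult:
    """Full pipeline: per-rate CDF fits, subgroup statistics, global fit.

    The global regression uses the full-sample per-rate F* values; subgroup
    splits provide the per-rate SD.  Per-dataset subgroup seeds derive
    deterministically from ``seed``.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one rupture dataset")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(datasets))
    per_rate, subgroups = [], []
    for data, child in zip(datasets, children):
        per_rate.append(fit_rupture_cdf(data, env, method=method, min_n=min_n))
        if data.n >= n_groups * min_n:
            subgroups.append(subgroup_statistics(
                data, env, n_groups=n_groups,
                seed=np.random.default_rng(child), method=method, min_n=min_n))
        else:
            subgroups.append(SubgroupResult(
                f_star_mean=per_rate[-1].f_star, f_star_sd=float("nan"),
                fits=(per_rate[-1],)))
    points = [(fit.loading_rate.f_dot, fit.f_star) for fit in per_rate]
    global_fit = fit_force_vs_loading_rate(points, env, n_serial=n_serial)
    return DFSFitResult(per_rate=tuple(per_rate), subgroups=tuple(subgroups),
                        global_fit=global_fit, n_serial=n_serial)
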