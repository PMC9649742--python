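"""Bell–Evans rupture-force statistics under a constant loading rate.

For a single bond whose dissociation rate grows exponentially with force,
k(F) = k_off·exp(F·ΔX / k_B T), pulled at a constant loading rate Ḟ, the
rupture-force density is

    p(F) = a1 · exp(a2·F) · exp[(a1/a2)·(1 − exp(a2·F))]

with reduced parameters a1 = k_off/Ḟ (1/pN) and a2 = ΔX/(k_B T) (1/pN).
The cumulative probability has a closed form,

    P(F) = 1 − exp[(a1/a2)·(1 − exp(a2·F))],

and a truncated-series form (the classical N-term expansion of the same
integral) provided for fidelity to common fitting practice:

    P_series(F) = [Σ_{n=1}^{N} a1ⁿ/(n!·a2ⁿ)·exp(n·a2·F)]
                  · exp[(a1/a2)·(1 − exp(a2·F))].

In the N→∞ limit the series equals the exact form plus the constant
exp(a1/a2) − 1 (the n=0 normalisation term is omitted from the series);
at typical parameters a1/a2 ≪ 1 so the offset is negligible, but the
exact form is the default because it is a true CDF (0 at F = 0).

The mode of p(F) is the most probable rupture force

    F* = (k_B T/ΔX) · ln[Ḟ·ΔX / (N_serial·k_B T·k_off)],

where N_serial identical bonds loaded in series fail N_serial-fold faster,
lowering F* by (k_B T/ΔX)·ln N_serial.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import EnergyLandscape, Environment, LoadingRate, ReducedParams

__all__ = [
    "rupture_density",
    "log_rupture_density",
    "rupture_cdf",
    "most_probable_force",
    "sample_rupture_forces",
    "NearEquilibriumWarning",
]


class NearEquilibriumWarning(UserWarning):
    """Loading rate too low for the rupture model's far-from-equilibrium regime."""


def _validate_force(force) -> np.ndarray:
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("force values must be finite")
    if np.any(f < 0):
        raise ValueError("force must be >= 0 (rupture forces are non-negative)")
    return f


def log_rupture_density(force, landscape: EnergyLandscape, rate: LoadingRate,
                        env: Environment) -> np.ndarray:
    """Natural log of the rupture-force density, stable for large a2·F."""
    f = _validate_force(force)
    p = ReducedParams.reduce(landscape, rate, env)
    # (a1/a2)(1 - e^{a2 F}) = -(a1/a2)·expm1(a2 F), large negative at high F
    return np.log(p.a1) + p.a2 * f - (p.a1 / p.a2) * np.expm1(p.a2 * f)


def rupture_density(force, landscape: EnergyLandscape, rate: LoadingRate,
                    env: Environment) -> np.ndarray:
    """Probability density of rupture at ``force`` (1/pN).

    Strictly positive for finite force; evaluated in log space so the
    exponentials never overflow.
    """
    return np.exp(log_rupture_density(force, landscape, rate, env))


def rupture_cdf(force, landscape: EnergyLandscape, rate: LoadingRate,
                env: Environment, method: str = "exact",
                n_terms: int = 50) -> np.ndarray:
    """Cumulative probability that the bond has ruptured by ``force``.

    Parameters
    ----------
    method : {"exact", "series"}
        "exact" evaluates the closed-form integral of the density;
        "series" evaluates the ``n_terms``-term expansion (log-sum-exp,
        overflow-safe).  The series differs from the exact form by the
        constant exp(a1/a2) − 1 once converged.
    n_terms : int
        Number of series terms (default 50); ignored for ``method="exact"``.
    """
    f = _validate_force(force)
    p = ReducedParams.reduce(landscape, rate, env)
    z = (p.a1 / p.a2) * np.expm1(p.a2 * f)  # (a1/a2)(e^{a2F} - 1) >= 0
    if method == "exact":
        return -np.expm1(-z)
    if method == "series":
        if n_terms < 1:
            raise ValueError("n_terms must be >= 1 for the series form")
        n = np.arange(1, n_terms + 1, dtype=float)
        log_ratio = np.log(p.a1 / p.a2)
        # term_n = exp(n·(log(a1/a2) + a2 F) - log n!)
        log_terms = (n[:, None] * (log_ratio + p.a2 * f.reshape(-1))
                     - gammaln(n + 1.0)[:, None])
        log_series = logsumexp(log_terms, axis=0)
        log_value = log_series - z.reshape(-1)
        if np.any(log_value > 700.0):
            raise FloatingPointError(
                "series CDF overflows despite log-space evaluation; "
                f"max log value {np.max(log_value):.1f}"
            )
        out = np.exp(log_value).reshape(f.shape)
        return out
    raise ValueError(f"unknown method {method!r}; expected 'exact' or 'series'")


def most_probable_force(landscape: EnergyLandscape, rate: LoadingRate,
                        env: Environment, n_serial: int = 1) -> float:
    """Most probable rupture force F* in pN (mode of the density for n_serial=1).

    For ``n_serial`` identical serially connected bonds, rupture is
    n_serial-fold more likely, which lowers F* by (k_BT/ΔX)·ln(n_serial).
    A non-positive result (log argument ≤ 1) is returned as-is with a
    :class:`NearEquilibriumWarning` — there the bond dissociates thermally
    before the ramp loads it and the model's mode is not meaningful.
    """
    if n_serial < 1:
        raise ValueError("n_serial must be >= 1")
    kbt = env.thermal_energy
    arg = rate.f_dot * landscape.delta_x / (n_serial * kbt * landscape.k_off)
    f_star = (kbt / landscape.delta_x) * np.log(arg)
    if arg <= 1.0:
        warnings.warn(
            f"loading rate {rate.f_dot} pN/s is in the near-equilibrium regime "
            f"(log argument {arg:.3g} <= 1); returning flagged non-positive F*",
            NearEquilibriumWarning,
            stacklevel=2,
        )
    return float(f_star)


def sample_rupture_forces(landscape: EnergyLandscape, rate: LoadingRate,
                          env: Environment, n: int,
                          seed=None) -> np.ndarray:
    """Draw ``n`` rupture forces by exact inversion of the closed-form CDF.

    F = (1/a2)·ln[1 − (a2/a1)·ln(1 − u)] with u uniform on [0, 1).
    Reproducible for a fixed ``seed`` (int or numpy Generator).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    p = ReducedParams.reduce(landscape, rate, env)
    u = rng.random(n)
    return quantile(u, landscape, rate, env)


def quantile(prob, landscape: EnergyLandscape, rate: LoadingRate,
             env: Environment) -> np.ndarray:
    """Inverse of the exact CDF: force at cumulative probability ``prob``."""
    u = np.asarray(prob, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("prob must lie in [0, 1)")
    p = ReducedParams.reduce(landscape, rate, env)
    return (1.0 / p.a2) * np.log1p(-(p.a2 / p.a1) * np.log1p(-u))
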