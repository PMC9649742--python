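"""Worm-like-chain force–extension model and fitting.

dsDNA elasticity is modelled with the Marko–Siggia interpolation formula

    F(l) = (k_B T / P) · [ 1/(4(1 − l/Lc)²) − 1/4 + l/Lc ],

parameterised by persistence length P (nm) and contour length Lc (nm).
The formula is exact in the low- and high-force limits and accurate to a
few percent in between, which is ample at the sub-10 pN forces of a
flow-stretched tether (no enthalpic stretching term is needed there).

Fitting minimises residuals in *extension*, not force: in this assay the
force is the controlled variable (set by the flow calibration) and the
extension is the measured one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import Environment

__all__ = ["WLCParams", "ForceExtensionCurve", "WLCFit",
           "wlc_force", "wlc_extension", "fit_wlc", "dsdna_contour_length"]

#: Helical rise of B-form dsDNA, nm per base pair.
DSDNA_RISE_NM_PER_BP = 0.34


def dsdna_contour_length(n_bp: int, rise_nm_per_bp: float = DSDNA_RISE_NM_PER_BP) -> float:
    """Contour length (nm) of a B-form dsDNA of ``n_bp`` base pairs."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return n_bp * rise_nm_per_bp


@dataclass(frozen=True)
class WLCParams:
    """Persistence length and contour length, both in nm."""

    persistence_length: float
    contour_length: float

    def __post_init__(self) -> None:
        if not (self.persistence_length > 0):
            raise ValueError("persistence_length must be > 0")
        if not (self.contour_length > 0):
            raise ValueError("contour_length must be > 0")


@dataclass(frozen=True)
class ForceExtensionCurve:
    """Matched arrays of force (pN) and end-to-end extension (nm)."""

    forces: np.ndarray
    extensions: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=float)
        l = np.asarray(self.extensions, dtype=float)
        if f.shape != l.shape:
            raise ValueError("forces and extensions must have matching shapes")
        if np.any(f <= 0):
            raise ValueError("forces must be > 0")
        object.__setattr__(self, "forces", f)
        object.__setattr__(self, "extensions", l)
        if self.uncertainty is not None:
            u = np.asarray(self.uncertainty, dtype=float)
            if u.shape != f.shape:
                raise ValueError("uncertainty must match forces in shape")
            object.__setattr__(self, "uncertainty", u)


@dataclass(frozen=True)
class WLCFit:
    params: WLCParams
    covariance: np.ndarray  # 2x2 over (P, Lc)

    @property
    def persistence_length_sd(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def contour_length_sd(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def wlc_force(extension, params: WLCParams, env: Environment) -> np.ndarray:
    """Entropic restoring force (pN) at end-to-end ``extension`` (nm).

    Monotone increasing; diverges as extension approaches the contour
    length. Raises for extension ≥ Lc (outside the model domain).
    """
    l = np.asarray(extension, dtype=float)
    if np.any(l < 0):
        raise ValueError("extension must be >= 0")
    if np.any(l >= params.contour_length):
        raise ValueError("extension must be < contour_length")
    x = l / params.contour_length
    bracket = 0.25 / (1.0 - x) ** 2 - 0.25 + x
    return (env.thermal_energy / params.persistence_length) * bracket


def wlc_extension(force, params: WLCParams, env: Environment) -> np.ndarray:
    """Numerical inverse of :func:`wlc_force`: extension (nm) at ``force`` (pN).

    The interpolation force law is cubic in the fractional extension
    x = l/Lc, so the inverse is the unique root of

        4·φ·(1−x)² = 1 − (1−x)² + 4·x·(1−x)²,   φ = F·P/(k_B T),

    located in (0, 1); solved with Brent's method per point.
    """
    f = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    phi = f * params.persistence_length / env.thermal_energy
    out = np.empty_like(f)
    for i, ph in np.ndenumerate(phi):
        if ph == 0.0:
            out[i] = 0.0
            continue
        def g(x, ph=ph):
            return 0.25 / (1.0 - x) ** 2 - 0.25 + x - ph
        out[i] = optimize.brentq(g, 0.0, 1.0 - 1e-14, xtol=1e-15, rtol=8.9e-16)
    ext = out * params.contour_length
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(ext[0])
    return ext.reshape(np.shape(force))


def fit_wlc(curve: ForceExtensionCurve, env: Environment,
            init: WLCParams | None = None) -> WLCFit:
    """Fit persistence and contour length to a force–extension curve.

    Nonlinear least squares on extension residuals l_obs − l_model(F) with
    bounds P ∈ [1, 500] nm and Lc ∈ [1.001·max(l_obs), 10·max(l_obs)].
    Requires ≥ 4 points; warns when the force span is below 5× (the two
    parameters then decouple poorly).
    """
    f = curve.forces
    l_obs = curve.extensions
    if f.size < 4:
        raise ValueError("need at least 4 force-extension points to fit")
    if np.max(f) / np.min(f) < 5.0:
        warnings.warn("force span below 5x; persistence and contour length "
                      "may be poorly constrained", UserWarning, stacklevel=2)
    l_max = float(np.max(l_obs))
    lo = np.array([1.0, max(l_max * 1.001, 1.0)])
    hi = np.array([500.0, max(l_max, 1.0) * 10.0])
    if init is None:
        theta0 = np.array([50.0, np.clip(l_max * 1.2, lo[1], hi[1])])
    else:
        theta0 = np.clip([init.persistence_length, init.contour_length], lo, hi)

    def residuals(theta):
        p = WLCParams(persistence_length=theta[0], contour_length=theta[1])
        return wlc_extension(f, p, env) - l_obs

    res = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not res.success:
        raise RuntimeError(f"WLC fit did not converge: {res.message}")
    dof = max(f.size - 2, 1)
    s2 = float(res.cost * 2.0 / dof)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return WLCFit(params=WLCParams(*res.x), covariance=cov)
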