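"""Force calibration of flow-stretched tethered beads.

The tension on a tethered bead follows from the equipartition theorem: the
transverse (cross-flow) fluctuation of the bead center behaves as an
inverted pendulum of lever arm l + r, so

    F = k_B T · (l + r) / <δy²>,

where <δy²> is the variance of the transverse bead-center position.  The
lever arm itself comes from the in-plane excursion d of the bead under
flow, (l + r)² ≈ d² + r² (off-plane motion is negligible).  Repeating the
estimate over flow velocities yields a linear law F = c·V whose slope c
(pN·s·mm⁻¹) is the chip's calibration coefficient; it is valid only for
the bead radius, tether length and channel height it was measured with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (PA_S_TO_PN_S_PER_NM2, ChannelGeometry, ChipLayout,
                   Environment, TetherGeometry)

__all__ = [
    "CalibrationModel",
    "equipartition_force",
    "tether_extension_from_displacement",
    "mean_velocity",
    "fit_calibration",
    "channel_force_scale",
    "lorentzian_corner_frequency",
    "force_from_flow_rate",
    "loading_rate_from_ramp",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear force-vs-velocity law F = c·V.

    ``slope`` c is in pN·s·mm⁻¹ (V in mm/s).  The validity metadata records
    the geometry the calibration was performed with; a calibration must be
    redone if bead radius, tether length or channel height change.
    """

    slope: float
    valid_bead_radius_nm: float
    valid_tether_length_nm: float
    valid_channel_height_um: float
    intercept: float = 0.0
    residual_sd: float = float("nan")
    slope_sd: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError("calibration slope must be > 0")
        for name in ("valid_bead_radius_nm", "valid_tether_length_nm",
                     "valid_channel_height_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")

    def force(self, velocity_mm_s) -> np.ndarray:
        """F = c·V + intercept, in pN."""
        return self.slope * np.asarray(velocity_mm_s, dtype=float) + self.intercept


def equipartition_force(variance: float, tether: TetherGeometry,
                        env: Environment) -> float:
    """Tether tension (pN) from the transverse positional variance (nm²)."""
    if not (variance > 0) or not math.isfinite(variance):
        raise ValueError("variance must be a positive finite number (nm^2)")
    return env.thermal_energy * tether.lever_arm / variance


def tether_extension_from_displacement(d: float, r: float) -> float:
    """Tether end-to-end length l (nm) from in-plane excursion d and bead radius r.

    Inverts (l + r)² ≈ d² + r², valid when vertical bead motion is
    negligible compared with the in-plane excursion.
    """
    if d < 0:
        raise ValueError("in-plane displacement d must be >= 0")
    if not (r > 0):
        raise ValueError("bead radius r must be > 0")
    return math.hypot(d, r) - r


def mean_velocity(flow_rate_mm3_s: float, channel: ChannelGeometry) -> float:
    """Cross-section mean flow velocity V = Q/(w·h) in mm/s (Q in mm³/s)."""
    if flow_rate_mm3_s < 0:
        raise ValueError("flow rate must be >= 0")
    area = channel.cross_section_mm2
    if not (area > 0):
        raise ValueError("channel cross-section must be > 0")
    return flow_rate_mm3_s / area


def fit_calibration(forces, velocities, *,
                    bead_radius_nm: float, tether_length_nm: float,
                    channel_height_um: float,
                    through_origin: bool = True) -> CalibrationModel:
    """Fit the linear force-vs-velocity calibration law.

    Default is the through-origin least-squares slope c = Σ FV / Σ V²
    (zero force at zero flow is physical); ``through_origin=False`` fits a
    free intercept and reports it as a diagnostic.
    """
    f = np.asarray(forces, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if f.shape != v.shape or f.ndim != 1:
        raise ValueError("forces and velocities must be 1-D arrays of equal length")
    if f.size < 1 or (f.size < 2 and not through_origin):
        raise ValueError("insufficient points for the requested fit")
    if np.allclose(v, v[0]) and f.size > 1:
        raise ValueError("velocities are all equal; slope is not identifiable")

    if through_origin:
        denom = float(np.dot(v, v))
        if denom == 0.0:
            raise ValueError("all velocities are zero")
        slope = float(np.dot(f, v)) / denom
        intercept = 0.0
        resid = f - slope * v
        dof = max(f.size - 1, 1)
        slope_sd = math.sqrt(float(np.dot(resid, resid)) / dof / denom)
    else:
        (slope, intercept), cov = np.polyfit(v, f, 1, cov=True)
        resid = f - (slope * v + intercept)
        dof = max(f.size - 2, 1)
        slope_sd = float(np.sqrt(cov[0, 0]))
    residual_sd = float(np.sqrt(np.dot(resid, resid) / dof)) if f.size > 1 else 0.0
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            residual_sd=residual_sd, slope_sd=float(slope_sd),
                            n_points=int(f.size),
                            valid_bead_radius_nm=bead_radius_nm,
                            valid_tether_length_nm=tether_length_nm,
                            valid_channel_height_um=channel_height_um)


def channel_force_scale(chip: ChipLayout, channel_index: int) -> float:
    """Force (and loading-rate) scale of a channel relative to the narrowest.

    At the shared volumetric flow rate, force scales with mean velocity and
    hence inversely with channel width: factor = w_min / w_i.
    """
    widths = chip.widths_um
    if not (0 <= channel_index < len(widths)):
        raise IndexError(f"channel_index {channel_index} out of range")
    return min(widths) / widths[channel_index]


def lorentzian_corner_frequency(force: float, tether: TetherGeometry,
                                env: Environment) -> float:
    """Corner frequency f_c = κ/(2πγ) of the transverse fluctuation (Hz).

    κ = F/(l+r) is the pendulum stiffness (pN/nm) and γ = 6πηr the Stokes
    drag (pN·s/nm).  Sampling slower than f_c biases the variance estimate
    (aliasing), so calibration recordings must resolve it.
    """
    if not (force > 0):
        raise ValueError("force must be > 0")
    kappa = force / tether.lever_arm
    gamma = 6.0 * math.pi * (env.viscosity * PA_S_TO_PN_S_PER_NM2) * tether.bead_radius
    return kappa / (2.0 * math.pi * gamma)


def force_from_flow_rate(flow_rate_mm3_s, calibration: CalibrationModel,
                         channel: ChannelGeometry, *,
                         check_geometry: bool = True,
                         height_rtol: float = 1e-6) -> np.ndarray:
    """Bead force (pN) at volumetric flow rate Q: F = c·Q/(w·h)."""
    if check_geometry:
        h = calibration.valid_channel_height_um
        if abs(channel.height_um - h) > height_rtol * h:
            raise ValueError(
                f"calibration was performed at channel height {h} µm but the "
                f"channel has {channel.height_um} µm; recalibrate or pass "
                "check_geometry=False"
            )
    q = np.asarray(flow_rate_mm3_s, dtype=float)
    return calibration.slope * q / channel.cross_section_mm2


def loading_rate_from_ramp(ramp_slope_mm3_s2: float,
                           calibration: CalibrationModel,
                           channel: ChannelGeometry) -> float:
    """Loading rate Ḟ = c·β/(w·h) in pN/s for a linear flow ramp of slope β."""
    if not (ramp_slope_mm3_s2 > 0):
        raise ValueError("ramp slope must be > 0 to define a loading rate")
    return calibration.slope * ramp_slope_mm3_s2 / channel.cross_section_mm2
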