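"""Shared physical types and constants.

Units convention used throughout the package:

* force            pN
* length           nm (bead/tether scale), µm (channel scale), mm (velocity scale)
* time             s
* energy           pN·nm
* flow rate        mm³/s internally (1 µL/min = 1/60 mm³/s)
* velocity         mm/s
* calibration      pN·s·mm⁻¹ (force per mean flow velocity)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Boltzmann constant in pN·nm per K (1.380649e-23 J/K).
BOLTZMANN_PN_NM = 1.380649e-2

#: Conversion factor from µL/min to mm³/s.
UL_PER_MIN_TO_MM3_PER_S = 1.0 / 60.0

#: Conversion from Pa·s to pN·s/nm² (1 Pa·s = 1e-6 pN·s/nm²).
PA_S_TO_PN_S_PER_NM2 = 1.0e-6


def _require_finite_positive(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class Environment:
    """Thermal and solvent environment of the assay.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.
    thermal_energy : float
        k_B·T in pN·nm.  Must be consistent with ``temperature``.
    viscosity : float
        Dynamic viscosity of the medium in Pa·s; only the Brownian-dynamics
        simulator uses it (it sets the bead relaxation time, not the
        equilibrium statistics).
    """

    temperature: float = 4.114 / BOLTZMANN_PN_NM
    thermal_energy: float = 4.114
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        _require_finite_positive(self.temperature, "temperature")
        _require_finite_positive(self.thermal_energy, "thermal_energy")
        _require_finite_positive(self.viscosity, "viscosity")
        expected = BOLTZMANN_PN_NM * self.temperature
        if abs(self.thermal_energy - expected) > 1e-6 * expected:
            raise ValueError(
                f"thermal_energy={self.thermal_energy} inconsistent with "
                f"k_B*temperature={expected:.6f} pN·nm"
            )

    @classmethod
    def from_temperature(cls, temperature: float, viscosity: float = 1.0e-3) -> "Environment":
        return cls(temperature=temperature,
                   thermal_energy=BOLTZMANN_PN_NM * temperature,
                   viscosity=viscosity)

    @classmethod
    def from_thermal_energy(cls, thermal_energy: float, viscosity: float = 1.0e-3) -> "Environment":
        return cls(temperature=thermal_energy / BOLTZMANN_PN_NM,
                   thermal_energy=thermal_energy,
                   viscosity=viscosity)


@dataclass(frozen=True)
class EnergyLandscape:
    """Single-barrier bond energy landscape (Bell–Evans picture).

    ``k_off`` is the dissociation rate at zero force (1/s) and ``delta_x``
    the distance from the bound state to the transition state along the
    pulling coordinate (nm).
    """

    k_off: float
    delta_x: float

    def __post_init__(self) -> None:
        _require_finite_positive(self.k_off, "k_off")
        _require_finite_positive(self.delta_x, "delta_x")


@dataclass(frozen=True)
class LoadingRate:
    """Force loading rate Ḟ in pN/s."""

    f_dot: float

    def __post_init__(self) -> None:
        _require_finite_positive(self.f_dot, "f_dot")


@dataclass(frozen=True)
class ReducedParams:
    """Reduced rupture-model parameters a1 = k_off/Ḟ and a2 = ΔX/(k_B T), both 1/pN."""

    a1: float
    a2: float

    def __post_init__(self) -> None:
        _require_finite_positive(self.a1, "a1")
        _require_finite_positive(self.a2, "a2")

    @classmethod
    def reduce(cls, landscape: EnergyLandscape, rate: LoadingRate,
               env: Environment) -> "ReducedParams":
        return cls(a1=landscape.k_off / rate.f_dot,
                   a2=landscape.delta_x / env.thermal_energy)


@dataclass(frozen=True)
class TetherGeometry:
    """Bead-on-a-tether geometry.

    ``bead_radius`` r and ``tether_extension`` l in nm; the lever arm of the
    inverted-pendulum fluctuation is l + r.  ``in_plane_displacement`` d is
    the flow-direction excursion of the bead center, related to the lever
    arm by (l+r)² ≈ d² + r² when the bead stays in the focal plane.
    """

    bead_radius: float
    tether_extension: float
    in_plane_displacement: float | None = None

    def __post_init__(self) -> None:
        _require_finite_positive(self.bead_radius, "bead_radius")
        if self.tether_extension < 0:
            raise ValueError("tether_extension must be >= 0")
        if self.in_plane_displacement is not None and self.in_plane_displacement < 0:
            raise ValueError("in_plane_displacement must be >= 0")

    @property
    def lever_arm(self) -> float:
        """l + r in nm."""
        return self.tether_extension + self.bead_radius


@dataclass(frozen=True)
class ChannelGeometry:
    """One rectangular microchannel: width and height in µm, serial index."""

    width_um: float
    height_um: float
    index: int = 0

    def __post_init__(self) -> None:
        _require_finite_positive(self.width_um, "width_um")
        _require_finite_positive(self.height_um, "height_um")

    @property
    def cross_section_mm2(self) -> float:
        return (self.width_um * 1e-3) * (self.height_um * 1e-3)


@dataclass(frozen=True)
class ChipLayout:
    """Serially connected channels of shared height and differing widths.

    Serial connection means one volumetric flow rate Q passes through every
    channel, so mean velocity (and hence bead force and loading rate) scales
    as 1/width.
    """

    channels: tuple[ChannelGeometry, ...]
    shared_height_um: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChipLayout needs at least one channel")
        _require_finite_positive(self.shared_height_um, "shared_height_um")
        for ch in self.channels:
            if abs(ch.height_um - self.shared_height_um) > 1e-9:
                raise ValueError(
                    f"channel {ch.index} height {ch.height_um} µm differs from "
                    f"shared height {self.shared_height_um} µm"
                )

    @classmethod
    def from_widths(cls, widths_um, height_um: float) -> "ChipLayout":
        channels = tuple(
            ChannelGeometry(width_um=w, height_um=height_um, index=i)
            for i, w in enumerate(widths_um)
        )
        return cls(channels=channels, shared_height_um=height_um)

    @property
    def widths_um(self) -> tuple[float, ...]:
        return tuple(ch.width_um for ch in self.channels)


@dataclass(frozen=True)
class LoadingProtocol:
    """Inlet volumetric flow-rate program Q(t) = Q0 + β·t (mm³/s).

    ``ramp_slope`` β is dQ/dt in mm³/s²; ``duration`` in s.
    """

    ramp_slope: float
    duration: float
    q0: float = 0.0

    def __post_init__(self) -> None:
        if self.ramp_slope < 0:
            raise ValueError("ramp_slope must be >= 0")
        _require_finite_positive(self.duration, "duration")
        if self.q0 < 0:
            raise ValueError("q0 must be >= 0")

    def flow_rate(self, t):
        """Q(t) in mm³/s for scalar or array t."""
        return self.q0 + self.ramp_slope * t

    @property
    def q_max(self) -> float:
        return self.q0 + self.ramp_slope * self.duration
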