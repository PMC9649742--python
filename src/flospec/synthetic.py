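"""Forward models that generate every input the analysis pipeline consumes.

These generators encode the statistical structure the analysis assumes:

* transverse bead fluctuations are an overdamped mean-reverting
  (Ornstein–Uhlenbeck) process whose equilibrium variance is fixed by the
  equipartition theorem, k_B T (l+r)/F — independent of the drag model,
  which only sets the relaxation time;
* rupture forces follow the Bell–Evans density at the per-channel loading
  rate, with narrower channels of a serial chip loaded faster (Ḟ ∝ 1/w);
* a ruptured bead vanishes from the movie (pixel-area dropout);
* bead removal under constant force is a competition of independent
  exponential processes (anchor dissociation + strand displacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from . import evans
from .calibration import (CalibrationModel, loading_rate_from_ramp,
                          lorentzian_corner_frequency)
from .core import (PA_S_TO_PN_S_PER_NM2, ChipLayout, EnergyLandscape,
                   Environment, LoadingProtocol, LoadingRate, TetherGeometry)
from .tracking import BeadTrack
from .wlc import ForceExtensionCurve, WLCParams, wlc_extension

__all__ = [
    "FluctuationRecord",
    "SurvivalRecord",
    "simulate_tethered_bead",
    "render_bead_movie",
    "simulate_rupture_experiment",
    "simulate_force_extension",
    "simulate_survival",
]


@dataclass
class FluctuationRecord:
    """Transverse bead-center fluctuation time series.

    ``variance`` is the unbiased sample variance of ``transverse_positions``
    (nm²); ``warnings`` collects sampling-adequacy notes.
    """

    sample_times: np.ndarray  # s
    transverse_positions: np.ndarray  # nm
    sampling_frequency: float  # Hz
    variance: float  # nm^2
    warnings: tuple[str, ...] = ()


@dataclass
class SurvivalRecord:
    """Per-bead removal times under constant force, with right-censoring."""

    removal_times: np.ndarray  # s
    censored: np.ndarray  # bool
    applied_force: float  # pN
    observation_time: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        self.removal_times = np.asarray(self.removal_times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.removal_times.shape != self.censored.shape:
            raise ValueError("removal_times and censored must match in shape")
        if np.any(self.removal_times < 0):
            raise ValueError("removal times must be >= 0")


def simulate_tethered_bead(force: float, tether: TetherGeometry,
                           env: Environment, sampling_frequency: float,
                           duration: float, seed=None) -> FluctuationRecord:
    """Simulate the transverse fluctuation of a tethered bead under flow.

    Ornstein–Uhlenbeck process with stiffness κ = F/(l+r), Stokes drag
    γ = 6πηr and relaxation time τ = γ/κ, advanced with the exact
    discretisation x_{t+Δt} = ρ·x_t + σ_eq·√(1−ρ²)·ξ, ρ = e^{−Δt/τ}, so the
    equilibrium variance equals k_B T (l+r)/F for any step size.
    """
    if not (force > 0):
        raise ValueError("force must be > 0")
    if not (sampling_frequency > 0 and duration > 0):
        raise ValueError("sampling_frequency and duration must be > 0")
    n = int(round(duration * sampling_frequency))
    if n < 100:
        raise ValueError("need duration*sampling_frequency >= 100 samples")
    rng = np.random.default_rng(seed)

    lever = tether.lever_arm
    kappa = force / lever  # pN/nm
    gamma = 6.0 * np.pi * (env.viscosity * PA_S_TO_PN_S_PER_NM2) * tether.bead_radius
    tau = gamma / kappa
    var_eq = env.thermal_energy * lever / force
    dt = 1.0 / sampling_frequency
    rho = np.exp(-dt / tau)

    x0 = np.sqrt(var_eq) * rng.standard_normal()
    innovations = np.sqrt(var_eq * (1.0 - rho ** 2)) * rng.standard_normal(n)
    # AR(1) recursion x_t = rho*x_{t-1} + e_t via an IIR filter
    x, _ = signal.lfilter([1.0], [1.0, -rho], innovations,
                          zi=np.array([rho * x0]))

    notes = []
    f_c = lorentzian_corner_frequency(force, tether, env)
    if sampling_frequency < 2.0 * f_c:
        notes.append(
            f"sampling frequency {sampling_frequency:.3g} Hz is below twice the "
            f"corner frequency {f_c:.3g} Hz; the variance estimate may be biased"
        )
        warnings.warn(notes[-1], UserWarning, stacklevel=2)
    times = np.arange(n) * dt
    return FluctuationRecord(sample_times=times, transverse_positions=x,
                             sampling_frequency=sampling_frequency,
                             variance=float(np.var(x, ddof=1)),
                             warnings=tuple(notes))


def _disk_profile(shape: tuple[int, int], cx: float, cy: float,
                  radius_px: float, amplitude: float,
                  edge_sigma_px: float = 1.0) -> np.ndarray:
    """Bright disk of sub-pixel center with a Gaussian-blurred edge."""
    yy, xx = np.indices(shape)
    dist = np.hypot(xx - cx, yy - cy)
    from scipy.special import erf
    return amplitude * 0.5 * (1.0 + erf((radius_px - dist)
                                        / (np.sqrt(2.0) * edge_sigma_px)))


def render_bead_movie(tracks: list[BeadTrack], field_size: tuple[int, int],
                      pixel_size_nm: float, bead_radius_px: float = 8.0,
                      bead_profile: str = "disk", amplitude: float = 3000.0,
                      baseline: float = 500.0, noise_sd: float = 0.0,
                      seed=None) -> np.ndarray:
    """Render bead tracks into a 16-bit movie stack (n_frames, H, W).

    Beads are drawn as the chosen profile at their sub-pixel centers; a
    bead contributes nothing on frames where its track area is zero (the
    rupture dropout the detector looks for).  Gaussian read noise of SD
    ``noise_sd`` is added per pixel.
    """
    if not tracks:
        raise ValueError("need at least one track to render")
    if bead_profile not in ("disk", "gaussian"):
        raise ValueError("bead_profile must be 'disk' or 'gaussian'")
    if not (pixel_size_nm > 0):
        raise ValueError("pixel_size_nm must be > 0")
    h, w = field_size
    n_frames = tracks[0].frame_times.size
    for t in tracks:
        if t.frame_times.size != n_frames:
            raise ValueError("all tracks must share the frame grid")
        present = t.areas > 0
        if np.any((t.x_px[present] < 0) | (t.x_px[present] >= w)
                  | (t.y_px[present] < 0) | (t.y_px[present] >= h)):
            raise ValueError(f"bead {t.bead_id} leaves the field of view")

    # warn about tracking-window collisions at first frame
    first = [(t.x_px[0], t.y_px[0]) for t in tracks if t.areas[0] > 0]
    for i in range(len(first)):
        for j in range(i + 1, len(first)):
            d = np.hypot(first[i][0] - first[j][0], first[i][1] - first[j][1])
            if d < 2.0 * bead_radius_px:
                warnings.warn(
                    f"beads closer than two profile radii ({d:.1f} px): "
                    "tracking windows would collide", UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    movie = np.empty((n_frames, h, w), dtype=np.uint16)
    for k in range(n_frames):
        frame = np.full((h, w), baseline, dtype=float)
        for t in tracks:
            if t.areas[k] <= 0:
                continue
            cx, cy = t.x_px[k], t.y_px[k]
            if bead_profile == "disk":
                frame += _disk_profile((h, w), cx, cy, bead_radius_px, amplitude)
            else:
                yy, xx = np.indices((h, w))
                frame += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                            / (2.0 * (bead_radius_px / 2.0) ** 2))
        if noise_sd > 0:
            frame += noise_sd * rng.standard_normal((h, w))
        movie[k] = np.clip(frame, 0, 65535).astype(np.uint16)
    return movie


def simulate_rupture_experiment(chip: ChipLayout, calibration: CalibrationModel,
                                protocol: LoadingProtocol,
                                landscape: EnergyLandscape, env: Environment,
                                n_beads_per_channel: int,
                                seed=None) -> pd.DataFrame:
    """Simulate a multi-channel rupture experiment under a linear flow ramp.

    Each channel i of the serial chip carries the shared volumetric ramp, so
    its loading rate is Ḟᵢ = c·β/(wᵢ·h); rupture forces are drawn from the
    Bell–Evans density at Ḟᵢ and converted back to rupture flow rates
    Qᵢ = F·wᵢ·h/c.  Beads that would outlast the ramp are right-censored at
    the ramp's final flow rate.

    Returns a table with columns ``bead_id``, ``channel_index``,
    ``rupture_flow_rate`` (mm³/s), ``loading_rate_pn_s``,
    ``rupture_force_pn`` and ``censored``.
    """
    if protocol.ramp_slope <= 0:
        raise ValueError("a linear ramp with positive slope is required "
                         "(zero slope defines no loading rate)")
    if n_beads_per_channel < 1:
        raise ValueError("n_beads_per_channel must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    bead_id = 0
    for ch in chip.channels:
        f_dot = loading_rate_from_ramp(protocol.ramp_slope, calibration, ch)
        forces = evans.sample_rupture_forces(
            landscape, rate=LoadingRate(f_dot=f_dot), env=env,
            n=n_beads_per_channel, seed=rng)
        q_rupt = forces * ch.cross_section_mm2 / calibration.slope
        censored = q_rupt > protocol.q_max
        q_obs = np.where(censored, protocol.q_max, q_rupt)
        f_obs = np.where(censored,
                         calibration.slope * protocol.q_max / ch.cross_section_mm2,
                         forces)
        frames.append(pd.DataFrame({
            "bead_id": np.arange(bead_id, bead_id + n_beads_per_channel),
            "channel_index": ch.index,
            "rupture_flow_rate": q_obs,
            "loading_rate_pn_s": f_dot,
            "rupture_force_pn": f_obs,
            "censored": censored,
        }))
        bead_id += n_beads_per_channel
    return pd.concat(frames, ignore_index=True)


def simulate_force_extension(wlc: WLCParams, forces, env: Environment,
                             noise_sd_extension: float = 0.0,
                             seed=None) -> ForceExtensionCurve:
    """Synthesize a force–extension curve from the worm-like-chain model.

    Extensions come from the numerical inverse of the interpolation force
    law plus additive Gaussian noise of SD ``noise_sd_extension`` (nm).
    """
    f = np.asarray(forces, dtype=float)
    if np.any(f <= 0):
        raise ValueError("forces must be > 0")
    if noise_sd_extension < 0:
        raise ValueError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    l = wlc_extension(f, wlc, env)
    if np.any(l >= wlc.contour_length):
        raise ValueError("requested force implies extension >= contour length")
    if noise_sd_extension > 0:
        l = l + noise_sd_extension * rng.standard_normal(f.shape)
    return ForceExtensionCurve(forces=f, extensions=l)


def simulate_survival(rate_background: float, rate_sd: float, n_beads: int,
                      observation_time: float, applied_force: float = 0.0,
                      label: str = "", seed=None) -> SurvivalRecord:
    """Simulate bead removal as competing independent exponential processes.

    Each bead leaves at the first event of anchor dissociation (rate
    ``rate_background``) or strand displacement (rate ``rate_sd``); the
    waiting time is exponential with the summed rate.  Beads still present
    at ``observation_time`` are right-censored at the horizon.
    """
    if rate_background < 0 or rate_sd < 0:
        raise ValueError("rates must be >= 0")
    if not (observation_time > 0):
        raise ValueError("observation_time must be > 0")
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    rng = np.random.default_rng(seed)
    total = rate_background + rate_sd
    if n_beads == 0:
        return SurvivalRecord(removal_times=np.empty(0), censored=np.empty(0, bool),
                              applied_force=applied_force,
                              observation_time=observation_time, label=label)
    if total == 0:
        warnings.warn("both rates are zero: every bead is censored",
                      UserWarning, stacklevel=2)
        times = np.full(n_beads, observation_time)
        return SurvivalRecord(removal_times=times,
                              censored=np.ones(n_beads, bool),
                              applied_force=applied_force,
                              observation_time=observation_time, label=label)
    raw = rng.exponential(1.0 / total, n_beads)
    censored = raw > observation_time
    times = np.where(censored, observation_time, raw)
    return SurvivalRecord(removal_times=times, censored=censored,
                          applied_force=applied_force,
                          observation_time=observation_time, label=label)
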