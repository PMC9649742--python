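"""Bead detection, sub-pixel tracking, tether selection and rupture detection.

Coordinate convention: images are row-major with origin at the top-left,
x = column index, y = row index; positions are in pixel units and convert
to µm via the pixel size.  The flow axis is +x by default.

Sub-pixel displacement uses Fourier cross-correlation: the integer-pixel
peak of the inverse-transformed cross-power is refined by an upsampled DFT
evaluated only in a small neighbourhood of that peak (a matrix-multiply
DFT), which gives pixel_size/upsample_factor resolution at a fraction of
the cost of upsampling the full correlation grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

from .core import LoadingProtocol

__all__ = [
    "BeadTrack",
    "RuptureEvent",
    "SelectionResult",
    "detect_beads",
    "subpixel_displacement",
    "default_upsample_factor",
    "select_tethered_beads",
    "detect_rupture",
    "track_movie",
]


@dataclass
class BeadTrack:
    """Per-bead time series of sub-pixel center position and pixel area.

    ``x_px``/``y_px`` are sub-pixel centers; ``areas`` is the detected pixel
    count per frame (0 where the bead has vanished).  Positions at frames
    with zero area are not meaningful.
    """

    bead_id: int
    frame_times: np.ndarray  # s
    x_px: np.ndarray
    y_px: np.ndarray
    areas: np.ndarray  # pixel counts
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        n = self.frame_times.size
        if not (self.x_px.size == self.y_px.size == self.areas.size == n):
            raise ValueError("all per-frame series must have equal length")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be > 0")
        present = self.areas > 0
        if not np.all(np.isfinite(self.x_px[present])):
            raise ValueError("positions must be finite on frames with area > 0")

    @property
    def x_um(self) -> np.ndarray:
        return self.x_px * self.pixel_size_nm * 1e-3

    @property
    def y_um(self) -> np.ndarray:
        return self.y_px * self.pixel_size_nm * 1e-3


@dataclass(frozen=True)
class RuptureEvent:
    """Outcome of rupture detection for one bead."""

    bead_id: int
    flow_rate: float  # mm^3/s at rupture (or the final Q when censored)
    censored: bool
    rupture_time: float | None = None


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[int, ...]
    rejected_stuck: tuple[int, ...]
    rejected_orphan: tuple[int, ...]


def detect_beads(frame: np.ndarray, min_area: int = 5,
                 threshold="otsu") -> pd.DataFrame:
    """Detect beads in a single frame by thresholding and connected components.

    Returns a DataFrame with columns ``x_px``, ``y_px`` (intensity-weighted
    centroids), ``area_px`` and ``merged`` (area above 1.5x the median,
    flagging likely merged neighbours).  An empty or featureless frame
    yields an empty table, not an error.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_beads expects a single 2-D frame")
    if img.size == 0 or np.ptp(img) == 0:
        return pd.DataFrame(columns=["x_px", "y_px", "area_px", "merged"])
    if threshold == "otsu":
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    labels = measure.label(mask)
    props = measure.regionprops(labels, intensity_image=img)
    rows = []
    for p in props:
        if p.area < min_area:
            continue
        cy, cx = p.centroid_weighted
        rows.append((cx, cy, int(p.area)))
    if not rows:
        return pd.DataFrame(columns=["x_px", "y_px", "area_px", "merged"])
    df = pd.DataFrame(rows, columns=["x_px", "y_px", "area_px"])
    df["merged"] = df["area_px"] > 1.5 * df["area_px"].median()
    return df


def default_upsample_factor(pixel_size_nm: float, target_nm: float = 10.0) -> int:
    """Upsampling needed for ~``target_nm`` registration resolution."""
    if not (pixel_size_nm > 0 and target_nm > 0):
        raise ValueError("pixel size and target resolution must be > 0")
    return max(1, math.ceil(pixel_size_nm / target_nm))


def _upsampled_dft(cross_power: np.ndarray, region_size: int,
                   upsample_factor: int, offsets: tuple[float, float]) -> np.ndarray:
    """Evaluate the inverse DFT of ``cross_power`` on an upsampled local grid.

    Matrix-multiply DFT over a ``region_size`` x ``region_size`` patch of the
    1/upsample_factor-pixel grid starting at ``offsets`` (row, col).
    """
    nr, nc = cross_power.shape
    sample_r = (np.arange(region_size) / upsample_factor + offsets[0])
    sample_c = (np.arange(region_size) / upsample_factor + offsets[1])
    freq_r = np.fft.fftfreq(nr)  # cycles per pixel
    freq_c = np.fft.fftfreq(nc)
    kernel_r = np.exp(2j * np.pi * np.outer(sample_r, freq_r))
    kernel_c = np.exp(2j * np.pi * np.outer(freq_c, sample_c))
    return kernel_r @ cross_power @ kernel_c


def subpixel_displacement(window: np.ndarray, reference_window: np.ndarray,
                          upsample_factor: int = 10) -> tuple[float, float]:
    """Sub-pixel displacement (dx, dy) of ``window`` relative to ``reference_window``.

    A bead that moved by (+dx, +dy) pixels between the reference frame and
    the current frame yields exactly that return value.  The integer-pixel
    cross-correlation peak is refined on a 1/upsample_factor grid restricted
    to a +/-1.5 px neighbourhood of the peak.
    """
    win = np.asarray(window, dtype=float)
    ref = np.asarray(reference_window, dtype=float)
    if win.shape != ref.shape or win.ndim != 2:
        raise ValueError("windows must be 2-D arrays of identical shape")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    if np.ptp(win) == 0 or np.ptp(ref) == 0:
        raise ValueError("flat (zero-variance) window: correlation peak undefined")

    f_win = np.fft.fft2(win - win.mean())
    f_ref = np.fft.fft2(ref - ref.mean())
    cross_power = f_win * np.conj(f_ref)
    corr = np.fft.ifft2(cross_power)
    peak = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    nr, nc = win.shape
    shift_r = peak[0] if peak[0] <= nr // 2 else peak[0] - nr
    shift_c = peak[1] if peak[1] <= nc // 2 else peak[1] - nc

    if upsample_factor > 1:
        # refine on the upsampled grid in a +/-1.5 px neighbourhood of the peak
        region = int(math.ceil(upsample_factor * 3.0)) | 1
        offset_r = shift_r - (region // 2) / upsample_factor
        offset_c = shift_c - (region // 2) / upsample_factor
        local = _upsampled_dft(cross_power, region, upsample_factor,
                               (offset_r, offset_c))
        lpeak = np.unravel_index(np.argmax(np.abs(local)), local.shape)
        shift_r = offset_r + lpeak[0] / upsample_factor
        shift_c = offset_c + lpeak[1] / upsample_factor

    return float(shift_c), float(shift_r)


def select_tethered_beads(tracks_forward: list[BeadTrack],
                          tracks_backward: list[BeadTrack],
                          displacement_threshold_um: float = 2.0,
                          flow_axis: str = "x",
                          strict: bool = False) -> SelectionResult:
    """Select single-tether beads from bidirectional-flow excursions.

    A bead qualifies when its peak flow-parallel excursion from its initial
    position *strictly* exceeds the threshold under BOTH flow directions.
    Stuck beads (sub-threshold motion) and free-floating beads (present in
    only one direction) are rejected; with ``strict=True`` unmatched bead
    ids raise instead of being rejected.
    """
    if flow_axis not in ("x", "y"):
        raise ValueError("flow_axis must be 'x' or 'y'")
    fwd = {t.bead_id: t for t in tracks_forward}
    bwd = {t.bead_id: t for t in tracks_backward}
    if len(fwd) != len(tracks_forward) or len(bwd) != len(tracks_backward):
        raise ValueError("duplicate bead ids within one flow direction")
    orphans = sorted(set(fwd) ^ set(bwd))
    if orphans and strict:
        raise ValueError(f"bead ids present in only one flow direction: {orphans}")

    def excursion_um(track: BeadTrack) -> float:
        pos = track.x_um if flow_axis == "x" else track.y_um
        present = track.areas > 0
        if not np.any(present):
            return 0.0
        p = pos[present]
        return float(np.max(np.abs(p - p[0])))

    selected, stuck = [], []
    for bead_id in sorted(set(fwd) & set(bwd)):
        if (excursion_um(fwd[bead_id]) > displacement_threshold_um
                and excursion_um(bwd[bead_id]) > displacement_threshold_um):
            selected.append(bead_id)
        else:
            stuck.append(bead_id)
    return SelectionResult(selected=tuple(selected),
                           rejected_stuck=tuple(stuck),
                           rejected_orphan=tuple(orphans))


def detect_rupture(track: BeadTrack, protocol: LoadingProtocol,
                   area_floor_fraction: float = 0.5,
                   n_initial_frames: int = 10) -> RuptureEvent:
    """Rupture flow rate of one bead from its pixel-area dropout.

    The first frame where the detected area falls below
    ``area_floor_fraction`` x the median area of the first
    ``n_initial_frames`` frames marks the rupture; the ramp flow rate at
    that frame time is the rupture flow rate.  A bead whose area never
    drops is censored at the final flow rate.
    """
    if not (0 < area_floor_fraction <= 1):
        raise ValueError("area_floor_fraction must be in (0, 1]")
    areas = track.areas
    if np.all(areas <= 0):
        raise ValueError(f"bead {track.bead_id}: area series is all zero "
                         "(bead never detected)")
    initial = np.median(areas[:n_initial_frames])
    if initial <= 0:
        raise ValueError(f"bead {track.bead_id}: bead absent in the initial frames")
    below = np.flatnonzero(areas < area_floor_fraction * initial)
    if below.size == 0:
        return RuptureEvent(bead_id=track.bead_id,
                            flow_rate=float(protocol.flow_rate(track.frame_times[-1])),
                            censored=True)
    t_rupt = float(track.frame_times[below[0]])
    return RuptureEvent(bead_id=track.bead_id,
                        flow_rate=float(protocol.flow_rate(t_rupt)),
                        censored=False, rupture_time=t_rupt)


def track_movie(movie: np.ndarray, pixel_size_nm: float,
                frame_interval_s: float = 1.0, min_area: int = 5,
                window_half: int = 16, upsample_factor: int | None = None,
                threshold="otsu") -> list[BeadTrack]:
    """Track every bead detected in frame 0 through a movie stack.

    Each bead gets a fixed square window (half-width ``window_half``)
    centered at its frame-0 centroid.  Per frame, the pixel area above the
    frame-0 threshold inside the window is recorded, and the sub-pixel
    displacement relative to the frame-0 window is measured by upsampled
    Fourier cross-correlation while the bead is present; frames without
    the bead carry area 0 and NaN positions.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, H, W) stack")
    n_frames, h, w = movie.shape
    if upsample_factor is None:
        upsample_factor = default_upsample_factor(pixel_size_nm)
    frame0 = movie[0].astype(float)
    beads = detect_beads(frame0, min_area=min_area, threshold=threshold)
    if threshold == "otsu":
        thr = filters.threshold_otsu(frame0)
    else:
        thr = float(threshold)

    tracks: list[BeadTrack] = []
    times = np.arange(n_frames) * frame_interval_s
    for bead_id, row in enumerate(beads.itertuples(index=False)):
        cx0, cy0 = row.x_px, row.y_px
        r0 = int(round(cy0))
        c0 = int(round(cx0))
        rlo, rhi = max(r0 - window_half, 0), min(r0 + window_half + 1, h)
        clo, chi = max(c0 - window_half, 0), min(c0 + window_half + 1, w)
        ref = frame0[rlo:rhi, clo:chi]
        xs = np.full(n_frames, np.nan)
        ys = np.full(n_frames, np.nan)
        areas = np.zeros(n_frames)
        for k in range(n_frames):
            win = movie[k, rlo:rhi, clo:chi].astype(float)
            area = int(np.count_nonzero(win > thr))
            areas[k] = area
            if area < min_area:
                areas[k] = 0
                continue
            if k == 0:
                xs[k], ys[k] = cx0, cy0
                continue
            try:
                dx, dy = subpixel_displacement(win, ref, upsample_factor)
            except ValueError:
                areas[k] = 0
                continue
            xs[k] = cx0 + dx
            ys[k] = cy0 + dy
        tracks.append(BeadTrack(bead_id=bead_id, frame_times=times,
                                x_px=xs, y_px=ys, areas=areas,
                                pixel_size_nm=pixel_size_nm))
    return tracks
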