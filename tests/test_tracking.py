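"""Bead detection, sub-pixel registration, tether selection, rupture detection."""

import itertools

import numpy as np
import pytest

from flospec import LoadingProtocol
from flospec.synthetic import render_bead_movie
from flospec.tracking import (BeadTrack, default_upsample_factor, detect_beads,
                              detect_rupture, select_tethered_beads,
                              subpixel_displacement, track_movie)


def _bead_frame(centers, shape=(64, 64), radius=5.0, noise_sd=0.0, seed=0):
    n_frames = 1
    tracks = []
    for i, (x, y) in enumerate(centers):
        tracks.append(BeadTrack(bead_id=i, frame_times=[0.0], x_px=[x],
                                y_px=[y], areas=[1.0], pixel_size_nm=65.0))
    movie = render_bead_movie(tracks, shape, 65.0, bead_radius_px=radius,
                              noise_sd=noise_sd, seed=seed)
    return movie[0].astype(float)


class TestDetectBeads:
    def test_blank_frame_yields_no_beads(self):
        assert detect_beads(np.zeros((32, 32))).empty

    def test_ten_beads_detected_at_generator_centers(self):
        xs = [10.5, 30.2, 50.8, 10.1, 30.9, 50.3, 10.7, 30.4, 50.6, 40.2]
        ys = [10.2, 10.8, 10.4, 30.6, 30.1, 30.7, 50.3, 50.9, 50.5, 40.8]
        frame = _bead_frame(list(zip(xs, ys)), shape=(64, 64), radius=4.0)
        df = detect_beads(frame)
        assert len(df) == 10
        found = df.sort_values(["y_px", "x_px"])[["x_px", "y_px"]].to_numpy()
        truth = np.array(sorted(zip(xs, ys), key=lambda p: (p[1], p[0])))
        # match by nearest neighbour: every generator center within 0.5 px
        for x, y in zip(xs, ys):
            d = np.hypot(df["x_px"] - x, df["y_px"] - y).min()
            assert d < 0.5

    def test_merged_beads_flagged_by_area(self):
        centers = [(20.0, 20.0), (26.0, 20.0),  # touching pair -> one blob
                   (45.0, 45.0), (45.0, 12.0), (12.0, 45.0)]
        with pytest.warns(UserWarning, match="collide"):
            frame = _bead_frame(centers, shape=(64, 64), radius=4.0)
        df = detect_beads(frame)
        assert len(df) == 4  # the pair merges into one component
        assert df["merged"].sum() == 1
        assert df.loc[df["merged"], "area_px"].iloc[0] > \
            1.5 * df["area_px"].median()


def _full_grid_upsampled_shift(win, ref, upsample_factor):
    """Brute-force oracle: upsampled cross-correlation over the whole window."""
    f_win = np.fft.fft2(win - win.mean())
    f_ref = np.fft.fft2(ref - ref.mean())
    cp = f_win * np.conj(f_ref)
    nr, nc = win.shape
    freq_r = np.fft.fftfreq(nr)
    freq_c = np.fft.fftfreq(nc)
    rr = np.arange(-(nr // 2), nr // 2, 1.0 / upsample_factor)
    cc = np.arange(-(nc // 2), nc // 2, 1.0 / upsample_factor)
    kr = np.exp(2j * np.pi * np.outer(rr, freq_r))
    kc = np.exp(2j * np.pi * np.outer(freq_c, cc))
    corr = np.abs(kr @ cp @ kc)
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    return float(cc[j]), float(rr[i])  # (dx, dy)


class TestSubpixelDisplacement:
    def test_identical_windows_give_zero(self):
        frame = _bead_frame([(20.0, 20.0)], shape=(40, 40))
        assert subpixel_displacement(frame, frame, 50) == (0.0, 0.0)

    def test_known_subpixel_shift_recovered(self):
        ref = _bead_frame([(18.0, 21.0)], shape=(48, 48))
        win = _bead_frame([(18.0 + 3.40, 21.0 - 1.25)], shape=(48, 48))
        dx, dy = subpixel_displacement(win, ref, upsample_factor=100)
        assert dx == pytest.approx(3.40, abs=0.05)
        assert dy == pytest.approx(-1.25, abs=0.05)

    def test_matches_skimage_reference(self):
        from skimage.registration import phase_cross_correlation
        ref = _bead_frame([(20.0, 19.0)], shape=(48, 48))
        win = _bead_frame([(21.7, 20.4)], shape=(48, 48))
        dx, dy = subpixel_displacement(win, ref, upsample_factor=100)
        # skimage returns the (row, col) shift that maps moving onto reference;
        # it normalises the cross-power differently, so agreement is to a few
        # hundredths of a pixel, not machine precision
        shift, _, _ = phase_cross_correlation(ref, win, upsample_factor=100)
        assert dx == pytest.approx(-shift[1], abs=0.05)
        assert dy == pytest.approx(-shift[0], abs=0.05)

    def test_localized_equals_full_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x0, y0 = rng.uniform(14, 18, 2)
            dx0, dy0 = rng.uniform(-3, 3, 2)
            ref = _bead_frame([(x0, y0)], shape=(32, 32), radius=4.0)
            win = _bead_frame([(x0 + dx0, y0 + dy0)], shape=(32, 32), radius=4.0)
            got = subpixel_displacement(win, ref, upsample_factor=20)
            oracle = _full_grid_upsampled_shift(win, ref, 20)
            assert got[0] == pytest.approx(oracle[0], abs=1e-6)
            assert got[1] == pytest.approx(oracle[1], abs=1e-6)

    def test_noisy_registration_within_tenth_pixel(self):
        amp_noise = 0.05 * 3000.0  # 5% of bead peak intensity
        ref = _bead_frame([(20.0, 20.0)], shape=(48, 48), noise_sd=amp_noise,
                          seed=1)
        win = _bead_frame([(21.3, 18.6)], shape=(48, 48), noise_sd=amp_noise,
                          seed=2)
        dx, dy = subpixel_displacement(win, ref, upsample_factor=100)
        assert dx == pytest.approx(1.3, abs=0.1)
        assert dy == pytest.approx(-1.4, abs=0.1)

    def test_flat_window_rejected(self):
        flat = np.zeros((16, 16))
        with pytest.raises(ValueError):
            subpixel_displacement(flat, flat, 10)

    def test_default_upsample_targets_10nm(self):
        assert default_upsample_factor(65.0) == 7
        assert default_upsample_factor(100.0) == 10


def _excursion_track(bead_id, excursion_um, n_frames=20, pixel_size=65.0):
    px = excursion_um * 1e3 / pixel_size
    x = np.zeros(n_frames)
    x[n_frames // 2:] = px  # step to the flow-stretched position
    return BeadTrack(bead_id=bead_id, frame_times=np.arange(n_frames),
                     x_px=x + 50.0, y_px=np.full(n_frames, 50.0),
                     areas=np.full(n_frames, 40.0), pixel_size_nm=pixel_size)


class TestSelectTetheredBeads:
    def test_stuck_bead_rejected(self):
        fwd = [_excursion_track(0, 0.0)]
        bwd = [_excursion_track(0, 0.0)]
        res = select_tethered_beads(fwd, bwd)
        assert res.selected == ()
        assert res.rejected_stuck == (0,)

    def test_mixture_selects_exactly_the_tethered(self):
        fwd = [_excursion_track(i, 2.6) for i in range(50)] + \
              [_excursion_track(50 + i, 0.1) for i in range(50)]
        bwd = [_excursion_track(i, 2.6) for i in range(50)] + \
              [_excursion_track(50 + i, 0.1) for i in range(50)]
        res = select_tethered_beads(fwd, bwd)
        assert res.selected == tuple(range(50))

    def test_threshold_is_strict_inequality(self):
        fwd = [_excursion_track(0, 2.0)]
        bwd = [_excursion_track(0, 2.0)]
        assert select_tethered_beads(fwd, bwd).selected == ()

    def test_orphan_handling(self):
        fwd = [_excursion_track(0, 2.6), _excursion_track(1, 2.6)]
        bwd = [_excursion_track(0, 2.6)]
        res = select_tethered_beads(fwd, bwd)
        assert res.selected == (0,)
        assert res.rejected_orphan == (1,)
        with pytest.raises(ValueError, match=r"\[1\]"):
            select_tethered_beads(fwd, bwd, strict=True)

    def test_permutation_invariant(self):
        fwd = [_excursion_track(i, 2.6 if i % 2 else 0.3) for i in range(10)]
        bwd = [_excursion_track(i, 2.6 if i % 2 else 0.3) for i in range(10)]
        rng = np.random.default_rng(0)
        shuffled_fwd = [fwd[i] for i in rng.permutation(10)]
        shuffled_bwd = [bwd[i] for i in rng.permutation(10)]
        assert (select_tethered_beads(fwd, bwd).selected
                == select_tethered_beads(shuffled_fwd, shuffled_bwd).selected)


class TestDetectRupture:
    def _track_with_dropout(self, drop_frame, n_frames=200):
        areas = np.full(n_frames, 40.0)
        if drop_frame is not None:
            areas[drop_frame:] = 0.0
        return BeadTrack(bead_id=0, frame_times=np.arange(n_frames, dtype=float),
                         x_px=np.full(n_frames, 10.0),
                         y_px=np.full(n_frames, 10.0),
                         areas=areas, pixel_size_nm=65.0)

    def test_constructed_dropout_maps_to_ramp_flow_rate(self):
        protocol = LoadingProtocol(ramp_slope=0.1, duration=200.0)
        ev = detect_rupture(self._track_with_dropout(120), protocol)
        assert not ev.censored
        assert ev.flow_rate == pytest.approx(0.1 * 120.0, rel=1e-12)

    def test_no_dropout_is_censored_at_final_flow_rate(self):
        protocol = LoadingProtocol(ramp_slope=0.1, duration=200.0)
        ev = detect_rupture(self._track_with_dropout(None), protocol)
        assert ev.censored
        assert ev.flow_rate == pytest.approx(0.1 * 199.0, rel=1e-12)

    def test_never_detected_bead_rejected(self):
        protocol = LoadingProtocol(ramp_slope=0.1, duration=200.0)
        with pytest.raises(ValueError, match="never detected"):
            detect_rupture(self._track_with_dropout(0), protocol)


def test_movie_to_rupture_table_round_trip(env, dig_landscape):
    """End-to-end: rendered movie -> tracks -> rupture flow rates match truth."""
    from flospec.calibration import CalibrationModel
    from flospec.synthetic import simulate_rupture_experiment
    from flospec import ChipLayout

    cal = CalibrationModel(slope=3.0, valid_bead_radius_nm=1100,
                           valid_tether_length_nm=1900,
                           valid_channel_height_um=60)
    chip = ChipLayout.from_widths([500], 60.0)
    protocol = LoadingProtocol(ramp_slope=2e-3, duration=100.0)
    truth = simulate_rupture_experiment(chip, cal, protocol, dig_landscape,
                                        env, 20, seed=8)
    n_frames = 80
    times = np.linspace(0.0, protocol.duration, n_frames)
    grid = list(itertools.product(range(4), range(5)))
    tracks = []
    for k, row in enumerate(truth.itertuples(index=False)):
        gx, gy = grid[k]
        t_rupt = (np.inf if row.censored
                  else row.rupture_flow_rate / protocol.ramp_slope)
        areas = np.where(times < t_rupt, 50.0, 0.0)
        tracks.append(BeadTrack(
            bead_id=k, frame_times=times,
            x_px=np.full(n_frames, 14.0 + 25.0 * gx),
            y_px=np.full(n_frames, 14.0 + 25.0 * gy),
            areas=areas, pixel_size_nm=65.0))
    movie = render_bead_movie(tracks, (120, 120), 65.0, bead_radius_px=5.0,
                              noise_sd=30.0, seed=9)
    recovered = track_movie(movie, pixel_size_nm=65.0,
                            frame_interval_s=times[1] - times[0],
                            window_half=10)
    assert len(recovered) == 20
    events = [detect_rupture(t, protocol) for t in recovered]
    got = np.sort([e.flow_rate for e in events if not e.censored])
    expected = np.sort(truth.loc[~truth["censored"],
                                 "rupture_flow_rate"].to_numpy())
    assert got.size == expected.size
    dq_frame = protocol.ramp_slope * (times[1] - times[0])
    agree = np.abs(got - expected) <= dq_frame + 1e-12
    assert agree.mean() >= 0.99
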