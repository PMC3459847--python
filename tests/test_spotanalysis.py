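"""Spot detection, track linking, kymographs, sigmoid metrics, divergence."""

import numpy as np
import pytest

from omgrowth.flowfield import Patch, regular_polygon
from omgrowth.optics import OpticsConfig, apply_camera_noise, render_micrograph
from omgrowth.simulator import init_state
from omgrowth.spotanalysis import (
    PunctaCurve,
    SigmoidFitError,
    Spot,
    SpotTrack,
    count_spots,
    detect_spots,
    fit_sigmoid,
    kymograph_top_edge,
    link_tracks,
    pairwise_divergence,
    puncta_curve,
)

from conftest import state_with_patches

P = 2 * np.pi * 0.5
TOP = P / 4  # arc coordinate of the top edge (theta = pi/2)


def render_points(params, centers_x, optics, area=1e-3, rng=None):
    """Micrograph of sub-diffraction light patches at given axial positions
    on the top edge line."""
    st = state_with_patches(params, [(x, TOP) for x in centers_x], area=area)
    return render_micrograph(st, optics, rng=rng)


def synthetic_track(track_id, positions_nm, frames=None):
    tr = SpotTrack(track_id=track_id)
    frames = frames if frames is not None else range(len(positions_nm))
    for f, (x, y) in zip(frames, positions_nm):
        tr.frames.append(f)
        tr.spots.append(Spot(x_nm=x, y_nm=y, intensity=1.0, sigma_nm=86.0, frame=f))
    return tr


class TestDetect:
    def test_blank_noise_image_has_no_spots(self, headline_params, quiet_optics):
        st = init_state(None, headline_params, 0)
        m = render_micrograph(st, quiet_optics, rng=np.random.default_rng(0))
        assert detect_spots(m) == []

    def test_well_separated_spots_found_at_true_positions(
        self, headline_params, quiet_optics
    ):
        m = render_points(headline_params, [-0.4, 0.4], quiet_optics)
        spots = sorted(detect_spots(m), key=lambda s: s.x_nm)
        assert len(spots) == 2
        for s, x_true in zip(spots, (-0.4, 0.4)):
            expect = (x_true - m.x0_um) * 1000
            assert abs(s.x_nm - expect) <= m.pixel_nm

    def test_pair_below_rayleigh_merges_to_one_spot(
        self, headline_params, quiet_optics
    ):
        m = render_points(headline_params, [-0.075, 0.075], quiet_optics)  # 150 nm
        assert len(detect_spots(m)) == 1

    def test_detection_is_intensity_scale_invariant(
        self, headline_params, quiet_optics
    ):
        m = render_points(headline_params, [-0.4, 0.4], quiet_optics)
        a = detect_spots(m)
        scaled = m.data * 37.0
        b = detect_spots(scaled, pixel_nm=m.pixel_nm)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.x_nm == pytest.approx(sb.x_nm, abs=1.0)
            assert sa.y_nm == pytest.approx(sb.y_nm, abs=1.0)

    def test_bare_array_requires_pixel_size(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((10, 10)))


class TestLink:
    def test_static_spots_link_into_static_tracks(self):
        frames = [
            [Spot(1000.0, 500.0, 10, 86, f), Spot(3000.0, 500.0, 10, 86, f)]
            for f in range(5)
        ]
        tracks = link_tracks(frames, max_step_nm=300)
        assert len(tracks) == 2
        for tr in tracks:
            pos = tr.positions()
            assert np.ptp(pos, axis=0).max() == 0.0

    def test_diverging_spots_monotone_separation(self):
        frames = [
            [Spot(1000.0 - 25 * f, 500.0, 10, 86, f), Spot(1000.0 + 25 * f, 500.0, 10, 86, f)]
            for f in range(6)
        ]
        tracks = link_tracks(frames, max_step_nm=300)
        assert len(tracks) == 2
        seps = [
            abs(a.x_nm - b.x_nm)
            for a, b in zip(tracks[0].spots, tracks[1].spots)
        ]
        assert all(s2 > s1 for s1, s2 in zip(seps[:-1], seps[1:]))

    def test_new_adjacent_spot_is_annotated_as_split(self):
        frames = [
            [Spot(1000.0, 500.0, 10, 86, 0)],
            [Spot(1000.0, 500.0, 10, 86, 1)],
            [Spot(950.0, 500.0, 10, 86, 2), Spot(1150.0, 500.0, 10, 86, 2)],
        ]
        tracks = link_tracks(frames, max_step_nm=300)
        children = [t for t in tracks if t.parent is not None]
        assert len(children) == 1
        assert children[0].split_frame == 2
        assert children[0].track_id in tracks[children[0].parent].children

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            link_tracks([[Spot(0, 0, 1, 80, 0)]])


class TestKymograph:
    def test_static_punctum_gives_horizontal_line(self, headline_params, quiet_optics):
        m = render_points(headline_params, [0.0], quiet_optics)
        ky = kymograph_top_edge([m] * 6)
        peak_rows = ky.argmax(axis=0)
        assert np.ptp(peak_rows) == 0
        bg = np.median(ky)
        mad = np.median(np.abs(ky - bg))
        assert ky.max() - bg > 20 * mad  # a clear bright line over background

    def test_moving_punctum_gives_sloped_line(self, headline_params, quiet_optics):
        frames = [
            render_points(headline_params, [-0.4 + 0.1 * f], quiet_optics)
            for f in range(6)
        ]
        ky = kymograph_top_edge(frames)
        peak_rows = ky.argmax(axis=0)
        steps = np.diff(peak_rows)
        assert all(steps > 0)
        assert np.ptp(steps) <= 1  # constant speed -> straight line

    def test_normalized_policy_shape(self, headline_params, quiet_optics):
        m = render_points(headline_params, [0.0], quiet_optics)
        ky = kymograph_top_edge([m, m], policy="normalized", n_bins=64)
        assert ky.shape == (64, 2)

    def test_geometry_mismatch_rejected(self, headline_params, quiet_optics):
        m = render_points(headline_params, [0.0], quiet_optics)
        m2 = render_points(headline_params, [0.0], quiet_optics)
        m2.meta["R_um"] = 0.75
        with pytest.raises(ValueError):
            kymograph_top_edge([m, m2])


class TestPunctaCurve:
    def test_unlabeled_stack_gives_zero_curve(self, headline_params, quiet_optics):
        st = init_state(None, headline_params, 0)
        stack = [render_micrograph(st, quiet_optics, rng=np.random.default_rng(1))
                 for _ in range(4)]
        curve = puncta_curve([stack, stack])
        assert np.all(curve.mean == 0.0)

    def test_ragged_frame_times_rejected(self, headline_params, quiet_optics):
        a = render_points(headline_params, [0.0], quiet_optics)
        b = render_points(headline_params, [0.0], quiet_optics)
        b.t = 99.0
        with pytest.raises(ValueError):
            puncta_curve([[a, a], [a, b]])

    def test_top_edge_mode_excludes_off_edge_spots(self, headline_params, quiet_optics):
        # one punctum on the top edge, one at the midline (arc 0)
        st = state_with_patches(headline_params, [(0.0, TOP), (0.5, 0.0)], area=1e-3)
        m = render_micrograph(st, quiet_optics)
        assert count_spots([m], mode="whole")[0] >= 2
        assert count_spots([m], mode="top_edge")[0] == 1


class TestSigmoid:
    @staticmethod
    def curve_from(times, values):
        return PunctaCurve(
            times=np.asarray(times, float),
            mean=np.asarray(values, float),
            sd=np.zeros(len(times)),
            n_replicates=1,
        )

    def test_exact_logistic_recovered(self):
        t = np.linspace(0, 1800, 25)
        y = 12.0 / (1 + np.exp(-(t - 900) / 300))
        fit = fit_sigmoid(self.curve_from(t, y))
        assert fit.n_max == pytest.approx(12.0, rel=0.01)
        assert fit.midpoint == pytest.approx(900.0, rel=0.01)
        assert fit.rate == pytest.approx(12.0 / (4 * 300), rel=0.01)
        assert not fit.ill_conditioned

    def test_noisy_logistic_nmax_within_ten_percent(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1800, 25)
        y = 12.0 / (1 + np.exp(-(t - 900) / 300)) + rng.normal(0, 0.5, t.size)
        fit = fit_sigmoid(self.curve_from(t, y))
        assert fit.n_max == pytest.approx(12.0, rel=0.10)

    def test_plateau_only_input_flagged(self):
        t = np.linspace(0, 1800, 10)
        fit = fit_sigmoid(self.curve_from(t, np.full(10, 7.0)))
        assert fit.ill_conditioned

    def test_per_perimeter_normalization(self):
        t = np.linspace(0, 1800, 25)
        y = 12.0 / (1 + np.exp(-(t - 900) / 300))
        fit = fit_sigmoid(self.curve_from(t, y), perimeter_um=6.0)
        assert fit.n_max_per_um == pytest.approx(2.0, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(self.curve_from([0, 1, 2, 3], [0, 1, 2, 3]))

    def test_zero_curve_raises_with_diagnostics(self):
        with pytest.raises(SigmoidFitError):
            fit_sigmoid(self.curve_from(np.arange(6.0), np.zeros(6)))


class TestDivergence:
    def test_static_tracks_have_zero_rate(self):
        tracks = [
            synthetic_track(0, [(1000.0, 500.0)] * 5),
            synthetic_track(1, [(2000.0, 500.0)] * 5),
        ]
        out = pairwise_divergence(tracks, frame_times=np.arange(5.0) * 60)
        assert out[0].rate == pytest.approx(0.0, abs=1e-12)

    def test_exponential_separation_rate_recovered(self):
        lam = 1.2e-4
        times = np.arange(8.0) * 300
        xa = -500 * np.exp(lam * times)
        xb = +500 * np.exp(lam * times)
        tracks = [
            synthetic_track(0, [(x, 0.0) for x in xa]),
            synthetic_track(1, [(x, 0.0) for x in xb]),
        ]
        out = pairwise_divergence(tracks, frame_times=times)
        assert out[0].rate == pytest.approx(lam, rel=1e-6)

    def test_polar_pairs_classified_by_position(self):
        tracks = [
            synthetic_track(0, [(100.0, 0.0)] * 4),
            synthetic_track(1, [(200.0, 0.0)] * 4),
            synthetic_track(2, [(5000.0, 0.0)] * 4),
            synthetic_track(3, [(5200.0, 0.0)] * 4),
        ]
        out = pairwise_divergence(
            tracks, boundaries_nm=(0.0, 10000.0), polar_margin_nm=500.0
        )
        regions = {(p.track_a, p.track_b): p.region for p in out}
        assert regions[(0, 1)] == "polar"
        assert regions[(2, 3)] == "cylindrical"

    def test_requires_overlapping_tracks(self):
        a = synthetic_track(0, [(0.0, 0.0)] * 3, frames=[0, 1, 2])
        b = synthetic_track(1, [(10.0, 0.0)] * 3, frames=[5, 6, 7])
        with pytest.raises(ValueError):
            pairwise_divergence([a, b])
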