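import numpy as np
import pytest
from scipy.spatial.distance import pdist

from etlscan.core import TraceMatrix
from etlscan.etl import AcquisitionGeometry, row_z
from etlscan.responses import StimulusProtocol
from etlscan.synthetic import (
    ActivityModel,
    GroundTruth,
    OpticsProfile,
    generate_activity,
    generate_bead_stack,
    generate_brain,
    generate_lut_points,
    render_acquisition,
)


class TestGenerateBrain:
    def test_empty(self, whole_brain_geometry):
        truth = generate_brain(whole_brain_geometry, 0, seed=1)
        assert truth.n_cells == 0

    def test_2000_cells_respect_min_distance(self, whole_brain_geometry):
        truth = generate_brain(whole_brain_geometry, 2000, seed=1)
        assert truth.n_cells == 2000
        # brute-force all-pairs check
        assert pdist(truth.cell_positions).min() >= 6.0

    def test_positions_inside_volume(self, whole_brain_geometry):
        truth = generate_brain(whole_brain_geometry, 500, seed=2)
        pos = truth.cell_positions
        g = whole_brain_geometry
        assert (pos[:, 0] >= 0).all() and (pos[:, 0] <= g.fov_x).all()
        assert (pos[:, 1] >= 0).all() and (pos[:, 1] <= g.fov_y).all()
        assert (pos[:, 2] >= 0).all() and (pos[:, 2] <= g.z_range).all()

    def test_deterministic(self, whole_brain_geometry):
        a = generate_brain(whole_brain_geometry, 300, seed=1)
        b = generate_brain(whole_brain_geometry, 300, seed=1)
        assert np.array_equal(a.cell_positions, b.cell_positions)
        assert np.array_equal(a.motif_labels, b.motif_labels)

    def test_motifs_only_on_responsive_cells(self, whole_brain_geometry):
        truth = generate_brain(whole_brain_geometry, 400, seed=3)
        assert (truth.motif_labels[~truth.responsive_flags] == 0).all()
        assert (truth.motif_labels[truth.responsive_flags] >= 1).all()
        assert np.isnan(truth.response_amplitudes[~truth.responsive_flags]).all()

    def test_overfull_volume_reports_achievable_count(self):
        g = AcquisitionGeometry(fov_x=20, fov_y=20, z_range=20, n_x=8, n_y=8, n_planes=2)
        with pytest.raises(RuntimeError, match="achieved"):
            generate_brain(g, 5000, seed=1, margin=1.0, max_attempts_per_cell=20)

    def test_json_roundtrip(self, whole_brain_geometry, tmp_path):
        truth = generate_brain(whole_brain_geometry, 50, seed=4)
        truth.to_json(tmp_path / "t.json")
        back = GroundTruth.from_json(tmp_path / "t.json")
        assert np.array_equal(back.cell_positions, truth.cell_positions)
        assert np.array_equal(back.responsive_flags, truth.responsive_flags)


class TestGenerateActivity:
    def _single_cell_truth(self, responsive=False, motif=1):
        return GroundTruth(
            cell_positions=np.array([[10.0, 10.0, 10.0]]),
            responsive_flags=np.array([responsive]),
            motif_labels=np.array([motif if responsive else 0]),
            response_amplitudes=np.array([1.0 if responsive else np.nan]),
            seed=0,
        )

    def test_single_event_peaks_then_decays_with_tau(self):
        truth = self._single_cell_truth()
        truth.responsive_flags[0] = False
        proto = StimulusProtocol([])
        model = ActivityModel(baseline_rate=0.0, noise_model="none", tau_decay=3.5,
                              photon_gain=100.0, baseline_f0=0.0)
        # plant a single event by hand through a one-presentation protocol
        truth2 = self._single_cell_truth(responsive=True, motif=1)
        proto2 = StimulusProtocol([(10.0, 11.0)])
        model2 = ActivityModel(baseline_rate=0.0, noise_model="none", tau_decay=3.5,
                               photon_gain=100.0, baseline_f0=0.0, stim_response_prob=1.0)
        from etlscan.synthetic import ResponseMotif

        motifs = {1: ResponseMotif("impulse", latency=0.0, amplitude=1.0, trial_decay=1.0)}
        rate = 10.0
        tm = generate_activity(truth2, proto2, model2, duration=60.0, rate=rate, seed=0,
                               motifs=motifs)
        trace = tm.data[0]
        peak = trace.argmax()
        assert peak == int(round(10.0 * rate))
        # e-folding: value tau seconds after the peak is peak/e
        k = int(round(3.5 * rate))
        assert trace[peak + k] == pytest.approx(trace[peak] / np.e, rel=1e-6)

    def test_ten_presentations_give_ten_transients(self, looming_protocol):
        truth = self._single_cell_truth(responsive=True, motif=1)
        model = ActivityModel(baseline_rate=0.0, noise_model="none", stim_response_prob=1.0)
        tm = generate_activity(truth, looming_protocol, model,
                               duration=looming_protocol.duration + 20, rate=1.0, seed=0)
        assert len(truth.stim_transients[0]) == 10
        # the trace rises at every presentation onset
        trace = tm.data[0]
        for onset, _ in looming_protocol.presentations:
            i = int(onset)
            assert trace[i + 1] > trace[i - 1]

    def test_event_count_conservation(self, whole_brain_geometry, looming_protocol):
        truth = generate_brain(whole_brain_geometry, 200, seed=5)
        model = ActivityModel(baseline_rate=0.0, noise_model="none", stim_response_prob=1.0)
        generate_activity(truth, looming_protocol, model,
                          duration=looming_protocol.duration + 20, rate=1.0, seed=1)
        total = sum(len(t) for t in truth.stim_transients)
        n_resp = truth.responsive_flags.sum()
        assert total == 10 * n_resp

    def test_gaussian_noise_sd(self):
        truth = self._single_cell_truth()
        model = ActivityModel(baseline_rate=0.0, noise_model="gaussian", noise_sigma=1.0)
        tm = generate_activity(truth, StimulusProtocol([]), model,
                               duration=2000.0, rate=1.0, seed=2)
        assert tm.data[0].std() == pytest.approx(1.0, rel=0.10)

    def test_deterministic(self, short_protocol):
        truth = self._single_cell_truth(responsive=True)
        model = ActivityModel()
        a = generate_activity(truth, short_protocol, model, duration=120, rate=2.0, seed=9)
        b = generate_activity(truth, short_protocol, model, duration=120, rate=2.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_duration_must_cover_protocol(self, short_protocol):
        truth = self._single_cell_truth()
        with pytest.raises(ValueError, match="cover"):
            generate_activity(truth, short_protocol, ActivityModel(), duration=10.0,
                              rate=1.0, seed=0)


class TestRenderAcquisition:
    def _truth_one_cell(self, x, y, z):
        return GroundTruth(
            cell_positions=np.array([[x, y, z]]),
            responsive_flags=np.array([False]),
            motif_labels=np.array([0]),
            response_amplitudes=np.array([np.nan]),
            seed=0,
        )

    def test_no_cells_only_background_noise(self, small_geometry):
        truth = GroundTruth(
            cell_positions=np.empty((0, 3)),
            responsive_flags=np.empty(0, bool),
            motif_labels=np.empty(0, int),
            response_amplitudes=np.empty(0),
            seed=0,
        )
        traces = TraceMatrix(np.empty((0, 3)), rate=1.0)
        frames = render_acquisition(truth, small_geometry, traces,
                                    OpticsProfile(), seed=0, background=10.0)
        assert frames.shape == (3 * 6, 64, 64)
        assert frames.mean() == pytest.approx(10.0, rel=0.05)

    def test_brightest_plane_nearest_cell_z(self):
        g = AcquisitionGeometry(fov_x=50, fov_y=50, z_range=180, n_x=64, n_y=64,
                                n_planes=30, frame_rate=30)
        truth = self._truth_one_cell(25.0, 25.0, 90.0)
        traces = TraceMatrix(np.full((1, 2), 100.0), rate=1.0)
        frames = render_acquisition(truth, g, traces, OpticsProfile(sigma_xy=1.0, sigma_z=3.0),
                                    seed=0, noise="none")
        bright = frames[:30].max(axis=(1, 2))
        row = int(truth.cell_positions[0, 1] / g.pixel_pitch_y)
        expected = int(np.argmin([abs(row_z(g, p, row) - 90.0) for p in range(30)]))
        assert bright.argmax() == expected

    def test_planted_shift_recovered_by_correlation_oracle(self, small_geometry):
        g = small_geometry
        rng = np.random.default_rng(0)
        pos = np.column_stack([
            rng.uniform(10, 40, 12), rng.uniform(10, 40, 12), rng.uniform(0, 60, 12)
        ])
        truth = GroundTruth(pos, np.zeros(12, bool), np.zeros(12, int),
                            np.full(12, np.nan), seed=0)
        n_frames = 2 * g.n_planes
        shifts = np.zeros((n_frames, 2))
        shifts[g.n_planes] = (-2.0, 3.0)  # frame k = first frame of volume 1: (dy, dx)
        truth.motion_shifts = shifts
        traces = TraceMatrix(np.full((12, 2), 200.0), rate=1.0)
        frames = render_acquisition(truth, g, traces,
                                    OpticsProfile(sigma_xy=1.5, sigma_z=30.0),
                                    seed=0, noise="none")
        a, b = frames[0], frames[g.n_planes]
        # brute-force integer cross-correlation oracle: shifting the
        # reference by the planted displacement maximizes the correlation
        best, best_val = None, -np.inf
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                val = (np.roll(a, (dy, dx), axis=(0, 1)) * b).sum()
                if val > best_val:
                    best, best_val = (dy, dx), val
        assert best == (-2, 3)

    def test_forward_inverse_trace_consistency(self):
        # render one cell, re-extract its mean-ROI trace, correlate with input
        g = AcquisitionGeometry(fov_x=40, fov_y=40, z_range=30, n_x=48, n_y=48,
                                n_planes=3, frame_rate=3.0)
        truth = self._truth_one_cell(20.0, 20.0, 15.0)
        rng = np.random.default_rng(1)
        n_vol = 40
        sig = 100.0 + 100.0 * (rng.random(n_vol) > 0.7) * rng.random(n_vol)
        traces = TraceMatrix(sig[None, :], rate=1.0)
        frames = render_acquisition(truth, g, traces,
                                    OpticsProfile(sigma_xy=2.0, sigma_z=5.0),
                                    seed=2, background=10.0, noise="poisson")
        plane = 1  # z=15 um lies in the middle plane
        stream = frames[plane::3]
        cy = int(20.0 / g.pixel_pitch_y)
        cx = int(20.0 / g.pixel_pitch_x)
        roi = stream[:, cy - 2 : cy + 3, cx - 2 : cx + 3].mean(axis=(1, 2))
        r = np.corrcoef(roi, sig)[0, 1]
        assert r >= 0.95

    def test_invalid_optics(self, small_geometry):
        with pytest.raises(ValueError):
            OpticsProfile(sigma_xy=-1.0)

    def test_deterministic(self, small_geometry):
        truth = self._truth_one_cell(25.0, 25.0, 30.0)
        traces = TraceMatrix(np.full((1, 2), 50.0), rate=1.0)
        a = render_acquisition(truth, small_geometry, traces, OpticsProfile(), seed=5)
        b = render_acquisition(truth, small_geometry, traces, OpticsProfile(), seed=5)
        assert np.array_equal(a, b)


class TestGenerateBeadStack:
    def test_profile_maximum_at_planted_position(self):
        stack, truth = generate_bead_stack(0.5, 2.0, voxel_size=(0.5, 0.1, 0.1),
                                           extent=(40.0, 10.0, 10.0), n_beads=1, seed=0)
        b = truth.iloc[0]
        zi, yi, xi = np.unravel_index(stack.argmax(), stack.shape)
        assert abs(zi - b.z_vox) <= 1
        assert abs(yi - b.y_vox) <= 1
        assert abs(xi - b.x_vox) <= 1

    def test_seed_repeatability(self):
        a, ta = generate_bead_stack(0.5, 2.0, n_beads=3, seed=7,
                                    extent=(40.0, 10.0, 10.0), voxel_size=(0.5, 0.1, 0.1))
        b, tb = generate_bead_stack(0.5, 2.0, n_beads=3, seed=7,
                                    extent=(40.0, 10.0, 10.0), voxel_size=(0.5, 0.1, 0.1))
        assert np.array_equal(a, b)
        assert ta.equals(tb)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            generate_bead_stack(-0.5, 2.0)


class TestGenerateLutPoints:
    def test_eight_points_over_range(self):
        pts = generate_lut_points(n_points=8, seed=0)
        assert pts.shape == (8, 2)
        assert pts[:, 1].min() == 0.0
        assert pts[:, 1].max() == 233.0

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            generate_lut_points(n_points=5)

    def test_noise_free_points_lie_on_curve(self):
        from etlscan.synthetic import default_lut_curve

        pts = generate_lut_points(n_points=10, noise_sigma=0.0, seed=0)
        assert np.allclose(pts[:, 0], default_lut_curve(pts[:, 1]))
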