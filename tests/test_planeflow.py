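"""Cutplane sampling, flow integration, TTP indices, jets, streamlines."""

import dataclasses

import numpy as np
import pytest

import flow4d as f4
from flow4d.planeflow import (
    PlaneFlowError,
    interp_velocity,
    net_flow_series,
    time_to_peak_accel_series,
    time_to_peak_flow_series,
)

from conftest import center_plane, steady_tube_spec


def uniform_dataset(v=(0.0, 0.0, 10.0), shape=(16, 16, 16), n_frames=4):
    """A constant-velocity dataset (no phantom machinery)."""
    vel = np.zeros((3, n_frames, *shape))
    for c in range(3):
        vel[c] = v[c]
    return f4.FlowDataset(
        magnitude=np.ones((n_frames, *shape)),
        velocity=vel,
        voxel_size=1.0,
        frame_times=np.arange(n_frames) * 100.0,
        venc=200.0,
    )


# ---------------------------------------------------------------------------
# Plane sampling
# ---------------------------------------------------------------------------

class TestSamplePlane:
    def test_uniform_field_gives_uniform_through_plane_velocity(self):
        ds = uniform_dataset()
        plane = f4.CutPlane("tube", origin=np.array([8.0, 8.0, 8.0]),
                            normal=np.array([0.0, 0.0, 1.0]), half_extent=4.0,
                            grid_step=0.5, lumen_source="speed_threshold")
        s = f4.sample_plane(ds, plane, frame=0)
        assert np.allclose(s.vtp, 10.0)

    def test_sign_follows_the_plane_normal(self):
        ds = uniform_dataset()
        plane = f4.CutPlane("tube", origin=np.array([8.0, 8.0, 8.0]),
                            normal=np.array([0.0, 0.0, -1.0]), half_extent=4.0,
                            grid_step=0.5, lumen_source="speed_threshold")
        s = f4.sample_plane(ds, plane, frame=0)
        assert np.allclose(s.vtp, -10.0)

    def test_interpolation_identity_at_voxel_centers(self):
        rng = np.random.default_rng(0)
        ds = uniform_dataset(n_frames=1)
        ds.velocity[:] = rng.normal(size=ds.velocity.shape)
        # voxel (z=5, y=7, x=3) center is at (3.5, 7.5, 5.5) mm for 1 mm voxels
        pt = np.array([[3.5, 7.5, 5.5]])
        v = interp_velocity(ds, pt, 0)[0]
        assert np.allclose(v, ds.velocity[:, 0, 5, 7, 3])

    def test_plane_fully_outside_volume_is_an_error(self):
        ds = uniform_dataset()
        plane = f4.CutPlane("far", origin=np.array([500.0, 500.0, 500.0]),
                            normal=np.array([0.0, 0.0, 1.0]), half_extent=4.0,
                            grid_step=1.0, lumen_source="speed_threshold")
        with pytest.raises(PlaneFlowError, match="outside"):
            f4.sample_plane(ds, plane, frame=0)


class TestAutoOrient:
    def test_axial_tube(self):
        ds, _ = f4.make_vessel_phantom(steady_tube_spec(grid=32))
        n = f4.auto_orient(ds, np.array([20.8, 20.8, 20.8]), frame=0)
        angle = np.degrees(np.arccos(np.clip(abs(n[2]), -1, 1)))
        assert angle < 2.0

    def test_oblique_tube_recovers_axis(self):
        # tube along (1, 1, 0)/sqrt(2): analytic axis oracle
        ds, _ = f4.make_vessel_phantom(steady_tube_spec(grid=48, radius_mm=6.0, axis="xy"))
        n = f4.auto_orient(ds, np.array([31.2, 31.2, 31.2]), frame=0)
        axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        angle = np.degrees(np.arccos(np.clip(abs(n @ axis), -1, 1)))
        assert angle < 2.0

    def test_still_fluid_is_an_error(self):
        ds = uniform_dataset(v=(0.0, 0.0, 0.0))
        with pytest.raises(PlaneFlowError, match="manual"):
            f4.auto_orient(ds, np.array([8.0, 8.0, 8.0]), frame=0)


# ---------------------------------------------------------------------------
# Flow curves
# ---------------------------------------------------------------------------

class TestFlowCurve:
    def test_plug_tube_flow_within_two_percent(self):
        q_true = 10 * np.pi  # 10 cm/s through pi cm^2
        spec = steady_tube_spec(radius_mm=10.0, q_ml_s=q_true)
        ds, gt = f4.make_vessel_phantom(spec)
        curve = f4.flow_curve(ds, center_plane(spec), mask=gt.lumen)
        assert curve.q == pytest.approx(q_true, rel=0.02)
        assert curve.mean_velocity == pytest.approx(10.0, rel=0.02)

    def test_flow_is_linear_in_the_velocity_field(self):
        spec = steady_tube_spec(q_ml_s=10 * np.pi)
        half = steady_tube_spec(q_ml_s=5 * np.pi)
        ds1, gt1 = f4.make_vessel_phantom(spec)
        ds2, gt2 = f4.make_vessel_phantom(half)
        c1 = f4.flow_curve(ds1, center_plane(spec), mask=gt1.lumen)
        c2 = f4.flow_curve(ds2, center_plane(half), mask=gt2.lumen)
        assert np.allclose(c2.q, 0.5 * c1.q, rtol=1e-9)

    def test_agrees_with_fine_grid_summation_oracle(self):
        spec = steady_tube_spec(radius_mm=8.0, q_ml_s=20.0)
        ds, gt = f4.make_vessel_phantom(spec)
        plane = center_plane(spec)
        curve = f4.flow_curve(ds, plane, mask=gt.lumen)
        # brute-force oracle: sum through-plane velocity on a 4x finer plane grid
        fine = dataclasses.replace(plane, grid_step=plane.grid_step / 4)
        pts, shape = fine.grid_points()
        vtp = interp_velocity(ds, pts, 0) @ fine.normal
        q_oracle = vtp.sum() * fine.grid_step**2 / 100.0
        assert curve.q[0] == pytest.approx(q_oracle, rel=0.01)

    def test_flipping_the_normal_negates_the_curve_exactly(self):
        spec = steady_tube_spec(q_ml_s=15.0)
        ds, gt = f4.make_vessel_phantom(spec)
        plane = center_plane(spec)
        flipped = dataclasses.replace(plane, normal=-plane.normal)
        q1 = f4.flow_curve(ds, plane, mask=gt.lumen).q
        q2 = f4.flow_curve(ds, flipped, mask=gt.lumen).q
        assert np.allclose(q1, -q2, rtol=1e-12, atol=1e-12)

    def test_translation_invariance_along_a_straight_tube(self):
        spec = steady_tube_spec(radius_mm=6.0, q_ml_s=12.0)
        ds, gt = f4.make_vessel_phantom(spec)
        v = spec.vessels[0]
        nets = []
        for frac in (0.3, 0.5, 0.7):
            origin = np.asarray(v.start_point) + frac * v.length * v.axis
            p = f4.CutPlane("tube", origin=origin, normal=v.axis,
                            half_extent=12.0, grid_step=0.65)
            nets.append(f4.net_flow(f4.flow_curve(ds, p, mask=gt.lumen)))
        assert np.ptp(nets) / np.mean(nets) < 0.01

    def test_grid_refinement_stability(self):
        spec = steady_tube_spec(radius_mm=6.0, q_ml_s=12.0)
        ds, gt = f4.make_vessel_phantom(spec)
        plane = center_plane(spec)
        finer = dataclasses.replace(plane, grid_step=plane.grid_step / 2)
        n1 = f4.net_flow(f4.flow_curve(ds, plane, mask=gt.lumen))
        n2 = f4.net_flow(f4.flow_curve(ds, finer, mask=gt.lumen))
        assert abs(n2 - n1) / abs(n1) < 0.01

    def test_speed_threshold_lumen_fallback(self):
        spec = steady_tube_spec(radius_mm=8.0, q_ml_s=20.0)
        ds, _ = f4.make_vessel_phantom(spec)
        plane = center_plane(spec)
        plane.lumen_source = "speed_threshold"
        curve = f4.flow_curve(ds, plane)  # no mask needed
        assert curve.q[0] == pytest.approx(20.0, rel=0.03)

    def test_empty_lumen_at_every_frame_is_an_error(self):
        ds = uniform_dataset(v=(0.0, 0.0, 0.0))
        plane = f4.CutPlane("x", origin=np.array([8.0, 8.0, 8.0]),
                            normal=np.array([0.0, 0.0, 1.0]), half_extent=4.0,
                            grid_step=1.0, lumen_source="speed_threshold")
        with pytest.raises(PlaneFlowError, match="empty lumen"):
            f4.flow_curve(ds, plane)


# ---------------------------------------------------------------------------
# Net flow and TTP indices
# ---------------------------------------------------------------------------

class TestNetFlowSeries:
    def test_constant_flow_integrates_exactly(self):
        times = np.arange(20) * 50.0
        assert net_flow_series(times, np.full(20, 10.0), 1000.0) == pytest.approx(10.0)

    def test_zero_curve(self):
        times = np.arange(10) * 100.0
        assert net_flow_series(times, np.zeros(10), 1000.0) == 0.0

    def test_half_sine_matches_closed_form_at_20_frames(self):
        # analytic integral: (2/pi) * peak * T_sys + baseline * T
        wf = f4.WaveformSpec(cycle_duration=1000, n_frames=20, systole_fraction=0.35,
                             peak_flow=100.0, diastolic_baseline=0.0)
        q = f4.make_waveform(wf)
        net = net_flow_series(wf.frame_times, q, 1000.0)
        analytic = (2 / np.pi) * 100.0 * 0.35 * 1000.0 / 1000.0
        assert net == pytest.approx(analytic, rel=0.02)


class TestTimeToPeak:
    def test_half_sine_peaks_at_systole_midpoint(self):
        wf = f4.WaveformSpec(cycle_duration=1000, n_frames=20, systole_fraction=0.3,
                             peak_flow=100.0)
        t = wf.frame_times
        q = f4.make_waveform(wf)
        assert time_to_peak_flow_series(t, q) == 150.0

    def test_constant_curve_ties_break_to_earliest_frame(self):
        t = np.arange(10) * 50.0
        assert time_to_peak_flow_series(t, np.full(10, 3.0)) == 0.0
        assert time_to_peak_accel_series(t, np.full(10, 3.0)) == 0.0

    def test_linear_ramp_then_plateau_accelerates_at_zero(self):
        t = np.arange(10) * 50.0
        q = np.minimum(np.arange(10, dtype=float), 5.0)
        assert time_to_peak_accel_series(t, q) == 0.0

    def test_acceleration_never_after_flow_peak(self):
        wf = f4.WaveformSpec(cycle_duration=900, n_frames=20, systole_fraction=0.4,
                             peak_flow=80.0, diastolic_baseline=3.0)
        t, q = wf.frame_times, f4.make_waveform(wf)
        assert time_to_peak_accel_series(t, q) <= time_to_peak_flow_series(t, q)

    @pytest.mark.parametrize("trial", range(20))
    def test_random_curves_match_exhaustive_scan_oracles(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = rng.integers(5, 30)
        t = np.arange(n) * 40.0
        q = rng.normal(10, 4, size=n)
        # exhaustive-scan oracles
        best_f, best_q = 0, -np.inf
        for f in range(n):
            if q[f] > best_q:
                best_f, best_q = f, q[f]
        assert time_to_peak_flow_series(t, q) == t[best_f]
        if best_f == 0:
            assert time_to_peak_accel_series(t, q) == 0.0
        else:
            best_a, best_af = -np.inf, 0
            for f in range(best_f):
                a = (q[f + 1] - q[f]) / 40.0
                if a > best_a:
                    best_a, best_af = a, f
            assert time_to_peak_accel_series(t, q) == t[best_af]


# ---------------------------------------------------------------------------
# Jet peak velocity
# ---------------------------------------------------------------------------

def jet_spec(peak=300.0, noise_sd=0.0, seed=0, n_frames=6):
    wf = f4.WaveformSpec(cycle_duration=600, n_frames=n_frames, peak_flow=1.0)
    return f4.PhantomSpec(
        grid_shape=(40, 40, 40),
        waveforms={"w": wf},
        jet=f4.JetSpec(origin=(26.0, 26.0, 10.0), direction=(0.0, 0.0, 1.0),
                       peak_velocity=peak, core_radius=4.0),
        venc=400.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def jet_plane():
    return f4.CutPlane("TV", origin=np.array([26.0, 26.0, 22.0]),
                       normal=np.array([0.0, 0.0, 1.0]), half_extent=12.0,
                       grid_step=0.65)


class TestPeakJetVelocity:
    def test_programmed_jet_recovered_within_discretization_loss(self):
        ds, gt = f4.make_vessel_phantom(jet_spec(peak=300.0))
        res = f4.peak_jet_velocity(ds, jet_plane(), mask=gt.lumen)
        # analytic jet-profile oracle at the sampled voxel positions: the best
        # attainable value is the profile at the voxel center nearest the axis
        h = 1.3
        centers = (np.arange(40) + 0.5) * h
        r2_min = (centers - 26.0)[np.argmin(np.abs(centers - 26.0))] ** 2
        oracle = 300.0 * np.exp(-2 * r2_min / 4.0**2)  # same offset in x and y
        assert res.value == pytest.approx(oracle, rel=0.01)
        # worst-case loss bound: nearest voxel center within h/2 per in-plane axis
        floor = 300.0 * np.exp(-2 * (h / 2) ** 2 / 4.0**2)
        assert floor <= res.value <= 300.0
        # the maximum should sit near the jet axis
        assert np.linalg.norm(res.position[:2] - 26.0) < 1.5

    def test_zero_field_gives_zero(self):
        ds = uniform_dataset(v=(0.0, 0.0, 0.0))
        plane = f4.CutPlane("TV", origin=np.array([8.0, 8.0, 8.0]),
                            normal=np.array([0.0, 0.0, 1.0]), half_extent=4.0,
                            grid_step=1.0, lumen_source="speed_threshold")
        assert f4.peak_jet_velocity(ds, plane).value == 0.0

    def test_noise_shifts_peak_by_at_most_four_sigma(self):
        sd = 5.0
        base = f4.peak_jet_velocity(
            *_ds_and_mask(jet_spec(peak=300.0))
        ).value
        noisy = f4.peak_jet_velocity(
            *_ds_and_mask(jet_spec(peak=300.0, noise_sd=sd, seed=21))
        ).value
        assert abs(noisy - base) <= 4 * sd


def _ds_and_mask(spec):
    ds, gt = f4.make_vessel_phantom(spec)
    return ds, jet_plane(), gt.lumen


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

class TestStreamlines:
    def test_uniform_field_gives_a_straight_line(self):
        ds = uniform_dataset(v=(0.0, 10.0, 0.0))
        (line,) = f4.trace_streamlines(ds, np.array([[8.0, 2.0, 8.0]]), frame=0,
                                       step=0.5, max_len=100)
        assert len(line) > 10
        # x and z stay constant, y increases
        assert np.allclose(line[:, [0, 2]], 8.0, atol=1e-9)
        assert np.all(np.diff(line[:, 1]) > 0)

    def test_solid_body_rotation_closes_a_circle(self):
        # v = omega x r about the z axis through the volume center
        shape = (24, 40, 40)
        nz, ny, nx = shape
        h = 1.0
        x = (np.arange(nx) + 0.5) * h
        y = (np.arange(ny) + 0.5) * h
        X, Y = np.meshgrid(x, y, indexing="xy")
        cx = cy = 20.0
        vel = np.zeros((3, 1, nz, ny, nx))
        vel[0, 0] = -(Y - cy)[None, :, :]
        vel[1, 0] = (X - cx)[None, :, :]
        ds = f4.FlowDataset(
            magnitude=np.ones((1, *shape)), velocity=vel, voxel_size=h,
            frame_times=np.array([0.0]), venc=100.0,
        )
        r0 = 10.0
        seed = np.array([[cx + r0, cy, 12.0]])
        step = h / 4
        circumference = 2 * np.pi * r0
        (line,) = f4.trace_streamlines(ds, seed, frame=0, step=step,
                                       max_len=int(circumference / step) + 10)
        radii = np.linalg.norm(line[:, :2] - [cx, cy], axis=1)
        assert abs(radii[-1] - r0) / r0 < 0.01  # drift < 1% per revolution

    def test_zero_field_gives_single_point(self):
        ds = uniform_dataset(v=(0.0, 0.0, 0.0))
        (line,) = f4.trace_streamlines(ds, np.array([[8.0, 8.0, 8.0]]), frame=0)
        assert line.shape == (1, 3)

    def test_outside_seed_skipped_with_warning(self, caplog):
        ds = uniform_dataset()
        with caplog.at_level("WARNING", logger="flow4d.planeflow"):
            lines = f4.trace_streamlines(ds, np.array([[99.0, 99.0, 99.0]]), frame=0)
        assert lines == []
        assert any("outside" in r.message for r in caplog.records)
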