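"""Breathing phantom: kinematics, rasterization, overlap and labels."""

import numpy as np
import pytest

from mousect import (BreathingPattern, MouseModel, NoiseConfig, PhantomSpec,
                     TumorSphere, Volume, desk_geometry, forward_project,
                     label_motion, overlap_fractions, overlap_matrix,
                     own_motion_labels, rasterize_phantom,
                     sample_breathing_traces, simulate_scan)
from mousect.phantom import GroundTruthLabels, default_phantom


def single_mouse_spec(**mouse_kw) -> PhantomSpec:
    kw = dict(center_mm=(0.0, 0.0, 0.0), diaphragm_z_mm=2.0,
              tumors=(TumorSphere((1.4, -1.0, -1.5)),))
    kw.update(mouse_kw)
    return PhantomSpec(mice=[MouseModel(**kw)],
                       grid_shape=(40, 32, 52), voxel_size_mm=0.5,
                       origin_mm=(-10.0, -5.5, -13.0))


class TestBreathingTraces:
    def test_zero_amplitude_gives_zero_trace(self):
        pat = BreathingPattern(amplitude_mm=0.0)
        traces = sample_breathing_traces([pat], 200, seed=0)
        assert np.all(traces == 0)

    def test_gasp_count_and_support(self):
        """Period 40, duration 6, no jitter: 10 gasps, 60 nonzero samples,
        verified by brute-force scanning of the trace."""
        pat = BreathingPattern(gasp_period=40.0, gasp_duration=6.0,
                               amplitude_mm=1.0, phase_offset=0.0,
                               timing_jitter=0.0)
        trace = sample_breathing_traces([pat], 400, seed=0)[:, 0]
        nz = trace > 0
        assert nz.sum() == 60
        # brute-force run-length scan
        runs = np.flatnonzero(np.diff(np.concatenate([[0], nz.view(np.int8), [0]])) == 1)
        assert len(runs) == 10
        # discrete sampling of the raised-cosine pulse: peak sample is
        # sin^2(pi * 2.5 / 6) of the amplitude
        assert trace.max() == pytest.approx(np.sin(np.pi * 2.5 / 6) ** 2, abs=1e-12)

    def test_seed_determinism(self):
        pats = [BreathingPattern(seed=3)]
        t1 = sample_breathing_traces(pats, 300, seed=5)
        t2 = sample_breathing_traces(pats, 300, seed=5)
        t3 = sample_breathing_traces(pats, 300, seed=6)
        assert np.array_equal(t1, t2)
        assert not np.array_equal(t1, t3)

    def test_duration_must_be_shorter_than_period(self):
        with pytest.raises(ValueError):
            BreathingPattern(gasp_period=5.0, gasp_duration=5.0)

    def test_duty_cycle_matches_fraction_of_nonzero_samples(self):
        pat = BreathingPattern(gasp_period=18.0, gasp_duration=4.0,
                               timing_jitter=1.0)
        trace = sample_breathing_traces([pat], 4000, seed=2)[:, 0]
        duty = pat.gasp_duration / pat.gasp_period
        assert np.mean(trace > 0) == pytest.approx(duty, abs=0.02)


class TestRasterization:
    def test_rest_state_independent_of_displacement_argument(self):
        spec = single_mouse_spec()
        a = rasterize_phantom(spec)
        b = rasterize_phantom(spec, np.zeros(1))
        assert np.array_equal(a.values, b.values)
        assert a.domain == "hu"

    def test_tumor_voxel_count_matches_inside_test_oracle(self):
        """1 mm tumor at 0.08 mm voxels: voxel count equals a brute-force
        per-voxel-center inside test."""
        spec = PhantomSpec(
            mice=[MouseModel(center_mm=(0.0, 0.0, 0.0),
                             semi_axes_mm=(2.0, 2.0, 3.0),
                             diaphragm_z_mm=1.0, liver_length_mm=2.5,
                             tumors=(TumorSphere((0.3, -0.2, -0.2), 1.0),))],
            grid_shape=(56, 56, 80), voxel_size_mm=0.08,
            origin_mm=(-2.24, -2.24, -3.2))
        vol = rasterize_phantom(spec)
        count = int(np.sum(vol.values == 60.0))
        xs, ys, zs = vol.voxel_centers()
        oracle = 0
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    if (x - 0.3) ** 2 + (y + 0.2) ** 2 + (z + 0.2) ** 2 <= 0.25:
                        oracle += 1
        assert count == oracle
        assert oracle > 0

    def test_diaphragm_displacement_shifts_liver_edge_crossing(self):
        spec = single_mouse_spec()
        rest = rasterize_phantom(spec)
        moved = rasterize_phantom(spec, np.array([0.4]))

        def crossing_z(vol: Volume) -> float:
            xs, ys, zs = vol.voxel_centers()
            i = np.argmin(np.abs(xs)); j = np.argmin(np.abs(ys))
            profile = vol.values[i, j, :]
            liver = np.flatnonzero(profile == 400.0)
            return zs[liver[-1]]  # most cranial liver voxel

        shift = crossing_z(rest) - crossing_z(moved)
        assert shift == pytest.approx(0.4, abs=spec.voxel_size_mm)

    def test_overlapping_mice_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(mice=[
                MouseModel(center_mm=(-2.0, 0.0, 0.0)),
                MouseModel(center_mm=(2.0, 0.0, 0.0)),
            ], grid_shape=(60, 32, 52), voxel_size_mm=0.5,
                origin_mm=(-15.0, -5.5, -13.0))


class TestOverlap:
    def test_single_mouse_has_no_off_diagonal_overlap(self):
        spec = single_mouse_spec()
        geom = desk_geometry(n_angles=12, detector_cols=60, detector_rows=40,
                             pixel_pitch_mm=2.0)
        ov = overlap_matrix(spec, geom)
        assert ov.shape == (12, 1, 1)
        assert np.all(ov[:, 0, 0])

    def test_symmetry_and_diagonal(self):
        spec = default_phantom()
        geom = desk_geometry(n_angles=24)
        ov = overlap_matrix(spec, geom)
        assert np.array_equal(ov, np.swapaxes(ov, 1, 2))
        assert np.all(ov[:, range(4), range(4)])

    def test_overlap_agrees_with_silhouette_projection_oracle(self):
        """Two mice side by side: the overlap decision matches detector-support
        intersection of each mouse rasterized and projected alone."""
        from mousect.phantom import BedModel
        transparent_bed = BedModel(hu=-1000.0)   # keep only mouse silhouettes
        mice = [MouseModel(center_mm=(-8.0, 0.0, 0.0)),
                MouseModel(center_mm=(8.0, 0.0, 0.0))]
        spec = PhantomSpec(mice=mice, bed=transparent_bed,
                           grid_shape=(60, 32, 52),
                           voxel_size_mm=0.5, origin_mm=(-15.0, -5.5, -13.0))
        geom = desk_geometry(n_angles=36, detector_cols=120, detector_rows=60,
                             pixel_pitch_mm=1.2)
        frac = overlap_fractions(spec, geom)
        for a in range(36):
            supports = []
            for k in range(2):
                alone = PhantomSpec(mice=[mice[k]], bed=transparent_bed,
                                    grid_shape=spec.grid_shape,
                                    voxel_size_mm=0.5,
                                    origin_mm=spec.origin_mm)
                vol = rasterize_phantom(alone).to_mu()
                frame = forward_project(vol, geom, a)
                cols = np.flatnonzero(frame.max(axis=0) > 1e-6)
                supports.append((cols[0], cols[-1]))
            oracle = supports[0][0] <= supports[1][1] and supports[1][0] <= supports[0][1]
            shared = min(supports[0][1], supports[1][1]) \
                - max(supports[0][0], supports[1][0]) + 1
            if frac[a, 0, 1] == 0.0:
                # disjoint bounding cylinders imply disjoint silhouettes, up
                # to pixel granularity at exact-tangency angles
                assert shared <= 2, f"angle index {a}"
            elif frac[a, 0, 1] > 0.08:
                # clear cylinder overlap must show up in the silhouettes;
                # marginal overlaps are skipped (cylinder bounds the ellipsoid)
                assert oracle, f"angle index {a}"


class TestLabels:
    def test_full_moi_gasp_grades_ten(self):
        traces = np.array([[0.0], [2.0], [0.0]])
        ov = np.ones((3, 1, 1), dtype=bool)
        labels = label_motion(traces, ov, 0, [2.0])
        assert list(labels) == [0, 10, 0]

    def test_non_overlapping_breather_grades_zero(self):
        traces = np.zeros((4, 2))
        traces[:, 1] = 2.0                      # mouse 1 gasps constantly
        ov = np.zeros((4, 2, 2), dtype=bool)
        ov[:, 0, 0] = ov[:, 1, 1] = True        # no cross overlap
        labels = label_motion(traces, ov, 0, [2.0, 2.0])
        assert np.all(labels == 0)

    def test_partial_overlap_devalues_grade(self):
        traces = np.zeros((1, 2))
        traces[0, 1] = 2.0
        ov = np.zeros((1, 2, 2))
        ov[0, [0, 1], [0, 1]] = 1.0
        ov[0, 1, 0] = ov[0, 0, 1] = 0.3
        labels = label_motion(traces, ov, 0, [2.0, 2.0])
        assert labels[0] == 3                   # round(10 * 1.0 * 0.3)

    def test_discard_threshold_semantics(self):
        labels = GroundTruthLabels(np.array([[2], [3], [10]]))
        mask = labels.discard_mask(0)
        assert list(mask) == [False, True, True]

    def test_own_labels_round_half_up(self):
        traces = np.array([[0.5], [0.49]])
        labels = own_motion_labels(traces, [2.0])
        assert list(labels[:, 0]) == [3, 2]     # 2.5 rounds up, 2.45 down


class TestSimulateScan:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        spec = single_mouse_spec()
        geom = desk_geometry(n_angles=18, detector_cols=64, detector_rows=48,
                             pixel_pitch_mm=2.0)
        return spec, geom

    def test_static_noiseless_scan_equals_per_angle_projection(self, tiny_setup):
        spec, geom = tiny_setup
        traces = np.zeros((18, 1))
        proj, labels = simulate_scan(spec, geom, traces,
                                     NoiseConfig(i0=1000.0, enabled=False), seed=0)
        assert np.all(labels.labels == 0)
        static = rasterize_phantom(spec).to_mu()
        for a in [0, 7, 13]:
            expected = 1000.0 * np.exp(-forward_project(static, geom, a))
            np.testing.assert_allclose(proj.frames[a], expected, rtol=1e-12)

    def test_same_seed_reproduces_scan(self, tiny_setup):
        spec, geom = tiny_setup
        traces = sample_breathing_traces([spec.mice[0].breathing], 18, seed=0)
        p1, _ = simulate_scan(spec, geom, traces, NoiseConfig(i0=500.0), seed=9)
        p2, _ = simulate_scan(spec, geom, traces, NoiseConfig(i0=500.0), seed=9)
        assert np.array_equal(p1.frames, p2.frames)

    def test_gasp_frames_differ_only_near_diaphragm(self, tiny_setup):
        """Noiseless single-mouse scan: breathing changes the projection only
        inside the detector band of the moving diaphragm region."""
        spec, geom = tiny_setup
        traces = np.zeros((18, 1))
        traces[5, 0] = 2.0
        proj, labels = simulate_scan(spec, geom, traces,
                                     NoiseConfig(enabled=False), seed=0)
        assert labels.labels[5, 0] == 10
        static, _ = simulate_scan(spec, geom, np.zeros((18, 1)),
                                  NoiseConfig(enabled=False), seed=0)
        diff = np.abs(proj.frames[5] - static.frames[5])
        rows = np.flatnonzero(diff.max(axis=1) > 1e-9 * static.frames[5].max())
        # everything that moves (lung/liver interface, liver span, tumors)
        # lies between the displaced caudal liver edge and the rest diaphragm
        mouse = spec.mice[0]
        z_lo = mouse.diaphragm_z_mm - mouse.liver_length_mm - 2.0 - 1.0
        z_hi = mouse.diaphragm_z_mm + 1.0
        tau = geom.source_detector_mm / (geom.source_isocenter_mm - 5.0)
        _, v = geom.pixel_coords()
        band = np.flatnonzero((v >= z_lo * tau - 2.0) & (v <= z_hi * tau + 2.0))
        assert rows.size > 0
        assert set(rows).issubset(set(band))
        untouched = [a for a in range(18) if a != 5]
        np.testing.assert_array_equal(proj.frames[untouched],
                                      static.frames[untouched])


class TestSpecValidation:
    def test_roundtrip_yaml(self, tmp_path):
        spec = default_phantom()
        path = tmp_path / "spec.yaml"
        spec.save(path)
        loaded = PhantomSpec.load(path)
        assert loaded.to_dict() == spec.to_dict()

    def test_mouse_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(mice=[MouseModel(center_mm=(50.0, 0.0, 0.0))])

    def test_labels_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthLabels(np.array([[11]]))
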