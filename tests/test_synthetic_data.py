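import numpy as np
import pytest

from divekin.body_model import whole_body_cm
from divekin.calibration import project
from divekin.dive_events import detect_foot_events, find_prv
from divekin.dive_variables import compute_dive_variables
from divekin.errors import SpecError
from divekin.synthetic_data import (
    MIRROR_MAP,
    SyntheticDiveSpec,
    generate_cohort_specs,
    generate_cohort_variables,
    generate_dive_3d,
    make_camera_rig,
    render_views,
)


class TestSpecValidation:
    def test_impulse_longer_than_trial_rejected(self):
        with pytest.raises(SpecError):
            SyntheticDiveSpec(duration=1.0, impulse_duration=0.9)

    def test_step_longer_than_stance_rejected(self):
        with pytest.raises(SpecError):
            SyntheticDiveSpec(step_length=0.7, stance_ratio=0.75, leg_length=0.88)

    def test_bad_side_rejected(self):
        with pytest.raises(SpecError):
            SyntheticDiveSpec(side="up")


class TestGroundTruthSelfConsistency:
    def test_variables_recomputable_from_the_true_trajectory(self, default_dive):
        traj, gt = default_dive
        cm = whole_body_cm(traj)
        ev = detect_foot_events(traj, gt.side, ground_z=0.0)
        prv, t_prv = find_prv(cm.v_res, ev.t_start, ev.t_last_contact)
        v = compute_dive_variables(traj, cm, gt.side, ev, prv, t_prv, leg_ref_frame=12)
        assert abs(v.fsd - gt.variables.fsd) < 1e-3
        assert abs(v.fda - gt.variables.fda) < 0.1
        assert abs(t_prv - gt.t_prv) <= 1
        assert abs(v.dblpp - gt.variables.dblpp) < 1e-6

    def test_targets_hit_by_construction(self, default_dive):
        _, gt = default_dive
        spec = SyntheticDiveSpec()
        assert gt.variables.prv == pytest.approx(spec.peak_speed, rel=1e-3)
        assert gt.variables.fda == pytest.approx(spec.departure_angle, abs=0.1)
        assert gt.variables.trprv == pytest.approx(spec.impulse_duration, abs=1 / 120)
        assert gt.variables.fsd == pytest.approx(spec.step_length, abs=0.01)
        assert gt.variables.dblpp == pytest.approx(spec.stance_ratio, abs=0.01)

    def test_prescribed_half_second_impulse(self, cameras):
        _, gt = generate_dive_3d(SyntheticDiveSpec(impulse_duration=0.50))
        assert gt.variables.trprv == pytest.approx(0.50, abs=1 / 120)

    def test_cycle_ordering_invariant(self, default_dive):
        _, gt = default_dive
        assert gt.t_start <= gt.t_last_contact < gt.t_prv <= gt.t_last_contact + 6

    def test_ground_height_never_violated(self, default_dive):
        traj, _ = default_dive
        assert traj.positions[:, :, 2].min() >= -1e-9


class TestSymmetryAndMonotonicity:
    def test_left_right_trajectories_are_mirror_images(self):
        tl, _ = generate_dive_3d(SyntheticDiveSpec(side="left"))
        tr, _ = generate_dive_3d(SyntheticDiveSpec(side="right"))
        mirrored = tr.positions[:, MIRROR_MAP, :].copy()
        mirrored[:, :, 1] *= -1
        assert np.max(np.abs(tl.positions - mirrored)) < 1e-12

    def test_peak_speed_sweep_monotone_in_recovered_prv(self):
        prvs = [
            generate_dive_3d(SyntheticDiveSpec(peak_speed=p))[1].variables.prv
            for p in (2.0, 3.0, 4.0)
        ]
        assert prvs[0] < prvs[1] < prvs[2]

    def test_determinism_bit_identical(self):
        spec = SyntheticDiveSpec(noise_px=1.5, dropout_rate=0.02, seed=9)
        t1, _ = generate_dive_3d(spec)
        t2, _ = generate_dive_3d(spec)
        assert np.array_equal(t1.positions, t2.positions)
        cams, _ = make_camera_rig("lateral2cam")
        s1 = render_views(t1, cams, 1.5, 0.02, seed=9)
        s2 = render_views(t2, cams, 1.5, 0.02, seed=9)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.data, b.data)


class TestCameraRig:
    def test_field_preset_has_three_consistent_cameras(self, cameras, control_points):
        assert len(cameras) == 3
        from divekin.calibration import self_reconstruction_error

        err = self_reconstruction_error(cameras, control_points)
        assert np.max(err) < 1e-6

    def test_single_camera_rig_rejected(self):
        with pytest.raises(SpecError):
            make_camera_rig([("solo", (16.0, 0.0, 1.5))])

    def test_camera_inside_volume_rejected(self):
        with pytest.raises(SpecError):
            make_camera_rig([("a", (0.0, 0.0, 1.0)), ("b", (-2.0, 0.0, 1.0))])


class TestRenderViews:
    def test_noiseless_render_reconstruct_roundtrip(self, default_dive, cameras):
        from divekin.calibration import reconstruct_series

        traj, _ = default_dive
        seqs = render_views(traj, cameras)
        uv = np.stack([s.data[:, :, :2] for s in seqs])
        rec = reconstruct_series(cameras, uv)
        assert np.max(np.abs(rec - traj.positions)) < 1e-6

    def test_rendered_projections_match_forward_model(self, default_dive, cameras):
        traj, _ = default_dive
        seqs = render_views(traj, cameras)
        uv = project(cameras[0], traj.positions[50])
        assert np.allclose(seqs[0].data[50, :, :2], uv, atol=1e-9)

    def test_dropout_fraction_within_binomial_interval(self, default_dive, cameras):
        traj, _ = default_dive
        rate = 0.05
        seqs = render_views(traj, cameras, dropout_rate=rate, seed=11)
        conf = np.concatenate([s.data[:, :, 2].ravel() for s in seqs])
        frac = np.mean(conf == 0)
        half_width = 1.96 * np.sqrt(rate * (1 - rate) / conf.size)
        assert abs(frac - rate) < half_width + 1e-12


class TestCohorts:
    def test_variables_cohort_is_study_shaped(self):
        table, curves = generate_cohort_variables(seed=1)
        # 2 groups x 4 subjects x 2 conditions x 2 sides x 4 trials
        assert len(table) == 2 * 4 * 2 * 2 * 4
        assert set(table["group"]) == {"CG", "VG"}
        assert curves["v"].shape == (len(table), 101)
        assert curves["knee"].shape == (len(table), 101)
        assert (table["prv"] > 0).all() and (table["dblpp"] > 0).all()

    def test_injected_post_effect_shifts_vg_post_mean(self):
        null, _ = generate_cohort_variables(seed=2)
        shifted, _ = generate_cohort_variables(seed=2, post_effects={"fsd": 0.3})
        sel = (shifted["group"] == "VG") & (shifted["condition"] == "post")
        assert shifted.loc[sel, "fsd"].mean() > null.loc[sel, "fsd"].mean() + 0.2
        other = ~sel
        assert np.allclose(
            shifted.loc[other, "fsd"], null.loc[other, "fsd"], atol=0.11
        )

    def test_spec_cohort_applies_field_mapped_shifts(self):
        specs = generate_cohort_specs(seed=3, post_effects={"fsd": 0.1})
        assert len(specs) == 2 * 2 * 2 * 2  # groups x subjects x conditions x sides
        by_label = {}
        for labels, spec in specs:
            by_label[(labels["group"], labels["condition"], labels["subject"], labels["side"])] = spec
        for (g, c, s, sd), spec in by_label.items():
            if g == "VG" and c == "post":
                pre = by_label[(g, "pre", s, sd)]
                assert spec.step_length == pytest.approx(pre.step_length + 0.1)
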