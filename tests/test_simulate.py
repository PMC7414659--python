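"""Synthetic trial generator: determinism, geometry, ground truth."""

import numpy as np
import pytest

from reachkin.errors import InfeasibleConfigurationError, InvalidArgumentError
from reachkin.extract import extract_profile
from reachkin.geometry import PanelGeometry, default_geometry
from reachkin.simulate import SimConfig, mirror_markers, synth_reach_trial


class TestGeometry:
    def test_targets_lie_on_stated_radius(self):
        geo = default_geometry()
        for i in range(1, 13):
            r = np.linalg.norm(geo.target(i) - geo.center)
            assert r == pytest.approx(20.0, abs=1e-9)

    def test_start_on_center_shoulder_line_at_forearm_distance(self):
        shoulder = np.array([0.0, 0.0, 100.0])
        geo = PanelGeometry.from_subject(shoulder, 60.0, 24.0)
        d = np.linalg.norm(geo.start_position - geo.center)
        assert d == pytest.approx(24.0, abs=1e-9)
        # collinear with center -> shoulder
        v1 = geo.start_position - geo.center
        v2 = shoulder - geo.center
        cross = np.linalg.norm(np.cross(v1, v2))
        assert cross == pytest.approx(0.0, abs=1e-9)

    def test_clock_layout(self):
        geo = default_geometry()
        # 12 o'clock straight up, 3 o'clock to the subject's right
        assert geo.target(12)[2] == pytest.approx(geo.center[2] + 20.0)
        assert geo.target(3)[0] == pytest.approx(geo.center[0] + 20.0)

    def test_bad_target_index(self):
        geo = default_geometry()
        with pytest.raises(InvalidArgumentError):
            geo.target(13)


class TestSynthReachTrial:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(n_submovements=2, marker_noise_sd=0.1, seed=42)
        rec1, _ = synth_reach_trial(cfg, target_index=5)
        rec2, _ = synth_reach_trial(cfg, target_index=5)
        for label in rec1.markers:
            np.testing.assert_array_equal(rec1.markers[label], rec2.markers[label])

    def test_different_seed_different_noise(self):
        cfg1 = SimConfig(marker_noise_sd=0.1, seed=1)
        cfg2 = SimConfig(marker_noise_sd=0.1, seed=2)
        rec1, _ = synth_reach_trial(cfg1, target_index=5)
        rec2, _ = synth_reach_trial(cfg2, target_index=5)
        assert not np.array_equal(rec1.endpoint, rec2.endpoint)

    def test_noiseless_apex_reaches_target_exactly(self):
        cfg = SimConfig(marker_noise_sd=0.0)
        geo = default_geometry(
            cfg.default_panel_distance(), cfg.forearm_length, cfg.shoulder_height
        )
        for target in (1, 6, 12):
            rec, _ = synth_reach_trial(cfg, geometry=geo, target_index=target)
            dmin = np.linalg.norm(
                rec.endpoint - geo.target(target)[None, :], axis=1
            ).min()
            assert dmin < 1e-9

    def test_straight_noiseless_reach_ground_truth(self):
        cfg = SimConfig(
            path_curvature_gain=0.0, trunk_translation=0.0,
            trunk_rotation=0.0, marker_noise_sd=0.0,
        )
        _, truth = synth_reach_trial(cfg, target_index=3)
        assert truth.true_path_length == pytest.approx(
            truth.true_straight_distance, rel=1e-9
        )
        assert truth.true_curvature_index == pytest.approx(1.0, abs=1e-9)
        assert truth.true_trunk_excursion == 0.0

    def test_curved_path_length_matches_numeric_quadrature(self):
        cfg = SimConfig(path_curvature_gain=0.2, marker_noise_sd=0.0)
        rec, truth = synth_reach_trial(cfg, target_index=12)
        # independent oracle: chord-sum arc length of the outbound half on
        # the noiseless sampled endpoint path
        apex = int(
            np.argmax(np.linalg.norm(rec.endpoint - rec.endpoint[0], axis=1))
        )
        arc = np.sum(
            np.linalg.norm(np.diff(rec.endpoint[: apex + 1], axis=0), axis=1)
        )
        assert truth.true_path_length == pytest.approx(arc, rel=5e-4)
        assert truth.true_path_length >= truth.true_straight_distance

    def test_injected_trunk_translation_recovered_by_construction(self):
        cfg = SimConfig(
            trunk_translation=5.0, trunk_rotation=0.0, marker_noise_sd=0.0
        )
        rec, truth = synth_reach_trial(cfg, target_index=6)
        clav = rec.markers["CLAV"]
        disp = np.linalg.norm(clav - clav[0], axis=1).max()
        assert disp == pytest.approx(5.0, abs=1e-9)
        assert truth.true_trunk_excursion == pytest.approx(5.0, abs=1e-9)

    def test_marker_noise_sd_matches_empirical_sd_on_static_frames(self):
        # ~10,000 static frames from the lead-in/lead-out holds
        cfg = SimConfig(marker_noise_sd=0.05, pad_s=42.0, seed=9)
        rec, _ = synth_reach_trial(cfg, target_index=1)
        static = rec.endpoint[: int(41.0 * cfg.sample_rate)]
        sd = (static - static.mean(axis=0)).std(ddof=1)
        assert sd == pytest.approx(0.05, rel=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_reach_trial(SimConfig(), target_index=0)

    def test_unreachable_panel_rejected(self):
        cfg = SimConfig(panel_distance=80.0)  # beyond the 65 cm arm
        with pytest.raises(InfeasibleConfigurationError):
            synth_reach_trial(cfg, target_index=12)

    def test_left_arm_trial_mirrors_to_identical_parameters(self):
        cfg = SimConfig(
            n_submovements=2, path_curvature_gain=0.1,
            trunk_translation=4.0, trunk_rotation=5.0,
            marker_noise_sd=0.0, seed=4,
        )
        rec_r, _ = synth_reach_trial(cfg, target_index=4, side="right")
        rec_l, _ = synth_reach_trial(cfg, target_index=4, side="left")
        prof_r, _ = extract_profile(rec_r)
        prof_l, _ = extract_profile(rec_l)
        for name in ("MT", "CurvI", "Vmax", "TpctVmax", "LDJ",
                     "ShFE", "ShAA", "ElFE", "Th", "TExc"):
            assert getattr(prof_l, name) == pytest.approx(
                getattr(prof_r, name), rel=1e-9, abs=1e-9
            )
        assert prof_l.NVP == prof_r.NVP

    def test_mirroring_swaps_side_labels(self):
        cfg = SimConfig(marker_noise_sd=0.0)
        rec, _ = synth_reach_trial(cfg, target_index=3)
        mirrored = mirror_markers(rec.markers)
        np.testing.assert_allclose(
            mirrored["LFIN2"][:, 1:], rec.markers["RFIN2"][:, 1:]
        )
        np.testing.assert_allclose(
            mirrored["LFIN2"][:, 0], -rec.markers["RFIN2"][:, 0]
        )
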