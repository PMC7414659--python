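"""Joint-range and trunk parameters from markers."""

import numpy as np
import pytest

from reachkin import joints
from reachkin.errors import InsufficientMarkersError, InvalidGeometryError
from reachkin.extract import extract_profile
from reachkin.simulate import (
    SimConfig,
    _rest_skeleton,
    synth_joint_trial,
    synth_reach_trial,
)
from reachkin.validation import reach_roundtrip_battery, texc_recovery_battery


def _row(*xyz):
    return np.array([xyz], dtype=float)


class TestElbowFlexion:
    def test_collinear_chain_is_full_extension(self):
        ang = joints.elbow_flexion_angle(
            _row(0, 0, 0), _row(0, 30, 0), _row(0, 55, 0)
        )
        assert ang[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_segments(self):
        ang = joints.elbow_flexion_angle(
            _row(0, 0, 0), _row(0, 30, 0), _row(0, 30, -25)
        )
        assert ang[0] == pytest.approx(90.0, abs=1e-9)

    def test_prescribed_elbow_excursion_recovered(self):
        rec = synth_joint_trial(elfe_excursion=40.0)
        prof, _ = extract_profile(rec)
        assert prof.ElFE == pytest.approx(40.0, abs=0.5)


class TestShoulderAngles:
    def test_arm_hanging_along_thorax_vertical_is_zero(self):
        hum = _row(0, 0, -30.0)
        xt, yt, zt = _row(1, 0, 0), _row(0, 1, 0), _row(0, 0, 1)
        fe, aa = joints.shoulder_angles(hum, xt, yt, zt)
        assert fe[0] == pytest.approx(0.0, abs=1e-9)
        assert aa[0] == pytest.approx(0.0, abs=1e-9)

    def test_prescribed_flexion_excursion_recovered_with_flat_abduction(self):
        rec = synth_joint_trial(shfe_excursion=30.0)
        prof, _ = extract_profile(rec)
        assert prof.ShFE == pytest.approx(30.0, abs=0.5)
        assert prof.ShAA < 1.0

    def test_prescribed_abduction_excursion_recovered(self):
        rec = synth_joint_trial(shaa_excursion=25.0)
        prof, _ = extract_profile(rec)
        assert prof.ShAA == pytest.approx(25.0, abs=0.5)
        assert prof.ShFE < 1.0

    def test_trunk_rotation_with_arm_fixed_to_thorax_gives_flat_angles(self):
        """Angles are thorax-relative: rotating the whole body (arm rigid
        with trunk) must not register shoulder motion."""
        rest = _rest_skeleton(SimConfig())
        n = 240
        theta = np.deg2rad(15.0) * np.linspace(0, 1, n)
        m0 = 0.5 * (rest["RSHO"] + rest["LSHO"])

        # a rigid "body": trunk markers plus a static arm posture
        arm = {
            "RELB": rest["RSHO"] + np.array([2.0, 10.0, -25.0]),
        }
        arm["RWRA"] = arm["RELB"] + np.array([1.0, 21.0, -5.0])
        arm["RWRB"] = arm["RELB"] + np.array([-1.0, 21.0, -5.0])
        markers = {}
        for label, p0 in {**rest, **arm}.items():
            rel = p0 - m0
            x = np.cos(theta) * rel[0] - np.sin(theta) * rel[1]
            y = np.sin(theta) * rel[0] + np.cos(theta) * rel[1]
            markers[label] = m0[None, :] + np.column_stack(
                [x, y, np.full(n, rel[2])]
            )

        xt, yt, zt = joints.thorax_frame(
            markers["C7"], markers["T10"], markers["CLAV"], markers["STRN"],
            markers["RSHO"], markers["LSHO"],
        )
        fe, aa = joints.shoulder_angles(
            markers["RELB"] - markers["RSHO"], xt, yt, zt
        )
        assert joints.angle_range(fe) < 1e-6
        assert joints.angle_range(aa) < 1e-6
        # while the thorax rotation itself is fully registered
        th = joints.thorax_rotation(markers["RSHO"], markers["LSHO"], zt[0])
        assert joints.angle_range(th) == pytest.approx(15.0, abs=1e-9)


class TestThoraxRotation:
    def test_static_trunk_is_zero(self):
        rsho = np.tile([10.0, 0, 100], (50, 1))
        lsho = np.tile([-26.0, 0, 100], (50, 1))
        th = joints.thorax_rotation(rsho, lsho)
        assert joints.angle_range(th) == 0.0

    def test_rigid_translation_does_not_rotate_the_line(self):
        shift = np.linspace(0, 8, 60)[:, None] * np.array([0.3, 0.9, 0.1])
        rsho = np.array([10.0, 0, 100]) + shift
        lsho = np.array([-26.0, 0, 100]) + shift
        th = joints.thorax_rotation(rsho, lsho)
        assert np.abs(th).max() < 1e-9

    def test_injected_axial_rotation_recovered(self):
        cfg = SimConfig(trunk_rotation=10.0, trunk_translation=0.0,
                        marker_noise_sd=0.0)
        rec, _ = synth_reach_trial(cfg, target_index=6)
        prof, _ = extract_profile(rec)
        assert prof.Th == pytest.approx(10.0, abs=0.2)

    def test_coincident_acromions_rejected(self):
        p = np.tile([0.0, 0, 100], (10, 1))
        with pytest.raises(InvalidGeometryError):
            joints.thorax_rotation(p, p)


class TestTorsoExcursion:
    def test_static_trunk_is_zero(self):
        clav = np.tile([0.0, 2.0, 99.0], (40, 1))
        assert joints.torso_excursion(clav) == 0.0

    def test_forward_lean_recovered_noiseless(self):
        cfg = SimConfig(trunk_translation=5.0, marker_noise_sd=0.0)
        rec, _ = synth_reach_trial(cfg, target_index=6)
        prof, _ = extract_profile(rec)
        assert prof.TExc == pytest.approx(5.0, abs=0.1)

    def test_recovery_under_marker_noise(self):
        max_err, table = texc_recovery_battery(n_trials=60, noise_sd=0.05, seed=3)
        assert max_err <= 0.2
        assert table["abs_err"].mean() < 0.1


class TestMissingMarkers:
    def test_small_gaps_interpolated(self):
        pos = np.linspace(0, 10, 100)[:, None] * np.array([1.0, 0.5, 0.2])
        gappy = pos.copy()
        gappy[40:44] = np.nan
        filled = joints._fill_gaps(gappy, "CLAV")
        np.testing.assert_allclose(filled, pos, atol=1e-9)

    def test_too_many_gaps_rejected(self):
        pos = np.ones((100, 3))
        pos[:20] = np.nan
        with pytest.raises(InsufficientMarkersError):
            joints._fill_gaps(pos, "CLAV")


class TestRoundTrip:
    def test_reach_trial_round_trip_battery(self):
        """Simulator inverse kinematics -> marker-based recovery across all
        12 targets, noiseless: 0.5 deg / 0.1 cm, except ShAA on reaches
        where its frontal-plane projection is ill-conditioned (small
        in-plane component), where only a looser bound is meaningful."""
        table = reach_roundtrip_battery(n_trials=24, seed=0)
        assert table["err_ShFE"].max() <= 0.5
        assert table["err_ElFE"].max() <= 0.5
        assert table["err_Th"].max() <= 0.1
        assert table["err_TExc"].max() <= 0.1
        good = table[table["conditioning"] >= 0.2]
        assert len(good) >= 18
        assert good["err_ShAA"].max() <= 0.5
        assert table["err_ShAA"].max() <= 1.5
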