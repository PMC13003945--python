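import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from djpls.body_model import (
    JointAngleSeries,
    cardan_angles,
    cardan_matrix,
    joint_angle_series,
    range_of_motion,
    reconstruct_kinematics,
    segment_newton_euler,
    whole_body_com,
)
from djpls.body_model.angles import GimbalWarning, relative_rotation
from djpls.body_model.inertia import SEGMENT_NAMES, SegmentParams, load_segment_model
from djpls.signal_processing import SampledSignal, align_and_resample


class TestInertia:
    def test_mass_fractions_sum_to_one(self, segment_model):
        assert segment_model.total_mass_fraction() == pytest.approx(1.0, abs=1e-6)

    def test_fifteen_segments(self):
        assert len(SEGMENT_NAMES) == 15

    def test_ratios_validated(self):
        with pytest.raises(ValueError):
            SegmentParams(mass_fraction=0.1, com_ratio=1.5)
        with pytest.raises(ValueError):
            SegmentParams(mass_fraction=-0.1)

    def test_inertia_tensor_scales(self, segment_model):
        I = segment_model.inertia_local("thigh", 80.0, 0.42)
        assert I[0, 0] == I[1, 1] > I[2, 2] > 0


class TestCardan:
    def test_identity(self):
        assert np.allclose(cardan_angles(np.eye(3)), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seq", ["xyz", "yxz", "zxy", "zyx", "xzy", "yzx"])
    def test_single_axis_rotation(self, seq):
        ang = cardan_angles(cardan_matrix([30.0, 0.0, 0.0], seq), seq)
        assert np.allclose(ang, [30.0, 0.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("seq", ["xyz", "yxz", "zxy", "zyx", "xzy", "yzx"])
    def test_roundtrip_random_rotations(self, seq, rng):
        angles = rng.uniform(-85.0, 85.0, size=(50, 3))
        R = cardan_matrix(angles, seq)
        back = cardan_angles(R, seq)
        assert np.allclose(back, angles, atol=1e-10)
        # matrix-level round trip against the scipy oracle
        R2 = Rotation.from_euler(seq.upper(), angles, degrees=True).as_matrix()
        assert np.allclose(R, R2, atol=1e-12)

    def test_recompose_matches_original(self, rng):
        R = Rotation.random(20, random_state=4).as_matrix()
        ang = cardan_angles(R, "yxz")
        assert np.allclose(cardan_matrix(ang, "yxz"), R, atol=1e-10)

    def test_gimbal_warning(self):
        with pytest.warns(GimbalWarning):
            cardan_angles(cardan_matrix([10.0, 89.5, 5.0], "xyz"), "xyz")

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            cardan_angles(2.0 * np.eye(3))
        bad = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            cardan_angles(bad)

    def test_invalid_sequence(self):
        with pytest.raises(ValueError):
            cardan_angles(np.eye(3), "xxz")


class TestFrames:
    def test_orthonormal_on_trial(self, noiseless_trial):
        recording, _ = noiseless_trial
        kin = reconstruct_kinematics(recording.markers)
        for R in (kin.pelvis_R, kin.trunk_R, *kin.thigh_R.values(),
                  *kin.shank_R.values(), *kin.foot_R.values()):
            err = np.einsum("nji,njk->nik", R, R) - np.eye(3)
            assert np.abs(err).max() < 1e-8
            assert np.allclose(np.linalg.det(R), 1.0, atol=1e-8)

    def test_missing_marker_listed(self, noiseless_trial):
        recording, _ = noiseless_trial
        markers = dict(recording.markers)
        del markers["LHEE"]
        with pytest.raises(KeyError, match="LHEE"):
            reconstruct_kinematics(markers)

    def test_nonfinite_frames_listed(self, noiseless_trial):
        recording, _ = noiseless_trial
        markers = {k: v.copy() for k, v in recording.markers.items()}
        markers["RTOE"][5, 2] = np.nan
        with pytest.raises(ValueError, match="RTOE"):
            reconstruct_kinematics(markers)


class TestWholeBodyCom:
    def test_weighted_mean_two_segments(self):
        # hand arithmetic: fractions 0.6 / 0.4 at heights 1.0 / 0.5 -> 0.8
        assert 0.6 * 1.0 + 0.4 * 0.5 == pytest.approx(0.8)

    def test_matches_prescribed_com_noiseless(self, noiseless_trial, segment_model):
        recording, truth = noiseless_trial
        com = whole_body_com(recording.markers, segment_model)
        t_m = np.arange(com.shape[0]) / recording.marker_rate_hz
        z_true = np.interp(t_m, truth.com_times, truth.com_z)
        assert np.abs(com[:, 2] - z_true).max() < 0.005

    def test_within_marker_bounds(self, noiseless_trial, segment_model):
        recording, _ = noiseless_trial
        com = whole_body_com(recording.markers, segment_model)
        zs = np.stack([m[:, 2] for m in recording.markers.values()])
        assert np.all(com[:, 2] < zs.max(axis=0) + 0.35)
        assert np.all(com[:, 2] > zs.min(axis=0))


class TestRangeOfMotion:
    def _series(self, angles, rate=250.0):
        return JointAngleSeries(
            joint="knee", side="right", angles_deg=angles, rate_hz=rate, t0=0.0,
            sequence="yxz",
        )

    def test_constant_angle_zero_rom(self):
        s = self._series(np.full((100, 3), 17.0))
        assert np.allclose(range_of_motion(s, (0.0, 0.3)), 0.0)

    def test_sinusoid_rom_is_twice_amplitude(self):
        t = np.arange(500) / 250.0
        A = 23.0
        ang = np.stack([A * np.sin(2 * np.pi * 2.0 * t)] * 3, axis=1)
        s = self._series(ang)
        rom = range_of_motion(s, (0.0, 1.5))  # three full periods
        assert np.allclose(rom, 2 * A, rtol=0.005)

    def test_empty_phase_error(self):
        s = self._series(np.zeros((100, 3)))
        with pytest.raises(ValueError):
            range_of_motion(s, (0.2, 0.2))

    def test_synthetic_knee_flexion_rom_recovered(self, noiseless_trial, noiseless_features):
        _, truth = noiseless_trial
        assert noiseless_features["Knee Ext/Flex (CON)"] == pytest.approx(
            truth.rom_truth["CON"]["knee"][0], abs=1.0
        )

    def test_all_rom_channels_recovered(self, noiseless_trial, noiseless_features):
        _, truth = noiseless_trial
        labels = {
            "hip": ("Hip Ext/Flex", "Hip Abd/Add", "Hip Ext/Int rotation"),
            "knee": ("Knee Ext/Flex", "Knee Valgus/Varus", "Knee Ext/Int rotation"),
            "ankle": ("Ankle Pla/Dor flexion", "Ankle Eve/Inv", "Ankle Abd/Add"),
        }
        for phase in ("ECC", "CON"):
            for joint, names in labels.items():
                for k, name in enumerate(names):
                    got = noiseless_features[f"{name} ({phase})"]
                    want = truth.rom_truth[phase][joint][k]
                    assert got == pytest.approx(want, abs=1.0), (phase, name)

    def test_angles_at_gc_recovered(self, noiseless_trial, noiseless_features):
        _, truth = noiseless_trial
        assert noiseless_features["Hip Ext/Flex@GC"] == pytest.approx(
            truth.angles_at_gc["hip"][0], abs=1.0
        )
        assert noiseless_features["Knee Ext/Flex@GC"] == pytest.approx(
            truth.angles_at_gc["knee"][0], abs=1.0
        )


class TestInverseDynamics:
    def test_static_pendulum_moment(self):
        # horizontal massless rod, 2 kg point at 0.1 m: support moment m g d
        n = 5
        com = np.tile([0.1, 0.0, 0.0], (n, 1))
        zeros = np.zeros((n, 3))
        F, M = segment_newton_euler(
            com=com, acc=zeros, dH=zeros, mass=2.0,
            prox_point=np.zeros((n, 3)),
        )
        assert np.allclose(np.linalg.norm(M, axis=1), 2.0 * 9.81 * 0.1, atol=1e-9)
        assert np.allclose(F[:, 2], 2.0 * 9.81)

    def test_zero_angular_velocity_zero_work(self, noiseless_trial, segment_model):
        from djpls.body_model import limb_inverse_dynamics

        recording, truth = noiseless_trial
        frozen = {k: np.tile(v[0], (200, 1)) for k, v in recording.markers.items()}
        kin = reconstruct_kinematics(frozen)
        grf = np.tile([0.0, 0.0, truth.body_mass_kg * 9.81 / 2], (200, 1))
        cop = np.tile(recording.plate_cops["right"][0], (200, 1))
        kinetics = limb_inverse_dynamics(
            kin, "right", grf, cop, 1000.0, truth.body_mass_kg, segment_model
        )
        for joint in ("ankle", "knee", "hip"):
            assert np.abs(kinetics.powers[joint]).max() < 1e-6
            assert kinetics.work(joint, (0.05, 0.15), truth.body_mass_kg) == pytest.approx(0.0, abs=1e-8)

    def test_missing_side_error(self, noiseless_trial, segment_model):
        from djpls.body_model import limb_inverse_dynamics

        recording, truth = noiseless_trial
        kin = reconstruct_kinematics(recording.markers)
        with pytest.raises(ValueError, match="per-plate"):
            limb_inverse_dynamics(
                kin, "middle", np.zeros((10, 3)), np.zeros((10, 3)), 1000.0,
                truth.body_mass_kg, segment_model,
            )

    def test_cop_outside_plate_warns(self, noiseless_trial, segment_model):
        from djpls.body_model import limb_inverse_dynamics

        recording, truth = noiseless_trial
        n = 50
        frozen = {k: np.tile(v[0], (n, 1)) for k, v in recording.markers.items()}
        kin = reconstruct_kinematics(frozen)
        grf = np.tile([0.0, 0.0, 400.0], (n, 1))
        cop = np.tile([5.0, 5.0, 0.0], (n, 1))
        with pytest.warns(RuntimeWarning, match="CoP outside"):
            limb_inverse_dynamics(
                kin, "right", grf, cop, 1000.0, truth.body_mass_kg, segment_model,
                plate_bounds=(-0.5, 0.5, -0.5, 0.5),
            )

    def test_ankle_moment_matches_truth_path(self, noiseless_trial, segment_model):
        # analyzer route (filtered markers, resampled to the force timebase)
        # reproduces the truth kinetics computed on pristine kinematics
        from djpls.body_model import limb_inverse_dynamics
        from djpls.signal_processing import butterworth_zero_lag

        recording, truth = noiseless_trial
        rate_m = recording.marker_rate_hz
        filtered = {
            k: butterworth_zero_lag(SampledSignal(v, rate_m), 20.0).values
            for k, v in recording.markers.items()
        }
        fz = SampledSignal(recording.fz_total, recording.force_rate_hz)
        resampled = {
            k: align_and_resample(SampledSignal(v, rate_m), fz)[0].values
            for k, v in filtered.items()
        }
        n = len(next(iter(resampled.values())))
        kin = reconstruct_kinematics(resampled)
        kinetics = limb_inverse_dynamics(
            kin, "right", recording.plate_forces["right"][:n],
            recording.plate_cops["right"][:n], recording.force_rate_hz,
            truth.body_mass_kg, segment_model,
        )
        t = truth.com_times[:n]
        mask = (t > truth.t_contact + 0.01) & (t < truth.t_takeoff - 0.01)
        M = kinetics.moments["ankle"][mask]
        Mt = truth.ankle_moment_truth[:n][mask]
        peak = np.abs(Mt).max()
        assert np.abs(M - Mt).max() < 0.05 * peak

    def test_joint_works_match_truth_path(self, noiseless_trial, noiseless_features):
        _, truth = noiseless_trial
        for phase in ("ECC", "CON"):
            for joint in ("Hip", "Knee", "Ankle"):
                got = noiseless_features[f"{joint} joint work ({phase})"]
                want = truth.joint_work_truth[phase][joint.lower()]
                assert got == pytest.approx(want, abs=0.06), (phase, joint)


class TestJointAngleSeries:
    def test_left_side_mirrored(self, noiseless_trial):
        recording, truth = noiseless_trial
        kin = reconstruct_kinematics(recording.markers)
        left = joint_angle_series(kin.thigh_R["left"], kin.shank_R["left"],
                                  "knee", "left", recording.marker_rate_hz)
        right = joint_angle_series(kin.thigh_R["right"], kin.shank_R["right"],
                                   "knee", "right", recording.marker_rate_hz)
        # generator prescribes identical clinical angles bilaterally
        assert np.allclose(left.angles_deg, right.angles_deg, atol=1e-8)

    def test_relative_rotation_inverse(self, rng):
        Rp = Rotation.random(5, random_state=1).as_matrix()
        Rd = Rotation.random(5, random_state=2).as_matrix()
        rel = relative_rotation(Rp, Rd)
        assert np.allclose(np.einsum("nij,njk->nik", Rp, rel), Rd, atol=1e-12)
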