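import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rimdyn.io_core import (MARKER_LABELS, HandrimKineticSeries,
                            MarkerFrameSeries, WheelchairGeometry)
from rimdyn.upperlimb_model import (ARM_CLUSTER, SegmentFrames, SegmentInertia,
                                    build_frames, calibrate_cluster,
                                    derive_motion, estimate_axle,
                                    inverse_dynamics, joint_angles,
                                    reconstruct_markers)

GRAV = np.array([0.0, 0.0, -9.81])


def _cluster_series(frames_xyz, labels=("rm1", "rm2", "rm3", "epc", "ipc")):
    return MarkerFrameSeries(labels, np.asarray(frames_xyz, dtype=float), 50.0)


_BASE = np.array([
    [0.0, 0.0, 0.0],   # rm1
    [0.1, 0.0, 0.0],   # rm2
    [0.0, 0.1, 0.02],  # rm3
    [0.05, 0.05, -0.1],  # epc
    [0.02, -0.03, -0.1],  # ipc
])


class TestClusters:
    def test_translation_invariant_template(self):
        shifted = _BASE + np.array([1.0, 0.0, 0.0])
        t1 = calibrate_cluster(_cluster_series([_BASE]))
        t2 = calibrate_cluster(_cluster_series([shifted]))
        assert np.abs(t1.dependent_local - t2.dependent_local).max() < 1e-12

    def test_identity_reconstruction(self):
        static = _cluster_series([_BASE])
        tpl = calibrate_cluster(static)
        out = reconstruct_markers(tpl, static)
        assert np.abs(out.positions - static.positions).max() < 1e-12

    def test_pure_rotation(self):
        tpl = calibrate_cluster(_cluster_series([_BASE]))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rotated = _BASE @ R.T
        out = reconstruct_markers(tpl, _cluster_series([rotated]))
        assert np.abs(out.positions[0, 3:] - rotated[3:]).max() < 1e-12

    def test_random_rigid_transform(self, rng):
        tpl = calibrate_cluster(_cluster_series([_BASE]))
        for _ in range(20):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3)
            moved = _BASE @ R.T + t
            out = reconstruct_markers(tpl, _cluster_series([moved]))
            assert np.abs(out.positions[0, 3:] - moved[3:]).max() < 1e-9

    def test_noise_robustness(self, rng):
        tpl = calibrate_cluster(_cluster_series([_BASE]))
        n = 1000
        errs = np.empty((n, 2, 3))
        for i in range(n):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3)
            truth = _BASE @ R.T + t
            noisy = truth.copy()
            noisy[:3] += rng.normal(0, 1e-3, (3, 3))  # 1 mm on references
            out = reconstruct_markers(tpl, _cluster_series([noisy]))
            errs[i] = out.positions[0, 3:] - truth[3:]
        rms = np.sqrt(np.mean(errs**2))
        assert rms < 2e-3

    def test_gap_flag_when_references_missing(self):
        tpl = calibrate_cluster(_cluster_series([_BASE]))
        pos = _BASE[None].copy()
        pos[0, 0] = np.nan
        gaps = np.zeros((1, 5), dtype=bool)
        gaps[0, 0] = True
        dyn = MarkerFrameSeries(("rm1", "rm2", "rm3", "epc", "ipc"),
                                pos, 50.0, gaps)
        out = reconstruct_markers(tpl, dyn)
        assert out.gaps[0, 3:].all()

    def test_collinear_references_rejected(self):
        bad = _BASE.copy()
        bad[2] = [0.2, 0.0, 0.0]  # rm3 on the rm1-rm2 line
        with pytest.raises(ValueError, match="collinear"):
            calibrate_cluster(_cluster_series([bad]))


def _anatomical_markers(n=4):
    """Marker set in an idealized anatomical pose: every segment frame
    should come out as the identity rotation."""
    S = np.array([0.0, -0.2, 1.4])
    E = S + [0.0, 0.0, -0.30]
    W = E + [0.0, 0.0, -0.26]
    m3 = W + [0.0, 0.0, -0.07]
    pos = {
        "c7": S + [-0.08, 0.20, 0.04], "acrr": S + [0.0, 0.03, 0.04],
        "acrl": S + [0.0, 0.43, 0.04],
        "hha": S + [0.035, 0, 0], "hhp": S + [-0.035, 0, 0],
        "rm1": S + [0.03, -0.02, -0.10], "rm2": S + [0.05, -0.02, -0.14],
        "rm3": S + [0.02, 0.02, -0.18],
        "epc": E + [0.0, -0.035, 0.0], "ipc": E + [0.0, 0.035, 0.0],
        "ulr": W + [0.0, 0.03, 0.0], "rdl": W + [0.0, -0.03, 0.0],
        "2m": m3 + [0.01, -0.02, 0.01], "3m": m3, "5m": m3 + [0.0, 0.02, 0.02],
    }
    arr = np.stack([np.tile(pos[lab], (n, 1)) for lab in MARKER_LABELS], axis=1)
    return MarkerFrameSeries(MARKER_LABELS, arr, 240.0)


class TestFrames:
    def test_anatomical_pose_aligns_all_segments(self):
        # in the anatomical pose every segment frame equals the fixed
        # lab-to-anatomical axis permutation (anterior, up, right), so all
        # relative (joint) rotations are the identity
        fr = build_frames(_anatomical_markers())
        P = np.array([[1.0, 0.0, 0.0],
                      [0.0, 0.0, -1.0],
                      [0.0, 1.0, 0.0]])
        for seg, R in fr.rotations.items():
            assert np.abs(R[0] - P).max() < 1e-9, seg
        kin = joint_angles(fr)
        for name, v in kin.named.items():
            assert np.abs(v).max() < 1e-9, name

    def test_orthonormal_on_simulator(self, clean_trial_240):
        fr = build_frames(clean_trial_240.markers)
        fr.check_orthonormal(1e-9)

    def test_equivariance_under_lab_rotation(self, clean_trial_240):
        mk = clean_trial_240.markers
        R = Rotation.from_euler("xyz", [10, -35, 70], degrees=True).as_matrix()
        rot = MarkerFrameSeries(mk.labels,
                                mk.positions @ R.T, mk.rate)
        f1 = build_frames(mk)
        f2 = build_frames(rot)
        for seg in f1.rotations:
            err = np.abs(f2.rotations[seg] - R @ f1.rotations[seg]).max()
            assert err < 1e-9, seg
        # joint angles are relative: unchanged by a lab rotation
        a1, a2 = joint_angles(f1).named, joint_angles(f2).named
        for k in a1:
            assert np.abs(((a1[k] - a2[k] + 180) % 360) - 180).max() < 1e-6, k

    def test_degenerate_markers_named(self):
        mk = _anatomical_markers()
        i_ulr, i_rdl = mk.index("ulr"), mk.index("rdl")
        mk.positions[:, i_rdl] = mk.positions[:, i_ulr]  # collapse styloids
        with pytest.raises(ValueError, match="forearm|hand"):
            build_frames(mk)


def _frames_from_rotations(R_arm, R_fa, R_hand, n=1):
    eye = np.tile(np.eye(3), (n, 1, 1))
    z = np.zeros((n, 3))
    tile = lambda R: np.tile(R, (n, 1, 1)) if R.ndim == 2 else R
    return SegmentFrames(
        origins={"trunk": z, "arm": z, "forearm": z, "hand": z},
        rotations={"trunk": eye, "arm": tile(R_arm), "forearm": tile(R_fa),
                   "hand": tile(R_hand)},
        rate=240.0,
    )


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestJointAngles:
    def test_identity_gives_zero(self):
        eye = np.eye(3)
        kin = joint_angles(_frames_from_rotations(eye, eye, eye, n=4))
        for name, v in kin.named.items():
            assert np.abs(v).max() < 1e-9, name

    def test_constructed_elbow_flexion(self):
        R = _rz(np.deg2rad(90.0))
        kin = joint_angles(_frames_from_rotations(np.eye(3), R, R, n=4))
        assert np.abs(kin.named["gamma_e"] - 90.0).max() < 1e-6

    def test_compose_decompose_round_trip(self, rng):
        # independent composition with hand-written rotation matrices
        for _ in range(300):
            a, c = rng.uniform(-170, 170, 2)
            b = rng.uniform(5, 175)  # YXY middle angle away from 0/180
            R_sh = _ry(np.deg2rad(a)) @ _rx(np.deg2rad(b)) @ _ry(np.deg2rad(c))
            az, cz = rng.uniform(-170, 170, 2)
            bz = rng.uniform(-85, 85)  # ZXY middle away from +/-90
            R_zxy = _rz(np.deg2rad(az)) @ _rx(np.deg2rad(bz)) @ _ry(np.deg2rad(cz))
            kin = joint_angles(_frames_from_rotations(R_sh, R_sh @ R_zxy,
                                                      R_sh @ R_zxy, n=1))
            sh = kin.angles["shoulder"][0]
            err = np.abs(((sh - [a, b, c] + 180) % 360) - 180)
            assert err.max() < 1e-9
            el = kin.angles["elbow"][0]
            err = np.abs(((el - [az, bz, cz] + 180) % 360) - 180)
            assert err.max() < 1e-9

    def test_matches_simulator_truth(self, clean_trial_240):
        tr = clean_trial_240
        kin = joint_angles(build_frames(tr.markers))
        for name, v in kin.named.items():
            err = np.abs(((v - tr.truth.joint_angles[name] + 180) % 360) - 180)
            assert err.max() < 1e-6, name


class TestDeriveMotion:
    def test_stationary_segment(self, inertia):
        fr = _frames_from_rotations(np.eye(3), np.eye(3), np.eye(3), n=10)
        mo = derive_motion(fr, inertia, 240.0)
        for seg in ("arm", "forearm", "hand"):
            assert np.abs(mo.acc[seg]).max() < 1e-9
            assert np.abs(mo.omega[seg]).max() < 1e-9

    def test_centripetal_acceleration(self, inertia):
        rate, rc, om = 240.0, 0.3, 2 * np.pi * 1.0
        t = np.arange(int(rate)) / rate
        org = np.stack([rc * np.cos(om * t), rc * np.sin(om * t),
                        np.zeros_like(t)], axis=1)
        eye = np.tile(np.eye(3), (len(t), 1, 1))
        fr = SegmentFrames({s: org.copy() for s in
                            ("trunk", "arm", "forearm", "hand")},
                           {s: eye.copy() for s in
                            ("trunk", "arm", "forearm", "hand")}, rate)
        mo = derive_motion(fr, inertia, rate)
        # COM offset is along -y of the identity frame: same circular radius
        mag = np.linalg.norm(mo.acc["arm"][5:-5], axis=1)
        assert np.abs(mag - om**2 * rc).max() / (om**2 * rc) < 0.01

    def test_constant_spin(self, inertia):
        rate, om = 240.0, 3.0
        t = np.arange(int(rate)) / rate
        R = Rotation.from_euler("z", (om * t)[:, None]).as_matrix()
        z = np.zeros((len(t), 3))
        fr = SegmentFrames({s: z.copy() for s in
                            ("trunk", "arm", "forearm", "hand")},
                           {s: R.copy() for s in
                            ("trunk", "arm", "forearm", "hand")}, rate)
        mo = derive_motion(fr, inertia, rate)
        w = mo.omega["hand"][5:-5]
        assert np.abs(w - [0, 0, om]).max() < 1e-3

    def test_too_short(self, inertia):
        fr = _frames_from_rotations(np.eye(3), np.eye(3), np.eye(3), n=3)
        with pytest.raises(ValueError, match="5 samples"):
            derive_motion(fr, inertia, 240.0)


def _static_setup(rng, inertia, n=8, force_sw=None, theta=0.0):
    """Random static pose: constant random frames and origins, zero motion."""
    Rs = {s: np.tile(Rotation.random(random_state=rng).as_matrix(), (n, 1, 1))
          for s in ("trunk", "arm", "forearm", "hand")}
    Os = {s: np.tile(rng.normal(size=3), (n, 1))
          for s in ("trunk", "arm", "forearm", "hand")}
    fr = SegmentFrames(Os, Rs, 240.0)
    F = np.zeros((n, 3)) if force_sw is None else np.tile(force_sw, (n, 1))
    rim = HandrimKineticSeries(F, np.zeros((n, 3)), np.full(n, theta), 240.0)
    geo = WheelchairGeometry(axle_position=np.array([0.0, -0.28, 0.0]))
    grip = np.tile(geo.axle_position + [0.0, 0.0, geo.rim_radius], (n, 1))
    return fr, rim, geo, grip


def _statics_oracle(fr, inertia, F_ext, P_ext):
    """Hand-written static equilibrium, fully independent of the module."""
    coms = {}
    for seg in ("hand", "forearm", "arm"):
        off = np.array([0.0, -inertia.com_fraction[seg] * inertia.length[seg], 0.0])
        coms[seg] = fr.origins[seg][0] + fr.rotations[seg][0] @ off
    expected = {}
    chain = [("wrist", ("hand",)), ("elbow", ("hand", "forearm")),
             ("shoulder", ("hand", "forearm", "arm"))]
    prox = {"wrist": "hand", "elbow": "forearm", "shoulder": "arm"}
    for joint, segs in chain:
        P = fr.origins[prox[joint]][0]
        F = -sum(inertia.mass[s] for s in segs) * GRAV - F_ext
        M = -sum(np.cross(coms[s] - P, inertia.mass[s] * GRAV) for s in segs)
        M = M - np.cross(P_ext - P, F_ext)
        expected[joint] = (F, M)
    return expected


class TestInverseDynamics:
    def test_static_gravity_only(self, rng):
        inert = SegmentInertia(
            mass={"arm": 2.0, "forearm": 1.2, "hand": 0.5},
            length={"arm": 0.3, "forearm": 0.26, "hand": 0.18},
            com_fraction={"arm": 0.45, "forearm": 0.43, "hand": 0.5},
            inertia_local={s: np.eye(3) * 1e-3 for s in ("arm", "forearm", "hand")},
        )
        fr, rim, geo, grip = _static_setup(rng, inert)
        mo = derive_motion(fr, inert, 240.0)
        out = inverse_dynamics(fr, mo, inert, rim, geo, grip)
        # hand mass 0.5 kg -> wrist force 4.905 N, superior
        f = out.F["wrist"][4]
        assert np.linalg.norm(f) == pytest.approx(0.5 * 9.81, abs=1e-9)
        assert f[2] > 0

    def test_static_superposition_with_external_load(self, rng):
        inert = SegmentInertia(
            mass={"arm": 2.0, "forearm": 1.2, "hand": 0.5},
            length={"arm": 0.3, "forearm": 0.26, "hand": 0.18},
            com_fraction={"arm": 0.45, "forearm": 0.43, "hand": 0.5},
            inertia_local={s: np.eye(3) * 1e-3 for s in ("arm", "forearm", "hand")},
        )
        # 10 N inferior on the hand: grip at the rim top (zeta = 0) with
        # theta = pi/2 means a radial-inward sensor force of 10 N
        fr, rim, geo, grip = _static_setup(
            rng, inert, force_sw=np.array([0.0, 10.0, 0.0]), theta=np.pi / 2)
        mo = derive_motion(fr, inert, 240.0)
        out = inverse_dynamics(fr, mo, inert, rim, geo, grip)
        f = out.F["wrist"][4]
        assert np.linalg.norm(f) == pytest.approx(0.5 * 9.81 + 10.0, abs=1e-9)

    def test_fifty_random_static_poses_match_statics(self, rng, inertia):
        for _ in range(50):
            fr, rim, geo, grip = _static_setup(rng, inertia)
            mo = derive_motion(fr, inertia, 240.0)
            out = inverse_dynamics(fr, mo, inertia, rim, geo, grip)
            expected = _statics_oracle(fr, inertia, np.zeros(3), grip[0])
            for joint, (F, M) in expected.items():
                scale_f = max(np.linalg.norm(F), 1.0)
                scale_m = max(np.linalg.norm(M), 1.0)
                assert np.abs(out.F[joint][4] - F).max() / scale_f < 1e-6
                assert np.abs(out.M[joint][4] - M).max() / scale_m < 1e-6

    def test_oracle_equivalence_dynamic(self, clean_trial_240, inertia):
        from rimdyn.synthetic import forward_loads
        tr = clean_trial_240
        fr = build_frames(tr.markers)
        mo = derive_motion(fr, inertia)
        out = inverse_dynamics(fr, mo, inertia, tr.rim, tr.geometry,
                               tr.markers.marker("3m"))
        oracle = forward_loads(tr, inertia)
        sl = slice(5, -5)
        for joint in ("wrist", "elbow", "shoulder"):
            fo, mo_ = oracle[joint]["F"][sl], oracle[joint]["M"][sl]
            ef = np.abs(out.F[joint][sl] - fo).max() / np.linalg.norm(fo, axis=1).max()
            em = np.abs(out.M[joint][sl] - mo_).max() / np.linalg.norm(mo_, axis=1).max()
            assert ef < 0.02, joint
            assert em < 0.05, joint

    def test_equivariance_under_vertical_lab_rotation(self, clean_trial_240,
                                                      inertia):
        # rotating the whole lab about the vertical axis (gravity invariant)
        # with no external load must rotate joint forces identically
        tr = clean_trial_240
        mk = tr.markers
        n = mk.n_samples
        zero_rim = HandrimKineticSeries(np.zeros((n, 3)), np.zeros((n, 3)),
                                        tr.rim.theta, tr.rim.rate)
        geo = tr.geometry
        fr = build_frames(mk)
        mo = derive_motion(fr, inertia)
        out = inverse_dynamics(fr, mo, inertia, zero_rim, geo,
                               mk.marker("3m"))

        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        rotated = MarkerFrameSeries(mk.labels, mk.positions @ R.T, mk.rate)
        geo2 = WheelchairGeometry(
            geo.wheel_diameter, geo.rim_radius,
            axle_position=R @ np.asarray(geo.axle_position))
        fr2 = build_frames(rotated)
        mo2 = derive_motion(fr2, inertia)
        out2 = inverse_dynamics(fr2, mo2, inertia, zero_rim, geo2,
                                mk.marker("3m") @ R.T)
        sl = slice(5, -5)
        for joint in ("wrist", "elbow", "shoulder"):
            for got, ref in ((out2.F, out.F), (out2.M, out.M)):
                expect = ref[joint][sl] @ R.T
                scale = max(np.abs(expect).max(), 1e-9)
                assert np.abs(got[joint][sl] - expect).max() / scale < 1e-6, joint
        # and joint angles are unchanged
        a1, a2 = joint_angles(fr).named, joint_angles(fr2).named
        for k in a1:
            assert np.abs(((a1[k] - a2[k] + 180) % 360) - 180).max() < 1e-6

    def test_misaligned_lengths_rejected(self, clean_trial_240, inertia):
        tr = clean_trial_240
        fr = build_frames(tr.markers)
        mo = derive_motion(fr, inertia)
        short = HandrimKineticSeries(tr.rim.F[:-10], tr.rim.M[:-10],
                                     tr.rim.theta[:-10], tr.rim.rate)
        with pytest.raises(ValueError, match="misaligned"):
            inverse_dynamics(fr, mo, inertia, short, tr.geometry,
                             tr.markers.marker("3m"))

    def test_unphysical_inertia_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SegmentInertia(
                mass={"arm": -1.0}, length={"arm": 0.3},
                com_fraction={"arm": 0.45},
                inertia_local={"arm": np.eye(3)},
            )


class TestAxleEstimate:
    def test_circle_fit_recovers_axle(self, clean_trial_240):
        tr = clean_trial_240
        grip = tr.markers.marker("3m")
        active = np.linalg.norm(tr.rim.F, axis=1) > 1.0
        centre, r = estimate_axle(grip, active)
        assert np.abs(centre[[0, 2]]
                      - np.asarray(tr.params.axle)[[0, 2]]).max() < 1e-6
        assert r == pytest.approx(tr.params.rim_radius, abs=1e-6)
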