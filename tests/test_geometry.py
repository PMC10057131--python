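"""Geometric observables: oracle agreement, symmetry properties, aggregation, I/O."""

import numpy as np
import pytest

from chiralpmf.framegen import _build_frame, l_ala_like_schedule, generate_geometry_frames
from chiralpmf.geometry import (
    ATOM_LABELS,
    GeometryFrame,
    bd_angle,
    dihedral,
    fl_angle,
    key_distances,
    read_pdb,
    read_xyz,
    window_statistics,
    write_pdb,
    write_xyz,
)

from _oracles import angle_deg, place_by_internal_reference, random_rotation, torsion_deg


def make_frame(**overrides):
    """A valid, fully asymmetric base frame; overrides replace named atoms."""
    atoms = {
        "O3'": [0.9, 0.7, 2.8],
        "H3'": [1.2, 1.4, 3.5],
        "Ccarb": [0.0, 0.0, 0.0],
        "Ocarb": [1.23, 0.0, 0.0],
        "Calpha": [-0.78, 1.30, 0.0],
        "Ob": [-0.74, -1.14, 0.0],
        "N": [-2.0, 1.5, 0.9],
        "P5'": [-3.5, 0.5, 2.0],
    }
    atoms.update(overrides)
    return GeometryFrame.from_dict(atoms)


def random_frame(rng):
    while True:
        coords = rng.uniform(-3, 3, size=(8, 3))
        try:
            return GeometryFrame(coords)
        except ValueError:
            continue


class TestBdAngle:
    def test_collinear_opposite_is_180(self):
        f = make_frame(**{"O3'": [-1.0, 0.0, 0.0]})
        assert bd_angle(f) == pytest.approx(180.0)

    def test_normal_direction_is_90(self):
        f = make_frame(**{"O3'": [0.0, 0.0, 2.0]})
        assert bd_angle(f) == pytest.approx(90.0)

    def test_matches_vector_oracle_on_random_frames(self, rng):
        for _ in range(300):
            f = random_frame(rng)
            ref = angle_deg(f.position("O3'"), f.position("Ccarb"), f.position("Ocarb"))
            assert bd_angle(f) == pytest.approx(ref, abs=1e-9)


class TestFlAngle:
    def test_zero_when_o3_above_carbonyl_plane_on_co_axis_plane(self):
        # O3' in the plane spanned by the C=O axis and the carbonyl normal.
        f = make_frame(**{"O3'": [0.8, 0.0, 2.5]})
        assert fl_angle(f) == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_toward_ob_is_plus_90(self):
        f = make_frame(**{"O3'": [0.5, -2.5, 0.0]})  # carbonyl plane is z=0, Ob at -y
        assert fl_angle(f) == pytest.approx(90.0)

    def test_scheduled_17_degrees_roundtrip(self):
        t = dict(bd_angle=105.0, fl_angle=17.0, d_n_o3=4.0, d_n_p5=4.2,
                 tau=30.0, d_c_o3=3.0, d_h_o3=1.0)
        f = _build_frame(t, rc=-2.0)
        assert fl_angle(f) == pytest.approx(17.0, abs=1e-7)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        f = make_frame(N=[-1.55, 0.2, 0.0], Ob=[-0.74, -1.14, 0.0])
        # N and Ob on the same side of the Ccarb-Calpha bond, all in plane
        assert abs(dihedral(f)) < 45  # eclipsed-side arrangement
        t = dict(bd_angle=105.0, fl_angle=0.0, d_n_o3=4.0, d_n_p5=4.2,
                 tau=0.0, d_c_o3=3.5, d_h_o3=1.0)
        assert dihedral(_build_frame(t, rc=-2.5)) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        t = dict(bd_angle=105.0, fl_angle=0.0, d_n_o3=4.0, d_n_p5=4.2,
                 tau=180.0, d_c_o3=3.5, d_h_o3=1.0)
        assert dihedral(_build_frame(t, rc=-2.5)) == pytest.approx(180.0, abs=1e-9)

    def test_minus_sixty_reference_configuration(self):
        """A fixture built by an independent internal-coordinate routine with a
        clockwise-positive torsion of -60 degrees must evaluate to -60."""
        f0 = make_frame()
        n = place_by_internal_reference(
            f0.position("Ob"), f0.position("Ccarb"), f0.position("Calpha"),
            1.47, 110.0, -60.0,
        )
        f = make_frame(N=list(n))
        assert dihedral(f) == pytest.approx(-60.0, abs=1e-9)

    def test_matches_rotation_matrix_oracle_on_random_frames(self, rng):
        for _ in range(300):
            f = random_frame(rng)
            ref = torsion_deg(
                f.position("Ob"), f.position("Ccarb"), f.position("Calpha"), f.position("N")
            )
            d = abs(dihedral(f) - ref)
            assert min(d, 360 - d) < 1e-9

    def test_collinear_triple_rejected(self):
        f = make_frame(Ob=[-1.56, 2.60, 0.0])  # Ob, Ccarb, Calpha collinear
        with pytest.raises(ValueError, match="collinear"):
            dihedral(f)


class TestKeyDistances:
    def test_unit_cube_distances(self):
        f = make_frame(
            N=[0.0, 1.0, 1.0], **{"O3'": [1.0, 0.0, 0.0], "P5'": [1.0, 1.0, 1.0],
                                  "H3'": [1.0, 1.0, 0.0]}
        )
        kd = key_distances(f)
        assert kd.d_n_o3 == pytest.approx(np.sqrt(3.0))
        assert kd.d_n_p5 == pytest.approx(1.0)
        assert kd.d_c_o3 == pytest.approx(1.0)
        assert kd.d_h_o3 == pytest.approx(1.0)
        assert kd.rc == pytest.approx(0.0)

    @pytest.mark.parametrize("target", [4.0, 6.3])
    def test_scheduled_n_p5_distance_roundtrip(self, target):
        t = dict(bd_angle=105.0, fl_angle=0.0, d_n_o3=3.2, d_n_p5=target,
                 tau=60.0, d_c_o3=2.0, d_h_o3=1.0)
        assert key_distances(_build_frame(t, rc=-1.0)).d_n_p5 == pytest.approx(target)

    def test_missing_label_named(self):
        with pytest.raises(ValueError, match="P5'"):
            GeometryFrame.from_dict({label: [i, 0, 0] for i, label in enumerate(ATOM_LABELS[:-1])})


class TestSymmetryProperties:
    def test_rigid_motion_invariance(self, rng):
        for _ in range(50):
            f = random_frame(rng)
            R = random_rotation(rng)
            t = rng.uniform(-10, 10, 3)
            g = GeometryFrame(f.coords @ R.T + t)
            assert bd_angle(g) == pytest.approx(bd_angle(f), abs=1e-9)
            assert fl_angle(g) == pytest.approx(fl_angle(f), abs=1e-9)
            d = abs(dihedral(g) - dihedral(f))
            assert min(d, 360 - d) < 1e-9
            for a, b in zip(key_distances(g).__dict__.values(),
                            key_distances(f).__dict__.values()):
                assert a == pytest.approx(b, abs=1e-9)

    def test_reflection_flips_chiral_observables_only(self, rng):
        """Mirror images must flip the FL angle and the torsion sign while the BD
        angle and all distances are unchanged — the geometric signature that
        distinguishes the two enantiomeric reaction sites."""
        mirror = np.diag([1.0, 1.0, -1.0])
        for _ in range(50):
            f = random_frame(rng)
            g = GeometryFrame(f.coords @ mirror)
            assert bd_angle(g) == pytest.approx(bd_angle(f), abs=1e-9)
            assert fl_angle(g) == pytest.approx(-fl_angle(f), abs=1e-9)
            d = abs(dihedral(g) + dihedral(f))
            assert min(d, 360 - d) < 1e-9


class TestWindowStatistics:
    def test_identical_frames_have_zero_sd(self):
        f = make_frame()
        stats = window_statistics({-1.0: [f, f, f]}, "bd_angle")
        assert len(stats) == 1
        assert stats[0].sd == 0.0
        assert stats[0].mean == pytest.approx(bd_angle(f))
        assert stats[0].n == 3

    def test_circular_mean_handles_wraparound(self):
        frames = []
        for tau in (179.0, -179.0):
            t = dict(bd_angle=105.0, fl_angle=0.0, d_n_o3=4.0, d_n_p5=4.2,
                     tau=tau, d_c_o3=3.5, d_h_o3=1.0)
            frames.append(_build_frame(t, rc=-2.5))
        stats = window_statistics({-2.5: frames}, "tau", circular=True)
        assert abs(stats[0].mean) == pytest.approx(180.0, abs=1e-6)
        assert stats[0].sd < 2.0
        linear = window_statistics({-2.5: frames}, "tau", circular=False)
        assert abs(linear[0].mean) < 1.0  # the naive mean is wrong here, by design

    def test_linear_and_circular_agree_away_from_wrap(self, rng):
        taus = rng.uniform(55, 65, size=20)
        frames = [
            _build_frame(
                dict(bd_angle=105.0, fl_angle=0.0, d_n_o3=4.0, d_n_p5=4.2,
                     tau=float(t), d_c_o3=3.5, d_h_o3=1.0), rc=-2.5)
            for t in taus
        ]
        lin = window_statistics({-2.5: frames}, "tau", circular=False)[0]
        circ = window_statistics({-2.5: frames}, "tau", circular=True)[0]
        # for concentrated samples the circular mean/SD converge on the linear ones
        assert lin.mean == pytest.approx(circ.mean, abs=1e-3)
        assert lin.sd == pytest.approx(circ.sd, rel=0.06)

    def test_windows_outside_rc_range_excluded_and_empty_groups_skipped(self):
        f = make_frame()
        with pytest.warns(UserWarning, match="no frames"):
            stats = window_statistics(
                {-1.0: [f], -5.0: [f], -2.0: []}, "bd_angle", rc_range=(-4.0, 0.0)
            )
        assert [s.center for s in stats] == [-1.0]


class TestFrameIO:
    def test_xyz_roundtrip(self, tmp_path):
        sch = l_ala_like_schedule()
        frames = generate_geometry_frames(sch, [-3.0, -2.0, -1.0], seed=5)
        path = tmp_path / "frames.xyz"
        write_xyz(frames, path)
        back = read_xyz(path)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert np.allclose(a.coords, b.coords, atol=5e-8)
            assert b.rc == pytest.approx(a.rc, abs=1e-6)

    def test_pdb_roundtrip(self, tmp_path):
        frames = generate_geometry_frames(l_ala_like_schedule(), [-2.5, -1.5], seed=6)
        path = tmp_path / "frames.pdb"
        write_pdb(frames, path)
        back = read_pdb(path)
        assert len(back) == 2
        for a, b in zip(frames, back):
            assert np.allclose(a.coords, b.coords, atol=2e-3)  # PDB stores 3 decimals
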