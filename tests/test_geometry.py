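"""PDB I/O, helix detection, axis fits, superposition, register shifts."""

import math

import numpy as np
import pytest

from krabstrat.errors import DataError, ParseError, ValidationError
from krabstrat.geometry import (
    ResidueCoords,
    azimuthal_rotation,
    detect_helices,
    helix_axis,
    interhelix_angle,
    kabsch_superpose,
    pseudo_cb,
    read_structure,
    write_pdb,
)
from krabstrat.synth import composite_structure, ideal_helix


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform(residues, R, t):
    out = []
    for r in residues:
        out.append(ResidueCoords(
            index=r.index, name=r.name,
            ca=R @ r.ca + t,
            cb=None if r.cb is None else R @ r.cb + t,
            n=None if r.n is None else R @ r.n + t,
            c=None if r.c is None else R @ r.c + t,
        ))
    return out


class TestPdbIO:
    def test_round_trip_of_generated_helix(self, tmp_path, helix12):
        path = tmp_path / "helix.pdb"
        write_pdb(helix12, path)
        back = read_structure(path)
        assert len(back) == 12
        for a, b in zip(helix12, back):
            np.testing.assert_allclose(a.ca, b.ca, atol=1e-3)
            np.testing.assert_allclose(a.cb, b.cb, atol=1e-3)

    def test_glycine_without_cb_is_fine(self, tmp_path):
        helix = ideal_helix(8, with_cb=False)
        path = tmp_path / "gly.pdb"
        write_pdb(helix, path)
        back = read_structure(path)
        assert all(r.cb is None for r in back)

    def test_malformed_atom_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      bad.000   0.000   0.000\n")
        with pytest.raises(ParseError, match="line 1"):
            read_structure(path)

    def test_missing_ca_is_an_error(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00\n"
        )
        with pytest.raises(DataError, match="lacks CA"):
            read_structure(path)

    def test_plddt_carried_from_bfactor(self, tmp_path, helix12):
        for r in helix12:
            r.plddt = 91.5
        path = tmp_path / "plddt.pdb"
        write_pdb(helix12, path)
        back = read_structure(path)
        assert all(r.plddt == pytest.approx(91.5) for r in back)

    def test_first_altloc_taken_with_warning(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  1.00  0.00\n"
        )
        with pytest.warns(UserWarning, match="altloc"):
            back = read_structure(path)
        assert back[0].ca[0] == pytest.approx(1.0)

    def test_agreement_with_independent_reader(self, tmp_path, helix12):
        """CA coordinates agree with gemmi's PDB parser."""
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "check.pdb"
        write_pdb(helix12, path)
        ours = read_structure(path)
        theirs = gemmi.read_structure(str(path))
        cas = [a.pos for model in theirs for chain in model
               for res in chain for a in res if a.name == "CA"]
        assert len(cas) == len(ours)
        for mine, ref in zip(ours, cas):
            np.testing.assert_allclose(mine.ca, [ref.x, ref.y, ref.z], atol=1e-3)


class TestHelixDetection:
    def test_ideal_helix_detected_as_single_full_segment(self, helix12):
        segs = detect_helices(helix12)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 11)

    def test_extended_strand_rejected(self):
        # 3.4 A rise per residue: CA(i)-CA(i+3) far outside the helix window
        strand = [ResidueCoords(index=i + 1, name="GLY",
                                ca=np.array([0.0, 0.0, 3.4 * i]))
                  for i in range(10)]
        assert detect_helices(strand) == []

    def test_two_helices_joined_by_coil(self):
        body = composite_structure([(10, (0, 0, 1)), (10, (1, 0, 0))])
        segs = detect_helices(body)
        assert len(segs) == 2

    def test_three_helix_body(self):
        body = composite_structure([(10, (0, 0, 1)), (10, (0, 1, 0)),
                                    (10, (1, 0, 0))])
        assert len(detect_helices(body)) == 3


class TestHelixAxis:
    def test_generator_parameters_recovered(self, helix12):
        ca = np.array([r.ca for r in helix12])
        point, direction, rise, twist = helix_axis(ca)
        assert abs(np.dot(direction, [0, 0, 1])) > math.cos(math.radians(1.0))
        assert direction[2] > 0  # oriented N -> C
        assert rise == pytest.approx(1.5, abs=0.01)
        assert twist == pytest.approx(100.0, abs=0.5)
        np.testing.assert_allclose(point[:2], [0.0, 0.0], atol=0.05)

    @pytest.mark.parametrize("n_res", [6, 10, 18, 30])
    def test_twist_recovery_across_lengths(self, n_res):
        ca = np.array([r.ca for r in ideal_helix(n_res)])
        _, _, _, twist = helix_axis(ca)
        assert abs(twist - 100.0) < 0.5

    def test_equivariance_under_rigid_transforms(self, helix12):
        rng = np.random.default_rng(23)
        ca = np.array([r.ca for r in helix12])
        _, d0, _, _ = helix_axis(ca)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(scale=20, size=3)
            _, d1, rise, twist = helix_axis(ca @ R.T + t)
            np.testing.assert_allclose(d1, R @ d0, atol=1e-6)
            assert rise == pytest.approx(1.5, abs=0.01)
            assert twist == pytest.approx(100.0, abs=0.5)

    def test_noise_tolerance(self):
        rng = np.random.default_rng(29)
        ca = np.array([r.ca for r in ideal_helix(15)])
        worst = 0.0
        for _ in range(10):
            noisy = ca + rng.normal(scale=0.2, size=ca.shape)
            _, d, _, _ = helix_axis(noisy)
            ang = math.degrees(math.acos(np.clip(abs(d[2]), -1, 1)))
            worst = max(worst, ang)
        assert worst < 3.0

    def test_collinear_input_rejected(self):
        line = np.array([[0.0, 0.0, float(i)] for i in range(6)])
        with pytest.raises(ValidationError):
            helix_axis(line)


class TestInterhelixAngle:
    def test_parallel_and_orthogonal(self):
        body = composite_structure([(10, (0, 0, 1)), (10, (0, 0, 1))])
        segs = detect_helices(body)
        assert interhelix_angle(segs[0], segs[1]) == pytest.approx(0.0, abs=1.0)
        body = composite_structure([(12, (0, 0, 1)), (12, (0, 1, 0))])
        segs = detect_helices(body)
        assert interhelix_angle(segs[0], segs[1]) == pytest.approx(90.0, abs=1.0)

    def test_oblique_l_shape(self):
        d = (0, math.sin(math.radians(75)), math.cos(math.radians(75)))
        body = composite_structure([(12, (0, 0, 1)), (12, d)])
        segs = detect_helices(body)
        assert interhelix_angle(segs[0], segs[1]) == pytest.approx(75.0, abs=1.0)


class TestKabsch:
    def test_self_superposition_is_zero_rmsd(self, helix12):
        ca = np.array([r.ca for r in helix12])
        R, t, rmsd = kabsch_superpose(ca, ca)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_known_transform_recovered(self, helix12):
        rng = np.random.default_rng(31)
        ca = np.array([r.ca for r in helix12])
        R0 = random_rotation(rng)
        t0 = rng.normal(scale=15, size=3)
        moved = ca @ R0.T + t0
        R, t, rmsd = kabsch_superpose(ca, moved)
        assert rmsd < 1e-6
        np.testing.assert_allclose(R @ R0, np.eye(3), atol=1e-8)

    def test_mirrored_input_still_yields_proper_rotation(self, helix12):
        ca = np.array([r.ca for r in helix12])
        mirrored = ca * np.array([1.0, 1.0, -1.0])
        R, t, rmsd = kabsch_superpose(ca, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPseudoCb:
    def test_geometry_of_constructed_cb(self):
        # a roughly tetrahedral backbone triplet
        res = ResidueCoords(index=1, name="GLY",
                            ca=np.zeros(3),
                            n=np.array([-1.458, 0.0, 0.0]),
                            c=np.array([0.551, 1.420, 0.0]))
        cb = pseudo_cb(res)
        d = np.linalg.norm(cb - res.ca)
        assert 1.3 < d < 1.7
        for other in (res.n, res.c):
            v1 = (cb - res.ca) / d
            v2 = (other - res.ca) / np.linalg.norm(other - res.ca)
            ang = math.degrees(math.acos(np.clip(np.dot(v1, v2), -1, 1)))
            assert 100 < ang < 125

    def test_explicit_cb_passes_through(self, helix12):
        assert np.array_equal(pseudo_cb(helix12[3]), helix12[3].cb)

    def test_missing_backbone_rejected(self):
        res = ResidueCoords(index=1, name="GLY", ca=np.zeros(3))
        with pytest.raises(DataError):
            pseudo_cb(res)


class TestAzimuthalRotation:
    def test_identical_structures_give_zero(self, helix12):
        ang = azimuthal_rotation(helix12, helix12, (0, 7), 10)
        assert ang == pytest.approx(0.0, abs=1e-6)

    def test_one_residue_insertion_rotates_by_one_twist(self):
        """The analytic register shift: +1 residue upstream -> ~100 deg."""
        a = ideal_helix(20)
        b = ideal_helix(21)  # one residue inserted upstream of the probe
        ang = azimuthal_rotation(a, b, (0, 8), 15, probe_residue_b=16)
        assert abs(abs(ang) - 100.0) <= 2.0

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(37)
        a = ideal_helix(20)
        b = ideal_helix(21)
        R = random_rotation(rng)
        t = rng.normal(scale=10, size=3)
        b = transform(b, R, t)
        fwd = azimuthal_rotation(a, b, (0, 8), 15, probe_residue_b=16)
        rev = azimuthal_rotation(b, a, (0, 8), 16, probe_residue_b=15)
        assert (fwd + rev) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
               abs((fwd + rev) % 360.0 - 360.0) < 1e-6

    def test_invariant_under_global_transform_of_either_input(self):
        rng = np.random.default_rng(41)
        a = ideal_helix(20)
        b = ideal_helix(21)
        base = azimuthal_rotation(a, b, (0, 8), 15, probe_residue_b=16)
        for _ in range(3):
            Ra, ta = random_rotation(rng), rng.normal(scale=8, size=3)
            Rb, tb = random_rotation(rng), rng.normal(scale=8, size=3)
            moved = azimuthal_rotation(transform(a, Ra, ta), transform(b, Rb, tb),
                                       (0, 8), 15, probe_residue_b=16)
            assert moved == pytest.approx(base, abs=1e-6)

    def test_axis_parallel_probe_rejected(self):
        a = ideal_helix(12)
        bad = [ResidueCoords(index=r.index, name=r.name, ca=r.ca,
                             cb=r.ca + np.array([0.0, 0.0, 1.5]))
               for r in a]
        with pytest.raises(ValidationError):
            azimuthal_rotation(bad, bad, (0, 7), 10)
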