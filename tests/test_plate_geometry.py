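import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pybbq import constants as K
from pybbq import fixtures as fx
from pybbq.plate_geometry import (DegenerateGeometryError, LambdaSeries,
                                  classify_isomer, get_template,
                                  lambda_from_backbone, make_plate_template,
                                  place_plate, reconstruct_backbone, torsion,
                                  wrap_angle)
from conftest import random_rigid_motion


def brute_force_torsion(p1, p2, p3, p4):
    """Independent dihedral via explicit plane normals and a signed angle."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    cos_t = np.clip(np.dot(n1, n2), -1.0, 1.0)
    sign = np.sign(np.dot(np.cross(n1, n2), axis)) or 1.0
    return float(wrap_angle(sign * math.acos(cos_t)))


class TestTorsion:
    def test_canonical_right_handed_quadruple(self):
        value = torsion((1, 1, 0), (0, 0, 0), (0, 0, 1), (1, -1, 1))
        assert value == pytest.approx(-math.pi / 2, abs=1e-12)

    def test_coplanar_cis_is_zero(self):
        value = torsion((1, 1, 0), (0, 0, 0), (3, 0, 0), (4, 1, 0))
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_quadruples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                expected = brute_force_torsion(*pts)
            except FloatingPointError:
                continue
            assert torsion(*pts) == pytest.approx(expected, abs=1e-10)

    def test_sign_flips_under_reversal(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        t_fwd = torsion(*pts)
        t_rev = torsion(pts[3], pts[2], pts[1], pts[0])
        assert t_fwd == pytest.approx(t_rev, abs=1e-12)  # dihedral is symmetric
        # swapping p1<->p4 while keeping axis order flips the sign
        t_mirror = torsion(pts[3], pts[1], pts[2], pts[0])
        assert t_mirror == pytest.approx(wrap_angle(-t_fwd), abs=1e-10)

    def test_collinear_triple_raises(self):
        with pytest.raises(DegenerateGeometryError):
            torsion((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.lists(st.floats(-10, 10, allow_nan=False, allow_infinity=False),
                    min_size=12, max_size=12))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_brute_force_agreement_property(self, flat):
        pts = np.array(flat).reshape(4, 3)
        b2 = pts[2] - pts[1]
        assume(np.linalg.norm(b2) > 1e-3)
        assume(np.linalg.norm(np.cross(pts[1] - pts[0], b2)) > 1e-3)
        assume(np.linalg.norm(np.cross(b2, pts[3] - pts[2])) > 1e-3)
        assert torsion(*pts) == pytest.approx(brute_force_torsion(*pts),
                                              abs=1e-9)


class TestClassifyIsomer:
    @pytest.mark.parametrize("distance,expected", [
        (3.0, "cis"), (3.8, "trans"), (3.5, "trans"),
    ])
    def test_threshold(self, distance, expected):
        assert classify_isomer((0, 0, 0), (distance, 0, 0)) == expected


class TestPlateTemplates:
    @pytest.mark.parametrize("residue_class", ["generic", "proline"])
    @pytest.mark.parametrize("isomer", ["trans", "cis"])
    def test_planarity_and_omega(self, residue_class, isomer):
        t = make_plate_template(residue_class, isomer)
        for pos in t.atoms.values():
            assert abs(pos[2]) < 1e-9           # exactly coplanar, z = 0
        omega = torsion(t.atoms["CA1"], t.atoms["C"], t.atoms["N"],
                        t.atoms["CA2"])
        expected = math.pi if isomer == "trans" else 0.0
        assert abs(abs(wrap_angle(omega)) - expected) < 1e-9 or \
            abs(omega - expected) < 1e-9

    def test_bond_lengths_equal_config(self):
        t = make_plate_template("generic", "trans")
        assert np.linalg.norm(t.atoms["C"] - t.atoms["CA1"]) == pytest.approx(
            K.BOND_CA_C, abs=1e-12)
        assert np.linalg.norm(t.atoms["O"] - t.atoms["C"]) == pytest.approx(
            K.BOND_C_O, abs=1e-12)
        assert np.linalg.norm(t.atoms["N"] - t.atoms["C"]) == pytest.approx(
            K.BOND_C_N_GENERIC, abs=1e-12)
        assert np.linalg.norm(t.atoms["CA2"] - t.atoms["N"]) == pytest.approx(
            K.BOND_N_CA, abs=1e-12)

    def test_cis_template_consistent_with_cis_classification(self):
        cis = make_plate_template("generic", "cis")
        trans = make_plate_template("generic", "trans")
        assert cis.ca_ca_distance < K.CIS_THRESHOLD
        assert trans.ca_ca_distance == pytest.approx(3.80, abs=0.02)

    def test_amide_hydrogen_optional(self):
        with_h = make_plate_template("generic", "trans", include_h=True)
        without = make_plate_template("generic", "trans")
        assert "H" in with_h.atoms and "H" not in without.atoms
        assert abs(with_h.atoms["H"][2]) < 1e-9


class TestPlacePlate:
    def setup_method(self):
        self.t = get_template("generic", "trans")
        self.ca_p = np.array([0.0, 0.0, 0.0])
        self.ca_next = np.array([3.8, 0.0, 0.0])
        self.ref = np.array([5.0, 4.0, 0.0])

    def test_lambda_zero_puts_oxygen_in_reference_plane(self):
        placed = place_plate(self.t, self.ca_p, self.ca_next, 0.0, self.ref)
        assert abs(placed["O"][2]) < 1e-12      # in the z = 0 reference plane
        assert placed["O"][1] > 0               # on the reference side

    def test_periodicity(self):
        a = place_plate(self.t, self.ca_p, self.ca_next, 0.73, self.ref)
        b = place_plate(self.t, self.ca_p, self.ca_next, 0.73 + 2 * math.pi,
                        self.ref)
        for name in a:
            assert np.allclose(a[name], b[name], atol=1e-12)

    def test_degenerate_axis_raises(self):
        with pytest.raises(DegenerateGeometryError):
            place_plate(self.t, self.ca_p, self.ca_p, 0.0, self.ref)
        with pytest.raises(DegenerateGeometryError):
            place_plate(self.t, self.ca_p, self.ca_next, 0.0,
                        np.array([7.6, 0.0, 0.0]))   # collinear reference


class TestLambdaRoundTrip:
    """lambda_from_backbone inverts reconstruct_backbone exactly."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_chain_identity(self, seed):
        chain = fx.make_synthetic_chain(50, seed=seed, cis_fraction=0.05)
        measured = lambda_from_backbone(chain.backbone)
        err = wrap_angle(measured.values - chain.lambdas.values)
        assert np.abs(err[measured.defined_mask]).max() < 1e-9
        assert np.array_equal(chain.backbone.ca, chain.trace.coords)

    def test_helix_lambda_constant(self):
        helix = fx.backbone_from_dihedrals(
            ["ALA"] * 20, math.radians(-57), math.radians(-47))
        series = lambda_from_backbone(helix)
        interior = series.values[3:-3]
        assert interior.std() < 0.02
        assert interior.mean() == pytest.approx(K.LAMBDA_HELIX, abs=1e-9)

    def test_rigid_motion_invariance(self, random_chain):
        rot, trans = random_rigid_motion(11)
        moved = random_chain.backbone.transformed(rot, trans)
        a = lambda_from_backbone(random_chain.backbone)
        b = lambda_from_backbone(moved)
        assert np.abs(wrap_angle(a.values - b.values)).max() < 1e-9


class TestReconstructBackbone:
    def test_ca_copied_exactly(self, random_chain):
        bb = reconstruct_backbone(random_chain.trace, random_chain.lambdas)
        assert np.array_equal(bb.ca, random_chain.trace.coords)

    def test_terminal_atoms_absent(self, random_chain):
        bb = reconstruct_backbone(random_chain.trace, random_chain.lambdas)
        assert not bb.has_atom(0, "N")
        last = bb.n_residues - 1
        assert not bb.has_atom(last, "C") and not bb.has_atom(last, "O")
        for i in range(1, last):
            for name in ("N", "CA", "C", "O"):
                assert bb.has_atom(i, name)

    def test_equivariance_under_rigid_motion(self, random_chain):
        from pybbq.structure_io import CaTrace
        rot, trans = random_rigid_motion(5)
        bb = reconstruct_backbone(random_chain.trace, random_chain.lambdas)
        moved_trace = CaTrace(random_chain.trace.chain_id,
                              list(random_chain.trace.sequence),
                              random_chain.trace.coords @ rot.T + trans)
        bb_moved = reconstruct_backbone(moved_trace, random_chain.lambdas)
        expected = bb.transformed(rot, trans)
        for name in ("N", "C", "O"):
            got, want = bb_moved.coords(name), expected.coords(name)
            ok = np.all(np.isfinite(want), axis=1)
            assert np.abs(got[ok] - want[ok]).max() < 1e-9

    def test_proline_plate_geometry(self):
        chain = fx.make_synthetic_chain(20, seed=9)
        sequence = list(chain.trace.sequence)
        sequence[10] = "PRO"
        from pybbq.structure_io import CaTrace
        trace = CaTrace("A", sequence, chain.trace.coords)
        bb = reconstruct_backbone(trace, chain.lambdas)
        # the plate before a proline nitrogen uses the longer C-N bond
        d = np.linalg.norm(bb.n[10] - bb.c[9])
        assert d == pytest.approx(K.BOND_C_N_PROLINE, abs=1e-9)
        d_generic = np.linalg.norm(bb.n[11] - bb.c[10])
        assert d_generic == pytest.approx(K.BOND_C_N_GENERIC, abs=1e-9)

    def test_undefined_plates_leave_atoms_absent(self, random_chain):
        lams = LambdaSeries(random_chain.lambdas.values.copy(),
                            random_chain.lambdas.defined_mask.copy())
        lams.defined_mask[5] = False
        bb = reconstruct_backbone(random_chain.trace, lams)
        assert not bb.has_atom(5, "C") and not bb.has_atom(5, "O")
        assert not bb.has_atom(6, "N")

    def test_true_lambda_recovery_on_ideal_helix(self, helix_chain):
        from pybbq.evaluation import crmsd
        measured = lambda_from_backbone(helix_chain.backbone)
        bb = reconstruct_backbone(helix_chain.trace, measured)
        assert crmsd(helix_chain.backbone, bb) < 0.05
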