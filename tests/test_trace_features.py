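import numpy as np
import pytest

from pybbq import constants as K
from pybbq import fixtures as fx
from pybbq import trace_features as tf
from pybbq.structure_io import CaTrace
from conftest import random_rigid_motion


def straight_trace(kk: int, spacing: float = 3.8) -> CaTrace:
    coords = np.zeros((kk, 3))
    coords[:, 0] = np.arange(kk) * spacing
    return CaTrace("A", ["GLY"] * kk, coords)


class TestOneHot:
    def test_canonical_and_unknown_slots(self):
        m = tf.one_hot_residues(["ALA", "MSE", "VAL"])
        assert m[0, 0] == 1 and m[0].sum() == 1          # ALA slot
        assert m[1, 20] == 1 and m[1].sum() == 1         # X slot
        assert m[2, 19] == 1                             # VAL is last canonical

    def test_rows_sum_to_one_for_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = [fx.AMINO_ACIDS_3[i] for i in rng.integers(0, 20, 50)]
        assert np.all(tf.one_hot_residues(seq).sum(axis=1) == 1)


class TestLocalDistances:
    def test_collinear_spacing(self):
        d = tf.local_ca_distances(straight_trace(12))
        assert d[2, 3] == pytest.approx(3 * 3.8, abs=1e-12)   # +3 column
        assert d[6, 5] == pytest.approx(5 * 3.8, abs=1e-12)   # -5 column

    def test_terminal_sentinel_is_zero(self):
        d = tf.local_ca_distances(straight_trace(12))
        assert np.all(d[0, :3] == 0.0)          # residue 0 has no -j partners
        assert np.all(d[-1, 3:] == 0.0)

    def test_helix_values_are_compact(self, helix_chain):
        d = tf.local_ca_distances(helix_chain.trace)
        # frozen regression values of the ideal helix geometry
        assert d[5, 3] == pytest.approx(5.227, abs=0.01)      # d(i, i+3)
        assert d[5, 4] == pytest.approx(6.400, abs=0.01)      # d(i, i+4)
        assert d[5, 3] < 3 * 3.8                              # more compact than extended


class TestNeighborCounts:
    def test_three_collinear_atoms(self):
        counts = tf.neighbor_counts(straight_trace(3))
        assert np.all(counts[1] == 2)           # both ends within every radius
        assert np.all(counts[0] == 1) and np.all(counts[2] == 1)

    def test_strict_inequality_at_radius(self):
        trace = straight_trace(2, spacing=4.0)
        counts = tf.neighbor_counts(trace)
        assert counts[0, 0] == 0                # 4.0 not < 4.0
        assert counts[0, 1] == 1                # counted at 4.5

    def test_counts_monotone_in_radius(self, random_chain):
        counts = tf.neighbor_counts(random_chain.trace)
        assert np.all(np.diff(counts, axis=1) >= 0)

    def test_against_brute_force(self, random_chain):
        counts = tf.neighbor_counts(random_chain.trace)
        xyz = random_chain.trace.coords
        kk = len(xyz)
        for i in range(kk):
            for c, r in enumerate(K.NEIGHBOR_RADII):
                expected = sum(1 for j in range(kk) if j != i
                               and np.linalg.norm(xyz[i] - xyz[j]) < r)
                assert counts[i, c] == expected


class TestSecondaryStructure:
    def test_helix_interior_labeled_h(self, helix_chain):
        labels = tf.assign_secondary_structure(helix_chain.trace).labels
        assert all(l == "H" for l in labels[:len(labels) - 4])

    def test_sheet_strands_labeled_e(self, sheet_chain):
        labels = tf.assign_secondary_structure(sheet_chain.trace).labels
        n = (len(labels) - 2) // 2
        assert all(l == "E" for l in labels[:n])
        assert all(l == "E" for l in labels[-n:])

    def test_total_assignment_on_short_chain(self):
        chain = fx.make_synthetic_chain(6, seed=4)
        labels = tf.assign_secondary_structure(chain.trace).labels
        assert len(labels) == 6
        assert all(l in "HEC" for l in labels)

    def test_isolated_extended_chain_is_coil(self):
        labels = tf.assign_secondary_structure(straight_trace(12)).labels
        assert all(l == "C" for l in labels)    # extended but unpaired


class TestHbondCounts:
    def test_all_coil_chain_is_zero(self):
        trace = straight_trace(12)
        sse = tf.assign_secondary_structure(trace)
        assert np.all(tf.hbond_counts(trace, sse) == 0)

    def test_helix_interior_has_helix_partners(self, helix_chain):
        sse = tf.assign_secondary_structure(helix_chain.trace)
        hb = tf.hbond_counts(helix_chain.trace, sse)
        interior = slice(4, len(helix_chain.trace) - 6)
        assert np.all(hb[interior, 0] >= 1)
        assert np.all(hb[:, 1] == 0)

    def test_sheet_paired_region_has_strand_partners(self, sheet_chain):
        sse = tf.assign_secondary_structure(sheet_chain.trace)
        hb = tf.hbond_counts(sheet_chain.trace, sse)
        n = (len(sheet_chain.trace) - 2) // 2
        assert np.all(hb[1:n - 1, 1] >= 1)


class TestCisFlags:
    def test_all_trans_chain(self, random_chain):
        assert np.all(tf.cis_flags(random_chain.trace) == 0)

    def test_compressed_bond_flagged(self):
        trace = straight_trace(10)
        trace.coords[5:, 0] -= 3.8 - 2.9        # shrink bond (4, 5) to 2.9 A
        flags = tf.cis_flags(trace)
        assert flags[4, 0] == 1 and flags.sum() == 1

    def test_last_row_always_zero(self, random_chain):
        assert tf.cis_flags(random_chain.trace)[-1, 0] == 0


class TestFeatureMatrix:
    def test_shape_and_group_widths(self, random_chain):
        fm = tf.build_feature_matrix(random_chain.trace)
        assert fm.values.shape == (len(random_chain.trace), 37)
        assert len(tf.FEATURE_COLUMNS) == 37
        widths = [21, 6, 4, 3, 1, 2]
        assert sum(widths) == 37
        # one-hot blocks sum to one per residue
        assert np.all(fm.values[:, :21].sum(axis=1) == 1)
        assert np.all(fm.values[:, 31:34].sum(axis=1) == 1)

    def test_permuting_sequence_touches_only_onehot(self, random_chain):
        fm = tf.build_feature_matrix(random_chain.trace)
        shuffled = CaTrace("A", list(reversed(random_chain.trace.sequence)),
                           random_chain.trace.coords)
        fm2 = tf.build_feature_matrix(shuffled)
        assert np.array_equal(fm.values[:, 21:], fm2.values[:, 21:])

    def test_rigid_motion_invariance(self, random_chain):
        rot, trans = random_rigid_motion(17)
        moved = CaTrace("A", list(random_chain.trace.sequence),
                        random_chain.trace.coords @ rot.T + trans)
        fm = tf.build_feature_matrix(random_chain.trace)
        fm2 = tf.build_feature_matrix(moved)
        assert np.abs(fm.values - fm2.values).max() < 1e-9

    def test_invariants_on_many_random_traces(self):
        for seed in range(25):
            chain = fx.make_synthetic_chain(30, seed=500 + seed,
                                            cis_fraction=0.05)
            v = tf.build_feature_matrix(chain.trace).values
            assert np.all(v[:, :21].sum(axis=1) == 1)
            assert np.all(v[:, 31:34].sum(axis=1) == 1)
            assert np.all(np.diff(v[:, 27:31], axis=1) >= 0)
            assert np.all(v[:, 21:27] >= 0)
            counts = v[:, 27:31]
            assert np.array_equal(counts, np.round(counts))

    def test_tsv_export(self, random_chain, tmp_path):
        fm = tf.build_feature_matrix(random_chain.trace)
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == list(tf.FEATURE_COLUMNS)
        assert len(lines) == fm.n_residues + 1
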