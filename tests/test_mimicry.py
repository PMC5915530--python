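import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biotite.structure.info as struc_info

from retromimic import InputError, parse_sequence, retro_d_transform
from retromimic.mimicry import (
    POLICIES,
    build_retro_atom_map,
    count_clusters,
    cross_rmsd_matrix,
    kabsch_superpose,
    mapped_coordinates,
    mirror_cross_rmsd_matrix,
    rmsd_histogram,
    self_rmsd_matrix,
    sidechain_heavy_atoms,
    template_inventory,
)
from retromimic import synthetic as syn

from conftest import quaternion_rmsd


class TestRetroAtomMap:
    def test_ca_only_pairs(self, hai, retro_hai):
        inv_a = template_inventory(hai)
        inv_b = template_inventory(retro_hai)
        amap = build_retro_atom_map(hai, retro_hai, inv_a, inv_b, policy="ca")
        assert len(amap.pairs) == 7
        for k, (ia, ib) in enumerate(amap.pairs, start=1):
            assert inv_a[ia].atom_name == "CA"
            assert inv_b[ib].atom_name == "CA"
            assert inv_a[ia].residue_index == k
            assert inv_b[ib].residue_index == 8 - k

    def test_sidechain_atoms_matched_by_template_name(self, hai, retro_hai):
        # independent enumeration from the CCD residue template
        tyr = struc_info.residue("TYR")
        expected_tyr_side = {
            str(n)
            for n, e in zip(tyr.atom_name, tyr.element)
            if e != "H" and str(n) not in ("N", "CA", "C", "O", "OXT")
        }
        assert set(sidechain_heavy_atoms("Y")) == expected_tyr_side
        inv_a = template_inventory(hai)
        inv_b = template_inventory(retro_hai)
        amap = build_retro_atom_map(hai, retro_hai, inv_a, inv_b, "ca-sidechain")
        # parent Tyr is residue 4 -> retro residue 4 (center of 7-mer)
        tyr_pairs = [
            (ia, ib)
            for ia, ib in amap.pairs
            if inv_a[ia].residue_index == 4
        ]
        names = {inv_a[ia].atom_name for ia, _ in tyr_pairs}
        assert names == {"CA"} | expected_tyr_side
        for ia, ib in tyr_pairs:
            assert inv_a[ia].atom_name == inv_b[ib].atom_name

    def test_backbone_swap_policy(self, hai, retro_hai):
        inv_a = template_inventory(hai)
        inv_b = template_inventory(retro_hai)
        amap = build_retro_atom_map(hai, retro_hai, inv_a, inv_b, "all-heavy-swap")
        swapped = [
            (inv_a[ia].atom_name, inv_b[ib].atom_name)
            for ia, ib in amap.pairs
            if inv_a[ia].atom_name in ("N", "C")
        ]
        assert swapped and all(
            (a, b) in (("N", "C"), ("C", "N")) for a, b in swapped
        )
        # carbonyl O never mapped under any policy
        for policy in POLICIES:
            m = build_retro_atom_map(hai, retro_hai, inv_a, inv_b, policy)
            assert all(inv_a[ia].atom_name != "O" for ia, _ in m.pairs)
            assert all(inv_b[ib].atom_name != "O" for _, ib in m.pairs)

    def test_mismatch_rejected_with_position(self, hai):
        mutant = parse_sequence("hrpyiaa")
        with pytest.raises(InputError, match="position 7"):
            build_retro_atom_map(
                hai, mutant, template_inventory(hai), template_inventory(mutant)
            )

    def test_each_atom_at_most_once(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        assert len({a for a, _ in amap.pairs}) == len(amap.pairs)
        assert len({b for _, b in amap.pairs}) == len(amap.pairs)


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        fit = kabsch_superpose(x, x)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        y = x @ rot.T + t  # y = R x + t
        fit = kabsch_superpose(y, x)  # fit x onto y
        assert fit.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.rotation, rot, atol=1e-6)
        assert np.allclose(fit.translation, t, atol=1e-6)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=(10, 3))
            y = rng.normal(size=(10, 3))
            w = rng.uniform(0.5, 2.0, size=10)
            assert kabsch_superpose(x, y, w).rmsd == pytest.approx(
                quaternion_rmsd(x, y, w), abs=1e-8
            )

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(size=(6, 3))
            y = rng.normal(size=(6, 3))
            fit = kabsch_superpose(x, y)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_mirror_of_chiral_set_not_absorbed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 3))
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        assert kabsch_superpose(x, mirrored).rmsd > 0.1

    def test_collinear_flagged(self):
        x = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        fit = kabsch_superpose(x, x)
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCrossRMSD:
    def test_retro_relabeled_copy_zero_diagonal(self, hai, retro_hai):
        parent, retro, _ = syn.make_mimic_pair(
            hai, "mimic", noise_sigma=0.0, n_frames=6, seed=3
        )
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        res = cross_rmsd_matrix(parent, retro, amap)
        assert np.diag(res.matrix).max() <= 1e-6
        assert res.best_pair[2] == res.matrix.min()

    def test_single_frame_consistency(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        p1 = parent.subset([0])
        r1 = retro.subset([0])
        res = cross_rmsd_matrix(p1, r1, amap)
        direct = kabsch_superpose(
            mapped_coordinates(p1, amap, "A")[0],
            mapped_coordinates(r1, amap, "B")[0],
            amap.weights,
        )
        assert res.matrix.shape == (1, 1)
        assert res.matrix[0, 0] == pytest.approx(direct.rmsd, abs=1e-7)

    def test_transpose_equals_inverted_map(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        fwd = cross_rmsd_matrix(parent, retro, amap)
        rev = cross_rmsd_matrix(retro, parent, amap.inverted())
        assert np.allclose(fwd.matrix.T, rev.matrix, atol=1e-10)

    def test_rigid_motion_invariance(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        base = cross_rmsd_matrix(parent, retro, amap).matrix
        rot = Rotation.random(random_state=11).as_matrix()
        moved = type(retro)(
            retro.atoms, retro.frames @ rot.T + np.array([3.0, -1.0, 8.0])
        )
        again = cross_rmsd_matrix(parent, moved, amap).matrix
        assert np.allclose(base, again, atol=1e-8)

    def test_histogram_counts_conserved(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        res = cross_rmsd_matrix(parent, retro, amap)
        assert res.counts.sum() == res.matrix.size

    def test_mirror_diagnostic_not_larger(self, hai, retro_hai, small_pair):
        parent, retro, _ = small_pair
        amap = build_retro_atom_map(hai, retro_hai, parent, retro)
        proper = cross_rmsd_matrix(parent, retro, amap).matrix
        mirrored = mirror_cross_rmsd_matrix(parent, retro, amap)
        assert np.all(mirrored <= proper + 1e-10)


class TestHistogram:
    def test_all_zero_single_bin(self):
        edges, counts = rmsd_histogram(np.zeros((2, 2)), 0.5)
        assert np.allclose(edges, [0.0, 0.5])
        assert counts.tolist() == [4]

    def test_direct_binning(self):
        edges, counts = rmsd_histogram(np.array([[0.1, 0.6], [0.6, 1.2]]), 0.5)
        assert counts.tolist() == [1, 2, 1]
        assert np.allclose(edges, [0.0, 0.5, 1.0, 1.5])

    def test_right_open_bins(self):
        edges, counts = rmsd_histogram(np.array([[0.5, 0.999], [1.0, 0.0]]), 0.5)
        # 0.5 and 0.999 share bin [0.5, 1.0); 1.0 opens [1.0, 1.5)
        assert counts.tolist() == [1, 2, 1]

    def test_conservation_random(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(0, 10, size=(13, 17))
        _, counts = rmsd_histogram(m, 0.37)
        assert counts.sum() == m.size

    def test_bad_width(self):
        with pytest.raises(InputError):
            rmsd_histogram(np.zeros((2, 2)), 0.0)


class TestSelfRMSD:
    def test_identical_frames_all_zero(self, hai):
        ens = syn.build_peptide_coords(hai, np.full((7, 2), 140.0))
        stacked = type(ens)(ens.atoms, np.repeat(ens.frames, 4, axis=0))
        m = self_rmsd_matrix(stacked)
        assert np.abs(m).max() <= 1e-6

    def test_symmetry_and_repeated_frame(self, small_pair):
        parent, _, _ = small_pair
        frames = parent.frames.copy()
        frames[2] = frames[0]
        ens = type(parent)(parent.atoms, frames)
        m = self_rmsd_matrix(ens, mass_weighted=True)
        assert np.allclose(m, m.T, atol=1e-10)
        assert m[0, 2] == pytest.approx(0.0, abs=1e-8)
        assert m[0, 1] == pytest.approx(m[2, 1], abs=1e-8)

    def test_mass_weighting_changes_result(self, small_pair):
        parent, _, _ = small_pair
        mw = self_rmsd_matrix(parent, mass_weighted=True)
        uw = self_rmsd_matrix(parent, mass_weighted=False)
        assert not np.allclose(mw, uw)


class TestClusters:
    @staticmethod
    def brute_force_components(m, cutoff):
        n = len(m)
        labels = [-1] * n
        current = 0
        for start in range(n):
            if labels[start] != -1:
                continue
            stack = [start]
            labels[start] = current
            while stack:
                u = stack.pop()
                for v in range(n):
                    if labels[v] == -1 and m[u][v] <= cutoff:
                        labels[v] = current
                        stack.append(v)
            current += 1
        return current, labels

    def test_single_cluster_at_large_cutoff(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0, 3, size=(6, 6))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0)
        n, labels = count_clusters(m, cutoff=m.max() + 1)
        assert n == 1 and set(labels) == {0}

    def test_all_singletons_at_tiny_cutoff(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(1, 3, size=(5, 5))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0)
        n, labels = count_clusters(m, cutoff=0.5)
        assert n == 5
        assert labels.tolist() == [0, 1, 2, 3, 4]  # ordered by first frame

    def test_two_tight_groups(self):
        # frames 0-2 within 0.5 Å, frames 3-4 within 0.5 Å, groups 5 Å apart
        m = np.full((5, 5), 5.0)
        for i in range(3):
            for j in range(3):
                m[i, j] = 0.4 if i != j else 0.0
        for i in (3, 4):
            for j in (3, 4):
                m[i, j] = 0.4 if i != j else 0.0
        n, labels = count_clusters(m, cutoff=1.0)
        bf_n, bf_labels = self.brute_force_components(m.tolist(), 1.0)
        assert n == bf_n == 2
        assert labels.tolist() == bf_labels

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m = rng.uniform(0, 4, size=(8, 8))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 0)
            n, labels = count_clusters(m, cutoff=1.5)
            bf_n, bf_labels = self.brute_force_components(m.tolist(), 1.5)
            assert n == bf_n
            assert labels.tolist() == bf_labels
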