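"""Residue-pair decomposition against brute-force oracles and hand statistics."""

import numpy as np
import pytest

from chapdyn.core_io import Trajectory
from chapdyn.pair_energetics import (
    COULOMB_CONSTANT,
    EnergyMatrix,
    aggregate_replicas,
    direct_intergroup_energy,
    export_heatmap_table,
    pair_energy,
    rank_and_partition,
    residue_pair_matrix,
)

from conftest import simple_system


def brute_force_pair(system, coords, i, j, eps_in=1.0):
    """Independent slow evaluation of one pair (no shared code path)."""
    if (min(i, j), max(i, j)) in system.exclusions:
        return 0.0, 0.0
    r = np.linalg.norm(coords[i] - coords[j])
    ec = COULOMB_CONSTANT * system.charge[i] * system.charge[j] / (eps_in * r)
    sig = (system.sigma[i] + system.sigma[j]) / 2
    eps = np.sqrt(system.epsilon[i] * system.epsilon[j])
    ev = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    if (min(i, j), max(i, j)) in system.pairs14:
        ec /= 1.2
        ev /= 2.0
    return ec, ev


def random_two_group_system(rng, n_a=6, n_b=7):
    """Small random system: group A atoms then group B atoms, each its own
    residue, random charges and positions with a safe separation."""
    pos = np.vstack(
        [
            rng.uniform(0, 6, size=(n_a, 3)),
            rng.uniform(0, 6, size=(n_b, 3)) + np.array([12.0, 0, 0]),
        ]
    )
    charges = rng.uniform(-1, 1, size=n_a + n_b)
    chain = ["A"] * n_a + ["B"] * n_b
    return simple_system(pos, charges, chain=chain), n_a, n_b


class TestPairEnergy:
    def test_zero_charge_zero_coulomb(self):
        sys = simple_system([(0, 0, 0), (5, 0, 0)], [0.0, 1.0])
        ec, _ = pair_energy(sys, sys.structure.coords, 0, 1)
        assert ec == 0.0

    def test_coulomb_arithmetic(self):
        # k_e / 3.320637 = 100 exactly for unit charges
        sys = simple_system([(0, 0, 0), (3.320637, 0, 0)], [1.0, 1.0])
        ec, _ = pair_energy(sys, sys.structure.coords, 0, 1)
        assert ec == pytest.approx(100.0, rel=1e-9)

    def test_lj_minimum_depth(self):
        r_min = 2 ** (1 / 6) * 3.4
        sys = simple_system([(0, 0, 0), (r_min, 0, 0)], [0.0, 0.0], epsilon=0.25)
        _, ev = pair_energy(sys, sys.structure.coords, 0, 1)
        assert ev == pytest.approx(-0.25, rel=1e-12)

    def test_excluded_pair_is_zero(self):
        sys = simple_system([(0, 0, 0), (2, 0, 0)], [1.0, -1.0], exclusions={(0, 1)})
        assert pair_energy(sys, sys.structure.coords, 0, 1) == (0.0, 0.0)

    def test_scaled_14_pair(self):
        sys = simple_system([(0, 0, 0), (3.320637, 0, 0)], [1.0, 1.0], pairs14={(0, 1)})
        ec, ev = pair_energy(sys, sys.structure.coords, 0, 1)
        assert ec == pytest.approx(100.0 / 1.2, rel=1e-9)
        sys0 = simple_system([(0, 0, 0), (3.320637, 0, 0)], [1.0, 1.0])
        _, ev_full = pair_energy(sys0, sys0.structure.coords, 0, 1)
        assert ev == pytest.approx(ev_full / 2.0, rel=1e-12)

    def test_clash_raises(self):
        sys = simple_system([(0, 0, 0), (0.05, 0, 0)], [1.0, 1.0])
        with pytest.raises(ValueError, match="clash"):
            pair_energy(sys, sys.structure.coords, 0, 1)

    def test_coulomb_linear_in_charge_lj_invariant(self):
        rng = np.random.default_rng(3)
        pos = [(0, 0, 0), (4.1, 0.7, -0.3)]
        for q in rng.uniform(-2, 2, size=5):
            s1 = simple_system(pos, [q, 0.5])
            s2 = simple_system(pos, [2 * q, 0.5])
            ec1, ev1 = pair_energy(s1, s1.structure.coords, 0, 1)
            ec2, ev2 = pair_energy(s2, s2.structure.coords, 0, 1)
            assert ec2 == pytest.approx(2 * ec1, rel=1e-12)
            assert ev2 == ev1


class TestResiduePairMatrix:
    def test_zero_parameters_zero_matrix(self):
        sys = simple_system([(0, 0, 0), (4, 0, 0)], [0.0, 0.0], epsilon=0.0, chain=["A", "B"])
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        m = residue_pair_matrix(sys, traj, np.array([0]), np.array([1]))
        assert np.all(m.total == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle_equivalence(self, seed):
        """Each entry equals an independent double loop over atom pairs."""
        rng = np.random.default_rng(seed)
        sys, n_a, n_b = random_two_group_system(rng)
        coords = sys.structure.coords
        traj = Trajectory(coords=coords[None], template=sys.structure)
        sel_a, sel_b = np.arange(n_a), np.arange(n_a, n_a + n_b)
        m = residue_pair_matrix(sys, traj, sel_a, sel_b)
        for a in range(n_a):
            for b in range(n_b):
                ec, ev = brute_force_pair(sys, coords, a, n_a + b)
                assert m.coulomb[a, b] == pytest.approx(ec, abs=1e-8)
                assert m.vdw[a, b] == pytest.approx(ev, abs=1e-8)

    def test_conservation_pair_sums_equal_direct_total(self):
        rng = np.random.default_rng(11)
        sys, n_a, n_b = random_two_group_system(rng, 10, 12)
        coords = sys.structure.coords
        traj = Trajectory(coords=coords[None], template=sys.structure)
        sel_a, sel_b = np.arange(n_a), np.arange(n_a, n_a + n_b)
        m = residue_pair_matrix(sys, traj, sel_a, sel_b)
        ec, ev = direct_intergroup_energy(sys, coords, sel_a, sel_b)
        assert m.coulomb.sum() + m.vdw.sum() == pytest.approx(ec + ev, abs=1e-6)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        sys, n_a, n_b = random_two_group_system(rng)
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        sel_a, sel_b = np.arange(n_a), np.arange(n_a, n_a + n_b)
        m_ab = residue_pair_matrix(sys, traj, sel_a, sel_b)
        m_ba = residue_pair_matrix(sys, traj, sel_b, sel_a)
        np.testing.assert_allclose(m_ab.total, m_ba.total.T, atol=1e-12)

    def test_frame_averaging(self):
        sys = simple_system([(0, 0, 0), (3.320637, 0, 0)], [1.0, 1.0], chain=["A", "B"])
        frames = np.stack([sys.structure.coords, sys.structure.coords * np.array([2, 1, 1.0])])
        traj = Trajectory(coords=frames, template=sys.structure)
        m = residue_pair_matrix(sys, traj, np.array([0]), np.array([1]))
        assert m.coulomb[0, 0] == pytest.approx((100.0 + 50.0) / 2, rel=1e-6)

    def test_empty_or_overlapping_selection(self):
        sys = simple_system([(0, 0, 0), (4, 0, 0)], [0.0, 0.0])
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        with pytest.raises(ValueError, match="empty"):
            residue_pair_matrix(sys, traj, np.array([], dtype=int), np.array([1]))
        with pytest.raises(ValueError, match="disjoint"):
            residue_pair_matrix(sys, traj, np.array([0, 1]), np.array([1]))


class TestAggregateReplicas:
    def make(self, value):
        return EnergyMatrix(rows=["A:1:GLY"], cols=["B:1:GLY"],
                            coulomb=np.array([[value]]), vdw=np.array([[0.0]]))

    def test_identical_replicas_zero_sd(self):
        stats = aggregate_replicas([self.make(2.0)] * 4)
        assert stats.sd["coulomb"][0, 0] == 0.0
        assert stats.sem["coulomb"][0, 0] == 0.0

    def test_hand_statistics_1234(self):
        stats = aggregate_replicas([self.make(v) for v in (1.0, 2.0, 3.0, 4.0)])
        assert stats.mean["coulomb"][0, 0] == pytest.approx(2.5)
        assert stats.sd["coulomb"][0, 0] == pytest.approx(1.2910, abs=1e-4)
        assert stats.sem["coulomb"][0, 0] == pytest.approx(0.6455, abs=1e-4)

    def test_single_replica_missing_sd(self):
        stats = aggregate_replicas([self.make(1.0)])
        assert stats.sd is None and stats.sem is None
        assert stats.mean["coulomb"][0, 0] == 1.0

    def test_cross_replica_mean_is_mean_of_means(self):
        mats = [self.make(v) for v in (0.5, 1.5, 4.0)]
        stats = aggregate_replicas(mats)
        assert stats.mean["coulomb"][0, 0] == pytest.approx(2.0)


class TestRankAndPartition:
    def test_single_negative_entry_rank1(self):
        m = EnergyMatrix(rows=["A:1:X", "A:2:X"], cols=["C:1:Y"],
                         coulomb=np.array([[0.0], [-3.0]]), vdw=np.zeros((2, 1)))
        rep = rank_and_partition(m, 1, {"A:1:X": "a", "A:2:X": "a", "C:1:Y": "c"})
        assert rep.top_pairs["total"][0] == ("A:2:X", "C:1:Y", -3.0)

    def test_planted_block_sums(self):
        rows = ["A:1:X", "A:2:X", "B:1:X", "B:2:X"]
        vals = np.array([[1.0], [2.0], [10.0], [20.0]])
        m = EnergyMatrix(rows=rows, cols=["C:1:Y"], coulomb=vals, vdw=np.zeros((4, 1)))
        region = {r: ("pa" if r.startswith("A") else "pb") for r in rows}
        region["C:1:Y"] = "client"
        rep = rank_and_partition(m, 2, region)
        assert rep.block_sums["coulomb"].loc["pa", "client"] == 3.0
        assert rep.block_sums["coulomb"].loc["pb", "client"] == 30.0
        assert rep.asymmetry("pa", "pb", "coulomb") == pytest.approx(-27.0)

    def test_symmetric_matrix_zero_asymmetry(self):
        rows = ["A:1:X", "B:1:X"]
        m = EnergyMatrix(rows=rows, cols=["C:1:Y"],
                         coulomb=np.array([[-2.0], [-2.0]]), vdw=np.zeros((2, 1)))
        region = {"A:1:X": "pa", "B:1:X": "pb", "C:1:Y": "client"}
        rep = rank_and_partition(m, 1, region)
        assert rep.asymmetry("pa", "pb") == 0.0

    def test_unlabeled_residue_warns_other(self):
        m = EnergyMatrix(rows=["A:1:X"], cols=["C:1:Y"],
                         coulomb=np.array([[1.0]]), vdw=np.zeros((1, 1)))
        with pytest.warns(UserWarning, match="no region label"):
            rep = rank_and_partition(m, 1, {"A:1:X": "a"})
        assert rep.col_region_of["C:1:Y"] == "other"


class TestExportHeatmap:
    def test_clip_keeps_tsv_full_precision(self, tmp_path):
        m = EnergyMatrix(rows=["A:1:X"], cols=["C:1:Y"],
                         coulomb=np.array([[-3.65]]), vdw=np.zeros((1, 1)))
        out = tmp_path / "m.tsv"
        rendered = export_heatmap_table(m, out, clip=1.0, component="coulomb")
        assert rendered[0, 0] == -1.0
        assert "-3.65" in out.read_text()

    @pytest.mark.parametrize("value,clip,expected", [(0.0, 1.0, 0.0), (-1.5, 2.0, -1.5)])
    def test_clip_behaviour(self, tmp_path, value, clip, expected):
        m = EnergyMatrix(rows=["A:1:X"], cols=["C:1:Y"],
                         coulomb=np.array([[value]]), vdw=np.zeros((1, 1)))
        rendered = export_heatmap_table(m, tmp_path / "m.tsv", clip=clip, component="coulomb")
        assert rendered[0, 0] == expected

    def test_invalid_clip(self, tmp_path):
        m = EnergyMatrix(rows=["A:1:X"], cols=["C:1:Y"],
                         coulomb=np.zeros((1, 1)), vdw=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            export_heatmap_table(m, tmp_path / "m.tsv", clip=0.0)
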