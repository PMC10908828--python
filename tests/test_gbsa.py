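"""GB/SA energetics: Born limit, descreening-integral oracle, SASA vs
analytic spheres, binding-energy hand oracles, decomposition conservation."""

import numpy as np
import pytest
from scipy.integrate import quad

from chapdyn.core_io import Trajectory
from chapdyn.gbsa import (
    GBParams,
    effective_born_radii,
    gb_energy,
    mmgbsa_binding,
    per_residue_gbsa,
    sasa,
    sphere_points,
)
from chapdyn.pair_energetics import COULOMB_CONSTANT

from conftest import simple_system


def born_closed_form(q, radius, params):
    return -0.5 * COULOMB_CONSTANT * (1 / params.eps_in - 1 / params.eps_out) * q**2 / radius


def numeric_descreening_integral(d, s, rho):
    """(1/4pi) * integral of r^-4 over the neighbour sphere (radius s at
    distance d), excluding the region inside rho of the atom: evaluated by
    1D quadrature over spherical shells around the atom."""

    def shell(r):
        cos_alpha = np.clip((r**2 + d**2 - s**2) / (2 * r * d), -1.0, 1.0)
        return 0.5 * (1.0 - cos_alpha) / r**2

    lo = max(rho, d - s)
    hi = d + s
    if hi <= lo:
        return 0.0
    val, _ = quad(shell, lo, hi, limit=200)
    return val


class TestEffectiveBornRadii:
    def test_isolated_atom_equals_offset_radius(self):
        sys = simple_system([(0, 0, 0)], [1.0], rho=1.5)
        r = effective_born_radii(sys, sys.structure.coords)
        assert r[0] == pytest.approx(1.5 - 0.09, rel=1e-12)

    @pytest.mark.parametrize("d", [3.0, 4.5, 7.0])
    def test_two_atom_matches_numeric_integral(self, d):
        p = GBParams()
        rho_i, rho_j, screen = 1.5, 1.8, 0.8
        sys = simple_system([(0, 0, 0), (d, 0, 0)], [0.0, 0.0], screen=screen)
        sys.born_radius = np.array([rho_i, rho_j])
        radii = effective_born_radii(sys, sys.structure.coords, p)
        # independent oracle: numeric descreening integral -> OBC rescaling
        rho_t = rho_i - p.dielectric_offset
        integral = numeric_descreening_integral(d, screen * (rho_j - p.dielectric_offset), rho_t)
        psi = integral * rho_t
        inv = 1 / rho_t - np.tanh(p.alpha * psi - p.beta * psi**2 + p.gamma_obc * psi**3) / rho_i
        assert radii[0] == pytest.approx(1 / inv, rel=1e-6)

    def test_burial_increases_radius(self):
        # atom at the centre of a dense cage
        rng = np.random.default_rng(0)
        shell = rng.normal(size=(60, 3))
        shell = 3.0 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        pos = np.vstack([[0.0, 0.0, 0.0], shell])
        sys = simple_system(pos, np.zeros(len(pos)))
        radii = effective_born_radii(sys, pos)
        assert radii[0] > 3.0 * sys.born_radius[0]

    def test_monotone_in_burial(self):
        base = [(0.0, 0.0, 0.0), (4.0, 0.0, 0.0)]
        more = base + [(0.0, 4.0, 0.0)]
        r1 = effective_born_radii(simple_system(base, [0, 0]), np.asarray(base))
        r2 = effective_born_radii(simple_system(more, [0, 0, 0]), np.asarray(more))
        assert r2[0] > r1[0]


class TestGBEnergy:
    def test_zero_charges_zero_energy(self):
        sys = simple_system([(0, 0, 0), (4, 0, 0)], [0.0, 0.0])
        radii = effective_born_radii(sys, sys.structure.coords)
        assert gb_energy(sys.charge, sys.structure.coords, radii) == 0.0

    def test_born_limit_single_ion(self):
        p = GBParams()
        coords = np.zeros((1, 3))
        e = gb_energy(np.array([1.0]), coords, np.array([1.5]), p)
        assert e == pytest.approx(born_closed_form(1.0, 1.5, p), rel=1e-12)
        assert e == pytest.approx(-109.28, abs=0.01)

    def test_two_ion_hand_oracle(self):
        p = GBParams()
        r12 = 4.0
        q = np.array([1.0, -1.0])
        radii = np.array([1.4, 1.6])
        coords = np.array([[0.0, 0, 0], [r12, 0, 0]])
        # hand-evaluated double sum over f_GB
        f12 = np.sqrt(r12**2 + radii[0] * radii[1] * np.exp(-(r12**2) / (4 * radii[0] * radii[1])))
        pref = -0.5 * COULOMB_CONSTANT * (1 / p.eps_in - 1 / p.eps_out)
        expected = pref * (1 / radii[0] + 1 / radii[1] + 2 * q[0] * q[1] / f12)
        assert gb_energy(q, coords, radii, p) == pytest.approx(expected, abs=1e-8)

    def test_nonpositive_for_any_charges(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 6
            coords = rng.uniform(0, 8, size=(n, 3))
            q = rng.uniform(-1, 1, size=n)
            sys = simple_system(coords, q)
            radii = effective_born_radii(sys, coords)
            assert gb_energy(q, coords, radii) <= 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 6, size=(5, 3))
        q = rng.uniform(-1, 1, size=5)
        sys = simple_system(coords, q)
        radii = effective_born_radii(sys, coords)
        e0 = gb_energy(q, coords, radii, None)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.0])
        radii2 = effective_born_radii(sys, moved)
        np.testing.assert_allclose(radii, radii2, rtol=1e-10)
        assert gb_energy(q, moved, radii2) == pytest.approx(e0, rel=1e-10)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = sasa(np.zeros((1, 3)), np.array([1.7]), probe_radius=1.4, n_points=960)
        analytic = 4 * np.pi * 3.1**2
        assert area[0] == pytest.approx(analytic, rel=1e-12)  # no neighbours: exact
        assert analytic == pytest.approx(120.76, abs=0.01)

    def test_enclosed_atom_zero(self):
        pts = sphere_points(30) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], pts])
        radii = np.array([0.5] + [1.7] * 30)
        areas = sasa(coords, radii, n_points=240)
        assert areas[0] == 0.0

    def test_two_overlapping_spheres_closed_form(self):
        # two equal spheres radius R (probe-expanded), centre distance d:
        # each loses a cap of height h = R - d/2
        r_atom, probe, d = 1.7, 1.4, 2.0
        big = r_atom + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa(coords, np.array([r_atom, r_atom]), probe, n_points=960)
        cap = 2 * np.pi * big * (big - d / 2)
        expected = 2 * (4 * np.pi * big**2 - cap)
        assert areas.sum() == pytest.approx(expected, rel=0.01)

    def test_cross_check_against_mdtraj(self):
        """Independent implementation check: mdtraj's Shrake-Rupley on a
        random carbon cluster (mdtraj's internal carbon radius is 1.7 A,
        matching the fixture radius)."""
        import mdtraj as md

        rng = np.random.default_rng(17)
        coords = rng.uniform(0, 0.8, size=(12, 3)) * 10.0  # Angstrom
        top = md.Topology()
        chain = top.add_chain()
        for i in range(len(coords)):
            res = top.add_residue("GLY", chain)
            top.add_atom("C", md.element.carbon, res)
        traj = md.Trajectory(xyz=coords[None] / 10.0, topology=top)  # nm
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)[0] * 100.0
        mine = sasa(coords, np.full(12, 1.7), probe_radius=1.4, n_points=960)
        np.testing.assert_allclose(mine, ref, rtol=0.03, atol=0.5)

    def test_convergence_with_point_count(self):
        r_atom, probe, d = 1.7, 1.4, 2.0
        big = r_atom + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        cap = 2 * np.pi * big * (big - d / 2)
        expected = 2 * (4 * np.pi * big**2 - cap)
        errors = [
            abs(sasa(coords, np.array([r_atom] * 2), probe, n).sum() - expected)
            for n in (60, 240, 960)
        ]
        assert errors[2] < errors[0]


class TestMMGBSA:
    def two_chain_system(self, gap, charges):
        pos = [(0.0, 0, 0), (3.8, 0, 0), (0.0 + gap, 8.0, 0), (3.8 + gap, 8.0, 0)]
        return simple_system(pos, charges, chain=["A", "A", "B", "B"])

    def test_non_interacting_neutral_partners_zero(self):
        # neutral, epsilon=0, far apart: every component vanishes
        pos = [(0.0, 0, 0), (500.0, 0, 0)]
        sys = simple_system(pos, [0.0, 0.0], epsilon=0.0)
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        rep = mmgbsa_binding(sys, traj, np.array([0]), np.array([1]),
                             GBParams(gamma_np=0.0))
        row = rep.per_frame.iloc[0]
        for c in ("dE_vdw", "dE_coul", "dG_gb", "dG_np", "dG_total"):
            assert row[c] == pytest.approx(0.0, abs=1e-9)

    def test_two_ion_complex_hand_oracle(self):
        p = GBParams()
        d = 6.0
        sys = simple_system([(0.0, 0, 0), (d, 0, 0)], [1.0, -1.0])
        coords = sys.structure.coords
        traj = Trajectory(coords=coords[None], template=sys.structure)
        rep = mmgbsa_binding(sys, traj, np.array([0]), np.array([1]), p)
        row = rep.per_frame.iloc[0]
        # gas-phase terms
        ec = COULOMB_CONSTANT * 1.0 * -1.0 / d
        sig, eps = 3.4, 0.1
        ev = 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
        assert row["dE_coul"] == pytest.approx(ec, rel=1e-9)
        assert row["dE_vdw"] == pytest.approx(ev, rel=1e-9)
        # GB: complex minus two isolated ions
        radii = effective_born_radii(sys, coords, p)
        e_complex = gb_energy(sys.charge, coords, radii, p)
        iso = sum(
            gb_energy(np.array([q]), np.zeros((1, 3)),
                      np.array([sys.born_radius[i] - p.dielectric_offset]), p)
            for i, q in enumerate(sys.charge)
        )
        assert row["dG_gb"] == pytest.approx(e_complex - iso, abs=1e-8)
        # nonpolar: gamma * (SASA_complex - SASA_r - SASA_l)
        area_c = sasa(coords, sys.rmin_half(), p.probe_radius, p.n_sphere_points).sum()
        area_iso = 2 * 4 * np.pi * (sys.rmin_half()[0] + p.probe_radius) ** 2
        assert row["dG_np"] == pytest.approx(p.gamma_np * (area_c - area_iso), abs=1e-8)
        assert row["dG_total"] == pytest.approx(
            row[["dE_vdw", "dE_coul", "dG_gb", "dG_np"]].sum(), abs=1e-10)

    def test_replica_statistics(self):
        sys = self.two_chain_system(0.0, [0.3, -0.3, 0.2, -0.2])
        coords = sys.structure.coords
        frames = np.stack([coords, coords + 0.1, coords, coords - 0.1])
        traj = Trajectory(coords=frames, template=sys.structure,
                          replica_ids=np.array([0, 0, 1, 1]))
        rep = mmgbsa_binding(sys, traj, np.array([0, 1]), np.array([2, 3]))
        assert rep.summary["n_replicas"] == 2
        assert rep.summary["dG_total_sem"] == pytest.approx(
            rep.summary["dG_total_sd"] / np.sqrt(2))

    def test_overlapping_selections_error(self):
        sys = self.two_chain_system(0.0, [0.0] * 4)
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        with pytest.raises(ValueError, match="overlap"):
            mmgbsa_binding(sys, traj, np.array([0, 1]), np.array([1, 2]))


class TestPerResidueDecomposition:
    def test_symmetric_two_ion_equal_split(self):
        sys = simple_system([(0.0, 0, 0), (5.0, 0, 0)], [1.0, 1.0])
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        df = per_residue_gbsa(sys, traj, np.array([0]), np.array([1]))
        np.testing.assert_allclose(df["dE_coul"].iloc[0], df["dE_coul"].iloc[1], rtol=1e-12)
        np.testing.assert_allclose(df["dG_gb"].iloc[0], df["dG_gb"].iloc[1], rtol=1e-10)

    def test_conservation_residue_sums_equal_total(self):
        rng = np.random.default_rng(21)
        pos = np.vstack([rng.uniform(0, 5, (4, 3)), rng.uniform(0, 5, (3, 3)) + [9.0, 0, 0]])
        q = rng.uniform(-0.5, 0.5, 7)
        sys = simple_system(pos, q, chain=["A"] * 4 + ["B"] * 3)
        traj = Trajectory(coords=pos[None], template=sys.structure)
        sel_r, sel_l = np.arange(4), np.arange(4, 7)
        df = per_residue_gbsa(sys, traj, sel_r, sel_l)
        rep = mmgbsa_binding(sys, traj, sel_r, sel_l)
        for comp in ("dE_vdw", "dE_coul", "dG_gb", "dG_np", "dG_total"):
            assert df[comp].sum() == pytest.approx(rep.per_frame[comp].iloc[0], abs=1e-6)

    def test_zero_charges_zero_polar(self):
        sys = simple_system([(0.0, 0, 0), (6.0, 0, 0)], [0.0, 0.0])
        traj = Trajectory(coords=sys.structure.coords[None], template=sys.structure)
        df = per_residue_gbsa(sys, traj, np.array([0]), np.array([1]))
        assert np.all(df["dG_gb"] == 0.0) and np.all(df["dE_coul"] == 0.0)
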