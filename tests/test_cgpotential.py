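import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demonmd import (PotentialSpec, RestraintSet, SiteModification, System,
                     apply_modification, energy, forces, zinc_restraints)
from demonmd.cgpotential import OverlapError

from conftest import make_chain


class TestEnergy:
    def test_bonded_pair_at_rest_length_has_zero_bond_term(self, pspec):
        s = make_chain([[0, 0, 0], [pspec.bond_r0, 0, 0]])
        _, terms = energy(s, PotentialSpec(lj_epsilon=0.0))
        assert terms["bond"] == pytest.approx(0.0, abs=1e-12)

    def test_single_bead_has_zero_energy(self, pspec):
        s = make_chain([[0, 0, 0]])
        total, _ = energy(s, pspec)
        assert total == 0.0

    def test_three_bead_closed_form(self):
        """Hand-summed bond + angle + (excluded) nonbonded energy."""
        p = PotentialSpec(bond_k=10.0, bond_r0=3.8, angle_k=2.0,
                          angle_theta0=math.pi / 2, lj_epsilon=0.0)
        s = make_chain([[0, 0, 0], [4.0, 0, 0], [4.0, 4.5, 0]])
        total, terms = energy(s, p)
        e_bonds = 0.5 * 10 * (4.0 - 3.8) ** 2 + 0.5 * 10 * (4.5 - 3.8) ** 2
        # the bend is exactly 90 degrees, matching theta0
        assert terms["bond"] == pytest.approx(e_bonds, rel=1e-12)
        assert terms["angle"] == pytest.approx(0.0, abs=1e-12)
        # 1-3 pair is excluded, so no LJ/Coulomb at all
        assert total == pytest.approx(e_bonds, rel=1e-12)

    def test_coulomb_distance_dielectric_closed_form(self):
        # two charged beads, far enough apart that LJ is negligible
        p = PotentialSpec(lj_epsilon=0.0, nonbonded_cutoff=9.0)
        s = make_chain([[0, 0, 0], [100, 100, 100], [0, 0, 6.0]],
                       charges=[1.0, 0.0, -1.0],
                       res_ids=[1, 3, 5])  # non-consecutive: no bonds
        total, terms = energy(s, p)
        expect = 332.0637 / 4.0 * (-1.0) * (1 / 6.0 ** 2 - 1 / 9.0 ** 2)
        assert terms["coulomb"] == pytest.approx(expect, rel=1e-9)

    def test_overlapping_beads_raise(self, pspec):
        s = make_chain([[0, 0, 0], [0, 0, 0]], res_ids=[1, 5])
        with pytest.raises(OverlapError):
            energy(s, pspec)

    def test_rigid_rotation_invariance(self, small_toy, pspec):
        e0, _ = energy(small_toy, pspec)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        rotated = small_toy.with_coords(small_toy.coords @ R.T + [5, -3, 2])
        sys_ = System(rotated, pspec, reference=rotated)
        # the elastic network/angle references must rotate with the frame,
        # so build the system from the rotated structure itself
        e1, _, _ = sys_.energy_forces(rotated.coords)
        sys0 = System(small_toy, pspec)
        e0, _, _ = sys0.energy_forces(small_toy.coords)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_elastic_network_vanishes_on_reference(self, small_toy, pspec):
        _, terms = energy(small_toy, pspec)
        assert terms["elastic_network"] == pytest.approx(0.0, abs=1e-12)
        stretched = small_toy.with_coords(small_toy.coords * 1.02)
        sys_ = System(small_toy, pspec)
        _, _, terms = sys_.energy_forces(stretched.coords)
        assert terms["elastic_network"] > 0


class TestForces:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forces_match_finite_differences(self, small_toy, seed):
        """Analytic gradient oracle on randomized 20-bead systems."""
        p = PotentialSpec(torsions=((0.5, 3, 0.3),))
        s = small_toy.copy()
        rng = np.random.default_rng(seed)
        s.charges[:] = rng.uniform(-0.5, 0.5, s.n_beads)
        x = s.coords + rng.normal(0, 0.3, s.coords.shape)
        sys_ = System(s, p)
        _, F, _ = sys_.energy_forces(x)
        h = 1e-6
        Fn = np.zeros_like(F)
        for i in range(s.n_beads):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                ep, _, _ = sys_.energy_forces(xp)
                em, _, _ = sys_.energy_forces(xm)
                Fn[i, k] = -(ep - em) / (2 * h)
        assert np.max(np.abs(F - Fn)) / np.max(np.abs(Fn)) < 1e-4

    def test_newtons_third_law_on_pair(self, pspec):
        s = make_chain([[0, 0, 0], [0, 0, 4.4]], charges=[0.5, -0.5],
                       res_ids=[1, 5])
        F = forces(s, pspec)
        assert np.allclose(F[0] + F[1], 0.0, atol=1e-10)

    def test_positional_restraint_zero_at_anchor(self, pspec):
        s = make_chain([[0, 0, 0]])
        r = RestraintSet(positional=[(0, np.zeros(3), 10.0)])
        F = forces(s, pspec, r)
        assert np.allclose(F, 0.0)


class TestModifications:
    def test_identity_is_noop(self, small_toy):
        out = apply_modification(small_toy, SiteModification(5, "identity"))
        assert out == small_toy

    def test_pser_reduces_net_charge_by_two(self, parkin_toy):
        before = parkin_toy.net_charge()
        out = apply_modification(parkin_toy, SiteModification(65, "pSer"))
        assert out.net_charge() == pytest.approx(before - 2.0)
        # and grows the bead
        i = np.where(parkin_toy.res_ids == 65)[0][0]
        assert out.radii[i] == pytest.approx(parkin_toy.radii[i] + 0.4)

    def test_s_to_d_reduces_net_charge_by_one(self, parkin_toy):
        before = parkin_toy.net_charge()
        out = apply_modification(parkin_toy, SiteModification(65, "S->D"))
        assert out.net_charge() == pytest.approx(before - 1.0)

    def test_s_to_a_neutralizes_site(self, parkin_toy):
        out = apply_modification(parkin_toy, SiteModification(65, "S->A"))
        i = np.where(parkin_toy.res_ids == 65)[0][0]
        assert out.charges[i] == 0.0

    def test_input_structure_untouched(self, parkin_toy):
        snapshot = parkin_toy.charges.copy()
        apply_modification(parkin_toy, SiteModification(65, "pSer"))
        assert np.array_equal(parkin_toy.charges, snapshot)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown modification"):
            SiteModification(65, "S->W")


class TestZincRestraints:
    def test_four_bead_group_gets_six_pairs(self, small_toy):
        rs = zinc_restraints(small_toy, [[10, 11, 12, 13]])
        assert len(rs.relative) == 6
        assert all(k == 50.0 for *_, k in rs.relative)

    def test_rigid_translation_costs_nothing(self, small_toy, pspec):
        rs = zinc_restraints(small_toy, [[10, 11, 12, 13]])
        p0 = PotentialSpec(bond_k=0, angle_k=0, lj_epsilon=0, en_k=0)
        sys_ = System(small_toy, p0, rs)
        e0, _, t0 = sys_.energy_forces(small_toy.coords)
        e1, _, t1 = sys_.energy_forces(small_toy.coords + [10.0, -4.0, 2.0])
        assert t1["restraint"] == pytest.approx(t0["restraint"], abs=1e-9)

    def test_single_displaced_bead_harmonic_energy(self, small_toy):
        rs = zinc_restraints(small_toy, [[10, 12]])
        rs.torsional = []  # isolate the pair term
        p0 = PotentialSpec(bond_k=0, angle_k=0, lj_epsilon=0, en_k=0)
        sys_ = System(small_toy, p0, rs)
        x = small_toy.coords.copy()
        d = x[10] - x[12]
        x[10] += d / np.linalg.norm(d)  # stretch the pair by exactly 1 A
        _, _, terms = sys_.energy_forces(x)
        assert terms["restraint"] == pytest.approx(0.5 * 50.0, rel=1e-9)

    def test_group_of_one_rejected(self, small_toy):
        with pytest.raises(ValueError):
            zinc_restraints(small_toy, [[4]])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_energy_invariant_under_rototranslation(seed):
    """Property: CG energy without positional anchors is frame-invariant."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 12, (8, 3))
    # keep beads from overlapping
    coords += np.arange(8)[:, None] * [4.0, 0, 0]
    s = make_chain(coords, charges=rng.uniform(-0.4, 0.4, 8))
    p = PotentialSpec()
    sys_ = System(s, p)
    e0, _, _ = sys_.energy_forces(s.coords)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0, 2 * math.pi)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
    moved = s.coords @ R.T + rng.uniform(-20, 20, 3)
    e1, _, _ = sys_.energy_forces(moved)
    assert e1 == pytest.approx(e0, rel=1e-8, abs=1e-8)
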