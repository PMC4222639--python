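import math

import numpy as np
import pytest

from demonmd import (PotentialSpec, Selection, SiteModification, ZoneSpec,
                     apply_modification, apply_selection, ddg_interaction,
                     ddg_mutation, equilibrate_zone, extract, flexibility_zone,
                     physics_zone)
from demonmd.zemu import _apply_zone_torsions, _physics_energy, _zone_torsion_params

from conftest import make_chain


class TestFlexibilityZone:
    def test_site_65_gives_five_residue_window(self, parkin_toy):
        sel = flexibility_zone(parkin_toy, ZoneSpec(site=65))
        assert sel.res_ids == frozenset({63, 64, 65, 66, 67})

    def test_clipped_at_n_terminus(self, parkin_toy):
        sel = flexibility_zone(parkin_toy, ZoneSpec(site=1))
        assert sel.res_ids == frozenset({1, 2, 3})

    def test_clipped_at_c_terminus(self, parkin_toy):
        sel = flexibility_zone(parkin_toy, ZoneSpec(site=465))
        assert sel.res_ids == frozenset({463, 464, 465})

    def test_invalid_site_rejected(self, parkin_toy):
        with pytest.raises(ValueError):
            flexibility_zone(parkin_toy, ZoneSpec(site=999))


class TestPhysicsZone:
    def test_isolated_short_peptide_is_all_inside(self):
        s = make_chain(np.arange(5)[:, None] * [3.8, 0, 0])
        flex = flexibility_zone(s, ZoneSpec(site=3))
        zone = physics_zone(s, flex, cutoff=12.0)
        assert zone.res_ids == frozenset({1, 2, 3, 4, 5})

    def test_distant_residues_excluded(self):
        coords = np.vstack([np.arange(5)[:, None] * [3.8, 0, 0],
                            np.arange(5)[:, None] * [3.8, 0, 0] + [0, 50, 0]])
        s = make_chain(coords, res_ids=[1, 2, 3, 4, 5, 10, 11, 12, 13, 14])
        flex = Selection("flex", {2, 3, 4})
        zone = physics_zone(s, flex, cutoff=12.0)
        assert zone.res_ids == frozenset({1, 2, 3, 4, 5})

    def test_matches_brute_force_all_pairs(self, medium_toy):
        flex = flexibility_zone(medium_toy, ZoneSpec(site=12))
        zone = physics_zone(medium_toy, flex, cutoff=12.0)
        flex_idx = apply_selection(medium_toy, flex)
        expected = set()
        for i in range(medium_toy.n_beads):
            for j in flex_idx:
                if np.linalg.norm(medium_toy.coords[i]
                                  - medium_toy.coords[j]) <= 12.0:
                    expected.add(int(medium_toy.res_ids[i]))
        assert zone.res_ids == frozenset(expected)

    def test_monotone_in_cutoff(self, medium_toy):
        flex = flexibility_zone(medium_toy, ZoneSpec(site=12))
        small = physics_zone(medium_toy, flex, cutoff=8.0)
        large = physics_zone(medium_toy, flex, cutoff=14.0)
        assert small.res_ids <= large.res_ids
        assert flex.res_ids <= small.res_ids


class TestEquilibrateZone:
    def test_outside_beads_bit_identical(self, medium_toy, pspec):
        flex = flexibility_zone(medium_toy, ZoneSpec(site=12))
        phys = physics_zone(medium_toy, flex, 12.0)
        out = equilibrate_zone(medium_toy, flex, phys, pspec)
        flex_idx = set(apply_selection(medium_toy, flex).tolist())
        frozen = [i for i in range(medium_toy.n_beads) if i not in flex_idx]
        assert np.array_equal(out.coords[frozen], medium_toy.coords[frozen])

    def test_energy_never_increases(self, medium_toy, pspec):
        rng = np.random.default_rng(8)
        start = medium_toy.copy()
        flex = flexibility_zone(start, ZoneSpec(site=12))
        phys = physics_zone(start, flex, 12.0)
        idx = apply_selection(start, flex)
        start.coords[idx] += rng.normal(0, 0.4, (len(idx), 3))
        e0 = _physics_energy(start, phys, pspec, reference=start)
        out = equilibrate_zone(start, flex, phys, pspec, reference=start)
        e1 = _physics_energy(out, phys, pspec, reference=start)
        assert e1 <= e0 + 1e-9

    def test_perturbed_torsion_returns_to_minimum(self, pspec):
        """1-D torsion scan oracle on a short peptide analog."""
        s = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                        [11.4, 0, 0], [15.2, 0, 0]])
        p = PotentialSpec(lj_epsilon=0.0, angle_k=3.0, angle_theta0=math.pi)
        flex = Selection("flex", {1, 2, 3, 4, 5})
        phys = Selection("phys", {1, 2, 3, 4, 5})
        idx = np.arange(5)
        pivots = _zone_torsion_params(s, idx)
        bent = s.with_coords(_apply_zone_torsions(
            s.coords, pivots, [0.6] * len(pivots)))
        # scan the first pivot angle to find the 1-D optimum independently
        best_theta, best_e = None, np.inf
        for th in np.linspace(-1.0, 1.0, 401):
            x = _apply_zone_torsions(bent.coords, pivots[:1], [th])
            e = _physics_energy(bent.with_coords(x), phys, p, reference=s)
            if e < best_e:
                best_e, best_theta = e, th
        out = equilibrate_zone(bent, flex, phys, p, reference=s)
        e_out = _physics_energy(out, phys, p, reference=s)
        assert e_out <= best_e + 1e-2


class TestDdgMutation:
    def test_identity_modification_gives_zero(self, medium_toy, pspec):
        res = ddg_mutation(medium_toy, SiteModification(12, "identity"),
                           ZoneSpec(site=12), pspec)
        assert res.ddG == pytest.approx(0.0, abs=1e-6)
        assert res.ddG == res.dG_wt - res.dG_mut

    def test_charge_magnitude_orders_ddg(self, pspec):
        """Electrostatic scoring scales with the site charge in a fixed
        environment (zone frozen to isolate the charge term)."""
        coords = np.vstack([np.arange(5)[:, None] * [3.8, 0, 0],
                            np.arange(5)[:, None] * [3.8, 0, 0] + [0, 5.0, 0]])
        s = make_chain(coords, charges=[0, 0, 0.4, 0, 0,
                                        -0.4, -0.4, -0.4, -0.4, -0.4],
                       res_ids=[1, 2, 3, 4, 5, 20, 21, 22, 23, 24])
        zspec = ZoneSpec(site=3, flex_halfwidth=0)  # single-residue zone: no-op
        d_pser = ddg_mutation(s, SiteModification(3, "pSer"), zspec, pspec)
        d_asp = ddg_mutation(s, SiteModification(3, "S->D"), zspec, pspec)
        assert abs(d_pser.ddG) >= abs(d_asp.ddG)

    def test_antisymmetry_when_equilibration_is_noop(self, pspec):
        s = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]],
                       charges=[0.0, 0.3, 0.0])
        zspec = ZoneSpec(site=2, flex_halfwidth=0)
        fwd = ddg_mutation(s, SiteModification(2, "S->D"), zspec, pspec)
        mut = apply_modification(s, SiteModification(2, "S->D"))
        # reverse the edit by hand and score the opposite direction
        back = mut.copy()
        back.charges[1] += 1.0
        zone = flexibility_zone(mut, zspec)
        phys = physics_zone(mut, zone, zspec.physics_cutoff)
        dG_mut = _physics_energy(mut, phys, pspec, reference=mut)
        dG_back = _physics_energy(back, phys, pspec, reference=back)
        assert dG_back - dG_mut == pytest.approx(-fwd.ddG, rel=1e-9)

    def test_zone_sizes_recorded(self, parkin_toy, pspec):
        res = ddg_mutation(parkin_toy, SiteModification(65, "S->D"),
                           ZoneSpec(site=65), pspec)
        assert res.flex_zone_size == 5
        assert res.physics_zone_size >= 5


class TestDdgInteraction:
    def _split(self, offset):
        a = make_chain(np.arange(4)[:, None] * [3.8, 0, 0])
        b_coords = np.arange(4)[:, None] * [3.8, 0, 0] + [0, offset, 0]
        b = make_chain(b_coords)
        b.serials = b.serials + 10
        b.res_ids = b.res_ids + 10
        ab = make_chain(np.vstack([a.coords, b_coords]),
                        res_ids=list(range(1, 5)) + list(range(11, 15)))
        ab.serials = np.array(list(range(1, 5)) + list(range(11, 15)))
        return ab, a, b

    def test_non_interacting_partners_give_zero(self, pspec):
        ab, a, b = self._split(offset=25.0)  # beyond 2x cutoff
        assert ddg_interaction(ab, a, b, p=pspec) == pytest.approx(0.0, abs=1e-6)

    def test_auxiliary_terms_add_linearly(self, pspec):
        ab, a, b = self._split(offset=25.0)
        v = ddg_interaction(ab, a, b, dG_kon=1.5, dS_sc=0.5, p=pspec)
        assert v == pytest.approx(2.0, abs=1e-6)

    def test_bound_dimer_matches_cross_pair_sum(self, pspec):
        """Interaction energy equals the hand-computed cross-pair nonbonded
        sum for a rigid bound dimer."""
        ab, a, b = self._split(offset=4.5)
        v = ddg_interaction(ab, a, b, p=pspec)
        from demonmd.cgpotential import System
        sys_ab = System(ab, pspec)
        total = 0.0
        rc = pspec.nonbonded_cutoff
        sig = pspec.lj_sigma * (1.9 + 1.9) / 3.8
        for i in range(4):
            for j in range(4, 8):
                r = np.linalg.norm(ab.coords[i] - ab.coords[j])
                if r < rc:
                    sr6 = (sig / r) ** 6
                    sr6c = (sig / rc) ** 6
                    total += 4 * pspec.lj_epsilon * ((sr6 ** 2 - sr6)
                                                     - (sr6c ** 2 - sr6c))
        assert v == pytest.approx(total, rel=1e-9)

    def test_partition_check(self, pspec):
        ab, a, b = self._split(offset=25.0)
        with pytest.raises(ValueError, match="partition"):
            ddg_interaction(ab, a, a, p=pspec)


def test_ddg_invariant_under_rototranslation(parkin_toy, pspec):
    m = SiteModification(65, "S->D")
    zspec = ZoneSpec(site=65)
    base = ddg_mutation(parkin_toy, m, zspec, pspec)
    theta = 0.9
    R = np.array([[math.cos(theta), 0, math.sin(theta)],
                  [0, 1, 0],
                  [-math.sin(theta), 0, math.cos(theta)]])
    moved = parkin_toy.with_coords(parkin_toy.coords @ R.T + [11, -3, 6])
    rotated = ddg_mutation(moved, m, zspec, pspec)
    assert rotated.ddG == pytest.approx(base.ddG, abs=1e-6)
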