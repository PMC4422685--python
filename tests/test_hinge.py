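import numpy as np
import pytest

from apehkit import (
    ChargeProfile,
    Conformer,
    DomainPartition,
    HingeSpec,
    Region,
    TriadSpec,
    clash_count,
    opening_metrics,
    opening_propensity_score,
    opening_series,
    rotate_about_bond,
)
from apehkit.charge_profile import RegionCharge
from apehkit.errors import ConfigurationError
from apehkit.reference import reported_charge_profiles
from apehkit.structures import Structure
from conftest import residue_from_atoms


def _coords(structure):
    return structure.atom_array()[0]


@pytest.fixture()
def toy(bridged_toy):
    return bridged_toy[0]


HINGE = HingeSpec(residue=18, bond="N-CA")


class TestRotation:
    def test_zero_angle_is_identity(self, toy):
        conf = rotate_about_bond(toy, HINGE, 0.0)
        assert np.abs(_coords(conf.structure) - _coords(toy)).max() < 1e-12

    def test_rotation_inverts(self, toy):
        there = rotate_about_bond(toy, HINGE, 37.5)
        back = rotate_about_bond(there.structure, HINGE, -37.5)
        assert np.abs(_coords(back.structure) - _coords(toy)).max() < 1e-6

    def test_full_turn_is_identity(self, toy):
        conf = rotate_about_bond(toy, HINGE, 360.0)
        assert np.abs(_coords(conf.structure) - _coords(toy)).max() < 1e-6

    def test_composition_is_additive(self, toy):
        two_step = rotate_about_bond(
            rotate_about_bond(toy, HINGE, 25.0).structure, HINGE, 30.0)
        one_step = rotate_about_bond(toy, HINGE, 55.0)
        assert np.abs(_coords(two_step.structure) - _coords(one_step.structure)).max() < 1e-6

    def test_hand_checked_90_degrees(self):
        # bond along +z through the origin; a moving atom at (1, 0, 1) must
        # land on (0, 1, 1) after +90 degrees (right-handed)
        res = residue_from_atoms("A", 1, "GLY", {
            "N": (0, 0, 0), "CA": (0, 0, 1), "C": (1, 0, 1)})
        s = Structure("mini", [res])
        conf = rotate_about_bond(s, HingeSpec(residue=1, bond="N-CA"), 90.0)
        moved = conf.structure.residues[0].atom("C").coords
        assert np.allclose(moved, [0, 1, 1], atol=1e-9)

    def test_rigid_body_fidelity(self, toy):
        conf = rotate_about_bond(toy, HINGE, 63.0)
        # pairwise distances within the fixed and within the moving segment
        fixed = slice(0, 14)
        moving = slice(24, 38)
        for seg in (fixed, moving):
            before = np.array([a.coords for r in toy.residues[seg] for a in r.atoms])
            after = np.array([a.coords for r in conf.structure.residues[seg]
                              for a in r.atoms])
            d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
            d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
            assert np.abs(d_before - d_after).max() < 1e-6

    def test_hinge_bond_length_invariant(self, toy):
        res = toy.residue(HINGE.residue)
        before = np.linalg.norm(res.atom("N").coords - res.atom("CA").coords)
        conf = rotate_about_bond(toy, HINGE, 80.0)
        res2 = conf.structure.residue(HINGE.residue)
        after = np.linalg.norm(res2.atom("N").coords - res2.atom("CA").coords)
        assert after == pytest.approx(before, abs=1e-9)

    def test_upstream_atoms_untouched(self, toy):
        conf = rotate_about_bond(toy, HINGE, 45.0)
        for res_in, res_out in zip(toy.residues[:4], conf.structure.residues[:4]):
            for a_in, a_out in zip(res_in.atoms, res_out.atoms):
                assert np.array_equal(a_in.coords, a_out.coords)

    def test_missing_bond_atoms(self):
        res = residue_from_atoms("A", 1, "GLY", {"N": (0, 0, 0)})
        with pytest.raises(ConfigurationError):
            rotate_about_bond(Structure("x", [res]), HingeSpec(1, "N-CA"), 10.0)

    def test_ca_c_bond_moves_only_carbonyl_within_hinge_residue(self, toy):
        conf = rotate_about_bond(toy, HingeSpec(18, "CA-C"), 90.0)
        res_in = toy.residue(18)
        res_out = conf.structure.residue(18)
        assert np.array_equal(res_in.atom("N").coords, res_out.atom("N").coords)
        assert np.array_equal(res_in.atom("CA").coords, res_out.atom("CA").coords)
        assert not np.array_equal(res_in.atom("O").coords, res_out.atom("O").coords)


class TestOpeningSeries:
    def test_monotone_opening_on_designed_toy(self, opening_scenario):
        closed, partition, hinge, triad = opening_scenario
        series = opening_series(closed, hinge, [20, 40, 60, 80], partition, triad,
                                exposure_radius=18.0)
        assert len(series) == 4
        centroids = [c.metrics.centroid_distance for c in series]
        assert all(b > a for a, b in zip(centroids, centroids[1:]))

    def test_exposure_proxy_drops_when_open(self, opening_scenario):
        closed, partition, hinge, triad = opening_scenario
        m_closed = opening_metrics(Conformer(closed, hinge, 0.0), partition, triad,
                                   exposure_radius=18.0)
        m_open = opening_metrics(rotate_about_bond(closed, hinge, 80.0), partition,
                                 triad, exposure_radius=18.0)
        assert m_open.exposure_count < m_closed.exposure_count

    def test_empty_angle_list(self, opening_scenario):
        closed, partition, hinge, triad = opening_scenario
        assert opening_series(closed, hinge, [], partition, triad) == []

    def test_identical_conformers_identical_metrics(self, opening_scenario):
        closed, partition, hinge, triad = opening_scenario
        m1 = opening_metrics(rotate_about_bond(closed, hinge, 40.0), partition, triad)
        m2 = opening_metrics(rotate_about_bond(closed, hinge, 40.0), partition, triad)
        assert m1 == m2

    def test_single_domain_partition_rejected(self, opening_scenario):
        closed, _, hinge, triad = opening_scenario
        single = DomainPartition("x", [Region("N-ter", 1, len(closed))])
        with pytest.raises(ValueError):
            opening_metrics(Conformer(closed, hinge, 0.0), single, triad)


class TestClashCount:
    def test_open_structure_has_none(self, toy):
        assert clash_count(Conformer(toy, HINGE, 0.0)) == 0

    def test_collision_detected(self, opening_scenario):
        closed, partition, hinge, _ = opening_scenario
        # scan for an angle that drives the domains through each other
        counts = [clash_count(rotate_about_bond(closed, hinge, a), threshold=2.5)
                  for a in range(0, 360, 10)]
        assert max(counts) > 0

    def test_zero_threshold(self, toy):
        assert clash_count(Conformer(toy, HINGE, 0.0), threshold=0.0) == 0


def _profile(pid, n_net_counts, c_net_counts):
    per_region = [RegionCharge("N-ter", *n_net_counts), RegionCharge("C-ter", *c_net_counts)]
    total = sum(rc.net for rc in per_region)
    return ChargeProfile(pid, per_region, total)


class TestOpeningPropensity:
    def test_reported_isoform_scores(self):
        ranked = opening_propensity_score(reported_charge_profiles())
        scores = {pid: score for pid, score, _ in ranked}
        # products of the reported domain net charges
        assert scores["APEH-1_Ch"] == 1 * -2 == -2
        assert scores["APEH-1_Tb"] == -6 * -3 == 18
        assert scores["APEH-2_Tb"] == 9 * 7 == 63
        assert scores["APEH-2_Ch"] == 7 * 7 == 49

    def test_attractive_pair_ranks_below_repulsive(self):
        ranked = opening_propensity_score(reported_charge_profiles())
        assert ranked[0][0] == "APEH-1_Ch"  # opposite domain charges: closed-prone
        assert ranked[0][1] < 0 < ranked[1][1]

    def test_zero_net_domain_scores_zero(self):
        prof = _profile("z", (3, 3), (1, 5))  # N-ter net 0
        ranked = opening_propensity_score([prof])
        assert ranked[0][1] == 0

    def test_missing_domain_region(self):
        prof = ChargeProfile("bad", [RegionCharge("N-ter", 1, 2)], 1)
        with pytest.raises(ValueError):
            opening_propensity_score([prof])
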