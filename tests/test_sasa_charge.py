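"""SASA against analytic sphere oracles; charge accounting; salt bridges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbkit.sasa_charge import (
    assembly_charge_delta,
    detect_salt_bridges,
    golden_spiral_points,
    mutation_charge_delta,
    net_formal_charge,
    sasa_decomposition,
    shrake_rupley_sasa,
    trajectory_sasa_decomposition,
)
from ssbkit.structure_io import Atom, StructureModel

from conftest import make_ca_model


def sphere_model(specs):
    """specs: list of (resname, center, radius)."""
    atoms = [
        Atom(i + 1, "CA", "C", resname, i + 1, "A", np.asarray(center, float), radius=r)
        for i, (resname, center, r) in enumerate(specs)
    ]
    return StructureModel(atoms)


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        m = sphere_model([("GLY", (0, 0, 0), 1.6)])
        res = shrake_rupley_sasa(m, probe=1.4, n_points=960)
        assert res.total == pytest.approx(4 * np.pi * 3.0**2, rel=0.005)

    def test_fully_buried_atom(self):
        # small atom caged by 6 large spheres along the axes
        specs = [("GLY", (0, 0, 0), 1.0)]
        for k, axis in enumerate(np.vstack([np.eye(3), -np.eye(3)])):
            specs.append(("GLY", 2.5 * axis, 3.0))
        m = sphere_model(specs)
        res = shrake_rupley_sasa(m, probe=1.4, n_points=960)
        assert res.per_atom[0] == 0.0

    def test_two_spheres_match_cap_formula(self):
        # equal spheres radius r, probe rho, centres d apart: each loses a
        # spherical cap of height h = R - d/2 on the expanded radius R = r + rho
        r, rho, d = 1.6, 1.4, 2.0
        R = r + rho
        h = R - d / 2
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * h
        m = sphere_model([("GLY", (0, 0, 0), r), ("GLY", (d, 0, 0), r)])
        res = shrake_rupley_sasa(m, probe=rho, n_points=960)
        assert res.per_atom[0] == pytest.approx(expected, rel=0.01)
        assert res.per_atom[1] == pytest.approx(expected, rel=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(8)
        centers = rng.normal(scale=4.0, size=(30, 3))
        m = sphere_model([("GLY", c, 1.7) for c in centers])
        a = shrake_rupley_sasa(m, n_points=960).total
        b = shrake_rupley_sasa(m, n_points=3840).total
        assert abs(a - b) / b < 0.02

    def test_additivity_and_validation(self, toy_tetramer):
        res = shrake_rupley_sasa(toy_tetramer, mode="ca_spheres")
        assert res.total == pytest.approx(res.per_atom.sum(), rel=1e-12)
        assert res.total == pytest.approx(sum(res.per_residue.values()), rel=1e-12)
        assert np.all(res.per_atom >= 0)
        with pytest.raises(ValueError):
            shrake_rupley_sasa(toy_tetramer, n_points=8)

    def test_missing_radius_reported(self):
        m = StructureModel([Atom(1, "XX", "ZZ", "GLY", 1, "A", np.zeros(3))])
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(m, mode="vdw")

    def test_golden_spiral_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # quasi-uniform: centroid near origin
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


class TestDecomposition:
    def test_all_glycine_is_neutral(self):
        m = sphere_model([("GLY", (4 * i, 0, 0), 2.0) for i in range(3)])
        dec = sasa_decomposition(shrake_rupley_sasa(m), m)
        assert dec.positive == dec.negative == dec.net_positive == 0.0
        assert dec.total > 0

    def test_single_exposed_lysine_analytic(self):
        m = sphere_model([("LYS", (0, 0, 0), 2.0)])
        dec = sasa_decomposition(shrake_rupley_sasa(m, probe=1.4, n_points=960), m)
        assert dec.positive == pytest.approx(4 * np.pi * 3.4**2, rel=0.005)
        assert dec.net_positive == dec.positive
        assert dec.negative == 0.0

    def test_basic_acidic_swap_negates_net(self, toy_tetramer):
        swap = {"LYS": "GLU", "GLU": "LYS", "ARG": "ASP", "ASP": "ARG"}
        from dataclasses import replace

        swapped = StructureModel(
            [replace(a, residue_name=swap.get(a.residue_name, a.residue_name))
             for a in toy_tetramer.atoms]
        )
        d1 = sasa_decomposition(shrake_rupley_sasa(toy_tetramer, mode="ca_spheres"), toy_tetramer)
        d2 = sasa_decomposition(shrake_rupley_sasa(swapped, mode="ca_spheres"), swapped)
        assert d2.net_positive == pytest.approx(-d1.net_positive, abs=1e-9)
        assert d1.net_positive == pytest.approx(d1.positive - d1.negative, abs=1e-12)

    def test_trajectory_average_has_sd(self, toy_tetramer):
        from ssbkit.synthetic_data import HarmonicTrajSpec, simulate_harmonic_trajectory

        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(12, 0.3, seed=5))
        stats = trajectory_sasa_decomposition(traj, window=0.5, n_points=240)
        assert set(stats) == {"total", "positive", "negative", "net_positive"}
        assert stats["total"][0] > 0 and stats["total"][1] > 0
        m, _s = stats["net_positive"]
        assert m == pytest.approx(stats["positive"][0] - stats["negative"][0], rel=1e-9)


class TestChargeAccounting:
    @pytest.mark.parametrize(
        "seq,expected",
        [("EK", 0), ("KKKKK", 5), ("DDD", -3), ("ACGX", 0), ("KRED", 0)],
    )
    def test_sequence_charges(self, seq, expected):
        assert net_formal_charge(seq) == expected

    def test_illegal_letter(self):
        with pytest.raises(ValueError):
            net_formal_charge("KRB")

    def test_structure_charge(self, toy_tetramer):
        # per chain AEKARDGLSTVE: K+R = +2, E+E+D = -3 -> -1; tetramer -4
        assert net_formal_charge(toy_tetramer) == -4

    @pytest.mark.parametrize(
        "wt,mut,expected", [("E", "K", 2), ("E", "D", 0), ("K", "E", -2), ("A", "R", 1)]
    )
    def test_mutation_delta(self, wt, mut, expected):
        assert mutation_charge_delta(wt, mut) == expected

    def test_mutation_delta_rejects_garbage(self):
        with pytest.raises(ValueError):
            mutation_charge_delta("E", "Z")

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 2), (2, 4), (3, 6), (4, 8)])
    def test_assembly_delta(self, n, expected):
        assert assembly_charge_delta(n, 2) == expected

    def test_assembly_tetramer_contract(self):
        with pytest.raises(ValueError):
            assembly_charge_delta(5, 2)

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=30),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=30))
    def test_charge_linearity(self, a, b):
        assert net_formal_charge(a + b) == net_formal_charge(a) + net_formal_charge(b)


class TestSaltBridges:
    @staticmethod
    def pair_model(distance):
        atoms = [
            Atom(1, "CA", "C", "GLU", 1, "A", np.array([0.0, 0.0, 0.0])),
            Atom(2, "OE1", "O", "GLU", 1, "A", np.array([1.0, 0.0, 0.0])),
            Atom(3, "CA", "C", "LYS", 5, "B", np.array([1.0 + distance, 3.0, 0.0])),
            Atom(4, "NZ", "N", "LYS", 5, "B", np.array([1.0 + distance, 0.0, 0.0])),
        ]
        return StructureModel(atoms)

    def test_engineered_pair_found(self):
        bridges = detect_salt_bridges(self.pair_model(3.0), cutoff=4.0)
        assert len(bridges) == 1
        b = bridges[0]
        assert b.min_distance == pytest.approx(3.0)
        assert b.basic == ("B", 5, "LYS") and b.acidic == ("A", 1, "GLU")
        assert b.inter_chain

    def test_distant_pair_not_found(self):
        assert detect_salt_bridges(self.pair_model(6.0), cutoff=4.0) == []

    def test_missing_sidechain_warns_and_skips(self):
        atoms = [
            Atom(1, "CA", "C", "GLU", 1, "A", np.zeros(3)),
            Atom(2, "CA", "C", "LYS", 2, "A", np.array([2.0, 0, 0])),
            Atom(3, "NZ", "N", "LYS", 2, "A", np.array([2.5, 0, 0])),
        ]
        with pytest.warns(UserWarning, match="GLU"):
            assert detect_salt_bridges(StructureModel(atoms), cutoff=4.0) == []

    def test_matches_brute_force_on_toy_tetramer(self, toy_tetramer_sidechain):
        m = toy_tetramer_sidechain
        got = detect_salt_bridges(m, cutoff=12.0)
        # brute-force all-pairs scan over charged-group atoms
        table = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"},
                 "GLU": {"OE1", "OE2"}, "ASP": {"OD1", "OD2"}}
        groups = {}
        for i, a in enumerate(m.atoms):
            if a.residue_name in table and a.name in table[a.residue_name]:
                groups.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(i)
        coords = m.coords
        expected = set()
        for bk, bi in groups.items():
            if bk[2] not in ("LYS", "ARG"):
                continue
            for ak, ai in groups.items():
                if ak[2] not in ("GLU", "ASP"):
                    continue
                dmin = min(np.linalg.norm(coords[x] - coords[y]) for x in bi for y in ai)
                if dmin <= 12.0:
                    expected.add((bk, ak, round(dmin, 9)))
        assert {(b.basic, b.acidic, round(b.min_distance, 9)) for b in got} == expected
        assert [b.min_distance for b in got] == sorted(b.min_distance for b in got)

    def test_coarse_mode_uses_ca(self, toy_tetramer):
        bridges = detect_salt_bridges(toy_tetramer, coarse=True, coarse_cutoff=8.0)
        for b in bridges:
            assert b.min_distance <= 8.0
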