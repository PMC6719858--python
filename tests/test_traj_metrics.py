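"""Trajectory statistics against independent oracles.

The Kabsch oracle minimizes RMSD numerically over SO(3) (coarse grid +
Nelder–Mead on the rotation vector), sharing no code with the SVD path.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ssbkit.structure_io import TrajectoryEnsemble
from ssbkit.synthetic_data import HarmonicTrajSpec, simulate_harmonic_trajectory
from ssbkit.traj_metrics import (
    ca_deviation_map,
    convergence_check,
    kabsch_superpose,
    pair_mobility_fraction,
    rmsd_series,
    rmsf_profile,
)

from conftest import make_ca_model


def brute_force_min_rmsd(P, Q, n_grid=12):
    """Independent rigid-fit oracle: centred rotation search over SO(3)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    candidates = []
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    for a in grid:
        for b in grid:
            for c in grid:
                v = Rotation.from_euler("zyx", [a, b, c]).as_rotvec()
                candidates.append((cost(v), v))
    candidates.sort(key=lambda t: t[0])
    best = candidates[0][0]
    # polish the few best grid cells to escape local basins
    for val, v in candidates[:8]:
        res = minimize(cost, v, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def rigid(coords, seed=0, angle=None):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix() if angle is None else angle
    return coords @ R.T + rng.normal(size=3)


class TestKabsch:
    def test_identical_sets(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_exact_rigid_motion_recovered(self):
        P = np.random.default_rng(1).normal(size=(10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, Rz, atol=1e-10)
        assert np.allclose(res.apply(P), Q, atol=1e-10)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R = kabsch_superpose(P, Q).rotation
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)

    def test_reflection_case_corrected(self):
        # a mirrored cloud must NOT be matched by an improper rotation
        P = np.random.default_rng(3).normal(size=(12, 3))
        Q = P * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd > 0.1

    def test_degenerate_input_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @pytest.mark.parametrize("n_points", [4, 10, 20])
    def test_matches_rotation_search_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        P = rng.normal(size=(n_points, 3))
        Q = rng.normal(size=(n_points, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(
            brute_force_min_rmsd(P, Q), abs=1e-3
        )

    def test_superposition_optimality(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            P = rng.normal(size=(9, 3))
            Q = rng.normal(size=(9, 3))
            raw = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
            assert kabsch_superpose(P, Q).rmsd <= raw + 1e-12


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(4, 0.0, seed=0))
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigidly_moved_frames_zero_after_superposition(self, toy_tetramer):
        ref = toy_tetramer.coords
        frames = np.stack([ref] + [rigid(ref, seed=s) for s in range(4)])
        traj = TrajectoryEnsemble(toy_tetramer, frames)
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-8)
        assert not np.allclose(rmsd_series(traj, superpose=False)[1:], 0.0, atol=1e-3)

    def test_single_displaced_atom_without_superposition(self):
        # displacing one of n atoms by delta gives raw RMSD delta/sqrt(n)
        n, delta = 16, 1.7
        coords = np.random.default_rng(5).normal(size=(n, 3)) * 5
        model = make_ca_model(coords)
        moved = coords.copy()
        moved[3, 0] += delta
        traj = TrajectoryEnsemble(model, np.stack([coords, moved]))
        series = rmsd_series(traj, superpose=False)
        assert series[1] == pytest.approx(delta / np.sqrt(n), rel=1e-12)
        # re-superposition can only lower it
        assert rmsd_series(traj)[1] <= series[1]


class TestDeviationMap:
    def test_static_map_is_zero(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(6, 0.0, seed=0))
        dm = ca_deviation_map(traj, window=0.5)
        assert np.allclose(dm.matrix, 0.0)
        assert np.allclose(np.diag(dm.matrix), 0.0)
        assert np.allclose(dm.matrix, dm.matrix.T)

    def test_rigid_motion_invariance(self, toy_tetramer):
        ref = toy_tetramer.coords
        frames = np.stack([ref] + [rigid(ref, seed=s) for s in range(5)])
        dm = ca_deviation_map(TrajectoryEnsemble(toy_tetramer, frames), window=0.5)
        assert np.abs(dm.matrix).max() < 1e-9

    def test_displaced_chain_matches_direct_recomputation(self, toy_tetramer):
        ref = toy_tetramer.coords
        shift = np.array([3.0, 0.0, 0.0])
        moved = ref.copy()
        d_mask = np.array([a.chain_id == "d" for a in toy_tetramer.atoms])
        moved[d_mask] += shift
        frames = np.stack([ref, moved, moved])
        dm = ca_deviation_map(TrajectoryEnsemble(toy_tetramer, frames), window=(1, 3))
        labels_chain = dm.chains
        from scipy.spatial.distance import cdist

        expected = cdist(moved, moved) - cdist(ref, ref)
        assert np.allclose(dm.matrix, expected, atol=1e-10)
        intra = np.ix_(labels_chain == "d", labels_chain == "d")
        assert np.abs(dm.matrix[intra]).max() < 1e-10
        cross = np.ix_(labels_chain == "d", labels_chain == "a")
        assert np.abs(dm.matrix[cross]).max() > 0.1

    def test_window_out_of_range(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(5, 0.1, seed=0))
        with pytest.raises(ValueError):
            ca_deviation_map(traj, window=(3, 10))

    def test_requires_single_ca_per_residue(self, toy_tetramer_sidechain):
        traj = simulate_harmonic_trajectory(
            toy_tetramer_sidechain, HarmonicTrajSpec(3, 0.1, seed=0)
        )
        with pytest.raises(ValueError, match="CA"):
            ca_deviation_map(traj)


class TestMobilityFraction:
    @staticmethod
    def _map_from_matrix(matrix, chains):
        from ssbkit.traj_metrics import DeviationMap

        labels = [(c, i + 1) for i, c in enumerate(chains)]
        return DeviationMap(labels, matrix, (0, 1))

    def test_zero_map_fraction_one(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(4, 0.0, seed=0))
        dm = ca_deviation_map(traj, window=0.5)
        for scope in ("intra_monomer", "inter_monomer", "overall"):
            assert pair_mobility_fraction(dm, 2.0, scope).fraction == 1.0

    def test_forced_count_five_residues(self):
        # exactly 3 of the 10 i<j pairs exceed |delta| = 2
        m = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (3, 4)]:
            m[i, j] = m[j, i] = 5.0
        dm = self._map_from_matrix(m, ["A"] * 5)
        res = pair_mobility_fraction(dm, 2.0, "overall")
        assert res.fraction == pytest.approx(0.7)
        assert res.n_pairs == 10

    def test_random_map_matches_brute_force(self):
        rng = np.random.default_rng(11)
        n = 24
        chains = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        sym = rng.normal(scale=2.0, size=(n, n))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 0.0)
        dm = self._map_from_matrix(sym, chains)
        for scope in ("intra_monomer", "inter_monomer", "overall"):
            got = pair_mobility_fraction(dm, 2.0, scope)
            inside = total = 0
            for i in range(n):
                for j in range(i + 1, n):
                    same = chains[i] == chains[j]
                    if scope == "intra_monomer" and not same:
                        continue
                    if scope == "inter_monomer" and same:
                        continue
                    total += 1
                    inside += abs(sym[i, j]) <= 2.0
            assert got.n_pairs == total
            assert got.fraction == pytest.approx(inside / total)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        sym = rng.normal(scale=3.0, size=(10, 10))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 0.0)
        dm = self._map_from_matrix(sym, ["A"] * 10)
        fracs = [pair_mobility_fraction(dm, t, "overall").fraction for t in np.linspace(0.1, 8, 25)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_single_chain_inter_scope_rejected(self):
        dm = self._map_from_matrix(np.zeros((4, 4)), ["A"] * 4)
        with pytest.raises(ValueError):
            pair_mobility_fraction(dm, 2.0, "inter_monomer")


class TestRmsf:
    def test_static_trajectory(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(3, 0.0, seed=0))
        prof = rmsf_profile(traj)
        assert np.allclose(prof.rmsf, 0.0)
        assert np.allclose(prof.normalized_b, 1.0)

    def test_single_frame_rejected(self, toy_tetramer):
        traj = TrajectoryEnsemble(toy_tetramer, toy_tetramer.coords[None])
        with pytest.raises(ValueError):
            rmsf_profile(traj)

    def test_harmonic_sigma_recovered(self, toy_tetramer):
        sigma = 0.5
        traj = simulate_harmonic_trajectory(
            toy_tetramer, HarmonicTrajSpec(4000, sigma, seed=21)
        )
        prof = rmsf_profile(traj, align=False)
        expected = sigma * np.sqrt(3.0)
        assert np.all(np.abs(prof.rmsf - expected) / expected < 0.10)
        assert prof.normalized_b.mean() == pytest.approx(1.0, abs=1e-9)

    def test_b_factor_relation(self, toy_tetramer):
        traj = simulate_harmonic_trajectory(toy_tetramer, HarmonicTrajSpec(200, 0.4, seed=3))
        prof = rmsf_profile(traj)
        assert np.allclose(prof.b_factor, 8 * np.pi**2 / 3 * prof.rmsf**2, rtol=1e-12)


class TestConvergence:
    def test_constant_series(self):
        res = convergence_check(np.full(100, 2.5), window=0.5, tolerance=0.1)
        assert res.converged and res.range == 0.0 and res.mean == pytest.approx(2.5)

    def test_linear_ramp_not_converged(self):
        series = 0.01 * np.arange(3000)
        res = convergence_check(series, window=(2000, 3000), tolerance=1.0)
        assert not res.converged
        assert res.range == pytest.approx(9.99, abs=0.02)

    def test_noisy_plateau_converges(self):
        rng = np.random.default_rng(42)
        series = 3.0 + rng.normal(scale=0.05, size=1000)
        assert convergence_check(series, window=1 / 3, tolerance=0.5).converged

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            convergence_check(np.zeros(100), window=(95, 100), tolerance=1.0)
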