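"""Contact occupancies, masked displacement correlations, interface scoring."""

import numpy as np
import pytest

from conftest import make_trajectory
from allopep.dynamic_network import (
    NoInterfaceError,
    ZeroVarianceError,
    build_contact_network,
    build_edges,
    compute_correlation,
    compute_occupancies,
    interface_mean_correlation,
    masked_correlation,
    rank_interface_stability,
)
from allopep.synthetic_data import TrajectorySpec, generate_trajectory


def brute_force_correlation(x: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle for the normalized displacement
    cross-correlation of representative points x (frames, nodes, 3)."""
    f, n, _ = x.shape
    mean = x.mean(axis=0)
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = vi = vj = 0.0
            for t in range(f):
                di = x[t, i] - mean[i]
                dj = x[t, j] - mean[j]
                num += float(di @ dj)
                vi += float(di @ di)
                vj += float(dj @ dj)
            c[i, j] = num / np.sqrt(vi * vj)
    return c


class TestOccupancy:
    def static_pair(self, distance, n_frames=10):
        coords = np.zeros((n_frames, 2, 3))
        coords[:, 1, 0] = distance
        return make_trajectory(coords, resids=[1, 5])

    def test_static_pair_below_cutoff(self):
        occ = compute_occupancies(self.static_pair(4.0))
        assert occ[0, 1] == 1.0

    def test_boundary_distance_is_excluded(self):
        """Contact requires strictly less than the 4.5 Å cutoff."""
        occ = compute_occupancies(self.static_pair(4.5))
        assert occ[0, 1] == 0.0

    def test_partial_occupancy_counts_frames(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 4.0
        coords[7:, 1, 0] = 6.0  # 3 of 10 frames out of contact
        occ = compute_occupancies(make_trajectory(coords, resids=[1, 5]))
        assert occ[0, 1] == pytest.approx(0.7)

    def test_heavy_atom_minimum_governs(self):
        # representative CAs far apart, but one member atom reaches across
        coords = np.zeros((2, 3, 3))
        coords[:, 1, 0] = 20.0      # CA of residue 5
        coords[:, 2, 0] = 3.0       # CB member of residue 5
        traj = make_trajectory(coords, resids=[1, 5, 5], names=["CA", "CA", "CB"])
        assert compute_occupancies(traj, heavy_atom=True)[0, 1] == 1.0
        assert compute_occupancies(traj, heavy_atom=False)[0, 1] == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_occupancies(self.static_pair(4.0, n_frames=1))

    def test_frame_permutation_invariance(self, rng):
        coords = rng.normal(0, 3, (20, 3, 3))
        traj = make_trajectory(coords, resids=[1, 5, 9])
        perm = make_trajectory(coords[rng.permutation(20)], resids=[1, 5, 9])
        np.testing.assert_allclose(
            compute_occupancies(traj), compute_occupancies(perm)
        )


class TestEdges:
    def occ(self, value):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = value
        return m

    def nodes(self, chains=("A", "A", "A"), resids=(1, 5, 9)):
        import pandas as pd
        return pd.DataFrame({"chain": chains, "resid": resids, "resname": "GLY"})

    def test_threshold_inclusive_at_075(self):
        assert (0, 1) in build_edges(self.occ(0.75), self.nodes())

    def test_below_threshold_excluded(self):
        assert build_edges(self.occ(0.70), self.nodes()) == set()

    def test_sequence_neighbours_never_bond(self):
        nodes = self.nodes(resids=(1, 2, 9))
        assert (0, 1) not in build_edges(self.occ(1.0), nodes)

    def test_cross_chain_neighbours_allowed(self):
        nodes = self.nodes(chains=("A", "B", "B"), resids=(1, 2, 9))
        assert (0, 1) in build_edges(self.occ(1.0), nodes)


class TestCorrelation:
    def test_oracle_equivalence_small_random(self, rng):
        """Matrix form matches the double-loop definition to 1e-12."""
        coords = rng.normal(0, 2, (10, 5, 3))
        traj = make_trajectory(coords, resids=[1, 3, 5, 7, 9])
        c = compute_correlation(traj)
        np.testing.assert_allclose(c, brute_force_correlation(coords), atol=1e-12)

    def test_rigid_translation_fully_correlated(self):
        base = np.arange(9, dtype=float).reshape(3, 3)
        coords = np.stack([base + t * np.array([1.0, 0.5, -0.2]) for t in range(6)])
        traj = make_trajectory(coords, resids=[1, 5, 9])
        np.testing.assert_allclose(compute_correlation(traj), 1.0, atol=1e-12)

    def test_opposite_displacements_anticorrelated(self):
        coords = np.zeros((4, 2, 3))
        steps = np.array([1.0, -1.0, 2.0, -2.0])
        coords[:, 0, 0] = steps
        coords[:, 1, 0] = -steps
        traj = make_trajectory(coords, resids=[1, 5])
        assert compute_correlation(traj)[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        coords = rng.normal(0, 1, (12, 4, 3))
        shifted = coords + np.array([100.0, -50.0, 7.0])
        t1 = make_trajectory(coords, resids=[1, 4, 7, 10])
        t2 = make_trajectory(shifted, resids=[1, 4, 7, 10])
        np.testing.assert_allclose(
            compute_correlation(t1), compute_correlation(t2), atol=1e-10
        )

    def test_zero_variance_node_strict_error(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = np.arange(5.0)
        traj = make_trajectory(coords, resids=[1, 5])
        with pytest.raises(ZeroVarianceError):
            compute_correlation(traj)
        c = compute_correlation(traj, strict=False)
        assert np.isnan(c[0, 1])


class TestMask:
    def test_empty_edge_set_zeroes_offdiagonal(self, rng):
        c = compute_correlation(
            make_trajectory(rng.normal(0, 1, (8, 3, 3)), resids=[1, 5, 9])
        )
        m = masked_correlation(c, set())
        assert np.all(m[~np.eye(3, dtype=bool)] == 0)
        np.testing.assert_allclose(np.diag(m), np.diag(c))

    def test_complete_edge_set_preserves(self, rng):
        c = compute_correlation(
            make_trajectory(rng.normal(0, 1, (8, 3, 3)), resids=[1, 5, 9])
        )
        m = masked_correlation(c, {(0, 1), (0, 2), (1, 2)})
        np.testing.assert_allclose(m, c)

    def test_random_mask_is_elementwise_product(self, rng):
        c = compute_correlation(
            make_trajectory(rng.normal(0, 1, (8, 4, 3)), resids=[1, 4, 7, 10])
        )
        edges = {(0, 2), (1, 3)}
        m = masked_correlation(c, edges)
        indicator = np.eye(4)
        for i, j in edges:
            indicator[i, j] = indicator[j, i] = 1
        np.testing.assert_allclose(m, c * indicator)


class TestInterfaceScore:
    def engineered(self, rho, n_frames=5000, seed=0):
        cov = np.array([[1.0, rho], [rho, 1.0]]) * 0.25
        spec = TrajectorySpec(
            chains={"A": 1, "B": 1}, n_frames=n_frames, covariance=cov,
            contact_targets=((0, 1, 1.0),), seed=seed,
        )
        traj = generate_trajectory(spec)
        return build_contact_network(traj)

    @pytest.mark.parametrize("rho", [-0.9, 0.0, 0.5, 0.9])
    def test_engineered_rho_recovered_within_3se(self, rho):
        """Fisher-z 3-SE band around the generating cross-chain correlation."""
        n_frames = 5000
        net = self.engineered(rho, n_frames=n_frames, seed=42)
        score = interface_mean_correlation(net, "A", "B")
        se_z = 1.0 / np.sqrt(n_frames - 3)
        lo, hi = np.tanh(np.arctanh(rho) + np.array([-3, 3]) * se_z)
        assert lo <= score.mean_correlation <= hi

    def test_two_opposite_edges_average_to_zero(self):
        import pandas as pd
        from allopep.dynamic_network import ContactNetwork
        nodes = pd.DataFrame(
            {"chain": ["A", "A", "B", "B"], "resid": [1, 5, 1, 5], "resname": "GLY"}
        )
        c = np.eye(4)
        c[0, 2] = c[2, 0] = 0.5
        c[1, 3] = c[3, 1] = -0.5
        net = ContactNetwork(nodes=nodes, edges={(0, 2), (1, 3)},
                             occupancy=np.ones((4, 4)), correlation=c)
        assert interface_mean_correlation(net, "A", "B").mean_correlation == pytest.approx(0.0)

    def test_no_cross_chain_edges_raises(self):
        net = self.engineered(0.5, n_frames=100, seed=1)
        with pytest.raises(NoInterfaceError):
            interface_mean_correlation(net, "A", "Z")


class TestStabilityRanking:
    PUBLISHED = {
        "DAALT": 0.31, "YAALQ": 0.27, "RAALG": 0.44,
        "FAALA": 0.39, "KAALE": 0.33, "RAALW": 0.38,
    }

    def test_published_scores_reproduce_published_order(self):
        order = rank_interface_stability(self.PUBLISHED)
        assert order == ["YAALQ", "DAALT", "KAALE", "RAALW", "FAALA", "RAALG"]

    def test_single_condition(self):
        assert rank_interface_stability({"only": 0.2}) == ["only"]

    def test_input_order_invariance(self):
        items = list(self.PUBLISHED.items())
        reordered = dict(reversed(items))
        assert rank_interface_stability(reordered) == rank_interface_stability(self.PUBLISHED)

    def test_ties_break_lexicographically(self):
        assert rank_interface_stability({"b": 0.3, "a": 0.3}) == ["a", "b"]


def test_exports_round_trip(tmp_path, rng):
    import networkx as nx
    coords = rng.normal(0, 1, (20, 3, 3)) + np.array([[0, 0, 0], [3, 0, 0], [30, 0, 0]])
    traj = make_trajectory(coords, chains=["A", "B", "B"], resids=[1, 1, 9])
    net = build_contact_network(traj)
    net.write_edge_list(tmp_path / "edges.tsv")
    net.write_matrix(tmp_path / "c.csv")
    net.write_graphml(tmp_path / "net.graphml")
    g = nx.read_graphml(tmp_path / "net.graphml")
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == len(net.edges)
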