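import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import rinflow as rf
from conftest import (brute_force_betweenness, brute_force_closeness,
                      make_network, random_graph_edges)
from rinflow.rin_centrality import (CONTACT_BB, _bfs_distances,
                                    _dijkstra_distances, betweenness_centrality,
                                    closeness_centrality, degree_centrality)
from rinflow.structure_io import Atom, StructureModel


def star(n=5):
    return make_network(n, [(0, i) for i in range(1, n)])


def path(n=4):
    return make_network(n, [(i, i + 1) for i in range(n - 1)])


def cycle(n=5):
    return make_network(n, [(i, (i + 1) % n) for i in range(n)])


def complete(n=5):
    return make_network(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


class TestClosedForms:
    def test_star_hub(self):
        net = star(5)
        assert closeness_centrality(net)[0] == pytest.approx(1.0)
        assert betweenness_centrality(net)[0] == pytest.approx(1.0)

    def test_star_leaf_closeness(self):
        # leaf distances 1,2,2,2 -> C_C = 4/7
        assert closeness_centrality(star(5))[1] == pytest.approx(4.0 / 7.0)

    def test_path_end_closeness(self):
        # end node of 0-1-2: distances 1,2 -> C_C = 2/3
        assert closeness_centrality(path(3))[0] == pytest.approx(2.0 / 3.0)

    def test_path_inner_betweenness(self):
        # node 1 of 0-1-2-3 carries pairs (0,2) and (0,3): 2 * 2/6 = 2/3
        assert betweenness_centrality(path(4))[1] == pytest.approx(2.0 / 3.0)

    def test_five_cycle_betweenness(self):
        np.testing.assert_allclose(betweenness_centrality(cycle(5)),
                                   1.0 / 6.0, atol=1e-12)

    def test_complete_graph_degrees(self):
        raw, norm = degree_centrality(complete(5))
        np.testing.assert_array_equal(raw, 4)
        np.testing.assert_allclose(norm, 1.0)

    def test_degree_one_node_zero_betweenness(self):
        assert betweenness_centrality(star(5))[1] == 0.0

    def test_handshake_lemma(self):
        rng = np.random.default_rng(0)
        edges = random_graph_edges(10, 0.4, rng)
        raw, _ = degree_centrality(make_network(10, edges))
        assert raw.sum() == 2 * len(edges)

    def test_isolated_node_degree_zero(self):
        net = make_network(4, [(0, 1), (1, 2)])
        raw, _ = degree_centrality(net)
        assert raw[3] == 0


class TestOracleEquivalence:
    def test_brandes_matches_enumeration_on_random_graphs(self):
        """Betweenness by Brandes accumulation equals explicit geodesic
        enumeration, exactly."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            edges = random_graph_edges(n, float(rng.uniform(0.2, 0.7)), rng)
            net = make_network(n, edges)
            if n < 3:
                continue
            cb = betweenness_centrality(net)
            np.testing.assert_allclose(cb, brute_force_betweenness(n, edges),
                                       atol=1e-12)

    def test_closeness_matches_bfs_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            edges = random_graph_edges(n, float(rng.uniform(0.2, 0.7)), rng)
            net = make_network(n, edges)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cc = closeness_centrality(net)
            np.testing.assert_allclose(cc, brute_force_closeness(n, edges),
                                       atol=1e-12)

    def test_matches_networkx(self):
        """Independent library cross-check on a random connected graph."""
        rng = np.random.default_rng(44)
        while True:
            edges = random_graph_edges(9, 0.4, rng)
            g = nx.Graph(edges)
            g.add_nodes_from(range(9))
            if nx.is_connected(g):
                break
        net = make_network(9, edges)
        nx_cb = np.array([v for _, v in sorted(nx.betweenness_centrality(g).items())])
        nx_cc = np.array([v for _, v in sorted(nx.closeness_centrality(g).items())])
        np.testing.assert_allclose(betweenness_centrality(net), nx_cb, atol=1e-12)
        np.testing.assert_allclose(closeness_centrality(net), nx_cc, atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(3, 10), st.integers(0, 10 ** 6))
    def test_betweenness_matches_networkx_property(self, n, graph_seed):
        rng = np.random.default_rng(graph_seed)
        edges = random_graph_edges(n, 0.45, rng)
        net = make_network(n, edges)
        g = nx.Graph(edges)
        g.add_nodes_from(range(n))
        nx_cb = np.array([v for _, v in sorted(nx.betweenness_centrality(g).items())])
        np.testing.assert_allclose(betweenness_centrality(net), nx_cb,
                                   atol=1e-12)

    def test_dijkstra_equals_bfs_on_unit_weights(self):
        rng = np.random.default_rng(45)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            net = make_network(n, random_graph_edges(n, 0.4, rng))
            adj = net.adjacency()
            for s in range(n):
                np.testing.assert_array_equal(_bfs_distances(adj, s),
                                              _dijkstra_distances(adj, s))

    def test_weighted_betweenness_matches_networkx(self):
        rng = np.random.default_rng(46)
        edges = random_graph_edges(8, 0.5, rng)
        net = make_network(8, edges)
        for e in net.edges:
            e.hbond_count = int(rng.integers(0, 4))
        g = nx.Graph()
        g.add_nodes_from(range(8))
        for e in net.edges:
            g.add_edge(e.i, e.j, length=1.0 / (1.0 + e.hbond_count))
        nx_cb = np.array([v for _, v in sorted(
            nx.betweenness_centrality(g, weight="length").items())])
        ours = betweenness_centrality(net, weights="inverse-hbond")
        np.testing.assert_allclose(ours, nx_cb, atol=1e-9)


class TestBuildRin:
    def _two_residue_model(self, ca_sep, with_cb=False, cb_pos=None):
        atoms = [Atom(serial=1, name="CA", element="C", residue_index=0,
                      residue_name="GLY", chain_id="A",
                      position=[0.0, 0, 0], res_seq=1),
                 Atom(serial=2, name="CA", element="C", residue_index=1,
                      residue_name="GLY", chain_id="A",
                      position=[ca_sep, 0, 0], res_seq=2)]
        if with_cb:
            atoms[0] = Atom(serial=1, name="CA", element="C", residue_index=0,
                            residue_name="ALA", chain_id="A",
                            position=[0.0, 0, 0], res_seq=1)
            atoms.insert(1, Atom(serial=3, name="CB", element="C",
                                 residue_index=0, residue_name="ALA",
                                 chain_id="A", position=cb_pos, res_seq=1))
        return StructureModel(atoms)

    def test_backbone_contact_only(self):
        model = self._two_residue_model(6.5)
        net = rf.build_rin(model, cutoff=7.0)
        assert len(net.edges) == 1
        assert net.edges[0].contact_types == frozenset({CONTACT_BB})
        assert net.edges[0].min_center_distance == pytest.approx(6.5)

    def test_no_edge_beyond_cutoff(self):
        net = rf.build_rin(self._two_residue_model(7.5), cutoff=7.0)
        assert net.edges == []

    def test_cutoff_is_strict(self):
        net = rf.build_rin(self._two_residue_model(7.0), cutoff=7.0)
        assert net.edges == []

    def test_sidechain_contact_bridges_remote_backbones(self):
        # CA-CA 9 A apart but residue 0's CB reaches residue 1
        model = self._two_residue_model(9.0, with_cb=True, cb_pos=[5.0, 0, 0])
        net = rf.build_rin(model, cutoff=7.0)
        assert len(net.edges) == 1
        assert net.edges[0].contact_types == frozenset({"backbone-sidechain"})

    def test_designed_hbond_pair_weights_edge(self):
        ens = rf.generate_ensemble(rf.EnsembleSpec(
            n_residues=4, n_frames=2, fluctuation_profile=0.0,
            hbond_pairs=(rf.HBondPairSpec(0, 1, 1.0),), seed=0))
        model = ens.frame_model(0)
        net = rf.build_rin(model, cutoff=7.0)
        e01 = [e for e in net.edges
               if {net.nodes[e.i].residue_index,
                   net.nodes[e.j].residue_index} == {0, 1}]
        assert len(e01) == 1
        assert e01[0].hbond_count >= 1

    def test_edges_invariant_under_rigid_motion(self, hub_model):
        net = rf.build_rin(hub_model, cutoff=7.0)
        rot = Rotation.from_euler("zyx", [101, -33, 7], degrees=True).as_matrix()
        moved = hub_model.with_coords(hub_model.coords @ rot.T + [10.0, -3.0, 5.0])
        net2 = rf.build_rin(moved, cutoff=7.0)
        assert {(e.i, e.j) for e in net.edges} == {(e.i, e.j) for e in net2.edges}

    def test_exclude_neighbors_drops_sequence_contacts(self, static_ensemble):
        model = static_ensemble.topology.with_coords(static_ensemble.frames[0])
        full = rf.build_rin(model, cutoff=7.0)
        pruned = rf.build_rin(model, cutoff=7.0, exclude_neighbors=1)
        assert len(pruned.edges) < len(full.edges)
        for e in pruned.edges:
            assert abs(net_res(pruned, e.i) - net_res(pruned, e.j)) > 1

    def test_bad_cutoff(self, hub_model):
        with pytest.raises(ValueError, match="cutoff"):
            rf.build_rin(hub_model, cutoff=0.0)


def net_res(net, i):
    return net.nodes[i].residue_index


class TestTablesAndDiffs:
    def test_cycle_correlations_undefined(self):
        table = rf.centrality_table(cycle(6))
        assert table.correlations.isna().all().all()

    def test_hub_ranks_first_by_betweenness(self, hub_model):
        table = rf.centrality_table(rf.build_rin(hub_model, cutoff=7.0))
        top = table.table.sort_values("c_b", ascending=False).iloc[0]
        assert top["residue"] == "G5"  # hub residue (author numbering 5)

    def test_correlations_bounded(self):
        rng = np.random.default_rng(47)
        net = make_network(10, random_graph_edges(10, 0.45, rng))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rf.centrality_table(net)
        vals = table.correlations.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.all(finite >= -1.0 - 1e-12)
        assert np.all(finite <= 1.0 + 1e-12)

    def test_threshold_report_filters_and_sorts(self):
        table = rf.centrality_table(star(6))
        report = rf.threshold_report(table, cb_min=0.05)
        assert list(report["residue"]) == ["G1"]
        assert report.attrs["percentile"] == pytest.approx(100 * 5 / 6)
        empty = rf.threshold_report(table, cb_min=1.5)
        assert empty.empty

    def test_diff_identical_states_no_flags(self):
        t = rf.centrality_table(star(6))
        d = rf.centrality_diff(t, t)
        assert (d.table["abs_diff"] == 0).all()
        assert not d.table["flag_0.02"].any()

    def test_diff_arithmetic_and_flag_implication(self):
        a = rf.centrality_table(path(5))
        b = rf.centrality_table(star(5))
        d = rf.centrality_diff(a, b, threshold=0.02, map_threshold=0.03)
        implied = d.table["flag_0.03"] & ~d.table["flag_0.02"]
        assert not implied.any()
        manual = (a.table.set_index("residue")["c_b"]
                  - b.table.set_index("residue")["c_b"]).abs()
        for _, row in d.table.iterrows():
            assert row["abs_diff"] == pytest.approx(manual[row["residue"]])

    def test_diff_symmetric(self):
        a = rf.centrality_table(path(5))
        b = rf.centrality_table(star(5))
        dab = rf.centrality_diff(a, b).table.set_index("residue")["abs_diff"]
        dba = rf.centrality_diff(b, a).table.set_index("residue")["abs_diff"]
        np.testing.assert_allclose(dab.sort_index(), dba.sort_index())

    def test_disjoint_states_error(self):
        a = rf.centrality_table(star(4))
        b = rf.centrality_table(star(4))
        b.table["residue"] = [f"X{i}" for i in range(4)]
        with pytest.raises(ValueError, match="no residues"):
            rf.centrality_diff(a, b)
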