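import numpy as np
import pytest

from tcquant.trajectory import (
    Trajectory,
    align_cells,
    build_transition_graph,
    infer_trajectories,
    pseudotime,
)


def _p_from_pairs(rows):
    """Build a membership matrix from (argmax, second, p1, p2) tuples."""
    k = max(max(r[0], r[1]) for r in rows) + 1
    P = np.zeros((len(rows), k))
    for i, (a, b, pa, pb) in enumerate(rows):
        P[i, a], P[i, b] = pa, pb
        rest = 1.0 - pa - pb
        others = [j for j in range(k) if j not in (a, b)]
        for j in others:
            P[i, j] = rest / len(others) if others else 0.0
    return P


class TestTransitionGraph:
    def test_counts_attributed_to_top_two_pair(self):
        P = _p_from_pairs([(0, 1, 0.5, 0.4)] * 3 + [(2, 1, 0.9, 0.05)])
        g = build_transition_graph(P, np.array([True, True, True, False]))
        assert g.tc_counts[0, 1] == 3
        assert g.tc_counts.sum() == 6  # symmetric storage
        assert g.tc_fraction[0, 1] == pytest.approx(3 / 4)
        assert np.all(np.diag(g.tc_counts) == 0)

    def test_hub_cluster_is_ics_candidate(self):
        P = _p_from_pairs([(1, 0, 0.5, 0.4), (1, 2, 0.5, 0.4)])
        g = build_transition_graph(P, np.array([True, True]))
        assert g.ics_candidates == [1]

    def test_no_tc_gives_empty_graph(self):
        P = _p_from_pairs([(0, 1, 0.9, 0.05), (2, 1, 0.9, 0.05)])
        g = build_transition_graph(P, np.zeros(2, dtype=bool))
        assert g.tc_counts.sum() == 0
        assert g.neighbors.number_of_edges() == 0
        assert g.ics_candidates == []


class TestInferTrajectories:
    def test_linear_chain_collects_everyone(self):
        # E(0) - I(1) - M(2) linear topology
        P = _p_from_pairs(
            [(0, 1, 0.9, 0.05), (0, 1, 0.55, 0.4), (1, 0, 0.6, 0.35),
             (1, 2, 0.55, 0.4), (2, 1, 0.6, 0.35), (2, 1, 0.95, 0.03)]
        )
        tc = np.array([False, True, True, True, True, False])
        g = build_transition_graph(P, tc)
        trajs = infer_trajectories(g, 0, P, tc)
        best = trajs[0]
        assert best.cluster_path == [0, 1, 2]
        assert best.probability == 1.0

    def test_branched_graph_enumerates_both_routes(self):
        # edges: E-I1, I1-I2, I1-QM, I2-QM (QM reachable two ways)
        pairs = [(0, 1), (1, 2), (1, 3), (2, 3)]
        rows, tc = [], []
        for a, b in pairs:
            rows.append((a, b, 0.5, 0.45))
            tc.append(True)
        P = _p_from_pairs(rows)
        g = build_transition_graph(P, np.array(tc))
        paths = [t.cluster_path for t in infer_trajectories(g, 0, P, np.array(tc))]
        assert [0, 1, 2, 3] in paths
        assert [0, 1, 3] in paths

    def test_probability_counts_fraction_of_cells(self):
        rows = [(0, 1, 0.9, 0.05)] * 45 + [(1, 0, 0.9, 0.05)] * 45 + [(2, 0, 0.9, 0.05)] * 10
        P = _p_from_pairs(rows)
        tc = np.zeros(100, dtype=bool)
        tc[:2] = True  # a couple of TC on the 0-1 edge
        g = build_transition_graph(P, tc)
        trajs = infer_trajectories(g, 0, P, tc)
        assert trajs[0].cluster_path == [0, 1]
        assert trajs[0].probability == pytest.approx(0.90)

    def test_isolated_initial_cluster_yields_single_cluster_path(self):
        P = _p_from_pairs([(0, 1, 0.9, 0.05), (1, 0, 0.9, 0.05)])
        g = build_transition_graph(P, np.zeros(2, dtype=bool))
        trajs = infer_trajectories(g, 0, P, np.zeros(2, dtype=bool))
        assert trajs[0].cluster_path == [0]


class TestAlignCells:
    def test_membership_and_cpi_ordering(self):
        # two clusters; expected order A, B, C, D
        P = np.array([[0.9, 0.1], [0.6, 0.4], [0.3, 0.7], [0.05, 0.95]])
        cpi_v = np.array([0.15, 0.45, 0.4, 0.1])
        order, seg = align_cells(P, cpi_v, [0, 1])
        assert order == [0, 1, 2, 3]
        assert all(seg[c] == 0 for c in order)

    def test_start_cell_leads_the_ordering(self):
        P = np.array([[0.7, 0.3], [0.95, 0.05], [0.2, 0.8]])
        cpi_v = np.array([0.5, 0.9, 0.2])  # start cell has higher CPI but leads anyway
        order, _ = align_cells(P, cpi_v, [0, 1])
        assert order[0] == 1  # argmax of P[:, 0]

    def test_one_hot_cells_ordered_stably(self):
        P = np.tile([1.0, 0.0], (4, 1))
        order, _ = align_cells(P, np.zeros(4), [0, 1])
        assert order == [0, 1, 2, 3]


class TestPseudotime:
    def _traj(self, order, segs, path=(0, 1)):
        t = Trajectory(cluster_path=list(path), cell_order=order, probability=1.0)
        t.segment_of_cell = dict(zip(order, segs))
        return t

    def test_cumulative_distance_along_collinear_cells(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        traj = self._traj([0, 1, 2], [0, 0, 0])
        pt = pseudotime(coords, [traj])
        # one segment -> min-max scaled to [0, 1]; raw values 0, 1, 3
        np.testing.assert_allclose(pt, [0.0, 1 / 3, 1.0])
        np.testing.assert_allclose(traj.pseudotime, [0.0, 1 / 3, 1.0])

    def test_single_segment_spans_unit_interval(self, rng):
        coords = rng.normal(size=(6, 2))
        traj = self._traj(list(range(6)), [0] * 6)
        pt = pseudotime(coords, [traj])
        assert pt.min() == pytest.approx(0.0)
        assert pt.max() == pytest.approx(1.0)

    def test_cell_on_two_trajectories_keeps_minimum(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        t1 = self._traj([0, 1, 2], [0, 0, 0])
        t2 = self._traj([3, 2], [0, 0])  # shares cell 2, different scaling
        pt = pseudotime(coords, [t1, t2])
        v1 = (2 - 0) / 2  # scaled position of cell 2 in t1 -> 1.0
        v2 = 1.0  # end of t2 -> 1.0
        assert pt[2] == pytest.approx(min(v1, v2))

    def test_cell_on_no_trajectory_is_missing(self):
        coords = np.zeros((3, 2))
        traj = self._traj([0, 1], [0, 0])
        pt = pseudotime(coords, [traj])
        assert np.isnan(pt[2])

    def test_direct_mode_uses_straight_line_distance(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        traj = self._traj([0, 1, 2], [0, 0, 0])
        pt = pseudotime(coords, [traj], mode="direct")
        raw = [0.0, 1.0, np.sqrt(2)]
        np.testing.assert_allclose(pt, (np.array(raw)) / raw[-1])


class TestOnSimulatorData:
    def test_emt_axis_topology_recovered(self, sim_snapshot, tmp_path):
        """The main trajectory visits the four states in EMT order."""
        import collections

        from tcquant.pipeline import RunConfig, run_quantc

        out = run_quantc(
            RunConfig(seed=5, out_dir=str(tmp_path / "run")), X=sim_snapshot
        )
        sc = out["soft"]
        truth = sim_snapshot.metadata.loc[sc.cell_names]["phenotype"].to_numpy()
        maj = {
            c: collections.Counter(truth[sc.hard_labels == c]).most_common(1)[0][0]
            for c in range(out["k"])
        }
        top = out["trajectories"][0]
        path = [maj[c] for c in top.cluster_path]
        assert path in (["E", "I1", "I2", "M"], ["M", "I2", "I1", "E"])
        assert top.probability > 0.9
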