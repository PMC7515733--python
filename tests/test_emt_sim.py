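import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcquant import emt_sim
from tcquant.emt_sim import (
    CellAgent,
    RegulatoryNetwork,
    SimulationConfig,
    classify_phenotype,
    default_network,
    divide,
    integrate_cell,
    integrate_cells,
    run_simulation,
    steady_states,
)


class TestSteadyStates:
    def test_four_stable_attractors(self, attractors):
        assert len(attractors) == 4
        for a in attractors:
            assert a.eigenvalues.real.max() < 0

    def test_phenotype_labels_by_ecad_vim_dominance(self, attractors):
        by = {a.phenotype: a.state for a in attractors}
        assert set(by) == {"E", "I1", "I2", "M"}
        ie = emt_sim.SPECIES.index("Ecad")
        iv = emt_sim.SPECIES.index("Vim")
        assert by["E"][ie] == max(s[ie] for s in by.values())
        assert by["M"][iv] == max(s[iv] for s in by.values())
        assert by["I1"][ie] > by["I1"][iv]  # Ecad-dominant hybrid
        assert by["I2"][iv] > by["I2"][ie]  # Vim-dominant hybrid

    def test_attractor_is_its_own_limit(self, attractors):
        net = default_network()
        rng = np.random.default_rng(0)
        y = integrate_cell(attractors[0].state, net, dt=0.5, sigma=0.0, duration=500.0, rng=rng)
        assert np.linalg.norm(y - attractors[0].state) < 1e-3

    def test_network_round_trips_through_yaml(self, tmp_path):
        net = default_network()
        net.to_yaml(tmp_path / "net.yaml")
        net2 = RegulatoryNetwork.from_yaml(tmp_path / "net.yaml")
        assert net2.parameters == net.parameters
        assert net2.species_names == net.species_names


class TestIntegration:
    def test_zero_noise_matches_reference_ode_solver(self, attractors):
        """Deterministic Euler converges to a high-accuracy reference with
        first-order error in the step size."""
        net = default_network()
        y0 = attractors[0].state * 1.5 + 0.1
        rng = np.random.default_rng(0)
        ref = solve_ivp(
            lambda t, y: net.rhs(y), (0.0, 50.0), y0, rtol=1e-10, atol=1e-12
        ).y[:, -1]
        errs = []
        for dt in (1.0, 0.5):
            y = integrate_cell(y0.copy(), net, dt=dt, sigma=0.0, duration=50.0, rng=rng)
            errs.append(np.linalg.norm(y - ref))
        assert errs[0] < 0.05
        assert errs[1] < 0.75 * errs[0]  # shrinks roughly linearly with dt

    def test_seeded_runs_bit_identical(self, attractors):
        net = default_network()
        y0 = attractors[1].state
        a = integrate_cell(y0, net, 0.1, 0.05, 10.0, np.random.default_rng(42))
        b = integrate_cell(y0, net, 0.1, 0.05, 10.0, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_states_stay_non_negative(self, attractors):
        net = default_network()
        rng = np.random.default_rng(3)
        y = integrate_cells(
            np.stack([a.state for a in attractors]), net, 0.1, 0.5, 20.0, rng
        )
        assert np.all(y >= 0)

    def test_invalid_dt_rejected(self, attractors):
        with pytest.raises(ValueError):
            integrate_cell(attractors[0].state, default_network(), 0.0, 0.0, 1.0, np.random.default_rng(0))


class TestDivision:
    def _cell(self, state):
        return CellAgent(
            id=0, parent_id=None, state=np.asarray(state, dtype=float),
            divisions_remaining=3, birth_time=0.0, next_division_time=700.0,
        )

    def test_daughters_symmetric_about_mother(self):
        rng = np.random.default_rng(0)
        state = np.full(18, 2.0)
        d1, d2 = divide(self._cell(state), rng, noise_sd=0.1)
        unclamped = (d1 > 0) & (d2 > 0)
        np.testing.assert_allclose((d1 + d2)[unclamped], 2.0 * state[unclamped])

    def test_zero_noise_gives_identical_daughters(self):
        rng = np.random.default_rng(0)
        d1, d2 = divide(self._cell(np.ones(18)), rng, noise_sd=0.0)
        np.testing.assert_array_equal(d1, d2)

    def test_noise_magnitude_matches_configured_sd(self):
        # small sd keeps clamping at zero out of play, so the sampled
        # noise-to-expression ratio reflects the configured scale directly
        rng = np.random.default_rng(1)
        state = np.ones(4)
        ratios = []
        for _ in range(2500):
            d1, _ = divide(
                CellAgent(0, None, state, 1, 0.0, 0.0), rng, noise_sd=0.2
            )
            ratios.extend(d1 - state)  # = noise/state since state = 1
        assert np.std(ratios) == pytest.approx(0.2, rel=0.05)

    def test_exhausted_budget_rejected(self):
        cell = self._cell(np.ones(18))
        cell.divisions_remaining = 0
        with pytest.raises(ValueError):
            divide(cell, np.random.default_rng(0))


class TestClassify:
    def test_exact_attractor_gets_its_label(self, attractors):
        for a in attractors:
            assert classify_phenotype(a.state, attractors) == a.phenotype

    def test_far_midpoint_is_tc(self, attractors):
        mid = (attractors[0].state + attractors[-1].state) / 2.0
        assert classify_phenotype(mid, attractors) == "TC"

    def test_shrinking_radius_monotonically_increases_tc(self, attractors, rng):
        pts = np.stack([a.state for a in attractors]).repeat(5, axis=0)
        pts = pts * rng.uniform(0.7, 1.3, size=pts.shape)
        counts = []
        for r in (2.0, 1.0, 0.5, 0.25, 0.1):
            labels = classify_phenotype(pts, attractors, radius=r)
            counts.append(np.sum(labels == "TC"))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestRunSimulation:
    def test_no_noise_no_division_keeps_initial_states(self):
        cfg = SimulationConfig(
            n_initial={"E": 3, "M": 3},
            division_budget_min=0, division_budget_max=0,
            death_time_mean=1e9, death_time_sd=1.0,
            sde_sigma=0.0, n_cycles=1, dt=1.0, seed=0,
        )
        res = run_simulation(cfg)
        snap = res.snapshots[0]
        assert snap.n_cells == 6
        by = {a.phenotype: a.state for a in res.attractors}
        for name in snap.cell_names:
            state = snap.values[:, snap.cell_names.index(name)]
            pheno = snap.metadata.loc[name, "phenotype"]
            np.testing.assert_allclose(state, by[pheno], atol=1e-6)

    def test_lineage_is_consistent(self, sim_result):
        lin = sim_result.lineage
        assert lin["id"].is_unique
        known = set(lin["id"])
        nonroot = lin[lin["parent"] >= 0]
        assert set(nonroot["parent"]).issubset(known)
        # parents are born before their daughters
        birth = dict(zip(lin["id"], lin["birth_time"]))
        assert all(birth[p] < b for p, b in zip(nonroot["parent"], nonroot["birth_time"]))

    def test_population_grows_over_one_cycle(self, sim_result):
        assert sim_result.snapshots[0].n_cells > 200

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(n_initial={"E": 5, "M": 5}, n_cycles=1, seed=9, dt=0.5)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        np.testing.assert_array_equal(a.snapshots[0].values, b.snapshots[0].values)
        assert a.snapshots[0].cell_names == b.snapshots[0].cell_names

    def test_non_proliferative_state_never_divides(self):
        cfg = SimulationConfig(
            n_initial={"E": 20, "I1": 20},
            proliferating_phenotypes=frozenset({"E", "I2", "M"}),
            n_cycles=2, seed=4, dt=0.5,
        )
        res = run_simulation(cfg)
        assert not (res.lineage["parent_phenotype"] == "I1").any()
        assert (res.lineage["parent_phenotype"] == "E").any()
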