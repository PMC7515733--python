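"""Multiscale agent-based EMT simulator.

Each cell carries an 18-species gene-regulatory state evolved by an
Euler-Maruyama discretization of

    dI = f(I) dt + sigma * I * dW        (multiplicative noise per species)

where f is a deterministic EMT circuit: three cascaded bistable switch
modules (SNAIL, ZEB and TWIST, each a self-activating factor in a
double-negative loop with its microRNA antagonist, gated by the factor
upstream) driven by a TGF-beta input, plus epithelial (Ecad, Grhl2, Ovol2,
Klf4, Esrp1, Crb3, miR-34, miR-200, miR-1199) and mesenchymal (Vim, Ncad,
Fn1, Mmp9, Slug) readouts.  At the default parameterization the circuit has
exactly four stable steady states ordered along the epithelial-mesenchymal
axis: E (highest Ecad), I1 (Ecad-dominant hybrid), I2 (Vim-dominant hybrid)
and M (highest Vim).  Cells close to no attractor are transition cells (TC).

On top of the gene dynamics, cells divide at normally distributed intervals
with a per-lineage division budget, daughters inherit the mother state with
a large symmetric multiplicative perturbation (the main source of state
transitions), and budget-exhausted cells die after a normally distributed
delay.  The network is plain data (names, parameters) so an alternative
published parameterization can be dropped in from YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "CellAgent",
    "SimulationConfig",
    "SimulationResult",
    "default_network",
    "steady_states",
    "integrate_cells",
    "integrate_cell",
    "divide",
    "classify_phenotype",
    "run_simulation",
]

SPECIES = [
    "Tgfb", "Snail", "miR34", "Slug", "Zeb", "miR200", "Twist", "Grhl2",
    "Ovol2", "Klf4", "Ecad", "Vim", "Ncad", "Fn1", "Esrp1", "Mmp9", "Crb3",
    "miR1199",
]
_I = {s: i for i, s in enumerate(SPECIES)}

#: default circuit parameters; all rates are per hour via the shared
#: degradation constant ``lambda`` (protein half-life ~35 h).
DEFAULT_PARAMS: dict[str, float] = {
    "lambda": 0.03,      # first-order decay rate, 1/h
    "signal": 1.5,       # external TGF-beta level
    "switch_basal": 0.32,  # leaky production of switch factors
    "switch_max": 2.0,   # self-activation strength (bistable with basal)
    "switch_K": 1.0,
    "switch_n": 4.0,
    "gate_eps": 0.05,    # residual activity of an un-gated switch
    "gate_n": 4.0,
    "K_tgfb": 0.75,      # gate threshold of SNAIL on TGF-beta
    "K_snail": 1.0,      # gate threshold of ZEB on SNAIL
    "K_zeb": 1.0,        # gate threshold of TWIST on ZEB
    "readout_K": 1.0,
    "readout_n": 2.0,
}


def _hillp(x: np.ndarray, K: float, n: float) -> np.ndarray:
    xn = np.maximum(x, 0.0) ** n
    return xn / (K**n + xn)


def _hillm(x: np.ndarray, K: float, n: float) -> np.ndarray:
    return 1.0 - _hillp(x, K, n)


@dataclass
class RegulatoryNetwork:
    """The EMT circuit as data: species names + named parameters."""

    species_names: list[str] = field(default_factory=lambda: list(SPECIES))
    parameters: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    @property
    def signal(self) -> float:
        return self.parameters["signal"]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegulatoryNetwork":
        doc = yaml.safe_load(Path(path).read_text())
        net = cls()
        if "species" in doc:
            net.species_names = list(doc["species"])
        if "parameters" in doc:
            net.parameters.update(doc["parameters"])
        return net

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"species": self.species_names, "parameters": self.parameters})
        )

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Deterministic rate f(I) for states of shape (..., 18)."""
        p = self.parameters
        lam = p["lambda"]
        y = np.asarray(y, dtype=float)
        g = lambda name: y[..., _I[name]]
        T, S, Z, W = g("Tgfb"), g("Snail"), g("Zeb"), g("Twist")
        b, a, Ks, ns = p["switch_basal"], p["switch_max"], p["switch_K"], p["switch_n"]
        eps, ng = p["gate_eps"], p["gate_n"]
        Kr, nr = p["readout_K"], p["readout_n"]
        gate = lambda u, K: eps + (1.0 - eps) * _hillp(u, K, ng)
        hp = lambda u: _hillp(u, Kr, nr)
        hm = lambda u: _hillm(u, Kr, nr)

        prod = np.empty_like(y)
        set_ = lambda name, v: prod.__setitem__((..., _I[name]), v)
        set_("Tgfb", p["signal"])
        set_("Snail", gate(T, p["K_tgfb"]) * (b + a * _hillp(S, Ks, ns)))
        set_("Zeb", gate(S, p["K_snail"]) * (b + a * _hillp(Z, Ks, ns)))
        set_("Twist", gate(Z, p["K_zeb"]) * (b + a * _hillp(W, Ks, ns)))
        set_("miR34", 0.1 + 1.0 * hm(S))
        set_("Slug", 0.1 + 1.2 * hp(S))
        set_("miR200", 0.1 + 1.0 * hm(Z))
        set_("Grhl2", 0.1 + 1.1 * hm(Z) * hm(W))
        set_("Ovol2", 0.1 + 1.2 * hm(Z))
        set_("Klf4", 0.1 + 1.2 * hm(S))
        set_("Ecad", 0.2 + 1.2 * hm(S) + 1.0 * hm(Z) + 0.8 * hm(W))
        set_("Vim", 0.1 + 0.8 * hp(S) + 1.1 * hp(Z) + 1.0 * hp(W))
        set_("Ncad", 0.1 + 0.6 * hp(Z) + 1.0 * hp(W))
        set_("Fn1", 0.1 + 1.3 * hp(Z))
        set_("Esrp1", 0.1 + 1.3 * hm(Z))
        set_("Mmp9", 0.1 + 1.4 * hp(W))
        set_("Crb3", 0.1 + 1.3 * hm(S) * hm(Z))
        set_("miR1199", 0.1 + 1.0 * hm(W))
        out = lam * (prod - y)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite rate encountered")
        return out

    def jacobian(self, y: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Finite-difference Jacobian of the rate function at a state."""
        y = np.asarray(y, dtype=float)
        n = y.size
        J = np.empty((n, n))
        f0 = self.rhs(y)
        for j in range(n):
            yp = y.copy()
            yp[j] += h
            J[:, j] = (self.rhs(yp) - f0) / h
        return J


def default_network() -> RegulatoryNetwork:
    return RegulatoryNetwork()


@dataclass
class Attractor:
    state: np.ndarray
    phenotype: str
    eigenvalues: np.ndarray


def steady_states(
    net: RegulatoryNetwork,
    n_grid: int = 1000,
    tol: float = 0.25,
    seed: int | None = 0,
    t_max: float | None = None,
    dt: float | None = None,
    init_scale: float = 3.0,
) -> list[Attractor]:
    """Locate the stable fixed points by relaxation from a random grid.

    ``n_grid`` initial conditions drawn uniformly from [0, init_scale]^18
    are integrated deterministically to convergence; endpoints closer than
    ``tol`` merge into one attractor, local stability is confirmed via the
    Jacobian spectrum, and phenotypes are assigned by Ecad/Vim dominance:
    highest Ecad -> E, highest Vim -> M, the hybrids ordered by their
    Ecad:Vim balance into I1 (Ecad-dominant) and I2 (Vim-dominant).
    """
    lam = net.parameters.get("lambda", 0.05)
    if t_max is None:
        t_max = 80.0 / lam
    if dt is None:
        dt = 0.05 / lam
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.0, init_scale, size=(n_grid, net.n_species))
    t = 0.0
    while t < t_max:
        y = np.maximum(y + net.rhs(y) * dt, 0.0)
        t += dt
    # convergence check: one more window must not move the endpoints
    y2 = y.copy()
    for _ in range(int(5.0 / (lam * dt))):
        y2 = np.maximum(y2 + net.rhs(y2) * dt, 0.0)
    moved = np.linalg.norm(y2 - y, axis=1) > tol / 10.0
    if moved.any():
        logger.warning("%d of %d relaxations not converged; excluded", moved.sum(), n_grid)
    pts = y2[~moved]
    if pts.shape[0] == 0:
        raise RuntimeError("no converged relaxation; increase t_max")

    centers: list[np.ndarray] = []
    for p in pts:
        for i, c in enumerate(centers):
            if np.linalg.norm(p - c) < tol:
                centers[i] = (c + p) / 2.0
                break
        else:
            centers.append(p.copy())

    stable = []
    for c in centers:
        J = net.jacobian(c)
        ev = np.linalg.eigvals(J)
        if np.max(ev.real) < 1e-8:
            stable.append((c, ev))
    return _label_attractors(stable, net)


def _label_attractors(
    stable: list[tuple[np.ndarray, np.ndarray]], net: RegulatoryNetwork
) -> list[Attractor]:
    ie, iv = net.species_names.index("Ecad"), net.species_names.index("Vim")
    order = np.argsort([-c[ie] for c, _ in stable])  # descending Ecad
    labels = {}
    if len(stable) >= 1:
        labels[order[0]] = "E"
    if len(stable) >= 2:
        vim_rank = np.argsort([-stable[i][0][iv] for i in range(len(stable))])
        labels[vim_rank[0]] = "M"
    hybrids = [i for i in range(len(stable)) if i not in labels]
    hybrids.sort(key=lambda i: -(stable[i][0][ie] - stable[i][0][iv]))
    for rank, i in enumerate(hybrids):
        labels[i] = f"I{rank + 1}"
    out = [
        Attractor(state=c, phenotype=labels[i], eigenvalues=ev)
        for i, (c, ev) in enumerate(stable)
    ]
    # canonical order E, I1, I2, ..., M
    key = lambda a: (0 if a.phenotype == "E" else 2 if a.phenotype == "M" else 1, a.phenotype)
    out.sort(key=key)
    return out


def integrate_cells(
    states: np.ndarray,
    net: RegulatoryNetwork,
    dt: float,
    sigma: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler-Maruyama for a batch of cells (rows), clamped at zero.

    I <- I + f(I) dt + sigma * I * sqrt(dt) * Z with independent standard
    normals Z per cell and species.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.array(states, dtype=float)
    n_steps = int(round(duration / dt))
    sq = np.sqrt(dt)
    for _ in range(n_steps):
        drift = net.rhs(y) * dt
        if sigma > 0:
            y = y + drift + sigma * y * sq * rng.standard_normal(y.shape)
        else:
            y = y + drift
        y = np.maximum(y, 0.0)
        if not np.all(np.isfinite(y)):
            bad = np.flatnonzero(~np.all(np.isfinite(y), axis=-1))
            raise FloatingPointError(f"non-finite state for cell index {bad[:5]}")
    return y


def integrate_cell(
    state: np.ndarray,
    net: RegulatoryNetwork,
    dt: float,
    sigma: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-cell convenience wrapper around :func:`integrate_cells`."""
    return integrate_cells(state[None, :], net, dt, sigma, duration, rng)[0]


@dataclass
class CellAgent:
    id: int
    parent_id: int | None
    state: np.ndarray
    divisions_remaining: int
    birth_time: float
    next_division_time: float | None
    death_time: float | None = None
    phenotype: str | None = None


@dataclass
class SimulationConfig:
    n_initial: dict[str, int] = field(
        default_factory=lambda: {"E": 50, "I1": 50, "I2": 50, "M": 50}
    )
    division_time_mean: float = 700.0
    division_time_sd: float = 200.0
    division_budget_min: int = 2
    division_budget_max: int = 7
    death_time_mean: float = 1000.0
    death_time_sd: float = 100.0
    sde_sigma: float = 0.01
    division_noise_sd: float = 0.7
    dt: float = 0.1
    n_cycles: int = 5
    seed: int = 0
    attractor_radius_frac: float = 0.20  # of the min inter-attractor distance
    proliferating_phenotypes: frozenset | None = None  # None = all divide


@dataclass
class SimulationResult:
    snapshots: list[ExpressionMatrix]
    snapshot_times: list[float]
    lineage: pd.DataFrame  # id, parent, birth_time
    attractors: list[Attractor]
    final_population: int


def divide(
    cell: CellAgent, rng: np.random.Generator, noise_sd: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric division perturbation of the mother state.

    noise = state * N(0, sd) per species; daughters get state +/- noise,
    clamped at zero.  Before clamping the daughters average to the mother.
    """
    if cell.divisions_remaining <= 0:
        raise ValueError("cell has no divisions remaining")
    noise = cell.state * rng.normal(0.0, noise_sd, size=cell.state.shape)
    d1 = np.maximum(cell.state + noise, 0.0)
    d2 = np.maximum(cell.state - noise, 0.0)
    return d1, d2


def classify_phenotype(
    state: np.ndarray, attractors: list[Attractor], radius: float | None = None
) -> str | np.ndarray:
    """Label of the nearest attractor within ``radius``, else "TC".

    Default radius is 10% of the minimum inter-attractor distance.  Accepts
    a single state vector or a batch (rows)."""
    states = np.atleast_2d(np.asarray(state, dtype=float))
    cents = np.stack([a.state for a in attractors])
    if radius is None:
        radius = _default_radius(attractors)
    d = np.linalg.norm(states[:, None, :] - cents[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    labels = np.array(
        [
            attractors[j].phenotype if d[i, j] < radius else "TC"
            for i, j in enumerate(nearest)
        ]
    )
    return labels[0] if np.asarray(state).ndim == 1 else labels


def _default_radius(attractors: list[Attractor]) -> float:
    cents = np.stack([a.state for a in attractors])
    dmin = np.inf
    for i in range(len(cents)):
        for j in range(i + 1, len(cents)):
            dmin = min(dmin, np.linalg.norm(cents[i] - cents[j]))
    return 0.10 * dmin


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Positive draws; negative samples are redrawn (truncation at 0)."""
    x = rng.normal(mean, sd, size=size)
    bad = x <= 0
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = x <= 0
    return x


def run_simulation(
    cfg: SimulationConfig, net: RegulatoryNetwork | None = None
) -> SimulationResult:
    """Event-driven population simulation with snapshots at each cycle end.

    The population starts with the configured number of cells placed exactly
    at each attractor; between division/death events all live cells advance
    in lockstep Euler-Maruyama steps.  At each division the mother is
    replaced by two daughters carrying the perturbed state and a decremented
    division budget; once the budget is spent the cell is scheduled to die
    after a further truncated-normal delay.  "Five cycles" means five mean
    division times of simulated time, with a snapshot at every multiple of
    the mean division time.
    """
    net = net or default_network()
    rng = np.random.default_rng(cfg.seed)
    attractors = steady_states(net, n_grid=200, seed=int(rng.integers(2**31 - 1)))
    by_label = {a.phenotype: a for a in attractors}
    radius = cfg.attractor_radius_frac * _default_radius(attractors) / 0.10

    states, budgets, births, div_times, death_times, ids, parents = (
        [], [], [], [], [], [], [],
    )
    next_id = 0
    for label, count in cfg.n_initial.items():
        if label not in by_label:
            raise ValueError(f"no attractor labeled {label!r}")
        for _ in range(count):
            states.append(by_label[label].state.copy())
            budgets.append(int(rng.integers(cfg.division_budget_min, cfg.division_budget_max + 1)))
            births.append(0.0)
            div_times.append(float(_truncated_normal(rng, cfg.division_time_mean, cfg.division_time_sd)))
            death_times.append(np.inf)
            ids.append(next_id)
            parents.append(-1)
            next_id += 1

    states = np.array(states)
    budgets = np.array(budgets)
    births = np.array(births)
    div_times = np.array(div_times)
    death_times = np.array(death_times)
    ids = np.array(ids)
    parents = np.array(parents)
    alive = np.ones(len(ids), dtype=bool)
    lineage_rows = [
        {"id": int(i), "parent": int(p), "birth_time": float(b), "parent_phenotype": "initial"}
        for i, p, b in zip(ids, parents, births)
    ]

    cycle = cfg.division_time_mean
    t_end = cfg.n_cycles * cycle
    snap_times = [cycle * (c + 1) for c in range(cfg.n_cycles)]
    snapshots: list[ExpressionMatrix] = []
    taken = 0

    t = 0.0
    while t < t_end - 1e-9:
        t_next = t + cfg.dt
        # 1. gene dynamics over one step for all live cells
        live = np.flatnonzero(alive)
        if live.size == 0:
            logger.warning("population extinct at t=%.1f h", t)
            break
        states[live] = integrate_cells(
            states[live], net, cfg.dt, cfg.sde_sigma, cfg.dt, rng
        )
        t = t_next
        # 2. deaths
        dying = alive & (death_times <= t)
        alive[dying] = False
        # 3. divisions
        due = np.flatnonzero(alive & (div_times <= t) & (budgets > 0))
        if cfg.proliferating_phenotypes is not None and due.size:
            labels_due = classify_phenotype(states[due], attractors, radius)
            allowed = np.isin(labels_due, list(cfg.proliferating_phenotypes) + ["TC"])
            # non-proliferating cells simply skip this division opportunity
            skip = due[~allowed]
            div_times[skip] = t + _truncated_normal(
                rng, cfg.division_time_mean, cfg.division_time_sd, size=skip.size
            )
            due = due[allowed]
        for i in due:
            mother = CellAgent(
                id=int(ids[i]), parent_id=int(parents[i]), state=states[i],
                divisions_remaining=int(budgets[i]), birth_time=float(births[i]),
                next_division_time=float(div_times[i]),
            )
            mother_pheno = str(classify_phenotype(states[i], attractors, radius))
            d1, d2 = divide(mother, rng, cfg.division_noise_sd)
            new_budget = budgets[i] - 1
            for dstate in (d1, d2):
                ids = np.append(ids, next_id)
                parents = np.append(parents, mother.id)
                states = np.vstack([states, dstate[None, :]])
                budgets = np.append(budgets, new_budget)
                births = np.append(births, t)
                if new_budget > 0:
                    div_times = np.append(
                        div_times,
                        t + _truncated_normal(rng, cfg.division_time_mean, cfg.division_time_sd),
                    )
                    death_times = np.append(death_times, np.inf)
                else:
                    div_times = np.append(div_times, np.inf)
                    death_times = np.append(
                        death_times,
                        t + _truncated_normal(rng, cfg.death_time_mean, cfg.death_time_sd),
                    )
                alive = np.append(alive, True)
                lineage_rows.append(
                    {
                        "id": int(next_id),
                        "parent": int(mother.id),
                        "birth_time": float(t),
                        "parent_phenotype": mother_pheno,
                    }
                )
                next_id += 1
            alive[i] = False  # mother replaced by daughters
        # 4. snapshot
        while taken < len(snap_times) and t >= snap_times[taken] - 1e-9:
            snapshots.append(_snapshot(states, ids, parents, births, alive, attractors, radius))
            taken += 1

    return SimulationResult(
        snapshots=snapshots,
        snapshot_times=snap_times[: len(snapshots)],
        lineage=pd.DataFrame(lineage_rows),
        attractors=attractors,
        final_population=int(alive.sum()),
    )


def _snapshot(states, ids, parents, births, alive, attractors, radius) -> ExpressionMatrix:
    live = np.flatnonzero(alive)
    labels = classify_phenotype(states[live], attractors, radius)
    meta = pd.DataFrame(
        {
            "phenotype": labels,
            "parent": parents[live],
            "birth_time": births[live],
        },
        index=[f"cell_{ids[i]}" for i in live],
    )
    return ExpressionMatrix(
        values=states[live].T,
        gene_names=list(SPECIES),
        cell_names=list(meta.index),
        metadata=meta,
    )
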