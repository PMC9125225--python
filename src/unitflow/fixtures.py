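"""Packaged example systems and seeded random generators.

Three worked examples ship with the package:

* ``build_fig1`` — a two-cell sensing network: an external ligand
  concentration (subsystem 3) evolves autonomously, two receptor subsystems
  (2 and 4) observe it, and a memory subsystem (1) observes receptor 2.
  A multipartite process with unit structure {{1,2,3},{3,4},{3}}.
* ``build_example2`` — three two-state subsystems with unit structure
  A∗ = {{1,2},{2},{2,3}}: subsystem 2 relaxes autonomously while 1 and 3
  relax conditioned on it, so the final joint factorizes as
  p(x1|x2) p(x3|x2) p(x2) and the strengthened second law gives σ_N ≥ ln 2.
* ``build_walker`` — a random walker on an L·N × L·N torus whose position is
  coded as within-square coordinates (x1, x2) plus a coarse-grained square
  index x3, with nutrient stores A (reading x1) and B (reading x2).
  Boundary crossings change x1 (or x2) and x3 simultaneously, so this is
  *not* a multipartite process; its height-2 unit structure is
  {{1},{2},{1,2,3},{A,1},{B,2}}.

``random_unit_system`` draws a rate matrix conforming to an arbitrary unit
structure (one reservoir per coordinate, leader set equal to the smallest
containing unit), which powers the Monte-Carlo property suites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import conditional_map, evolve
from .errors import FixtureError
from .reservoirs import (
    CompositeSystem,
    ConstantRates,
    PiecewiseRates,
    Reservoir,
    _build_embedding,
)
from .statespace import Coordinate, Distribution, JointSpace
from .structures import UnitStructure, build_dependency_graph, intersection_closure

__all__ = [
    "FixtureBundle",
    "build_fig1",
    "build_example2",
    "build_walker",
    "random_unit_system",
    "random_height2_structure",
    "random_distribution",
]

DESK_CAP = 20_000


@dataclass
class FixtureBundle:
    """A ready-to-run example: system, structure, initial condition, time
    window, and the example's analytically expected values."""

    name: str
    system: CompositeSystem
    structure: UnitStructure
    initial: Distribution
    ti: float
    tf: float
    expected: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def run(self, *, n_grid: int = 201):
        return evolve(self.system, self.initial, self.ti, self.tf,
                      n_grid=n_grid)


# ---------------------------------------------------------------------------
# random building blocks
# ---------------------------------------------------------------------------


def _random_table(rng: np.random.Generator, space: JointSpace,
                  puppets, leaders, scale: float = 1.0) -> np.ndarray:
    """A compact rate table with strictly positive off-diagonal entries
    (hence symmetric support) and zero column sums."""
    emb = _build_embedding(space, frozenset(puppets), frozenset(leaders))
    T = rng.uniform(0.5, 1.5, size=(emb.n_puppet, emb.n_leader)) * scale
    diag = (emb.leader_puppet_part, np.arange(emb.n_leader))
    T[diag] = 0.0
    T[diag] = -T.sum(axis=0)
    return T


def _random_reservoir(rng: np.random.Generator, space: JointSpace, name: str,
                      puppets, leaders, scale: float = 1.0) -> Reservoir:
    return Reservoir(name, puppets, leaders,
                     ConstantRates(_random_table(rng, space, puppets, leaders,
                                                 scale)))


def random_distribution(rng: np.random.Generator,
                        space: JointSpace) -> Distribution:
    """A strictly positive Dirichlet(1) random distribution."""
    return Distribution(space, rng.dirichlet(np.ones(space.size)))


# ---------------------------------------------------------------------------
# Figure-1 sensing network
# ---------------------------------------------------------------------------


def build_fig1(cardinalities: Sequence[int] = (2, 2, 2, 2), seed: int = 0,
               rate_scale: float = 1.0, t_final: float = 2.0) -> FixtureBundle:
    """The four-subsystem sensing network.

    Singleton puppet sets (a multipartite process) with leader sets
    3 → {3}, 2 → {2,3}, 1 → {1,2}, 4 → {3,4}; unit structure
    {{1,2,3},{3,4},{3}} whose dependency graph has two roots, one leaf and
    height 2.
    """
    if any(c < 2 for c in cardinalities):
        raise ValueError("subsystem cardinalities must be >= 2")
    rng = np.random.default_rng(seed)
    space = JointSpace([Coordinate(str(i + 1), c)
                        for i, c in enumerate(cardinalities)])
    leader_map = {"1": {"1", "2"}, "2": {"2", "3"}, "3": {"3"},
                  "4": {"3", "4"}}
    reservoirs = [
        _random_reservoir(rng, space, f"res{i}", {i}, leader_map[i],
                          rate_scale)
        for i in ("1", "2", "3", "4")
    ]
    system = CompositeSystem(space, reservoirs)
    structure = UnitStructure([{"1", "2", "3"}, {"3", "4"}, {"3"}])
    initial = random_distribution(rng, space)
    expected = {"roots": 2, "leaves": 1, "height": 2,
                "n_reservoirs_of_3": 1, "is_multipartite": True}
    return FixtureBundle("fig1", system, structure, initial, 0.0, t_final,
                         expected)


# ---------------------------------------------------------------------------
# Example 2: three relaxing subsystems
# ---------------------------------------------------------------------------


def _jump_to_target_table(space: JointSpace, puppet: str, leaders,
                          target: np.ndarray, rate: float = 1.0) -> np.ndarray:
    """Rates that jump the puppet to a target distribution q(·|leaders∖puppet)
    at total rate ``rate`` regardless of the source state, relaxing the
    puppet's conditional to q exponentially."""
    emb = _build_embedding(space, frozenset({puppet}), frozenset(leaders))
    # target has shape (n_puppet, n_leader): q(x_p | column's leader config)
    T = rate * np.asarray(target, float).copy()
    diag = (emb.leader_puppet_part, np.arange(emb.n_leader))
    T[diag] = 0.0
    T[diag] = -T.sum(axis=0)
    return T


def build_example2(seed: int = 0, relax_time: float = 30.0,
                   rate: float = 1.0, *, residual_tol: float = 1e-4
                   ) -> FixtureBundle:
    """Three two-state subsystems with unit structure A∗ = {{1,2},{2},{2,3}}.

    Initially x1 = x3 uniformly while x2 is uniform and independent, so
    S(p_i) = 2 ln 2 and I_A∗(p_i) = ln 2.  The protocol has two stages of
    equal length: first subsystem 2 uniformizes (losing all memory of its
    start) while 1 and 3 relax toward x2-conditioned targets; then 2 is
    frozen and 1, 3 finish relaxing conditioned on the now-fixed x2.  The
    endpoint conditional therefore factorizes as p(x1|x2) p(x3|x2) p(x2) up
    to an exponentially small residual, giving I_A∗(p_f) ≈ 0 and the SSL
    bound σ_N ≥ ln 2.

    Raises :class:`FixtureError` if ``relax_time`` is too short for the
    factorization residual to reach ``residual_tol``.
    """
    rng = np.random.default_rng(seed)
    space = JointSpace([Coordinate(n, 2) for n in ("1", "2", "3")])
    t_half, t_end = relax_time / 2.0, relax_time

    # subsystem 2: uniformizing flips, then frozen
    flip = rate * np.array([[-1.0, 1.0], [1.0, -1.0]])
    res2 = Reservoir("res2", {"2"}, {"2"}, PiecewiseRates([
        (0.0, t_half, flip), (t_half, t_end, np.zeros((2, 2)))
    ]))

    # subsystems 1 and 3: jump-to-target conditioned on x2, active throughout.
    # Leader columns follow the sub-space enumeration (last coordinate
    # fastest): (x1, x2) for subsystem 1 but (x2, x3) for subsystem 3.
    def target(rng, self_first: bool) -> tuple[np.ndarray, np.ndarray]:
        q = rng.uniform(0.15, 0.85, size=2)          # q(x_self = 1 | x2)
        cond = np.array([[1.0 - q[0], 1.0 - q[1]], [q[0], q[1]]])
        cols = []
        for outer in (0, 1):
            for inner in (0, 1):
                x2 = inner if self_first else outer
                cols.append(cond[:, x2])
        return cond, np.array(cols).T                 # (2, 2), (2, 4)

    q1, table1 = target(rng, self_first=True)
    q3, table3 = target(rng, self_first=False)
    res1 = Reservoir("res1", {"1"}, {"1", "2"}, ConstantRates(
        _jump_to_target_table(space, "1", {"1", "2"}, table1, rate)))
    res3 = Reservoir("res3", {"3"}, {"2", "3"}, ConstantRates(
        _jump_to_target_table(space, "3", {"2", "3"}, table3, rate)))

    system = CompositeSystem(space, [res1, res2, res3])
    structure = UnitStructure([{"1", "2"}, {"2"}, {"2", "3"}])

    p0 = np.zeros(space.size)
    for k in (0, 1):
        for m in (0, 1):
            p0[space.index((k, m, k))] = 0.25
    initial = Distribution(space, p0)

    # the exact factorized endpoint the protocol relaxes to
    target_final = np.zeros(space.size)
    for x1, x2, x3 in space.states():
        target_final[space.index((x1, x2, x3))] = (
            0.5 * q1[x1, x2] * q3[x3, x2]
        )
    p_target = Distribution(space, target_final)

    # verify the endpoint conditional loses all memory (mixing check)
    cmap = conditional_map(system, 0.0, t_end)
    residual = float(np.max(np.abs(cmap.matrix - p_target.p[:, None])))
    if residual > residual_tol:
        raise FixtureError(
            f"example 2: factorization residual {residual:.2e} exceeds "
            f"{residual_tol:.0e}; increase relax_time"
        )

    expected = {"S_initial": 2 * np.log(2), "I_initial": np.log(2),
                "I_final_max": residual_tol, "B": np.log(2),
                "factorization_residual": residual}
    return FixtureBundle("example2", system, structure, initial, 0.0, t_end,
                         expected, extras={"target_final": p_target,
                                           "q1": q1, "q3": q3})


# ---------------------------------------------------------------------------
# Example 3: coarse-grained random walker
# ---------------------------------------------------------------------------


def _walker_walk_table(L: int, ncg: int, which: int) -> np.ndarray:
    """Compact table for one walk direction over the puppet pair (x_i, x3).

    ``which`` = 0 moves x1 and the first (row-major) square index; 1 moves
    x2 and the second.  Interior hops change only x_i; hops across a square
    boundary wrap x_i and step the corresponding component of x3 on the
    torus.  Both directions fire at rate 1 (a symmetric nearest-neighbour
    walk on a ring of circumference L·ncg).
    """
    n = L * ncg * ncg
    sub = JointSpace([Coordinate("i", L), Coordinate("3", ncg * ncg)])
    T = np.zeros((n, n))
    for xi in range(L):
        for c_move in range(ncg):
            for c_other in range(ncg):
                c1, c2 = (c_move, c_other) if which == 0 else (c_other, c_move)
                src = sub.index((xi, c1 * ncg + c2))
                for step in (+1, -1):
                    g = xi + step
                    if 0 <= g < L:
                        nxt_xi, nxt_c = g, c_move
                    else:
                        nxt_xi = g % L
                        nxt_c = (c_move + step) % ncg
                    n1, n2 = ((nxt_c, c_other) if which == 0
                              else (c_other, nxt_c))
                    dst = sub.index((nxt_xi, n1 * ncg + n2))
                    T[dst, src] += 1.0
                T[src, src] = -T[:, src].sum() + T[src, src]
    return T


def build_walker(L: int = 2, ncg: int = 4, n_a: int = 2, n_b: int = 2,
                 seed: int = 0, t_final: float | None = None
                 ) -> FixtureBundle:
    """The coarse-grained walker with nutrient stores.

    Coordinates: within-square positions x1, x2 ∈ {0..L−1}, square index
    x3 ∈ {0..ncg²−1} (torus), nutrient stores A (reads x1) and B (reads x2).
    Boundary crossings change x1 (or x2) and x3 together, so the process is
    not multipartite; the structure {{1},{2},{1,2,3},{A,1},{B,2}} has
    height 2.  From a deterministic start the position mixes to uniform and
    the stationary joint factorizes as u(x3) π(A, x1) π(B, x2), so the
    in-ex information at the endpoint collapses to
    S(A,B|1,2,3) − S(A|1) − S(B|2) = 0; the widely quoted 2 ln L figure for
    this scenario corresponds to truncating the in-ex expansion at second
    order (see the methods note) and is recorded in ``expected`` under
    ``minus_delta_I_second_order``.
    """
    size = L * L * ncg * ncg * n_a * n_b
    if size > DESK_CAP:
        raise ValueError(
            f"joint space has {size} states (cap {DESK_CAP}); reduce L, "
            "the grid, or the nutrient cardinalities"
        )
    rng = np.random.default_rng(seed)
    space = JointSpace([
        Coordinate("1", L), Coordinate("2", L),
        Coordinate("3", ncg * ncg),
        Coordinate("A", n_a), Coordinate("B", n_b),
    ])
    w1 = Reservoir("walk1", {"1", "3"}, {"1", "3"},
                   ConstantRates(_walker_walk_table(L, ncg, 0)))
    w2 = Reservoir("walk2", {"2", "3"}, {"2", "3"},
                   ConstantRates(_walker_walk_table(L, ncg, 1)))
    ra = _random_reservoir(rng, space, "nutrientA", {"A"}, {"A", "1"})
    rb = _random_reservoir(rng, space, "nutrientB", {"B"}, {"B", "2"})
    system = CompositeSystem(space, [w1, w2, ra, rb])

    structure = UnitStructure([
        {"1"}, {"2"}, {"1", "2", "3"}, {"A", "1"}, {"B", "2"},
    ])

    p0 = np.zeros(space.size)
    p0[space.index((0, 0, 0, 0, 0))] = 1.0
    initial = Distribution(space, p0)

    if t_final is None:
        # slowest position mode of the ring of circumference L·ncg
        gap = 2.0 * (1.0 - np.cos(2.0 * np.pi / (L * ncg)))
        t_final = max(40.0 / gap, 20.0)

    # Under the strict in-ex definition the third-order intersection terms
    # cancel the leaf entropies, so −ΔI = Δ[S(A,B|1,2,3) − S(A|1) − S(B|2)]
    # = 0 at product-form endpoints; truncating the in-ex expansion at
    # second order instead leaves the leaf terms and yields 2 ln L.
    expected = {"minus_delta_I": 0.0,
                "minus_delta_I_second_order": 2.0 * np.log(L),
                "height": 2, "roots": 3, "leaves": 2,
                "is_multipartite": False}
    return FixtureBundle("walker", system, structure, initial, 0.0,
                         float(t_final), expected)


# ---------------------------------------------------------------------------
# seeded random systems conforming to a structure
# ---------------------------------------------------------------------------


def random_unit_system(structure: UnitStructure, space: JointSpace,
                       seed: int = 0, rate_scale: float = 1.0
                       ) -> CompositeSystem:
    """A random composite system for which the given structure is valid.

    One reservoir per coordinate (singleton puppet set), with leader set
    equal to the smallest unit containing the coordinate — so every unit's
    dynamics closes on itself and the structure is tight.  Off-diagonal
    rates are strictly positive (symmetric support); identical seeds give
    identical systems.
    """
    rng = np.random.default_rng(seed)
    reservoirs = []
    for name in space.names:
        containing = [u for u in structure.units if name in u]
        if not containing:
            raise ValueError(f"structure does not cover coordinate {name!r}")
        leader = frozenset.intersection(*containing)
        reservoirs.append(
            _random_reservoir(rng, space, f"res_{name}", {name}, leader,
                              rate_scale)
        )
    return CompositeSystem(space, reservoirs)


def _structurally_vacuous(units: Sequence[frozenset]) -> bool:
    for u in units:
        proper = [v for v in units if v < u]
        if proper and u <= frozenset().union(*proper):
            return True
    return False


def random_height2_structure(names: Sequence[str],
                             rng: np.random.Generator, *,
                             max_roots: int = 3,
                             max_tries: int = 500) -> UnitStructure:
    """A random valid unit structure of height ≤ 2 over the given
    coordinates (full set excluded, no vacuous units)."""
    names = list(names)
    for _ in range(max_tries):
        k = int(rng.integers(1, max_roots + 1))
        units: list[frozenset] = []
        for _ in range(k):
            size = int(rng.integers(1, len(names)))
            pick = rng.choice(names, size=size, replace=False)
            units.append(frozenset(str(x) for x in pick))
        covered = frozenset().union(*units)
        units += [frozenset({n}) for n in names if n not in covered]
        try:
            st = intersection_closure(units, allow_full=False)
        except ValueError:
            continue
        if _structurally_vacuous(st.units):
            continue
        if build_dependency_graph(st).height > 2:
            continue
        return st
    raise RuntimeError("could not draw a valid height-2 structure")
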