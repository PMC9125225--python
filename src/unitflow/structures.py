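"""Unit-structure algebra: closure, validation, dependency graphs, and the
inclusion–exclusion machinery.

A *unit* is a coordinate subset whose marginal evolves as a self-contained
CTMC.  A *unit structure* is a set of units that covers every coordinate and
is closed under non-empty pairwise intersection; by default the full
coordinate set N is excluded from the structure (it may be admitted with
``allow_full=True``, but the height-2 guarantee for the strengthened second
law was stated for structures without N).

The inclusion–exclusion sum of a unit-indexed quantity f is

    Σ̂_ω f_ω = Σ_j f_{ω_j} − Σ_{j<j'} f_{ω_j ∩ ω_j'} + …

evaluated per index subset (repeated intersections are *not* deduplicated),
with f(∅) := 0.  Applied to marginal entropies minus the joint entropy this
yields the in-ex information, which generalizes mutual information (two
disjoint units) and multi-information (any disjoint family).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .reservoirs import GEN_TOL, CompositeSystem
from .statespace import Distribution, shannon_entropy

__all__ = [
    "UnitStructure",
    "DependencyGraph",
    "intersection_closure",
    "StructureReport",
    "validate_structure",
    "build_dependency_graph",
    "inclusion_exclusion_sum",
    "in_ex_information",
    "enumerate_height2_structures",
]

Unit = frozenset

MAX_INEX_UNITS = 20


def _canon(units: Iterable[Iterable[str]]) -> tuple[frozenset, ...]:
    """Canonical ordering: by size then sorted coordinate tuple."""
    us = {frozenset(u) for u in units}
    if any(not u for u in us):
        raise ValueError("units must be non-empty")
    return tuple(sorted(us, key=lambda u: (len(u), tuple(sorted(u)))))


class UnitStructure:
    """A finite set of units over a coordinate set.

    Construction checks coverage and intersection-closure; whether each
    member actually *is* a unit of a given system is checked by
    :func:`validate_structure`.
    """

    def __init__(self, units: Iterable[Iterable[str]],
                 coordinates: Iterable[str] | None = None, *,
                 allow_full: bool = False):
        self.units = _canon(units)
        if not self.units:
            raise ValueError("a unit structure needs at least one unit")
        cover = frozenset().union(*self.units)
        self.coordinates = frozenset(coordinates) if coordinates is not None else cover
        if cover != self.coordinates:
            raise ValueError(
                f"units must cover all coordinates; missing "
                f"{sorted(self.coordinates - cover)}"
            )
        for a, b in itertools.combinations(self.units, 2):
            inter = a & b
            if inter and inter not in self.units:
                raise ValueError(
                    f"not closed under intersection: {sorted(a)} ∩ {sorted(b)} "
                    f"= {sorted(inter)} is missing"
                )
        if self.coordinates in self.units and not allow_full:
            raise ValueError(
                "the full coordinate set is excluded from unit structures by "
                "default; pass allow_full=True to admit it"
            )
        self.allow_full = allow_full

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, unit) -> bool:
        return frozenset(unit) in self.units

    def __eq__(self, other) -> bool:
        return isinstance(other, UnitStructure) and self.units == other.units

    def __hash__(self) -> int:
        return hash(self.units)

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(sorted(u)) + "}" for u in self.units)
        return f"UnitStructure({inner})"

    def to_lists(self) -> list[list[str]]:
        return [sorted(u) for u in self.units]


def intersection_closure(units: Iterable[Iterable[str]], *,
                         allow_full: bool = True) -> UnitStructure:
    """Smallest superset of ``units`` closed under non-empty intersection."""
    us = {frozenset(u) for u in units}
    if not us or any(not u for u in us):
        raise ValueError("need a non-empty collection of non-empty units")
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(tuple(us), 2):
            inter = a & b
            if inter and inter not in us:
                us.add(inter)
                changed = True
    return UnitStructure(us, allow_full=allow_full)


# ---------------------------------------------------------------------------
# dependency graph
# ---------------------------------------------------------------------------


@dataclass
class DependencyGraph:
    """Inclusion poset of a unit structure as a directed graph.

    There is an edge ω → ω′ iff ω′ ⊂ ω with no intervening unit.  Roots have
    no incoming edge (maximal units); leaves have no outgoing edge; the
    height of a node is the maximal number of nodes on a directed path
    starting there (a leaf has height 1).
    """

    graph: nx.DiGraph
    structure: UnitStructure

    @property
    def roots(self) -> list[frozenset]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    @property
    def leaves(self) -> list[frozenset]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def node_height(self, unit) -> int:
        unit = frozenset(unit)
        succ = list(self.graph.successors(unit))
        if not succ:
            return 1
        return 1 + max(self.node_height(s) for s in succ)

    @property
    def height(self) -> int:
        return max(self.node_height(n) for n in self.graph.nodes)

    def parents(self, unit) -> list[frozenset]:
        return list(self.graph.predecessors(frozenset(unit)))

    def descendants(self, unit) -> set[frozenset]:
        return set(nx.descendants(self.graph, frozenset(unit)))

    def family(self, unit) -> set[frozenset]:
        u = frozenset(unit)
        return {u} | self.descendants(u)

    def to_dot(self) -> str:
        lines = ["digraph units {"]
        label = {u: "{" + ",".join(sorted(u)) + "}" for u in self.graph.nodes}
        for u in self.graph.nodes:
            lines.append(f'  "{label[u]}";')
        for a, b in self.graph.edges:
            lines.append(f'  "{label[a]}" -> "{label[b]}";')
        lines.append("}")
        return "\n".join(lines)


def build_dependency_graph(structure: UnitStructure) -> DependencyGraph:
    g = nx.DiGraph()
    g.add_nodes_from(structure.units)
    for a, b in itertools.permutations(structure.units, 2):
        if b < a:  # proper subset
            intervening = any(
                b < c < a for c in structure.units if c not in (a, b)
            )
            if not intervening:
                g.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(g):  # impossible for a poset; guard
        raise RuntimeError("dependency graph has a cycle")
    return DependencyGraph(graph=g, structure=structure)


# ---------------------------------------------------------------------------
# inclusion–exclusion machinery
# ---------------------------------------------------------------------------


def inclusion_exclusion_sum(f: Callable[[frozenset], float] | Mapping,
                            structure: UnitStructure | Sequence[Iterable[str]]
                            ) -> float:
    """The in-ex sum Σ̂_ω f_ω over all non-empty index subsets.

    ``f`` is a callable on coordinate frozensets (or a mapping from
    frozensets); it must be defined on every unit and every non-empty
    intersection of units.  Empty intersections contribute f(∅) = 0.  The
    result is independent of the unit ordering.
    """
    units = list(structure.units if isinstance(structure, UnitStructure)
                 else _canon(structure))
    n = len(units)
    if n > MAX_INEX_UNITS:
        raise ValueError(
            f"inclusion–exclusion over {n} units needs 2^{n} terms; "
            f"restrict the structure to at most {MAX_INEX_UNITS} units"
        )
    get = f.__getitem__ if isinstance(f, Mapping) else f
    total = 0.0
    for k in range(1, n + 1):
        sign = 1.0 if k % 2 == 1 else -1.0
        for subset in itertools.combinations(units, k):
            inter = frozenset.intersection(*subset)
            if inter:
                # values may be scalars or arrays (e.g. rate time series)
                total = total + sign * np.asarray(get(inter), dtype=float)
    return float(total) if np.ndim(total) == 0 else total


def in_ex_information(dist: Distribution,
                      structure: UnitStructure | Sequence[Iterable[str]]
                      ) -> float:
    """In-ex information I_N∗(p) = Σ̂_ω S(p_ω) − S(p), in nats.

    For a family of pairwise-disjoint units this is the multi-information of
    the unit marginals; for two disjoint units it is their mutual
    information.  With overlapping units it can be negative.
    """
    cache: dict[frozenset, float] = {}

    def s(unit: frozenset) -> float:
        if unit not in cache:
            cache[unit] = float(
                shannon_entropy(dist.marginal(unit))
            )
        return cache[unit]

    return inclusion_exclusion_sum(s, structure) - shannon_entropy(dist)


# ---------------------------------------------------------------------------
# validation against a system
# ---------------------------------------------------------------------------


@dataclass
class StructureReport:
    """Outcome of validating a unit structure against a composite system."""

    covers: bool
    intersection_closed: bool
    all_units: bool
    flush: bool
    no_vacuous: bool
    no_equivalent: bool
    tight: bool
    witnesses: dict = field(default_factory=dict)

    @property
    def all_true(self) -> bool:
        return all([self.covers, self.intersection_closed, self.all_units,
                    self.flush, self.no_vacuous, self.no_equivalent,
                    self.tight])

    def to_dict(self) -> dict:
        return {
            "covers": self.covers,
            "intersection_closed": self.intersection_closed,
            "all_units": self.all_units,
            "flush": self.flush,
            "no_vacuous": self.no_vacuous,
            "no_equivalent": self.no_equivalent,
            "tight": self.tight,
            "witnesses": {k: str(v) for k, v in self.witnesses.items()},
        }


def validate_structure(sys: CompositeSystem, structure: UnitStructure,
                       times: Sequence[float] | None = None, *,
                       dist: Distribution | None = None) -> StructureReport:
    """Check the structural well-formedness conditions of a unit structure.

    Flags: coverage, intersection-closure, membership (every element passes
    ``is_unit``), *flush* (every simultaneous-transition coordinate set is
    contained in some unit), *no vacuous* units (some coordinate of each
    unit lies in no proper subunit), *no equivalent* nested units (for each
    ω′ ⊂ ω some transition changes a coordinate of ω ∖ ω′), and *tightness*
    (for every unit ω, every reservoir in ν(ω) has its leader set inside ω).

    The equivalence check is structural (full support) by default; pass a
    distribution to restrict it to the support of ``dist``.
    """
    if times is None:
        times = sys.sample_times()
    witnesses: dict = {}
    space = sys.space

    covers = frozenset().union(*structure.units) == set(space.names)
    closed = True  # guaranteed by the UnitStructure constructor

    all_units = True
    for u in structure:
        if not sys.is_unit(u, times):
            all_units = False
            witnesses["not_a_unit"] = sorted(u)
            break

    # flush: changed-coordinate set of every allowed transition is inside a unit
    flush = True
    nd = sys._ndiff_matrix()
    digits = np.array([s for s in space.states()])
    for t in times:
        K = sys.global_rate(t)
        rows, cols = np.nonzero((np.abs(K) > GEN_TOL) & (nd >= 1))
        for r, c in zip(rows, cols):
            changed = frozenset(
                space.names[i] for i in range(digits.shape[1])
                if digits[r, i] != digits[c, i]
            )
            if not any(changed <= u for u in structure):
                flush = False
                witnesses["not_flush"] = (sorted(changed), space.state(c),
                                          space.state(r))
                break
        if not flush:
            break

    # vacuous units
    no_vacuous = True
    for u in structure:
        subcover = set().union(*[v for v in structure.units if v < u]) \
            if any(v < u for v in structure.units) else set()
        if u <= subcover:
            no_vacuous = False
            witnesses["vacuous"] = sorted(u)
            break

    # equivalent nested units: ω' ⊂ ω equivalent at t if no transition of
    # K(ω;t) changes a coordinate in ω ∖ ω' (structural / support-restricted)
    no_equivalent = True
    support = None
    if dist is not None:
        support = dist.p > 0
    for u, v in itertools.permutations(structure.units, 2):
        if not v < u:
            continue
        equivalent_everywhere = True
        for t in times:
            K = sys.global_rate(t)
            if _changes_coordinates(K, sys, u - v, support):
                equivalent_everywhere = False
                break
        if equivalent_everywhere:
            no_equivalent = False
            witnesses["equivalent"] = (sorted(u), sorted(v))
            break

    # tightness
    tight = True
    for u in structure:
        for res in sys.reservoirs_affecting(u):
            if not res.leaders <= u:
                tight = False
                witnesses["not_tight"] = (sorted(u), res.name,
                                          sorted(res.leaders))
                break
        if not tight:
            break

    return StructureReport(covers=covers, intersection_closed=closed,
                           all_units=all_units, flush=flush,
                           no_vacuous=no_vacuous, no_equivalent=no_equivalent,
                           tight=tight, witnesses=witnesses)


def _changes_coordinates(K: np.ndarray, sys: CompositeSystem,
                         names: frozenset, support) -> bool:
    """True if some transition with nonzero rate changes a coordinate in
    ``names`` (restricted to source states in ``support`` if given)."""
    space = sys.space
    axes = space.axes(names)
    digits = np.array([s for s in space.states()])
    mask = np.abs(K) > GEN_TOL
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        if support is not None and not support[c]:
            continue
        if any(digits[r, a] != digits[c, a] for a in axes):
            return True
    return False


# ---------------------------------------------------------------------------
# height-2 search
# ---------------------------------------------------------------------------


def enumerate_height2_structures(sys: CompositeSystem, max_units: int = 6, *,
                                 times: Sequence[float] | None = None,
                                 allow_full: bool = False,
                                 budget: int = 200_000
                                 ) -> list[UnitStructure]:
    """All valid unit structures of dependency-graph height ≤ 2, by search.

    Candidate units are the coordinate subsets passing ``is_unit``; subsets
    of candidates of size ≤ ``max_units`` are kept when they form a
    structure passing every validation flag with height ≤ 2.  Results are in
    canonical order (by unit count, then unit tuples).  The search refuses
    spaces with more than 12 coordinates.
    """
    names = list(sys.space.names)
    if len(names) > 12:
        raise ValueError("height-2 search supports at most 12 coordinates")
    if times is None:
        times = sys.sample_times()

    candidates = []
    for k in range(1, len(names) + (1 if allow_full else 0)):
        for combo in itertools.combinations(names, k):
            if sys.is_unit(combo, times):
                candidates.append(frozenset(combo))
    if allow_full:
        candidates.append(frozenset(names))

    results: list[UnitStructure] = []
    tried = 0
    for k in range(1, max_units + 1):
        for combo in itertools.combinations(candidates, k):
            tried += 1
            if tried > budget:
                import warnings

                warnings.warn("height-2 search budget exhausted; results "
                              "are partial")
                return results
            us = set(combo)
            if frozenset().union(*us) != set(names):
                continue
            closed = all(
                (a & b) in us or not (a & b)
                for a, b in itertools.combinations(us, 2)
            )
            if not closed:
                continue
            try:
                structure = UnitStructure(us, allow_full=allow_full)
            except ValueError:
                continue
            if build_dependency_graph(structure).height > 2:
                continue
            report = validate_structure(sys, structure, times)
            if report.all_true:
                results.append(structure)
    results.sort(key=lambda s: (len(s), tuple(tuple(sorted(u)) for u in s)))
    return results
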