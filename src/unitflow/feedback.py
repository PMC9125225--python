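"""Feedback control of composite systems: measurement channels, the
frozen-controller extended system, lifted unit structures, and the
structure-aware work bounds.

A controller C observes the initial system state through a noisy channel
p(c|x) with no back-action, then stays frozen while the system may read c.
The controller is modelled as one extra coordinate, listed first in the
extended space, driven by a zero-rate reservoir (so it never moves) and
added to the leader set of every system reservoir that conditions on it.

With a uniform Hamiltonian at both endpoints and all reservoirs at one
temperature (k_B T = 1), the extractable work is bounded by the change in
the in-ex sum of unit entropies conditioned on C; the conventional bound
uses ΔS(X|C) without the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .reservoirs import CompositeSystem, ConstantRates, Reservoir
from .statespace import (
    Coordinate,
    Distribution,
    JointSpace,
    conditional_entropy,
    mutual_information,
    shannon_entropy,
)
from .structures import UnitStructure, inclusion_exclusion_sum

__all__ = [
    "Channel",
    "joint_initial",
    "lift_structure",
    "controlled_system",
    "feedback_bound_difference",
    "extractable_work_bound",
    "WorkBounds",
]

CONTROLLER = "C"


class Channel:
    """A measurement channel p(c|x) from system states to controller states.

    ``matrix[c, x]`` is the probability of outcome c given joint system
    state x (flat index); every column sums to one.  Observation has no
    back-action by construction: the joint state after measurement is
    p(c, x) = p(c|x) p(x), whose x-marginal is unchanged.
    """

    def __init__(self, space: JointSpace, matrix: np.ndarray,
                 name: str = CONTROLLER):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != space.size:
            raise ValueError(
                f"channel matrix must be (n_c, {space.size}), got {m.shape}"
            )
        if np.any(m < -1e-12):
            raise ValueError("negative channel probability")
        col = m.sum(axis=0)
        if np.max(np.abs(col - 1.0)) > 1e-9:
            raise ValueError("channel columns must sum to 1")
        if name in space.names:
            raise ValueError(f"coordinate name {name!r} already in use")
        self.space = space
        self.matrix = np.clip(m, 0.0, None)
        self.n_outcomes = m.shape[0]
        self.name = name

    def extended_space(self) -> JointSpace:
        """C × X with the controller listed first (so flat index = c·|X|+x)."""
        return JointSpace(
            [Coordinate(self.name, self.n_outcomes)] + list(self.space.coordinates)
        )


def joint_initial(p_dagger: Distribution, channel: Channel) -> Distribution:
    """Post-measurement joint distribution p(c, x) = p(c|x) p†(x).

    The X-marginal equals ``p_dagger`` exactly (no back-action).
    """
    if p_dagger.space != channel.space:
        raise ValueError("distribution and channel are over different spaces")
    joint = channel.matrix * p_dagger.p[None, :]
    return Distribution(channel.extended_space(), joint.reshape(-1))


def lift_structure(structure: UnitStructure,
                   controller: str = CONTROLLER) -> UnitStructure:
    """Replace each unit ω with ω ∪ {C}.

    When every pair of original units intersects, the lifted family is
    closed and its inclusion poset is isomorphic to the original (same
    height).  If some original units are disjoint, their lifted copies
    intersect in {C} alone, so the bare controller unit {C} is added to
    restore intersection-closure (the controller is frozen, hence trivially
    a unit).
    """
    lifted = {frozenset(set(u) | {controller}) for u in structure.units}
    needs_bare = any(
        (a & b) == frozenset({controller})
        for a in lifted for b in lifted if a != b
    )
    if needs_bare:
        lifted.add(frozenset({controller}))
    return UnitStructure(lifted, allow_full=True)


def controlled_system(channel: Channel, reservoirs: Sequence[Reservoir]
                      ) -> CompositeSystem:
    """The frozen-controller extended system over C × X.

    ``reservoirs`` drive the original coordinates; each may include the
    controller name in its leader set to realize per-c protocols.  A
    zero-rate reservoir is attached to C so that the controller never moves
    and its marginal is conserved.
    """
    space = channel.extended_space()
    frozen = Reservoir(
        "frozen-controller", [channel.name], [channel.name],
        ConstantRates(np.zeros((channel.n_outcomes, channel.n_outcomes))),
    )
    return CompositeSystem(space, list(reservoirs) + [frozen])


def _mi_with_controller(p: Distribution, unit: Iterable[str],
                        controller: str) -> float:
    unit = frozenset(unit) - {controller}
    if not unit:
        return 0.0
    return mutual_information(p, unit, {controller})


def feedback_bound_difference(p_ti: Distribution, p_tf: Distribution,
                              structure: UnitStructure,
                              controller: str = CONTROLLER) -> float:
    """B_M∗ − B_N∗ for the lifted structure M∗, from endpoint distributions
    over the extended space C × X:

        Δ[ Σ̂_ω I(X_ω; C) ] − ΔI(X_N; C).

    Vanishes when the controller is independent of the system at both
    endpoints.
    """
    sys_names = frozenset(p_ti.space.names) - {controller}

    def inex_mi(p: Distribution) -> float:
        return inclusion_exclusion_sum(
            lambda u: _mi_with_controller(p, u, controller), structure
        )

    delta_units = inex_mi(p_tf) - inex_mi(p_ti)
    delta_global = (
        mutual_information(p_tf, sys_names, {controller})
        - mutual_information(p_ti, sys_names, {controller})
    )
    return delta_units - delta_global


@dataclass
class WorkBounds:
    """Upper bounds on extractable work (nats, k_B T = 1) under feedback,
    assuming a uniform Hamiltonian at both endpoints."""

    structured: float     # Δ[ Σ̂_ω S(X_ω | C) ]
    conventional: float   # ΔS(X_N | C)

    @property
    def structured_is_tighter(self) -> bool:
        return self.structured <= self.conventional + 1e-12


def extractable_work_bound(p_ti: Distribution, p_tf: Distribution,
                           structure: UnitStructure,
                           controller: str = CONTROLLER) -> WorkBounds:
    """Structure-aware and conventional upper bounds on extracted work.

    Both are computed from the endpoint distributions over the extended
    space; whether the structure-aware bound is the smaller of the two is
    recorded, not assumed.
    """
    sys_names = frozenset(p_ti.space.names) - {controller}

    def inex_cond_entropy(p: Distribution) -> float:
        return inclusion_exclusion_sum(
            lambda u: _cond_entropy(p, u, controller), structure
        )

    structured = inex_cond_entropy(p_tf) - inex_cond_entropy(p_ti)
    conventional = (
        conditional_entropy(p_tf, sys_names, {controller})
        - conditional_entropy(p_ti, sys_names, {controller})
    )
    return WorkBounds(structured=structured, conventional=conventional)


def _cond_entropy(p: Distribution, unit: Iterable[str],
                  controller: str) -> float:
    unit = frozenset(unit) - {controller}
    if not unit:
        return 0.0
    return conditional_entropy(p, unit, {controller})
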