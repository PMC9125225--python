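"""Package exceptions."""

from __future__ import annotations


class UnitflowError(Exception):
    """Base class for package errors."""


class IndependenceError(UnitflowError):
    """A marginal generator does not exist: the summed rates depend on the
    state of coordinates outside the requested set.

    Attributes
    ----------
    discrepancy : float
        Maximal spread of the candidate marginal entry across outside states.
    witness : tuple
        ``(dest_substate, src_substate)`` where the spread is attained.
    """

    def __init__(self, names, discrepancy: float, witness):
        self.names = tuple(sorted(names))
        self.discrepancy = float(discrepancy)
        self.witness = witness
        super().__init__(
            f"coordinates {self.names} are not a unit: marginal rate for "
            f"transition {witness[1]} -> {witness[0]} varies by "
            f"{discrepancy:.3e} across outside states"
        )


class IrreversibleTransitionError(UnitflowError):
    """A rate matrix has a one-way transition (L[x,x'] > 0 but L[x',x] = 0),
    so the log-ratio in entropy flow is undefined."""

    def __init__(self, reservoir: str, pair):
        self.reservoir = reservoir
        self.pair = pair
        super().__init__(
            f"reservoir {reservoir!r}: transition {pair[1]} -> {pair[0]} has "
            "positive rate but its reverse rate is zero; entropy-flow "
            "log-ratios require weakly reversible rates"
        )


class ReservoirValidationError(UnitflowError):
    """A reservoir failed its structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class QuadratureError(UnitflowError):
    """The evolution grid is too coarse for converged time integrals."""


class FixtureError(UnitflowError):
    """A packaged example fixture failed its self-checks."""
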