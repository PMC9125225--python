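"""Finite product state spaces, distributions over them, and information measures.

Every quantity in this package lives on a :class:`JointSpace`: an ordered
product of named finite coordinates.  Joint states are flattened with a fixed
lexicographic enumeration in which the *last* listed coordinate varies
fastest (NumPy C order), so all vectors and matrices in the package share one
stable indexing convention.

All information measures are in nats (natural logarithms), with the usual
convention 0 * ln 0 = 0.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Coordinate",
    "JointSpace",
    "Distribution",
    "ConditionalMap",
    "marginalize",
    "shannon_entropy",
    "mutual_information",
    "conditional_entropy",
    "multi_information",
]

#: absolute tolerance for probability normalization on construction
PROB_TOL = 1e-9


@dataclass(frozen=True)
class Coordinate:
    """A named finite coordinate (one axis of the product state space)."""

    name: str
    cardinality: int

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ValueError(
                f"coordinate {self.name!r}: cardinality must be >= 2, "
                f"got {self.cardinality}"
            )


class JointSpace:
    """An ordered product of coordinates with a fixed flat enumeration.

    The flat index of a joint state tuple is lexicographic with the last
    listed coordinate varying fastest, i.e. ``np.ravel_multi_index`` in C
    order.  The enumeration is stable across runs.
    """

    def __init__(self, coordinates: Sequence[Coordinate]):
        coords = tuple(coordinates)
        names = [c.name for c in coords]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate coordinate names: {names}")
        self.coordinates: tuple[Coordinate, ...] = coords
        self.names: tuple[str, ...] = tuple(names)
        self.shape: tuple[int, ...] = tuple(c.cardinality for c in coords)
        self.size: int = int(np.prod(self.shape)) if coords else 0
        self._axis: dict[str, int] = {n: i for i, n in enumerate(names)}

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return self.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, JointSpace) and self.coordinates == other.coordinates

    def __hash__(self) -> int:
        return hash(self.coordinates)

    def __repr__(self) -> str:
        inner = ", ".join(f"{c.name}:{c.cardinality}" for c in self.coordinates)
        return f"JointSpace({inner})"

    def axis(self, name: str) -> int:
        try:
            return self._axis[name]
        except KeyError:
            raise KeyError(
                f"unknown coordinate {name!r}; known: {list(self.names)}"
            ) from None

    def axes(self, names: Iterable[str]) -> tuple[int, ...]:
        """Axis positions of ``names``, in space order (not argument order)."""
        idx = sorted(self.axis(n) for n in set(names))
        return tuple(idx)

    # -- enumeration ------------------------------------------------------

    def index(self, state: Sequence[int]) -> int:
        """Flat index of a joint-state tuple."""
        return int(np.ravel_multi_index(tuple(state), self.shape))

    def state(self, index: int) -> tuple[int, ...]:
        """Joint-state tuple of a flat index."""
        return tuple(int(v) for v in np.unravel_index(index, self.shape))

    def states(self) -> Iterable[tuple[int, ...]]:
        """All joint states in flat-enumeration order."""
        return itertools.product(*(range(c) for c in self.shape))

    def subspace(self, names: Iterable[str]) -> "JointSpace":
        """The product space of the named coordinates, in this space's order."""
        ax = self.axes(names)
        return JointSpace([self.coordinates[i] for i in ax])

    def restrict(self, vector: np.ndarray, names: Iterable[str]) -> np.ndarray:
        """Sum a flat joint vector over all coordinates not in ``names``."""
        keep = self.axes(names)
        drop = tuple(i for i in range(len(self.shape)) if i not in keep)
        t = np.asarray(vector).reshape(self.shape)
        return t.sum(axis=drop).reshape(-1)


class Distribution:
    """A probability distribution over a :class:`JointSpace`.

    Entries must be non-negative and sum to one within ``1e-9``.
    Renormalization never happens silently: pass ``renormalize=True`` to
    accept an unnormalized vector.
    """

    def __init__(
        self,
        space: JointSpace,
        probabilities: np.ndarray,
        *,
        renormalize: bool = False,
    ):
        p = np.asarray(probabilities, dtype=float).reshape(-1)
        if p.shape != (space.size,):
            raise ValueError(f"expected {space.size} probabilities, got {p.shape}")
        if np.any(p < -PROB_TOL):
            raise ValueError(f"negative probability: min={p.min()}")
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if abs(total - 1.0) > PROB_TOL:
            if not renormalize:
                raise ValueError(
                    f"probabilities sum to {total!r}; pass renormalize=True "
                    "to accept"
                )
            p = p / total
        self.space = space
        self.p = p

    def __repr__(self) -> str:
        return f"Distribution({self.space!r})"

    def marginal(self, names: Iterable[str]) -> "Distribution":
        return marginalize(self, names)

    def entropy(self) -> float:
        return shannon_entropy(self)

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per joint state: coordinate columns then 'probability'."""
        rows = [list(s) + [self.p[i]] for i, s in enumerate(self.space.states())]
        return pd.DataFrame(rows, columns=list(self.space.names) + ["probability"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: JointSpace, **kw) -> "Distribution":
        df = pd.read_csv(path)
        p = np.zeros(space.size)
        for _, row in df.iterrows():
            state = tuple(int(row[n]) for n in space.names)
            p[space.index(state)] = float(row["probability"])
        return cls(space, p, **kw)

    def to_json(self, path=None) -> str:
        obj = {
            ",".join(map(str, s)): float(self.p[i])
            for i, s in enumerate(self.space.states())
            if self.p[i] != 0.0
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source, space: JointSpace, **kw) -> "Distribution":
        if isinstance(source, Mapping):
            obj = source
        else:
            try:
                obj = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    obj = json.load(fh)
        p = np.zeros(space.size)
        for key, val in obj.items():
            state = tuple(int(v) for v in str(key).split(","))
            p[space.index(state)] = float(val)
        return cls(space, p, **kw)


class ConditionalMap:
    """A column-stochastic map over a joint space: column j is the final-state
    distribution given initial flat state j, i.e. p(x(tf) | x(ti))."""

    def __init__(self, space: JointSpace, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (space.size, space.size):
            raise ValueError(f"expected {(space.size,) * 2} matrix, got {m.shape}")
        if np.any(m < -PROB_TOL):
            raise ValueError("negative conditional probability")
        col = m.sum(axis=0)
        if np.max(np.abs(col - 1.0)) > PROB_TOL:
            raise ValueError(
                f"columns must sum to 1; worst deviation {np.max(np.abs(col - 1.0))}"
            )
        self.space = space
        self.matrix = np.clip(m, 0.0, None)

    def __call__(self, dist: Distribution) -> Distribution:
        if dist.space != self.space:
            raise ValueError("distribution is over a different space")
        return Distribution(self.space, self.matrix @ dist.p, renormalize=True)


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------


def marginalize(dist: Distribution, names: Iterable[str]) -> Distribution:
    """Marginal of ``dist`` over the coordinate-name set ``names``."""
    names = set(names)
    if not names:
        raise ValueError("cannot marginalize onto the empty coordinate set")
    sub = dist.space.subspace(names)
    return Distribution(sub, dist.space.restrict(dist.p, names), renormalize=True)


def shannon_entropy(dist: Distribution) -> float:
    """Shannon entropy S(p) in nats, with 0 ln 0 = 0."""
    return float(stats.entropy(dist.p))


def _subset_entropy(dist: Distribution, names: Iterable[str]) -> float:
    names = set(names)
    if not names:
        return 0.0
    return float(stats.entropy(dist.space.restrict(dist.p, names)))


def mutual_information(
    dist: Distribution, a: Iterable[str], b: Iterable[str]
) -> float:
    """I(A;B) = S(A) + S(B) - S(A,B) in nats, for disjoint coordinate sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("A and B must be non-empty")
    if a & b:
        raise ValueError(f"A and B must be disjoint; overlap {sorted(a & b)}")
    return (
        _subset_entropy(dist, a)
        + _subset_entropy(dist, b)
        - _subset_entropy(dist, a | b)
    )


def conditional_entropy(
    dist: Distribution, a: Iterable[str], b: Iterable[str]
) -> float:
    """S(A | B) = S(A,B) - S(B) in nats, for disjoint coordinate sets."""
    a, b = set(a), set(b)
    if not a:
        raise ValueError("A must be non-empty")
    if a & b:
        raise ValueError(f"A and B must be disjoint; overlap {sorted(a & b)}")
    return _subset_entropy(dist, a | b) - _subset_entropy(dist, b)


def multi_information(
    dist: Distribution, blocks: Sequence[Iterable[str]]
) -> float:
    """Total correlation sum_blocks S(block) - S(all) for a partition."""
    blocks = [set(b) for b in blocks]
    flat: list[str] = [n for b in blocks for n in b]
    if len(flat) != len(set(flat)) or set(flat) != set(dist.space.names):
        raise ValueError("blocks must partition the coordinate set")
    return sum(_subset_entropy(dist, b) for b in blocks) - shannon_entropy(dist)
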