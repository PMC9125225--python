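"""Reservoir-structured rate matrices and their assembly into a global CTMC.

A composite system couples a product state space to a set of reservoirs.
Each reservoir v fluctuates the coordinates in its *puppet set* P(v) while
its rates may read the coordinates in its *leader set* L(v) ⊇ P(v); all
other coordinates are untouched and unread.  The global generator is the sum
of the embedded reservoir matrices.

Entry convention (important — the literature is split): ``K[x, x']`` is the
rate of the transition x' → x, so the master equation reads ``dp/dt = K p``.
Columns of a generator sum to zero; off-diagonal entries are non-negative.

Compact reservoir tables are indexed ``T[a, l]`` where ``a`` enumerates the
destination puppet-set configuration and ``l`` the source leader-set
configuration, both in the flat enumeration of the corresponding sub-space.
Transitions leave every non-puppet coordinate fixed, so the embedded matrix
is ``K[(a, ctx), (l, ctx)] = T[a, l]`` for every context ``ctx`` of the
remaining coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import IndependenceError, ReservoirValidationError
from .statespace import Distribution, JointSpace

__all__ = [
    "ConstantRates",
    "PiecewiseRates",
    "CallableRates",
    "Reservoir",
    "CompositeSystem",
    "validate_reservoir",
    "marginal_generator",
    "check_rate_compatibility",
]

GEN_TOL = 1e-10


# ---------------------------------------------------------------------------
# rate protocols
# ---------------------------------------------------------------------------


class ConstantRates:
    """Time-independent rate table."""

    is_constant = True
    is_piecewise = True

    def __init__(self, table: np.ndarray):
        self.table = np.asarray(table, dtype=float)

    def at(self, t: float) -> np.ndarray:
        return self.table

    def breakpoints(self, ti: float, tf: float) -> list[float]:
        return []


class PiecewiseRates:
    """Piecewise-constant rate table given as ``(t0, t1, table)`` segments.

    Segments must tile an interval without gaps; a time is matched to the
    segment with ``t0 <= t < t1`` (the last segment is closed on the right).
    """

    is_constant = False
    is_piecewise = True

    def __init__(self, segments: Sequence[tuple[float, float, np.ndarray]]):
        segs = sorted(segments, key=lambda s: s[0])
        if not segs:
            raise ValueError("need at least one segment")
        for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
            if not np.isclose(a1, b0):
                raise ValueError(f"segments not contiguous at t={a1} vs {b0}")
        self.segments = [(float(t0), float(t1), np.asarray(m, float)) for t0, t1, m in segs]

    def at(self, t: float) -> np.ndarray:
        for t0, t1, m in self.segments:
            if t0 <= t < t1:
                return m
        t0, t1, m = self.segments[-1]
        if t >= t1 or t < self.segments[0][0]:
            # evaluate flat extension outside the protocol span
            return m if t >= t1 else self.segments[0][2]
        return m

    def breakpoints(self, ti: float, tf: float) -> list[float]:
        return [t0 for t0, _, _ in self.segments[1:] if ti < t0 < tf]


class CallableRates:
    """Arbitrary time dependence via a callable ``t -> table``."""

    is_constant = False
    is_piecewise = False

    def __init__(self, fn: Callable[[float], np.ndarray]):
        self.fn = fn

    def at(self, t: float) -> np.ndarray:
        return np.asarray(self.fn(t), dtype=float)

    def breakpoints(self, ti: float, tf: float) -> list[float]:
        return []


def _as_protocol(rates) -> ConstantRates | PiecewiseRates | CallableRates:
    if hasattr(rates, "at"):
        return rates
    if callable(rates):
        return CallableRates(rates)
    return ConstantRates(rates)


# ---------------------------------------------------------------------------
# index plumbing for embedding compact tables
# ---------------------------------------------------------------------------


def _group_contrib(space: JointSpace, axes: Sequence[int]) -> np.ndarray:
    """Flat-index contribution of each configuration of the given axes.

    The configurations are enumerated in the sub-space order (space order,
    last axis fastest); ``contrib[sub_index]`` is the summand such that the
    full flat index is the sum of the group contributions.
    """
    shape = space.shape
    strides = np.ones(len(shape), dtype=np.int64)
    for i in range(len(shape) - 2, -1, -1):
        strides[i] = strides[i + 1] * shape[i + 1]
    if not axes:
        return np.zeros(1, dtype=np.int64)
    sub_shape = [shape[i] for i in axes]
    grids = np.indices(sub_shape).reshape(len(axes), -1)
    return (grids * strides[list(axes)][:, None]).sum(axis=0)


@dataclass
class _Embedding:
    """Precomputed index arrays tying a reservoir's compact table to a space."""

    src: np.ndarray          # (nL, nCtx) flat source index
    dest: np.ndarray         # (nP, nL, nCtx) flat destination index
    n_puppet: int
    n_leader: int
    leader_puppet_part: np.ndarray  # (nL,) puppet sub-index of each leader config


def _build_embedding(space: JointSpace, puppets: frozenset, leaders: frozenset) -> _Embedding:
    p_axes = space.axes(puppets)
    l_axes = space.axes(leaders)
    q_axes = tuple(a for a in l_axes if a not in p_axes)      # leaders \ puppets
    r_axes = tuple(a for a in range(len(space.shape)) if a not in l_axes)

    cp = _group_contrib(space, p_axes)
    cq = _group_contrib(space, q_axes)
    cr = _group_contrib(space, r_axes)

    # decompose each leader configuration into its puppet and q parts
    l_shape = [space.shape[a] for a in l_axes]
    grids = np.indices(l_shape).reshape(len(l_axes), -1) if l_axes else np.zeros((0, 1), int)
    nL = grids.shape[1]
    lp = np.zeros(nL, dtype=np.int64)
    lq = np.zeros(nL, dtype=np.int64)
    p_pos = [i for i, a in enumerate(l_axes) if a in p_axes]
    q_pos = [i for i, a in enumerate(l_axes) if a in q_axes]
    for rank, i in enumerate(p_pos):
        mult = int(np.prod([space.shape[l_axes[j]] for j in p_pos[rank + 1:]], dtype=np.int64))
        lp += grids[i] * mult
    for rank, i in enumerate(q_pos):
        mult = int(np.prod([space.shape[l_axes[j]] for j in q_pos[rank + 1:]], dtype=np.int64))
        lq += grids[i] * mult

    nP = cp.size
    src = cp[lp][:, None] + cq[lq][:, None] + cr[None, :]               # (nL, nCtx)
    dest = cp[:, None, None] + (cq[lq][:, None] + cr[None, :])[None, :, :]  # (nP, nL, nCtx)
    return _Embedding(src=src, dest=dest, n_puppet=nP, n_leader=nL,
                      leader_puppet_part=lp)


# ---------------------------------------------------------------------------
# reservoirs
# ---------------------------------------------------------------------------


class Reservoir:
    """A thermodynamic reservoir coupled to a composite system.

    Parameters
    ----------
    name : str
    puppets : iterable of coordinate names the reservoir can move, P(v).
    leaders : iterable of coordinate names the rates may depend on, L(v) ⊇ P(v).
    rates :
        Either a compact table (ndarray of shape ``(nP, nL)``), a rate
        protocol object, a callable ``t -> table``, or — with
        ``full_matrix=True`` — any of those producing a full joint-space
        matrix (used mainly to express *invalid* reservoirs in tests).
    """

    def __init__(self, name: str, puppets: Iterable[str], leaders: Iterable[str],
                 rates, *, full_matrix: bool = False):
        self.name = name
        self.puppets = frozenset(puppets)
        self.leaders = frozenset(leaders)
        if not self.puppets:
            raise ValueError(f"reservoir {name!r}: puppet set must be non-empty")
        if not self.puppets <= self.leaders:
            raise ValueError(
                f"reservoir {name!r}: leader set must contain the puppet set"
            )
        self.protocol = _as_protocol(rates)
        self.full_matrix = bool(full_matrix)
        self._embeddings: dict[JointSpace, _Embedding] = {}

    def __repr__(self) -> str:
        return (f"Reservoir({self.name!r}, P={sorted(self.puppets)}, "
                f"L={sorted(self.leaders)})")

    def _embedding(self, space: JointSpace) -> _Embedding:
        emb = self._embeddings.get(space)
        if emb is None:
            emb = _build_embedding(space, self.puppets, self.leaders)
            self._embeddings[space] = emb
        return emb

    def table_at(self, t: float, space: JointSpace) -> np.ndarray:
        """Compact table ``T[a, l]`` at time t (extracted if full-matrix)."""
        emb = self._embedding(space)
        raw = self.protocol.at(t)
        if not self.full_matrix:
            if raw.shape != (emb.n_puppet, emb.n_leader):
                raise ValueError(
                    f"reservoir {self.name!r}: table shape {raw.shape} != "
                    f"{(emb.n_puppet, emb.n_leader)}"
                )
            return raw
        # read the entries at context 0; validation checks the rest
        return raw[emb.dest[:, :, 0], emb.src[None, :, 0]]

    def embedded(self, t: float, space: JointSpace) -> np.ndarray:
        """The reservoir's full rate matrix over the joint space at time t."""
        if self.full_matrix:
            m = self.protocol.at(t)
            if m.shape != (space.size, space.size):
                raise ValueError(
                    f"reservoir {self.name!r}: matrix shape {m.shape} != "
                    f"{(space.size,) * 2}"
                )
            return m
        emb = self._embedding(space)
        table = self.table_at(t, space)
        K = np.zeros((space.size, space.size))
        for a in range(emb.n_puppet):
            K[emb.dest[a].ravel(), emb.src.ravel()] += np.repeat(
                table[a], emb.src.shape[1]
            )
        return K

    def restricted(self, names: Iterable[str]) -> "Reservoir":
        """The same reservoir viewed inside a sub-space containing L(v)."""
        names = frozenset(names)
        if not self.leaders <= names:
            raise ValueError(
                f"reservoir {self.name!r}: leader set {sorted(self.leaders)} "
                f"not inside {sorted(names)}"
            )
        if self.full_matrix:
            raise ValueError(
                f"reservoir {self.name!r}: full-matrix reservoirs cannot be "
                "restricted"
            )
        return Reservoir(self.name, self.puppets, self.leaders, self.protocol)


def validate_reservoir(res: Reservoir, space: JointSpace,
                       times: Sequence[float] = (0.0,), tol: float = GEN_TOL
                       ) -> list[str]:
    """Check the four structural invariants of a reservoir rate matrix.

    Returns a list of violation messages (empty iff valid): off-diagonal
    non-negativity, zero column sums, transitions moving only puppet
    coordinates, and rate dependence restricted to leader coordinates.
    """
    violations: list[str] = []
    emb = res._embedding(space)
    for t in times:
        M = res.embedded(t, space)
        table = res.table_at(t, space)
        # reconstruct the matrix implied by the compact reading of M
        implied = np.zeros_like(M)
        for a in range(emb.n_puppet):
            implied[emb.dest[a].ravel(), emb.src.ravel()] += np.repeat(
                table[a], emb.src.shape[1]
            )
        diff = M - implied
        if np.max(np.abs(diff)) > tol:
            rows, cols = np.nonzero(np.abs(diff) > tol)
            moved_outside = False
            for r, c in zip(rows, cols):
                changed = {
                    space.names[i]
                    for i, (a, b) in enumerate(zip(space.state(r), space.state(c)))
                    if a != b
                }
                if not changed <= res.puppets:
                    moved_outside = True
                    violations.append(
                        f"t={t}: moves non-puppet coordinate(s) "
                        f"{sorted(changed - res.puppets)} in transition "
                        f"{space.state(c)} -> {space.state(r)}"
                    )
                    break
            if not moved_outside:
                r, c = rows[0], cols[0]
                violations.append(
                    f"t={t}: non-leader dependence — entry for "
                    f"{space.state(c)} -> {space.state(r)} differs across "
                    "non-leader states"
                )
        # off-diagonal sign and column normalization on the compact table
        off = table.copy()
        off[emb.leader_puppet_part, np.arange(emb.n_leader)] = 0.0
        if np.min(off, initial=0.0) < -tol:
            violations.append(f"t={t}: negative off-diagonal rate")
        col = table.sum(axis=0)
        if np.max(np.abs(col), initial=0.0) > tol:
            violations.append(
                f"t={t}: column sums not zero (max |sum| = {np.max(np.abs(col)):.2e})"
            )
    return violations


# ---------------------------------------------------------------------------
# composite system
# ---------------------------------------------------------------------------


class CompositeSystem:
    """A joint space plus the reservoirs that drive it.

    The puppet sets must cover every coordinate, and no two reservoirs may
    share an identical puppet set (set ``allow_duplicate_puppets=True`` to
    lift the latter restriction).
    """

    def __init__(self, space: JointSpace, reservoirs: Sequence[Reservoir], *,
                 allow_duplicate_puppets: bool = False):
        self.space = space
        self.reservoirs = list(reservoirs)
        all_names = set(space.names)
        for res in self.reservoirs:
            unknown = (res.puppets | res.leaders) - all_names
            if unknown:
                raise KeyError(
                    f"reservoir {res.name!r} references unknown coordinates "
                    f"{sorted(unknown)}"
                )
        covered = frozenset().union(*(r.puppets for r in self.reservoirs)) \
            if self.reservoirs else frozenset()
        if covered != all_names:
            raise ValueError(
                f"puppet sets must cover all coordinates; missing "
                f"{sorted(all_names - covered)}"
            )
        puppet_sets = [r.puppets for r in self.reservoirs]
        if len(set(puppet_sets)) != len(puppet_sets) and not allow_duplicate_puppets:
            raise ValueError(
                "two reservoirs share a puppet set; pass "
                "allow_duplicate_puppets=True to permit this"
            )
        self._ndiff: np.ndarray | None = None

    def __repr__(self) -> str:
        return f"CompositeSystem({self.space!r}, {len(self.reservoirs)} reservoirs)"

    # -- reservoir-structure queries (ν, L, P closures) -------------------

    def reservoirs_affecting(self, names: Iterable[str]) -> list[Reservoir]:
        """ν(A): reservoirs whose puppet set intersects A."""
        a = self._check_names(names)
        return [r for r in self.reservoirs if r.puppets & a]

    def leader_closure(self, names: Iterable[str]) -> frozenset:
        """L(A): coordinates that can directly affect the dynamics of A."""
        a = self._check_names(names)
        out = set(a)
        for r in self.reservoirs:
            if r.puppets & a:
                out |= r.leaders
        return frozenset(out)

    def puppet_closure(self, names: Iterable[str]) -> frozenset:
        """P(A): coordinates whose dynamics is governed jointly with A."""
        a = self._check_names(names)
        out = set(a)
        for r in self.reservoirs:
            if r.puppets & a:
                out |= r.puppets
        return frozenset(out)

    def _check_names(self, names: Iterable[str]) -> frozenset:
        a = frozenset(names)
        unknown = a - set(self.space.names)
        if unknown:
            raise KeyError(f"unknown coordinates {sorted(unknown)}")
        return a

    # -- protocol bookkeeping ---------------------------------------------

    @property
    def is_piecewise(self) -> bool:
        return all(r.protocol.is_piecewise for r in self.reservoirs)

    def breakpoints(self, ti: float, tf: float) -> list[float]:
        pts: set[float] = set()
        for r in self.reservoirs:
            pts.update(r.protocol.breakpoints(ti, tf))
        return sorted(pts)

    def sample_times(self, ti: float = 0.0, tf: float = 1.0,
                     n_interior: int = 10) -> np.ndarray:
        """Times at which structural properties are checked.

        Constant protocols need a single sample; otherwise segment
        boundaries plus interior points are used.
        """
        if all(r.protocol.is_constant for r in self.reservoirs):
            return np.array([ti])
        pts = [ti, tf] + self.breakpoints(ti, tf)
        pts += list(np.linspace(ti, tf, n_interior + 2)[1:-1])
        return np.unique(pts)

    # -- the global generator ----------------------------------------------

    def global_rate(self, t: float, *, validate: bool = False) -> np.ndarray:
        """The global rate matrix K(t) = Σ_v (embedded reservoir matrix)."""
        if validate:
            for r in self.reservoirs:
                v = validate_reservoir(r, self.space, times=[t])
                if v:
                    raise ReservoirValidationError(v)
        K = np.zeros((self.space.size, self.space.size))
        for r in self.reservoirs:
            K += r.embedded(t, self.space)
        return K

    # -- units --------------------------------------------------------------

    def marginal_rate(self, names: Iterable[str], t: float,
                      tol: float = GEN_TOL) -> np.ndarray:
        """The marginal generator over ``names`` at time t.

        Raises :class:`IndependenceError` if the summed rates depend on the
        outside coordinates (i.e. ``names`` is not a unit at time t).
        """
        a = self._check_names(names)
        if not a:
            raise ValueError("coordinate set must be non-empty")
        M, resid, witness = marginal_generator(self.global_rate(t), self.space, a)
        if resid > tol:
            raise IndependenceError(a, resid, witness)
        return M

    def is_unit(self, names: Iterable[str],
                times: Sequence[float] | None = None) -> bool:
        """True iff the marginal of ``names`` evolves as its own CTMC at
        every sampled protocol time."""
        if times is None:
            times = self.sample_times()
        try:
            for t in times:
                self.marginal_rate(names, t)
        except IndependenceError:
            return False
        return True

    def is_multipartite(self, times: Sequence[float] | None = None) -> bool:
        """True iff no transition changes more than one coordinate."""
        if times is None:
            times = self.sample_times()
        nd = self._ndiff_matrix()
        for t in times:
            K = self.global_rate(t)
            if np.any((np.abs(K) > GEN_TOL) & (nd > 1)):
                return False
        return True

    def _ndiff_matrix(self) -> np.ndarray:
        if self._ndiff is None:
            digits = np.array([s for s in self.space.states()])  # (n, n_axes)
            self._ndiff = (digits[:, None, :] != digits[None, :, :]).sum(axis=2)
        return self._ndiff

    def subsystem(self, names: Iterable[str]) -> "CompositeSystem":
        """The self-contained system over a unit ω of a tight structure:
        the sub-space of ω driven by the reservoirs ν(ω), all of whose
        leader sets must lie inside ω."""
        a = self._check_names(names)
        res = self.reservoirs_affecting(a)
        for r in res:
            if not r.leaders <= a:
                raise ValueError(
                    f"{sorted(a)} is not tight: reservoir {r.name!r} has "
                    f"leader set {sorted(r.leaders)} outside it"
                )
        sub = self.space.subspace(a)
        return CompositeSystem(sub, [r.restricted(a) for r in res])


# ---------------------------------------------------------------------------
# marginal generators and compatibility
# ---------------------------------------------------------------------------


def marginal_generator(K: np.ndarray, space: JointSpace,
                       names: Iterable[str]) -> tuple[np.ndarray, float, tuple]:
    """Candidate marginal generator of ``K`` over ``names``.

    Sums the destination states of the outside coordinates, then checks that
    the result is independent of the *source* outside state.  Returns
    ``(matrix, max_discrepancy, witness)`` where the matrix averages over
    outside sources and the witness locates the worst spread.
    """
    keep = space.axes(names)
    nax = len(space.shape)
    drop = tuple(i for i in range(nax) if i not in keep)
    sub_shape = [space.shape[i] for i in keep]
    n_sub = int(np.prod(sub_shape))
    n_rest = space.size // n_sub

    T = np.asarray(K).reshape(space.shape + space.shape)
    # sum over destination outside-axes
    T = T.sum(axis=drop)
    # move source kept-axes forward, flatten: (n_sub, n_sub, n_rest)
    src_order = tuple(len(sub_shape) + i
                      for i in list(keep) + list(drop))
    T = np.transpose(T, tuple(range(len(sub_shape))) + src_order)
    T = T.reshape(n_sub, n_sub, n_rest)

    mean = T.mean(axis=2)
    spread = T.max(axis=2) - T.min(axis=2)
    resid = float(spread.max(initial=0.0))
    i, j = np.unravel_index(int(np.argmax(spread)), spread.shape)
    sub = space.subspace(names)
    witness = (sub.state(int(i)), sub.state(int(j)))
    return mean, resid, witness


def check_rate_compatibility(K_alpha: np.ndarray, K_omega: np.ndarray,
                             alpha: Iterable[str], omega_space: JointSpace,
                             tol: float = GEN_TOL) -> tuple[bool, float]:
    """Check that a sub-unit generator is the consistent marginal of a
    containing unit's generator, for every source state of ω∖α.

    Returns ``(compatible, max_residual)``.
    """
    a = frozenset(alpha)
    if not a <= set(omega_space.names):
        raise ValueError(f"{sorted(a)} not contained in {omega_space.names}")
    M, resid, _ = marginal_generator(K_omega, omega_space, a)
    K_alpha = np.asarray(K_alpha)
    if K_alpha.shape != M.shape:
        raise ValueError(f"shape mismatch: {K_alpha.shape} vs {M.shape}")
    resid = max(resid, float(np.max(np.abs(M - K_alpha))))
    return resid <= tol, resid
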