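"""Master-equation integration: dp/dt = K(t) p.

Piecewise-constant protocols are propagated exactly with matrix exponentials
on the output grid; arbitrary time dependence falls back to a dense ODE
solver.  The resulting :class:`EvolutionRecord` carries the distribution
snapshots that all integrated thermodynamic quantities are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import UnitflowError
from .reservoirs import CompositeSystem
from .statespace import ConditionalMap, Distribution

__all__ = ["EvolutionRecord", "evolve", "conditional_map",
           "conditional_consistency_check"]


@dataclass
class EvolutionRecord:
    """Distribution snapshots of a composite system on a time grid."""

    system: CompositeSystem
    times: np.ndarray            # strictly increasing, (n_t,)
    probs: np.ndarray            # (n_t, n_states)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        norms = self.probs.sum(axis=1)
        worst = float(np.max(np.abs(norms - 1.0)))
        if worst > 1e-8:
            raise UnitflowError(f"snapshot normalization error {worst:.2e}")

    def __len__(self) -> int:
        return len(self.times)

    def snapshot(self, i: int) -> Distribution:
        return Distribution(self.system.space, self.probs[i], renormalize=True)

    @property
    def initial(self) -> Distribution:
        return self.snapshot(0)

    @property
    def final(self) -> Distribution:
        return self.snapshot(len(self.times) - 1)

    def to_frame(self):
        import pandas as pd

        labels = ["-".join(map(str, s)) for s in self.system.space.states()]
        df = pd.DataFrame(self.probs, columns=labels)
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _grid(sys: CompositeSystem, ti: float, tf: float, n_grid: int) -> np.ndarray:
    base = np.linspace(ti, tf, n_grid)
    return np.unique(np.concatenate([base, sys.breakpoints(ti, tf)]))


def evolve(sys: CompositeSystem, p0: Distribution, ti: float, tf: float, *,
           n_grid: int = 201, rtol: float = 1e-8, atol: float = 1e-12
           ) -> EvolutionRecord:
    """Integrate the master equation from ti to tf.

    For piecewise-constant protocols each grid step is propagated exactly by
    ``expm(K dt)``; otherwise an adaptive solver (LSODA) is evaluated on the
    grid.  Snapshots are normalized to 1e-8 by construction (probability is
    conserved because columns of K sum to zero).
    """
    if p0.space != sys.space:
        raise ValueError("initial distribution is over a different space")
    if not ti < tf:
        raise ValueError(f"need ti < tf, got {ti} >= {tf}")
    times = _grid(sys, ti, tf, n_grid)
    n = sys.space.size
    probs = np.empty((len(times), n))
    probs[0] = p0.p

    if sys.is_piecewise:
        prop_cache: dict[tuple[float, float], np.ndarray] = {}
        for k in range(len(times) - 1):
            t0, t1 = float(times[k]), float(times[k + 1])
            mid = 0.5 * (t0 + t1)
            dt = t1 - t0
            K = sys.global_rate(mid)
            key = (round(dt, 15), _matrix_key(K))
            P = prop_cache.get(key)
            if P is None:
                P = expm(K * dt)
                prop_cache[key] = P
            probs[k + 1] = P @ probs[k]
        meta = {"method": "expm", "rtol": 0.0, "n_steps": len(times) - 1}
    else:
        def rhs(t: float, p: np.ndarray) -> np.ndarray:
            return sys.global_rate(t) @ p

        sol = solve_ivp(rhs, (ti, tf), p0.p, t_eval=times, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise UnitflowError(f"integrator failed: {sol.message}")
        probs = sol.y.T
        meta = {"method": "LSODA", "rtol": rtol, "n_steps": int(sol.nfev)}

    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return EvolutionRecord(system=sys, times=times, probs=probs, meta=meta)


def _matrix_key(K: np.ndarray) -> int:
    return hash(K.tobytes())


def conditional_map(sys: CompositeSystem, ti: float, tf: float, *,
                    rtol: float = 1e-8, n_grid: int = 201) -> ConditionalMap:
    """The transition kernel p(x(tf) | x(ti)) as a column-stochastic matrix.

    Column j is the solution of the master equation started from the delta
    distribution on flat state j.
    """
    if not ti < tf:
        raise ValueError(f"need ti < tf, got {ti} >= {tf}")
    n = sys.space.size
    if sys.is_piecewise:
        pts = np.unique([ti, tf] + sys.breakpoints(ti, tf))
        M = np.eye(n)
        for t0, t1 in zip(pts[:-1], pts[1:]):
            K = sys.global_rate(0.5 * (t0 + t1))
            M = expm(K * (t1 - t0)) @ M
    else:
        def rhs(t: float, m: np.ndarray) -> np.ndarray:
            return (sys.global_rate(t) @ m.reshape(n, n)).ravel()

        sol = solve_ivp(rhs, (ti, tf), np.eye(n).ravel(), method="LSODA",
                        rtol=rtol, atol=1e-12)
        if not sol.success:
            raise UnitflowError(f"integrator failed: {sol.message}")
        M = sol.y[:, -1].reshape(n, n)
    M = np.clip(M, 0.0, None)
    M /= M.sum(axis=0, keepdims=True)
    return ConditionalMap(sys.space, M)


def conditional_consistency_check(cmap: ConditionalMap, units, *,
                                  tol: float = 1e-8) -> bool:
    """Necessary conditions for a transition kernel to be consistent with a
    unit structure.

    For every unit ω the marginal kernel p(x_ω(tf) | x(ti)) must be
    independent of the initial state of the outside coordinates.  This is
    necessary but not sufficient: whether some generator obeying the
    structure realizes the kernel is an embedding-existence question that is
    not decided here.
    """
    space = cmap.space
    shape = space.shape
    nax = len(shape)
    for unit in units:
        keep = space.axes(unit)
        drop = tuple(i for i in range(nax) if i not in keep)
        T = cmap.matrix.reshape(shape + shape)
        T = T.sum(axis=drop)  # marginal over destination outside-axes
        # order source axes: kept first, outside last; flatten outside
        perm = tuple(range(len(keep))) + tuple(len(keep) + i for i in list(keep) + list(drop))
        T = np.transpose(T, perm)
        n_keep = int(np.prod([shape[i] for i in keep]))
        T = T.reshape(n_keep, n_keep, -1)
        if float(np.max(T.max(axis=2) - T.min(axis=2), initial=0.0)) > tol:
            return False
    return True
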