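"""Entropy flow, entropy production, their unit-level decompositions, and
the strengthened second law (SSL).

Conventions: all quantities are in nats (k_B = 1).  The entropy-flow (EF)
rate counts entropy flowing *into the reservoirs*,

    ⟨Q̇⟩ = Σ_v Σ_{x ≠ x'} L_xx'(v) p_x' ln( L_xx'(v) / L_x'x(v) ),

so the EP rate is ⟨σ̇⟩ = dS/dt + ⟨Q̇⟩ ≥ 0, and integrated EP over a process
is σ = ΔS + Q.  Per-unit quantities restrict the reservoir sum to ν(ω); the
per-unit EP additionally uses the unit's own marginal distribution, which
requires the structure to be tight (so the unit generator is the sum of its
own reservoirs' matrices).

The in-ex decomposition of the global EF rate over a unit structure,
⟨Q̇_N⟩ = Σ̂_ω ⟨Q̇_ω⟩, integrates to  σ_N = Σ̂_ω σ_ω − ΔI_N∗,  and dropping
the non-negative in-ex sum of local EPs gives the SSL bound σ_N ≥ −ΔI_N∗,
guaranteed for unit structures of dependency-graph height ≤ 2.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import simpson, trapezoid

from .dynamics import EvolutionRecord
from .errors import IrreversibleTransitionError, QuadratureError
from .reservoirs import GEN_TOL, CompositeSystem, Reservoir
from .statespace import Distribution, shannon_entropy
from .structures import (
    UnitStructure,
    build_dependency_graph,
    in_ex_information,
    inclusion_exclusion_sum,
)

__all__ = [
    "ef_rate",
    "ep_rate",
    "integrate_thermo",
    "ThermoReport",
    "SSLBound",
    "ssl_bound",
    "example1_bound",
    "check_inequalities",
]

#: tolerance on integrated quantities (quadrature refinement target)
QUAD_TOL = 1e-6
#: slack allowed when checking inequalities on integrated quantities
CHECK_TOL = 1e-6


def _label(unit: Iterable[str]) -> str:
    return ",".join(sorted(unit))


def _reservoir_ef_rate(res: Reservoir, sys: CompositeSystem,
                       p: np.ndarray, t: float) -> float:
    """EF rate into a single reservoir, Σ_{x≠x'} L p' ln(L/L~)."""
    L = res.embedded(t, sys.space)
    off = L.copy()
    np.fill_diagonal(off, 0.0)
    fwd = off > GEN_TOL
    if np.any(fwd & ~fwd.T):
        r, c = np.argwhere(fwd & ~fwd.T)[0]
        raise IrreversibleTransitionError(
            res.name, (sys.space.state(int(r)), sys.space.state(int(c)))
        )
    total = 0.0
    rows, cols = np.nonzero(fwd)
    if rows.size:
        lf = off[rows, cols]
        lb = off[cols, rows]
        total = float(np.sum(lf * p[cols] * np.log(lf / lb)))
    return total


def _reservoir_ep_rate(res: Reservoir, sys: CompositeSystem,
                       p: np.ndarray, t: float) -> float:
    """EP-rate contribution Σ_{x≠x'} L p' ln(L p' / (L~ p))."""
    L = res.embedded(t, sys.space)
    off = L.copy()
    np.fill_diagonal(off, 0.0)
    fwd = off > GEN_TOL
    if np.any(fwd & ~fwd.T):
        r, c = np.argwhere(fwd & ~fwd.T)[0]
        raise IrreversibleTransitionError(
            res.name, (sys.space.state(int(r)), sys.space.state(int(c)))
        )
    rows, cols = np.nonzero(fwd)
    if not rows.size:
        return 0.0
    lf = off[rows, cols] * p[cols]
    lb = off[cols, rows] * p[rows]
    active = lf > 0
    if np.any(active & (lb <= 0)):
        return float("inf")
    lf, lb = lf[active], lb[active]
    return float(np.sum(lf * np.log(lf / lb)))


def _scope_reservoirs(sys: CompositeSystem, scope) -> list[Reservoir]:
    if isinstance(scope, str) and scope == "global":
        return list(sys.reservoirs)
    return sys.reservoirs_affecting(scope)


def ef_rate(sys: CompositeSystem, p: Distribution, t: float,
            scope="global", *, check_unit: bool = False) -> float:
    """Expected entropy-flow rate into the reservoirs of ``scope``, nats/time.

    ``scope`` is ``"global"`` (all reservoirs), a coordinate set naming a
    unit (reservoirs ν(ω)), or a pair ``(ω, ω')`` of coordinate sets, which
    yields the signed-measure difference ⟨Q̇_ω⟩ − ⟨Q̇_ω'⟩.
    """
    if (isinstance(scope, tuple) and len(scope) == 2
            and not isinstance(scope[0], str)):
        return (ef_rate(sys, p, t, scope[0], check_unit=check_unit)
                - ef_rate(sys, p, t, scope[1], check_unit=check_unit))
    if check_unit and scope != "global" and not sys.is_unit(scope):
        raise ValueError(f"{sorted(scope)} is not a unit of the system")
    return sum(_reservoir_ef_rate(r, sys, p.p, t)
               for r in _scope_reservoirs(sys, scope))


def ep_rate(sys: CompositeSystem, p: Distribution, t: float,
            scope="global") -> float:
    """Expected entropy-production rate, nats/time; non-negative.

    Global scope sums the Schnakenberg form over all reservoirs with the
    full distribution.  Unit scope builds the unit's own self-contained
    system (requires every reservoir in ν(ω) to have its leader set inside
    ω, i.e. tightness) and evaluates the same form with the marginal
    distribution.  Returns +inf when a state with zero probability receives
    probability current.
    """
    if isinstance(scope, str) and scope == "global":
        return sum(_reservoir_ep_rate(r, sys, p.p, t) for r in sys.reservoirs)
    sub = sys.subsystem(scope)  # raises if not tight around this unit
    pm = p.marginal(scope)
    return sum(_reservoir_ep_rate(r, sub, pm.p, t) for r in sub.reservoirs)


# ---------------------------------------------------------------------------
# integrated report
# ---------------------------------------------------------------------------


@dataclass
class SSLBound:
    """The strengthened-second-law lower bound B = −ΔI_N∗ on integrated EP.

    ``guaranteed`` is True when the structure's dependency graph has height
    ≤ 2, the regime in which the bound is proven; for taller structures the
    value is still computed but is not guaranteed to be a valid bound.
    """

    value: float
    guaranteed: bool
    height: int

    def __float__(self) -> float:
        return self.value


def ssl_bound(p_i: Distribution, p_f: Distribution,
              structure: UnitStructure) -> SSLBound:
    """B_N∗ = I_N∗(p_i) − I_N∗(p_f): depends only on the endpoint
    distributions and the unit structure, never on the dynamics."""
    height = build_dependency_graph(structure).height
    value = in_ex_information(p_i, structure) - in_ex_information(p_f, structure)
    return SSLBound(value=value, guaranteed=height <= 2, height=height)


def example1_bound(p_i: Distribution, p_f: Distribution,
                   structure: UnitStructure) -> float:
    """EP lower bound for processes whose shared (intersection) coordinates
    stay constant: root-unit entropy drops minus the global entropy drop.

    For pairwise-disjoint singleton units this is the drop in
    multi-information among the coordinates, which is non-negative whenever
    the dynamics factorizes (data processing).
    """
    graph = build_dependency_graph(structure)
    roots = graph.roots
    drop_units = sum(
        shannon_entropy(p_i.marginal(u)) - shannon_entropy(p_f.marginal(u))
        for u in roots
    )
    drop_global = shannon_entropy(p_i) - shannon_entropy(p_f)
    return drop_units - drop_global


@dataclass
class ThermoReport:
    """Integrated per-unit and global EF/EP with decomposition diagnostics.

    Keys of the per-unit maps are comma-joined sorted coordinate labels.
    ``residual_ef_pointwise`` is the worst grid-point violation of the in-ex
    EF decomposition ⟨Q̇_N⟩ = Σ̂⟨Q̇_ω⟩; ``residual_ep_integrated`` is the
    defect of σ_N = Σ̂σ_ω − ΔI_N∗.
    """

    structure: UnitStructure
    times: np.ndarray
    Q: dict[str, float]
    sigma: dict[str, float]
    Q_N: float
    sigma_N: float
    S_initial: dict[str, float]
    S_final: dict[str, float]
    S_N_initial: float
    S_N_final: float
    I_initial: float
    I_final: float
    B: SSLBound
    residual_ef_pointwise: float
    residual_ep_integrated: float
    checks: dict[str, bool] = field(default_factory=dict)
    slacks: dict[str, float] = field(default_factory=dict)
    quad_error: float = 0.0

    def to_dict(self) -> dict:
        return {
            "units": self.structure.to_lists(),
            "Q": self.Q,
            "sigma": self.sigma,
            "Q_N": self.Q_N,
            "sigma_N": self.sigma_N,
            "I_initial": self.I_initial,
            "I_final": self.I_final,
            "B": self.B.value,
            "B_guaranteed": self.B.guaranteed,
            "residuals": {
                "ef_pointwise": self.residual_ef_pointwise,
                "ep_integrated": self.residual_ep_integrated,
                "quadrature": self.quad_error,
            },
            "checks": self.checks,
            "slacks": self.slacks,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def integrate_thermo(sys: CompositeSystem, record: EvolutionRecord,
                     structure: UnitStructure, *,
                     quad_tol: float = QUAD_TOL) -> ThermoReport:
    """Integrate EF/EP over a recorded evolution and fill a ThermoReport.

    Per-unit EF rates are additive over reservoirs, so the per-reservoir EF
    rate series is computed once on the record grid and summed over ν(ω)
    for each unit.  Integrated per-unit EP uses σ_ω = ΔS_ω + Q_ω, which is
    exact given the endpoint marginals and avoids the (integrable) log
    divergence of the EP rate at deterministic starts.  Quadrature uses
    Simpson's rule with a trapezoid cross-check; a grid too coarse for the
    requested tolerance raises :class:`QuadratureError`.
    """
    if record.system is not sys and record.system.space != sys.space:
        raise ValueError("record does not belong to this system")
    times = record.times
    n_t = len(times)

    # per-reservoir EF rate series on the grid
    series = np.zeros((len(sys.reservoirs), n_t))
    for k in range(n_t):
        p = record.probs[k]
        t = float(times[k])
        for j, res in enumerate(sys.reservoirs):
            series[j, k] = _reservoir_ef_rate(res, sys, p, t)

    res_index = {res.name: j for j, res in enumerate(sys.reservoirs)}

    def unit_series(unit: frozenset) -> np.ndarray:
        rows = [res_index[r.name] for r in sys.reservoirs_affecting(unit)]
        return series[rows].sum(axis=0) if rows else np.zeros(n_t)

    def integrate(y: np.ndarray) -> tuple[float, float]:
        a = float(simpson(y, x=times))
        b = float(trapezoid(y, x=times))
        return a, abs(a - b)

    p_i, p_f = record.initial, record.final

    Q: dict[str, float] = {}
    sigma: dict[str, float] = {}
    S_i: dict[str, float] = {}
    S_f: dict[str, float] = {}
    sigma_by_unit: dict[frozenset, float] = {}
    quad_err = 0.0
    for u in structure:
        q, err = integrate(unit_series(u))
        quad_err = max(quad_err, err)
        si = shannon_entropy(p_i.marginal(u))
        sf = shannon_entropy(p_f.marginal(u))
        lab = _label(u)
        Q[lab], S_i[lab], S_f[lab] = q, si, sf
        sigma[lab] = (sf - si) + q
        sigma_by_unit[u] = sigma[lab]

    qn_series = series.sum(axis=0)
    Q_N, err = integrate(qn_series)
    quad_err = max(quad_err, err)
    if quad_err > max(quad_tol, 1e-3 * max(1.0, abs(Q_N))):
        raise QuadratureError(
            f"quadrature cross-check error {quad_err:.2e} exceeds tolerance; "
            "re-run evolve() with a denser grid (larger n_grid)"
        )
    S_N_i = shannon_entropy(p_i)
    S_N_f = shannon_entropy(p_f)
    sigma_N = (S_N_f - S_N_i) + Q_N

    I_i = in_ex_information(p_i, structure)
    I_f = in_ex_information(p_f, structure)
    bound = ssl_bound(p_i, p_f, structure)

    # Eq-level residuals
    inex_series = inclusion_exclusion_sum(unit_series, structure)
    residual_ef = float(np.max(np.abs(qn_series - inex_series)))
    inex_sigma = inclusion_exclusion_sum(
        lambda u: sigma_by_unit[u], structure
    )
    residual_ep = abs(sigma_N - (inex_sigma - (I_f - I_i)))

    report = ThermoReport(
        structure=structure, times=times, Q=Q, sigma=sigma, Q_N=Q_N,
        sigma_N=sigma_N, S_initial=S_i, S_final=S_f,
        S_N_initial=S_N_i, S_N_final=S_N_f,
        I_initial=I_i, I_final=I_f, B=bound,
        residual_ef_pointwise=residual_ef,
        residual_ep_integrated=residual_ep,
        quad_error=quad_err,
    )
    check_inequalities(report)
    return report


def check_inequalities(report: ThermoReport, tol: float = CHECK_TOL) -> dict:
    """Verify the EP inequalities on an integrated report.

    Checks the conventional second law (σ_N ≥ 0 and σ_ω ≥ 0 for every
    unit), monotonicity under inclusion (σ_ω ≥ σ_α for nested units), the
    disjoint-sum bound (σ_ω ≥ Σ_j σ_αj for pairwise-disjoint subunits), the
    nested-structure bound σ_ω − Σ̂_{M∗} σ_ω′ ≥ −ΔI_{M∗}, and σ_N ≥ B_N∗.
    Fills ``report.checks`` / ``report.slacks`` and returns the checks dict.
    """
    checks: dict[str, bool] = {}
    slacks: dict[str, float] = {}
    structure = report.structure
    sig = {frozenset(lab.split(",")): v for lab, v in report.sigma.items()}

    worst = min(sig.values()) if sig else 0.0
    checks["sigma_unit_nonneg"] = worst >= -tol
    slacks["sigma_unit_nonneg"] = worst
    checks["sigma_N_nonneg"] = report.sigma_N >= -tol
    slacks["sigma_N_nonneg"] = report.sigma_N

    nested_ok, nested_slack = True, float("inf")
    for a, w in itertools.permutations(structure.units, 2):
        if a < w:
            s = sig[w] - sig[a]
            nested_slack = min(nested_slack, s)
            if s < -tol:
                nested_ok = False
    checks["nested_monotone"] = nested_ok
    slacks["nested_monotone"] = nested_slack if nested_slack != float("inf") else 0.0

    disjoint_ok, disjoint_slack = True, float("inf")
    for w in structure.units:
        inside = [a for a in structure.units if a < w]
        for k in range(2, len(inside) + 1):
            for family in itertools.combinations(inside, k):
                if all(not (a & b) for a, b in itertools.combinations(family, 2)):
                    s = sig[w] - sum(sig[a] for a in family)
                    disjoint_slack = min(disjoint_slack, s)
                    if s < -tol:
                        disjoint_ok = False
    checks["disjoint_sum"] = disjoint_ok
    slacks["disjoint_sum"] = (disjoint_slack
                              if disjoint_slack != float("inf") else 0.0)

    checks["ssl"] = report.sigma_N >= report.B.value - max(
        tol, 10 * report.quad_error
    )
    slacks["ssl"] = report.sigma_N - report.B.value

    checks["ef_decomposition"] = report.residual_ef_pointwise < 1e-8
    checks["ep_decomposition"] = report.residual_ep_integrated < 1e-5

    report.checks.update(checks)
    report.slacks.update(slacks)
    return checks


def nested_structure_bound(report: ThermoReport, omega: Iterable[str],
                           substructure: UnitStructure,
                           p_i: Distribution, p_f: Distribution
                           ) -> tuple[float, float]:
    """σ_ω − Σ̂_{M∗} σ_ω′ and its lower bound −ΔI_{M∗}, for a unit ω of the
    report's structure and any validated structure M∗ over a subset of ω.

    The sub-structure's σ values must be available in the report (i.e. its
    units must belong to the report's structure).
    """
    omega = frozenset(omega)
    sig = {frozenset(lab.split(",")): v for lab, v in report.sigma.items()}
    if omega not in sig:
        raise KeyError(f"{sorted(omega)} is not a unit of the report")
    m_coords = frozenset().union(*substructure.units)
    if not m_coords <= omega:
        raise ValueError("sub-structure must live inside the unit")
    inex = inclusion_exclusion_sum(lambda u: sig[u], substructure)

    def info(p: Distribution) -> float:
        s_units = inclusion_exclusion_sum(
            lambda u: shannon_entropy(p.marginal(u)), substructure
        )
        return s_units - shannon_entropy(p.marginal(m_coords))

    bound = -(info(p_f) - info(p_i))
    return sig[omega] - inex, bound
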