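"""Flux balance analysis over :class:`~ecflux.model.EcModel`.

Solves ``max/min c.v`` subject to ``S.v = 0`` and flux bounds with the
HiGHS solver through :func:`scipy.optimize.linprog`.  Provides plain
FBA, flexibilized ("observed value +/- delta") constraints,
lexicographic multi-objective optimization, and the maximum-NGAM
computation used to compare maintenance expenditure between strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import EcModel

#: solver feasibility tolerances (HiGHS)
SOLVER_TOL = 1e-9

#: tolerance for mass-balance / bound checks on returned distributions
CHECK_TOL = 1e-6


class InfeasibleConstraintError(RuntimeError):
    """Raised when a fixed (flexibilized) constraint makes the model infeasible."""


@dataclass
class FlexSpec:
    """Fix a flux to an observed value with relative slack ``delta``.

    Bounds become ``[max(0, value*(1-delta)), value*(1+delta)]`` —
    clipped below at zero, matching the irreversible (uptake-positive)
    convention.
    """

    reaction_id: str
    value: float
    delta: float = 0.0

    def bounds(self) -> tuple[float, float]:
        lo = max(0.0, self.value * (1.0 - self.delta))
        hi = self.value * (1.0 + self.delta)
        return lo, hi


@dataclass
class FluxDistribution:
    """One flux vector with its objective value and solver status."""

    values: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    info: dict = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _objective_vector(model: EcModel, objective: dict[str, float]) -> np.ndarray:
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    c = np.zeros(len(model.reactions))
    for rid, w in objective.items():
        if rid not in idx:
            raise KeyError(f"objective references unknown reaction {rid!r}")
        c[idx[rid]] = w
    return c


def _solve(model: EcModel, c: np.ndarray, sense: str,
           extra_rows: list[np.ndarray] | None = None,
           extra_rhs: list[float] | None = None):
    """Solve max/min c.v over the model polytope (plus optional c.v cuts)."""
    S, _, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    sign = -1.0 if sense == "max" else 1.0
    A_ub = b_ub = None
    if extra_rows:
        A_ub = np.vstack(extra_rows)
        b_ub = np.asarray(extra_rhs, dtype=float)
    res = linprog(
        sign * c,
        A_eq=sparse.csr_matrix(S),
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": SOLVER_TOL,
            "dual_feasibility_tolerance": SOLVER_TOL,
        },
    )
    return res, sign


def fba(model: EcModel, objective: dict[str, float], sense: str = "max") -> FluxDistribution:
    """Single-objective flux balance analysis.

    Returns an optimal vertex solution, or a distribution with status
    ``infeasible`` / ``unbounded`` (no exception) when the polytope is
    empty or the objective unbounded.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = _objective_vector(model, objective)
    res, sign = _solve(model, c, sense)
    status = _STATUS.get(res.status)
    if status is None:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
    if status != "optimal":
        return FluxDistribution({}, float("nan"), status)
    values = {r.id: float(x) for r, x in zip(model.reactions, res.x)}
    z = float(-res.fun if sense == "max" else res.fun)
    return FluxDistribution(values, z, "optimal")


def apply_flexible_constraint(model: EcModel, spec: FlexSpec) -> EcModel:
    """Return a copy with the reaction's bounds set to the flexibilized window."""
    out = model.copy()
    r = out.reaction(spec.reaction_id)
    r.lower_bound, r.upper_bound = spec.bounds()
    return out


def apply_flexible_constraints(model: EcModel, specs) -> EcModel:
    out = model.copy()
    for spec in specs:
        r = out.reaction(spec.reaction_id)
        r.lower_bound, r.upper_bound = spec.bounds()
    return out


def lexicographic_optimize(
    model: EcModel,
    objectives: list[tuple[dict[str, float], str]],
    fix_tolerance: float = 1e-6,
) -> FluxDistribution:
    """Optimize objectives in priority order.

    After each stage the achieved optimum ``z`` is fixed as a linear
    constraint with relative slack ``fix_tolerance`` (``c.v >= z -
    tol*max(1, |z|)`` for maximization) before the next solve.  The
    returned distribution carries ``info["stage_optima"]``; on mid-way
    infeasibility, ``info["failed_stage"]`` records the 0-based stage.
    """
    if not objectives:
        raise ValueError("at least one objective is required")
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    stage_optima: list[float] = []
    last = None
    for k, (objective, sense) in enumerate(objectives):
        c = _objective_vector(model, objective)
        res, _ = _solve(model, c, sense, rows or None, rhs or None)
        status = _STATUS.get(res.status)
        if status is None:
            raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
        if status != "optimal":
            return FluxDistribution(
                {}, float("nan"), status,
                {"stage_optima": stage_optima, "failed_stage": k},
            )
        z = float(-res.fun if sense == "max" else res.fun)
        stage_optima.append(z)
        slack = fix_tolerance * max(1.0, abs(z))
        if sense == "max":
            rows.append(-c)
            rhs.append(-(z - slack))
        else:
            rows.append(c)
            rhs.append(z + slack)
        last = res
    values = {r.id: float(x) for r, x in zip(model.reactions, last.x)}
    return FluxDistribution(values, stage_optima[-1], "optimal",
                            {"stage_optima": stage_optima})


def feasible(model: EcModel) -> bool:
    """Whether the steady-state polytope is non-empty."""
    res, _ = _solve(model, np.zeros(len(model.reactions)), "min")
    return res.status == 0


def max_ngam(model: EcModel, fixed_exchanges: list[FlexSpec] = ()) -> float:
    """Maximum flux through the NGAM reaction under observed exchange fluxes.

    Applies every :class:`FlexSpec` (glucose uptake, by-product
    secretion, biomass formation ...) then maximizes the
    non-growth-associated-maintenance ATP hydrolysis flux.  Raises
    :class:`InfeasibleConstraintError` naming the first constraint whose
    addition empties the polytope.
    """
    if model.ngam_id is None:
        raise ValueError("model has no ngam_id")
    m = model
    for spec in fixed_exchanges:
        m = apply_flexible_constraint(m, spec)
        if not feasible(m):
            raise InfeasibleConstraintError(
                f"fixing {spec.reaction_id} to {spec.value} (+/-{spec.delta:.0%}) "
                "makes the model infeasible"
            )
    fd = fba(m, {model.ngam_id: 1.0}, "max")
    if not fd.optimal:
        raise InfeasibleConstraintError(f"NGAM maximization ended with status {fd.status}")
    return fd.objective_value


def check_distribution(model: EcModel, fd: FluxDistribution, tol: float = CHECK_TOL) -> None:
    """Assert mass balance and bound satisfaction of an optimal distribution."""
    if not fd.optimal:
        raise ValueError("can only check optimal distributions")
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([fd.values[r] for r in rxn_ids])
    imbalance = np.abs(S @ v).max() if len(v) else 0.0
    if imbalance > tol:
        raise AssertionError(f"mass balance violated by {imbalance:.3g}")
    lb, ub = model.bounds()
    if (v < lb - tol).any() or (v > ub + tol).any():
        j = int(np.argmax(np.maximum(lb - v, v - ub)))
        raise AssertionError(f"bound violated at reaction {rxn_ids[j]}")
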