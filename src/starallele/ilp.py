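"""Shared integer-programming substrate.

All three decomposition stages (copy-number fit, major-allele selection,
genotype refinement) are small mixed-integer linear programs.  This module
provides the model-building contract they share:

* :func:`LinearModel.abs_term` — split-variable linearization of ``|expr|``;
* :func:`LinearModel.product_term` — standard linearization of a product of
  two binaries (``w <= x, w <= y, w >= x+y-1``);
* :func:`enumerate_optima` — enumeration of *all* co-optimal integer
  assignments, via iterative no-good cuts on the HiGHS backend or a single
  exhaustive sweep on the fallback backend.

Backends: ``"highs"`` (scipy's MILP interface) and ``"exhaustive"`` (pure
enumeration over the integer box, kept deliberately dependency-free so the
whole pipeline runs even with no MILP solver at all).  ``"auto"`` resolves
to HiGHS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

DEFAULT_TOL = 1e-6
DEFAULT_CAP = 100

BACKENDS = ("highs", "exhaustive")


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Var:
    index: int
    name: str
    lb: float
    ub: float
    kind: str  # "int" | "bin" | "cont"

    def __mul__(self, k: float) -> "LinExpr":
        return LinExpr.of(self) * k

    __rmul__ = __mul__

    def __add__(self, other) -> "LinExpr":
        return LinExpr.of(self) + other

    __radd__ = __add__

    def __sub__(self, other) -> "LinExpr":
        return LinExpr.of(self) - other

    def __rsub__(self, other) -> "LinExpr":
        return LinExpr.of(other) - LinExpr.of(self)


class LinExpr:
    """A linear expression ``sum(coef * var) + const`` over model variables."""

    __slots__ = ("coefs", "const")

    def __init__(self, coefs: dict[int, float] | None = None, const: float = 0.0):
        self.coefs = dict(coefs or {})
        self.const = const

    @classmethod
    def of(cls, term) -> "LinExpr":
        if isinstance(term, LinExpr):
            return term
        if isinstance(term, Var):
            return cls({term.index: 1.0})
        return cls(const=float(term))

    def __add__(self, other) -> "LinExpr":
        other = LinExpr.of(other)
        coefs = dict(self.coefs)
        for i, c in other.coefs.items():
            coefs[i] = coefs.get(i, 0.0) + c
        return LinExpr(coefs, self.const + other.const)

    __radd__ = __add__

    def __mul__(self, k: float) -> "LinExpr":
        return LinExpr({i: c * k for i, c in self.coefs.items()}, self.const * k)

    __rmul__ = __mul__

    def __sub__(self, other) -> "LinExpr":
        return self + LinExpr.of(other) * -1.0

    def __rsub__(self, other) -> "LinExpr":
        return LinExpr.of(other) + self * -1.0

    def value(self, x: np.ndarray) -> float:
        return self.const + sum(c * x[i] for i, c in self.coefs.items())


def lsum(terms) -> LinExpr:
    out = LinExpr()
    for t in terms:
        out = out + LinExpr.of(t)
    return out


@dataclass
class _Constraint:
    expr: LinExpr
    lb: float
    ub: float
    definitional: bool = False  # added by abs/product helpers; implied on exhaustive path


@dataclass
class _Derived:
    """A variable whose optimal value is a function of earlier variables
    (used by the exhaustive backend to avoid enumerating it)."""

    kind: str  # "abs_pos" | "abs_neg" | "product"
    var: Var
    expr: LinExpr | None = None
    args: tuple[Var, Var] | None = None


class LinearModel:
    """A minimization MILP with explicit variable/constraint records."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.vars: list[Var] = []
        self.constraints: list[_Constraint] = []
        self.objective: LinExpr = LinExpr()
        self.derived: list[_Derived] = []

    # ------------------------------------------------------------- building
    def add_var(self, name: str, lb: float, ub: float, kind: str = "int") -> Var:
        if kind not in ("int", "bin", "cont"):
            raise ValueError(kind)
        if kind == "bin":
            lb, ub = 0.0, 1.0
        if kind in ("int", "bin") and not (math.isfinite(lb) and math.isfinite(ub)):
            raise ValueError(f"integer variable {name!r} needs finite bounds")
        v = Var(len(self.vars), name, float(lb), float(ub), kind)
        self.vars.append(v)
        return v

    def add_constraint(self, expr, lb: float = -np.inf, ub: float = np.inf,
                       definitional: bool = False) -> None:
        self.constraints.append(_Constraint(LinExpr.of(expr), lb, ub, definitional))

    def set_objective(self, expr) -> None:
        self.objective = LinExpr.of(expr)

    def abs_term(self, expr) -> LinExpr:
        """Return a linear term equal to ``|expr|`` at any optimum of a
        minimizing objective that contains it (split-variable trick)."""
        expr = LinExpr.of(expr)
        k = len(self.derived)
        sp = self.add_var(f"_abs{k}+", 0.0, np.inf, "cont")
        sn = self.add_var(f"_abs{k}-", 0.0, np.inf, "cont")
        # sp - sn = expr
        self.add_constraint(LinExpr.of(sp) - sn - expr, 0.0, 0.0, definitional=True)
        self.derived.append(_Derived("abs_pos", sp, expr=expr))
        self.derived.append(_Derived("abs_neg", sn, expr=expr))
        return LinExpr.of(sp) + sn

    def product_term(self, x: Var, y: Var, name: str | None = None) -> Var:
        """Binary ``w = x*y`` via w <= x, w <= y, w >= x+y-1."""
        if x.kind != "bin" or y.kind != "bin":
            raise ValueError("product_term needs binary factors")
        w = self.add_var(name or f"_prod{len(self.derived)}", 0, 1, "bin")
        self.add_constraint(LinExpr.of(w) - x, ub=0.0, definitional=True)
        self.add_constraint(LinExpr.of(w) - y, ub=0.0, definitional=True)
        self.add_constraint(LinExpr.of(x) + y - w, ub=1.0, definitional=True)
        self.derived.append(_Derived("product", w, args=(x, y)))
        return w

    # -------------------------------------------------------------- solving
    def _free_vars(self) -> list[Var]:
        derived_ix = {d.var.index for d in self.derived}
        return [v for v in self.vars if v.index not in derived_ix]

    def _matrices(self, extra: list[_Constraint] | None = None):
        cons = self.constraints + (extra or [])
        nv = len(self.vars)
        A = np.zeros((len(cons), nv))
        lb = np.empty(len(cons))
        ub = np.empty(len(cons))
        for j, c in enumerate(cons):
            for i, coef in c.expr.coefs.items():
                A[j, i] = coef
            lb[j] = c.lb - c.expr.const
            ub[j] = c.ub - c.expr.const
        return A, lb, ub

    def _solve_highs(self, extra=None):
        nv = len(self.vars)
        c = np.zeros(nv)
        for i, coef in self.objective.coefs.items():
            c[i] = coef
        integrality = np.array(
            [1 if v.kind in ("int", "bin") else 0 for v in self.vars]
        )
        bounds = Bounds(
            np.array([v.lb for v in self.vars]), np.array([v.ub for v in self.vars])
        )
        A, lb, ub = self._matrices(extra)
        constraints = [LinearConstraint(A, lb, ub)] if len(A) else []
        res = milp(c=c, constraints=constraints, integrality=integrality, bounds=bounds)
        if res.status == 4:
            # HiGHS presolve occasionally errors out on big-M cut models;
            # the un-presolved solve handles them fine
            res = milp(c=c, constraints=constraints, integrality=integrality,
                       bounds=bounds, options={"presolve": False})
        if res.status == 2:  # infeasible
            return None
        if not res.success:
            raise SolverError(f"{self.name}: HiGHS failed: {res.message}")
        return res.x, float(res.fun) + self.objective.const

    def _round_and_complete(self, x: np.ndarray) -> np.ndarray:
        """Round integer variables to exact integers and recompute the
        derived (abs-split / product) variables, undoing the MILP solver's
        integrality slack so objectives are exact."""
        xr = np.array(x[: len(self.vars)], dtype=float)
        for v in self.vars:
            if v.kind in ("int", "bin"):
                xr[v.index] = round(xr[v.index])
        return self._complete(xr)

    def solve(self, solver: str = "auto"):
        """Solve; returns ``(assignment dict name->value, objective)`` or
        ``None`` if infeasible."""
        solver = _resolve(solver)
        if solver == "highs":
            out = self._solve_highs()
            if out is None:
                return None
            x, _ = out
            xr = self._round_and_complete(x)
            return self._assignment(xr), self.objective.value(xr)
        sols = self._exhaustive(keep_all=False)
        if not sols:
            return None
        x, obj = sols[0]
        return self._assignment(x), obj

    def _assignment(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for v in self.vars:
            val = x[v.index]
            out[v.name] = int(round(val)) if v.kind in ("int", "bin") else float(val)
        return out

    # ----------------------------------------------------------- exhaustive
    def _complete(self, partial: np.ndarray) -> np.ndarray | None:
        """Fill derived variables given values of the free variables."""
        x = partial.copy()
        for d in self.derived:
            if d.kind == "product":
                x[d.var.index] = x[d.args[0].index] * x[d.args[1].index]
            else:
                val = d.expr.value(x)
                if d.kind == "abs_pos":
                    x[d.var.index] = max(val, 0.0)
                else:
                    x[d.var.index] = max(-val, 0.0)
        return x

    def _feasible(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        for c in self.constraints:
            if c.definitional:
                continue
            v = c.expr.value(x)
            if v < c.lb - tol or v > c.ub + tol:
                return False
        return True

    def _exhaustive(self, keep_all: bool, tol: float = DEFAULT_TOL,
                    guard: int = 10_000_000):
        free = self._free_vars()
        for v in free:
            if v.kind == "cont":
                raise SolverError(
                    f"{self.name}: exhaustive backend cannot handle free "
                    f"continuous variable {v.name!r}"
                )
        ranges = [range(int(v.lb), int(v.ub) + 1) for v in free]
        states = math.prod(len(r) for r in ranges) if ranges else 1
        if states > guard:
            raise SolverError(f"{self.name}: {states} states exceed exhaustive guard")
        best = np.inf
        sols: list[tuple[np.ndarray, float]] = []
        base = np.zeros(len(self.vars))
        for combo in itertools.product(*ranges):
            x = base.copy()
            for v, val in zip(free, combo):
                x[v.index] = val
            x = self._complete(x)
            if not self._feasible(x):
                continue
            obj = self.objective.value(x)
            if obj <= best + tol:
                sols.append((x, obj))
            if obj < best:
                best = obj
        if not sols:
            return []
        # drop stragglers collected before the incumbent improved
        sols = [(x, o) for (x, o) in sols if o <= best + tol]
        if not keep_all:
            sols = sols[:1]
        return sols


def _resolve(solver: str) -> str:
    if solver == "auto":
        return "highs"
    if solver not in BACKENDS:
        raise ValueError(f"unknown solver {solver!r}")
    return solver


def enumerate_optima(
    model: LinearModel,
    key_vars: list[Var],
    tol: float = DEFAULT_TOL,
    cap: int = DEFAULT_CAP,
    solver: str = "auto",
) -> list[dict[str, float]]:
    """All assignments of ``key_vars`` attaining the model optimum.

    On the MILP backend: solve, then repeatedly add an integer no-good cut
    excluding the incumbent key assignment (binary deviation indicators per
    key variable) and re-solve while the objective stays within ``tol`` of
    the optimum.  On the exhaustive backend: one sweep.  Results are
    deterministic (sorted lexicographically on the key variables) and
    deduplicated; at most ``cap`` assignments are returned.
    """
    solver = _resolve(solver)
    if solver == "exhaustive":
        sols = model._exhaustive(keep_all=True, tol=tol)
        assigns = [model._assignment(x) for x, _ in sols]
    else:
        assigns = _enumerate_highs(model, key_vars, tol, cap)
    seen = set()
    uniq = []
    for a in assigns:
        key = tuple(int(round(a[v.name])) for v in key_vars)
        if key in seen:
            continue
        seen.add(key)
        uniq.append(a)
    uniq.sort(key=lambda a: tuple(a[v.name] for v in key_vars))
    return uniq[:cap]


def _enumerate_highs(model, key_vars, tol, cap):
    first = model._solve_highs()
    if first is None:
        return []
    x0 = model._round_and_complete(first[0])
    best = model.objective.value(x0)
    found = [model._assignment(x0)]
    while len(found) < cap:
        cut_model = _with_nogood(model, key_vars, [
            tuple(int(round(a[v.name])) for v in key_vars) for a in found
        ])
        # allow a little integrality slack in the bound; the exact rounded
        # objective is re-checked below
        cut_model.constraints.append(
            _Constraint(cut_model.objective, -np.inf, best + tol + 1e-4)
        )
        try:
            out = cut_model._solve_highs()
        except SolverError:
            # rare HiGHS failures on deeply-cut models: fall back to a
            # guarded exhaustive sweep of the original model
            sols = model._exhaustive(keep_all=True, tol=tol)
            return [model._assignment(x) for x, _ in sols]
        if out is None:
            break
        x = model._round_and_complete(out[0])
        if model.objective.value(x) > best + tol:
            break
        found.append(model._assignment(x))
    return found


def _with_nogood(model: LinearModel, key_vars, excluded: list[tuple[int, ...]]):
    """Copy of ``model`` plus one no-good cut per excluded key assignment.

    For each key variable z with incumbent value z*, two binaries d+ and d-
    signal deviation (z >= z*+1 or z <= z*-1 via big-M on the variable's own
    bounds); each cut requires at least one deviation."""
    clone = LinearModel(model.name + "+cuts")
    clone.vars = list(model.vars)
    clone.constraints = list(model.constraints)
    clone.objective = model.objective
    clone.derived = list(model.derived)
    for assign in excluded:
        devs = []
        for v, zstar in zip(key_vars, assign):
            span_up = v.ub - zstar  # max possible upward deviation
            span_dn = zstar - v.lb
            if span_up >= 1:
                dup = clone.add_var(f"_dev+{v.name}_{len(clone.vars)}", 0, 1, "bin")
                # z >= z* + 1 - (span_dn + 1) * (1 - dup)
                M = span_dn + 1
                clone.add_constraint(
                    LinExpr.of(v) + LinExpr.of(dup) * -M, lb=zstar + 1 - M,
                    definitional=True,
                )
                devs.append(dup)
            if span_dn >= 1:
                ddn = clone.add_var(f"_dev-{v.name}_{len(clone.vars)}", 0, 1, "bin")
                M = span_up + 1
                clone.add_constraint(
                    LinExpr.of(v) + LinExpr.of(ddn) * M, ub=zstar - 1 + M,
                    definitional=True,
                )
                devs.append(ddn)
        if not devs:
            # keys have zero feasible deviation: the assignment is unique
            clone.add_constraint(LinExpr(const=1.0), lb=2.0)  # infeasible cut
            continue
        clone.add_constraint(lsum(devs), lb=1.0)
    return clone
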