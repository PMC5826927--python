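"""Copy-number decomposition of segmented coverage.

Given the observed per-region copy-number vector ``cn`` and the database's
catalogue ``V`` of structural-configuration vectors, find every non-negative
integer combination ``z`` minimizing the total absolute residual

    sum_r | cn[r] - sum_i z_i * v_i[r] |

over unmasked regions, and keep only the *most parsimonious* optima — those
with minimal total copy count ``sum_i z_i``.  Parsimony is applied
lexicographically (first the residual objective, then the copy count within
a small tolerance), and all surviving co-optimal decompositions are
reported.

A brute-force enumerator over the integer box is provided as an independent
oracle for the MILP path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .database import GeneDatabase
from .ilp import DEFAULT_TOL, LinearModel, enumerate_optima, lsum

DEFAULT_MAX_CN = 12


@dataclass
class CNSolution:
    """One parsimonious copy-number decomposition."""

    z: dict[str, int]
    objective: float
    config_ids: tuple[str, ...] = ()
    residuals: dict[str, float] = field(default_factory=dict)
    bound_active: bool = False  # some z_i sits at the max_cn guard

    @property
    def parsimony(self) -> int:
        return sum(self.z.values())

    def total_gene_copies(self, db: GeneDatabase) -> int:
        """Copies of gene-bearing configurations (fusions included)."""
        bearing = set(db.gene_bearing_configs())
        return sum(c for cid, c in self.z.items() if cid in bearing)

    def __repr__(self) -> str:
        inner = "+".join(
            f"{c}x{cid}" if c > 1 else cid for cid, c in sorted(self.z.items()) if c
        )
        return f"CNSolution({inner or 'empty'}, obj={self.objective:.3g})"


def _as_matrix(V: dict[str, np.ndarray]):
    ids = tuple(V)
    mat = np.array([np.asarray(V[c], dtype=float) for c in ids])
    return ids, mat


def _residual_map(cn, ids, mat, z, include):
    resid = np.asarray(cn, dtype=float) - np.array([z[c] for c in ids]) @ mat
    return {
        f"r{j}": float(resid[j]) for j in range(len(cn)) if include[j]
    }


def _check_inputs(cn, V, include):
    if not V:
        raise ValueError("empty configuration set V")
    lens = {len(v) for v in V.values()}
    if len(lens) != 1 or lens.pop() != len(cn):
        raise ValueError("configuration vectors and cn must share one length")
    if not np.any(include):
        raise ValueError("all regions are masked; copy-number fit is undetermined")


def solve_cnep(
    cn: np.ndarray,
    V: dict[str, np.ndarray],
    max_cn: int = DEFAULT_MAX_CN,
    region_mask: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    solver: str = "auto",
) -> list[CNSolution]:
    """All most-parsimonious optimal integer decompositions of ``cn``.

    Parameters
    ----------
    cn
        Real-valued observed copy number per region, canonical order.
    V
        Candidate configuration vectors, config id -> integer vector.
    max_cn
        Upper bound on each individual copy count (guard, reported when
        active at an optimum).
    region_mask
        Boolean array; ``True`` marks a fully-masked region that contributes
        no residual term (rather than a zero observation).
    """
    cn = np.asarray(cn, dtype=float)
    include = np.ones(len(cn), bool) if region_mask is None else ~np.asarray(region_mask)
    _check_inputs(cn, V, include)
    ids, mat = _as_matrix(V)

    def build():
        m = LinearModel("cnep")
        zs = [m.add_var(f"z[{c}]", 0, max_cn, "int") for c in ids]
        terms = []
        for j in np.flatnonzero(include):
            fit = lsum(zs[i] * float(mat[i, j]) for i in range(len(ids)))
            terms.append(m.abs_term(float(cn[j]) - fit))
        return m, zs, lsum(terms)

    # stage 1: minimal residual objective
    model, zs, resid_term = build()
    model.set_objective(resid_term)
    first = model.solve(solver)
    if first is None:  # unconstrained minimization: cannot happen
        raise ValueError("copy-number fit infeasible")
    _, best_obj = first

    # stage 2: minimal total copies subject to near-optimal residual
    model2, zs2, resid2 = build()
    model2.add_constraint(resid2, ub=best_obj + tol)
    model2.set_objective(lsum(zs2))
    assigns = enumerate_optima(model2, zs2, tol=tol, solver=solver)

    out = []
    for a in assigns:
        z = {c: int(round(a[f"z[{c}]"])) for c in ids}
        resid = _residual_map(cn, ids, mat, z, include)
        obj = sum(abs(v) for v in resid.values())
        out.append(
            CNSolution(
                z=z,
                objective=obj,
                config_ids=ids,
                residuals=resid,
                bound_active=any(v == max_cn for v in z.values()),
            )
        )
    out.sort(key=lambda s: tuple(s.z[c] for c in ids))
    return out


def brute_force_cnep(
    cn: np.ndarray,
    V: dict[str, np.ndarray],
    max_cn: int = DEFAULT_MAX_CN,
    region_mask: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    guard: int = 10_000_000,
) -> list[CNSolution]:
    """Independent oracle: exhaustive sweep of the z-box.

    Vectorized enumeration over all ``(max_cn+1)^k`` copy-count tuples;
    guarded so it is only usable on small instances.
    """
    cn = np.asarray(cn, dtype=float)
    include = np.ones(len(cn), bool) if region_mask is None else ~np.asarray(region_mask)
    _check_inputs(cn, V, include)
    ids, mat = _as_matrix(V)
    k = len(ids)
    states = (max_cn + 1) ** k
    if states > guard:
        raise ValueError(f"{states} states exceed the brute-force guard")

    grid = np.array(list(itertools.product(range(max_cn + 1), repeat=k)))
    resid = cn[include][None, :] - grid @ mat[:, include]
    obj = np.abs(resid).sum(axis=1)
    best = obj.min()
    optimal = grid[obj <= best + tol]
    pars = optimal.sum(axis=1)
    keep = optimal[pars == pars.min()]

    out = []
    for row in keep:
        z = {c: int(v) for c, v in zip(ids, row)}
        rmap = _residual_map(cn, ids, mat, z, include)
        out.append(
            CNSolution(
                z=z,
                objective=sum(abs(v) for v in rmap.values()),
                config_ids=ids,
                residuals=rmap,
                bound_active=any(v == max_cn for v in z.values()),
            )
        )
    out.sort(key=lambda s: tuple(s.z[c] for c in ids))
    return out


def database_V(db: GeneDatabase) -> dict[str, np.ndarray]:
    """The candidate set V: every coverage-contributing database config."""
    return {c: db.config_vector(c) for c in db.coding_configs()}
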