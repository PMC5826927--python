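"""Major star-allele identification.

Given a copy-number decomposition and the set ``M`` of gene-disrupting
mutations detected in the sample, choose how many copies of each candidate
major star-allele are present.  Candidates are majors whose defining
mutations are all in ``M`` and whose structural configuration received a
positive copy count.  Copy counts ``p`` minimize the total mismatch

    sum_{m in M} | mutcn(m) - sum_{a : m in gdm(a)} p_a |

subject to (i) every detected gene-disrupting mutation being carried by at
least one selected allele, and (ii) per-configuration linkage: the alleles
of a configuration collectively account for exactly its copy count.

Whole-gene deletion alleles are ordinary majors bound to the (zero-
coverage) deletion configuration; one is reported per missing gene copy of
a diploid, so a hemizygous sample reads ``*X / *DEL`` uniformly.

When no database assignment can satisfy the constraints the problem is
infeasible — the sample carries a major allele absent from the database —
and an empty solution is flagged for the refinement stage, which may then
mint a novel major.
"""

from __future__ import annotations

from dataclasses import dataclass

from .copy_number import CNSolution
from .database import GeneDatabase
from .ilp import DEFAULT_TOL, LinearModel, enumerate_optima, lsum

DEFAULT_PLOIDY = 2
DEFAULT_GAMMA = 0.15
DEFAULT_MIN_FRAGS = 5


@dataclass
class MajorSolution:
    cn_solution: CNSolution
    p: dict[str, int]
    objective: float
    infeasible: bool = False
    relaxed: bool = False  # candidate filter was relaxed (novel-allele path)

    @property
    def total_copies(self) -> int:
        return sum(self.p.values())

    def __repr__(self) -> str:
        inner = " + ".join(
            f"{c}x{a}" if c > 1 else a for a, c in sorted(self.p.items()) if c
        )
        flag = " INFEASIBLE" if self.infeasible else ""
        return f"MajorSolution({inner or 'empty'}, obj={self.objective:.3g}{flag})"


def deletion_copies(db: GeneDatabase, cn_solution: CNSolution,
                    ploidy: int = DEFAULT_PLOIDY) -> int:
    """Number of whole-gene deletion alleles implied by the decomposition:
    one per gene copy missing from the expected ploidy (never negative)."""
    return max(0, ploidy - cn_solution.total_gene_copies(db))


def build_candidates(
    db: GeneDatabase,
    M: set[str],
    cn_solution: CNSolution,
    relaxed: bool = False,
    exclude: set[str] | None = None,
) -> list[str]:
    """Candidate major alleles for one copy-number decomposition.

    Keeps majors whose gene-disrupting mutations are all detected
    (``gdm(a) ⊆ M``; dropped when ``relaxed``) and whose configuration has a
    positive copy count.  Deletion majors are included whenever the
    decomposition leaves fewer gene copies than the diploid expectation.
    """
    out = []
    n_del = deletion_copies(db, cn_solution)
    for a in db.majors.values():
        if exclude and a.id in exclude:
            continue
        cfg = db.configs[a.config]
        if cfg.deletion:
            if n_del > 0:
                out.append(a.id)
            continue
        if cn_solution.z.get(a.config, 0) <= 0:
            continue
        if not relaxed and not (a.gdm <= M):
            continue
        out.append(a.id)
    return out


def solve_msaip(
    db: GeneDatabase,
    A: list[str],
    M: set[str],
    mutcn: dict[str, float],
    cn_solution: CNSolution,
    ploidy: int = DEFAULT_PLOIDY,
    tol: float = DEFAULT_TOL,
    solver: str = "auto",
    relaxed: bool = False,
) -> list[MajorSolution]:
    """All co-optimal major-allele copy assignments, or a single infeasible
    marker when none exists."""
    infeasible_marker = [
        MajorSolution(cn_solution, {}, float("inf"), infeasible=True, relaxed=relaxed)
    ]

    coding = [a for a in A if not db.configs[db.majors[a].config].deletion]
    n_del = deletion_copies(db, cn_solution, ploidy)
    del_majors = [a for a in A if db.configs[db.majors[a].config].deletion]

    # structural feasibility: every gene-bearing config with copies needs a
    # candidate allele, and every detected mutation needs a carrier
    by_config: dict[str, list[str]] = {}
    for a in coding:
        by_config.setdefault(db.majors[a].config, []).append(a)
    gene_bearing = set(db.gene_bearing_configs())
    for cfg, z in cn_solution.z.items():
        if z > 0 and cfg in gene_bearing and not by_config.get(cfg):
            return infeasible_marker
    if not relaxed:
        for m in M:
            if not any(m in db.majors[a].gdm for a in coding):
                return infeasible_marker

    if not coding:
        # deletion-only decomposition: nothing to optimize
        p = {del_majors[0]: n_del} if del_majors and n_del > 0 else {}
        if M and not relaxed:
            return infeasible_marker
        return [MajorSolution(cn_solution, p, _objective(db, p, M, mutcn),
                              relaxed=relaxed)]

    model = LinearModel("msaip")
    pvars = {
        a: model.add_var(f"p[{a}]", 0, cn_solution.z.get(db.majors[a].config, 0), "int")
        for a in coding
    }
    # linkage: alleles of a configuration account for exactly its copies
    for cfg, alleles in by_config.items():
        model.add_constraint(
            lsum(pvars[a] for a in alleles), lb=cn_solution.z[cfg],
            ub=cn_solution.z[cfg],
        )
    # coverage: each detected gene-disrupting mutation has >= 1 carrier
    for m in M:
        carriers = [pvars[a] for a in coding if m in db.majors[a].gdm]
        if carriers:
            model.add_constraint(lsum(carriers), lb=1)
        elif not relaxed:
            return infeasible_marker
    terms = []
    for m in M:
        carried = lsum(pvars[a] for a in coding if m in db.majors[a].gdm)
        terms.append(model.abs_term(float(mutcn.get(m, 0.0)) - carried))
    model.set_objective(lsum(terms))

    assigns = enumerate_optima(model, list(pvars.values()), tol=tol, solver=solver)
    if not assigns:
        return infeasible_marker

    out = []
    for assign in assigns:
        p = {a: int(round(assign[f"p[{a}]"])) for a in coding}
        obj = _objective(db, p, M, mutcn)
        # deletion alleles: fixed count, spread over (usually one) del major
        if del_majors and n_del > 0:
            p[del_majors[0]] = n_del
        out.append(MajorSolution(cn_solution, p, obj, relaxed=relaxed))
    out.sort(key=lambda s: sorted(s.p.items()))
    return out


def _objective(db: GeneDatabase, p: dict[str, int], M: set[str],
               mutcn: dict[str, float]) -> float:
    return sum(
        abs(
            mutcn.get(m, 0.0)
            - sum(c for a, c in p.items() if m in db.majors[a].gdm)
        )
        for m in M
    )


def identify_majors(
    db: GeneDatabase,
    M: set[str],
    mutcn: dict[str, float],
    cn_solution: CNSolution,
    ploidy: int = DEFAULT_PLOIDY,
    tol: float = DEFAULT_TOL,
    solver: str = "auto",
    exclude: set[str] | None = None,
) -> list[MajorSolution]:
    """Candidate filtering + assignment, with a tiered novel-allele fallback.

    When the strict problem is infeasible the sample carries a major allele
    absent from the database.  The fallback first keeps the strict
    candidate filter but drops the presence constraints no candidate can
    satisfy — refinement then *adds* the orphan mutations to a slot,
    minting a novel major.  Only if the decomposition demands copies of a
    configuration with no compatible major at all are incompatible majors
    re-admitted as scaffolds.  Either way the solutions stay flagged
    infeasible: the strict stage's output is, by contract, empty.
    """
    A = build_candidates(db, M, cn_solution, exclude=exclude)
    sols = solve_msaip(db, A, M, mutcn, cn_solution, ploidy, tol, solver)
    if not sols[0].infeasible:
        return sols
    relaxed = solve_msaip(
        db, A, M, mutcn, cn_solution, ploidy, tol, solver, relaxed=True
    )
    if relaxed[0].infeasible:
        A = build_candidates(db, M, cn_solution, relaxed=True, exclude=exclude)
        relaxed = solve_msaip(
            db, A, M, mutcn, cn_solution, ploidy, tol, solver, relaxed=True
        )
    if relaxed[0].infeasible:
        return relaxed
    # scaffolds for novel-allele refinement
    for s in relaxed:
        s.infeasible = True
    return relaxed


# ------------------------------------------------------------------- phasing

def phase_filter(
    solutions: list[MajorSolution],
    phase: dict,
    db: GeneDatabase,
    gamma: float = DEFAULT_GAMMA,
    min_frags: int = DEFAULT_MIN_FRAGS,
) -> list[MajorSolution]:
    """Drop solutions contradicted by read-pair phasing.

    A solution is eliminated iff it selects an allele with two defining
    gene-disrupting mutations whose loci are co-covered by at least
    ``min_frags`` fragments while the fraction of those fragments carrying
    *both* alternates falls below ``gamma`` (a trans configuration).  With
    no phase observations the filter passes everything through.
    """
    if not phase:
        return solutions
    kept = []
    for sol in solutions:
        if sol.infeasible or all(
            allele_in_phase(db, a, phase, gamma, min_frags)
            for a, c in sol.p.items()
            if c > 0
        ):
            kept.append(sol)
    return kept


def allele_in_phase(
    db: GeneDatabase,
    allele_id: str,
    phase: dict,
    gamma: float = DEFAULT_GAMMA,
    min_frags: int = DEFAULT_MIN_FRAGS,
) -> bool:
    """Whether read-pair evidence is compatible with the allele carrying
    all its defining mutations in cis."""
    gdm = sorted(db.majors[allele_id].gdm, key=lambda m: db.mutations[m].pos)
    for i in range(len(gdm)):
        for j in range(i + 1, len(gdm)):
            m1, m2 = db.mutations[gdm[i]], db.mutations[gdm[j]]
            if m1.pos == m2.pos:
                continue
            total = both = 0
            for ((p1, a1), (p2, a2)), count in phase.items():
                if p1 == m1.pos and p2 == m2.pos:
                    total += count
                    if a1 == m1.op and a2 == m2.op:
                        both += count
            if total >= min_frags and both / total < gamma:
                return False
    return True
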