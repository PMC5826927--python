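"""Genotype refinement: assign a minor star-allele to every gene copy.

Each copy of each selected major star-allele becomes a *slot*; each slot
chooses exactly one minor allele of its major (binary ``x``), may drop
individual neutral mutations from the chosen definition (``e = 0``, penalty
``alpha`` each) and may gain observed mutations absent from it (``f = 1``,
penalty ``beta`` each; adding a *gene-disrupting* mutation costs an extra
``eta``, which is set so high that it is only ever paid when the major-
allele stage was infeasible and a novel major must be minted).  The
residual term ``|F_m|`` keeps the number of copies carrying each mutation
close to its estimated copy number ``mutcn(m)``:

    minimize  sum_m |F_m|
            + sum_slots x * [ alpha * (#dropped known)
                              + beta * (#added)
                              + eta  * (#added gene-disrupting) ]

Gene-disrupting members of a chosen minor can never be dropped.  Sentinel
constraints stop over-calling: across all slots, a mutation may occur at
most ``max(1, round(mutcn))`` times (or as many times as the selected
majors already force).  Observed gene-disrupting mutations must be carried
by at least one slot — the same presence axiom the major stage enforces.

Slots whose definitions end up differing from every database record mint
novel minor (and, via ``eta``, novel major) star-alleles, named by the
database's nomenclature rules.

All co-optimal refinements of all upstream decompositions are ranked by
this score; the genotypes attaining the minimum are reported as equally
likely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .database import GeneDatabase
from .ilp import DEFAULT_TOL, LinearModel, LinExpr, enumerate_optima, lsum
from .major import MajorSolution

DEFAULT_ALPHA = 2.0
DEFAULT_BETA = 1.0
DEFAULT_ETA = 100_000.0


class RefinementError(RuntimeError):
    """No feasible minor-allele assignment exists even with additions —
    the database and the observed profile are inconsistent."""


@dataclass(frozen=True)
class AlleleSlot:
    """One gene copy: its major, the minor it selects, and edits."""

    major: str
    minor: str
    kept: frozenset[str]
    added: frozenset[str] = frozenset()
    novel_minor: str | None = None
    novel_major: str | None = None

    @property
    def label(self) -> str:
        """Display name: the minted name when novel, else the db minor."""
        return self.novel_minor or self.minor

    def mutations(self) -> frozenset[str]:
        return self.kept | self.added


@dataclass
class RefinedGenotype:
    slots: list[AlleleSlot]
    score: float
    residuals: dict[str, float]
    major_solution: MajorSolution
    novel_majors: dict[str, frozenset[str]] = field(default_factory=dict)
    novel_minors: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def cn_solution(self):
        return self.major_solution.cn_solution

    def minor_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(s.minor for s in self.slots))

    def diplotype(self) -> str:
        return " / ".join(sorted(s.label for s in self.slots))

    def __repr__(self) -> str:
        return f"RefinedGenotype({self.diplotype()}, score={self.score:.3g})"


def grp_universe(db: GeneDatabase, majors: list[str], observed: set[str]) -> set[str]:
    """Mutations the refinement objective ranges over: everything observed
    plus everything any candidate minor of a selected major defines."""
    universe = set(observed)
    for major_id in majors:
        for minor in db.minors_of(major_id):
            universe |= db.mut(minor.id)
    return universe


def score_genotype(
    db: GeneDatabase,
    slots: list[AlleleSlot],
    mutcn: dict[str, float],
    observed: set[str],
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    eta: float = DEFAULT_ETA,
) -> tuple[float, dict[str, float]]:
    """Independent arithmetic recomputation of the refinement score."""
    universe = grp_universe(db, [s.major for s in slots], observed)
    residuals = {}
    for m in universe:
        count = sum(1 for s in slots if m in s.mutations())
        residuals[m] = mutcn.get(m, 0.0) - count
    score = sum(abs(v) for v in residuals.values())
    for s in slots:
        known = db.mut(s.minor)
        dropped = known - s.kept
        score += alpha * len(dropped) + beta * len(s.added)
        score += eta * sum(1 for m in s.added if db.mutations[m].gene_disrupting)
    return score, residuals


def solve_grp(
    db: GeneDatabase,
    major_solution: MajorSolution,
    mutcn: dict[str, float],
    observed: set[str],
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    eta: float = DEFAULT_ETA,
    tol: float = DEFAULT_TOL,
    solver: str = "auto",
) -> list[RefinedGenotype]:
    """All co-optimal minor-allele assignments for one major-allele solution.

    When the major stage was infeasible (novel-major pathway), observed
    gene-disrupting mutations may be *added* to slots at cost ``eta``;
    otherwise gene-disrupting additions are disallowed outright, so novel
    majors can only arise from infeasibility.
    """
    allow_gd_additions = major_solution.infeasible
    M_observed = {m for m in observed if db.mutations[m].gene_disrupting}

    slot_list: list[tuple[str, int]] = []  # (major id, copy index)
    fixed_slots: list[AlleleSlot] = []  # deletion copies: nothing to decide
    for major_id, copies in sorted(major_solution.p.items()):
        if db.configs[db.majors[major_id].config].deletion:
            minor = db.minors_of(major_id)[0]
            for _ in range(copies):
                fixed_slots.append(
                    AlleleSlot(major_id, minor.id, frozenset(db.mut(minor.id)))
                )
            continue
        for b in range(copies):
            slot_list.append((major_id, b))

    if not slot_list:
        score, resid = score_genotype(
            db, fixed_slots, mutcn, observed, alpha, beta, eta
        )
        return [RefinedGenotype(fixed_slots, score, resid, major_solution)]

    universe = sorted(grp_universe(db, [m for m, _ in slot_list], observed))
    addable = {
        m
        for m in observed
        if allow_gd_additions or not db.mutations[m].gene_disrupting
    }

    model = LinearModel("grp")
    x = {}  # (minor, slot) -> var
    e = {}  # (minor, slot, mutation) -> var (neutral members only; gd fixed)
    f = {}  # (minor, slot, mutation) -> var
    we = {}  # linearized x*e keep terms; for gd members simply x
    wf = {}
    for slot in slot_list:
        minors = db.minors_of(slot[0])
        xs = []
        for a in minors:
            xv = model.add_var(f"x[{a.id},{slot}]", 0, 1, "bin")
            x[(a.id, slot)] = xv
            xs.append(xv)
            mut_a = db.mut(a.id)
            for m in sorted(mut_a):
                if db.mutations[m].gene_disrupting:
                    we[(a.id, slot, m)] = xv  # e forced to 1
                else:
                    ev = model.add_var(f"e[{a.id},{slot},{m}]", 0, 1, "bin")
                    e[(a.id, slot, m)] = ev
                    we[(a.id, slot, m)] = model.product_term(
                        xv, ev, f"ke[{a.id},{slot},{m}]"
                    )
            for m in sorted(addable - mut_a):
                fv = model.add_var(f"f[{a.id},{slot},{m}]", 0, 1, "bin")
                f[(a.id, slot, m)] = fv
                wf[(a.id, slot, m)] = model.product_term(
                    xv, fv, f"kf[{a.id},{slot},{m}]"
                )
        model.add_constraint(lsum(xs), lb=1, ub=1)  # one minor per slot

    def occurrences(m: str):
        terms = [v for (a, s, mm), v in we.items() if mm == m]
        terms += [v for (a, s, mm), v in wf.items() if mm == m]
        return lsum(terms)

    # presence: every observed gene-disrupting mutation is carried somewhere
    for m in sorted(M_observed):
        occ = occurrences(m)
        if not occ.coefs:
            if allow_gd_additions:
                raise RefinementError(
                    f"no slot can carry observed gene-disrupting mutation {m}"
                )
            # strict path: MSAIP guaranteed a carrier, so a forced-keep exists
            continue
        model.add_constraint(occ, lb=1)

    # sentinel: no over-calling beyond the rounded mutation copy number
    forced: dict[str, int] = {}
    for major_id, _ in slot_list:
        for m in db.majors[major_id].gdm:
            forced[m] = forced.get(m, 0) + 1
    for m in universe:
        occ = occurrences(m)
        if occ.coefs:
            cap = max(1, round(mutcn.get(m, 0.0)), forced.get(m, 0))
            model.add_constraint(occ, ub=cap)

    # objective (products already declared, so abs terms may reference them)
    terms = []
    for m in universe:
        terms.append(model.abs_term(float(mutcn.get(m, 0.0)) - occurrences(m)))
    for (a, slot), xv in x.items():
        known = db.mut(a)
        neutral_known = [m for m in known if not db.mutations[m].gene_disrupting]
        # alpha * x * (1 - e) == alpha * (x - w_e)
        for m in neutral_known:
            terms.append((LinExpr.of(xv) - we[(a, slot, m)]) * alpha)
    for (a, slot, m), w in wf.items():
        cost = beta + (eta if db.mutations[m].gene_disrupting else 0.0)
        terms.append(LinExpr.of(w) * cost)
    model.set_objective(lsum(terms))

    # enumerate on the selection variables and the linearized keep/add
    # products: when x=0 the raw e/f variables are unconstrained padding,
    # but the products are forced to 0, so (x, w) pins the genotype exactly
    key_vars = list(x.values())
    key_vars += [w for w in we.values() if w.name.startswith("ke[")]
    key_vars += list(wf.values())
    assigns = enumerate_optima(model, key_vars, tol=tol, solver=solver)
    if not assigns:
        raise RefinementError("refinement model infeasible")

    out: list[RefinedGenotype] = []
    seen: set[tuple] = set()
    for assign in assigns:
        slots = list(fixed_slots)
        for slot in slot_list:
            chosen = None
            for a in db.minors_of(slot[0]):
                if round(assign[f"x[{a.id},{slot}]"]) == 1:
                    chosen = a.id
                    break
            assert chosen is not None
            kept = set()
            for m in db.mut(chosen):
                if db.mutations[m].gene_disrupting:
                    kept.add(m)
                elif round(assign[f"ke[{chosen},{slot},{m}]"]) == 1:
                    kept.add(m)
            added = {
                m
                for m in addable - db.mut(chosen)
                if round(assign[f"kf[{chosen},{slot},{m}]"]) == 1
            }
            slots.append(AlleleSlot(slot[0], chosen, frozenset(kept), frozenset(added)))
        canon = tuple(
            sorted((s.major, s.minor, s.kept, s.added) for s in slots)
        )
        if canon in seen:
            continue
        seen.add(canon)
        slots = _mint_novel(db, slots)
        score, resid = score_genotype(db, slots, mutcn, observed, alpha, beta, eta)
        out.append(
            RefinedGenotype(
                slots,
                score,
                resid,
                major_solution,
                novel_majors={
                    s.novel_major: frozenset(
                        db.majors[s.major].gdm
                        | {m for m in s.added if db.mutations[m].gene_disrupting}
                    )
                    for s in slots
                    if s.novel_major
                },
                novel_minors={
                    s.novel_minor: (
                        s.novel_major or s.major,
                        frozenset(
                            m
                            for m in s.mutations()
                            if not db.mutations[m].gene_disrupting
                        ),
                    )
                    for s in slots
                    if s.novel_minor
                },
            )
        )
    out.sort(key=lambda g: (g.score, g.diplotype()))
    return out


def _mint_novel(db: GeneDatabase, slots: list[AlleleSlot]) -> list[AlleleSlot]:
    """Name slots whose final definition matches no database record.

    A slot that edits its minor's neutral set gets a fresh minor name under
    its major; a slot that gains a gene-disrupting mutation defines a fresh
    major (and a minor beneath it).  Names never collide with the database
    or with each other.
    """
    used_majors = set(db.majors)
    out: list[AlleleSlot] = []
    minted_minors: dict[str, set[str]] = {}

    def fresh_major() -> str:
        import re

        top = 0
        for mid in used_majors:
            m = re.fullmatch(r"\*(\d+)", mid)
            if m:
                top = max(top, int(m.group(1)))
        name = f"*{top + 1}"
        used_majors.add(name)
        return name

    def fresh_minor(major_id: str) -> str:
        from .database import _letter_suffixes

        used = minted_minors.setdefault(major_id, set())
        if major_id in db.majors:
            used |= {m.id[len(major_id):] for m in db.minors_of(major_id)}
        for suffix in _letter_suffixes():
            if suffix not in used:
                used.add(suffix)
                return major_id + suffix
        raise AssertionError("unreachable")

    for s in slots:
        added_gd = {m for m in s.added if db.mutations[m].gene_disrupting}
        edited = s.mutations() != db.mut(s.minor)
        if added_gd:
            new_major = fresh_major()
            out.append(
                AlleleSlot(
                    s.major, s.minor, s.kept, s.added,
                    novel_minor=fresh_minor(new_major), novel_major=new_major,
                )
            )
        elif edited:
            out.append(
                AlleleSlot(
                    s.major, s.minor, s.kept, s.added,
                    novel_minor=fresh_minor(s.major),
                )
            )
        else:
            out.append(s)
    return out


def rank_solutions(
    candidates: list[RefinedGenotype], tol: float = DEFAULT_TOL
) -> list[RefinedGenotype]:
    """The genotypes attaining the minimal refinement score — all reported
    as equally likely when tied."""
    if not candidates:
        raise ValueError("no candidate genotypes to rank")
    best = min(g.score for g in candidates)
    winners = [g for g in candidates if g.score <= best + tol]
    winners.sort(key=lambda g: g.diplotype())
    return winners
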