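"""Genotype refinement: minor-allele assignment, novel-allele minting,
score bookkeeping, tie handling and ranking."""

import pytest

from starallele.copy_number import CNSolution
from starallele.ilp import BACKENDS
from starallele.major import MajorSolution
from starallele.refine import (
    AlleleSlot,
    RefinedGenotype,
    rank_solutions,
    score_genotype,
    solve_grp,
)

GD1, GD2, GD3, GD4 = "1150:C>T", "1450:G>A", "250:G>A", "220:C>T"
NT2 = "1250:A>C"   # *2A / *2B neutral
NT3 = "2650:G>T"   # *2B-only neutral
NT4 = "950:T>G"    # *4A neutral
ETA = 100_000.0


def _major_solution(db, p, infeasible=False):
    z = {"gene": sum(
        c for a, c in p.items() if not db.configs[db.majors[a].config].deletion
    ), "pseudo": 2}
    return MajorSolution(CNSolution(z=z, objective=0.0), dict(p), 0.0,
                         infeasible=infeasible)


def _recompute(db, genotype, mutcn, observed, alpha=2.0, beta=1.0, eta=ETA):
    """Test-local arithmetic audit of the refinement objective, written
    independently of the package's own scorer."""
    universe = set(observed)
    for s in genotype.slots:
        for minor in db.minors_of(s.major):
            universe |= db.mut(minor.id)
    total = 0.0
    for m in universe:
        carried = sum(1 for s in genotype.slots if m in s.kept | s.added)
        total += abs(mutcn.get(m, 0.0) - carried)
    for s in genotype.slots:
        total += alpha * len(db.mut(s.minor) - s.kept)
        total += beta * len(s.added)
        total += eta * len([m for m in s.added if db.mutations[m].gene_disrupting])
    return total


@pytest.mark.parametrize("solver", BACKENDS)
def test_perfect_database_match_scores_zero(demo_db, solver):
    """Observed mutations exactly matching *1A and *2A give those minors
    at score 0."""
    msol = _major_solution(demo_db, {"*1": 1, "*2": 1})
    observed = set(demo_db.mut("*2A"))
    mutcn = {m: 1.0 for m in observed}
    genos = solve_grp(demo_db, msol, mutcn, observed, solver=solver)
    assert len(genos) == 1
    assert genos[0].diplotype() == "*1A / *2A"
    assert genos[0].score == pytest.approx(0.0)
    assert not genos[0].novel_minors


def test_extra_neutral_mutation_ties_novel_minor_against_residual(demo_db):
    """An observed neutral mutation foreign to every candidate minor can be
    left unexplained (residual 1) or adopted by a slot (beta = 1): both
    resolutions are co-optimal and all are reported."""
    msol = _major_solution(demo_db, {"*1": 1, "*2": 1})
    observed = set(demo_db.mut("*2A")) | {NT4}
    mutcn = {m: 1.0 for m in observed}
    genos = solve_grp(demo_db, msol, mutcn, observed)
    assert len(genos) > 1
    assert all(g.score == pytest.approx(1.0) for g in genos)
    unexplained = [g for g in genos if not g.novel_minors]
    adopted = [g for g in genos if g.novel_minors]
    assert unexplained and adopted
    assert any(
        NT4 in extra for g in adopted for (_, extra) in g.novel_minors.values()
    )


def test_infeasible_major_stage_mints_novel_major(demo_db):
    """With the major stage infeasible, the orphan gene-disrupting
    mutation is adopted at cost eta + beta, defining a novel major."""
    msol = _major_solution(demo_db, {"*1": 2}, infeasible=True)
    observed = {GD2}
    mutcn = {GD2: 1.0}
    genos = solve_grp(demo_db, msol, mutcn, observed)
    assert len(genos) == 1
    g = genos[0]
    assert g.score == pytest.approx(ETA + 1.0)
    assert list(g.novel_majors.values()) == [frozenset({GD2})]
    novel_name = next(iter(g.novel_majors))
    assert novel_name == "*69"  # smallest number above every db major
    assert sorted(s.label for s in g.slots) == ["*1A", f"{novel_name}A"]


def test_gene_disrupting_additions_forbidden_when_feasible(demo_db):
    """With eta at default no reported genotype adds a gene-disrupting
    mutation unless its major stage was infeasible."""
    msol = _major_solution(demo_db, {"*1": 1, "*4": 1})
    observed = {GD3, NT4, GD4}  # gd4 observed but *10 not among the majors
    mutcn = {GD3: 1.0, NT4: 1.0, GD4: 0.9}
    genos = solve_grp(demo_db, msol, mutcn, observed)
    for g in genos:
        for s in g.slots:
            assert not any(demo_db.mutations[m].gene_disrupting for m in s.added)


@pytest.mark.parametrize("solver", BACKENDS)
def test_reported_score_equals_independent_recomputation(demo_db, solver):
    """Every reported score equals a from-scratch arithmetic audit of the
    slot assignment."""
    cases = [
        ({"*1": 1, "*2": 1}, set(demo_db.mut("*2A")), False),
        ({"*1": 1, "*2": 1}, set(demo_db.mut("*2B")) | {NT4}, False),
        ({"*1": 2}, {GD2}, True),
        ({"*4": 1, "*5": 1}, set(demo_db.mut("*4A")), False),
    ]
    for p, observed, infeasible in cases:
        msol = _major_solution(demo_db, p, infeasible=infeasible)
        mutcn = {m: 1.0 for m in observed}
        for g in solve_grp(demo_db, msol, mutcn, observed, solver=solver):
            audit = _recompute(demo_db, g, mutcn, observed)
            assert g.score == pytest.approx(audit, abs=1e-6)
            own, _ = score_genotype(demo_db, g.slots, mutcn, observed)
            assert g.score == pytest.approx(own, abs=1e-9)


def test_deletion_slot_carries_fixed_minor(demo_db):
    msol = _major_solution(demo_db, {"*4": 1, "*5": 1})
    observed = set(demo_db.mut("*4A"))
    genos = solve_grp(demo_db, msol, {m: 1.0 for m in observed}, observed)
    assert genos[0].diplotype() == "*4A / *5A"
    assert genos[0].score == pytest.approx(0.0)


def test_homozygous_minor_allowed_across_slots(demo_db):
    """Two copies of one major may select the same minor."""
    msol = _major_solution(demo_db, {"*41": 2})
    observed = set(demo_db.mut("*41A"))
    mutcn = {m: 2.0 for m in observed}
    genos = solve_grp(demo_db, msol, mutcn, observed)
    assert genos[0].diplotype() == "*41A / *41A"
    assert genos[0].score == pytest.approx(0.0)


def test_dropping_known_neutral_costs_alpha(demo_db):
    """A selected minor missing one of its neutral mutations pays alpha
    (2) or keeps it as residual 1; keeping wins."""
    msol = _major_solution(demo_db, {"*2": 1})
    observed = {GD1, GD2}  # nt2 of *2A not observed
    mutcn = {m: 1.0 for m in observed}
    genos = solve_grp(demo_db, msol, mutcn, observed)
    # keeping nt2 at residual 1 beats dropping it at alpha=2
    assert genos[0].score == pytest.approx(1.0)
    assert genos[0].slots[0].minor == "*2A"
    assert NT2 in genos[0].slots[0].kept


def _fake(score):
    return RefinedGenotype(
        slots=[AlleleSlot("*1", "*1A", frozenset())],
        score=score,
        residuals={},
        major_solution=None,
    )


def test_rank_selects_minimum_and_reports_ties():
    best = rank_solutions([_fake(3.0), _fake(0.0)])
    assert [g.score for g in best] == [0.0]
    both = rank_solutions([_fake(1.0), _fake(1.0 + 1e-9)])
    assert len(both) == 2
    single = rank_solutions([_fake(2.5)])
    assert [g.score for g in single] == [2.5]
    with pytest.raises(ValueError):
        rank_solutions([])
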