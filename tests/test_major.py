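"""Major star-allele selection: candidate filtering, the assignment ILP,
linkage/coverage invariants, the infeasible (novel-allele) path, and the
read-pair phasing filter."""

import itertools

import numpy as np
import pytest

from starallele.copy_number import CNSolution
from starallele.ilp import BACKENDS
from starallele.major import (
    allele_in_phase,
    build_candidates,
    deletion_copies,
    identify_majors,
    phase_filter,
    solve_msaip,
)

GD1, GD2, GD3, GD4 = "1150:C>T", "1450:G>A", "250:G>A", "220:C>T"


def _cn(z):
    return CNSolution(z=z, objective=0.0)


def _psets(solutions):
    return {tuple(sorted((a, c) for a, c in s.p.items() if c)) for s in solutions}


# ------------------------------------------------------------- candidates

def test_candidates_require_detected_mutations(demo_db):
    A = build_candidates(demo_db, {GD1}, _cn({"gene": 2, "pseudo": 2}))
    # *2 needs gd2 as well; *41 = {gd1} qualifies; wild-type always eligible
    assert "*41" in A and "*1" in A
    assert "*2" not in A and "*4" not in A


def test_deletion_only_decomposition_offers_only_the_deletion_allele(demo_db):
    sol = _cn({"pseudo": 2})
    assert deletion_copies(demo_db, sol) == 2
    A = build_candidates(demo_db, set(), sol)
    assert A == ["*5"]


def test_fusion_major_excluded_when_its_config_has_no_copies(demo_db):
    A = build_candidates(demo_db, {GD4}, _cn({"gene": 2, "pseudo": 2}))
    assert "*10" in A  # gene-config carrier of gd4
    assert "*68" not in A  # fusion config has z=0


# ----------------------------------------------------------------- solving

def test_heterozygous_assignment_unique_optimum(demo_db):
    cn = _cn({"gene": 2, "pseudo": 2})
    A = build_candidates(demo_db, {GD3}, cn)
    sols = solve_msaip(demo_db, A, {GD3}, {GD3: 1.0}, cn)
    assert _psets(sols) == {(("*1", 1), ("*4", 1))}
    assert sols[0].objective == pytest.approx(0.0)
    assert not sols[0].infeasible


def test_wild_type_diploid_when_nothing_detected(demo_db):
    cn = _cn({"gene": 2, "pseudo": 2})
    A = build_candidates(demo_db, set(), cn)
    sols = solve_msaip(demo_db, A, set(), {}, cn)
    assert _psets(sols) == {(("*1", 2),)}


def test_uncarried_mutation_makes_strict_problem_infeasible(demo_db):
    """A detected gene-disrupting mutation carried by no candidate yields
    the empty, infeasible-flagged output."""
    cn = _cn({"gene": 2, "pseudo": 2})
    A = build_candidates(demo_db, {GD2}, cn)  # *2 filtered out (needs gd1 too)
    sols = solve_msaip(demo_db, A, {GD2}, {GD2: 1.0}, cn)
    assert len(sols) == 1
    assert sols[0].infeasible
    assert sols[0].p == {}
    # the tiered fallback still produces refinement scaffolds
    scaffolds = identify_majors(demo_db, {GD2}, {GD2: 1.0}, cn)
    assert scaffolds[0].infeasible and scaffolds[0].p


def test_linkage_and_coverage_invariants_on_random_instances(demo_db):
    """Per-config copy totals equal the CN solution's counts and every
    detected mutation is carried, for random feasible instances."""
    rng = np.random.default_rng(11)
    gds = [GD1, GD2, GD3, GD4]
    checked = 0
    for _ in range(60):
        z = {"gene": int(rng.integers(1, 4)), "pseudo": 2}
        if rng.random() < 0.4:
            z["fusion_e2"] = 1
        cn = _cn(z)
        M = {m for m in gds if rng.random() < 0.5}
        if GD2 in M:
            M.add(GD1)  # keep *2 eligible so the instance stays feasible
        mutcn = {m: float(rng.integers(1, 3)) for m in M}
        A = build_candidates(demo_db, M, cn)
        sols = solve_msaip(demo_db, A, M, mutcn, cn)
        if sols[0].infeasible:
            continue
        checked += 1
        gene_bearing = set(demo_db.gene_bearing_configs())
        for s in sols:
            by_cfg = {}
            for a, c in s.p.items():
                cfg = demo_db.majors[a].config
                if not demo_db.configs[cfg].deletion:
                    by_cfg[cfg] = by_cfg.get(cfg, 0) + c
            for cfg, zc in z.items():
                if cfg in gene_bearing:
                    assert by_cfg.get(cfg, 0) == zc
            for m in M:
                assert sum(
                    c for a, c in s.p.items() if m in demo_db.majors[a].gdm
                ) >= 1
    assert checked >= 20


def _brute_msaip(db, A, M, mutcn, cn_sol, tol=1e-6):
    """Independent oracle: enumerate every copy assignment over the p-box."""
    coding = [a for a in A if not db.configs[db.majors[a].config].deletion]
    del_majors = [a for a in A if db.configs[db.majors[a].config].deletion]
    n_del = deletion_copies(db, cn_sol)
    gene_bearing = set(db.gene_bearing_configs())
    need = {c: z for c, z in cn_sol.z.items() if z > 0 and c in gene_bearing}
    best, keep = np.inf, []
    ranges = [range(cn_sol.z.get(db.majors[a].config, 0) + 1) for a in coding]
    for combo in itertools.product(*ranges):
        p = dict(zip(coding, combo))
        if del_majors and n_del > 0:
            p[del_majors[0]] = n_del
        by_cfg = {}
        for a, c in p.items():
            cfg = db.majors[a].config
            if not db.configs[cfg].deletion:
                by_cfg[cfg] = by_cfg.get(cfg, 0) + c
        if {k: v for k, v in by_cfg.items() if v} != need:
            continue
        if any(
            sum(c for a, c in p.items() if m in db.majors[a].gdm) < 1 for m in M
        ):
            continue
        obj = sum(
            abs(mutcn.get(m, 0.0) - sum(c for a, c in p.items() if m in db.majors[a].gdm))
            for m in M
        )
        if obj < best - tol:
            best, keep = obj, [p]
        elif obj <= best + tol:
            keep.append(p)
    return best, {tuple(sorted((a, c) for a, c in p.items() if c)) for p in keep}


@pytest.mark.parametrize("solver", BACKENDS)
def test_oracle_equivalence_random_instances(demo_db, solver):
    """The ILP matches exhaustive p-box enumeration on 100 random
    instances with <= 5 candidate alleles and <= 4 total copies."""
    rng = np.random.default_rng(21)
    gds = [GD1, GD2, GD3, GD4]
    agreements = 0
    for _ in range(100):
        z = {"gene": int(rng.integers(1, 4)), "pseudo": int(rng.integers(0, 3))}
        cn = _cn(z)
        M = {m for m in gds if rng.random() < 0.6}
        if GD2 in M:
            M.add(GD1)
        mutcn = {m: float(np.round(rng.uniform(0.4, 2.6), 2)) for m in M}
        A = build_candidates(demo_db, M, cn)
        sols = solve_msaip(demo_db, A, M, mutcn, cn, solver=solver)
        b_obj, b_set = _brute_msaip(demo_db, A, M, mutcn, cn)
        if sols[0].infeasible:
            assert b_set == set()
            continue
        assert sols[0].objective == pytest.approx(b_obj, abs=1e-6)
        assert _psets(sols) == b_set
        agreements += 1
    assert agreements >= 60


# ----------------------------------------------------------------- phasing

def _solution(demo_db, p):
    return solve_msaip(
        demo_db,
        list(p),
        set().union(*(demo_db.majors[a].gdm for a in p)),
        {m: 1.0 for a in p for m in demo_db.majors[a].gdm},
        _cn({"gene": sum(p.values()), "pseudo": 2}),
    )


def test_phase_filter_eliminates_trans_configuration(demo_db):
    """30 fragments cover both defining loci of *2; none shows the two
    alternates together: solutions selecting *2 are removed."""
    sols = _solution(demo_db, {"*2": 1, "*1": 1})
    phase = {
        ((1150, "C>T"), (1450, "ref")): 15,
        ((1150, "ref"), (1450, "G>A")): 15,
    }
    assert phase_filter(sols, phase, demo_db) == []
    assert not allele_in_phase(demo_db, "*2", phase)


def test_phase_filter_retains_cis_configuration(demo_db):
    sols = _solution(demo_db, {"*2": 1, "*1": 1})
    phase = {
        ((1150, "C>T"), (1450, "G>A")): 15,
        ((1150, "ref"), (1450, "ref")): 15,
    }
    assert phase_filter(sols, phase, demo_db) == sols


def test_phase_filter_passes_through_without_coverage(demo_db):
    sols = _solution(demo_db, {"*2": 1, "*1": 1})
    assert phase_filter(sols, {}, demo_db) == sols
    sparse = {((1150, "C>T"), (1450, "ref")): 2}  # below min_frags
    assert phase_filter(sols, sparse, demo_db) == sols
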