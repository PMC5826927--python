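"""End-to-end genotyping: profile -> copy number -> majors -> refinement.

The four stages run in order; every co-optimal decomposition at each stage
is carried forward and refined, and the genotypes attaining the lowest
refinement score across *all* upstream decompositions are reported — when
several tie, all are reported as equally likely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .copy_number import DEFAULT_MAX_CN, database_V, solve_cnep
from .database import GeneDatabase
from .ilp import DEFAULT_TOL
from .major import (
    DEFAULT_GAMMA,
    DEFAULT_MIN_FRAGS,
    allele_in_phase,
    identify_majors,
    phase_filter,
)
from .profile import (
    DEFAULT_MIN_ALT,
    DEFAULT_TAU,
    RawPileup,
    SampleProfile,
    build_profile,
)
from .refine import (
    DEFAULT_ALPHA,
    DEFAULT_BETA,
    DEFAULT_ETA,
    RefinedGenotype,
    RefinementError,
    rank_solutions,
    solve_grp,
)

REPORT_SCHEMA = 1


class NoGenotypeError(RuntimeError):
    """No feasible genotype exists for the sample under the database."""


@dataclass
class GenotypeParams:
    """All pipeline thresholds and penalties in one place."""

    tau: float = DEFAULT_TAU
    min_alt: int = DEFAULT_MIN_ALT
    gamma: float = DEFAULT_GAMMA
    min_frags: int = DEFAULT_MIN_FRAGS
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    eta: float = DEFAULT_ETA
    max_cn: int = DEFAULT_MAX_CN
    tol: float = DEFAULT_TOL
    solver: str = "auto"
    use_phase_filter: bool = True


@dataclass
class GenotypeReport:
    genotypes: list[RefinedGenotype]
    profile: SampleProfile
    n_cn_solutions: int
    n_major_solutions: int
    n_candidates: int
    warnings: list[str] = field(default_factory=list)

    @property
    def equally_likely(self) -> bool:
        return len(self.genotypes) > 1

    def to_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "version": __version__,
            "genotypes": [
                {
                    "diplotype": g.diplotype(),
                    "score": g.score,
                    "copy_number": {k: v for k, v in g.cn_solution.z.items() if v},
                    "majors": {k: v for k, v in g.major_solution.p.items() if v},
                    "slots": [
                        {
                            "major": s.major,
                            "minor": s.label,
                            "based_on": s.minor,
                            "mutations": sorted(s.mutations()),
                            "added": sorted(s.added),
                            "novel_major": s.novel_major,
                        }
                        for s in g.slots
                    ],
                    "novel_majors": {
                        k: sorted(v) for k, v in g.novel_majors.items()
                    },
                    "novel_minors": {
                        k: [v[0], sorted(v[1])] for k, v in g.novel_minors.items()
                    },
                }
                for g in self.genotypes
            ],
            "equally_likely": self.equally_likely,
            "counts": {
                "cn_solutions": self.n_cn_solutions,
                "major_solutions": self.n_major_solutions,
                "refined_candidates": self.n_candidates,
            },
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def human_lines(self) -> list[str]:
        lines = []
        tag = " (equally likely)" if self.equally_likely else ""
        for g in self.genotypes:
            novel = "; ".join(
                f"{name} = {major} + {sorted(extra)}"
                for name, (major, extra) in g.novel_minors.items()
            )
            lines.append(
                f"{g.diplotype()} | score={g.score:.4g}{tag}"
                + (f" | novel: {novel}" if novel else "")
            )
        return lines


def genotype_profile(
    db: GeneDatabase,
    sample: RawPileup,
    reference: RawPileup,
    params: GenotypeParams | None = None,
) -> GenotypeReport:
    """Run the full decomposition on one sample pileup."""
    params = params or GenotypeParams()
    prof = build_profile(
        db, sample, reference, tau=params.tau, min_alt=params.min_alt
    )
    cn_vec = np.where(np.isnan(prof.cn), 0.0, prof.cn)
    cn_solutions = solve_cnep(
        cn_vec,
        database_V(db),
        max_cn=params.max_cn,
        region_mask=prof.region_masked,
        tol=params.tol,
        solver=params.solver,
    )

    major_solutions = []
    for cn_sol in cn_solutions:
        sols = identify_majors(
            db, prof.M, prof.mutcn, cn_sol, tol=params.tol, solver=params.solver
        )
        sols = [s for s in sols if not (s.infeasible and not s.p)]
        if params.use_phase_filter and prof.phase:
            filtered = phase_filter(
                sols, prof.phase, db, gamma=params.gamma, min_frags=params.min_frags
            )
            if not filtered and sols:
                # every co-optimum contradicted the phasing: eliminate the
                # out-of-phase alleles themselves and re-solve
                bad = {
                    a
                    for a in db.majors
                    if not allele_in_phase(
                        db, a, prof.phase, params.gamma, params.min_frags
                    )
                }
                resolved = identify_majors(
                    db, prof.M, prof.mutcn, cn_sol,
                    tol=params.tol, solver=params.solver, exclude=bad,
                )
                filtered = [r for r in resolved if not (r.infeasible and not r.p)]
            sols = filtered
        major_solutions.extend(sols)
    if not major_solutions:
        raise NoGenotypeError(
            "no major star-allele assignment is consistent with the sample"
        )

    candidates: list[RefinedGenotype] = []
    warnings = list(prof.warnings)
    for msol in major_solutions:
        try:
            candidates.extend(
                solve_grp(
                    db,
                    msol,
                    prof.mutcn,
                    prof.M | prof.observed_neutral,
                    alpha=params.alpha,
                    beta=params.beta,
                    eta=params.eta,
                    tol=params.tol,
                    solver=params.solver,
                )
            )
        except RefinementError as exc:
            warnings.append(f"refinement skipped one major solution: {exc}")
    if not candidates:
        raise NoGenotypeError("refinement produced no feasible genotype")

    winners = rank_solutions(candidates, tol=params.tol)
    return GenotypeReport(
        genotypes=winners,
        profile=prof,
        n_cn_solutions=len(cn_solutions),
        n_major_solutions=len(major_solutions),
        n_candidates=len(candidates),
        warnings=warnings,
    )


def write_mutation_assignments(
    report: GenotypeReport, db: GeneDatabase, path
) -> None:
    """VCF-style dump of per-copy mutation assignments for the best
    genotype (1-based positions; one sample column per gene copy)."""
    g = report.genotypes[0]
    slots = g.slots
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=starallele-{__version__}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Carried (1) or not (0)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.label.replace(" ", "") for s in slots),
    ]
    all_muts = sorted(
        {m for s in slots for m in s.mutations()},
        key=lambda mid: db.mutations[mid].pos,
    )
    for mid in all_muts:
        mut = db.mutations[mid]
        if ">" in mut.op:
            ref, alt = mut.op.split(">")
        elif mut.op.startswith("ins:"):
            ref, alt = "N", "N" + mut.op[4:]
        else:
            ref, alt = "N" * (int(mut.op[4:]) + 1), "N"
        carried = "\t".join(
            "1" if mid in s.mutations() else "0" for s in slots
        )
        lines.append(
            f"{db.gene}\t{mut.pos + 1}\t{mid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{carried}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
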