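"""Ground-truthed synthetic samples for the full decomposition pipeline.

The generator emulates short-read sequencing of one gene cluster under a
known genotype: per-position depth is Poisson around (per-copy depth x
capture bias x local copy count), alternate-allele read counts are binomial
in the fraction of copies carrying each mutation (plus a small substitution
error rate), and read-pair phasing counts record which allele pairs
co-occur on fragments drawn from the same physical copy.  WGS-like samples
use a uniform bias field; capture-like samples use a smooth strongly
non-uniform field shared between the sample and its technology-matched
reference, which is what makes ratio normalization against a single
reference per technology work.

Simulated copies are composed exactly from the database's structural
configurations, so fusion and partial-deletion genotypes produce stepped
region-level copy-number profiles whose integer decomposition is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import GeneDatabase
from .profile import PhaseKey, RawPileup

_REFSEQ_SEED = 91  # fixed: the reference sequence is a property of the db


@dataclass
class GenotypeSpec:
    """A simulated genotype: minor-allele copies plus sampling parameters."""

    alleles: list[tuple[str, int]]
    depth: float = 30.0
    bias: str = "uniform"  # "uniform" | "capture"
    error_rate: float = 0.001
    seed: int = 0
    noise: bool = True
    extra_configs: list[tuple[str, int]] = field(default_factory=list)
    background_pseudo: int = 2  # whole-pseudogene copies always present

    def copies(self) -> list[str]:
        out = []
        for minor, count in self.alleles:
            if count < 1:
                raise ValueError(f"allele {minor}: count must be >= 1")
            out.extend([minor] * count)
        return out


def capture_bias(db: GeneDatabase, tech_seed: int = 7) -> np.ndarray:
    """A smooth, strongly non-uniform positive field over the cluster span,
    deterministic per technology seed (shared by sample and reference)."""
    start, end = db.span
    size = end - start
    rng = np.random.default_rng(tech_seed)
    phases = rng.uniform(0, 2 * np.pi, 3)
    i = np.arange(size)
    field_ = (
        1.2 * np.sin(2 * np.pi * i / 700 + phases[0])
        + 0.8 * np.sin(2 * np.pi * i / 260 + phases[1])
        + 0.4 * np.sin(2 * np.pi * i / 90 + phases[2])
    )
    return np.exp(field_)  # ~10-100x dynamic range, like exon capture


def _bias_field(db: GeneDatabase, bias: str) -> np.ndarray:
    start, end = db.span
    if bias == "uniform":
        return np.ones(end - start)
    if bias == "capture":
        return capture_bias(db)
    raise ValueError(f"unknown bias model {bias!r}")


def _region_index(db: GeneDatabase) -> np.ndarray:
    """pos -> region ordinal in canonical order, -1 outside all regions."""
    start, end = db.span
    idx = np.full(end - start, -1, dtype=int)
    for j, r in enumerate(db.regions):
        idx[r.start - start : r.end - start] = j
    return idx


def _coverage(db: GeneDatabase, config_counts: dict[str, int]) -> np.ndarray:
    """Per-position copy count implied by a multiset of configurations;
    the copy-number-neutral span is always diploid."""
    start, end = db.span
    ridx = _region_index(db)
    region_cn = np.zeros(len(db.regions))
    for cfg, count in config_counts.items():
        region_cn += count * db.config_vector(cfg)
    cov = np.zeros(end - start)
    covered = ridx >= 0
    cov[covered] = region_cn[ridx[covered]]
    ns, ne = db.cn_neutral
    cov[ns - start : ne - start] = 2.0
    return cov


def _config_counts(db: GeneDatabase, spec: GenotypeSpec) -> dict[str, int]:
    counts: dict[str, int] = {}
    pseudo_cfg = _whole_pseudo_config(db)
    if pseudo_cfg and spec.background_pseudo:
        counts[pseudo_cfg] = spec.background_pseudo
    for minor in spec.copies():
        if minor not in db.minors:
            raise ValueError(f"unknown minor allele {minor!r}")
        cfg = db.majors[db.minors[minor].major].config
        if not db.configs[cfg].deletion:
            counts[cfg] = counts.get(cfg, 0) + 1
    for cfg, count in spec.extra_configs:
        if cfg not in db.configs:
            raise ValueError(f"unknown config {cfg!r}")
        counts[cfg] = counts.get(cfg, 0) + count
    return counts


def _whole_pseudo_config(db: GeneDatabase) -> str | None:
    """The config covering exactly one copy of every pseudogene region."""
    n = db.n
    for cid in db.coding_configs():
        v = db.config_vector(cid)
        if not v[:n].any() and (v[n:] == 1).all():
            return cid
    return None


def simulate_profile(
    db: GeneDatabase, spec: GenotypeSpec
) -> tuple[RawPileup, dict]:
    """Simulate one sample; returns the pileup and its truth record.

    The truth record stores the exact configuration counts ``z``, major
    copy counts ``p`` (deletion alleles included) and the minor-allele
    multiset the pipeline should recover.
    """
    rng = np.random.default_rng(spec.seed)
    start, end = db.span
    bias = _bias_field(db, spec.bias)
    config_counts = _config_counts(db, spec)
    cov = _coverage(db, config_counts)
    lam = spec.depth * bias * cov
    depth = rng.poisson(lam) if spec.noise else np.round(lam).astype(int)

    ridx = _region_index(db)
    copies = spec.copies()
    copy_vectors = [
        db.config_vector(db.majors[db.minors[m].major].config) for m in copies
    ]
    copy_muts = [db.mut(m) for m in copies]

    alts: dict[str, int] = {}
    for mid, mut in db.mutations.items():
        j = ridx[mut.pos - start]
        if j < 0:
            continue
        total = cov[mut.pos - start]
        if total <= 0:
            continue
        carriers = sum(
            int(v[j])
            for v, muts in zip(copy_vectors, copy_muts)
            if mid in muts
        )
        p_true = min(carriers / total, 1.0)
        err = spec.error_rate
        p = p_true * (1 - err) + (1 - p_true) * err / 3
        d = int(depth[mut.pos - start])
        alt = int(rng.binomial(d, p)) if spec.noise else int(round(d * p_true))
        if alt:
            alts[mid] = alt

    phase = _simulate_phase(db, spec, rng, copies, copy_vectors, copy_muts, ridx)

    raw = RawPileup(
        start=start,
        depth=depth,
        alts=alts,
        phase=phase,
        read_len=db.read_len,
        insert_size=db.insert_size,
        meta={"gene": db.gene, "bias": spec.bias},
    )
    truth = {
        "z": dict(config_counts),
        "p": _true_majors(db, spec),
        "minors": sorted(copies + _deletion_minors(db, spec)),
        "seed": spec.seed,
    }
    return raw, truth


def _true_majors(db: GeneDatabase, spec: GenotypeSpec) -> dict[str, int]:
    p: dict[str, int] = {}
    for minor in spec.copies():
        major = db.minors[minor].major
        p[major] = p.get(major, 0) + 1
    gene_copies = sum(
        c
        for major, c in p.items()
        if not db.configs[db.majors[major].config].deletion
        and db.config_vector(db.majors[major].config)[: db.n].any()
    )
    dels = db.deletion_majors()
    declared = sum(c for m, c in p.items() if db.configs[db.majors[m].config].deletion)
    implied = max(0, 2 - gene_copies)
    if dels and implied > declared:
        p[dels[0]] = p.get(dels[0], 0) + (implied - declared)
    return p


def _deletion_minors(db: GeneDatabase, spec: GenotypeSpec) -> list[str]:
    """Deletion-allele minors implied (not explicitly listed) by the spec."""
    explicit = spec.copies()
    truth_p = _true_majors(db, spec)
    out = []
    for major, count in truth_p.items():
        if not db.configs[db.majors[major].config].deletion:
            continue
        already = sum(1 for m in explicit if db.minors[m].major == major)
        minor = db.minors_of(major)[0].id
        out.extend([minor] * (count - already))
    return out


def _simulate_phase(db, spec, rng, copies, copy_vectors, copy_muts, ridx):
    """Fragment-level co-observations for mutation pairs within one
    fragment span, drawn per physical copy (background pseudogene copies
    carry the reference allele everywhere)."""
    start, _ = db.span
    span = db.insert_size + 2 * db.read_len
    muts = sorted(db.mutations.values(), key=lambda m: m.pos)
    phase: dict[PhaseKey, int] = {}
    pseudo_cfg = _whole_pseudo_config(db)
    units: list[tuple[np.ndarray, frozenset]] = [
        (v, m) for v, m in zip(copy_vectors, copy_muts)
    ]
    if pseudo_cfg and spec.background_pseudo:
        units += [
            (db.config_vector(pseudo_cfg), frozenset())
        ] * spec.background_pseudo
    per_copy = spec.depth / 2.0
    for i in range(len(muts)):
        for j in range(i + 1, len(muts)):
            m1, m2 = muts[i], muts[j]
            if m2.pos - m1.pos == 0 or m2.pos - m1.pos > span:
                continue
            j1, j2 = ridx[m1.pos - start], ridx[m2.pos - start]
            if j1 < 0 or j2 < 0:
                continue
            for v, mset in units:
                mult = int(min(v[j1], v[j2]))
                if mult == 0:
                    continue
                lam = per_copy * mult
                n = int(rng.poisson(lam)) if spec.noise else int(round(lam))
                if n == 0:
                    continue
                a1 = m1.op if m1.id in mset else "ref"
                a2 = m2.op if m2.id in mset else "ref"
                key = ((m1.pos, a1), (m2.pos, a2))
                phase[key] = phase.get(key, 0) + n
    return phase


def make_reference(
    db: GeneDatabase,
    depth: float = 30.0,
    bias: str = "uniform",
    seed: int = 1,
    noise: bool = True,
) -> RawPileup:
    """A technology-reference pileup: a plain diploid with no mutations,
    sharing the technology's bias field with samples of the same kind."""
    rng = np.random.default_rng(seed)
    start, end = db.span
    b = _bias_field(db, bias)
    pseudo = _whole_pseudo_config(db)
    gene_cfg = None
    n = db.n
    for cid in db.coding_configs():
        v = db.config_vector(cid)
        if (v[:n] == 1).all() and not v[n:].any():
            gene_cfg = cid
            break
    counts: dict[str, int] = {}
    if gene_cfg:
        counts[gene_cfg] = 2
    if pseudo:
        counts[pseudo] = 2
    cov = _coverage(db, counts)
    lam = depth * b * cov
    d = rng.poisson(lam) if noise else np.round(lam).astype(int)
    return RawPileup(
        start=start, depth=d, read_len=db.read_len, insert_size=db.insert_size,
        meta={"gene": db.gene, "bias": bias, "role": "reference"},
    )


# ----------------------------------------------------------------------- trios

def simulate_trio(
    db: GeneDatabase,
    mother: GenotypeSpec,
    father: GenotypeSpec,
    seed: int = 0,
) -> tuple[list[tuple[RawPileup, dict]], dict]:
    """Simulate mother, father and a Mendelian child.

    Each (minor, count) entry of a parent expands into ``count``
    transmissible allele copies; the child inherits one copy from each
    parent, chosen uniformly.  Returns the three (pileup, truth) pairs plus
    a trio record naming the transmitted alleles.
    """
    rng = np.random.default_rng(seed)
    inherited = []
    for parent in (mother, father):
        pool = parent.copies() + _deletion_minors(db, parent)
        if not pool:
            raise ValueError("parent with zero transmissible copies")
        inherited.append(pool[int(rng.integers(len(pool)))])
    child_alleles: dict[str, int] = {}
    for minor in inherited:
        child_alleles[minor] = child_alleles.get(minor, 0) + 1
    child = GenotypeSpec(
        alleles=sorted(child_alleles.items()),
        depth=mother.depth,
        bias=mother.bias,
        error_rate=mother.error_rate,
        seed=int(rng.integers(2**31)),
        noise=mother.noise,
    )
    out = [
        simulate_profile(db, mother),
        simulate_profile(db, father),
        simulate_profile(db, child),
    ]
    trio = {"transmitted": inherited, "child_minors": out[2][1]["minors"]}
    return out, trio


# ------------------------------------------------------------------------- SAM

def reference_sequence(db: GeneDatabase) -> str:
    """Deterministic reference sequence for the cluster span, with SNV
    reference bases forced to match the mutation catalogue."""
    start, end = db.span
    rng = np.random.default_rng(_REFSEQ_SEED)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, end - start))
    for mut in db.mutations.values():
        if ">" in mut.op:
            seq[mut.pos - start] = mut.op.split(">")[0]
    return "".join(seq)


def write_sam(raw: RawPileup, db: GeneDatabase, path, seed: int = 0) -> None:
    """Emit single-end SAM records realizing a pileup's depth and alternate
    counts.

    Reads tile the depth profile exactly (coverage at every position equals
    the pileup depth, up to edge effects of at most one read); alternate
    alleles are planted on reads overlapping each mutation locus to match
    its alternate count.  Quality strings are constant; phasing evidence
    travels in the profile dialect, not in read pairing.
    """
    import pysam

    rng = np.random.default_rng(seed)
    start, end = db.span
    refseq = reference_sequence(db)
    read_len = raw.read_len

    # sweep: open reads when depth steps up, close oldest when it steps down
    reads: list[tuple[int, int]] = []  # (start, end) half-open
    open_reads: list[int] = []  # start positions
    for i in range(len(raw.depth)):
        pos = start + i
        # retire reads at max length
        still = []
        for s in open_reads:
            if pos - s >= read_len:
                reads.append((s, pos))
            else:
                still.append(s)
        open_reads = still
        need = int(raw.depth[i])
        while len(open_reads) > need:
            # close the newest read so older ones reach full length
            s = open_reads.pop()
            reads.append((s, pos))
        while len(open_reads) < need:
            open_reads.append(pos)
    for s in open_reads:
        reads.append((s, end))
    reads = [(s, e) for s, e in reads if e > s]

    # plant alternate alleles: first alt_count reads overlapping each locus
    snv_plan: dict[int, set[str]] = {}
    indel_plan: dict[int, str] = {}
    for mid, count in raw.alts.items():
        p, op = mid.split(":", 1)
        p = int(p)
        overlapping = [k for k, (s, e) in enumerate(reads) if s <= p < e]
        chosen = rng.permutation(len(overlapping))[:count]
        for c in chosen:
            k = overlapping[c]
            if ">" in op:
                snv_plan.setdefault(k, set()).add(mid)
            else:
                indel_plan[k] = mid

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": "ref", "LN": int(end + 1000)}],
    }
    mode = "w"  # text SAM
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for k, (s, e) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"sim{k}"
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            seq = list(refseq[s - start : e - start])
            for mid in snv_plan.get(k, ()):  # substitute alt base
                p, op = mid.split(":", 1)
                seq[int(p) - s] = op.split(">")[1]
            mid = indel_plan.get(k)
            if mid is not None:
                p, op = mid.split(":", 1)
                p = int(p)
                if op.startswith("ins:") and s < p < e:
                    ins = op[4:]
                    seq = seq[: p - s] + list(ins) + seq[p - s :]
                    a.cigartuples = [(0, p - s), (1, len(ins)), (0, e - p)]
                elif op.startswith("del:"):
                    ln = int(op[4:])
                    if s < p and p + ln < e:
                        seq = seq[: p - s] + seq[p - s + ln :]
                        a.cigartuples = [(0, p - s), (2, ln), (0, e - p - ln)]
                    else:
                        mid = None
                else:
                    mid = None
            if mid is None and k in indel_plan:
                pass  # indel did not fit; read stays reference
            if a.cigartuples is None:
                a.cigartuples = [(0, e - s)]
            a.query_sequence = "".join(seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.flag = 0
            out.write(a)
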