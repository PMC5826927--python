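"""From alignments (or a plain-text gene profile) to the quantities the
optimizers consume.

The pipeline needs four things from the sample:

* ``cn_s`` — per-position copy number, obtained by normalizing the sample's
  read depth against a reference sample of the same sequencing technology
  and calibrating so that the copy-number-neutral span averages exactly 2
  (diploid);
* ``cn[r]`` — per-region copy number, the mean of ``cn_s`` over the
  unmasked positions of each intron/exon;
* ``mutcn(m)`` — per-mutation copy number: alternate-read count divided by
  the per-copy depth at the locus, capped by ``cn_s`` there;
* phasing evidence — counts of fragments co-observing allele pairs at two
  database mutation loci.

Positions inside gene/pseudogene segments that are identical over more than
one fragment length (``insert + 2 * read_len``) cannot be mapped
unambiguously; they are masked and ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .database import GeneDatabase, Mutation

#: default mutation-presence thresholds: a mutation is called present when
#: its copy number reaches tau AND it is supported by at least min_alt reads
DEFAULT_TAU = 0.5
DEFAULT_MIN_ALT = 3

PhaseKey = tuple[tuple[int, str], tuple[int, str]]  # ((pos, op|"ref"), (pos, op|"ref"))


class EmptyInputError(ValueError):
    """No reads (or depth rows) overlap the gene-cluster span."""


class NormalizationError(ValueError):
    """The copy-number-neutral span carries no usable coverage."""


@dataclass
class RawPileup:
    """Raw per-position evidence over the cluster span ``[start, start+len)``."""

    start: int
    depth: np.ndarray  # int, per position
    alts: dict[str, int] = field(default_factory=dict)  # mutation id -> alt reads
    phase: dict[PhaseKey, int] = field(default_factory=dict)
    read_len: int = 100
    insert_size: int = 300
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def depth_at(self, pos: int) -> int:
        if not (self.start <= pos < self.end):
            return 0
        return int(self.depth[pos - self.start])

    def alt_count(self, mutation_id: str) -> int:
        return self.alts.get(mutation_id, 0)


@dataclass
class SampleProfile:
    """Everything the decomposition stages consume."""

    start: int
    cn_s: np.ndarray  # float per position; nan where masked
    masked: np.ndarray  # bool per position
    cn: np.ndarray  # float per region, canonical order
    region_masked: np.ndarray  # bool per region (fully masked -> excluded)
    mutcn: dict[str, float]
    M: set[str]  # detected gene-disrupting mutations
    observed_neutral: set[str]
    phase: dict[PhaseKey, int]
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------- dialect

def write_profile(raw: RawPileup, path: str | Path) -> None:
    """Serialize a pileup in the tab-separated gene-profile dialect."""
    lines = []
    meta = dict(raw.meta)
    meta.setdefault("start", str(raw.start))
    meta["read_len"] = str(raw.read_len)
    meta["insert_size"] = str(raw.insert_size)
    meta["start"] = str(raw.start)
    lines.append("#meta\t" + "\t".join(f"{k}={v}" for k, v in sorted(meta.items())))
    for i, d in enumerate(raw.depth):
        if d:
            lines.append(f"D\t{raw.start + i}\t{int(d)}")
    for mid, count in sorted(raw.alts.items()):
        pos, op = mid.split(":", 1)
        lines.append(f"M\t{pos}\t{op}\t{count}")
    for ((p1, a1), (p2, a2)), count in sorted(raw.phase.items()):
        lines.append(f"P\t{p1}:{a1}\t{p2}:{a2}\t{count}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> RawPileup:
    """Parse the gene-profile dialect back into a :class:`RawPileup`."""
    meta: dict[str, str] = {}
    depths: dict[int, int] = {}
    alts: dict[str, int] = {}
    phase: dict[PhaseKey, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "#meta":
            for kv in fields[1:]:
                k, _, v = kv.partition("=")
                meta[k] = v
        elif fields[0] == "D":
            depths[int(fields[1])] = int(fields[2])
        elif fields[0] == "M":
            alts[f"{int(fields[1])}:{fields[2]}"] = int(fields[3])
        elif fields[0] == "P":
            p1, _, a1 = fields[1].partition(":")
            p2, _, a2 = fields[2].partition(":")
            phase[((int(p1), a1), (int(p2), a2))] = int(fields[3])
        else:
            raise ValueError(f"unknown profile row type {fields[0]!r}")
    if not depths:
        raise EmptyInputError("profile contains no depth rows")
    start = int(meta.get("start", min(depths)))
    end = max(depths) + 1
    depth = np.zeros(end - start, dtype=np.int64)
    for pos, d in depths.items():
        depth[pos - start] = d
    return RawPileup(
        start=start,
        depth=depth,
        alts=alts,
        phase=phase,
        read_len=int(meta.get("read_len", 100)),
        insert_size=int(meta.get("insert_size", 300)),
        meta=meta,
    )


# ------------------------------------------------------------------ alignments

_SKIP_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800  # unmapped/secondary/qcfail/dup/supp


def _walk_cigar(read):
    """Yield matched reference positions plus indel events for one read.

    Returns ``(matched: dict ref_pos -> query_pos, insertions: list of
    (ref_pos, seq), deletions: list of (ref_pos, length))``.  An insertion
    is anchored at the reference position *before which* the bases are
    inserted; a deletion at its first deleted position.
    """
    matched: dict[int, int] = {}
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    rpos = read.reference_start
    qpos = 0
    seq = read.query_sequence or ""
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                matched[rpos + k] = qpos + k
            rpos += length
            qpos += length
        elif op == 1:  # I
            insertions.append((rpos, seq[qpos : qpos + length]))
            qpos += length
        elif op == 2:  # D
            deletions.append((rpos, length))
            rpos += length
        elif op == 3:  # N
            rpos += length
        elif op in (4,):  # S
            qpos += length
        # H/P consume nothing we track
    return matched, insertions, deletions


def _read_allele(read, matched, insertions, deletions, mut: Mutation) -> str | None:
    """Allele carried by one read at a mutation locus: the mutation's op,
    ``"ref"``, or ``None`` when the locus is not covered."""
    seq = read.query_sequence or ""
    if mut.op.startswith("ins:"):
        inserted = mut.op[4:]
        if any(p == mut.pos and s == inserted for p, s in insertions):
            return mut.op
        return "ref" if mut.pos in matched and mut.pos - 1 in matched else None
    if mut.op.startswith("del:"):
        length = int(mut.op[4:])
        if any(p == mut.pos and ln == length for p, ln in deletions):
            return mut.op
        return "ref" if mut.pos in matched else None
    # SNV "X>Y"
    ref_base, _, alt_base = mut.op.partition(">")
    q = matched.get(mut.pos)
    if q is None:
        return None
    return mut.op if seq[q : q + 1] == alt_base else "ref"


def ingest_alignments(path: str | Path, db: GeneDatabase) -> RawPileup:
    """Build a :class:`RawPileup` from a SAM/BAM file restricted to the
    cluster region.

    Duplicate-marked, secondary, supplementary and unmapped reads are
    skipped.  Phase observations are collected for every fragment whose
    reads cover two or more database mutation loci (both mates pooled).
    """
    import pysam

    start, end = db.span
    depth = np.zeros(end - start, dtype=np.int64)
    alts: dict[str, int] = {}
    fragment_calls: dict[str, dict[int, str]] = {}
    n_reads = 0
    muts = sorted(db.mutations.values(), key=lambda m: m.pos)

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.flag & _SKIP_FLAGS or read.cigartuples is None:
                continue
            if read.reference_end is None or read.reference_end <= start:
                continue
            if read.reference_start >= end:
                continue
            n_reads += 1
            matched, insertions, deletions = _walk_cigar(read)
            for rp in matched:
                if start <= rp < end:
                    depth[rp - start] += 1
            calls = fragment_calls.setdefault(read.query_name, {})
            for mut in muts:
                if not (read.reference_start - 1 <= mut.pos < (read.reference_end or 0) + 1):
                    continue
                allele = _read_allele(read, matched, insertions, deletions, mut)
                if allele is None:
                    continue
                if allele != "ref":
                    alts[mut.id] = alts.get(mut.id, 0) + 1
                prev = calls.get(mut.pos)
                if prev is None:
                    calls[mut.pos] = allele
                elif prev != allele:
                    calls[mut.pos] = "?"  # mate disagreement: discard locus

    if n_reads == 0:
        raise EmptyInputError(f"no reads overlap {db.gene} span [{start}, {end})")

    phase: dict[PhaseKey, int] = {}
    for calls in fragment_calls.values():
        loci = sorted((p, a) for p, a in calls.items() if a != "?")
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                key = (loci[i], loci[j])
                phase[key] = phase.get(key, 0) + 1

    return RawPileup(
        start=start,
        depth=depth,
        alts=alts,
        phase=phase,
        read_len=db.read_len,
        insert_size=db.insert_size,
    )


# --------------------------------------------------------------------- masking

def mask_ambiguous(
    db: GeneDatabase,
    identity_segments: list[tuple[int, int]] | None = None,
    insert_size: int | None = None,
    read_len: int | None = None,
) -> np.ndarray:
    """Boolean mask over the cluster span for ambiguously-mappable positions.

    A gene↔pseudogene identical segment longer than one fragment span
    (``insert + 2 * read_len``) cannot be resolved by paired reads; every
    position inside such a segment is masked.  Shorter segments are left
    untouched.
    """
    segments = db.identity_segments if identity_segments is None else identity_segments
    insert_size = db.insert_size if insert_size is None else insert_size
    read_len = db.read_len if read_len is None else read_len
    threshold = insert_size + 2 * read_len
    start, end = db.span
    mask = np.zeros(end - start, dtype=bool)
    for s, e in segments:
        if e - s > threshold:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                mask[lo - start : hi - start] = True
    return mask


# --------------------------------------------------------------- normalization

def normalize_coverage(
    sample: RawPileup,
    reference: RawPileup,
    db: GeneDatabase,
    masked: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position copy number ``cn_s`` from depth ratios to the reference.

    ``cn_s(i) = 2 * (depth_sample(i) / depth_ref(i)) / c`` where ``c`` is
    the mean depth ratio over the copy-number-neutral span, so that span
    averages exactly 2.  Sharing the reference's technology-specific
    capture bias cancels it, which is why one reference per technology
    suffices.  Positions with zero reference coverage are masked.

    Returns ``(cn_s, masked)`` — the updated position mask included.
    """
    start, end = db.span
    size = end - start
    mask = np.zeros(size, bool) if masked is None else masked.copy()

    def window(raw: RawPileup) -> np.ndarray:
        out = np.zeros(size, dtype=float)
        lo = max(raw.start, start)
        hi = min(raw.end, end)
        if lo < hi:
            out[lo - start : hi - start] = raw.depth[lo - raw.start : hi - raw.start]
        return out

    ds = window(sample)
    dr = window(reference)
    mask |= dr == 0
    ratio = np.divide(ds, dr, out=np.zeros(size), where=dr > 0)

    ns, ne = db.cn_neutral
    sel = np.zeros(size, bool)
    sel[ns - start : ne - start] = True
    sel &= ~mask
    if not sel.any() or ratio[sel].sum() == 0:
        raise NormalizationError("no usable coverage over the cn-neutral span")
    c = ratio[sel].mean()
    cn_s = 2.0 * ratio / c
    cn_s[mask] = np.nan
    return cn_s, mask


def region_copy_number(
    cn_s: np.ndarray, region, masked: np.ndarray, start: int
) -> float:
    """Mean of ``cn_s`` over the unmasked positions of one region span.

    Returns ``nan`` for a fully-masked region (the caller must exclude it
    from the copy-number fit).
    """
    sl = slice(region.start - start, region.end - start)
    keep = ~masked[sl]
    if not keep.any():
        return float("nan")
    return float(cn_s[sl][keep].mean())


# ------------------------------------------------------------------- mutations

def mutation_copy_number(
    raw: RawPileup,
    cn_s: np.ndarray,
    mut: Mutation,
    start: int,
    warnings: list[str] | None = None,
) -> float:
    """Estimated copies carrying mutation ``m``.

    ``mutcn(m) = alt_count(m) / per_copy_depth`` where ``per_copy_depth =
    depth(locus) / cn_s(locus)``; capped at ``cn_s(locus)`` since reads at
    the locus may originate from copies not carrying ``m``.
    """
    depth = raw.depth_at(mut.pos)
    if depth == 0:
        if warnings is not None:
            warnings.append(f"zero depth at {mut.id}; mutcn set to 0")
        return 0.0
    local_cn = cn_s[mut.pos - start]
    if np.isnan(local_cn):
        if warnings is not None:
            warnings.append(f"masked locus at {mut.id}; mutcn set to 0")
        return 0.0
    per_copy = depth / local_cn if local_cn > 0 else float("inf")
    if not np.isfinite(per_copy) or per_copy == 0:
        return 0.0
    return float(min(raw.alt_count(mut.id) / per_copy, local_cn))


def detect_mutations(
    raw: RawPileup,
    cn_s: np.ndarray,
    db: GeneDatabase,
    tau: float = DEFAULT_TAU,
    min_alt: int = DEFAULT_MIN_ALT,
    start: int | None = None,
) -> tuple[set[str], set[str], dict[str, float]]:
    """Split database mutations into detected gene-disrupting (``M``) and
    detected neutral sets.

    A mutation is present iff its alternate-read support reaches
    ``min_alt`` *and* its estimated copy number reaches ``tau``.
    Returns ``(M, observed_neutral, mutcn)`` with mutcn for every database
    mutation.
    """
    start = db.span[0] if start is None else start
    M: set[str] = set()
    neutral: set[str] = set()
    mutcn: dict[str, float] = {}
    for mid, mut in db.mutations.items():
        cn = mutation_copy_number(raw, cn_s, mut, start)
        mutcn[mid] = cn
        if raw.alt_count(mid) >= min_alt and cn >= tau:
            (M if mut.gene_disrupting else neutral).add(mid)
    return M, neutral, mutcn


# ------------------------------------------------------------------- pipeline

def build_profile(
    db: GeneDatabase,
    sample: RawPileup,
    reference: RawPileup,
    tau: float = DEFAULT_TAU,
    min_alt: int = DEFAULT_MIN_ALT,
    extra_mask: np.ndarray | None = None,
) -> SampleProfile:
    """Run masking, normalization, segmentation and mutation detection."""
    warnings: list[str] = []
    start, _ = db.span
    mask = mask_ambiguous(db)
    if extra_mask is not None:
        mask |= extra_mask
    cn_s, mask = normalize_coverage(sample, reference, db, mask)
    cn = np.array([region_copy_number(cn_s, r, mask, start) for r in db.regions])
    region_masked = np.isnan(cn)
    for r, flagged in zip(db.regions, region_masked):
        if flagged:
            warnings.append(f"region {r.name} fully masked; excluded from CN fit")
    M, observed_neutral, mutcn = detect_mutations(sample, cn_s, db, tau, min_alt, start)
    return SampleProfile(
        start=start,
        cn_s=cn_s,
        masked=mask,
        cn=cn,
        region_masked=region_masked,
        mutcn=mutcn,
        M=M,
        observed_neutral=observed_neutral,
        phase=dict(sample.phase),
        warnings=warnings,
    )
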