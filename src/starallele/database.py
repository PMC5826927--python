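"""Star-allele database: region model, mutation catalogue, structural
configurations and major/minor allele definitions.

A *star-allele* is a named haplotype of a gene, defined by the set of
mutations it carries relative to the wild-type (*1) sequence.  Mutations are
either *gene-disrupting* (they change the protein product or enzyme
activity) or *neutral*.  A **major** star-allele is defined solely by its
gene-disrupting mutations and is numbered (*2, *4, ...); a **minor**
star-allele extends a major with neutral mutations and is lettered
(*2A, *2B, ...).

The database also carries the *structural-configuration* catalogue: each
configuration describes one physical copy of the gene (a whole gene, a
whole pseudogene, a gene/pseudogene fusion, a partial deletion or
duplication) as an integer vector ``v`` of length ``n*(d+1)`` — one entry
per intron/exon region of the gene and each of its ``d`` pseudogenes,
counting how many copies of that region the arrangement contributes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

SCHEMA_VERSION = 1

#: suffix used when a bare major implicitly owns a single minor allele
_IMPLICIT_MINOR_SUFFIX = "A"


class DatabaseError(ValueError):
    """Base class for database validation failures."""


class SchemaError(DatabaseError):
    """The file does not conform to the documented schema."""


class DanglingReferenceError(DatabaseError):
    """An allele refers to a mutation, config or major that does not exist."""


@dataclass(frozen=True)
class RegionDef:
    """One intron or exon of one gene unit.

    ``span`` is 0-based half-open in reference coordinates.
    """

    unit: str
    kind: str  # "intron" | "exon"
    ordinal: int
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.unit}.{self.kind[0]}{self.ordinal}"

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Mutation:
    """A database mutation: SNV (``C>T``), insertion (``ins:ACGT``) or
    deletion (``del:<length>``), at a 0-based position."""

    pos: int
    op: str
    gene_disrupting: bool

    @property
    def id(self) -> str:
        return f"{self.pos}:{self.op}"


@dataclass(frozen=True)
class StructuralConfig:
    """A structural arrangement of one gene copy, as a region-count vector.

    The special *deletion* configuration (``vector is None``) represents the
    absence of a gene copy on a chromosome; it contributes nothing to
    coverage and is never part of the copy-number fit, but lets whole-gene
    deletion alleles be reported uniformly in a diplotype.
    """

    id: str
    vector: tuple[int, ...] | None = None
    deletion: bool = False

    def __post_init__(self) -> None:
        if self.deletion:
            if self.vector is not None:
                raise SchemaError(f"config {self.id!r}: deletion configs carry no vector")
        else:
            if self.vector is None:
                raise SchemaError(f"config {self.id!r}: missing vector")
            if any(x < 0 for x in self.vector):
                raise SchemaError(f"config {self.id!r}: negative vector entry")
            if not any(self.vector):
                raise SchemaError(f"config {self.id!r}: all-zero vector")


@dataclass(frozen=True)
class MajorAllele:
    id: str
    config: str
    gdm: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MinorAllele:
    id: str
    major: str
    neutral: frozenset[str] = frozenset()


def _star_number(major_id: str) -> int | None:
    m = re.fullmatch(r"\*(\d+)", major_id)
    return int(m.group(1)) if m else None


def _letter_suffixes() -> Iterator[str]:
    """A, B, ..., Z, AA, AB, ... — minor-allele letter sequence."""
    alphabet = [chr(c) for c in range(ord("A"), ord("Z") + 1)]
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


@dataclass
class GeneDatabase:
    """A validated gene-cluster model for one gene and its pseudogene(s)."""

    gene: str
    units: list[str]  # gene first, then each pseudogene
    regions: list[RegionDef]  # canonical order: unit-major, ordinal asc, intron<exon
    mutations: dict[str, Mutation]
    configs: dict[str, StructuralConfig]
    majors: dict[str, MajorAllele]
    minors: dict[str, MinorAllele]
    cn_neutral: tuple[int, int]
    read_len: int = 100
    insert_size: int = 300
    identity_segments: list[tuple[int, int]] = field(default_factory=list)

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        """Regions per unit."""
        return len(self.regions) // len(self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def span(self) -> tuple[int, int]:
        """Coordinate span covered by all regions plus the cn-neutral span."""
        starts = [r.start for r in self.regions] + [self.cn_neutral[0]]
        ends = [r.end for r in self.regions] + [self.cn_neutral[1]]
        return min(starts), max(ends)

    def region_index(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(name)

    def region_at(self, pos: int) -> RegionDef | None:
        for r in self.regions:
            if r.contains(pos):
                return r
        return None

    def config_vector(self, config_id: str) -> np.ndarray:
        """Integer region-count vector of a configuration, canonical order."""
        try:
            cfg = self.configs[config_id]
        except KeyError:
            raise KeyError(f"unknown config {config_id!r}") from None
        if cfg.deletion:
            return np.zeros(len(self.regions), dtype=int)
        return np.asarray(cfg.vector, dtype=int)

    def coding_configs(self) -> list[str]:
        """Configs that contribute coverage (everything but deletion), i.e.
        the candidate set V of the copy-number fit."""
        return [c for c, cfg in self.configs.items() if not cfg.deletion]

    def gene_bearing_configs(self) -> list[str]:
        """Configs with at least one copy of a gene-unit region."""
        n = self.n
        out = []
        for c in self.coding_configs():
            if self.config_vector(c)[:n].any():
                out.append(c)
        return out

    # --------------------------------------------------------------- alleles
    def minors_of(self, major_id: str) -> list[MinorAllele]:
        if major_id not in self.majors:
            raise KeyError(f"unknown major {major_id!r}")
        return [m for m in self.minors.values() if m.major == major_id]

    def mut(self, minor_id: str) -> frozenset[str]:
        """mut(a): all mutations (gene-disrupting + neutral) of minor a."""
        a = self.minors[minor_id]
        return self.majors[a.major].gdm | a.neutral

    def deletion_majors(self) -> list[str]:
        return [
            m.id for m in self.majors.values() if self.configs[m.config].deletion
        ]

    # ---------------------------------------------------------------- naming
    def name_novel_major(self) -> str:
        """Star number for a newly discovered major allele.

        Historic numbering can be sparse, so instead of counting known
        majors the next number is the smallest integer above every numeric
        id already in use — collision-free by construction.
        """
        used = [_star_number(m) for m in self.majors]
        top = max((u for u in used if u is not None), default=0)
        return f"*{top + 1}"

    def name_novel_minor(self, major_id: str) -> str:
        """``major + X`` where X is the lexicographically smallest unused
        letter suffix (A..Z, then AA, AB, ...)."""
        if major_id not in self.majors:
            raise DanglingReferenceError(f"unknown major {major_id!r}")
        used = {m.id[len(major_id):] for m in self.minors_of(major_id)}
        for suffix in _letter_suffixes():
            if suffix not in used:
                return major_id + suffix
        raise AssertionError("unreachable")

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        """Check every structural invariant; raise on the first violation."""
        if not self.units:
            raise SchemaError("no gene units")
        if self.units[0] != self.gene:
            raise SchemaError("first unit must be the gene itself")
        n_total = len(self.regions)
        if n_total == 0 or n_total % len(self.units):
            raise SchemaError(
                f"{n_total} regions do not split evenly over {len(self.units)} units"
            )
        n = self.n
        for u in self.units:
            unit_regions = [r for r in self.regions if r.unit == u]
            if len(unit_regions) != n:
                raise SchemaError(f"unit {u!r} has {len(unit_regions)} regions, expected {n}")
            spans = sorted((r.start, r.end) for r in unit_regions)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise SchemaError(f"unit {u!r}: overlapping region spans")
            for r in unit_regions:
                if r.end <= r.start:
                    raise SchemaError(f"region {r.name}: empty span")
        # canonical order: unit-major, ordinal ascending, intron before exon
        expect = sorted(
            self.regions,
            key=lambda r: (self.units.index(r.unit), r.ordinal, r.kind != "intron"),
        )
        if [r.name for r in expect] != [r.name for r in self.regions]:
            raise SchemaError("regions are not in canonical order")

        for m in self.mutations.values():
            if self.region_at(m.pos) is None:
                raise SchemaError(f"mutation {m.id} lies outside every region span")

        want_len = n_total
        for cfg in self.configs.values():
            if not cfg.deletion and len(cfg.vector) != want_len:
                raise SchemaError(
                    f"config {cfg.id!r}: vector length {len(cfg.vector)} != {want_len}"
                )

        for a in self.majors.values():
            if a.config not in self.configs:
                raise DanglingReferenceError(f"major {a.id}: unknown config {a.config!r}")
            for mid in a.gdm:
                mut = self.mutations.get(mid)
                if mut is None:
                    raise DanglingReferenceError(f"major {a.id}: unknown mutation {mid!r}")
                if not mut.gene_disrupting:
                    raise SchemaError(f"major {a.id}: {mid} is neutral but listed in gdm")
        for a in self.minors.values():
            if a.major not in self.majors:
                raise DanglingReferenceError(f"minor {a.id}: unknown major {a.major!r}")
            for mid in a.neutral:
                mut = self.mutations.get(mid)
                if mut is None:
                    raise DanglingReferenceError(f"minor {a.id}: unknown mutation {mid!r}")
                if mut.gene_disrupting:
                    raise SchemaError(
                        f"minor {a.id}: {mid} is gene-disrupting but listed as neutral"
                    )
        for major_id in self.majors:
            if not self.minors_of(major_id):
                raise SchemaError(f"major {major_id} has no minor allele")
        s, e = self.cn_neutral
        if e <= s:
            raise SchemaError("empty cn-neutral span")

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "gene": self.gene,
            "pseudogenes": self.units[1:],
            "regions": {
                u: [
                    {"kind": r.kind, "ordinal": r.ordinal, "span": [r.start, r.end]}
                    for r in self.regions
                    if r.unit == u
                ]
                for u in self.units
            },
            "cn_neutral_region": list(self.cn_neutral),
            "read_model": {"read_length": self.read_len, "insert_size": self.insert_size},
            "identity_segments": [list(s) for s in self.identity_segments],
            "mutations": [
                {
                    "pos": m.pos,
                    "op": m.op,
                    "class": "gene_disrupting" if m.gene_disrupting else "neutral",
                }
                for m in self.mutations.values()
            ],
            "configs": {
                c.id: ({"deletion": True} if c.deletion else {"vector": list(c.vector)})
                for c in self.configs.values()
            },
            "majors": {
                a.id: {"config": a.config, "gdm": sorted(a.gdm)}
                for a in self.majors.values()
            },
            "minors": {
                a.id: {"major": a.major, "neutral": sorted(a.neutral)}
                for a in self.minors.values()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _require(data: Mapping, key: str, where: str):
    if key not in data:
        raise SchemaError(f"{where}: missing key {key!r}")
    return data[key]


def database_from_dict(data: Mapping) -> GeneDatabase:
    """Build and validate a :class:`GeneDatabase` from parsed YAML/JSON."""
    if not isinstance(data, Mapping):
        raise SchemaError("database root must be a mapping")
    version = data.get("schema")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {version!r}")
    gene = _require(data, "gene", "root")
    units = [gene] + list(data.get("pseudogenes", []))
    regions_raw = _require(data, "regions", "root")
    regions: list[RegionDef] = []
    for u in units:
        if u not in regions_raw:
            raise SchemaError(f"regions: missing unit {u!r}")
        unit_regions = []
        for rec in regions_raw[u]:
            kind = _require(rec, "kind", f"region of {u}")
            if kind not in ("intron", "exon"):
                raise SchemaError(f"region of {u}: bad kind {kind!r}")
            span = _require(rec, "span", f"region of {u}")
            unit_regions.append(
                RegionDef(u, kind, int(rec["ordinal"]), int(span[0]), int(span[1]))
            )
        unit_regions.sort(key=lambda r: (r.ordinal, r.kind != "intron"))
        regions.extend(unit_regions)

    mutations: dict[str, Mutation] = {}
    for rec in _require(data, "mutations", "root"):
        klass = _require(rec, "class", "mutation")
        if klass not in ("gene_disrupting", "neutral"):
            raise SchemaError(f"mutation {rec}: bad class {klass!r}")
        m = Mutation(int(rec["pos"]), str(rec["op"]), klass == "gene_disrupting")
        if m.id in mutations:
            raise SchemaError(f"duplicate mutation {m.id}")
        mutations[m.id] = m

    configs: dict[str, StructuralConfig] = {}
    for cid, rec in _require(data, "configs", "root").items():
        if rec.get("deletion"):
            configs[cid] = StructuralConfig(cid, deletion=True)
        else:
            vec = _require(rec, "vector", f"config {cid}")
            configs[cid] = StructuralConfig(cid, tuple(int(x) for x in vec))

    majors: dict[str, MajorAllele] = {}
    for aid, rec in _require(data, "majors", "root").items():
        majors[aid] = MajorAllele(
            aid, _require(rec, "config", f"major {aid}"), frozenset(rec.get("gdm", []))
        )
    minors: dict[str, MinorAllele] = {}
    for aid, rec in data.get("minors", {}).items():
        minors[aid] = MinorAllele(
            aid, _require(rec, "major", f"minor {aid}"), frozenset(rec.get("neutral", []))
        )
    # a bare major implicitly owns one minor with an empty neutral set
    for aid in majors:
        if not any(m.major == aid for m in minors.values()):
            implicit = aid + _IMPLICIT_MINOR_SUFFIX
            minors[implicit] = MinorAllele(implicit, aid)

    read_model = data.get("read_model", {})
    neutral_span = _require(data, "cn_neutral_region", "root")
    db = GeneDatabase(
        gene=gene,
        units=units,
        regions=regions,
        mutations=mutations,
        configs=configs,
        majors=majors,
        minors=minors,
        cn_neutral=(int(neutral_span[0]), int(neutral_span[1])),
        read_len=int(read_model.get("read_length", 100)),
        insert_size=int(read_model.get("insert_size", 300)),
        identity_segments=[
            (int(s[0]), int(s[1])) for s in data.get("identity_segments", [])
        ],
    )
    db.validate()
    return db


def load_database(path: str | Path) -> GeneDatabase:
    """Load and validate a gene database from a YAML (or JSON) file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise SchemaError(f"{path}: cannot parse: {exc}") from exc
    return database_from_dict(data)


def bundled_database(name: str) -> GeneDatabase:
    """Load one of the databases shipped with the package
    (``"toy"`` or ``"cyp2d6_demo"``)."""
    here = Path(__file__).parent / "data"
    return load_database(here / f"{name}.yml")
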