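"""Coverage normalization, masking, mutation copy numbers, detection
thresholds, the profile dialect, and SAM/BAM ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starallele.database import RegionDef
from starallele.profile import (
    EmptyInputError,
    RawPileup,
    build_profile,
    detect_mutations,
    ingest_alignments,
    mask_ambiguous,
    mutation_copy_number,
    normalize_coverage,
    read_profile,
    region_copy_number,
    write_profile,
)
from starallele.simulate import GenotypeSpec, make_reference, simulate_profile


def _flat(db, depth):
    size = db.span[1] - db.span[0]
    return RawPileup(start=db.span[0], depth=np.full(size, depth), read_len=100,
                     insert_size=300)


# ------------------------------------------------------------------ dialect

def test_profile_dialect_round_trip(toy_db, tmp_path):
    spec = GenotypeSpec(alleles=[("*2A", 1), ("*4C", 1)], depth=40, seed=2)
    raw, _ = simulate_profile(toy_db, spec)
    path = tmp_path / "sample.profile"
    write_profile(raw, path)
    back = read_profile(path)
    assert np.array_equal(back.depth, raw.depth)
    assert back.alts == raw.alts
    assert back.phase == raw.phase
    assert back.start == raw.start
    assert (back.read_len, back.insert_size) == (raw.read_len, raw.insert_size)


def test_empty_profile_rejected(tmp_path):
    path = tmp_path / "empty.profile"
    path.write_text("#meta\tstart=0\n")
    with pytest.raises(EmptyInputError):
        read_profile(path)


# ------------------------------------------------------------- normalization

def test_sample_equal_to_reference_normalizes_to_diploid(toy_db):
    raw = _flat(toy_db, 80)
    cn_s, mask = normalize_coverage(raw, raw, toy_db)
    assert np.allclose(cn_s[~mask], 2.0)


def test_doubled_gene_depth_reads_as_four_copies(toy_db):
    ref = _flat(toy_db, 80)
    sample = _flat(toy_db, 80)
    sample.depth[:600] *= 2  # the gene unit only
    cn_s, mask = normalize_coverage(sample, ref, toy_db)
    start = toy_db.span[0]
    assert np.allclose(cn_s[0:600], 4.0)
    assert np.allclose(cn_s[600 - start : 1200], 2.0)


def test_capture_bias_cancels_against_matched_reference(demo_db):
    """A 10-100x exon/intron depth swing shared between sample and
    reference leaves the normalized copy number flat at 2 (up to integer
    quantization of depths in the deepest bias troughs)."""
    spec = GenotypeSpec(alleles=[("*1A", 2)], depth=40, bias="capture",
                        seed=3, noise=False, error_rate=0)
    raw, _ = simulate_profile(demo_db, spec)
    ref = make_reference(demo_db, depth=25, bias="capture", seed=4, noise=False)
    cn_s, mask = normalize_coverage(raw, ref, demo_db)
    dev = np.abs(cn_s[~mask] - 2.0)
    assert np.mean(cn_s[~mask]) == pytest.approx(2.0, abs=0.02)
    assert np.percentile(dev, 99) < 0.15
    assert dev.max() < 0.35


def test_zero_coverage_neutral_span_raises(toy_db):
    sample = _flat(toy_db, 50)
    ref = _flat(toy_db, 50)
    ns, ne = toy_db.cn_neutral
    ref.depth[ns - toy_db.span[0] : ne - toy_db.span[0]] = 0
    with pytest.raises(Exception, match="neutral"):
        normalize_coverage(sample, ref, toy_db)


# ---------------------------------------------------------------- region cn

@pytest.mark.parametrize(
    "cn_s, masked, expected",
    [
        ([1.0, 2.0, 3.0], [False] * 3, 2.0),
        ([2.0, 2.0, 2.0, 2.0], [True, False, True, False], 2.0),
        ([2.0, 2.0, 4.0, 4.0], [False, False, True, True], 2.0),
    ],
)
def test_region_copy_number_is_mean_over_unmasked(cn_s, masked, expected):
    region = RegionDef("G", "exon", 1, 0, len(cn_s))
    value = region_copy_number(np.array(cn_s), region, np.array(masked), 0)
    assert value == pytest.approx(expected)


def test_fully_masked_region_is_flagged():
    region = RegionDef("G", "exon", 1, 0, 3)
    value = region_copy_number(np.ones(3), region, np.ones(3, bool), 0)
    assert np.isnan(value)


# ------------------------------------------------------------------- masking

def test_masking_threshold_boundary(toy_db):
    """Identity segments are masked iff longer than insert + 2*read_len."""
    thr = 300 + 2 * 100
    over = mask_ambiguous(toy_db, [(0, thr + 1)], insert_size=300, read_len=100)
    assert over[: thr + 1].all()
    at = mask_ambiguous(toy_db, [(0, thr)], insert_size=300, read_len=100)
    assert not at.any()


def test_demo_identity_stretch_masks_its_regions(demo_db, demo_ref):
    """The long identical stretch between exon 6 and exon 9 is masked in
    both units and its regions are excluded from the copy-number fit."""
    raw, _ = simulate_profile(
        demo_db, GenotypeSpec(alleles=[("*1A", 2)], depth=30, seed=0, noise=False)
    )
    prof = build_profile(demo_db, raw, demo_ref)
    flagged = {r.name for r, f in zip(demo_db.regions, prof.region_masked) if f}
    for unit in demo_db.units:
        for name in ("i7", "e7", "i8", "e8", "i9"):
            assert f"{unit}.{name}" in flagged
    assert len(flagged) == 10


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seg=st.integers(100, 1200),
    insert1=st.integers(100, 400),
    insert2=st.integers(0, 200),
    rl=st.integers(50, 150),
)
def test_masking_is_monotone_in_fragment_span(seg, insert1, insert2, rl):
    """Enlarging the insert size (or read length) never unmasks."""
    import starallele as sa

    db = sa.bundled_database("toy_gene")
    small = mask_ambiguous(db, [(0, seg)], insert_size=insert1, read_len=rl)
    large = mask_ambiguous(db, [(0, seg)], insert_size=insert1 + insert2, read_len=rl)
    assert not (large & ~small).any()


# -------------------------------------------------------------------- mutcn

@pytest.mark.parametrize(
    "depth, cn, alt, expected",
    [
        (100, 2.0, 50, 1.0),
        (100, 2.0, 100, 2.0),
        (120, 3.0, 41, 1.025),
        (100, 2.0, 300, 2.0),  # capped at the local copy number
    ],
)
def test_mutation_copy_number_arithmetic(toy_db, depth, cn, alt, expected):
    mut = toy_db.mutations["200:C>T"]
    raw = _flat(toy_db, depth)
    raw.alts[mut.id] = alt
    cn_s = np.full(raw.depth.shape, cn)
    assert mutation_copy_number(raw, cn_s, mut, toy_db.span[0]) == pytest.approx(expected)


def test_zero_depth_gives_zero_mutcn_with_warning(toy_db):
    mut = toy_db.mutations["200:C>T"]
    raw = _flat(toy_db, 0)
    warnings = []
    cn_s = np.full(raw.depth.shape, 2.0)
    assert mutation_copy_number(raw, cn_s, mut, toy_db.span[0], warnings) == 0.0
    assert warnings


def test_mutcn_invariant_under_depth_rescaling(toy_db):
    mut = toy_db.mutations["200:C>T"]
    cn_s = np.full(toy_db.span[1], 2.0)
    values = []
    for scale in (1, 3, 10):
        raw = _flat(toy_db, 60 * scale)
        raw.alts[mut.id] = 20 * scale
        values.append(mutation_copy_number(raw, cn_s, mut, 0))
    assert values[0] == pytest.approx(values[1]) == pytest.approx(values[2])


# ----------------------------------------------------------------- detection

def test_detection_thresholds(toy_db):
    raw = _flat(toy_db, 84)
    cn_s = np.full(raw.depth.shape, 2.0)
    raw.alts["200:C>T"] = 40  # mutcn = 40/42 ~ 0.95 -> detected
    raw.alts["500:G>A"] = 1   # below min_alt -> never detected
    M, neutral, mutcn = detect_mutations(raw, cn_s, toy_db, tau=0.5, min_alt=3)
    assert M == {"200:C>T"}
    assert mutcn["200:C>T"] == pytest.approx(40 / 42)
    assert "500:G>A" not in M


def test_detection_recall_and_specificity_on_simulations(demo_db, demo_ref):
    """Every simulated mutation present at >= 1 copy is detected at the
    study's per-copy depth of 30, with no false positives, across 200
    seeded binomial-noise samples."""
    want = demo_db.mut("*2A") | demo_db.mut("*4A")
    for seed in range(200):
        spec = GenotypeSpec(alleles=[("*2A", 1), ("*4A", 1)], depth=30, seed=seed)
        raw, _ = simulate_profile(demo_db, spec)
        prof = build_profile(demo_db, raw, demo_ref)
        detected = prof.M | prof.observed_neutral
        assert detected == want, f"seed {seed}: {detected ^ want}"


def test_no_false_positives_at_deep_coverage(demo_db, demo_ref):
    """At 60x per copy with 0.1% substitution error, exactly the defining
    mutations of the simulated alleles are detected over 50 seeds."""
    want = demo_db.mut("*2A")  # *1A contributes nothing
    for seed in range(50):
        spec = GenotypeSpec(alleles=[("*1A", 1), ("*2A", 1)], depth=60, seed=seed)
        raw, _ = simulate_profile(demo_db, spec)
        prof = build_profile(demo_db, raw, demo_ref)
        assert prof.M | prof.observed_neutral == want, f"seed {seed}"


# ----------------------------------------------------------------- alignment

def test_ingest_alignments_round_trip(toy_db, tmp_path):
    from starallele.simulate import write_sam

    spec = GenotypeSpec(alleles=[("*2A", 1), ("*4C", 1)], depth=40, seed=3)
    raw, _ = simulate_profile(toy_db, spec)
    sam = tmp_path / "sample.sam"
    write_sam(raw, toy_db, sam)
    back = ingest_alignments(sam, toy_db)
    assert np.abs(back.depth - raw.depth).max() <= 1
    # SNV, insertion and deletion alternate counts all recovered
    for mid, count in raw.alts.items():
        assert back.alts.get(mid, 0) == count, mid


def test_ingest_empty_alignments_errors(toy_db, tmp_path):
    import pysam

    sam = tmp_path / "empty.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 5000}]}
    with pysam.AlignmentFile(str(sam), "w", header=header):
        pass
    with pytest.raises(EmptyInputError):
        ingest_alignments(sam, toy_db)


def test_fragment_covering_two_alt_loci_increments_phase(toy_db, tmp_path):
    """Both mates of one fragment showing alternates at two loci count as
    one cis co-observation."""
    import pysam

    from starallele.simulate import reference_sequence

    refseq = reference_sequence(toy_db)
    sam = tmp_path / "pair.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 5000}]}
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        for i, (start, alt_at) in enumerate([(150, 200), (450, 500)]):
            a = pysam.AlignedSegment(out.header)
            a.query_name = "frag1"  # same fragment
            a.reference_id = 0
            a.reference_start = start
            a.flag = 0
            seq = list(refseq[start : start + 100])
            op = toy_db.mutations[f"{alt_at}:{'C>T' if alt_at == 200 else 'G>A'}"].op
            seq[alt_at - start] = op.split(">")[1]
            a.query_sequence = "".join(seq)
            a.cigartuples = [(0, 100)]
            a.mapping_quality = 60
            out.write(a)
    raw = ingest_alignments(sam, toy_db)
    assert raw.phase.get(((200, "C>T"), (500, "G>A"))) == 1
    assert raw.alts == {"200:C>T": 1, "500:G>A": 1}
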