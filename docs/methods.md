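# Methods

## Model overview

`starallele` decomposes a gene cluster — one gene plus *d* highly homologous
pseudogenes — into physical copies and assigns each copy a star-allele. The
locus model lives in a YAML database: each unit is segmented into the same
number *n* of intron/exon regions (canonical order: unit-major, ordinal
ascending, intron before its same-ordinal exon), every catalogued mutation
is classed gene-disrupting or neutral, and every plausible structural
arrangement of one copy (whole gene, whole pseudogene, fusion, gene
conversion, partial deletion/duplication) is a length-*n(d+1)* integer
vector **v** counting how many copies of each region the arrangement
contributes. Restricting copy-number fitting to catalogued vectors is
deliberate: breakpoints are only ever reported at database resolution, and a
sample with a genuinely novel breakpoint will be fit by the nearest
catalogued one.

Whole-gene deletion alleles are a special case: a deleted chromosome
contributes no coverage, so the deletion "configuration" has no vector and
never enters the fit. Instead the number of deletion alleles is derived as
max(0, 2 − gene-bearing copies), which keeps diplotype reports uniform
(e.g. `*4A / *5A` for a hemizygote) without distorting the optimization.

## Coverage normalization

Per-position copy number is cn_s(i) = 2·(d_sample(i)/d_ref(i))/c, where the
reference is a single copy-number-normal sample of the same sequencing
technology and c is the mean depth ratio over a copy-number-neutral span,
so that span averages exactly 2. Because capture bias is a property of the
technology, it appears in both numerator and denominator and cancels — the
reason one reference per technology suffices, and the property the
simulator's shared-bias-field design reproduces. Positions with zero
reference depth are masked. Region copy number **cn**[r] is the arithmetic
mean of cn_s over the region's unmasked positions; a fully-masked region is
flagged and contributes no term to the fit (a zero observation would bias
against pseudogene-identical segments).

Gene↔pseudogene identical segments longer than one fragment span, taken as
insert size + 2 × read length (default 300 + 200 = 500 bp), cannot be
resolved by paired short reads; all their positions are masked. Fusion
breakpoints falling inside such a segment are inherently
interval-ambiguous; masking them loses nothing.

## Mutation evidence

mutcn(m) = alt(m) / (depth(locus)/cn_s(locus)), capped at cn_s(locus);
position-level cn_s is used in the denominator. A mutation is *present*
when alt ≥ min_alt (default 3 reads — a floor below which 0.1%-class
sequencing error could mimic a call) and mutcn ≥ τ (default 0.5 copies —
halfway between absence and a single carrying copy). Note that with
position-level cn_s the locus depth cancels, so mutcn is effectively
alt/expected-per-copy-depth and its sampling noise is binomial-plus-Poisson
in the alt count alone; at per-copy depth ≲ 25 a heterozygous mutation sits
within ~2.5 σ of the τ threshold, which is why the recovery suites run at
per-copy depth 30.

Phasing evidence is collected per fragment: for every pair of catalogued
mutation loci co-covered by one fragment, the pair of observed alleles
(alternate or reference, strand collapsed) is counted. A major allele with
two defining mutations is *out of phase* when ≥ min_frags (default 5)
fragments co-cover the loci and fewer than γ (default 0.15) of them show
both alternates together; γ tolerates mapping noise while catching clear
trans configurations. The filter removes contradicted solutions after
enumeration; if that eliminates every co-optimum, the major stage is
re-solved with the out-of-phase alleles excluded so the best in-phase
explanation surfaces instead.

## The three integer programs

All three stages share one modeling substrate: |·| terms are linearized
with split variables, binary products with the standard w ≤ x, w ≤ y,
w ≥ x+y−1 triple, and *all* co-optimal integer assignments are enumerated —
by iterated integer no-good cuts (binary deviation indicators per key
variable) on the HiGHS backend, or a single sweep on the bundled exhaustive
backend (tolerance 10⁻⁶, cap 100 solutions). Because MILP solvers honor
integrality only to ~10⁻⁶, every reported objective is recomputed exactly
at the rounded integer point before bounds or comparisons use it.

**Copy number.** Minimize Σ_r |**cn**[r] − Σ_i z_i **v**_i[r]| over
z_i ∈ [0, max_cn]; among residual-optimal solutions keep those with minimal
Σ z_i (lexicographic two-stage solve, not a weighted sum), and report all
of them. max_cn defaults to 12 — known multiplications rarely exceed ~6
copies, margin ×2; the bound is flagged if active at an optimum.

**Major alleles.** Candidates are majors whose gene-disrupting mutations
were all detected and whose configuration has copies; the wild-type is
always eligible. Minimize Σ_{m∈M} |mutcn(m) − Σ_{carriers} p_i| subject to
(i) each detected gene-disrupting mutation carried at least once and
(ii) per-configuration linkage Σ_{config(a)=c} p_a = z_c — the strictest
reading of consistency with the copy-number stage, which makes copy totals
well-defined. Shared mutations are not apportioned a priori; the residual
handles sharing. Infeasibility means the sample carries an uncatalogued
major; the strict output is then empty and refinement proceeds on
scaffolds: first the same candidates with only the unsatisfiable presence
constraints dropped (so the orphan mutation must be *added* at cost η+β,
minting a novel major), and only if a configuration has no compatible
candidate at all are incompatible majors re-admitted.

**Refinement.** Each copy of each selected major is a slot; each slot picks
exactly one minor of its major (two copies may pick the same minor — a
`*1A/*1A` homozygote is one genotype, not two). Gene-disrupting members of
the chosen minor are unremovable; neutral members may be dropped at α = 2;
observed mutations absent from the minor may be added at β = 1, plus
η = 100 000 if gene-disrupting — η is paid only on the infeasible pathway,
so novel majors can arise only there (α > β reflects additions being
roughly twice as likely as omissions in practice). The residual term |F_m|
keeps each mutation's carrier count near mutcn(m) over the universe of
observed mutations plus all candidate minors' definitions. Sentinel
constraints cap each mutation's total occurrences at
max(1, round(mutcn(m)), forced-carrier count) — the last term prevents a
noisy mutcn from making a legitimate assignment infeasible — and every
observed gene-disrupting mutation must be carried at least once. Slot
assignments that edit their minor mint novel names: next letter (A…Z, AA…)
for minors, smallest integer above every existing numeric id for majors
(the literal "count + 1" convention assumes dense historical numbering and
would collide on sparse catalogues). Co-optimal refinements of *all*
upstream co-optima are pooled; the minimal-score genotypes are reported as
equally likely. A β-cost adoption and a |F| = 1 residual tie exactly and
are both reported, by design.

## Synthetic data

The generator emulates the study conditions end to end: depth(i) ~
Poisson(per-copy depth × bias(i) × local copy count) with per-copy depth 30
as the default recovery condition; alternate counts ~ Binomial(depth,
carrier fraction) with a 0.1% substitution error (Illumina-like; indel
errors omitted); phasing counts ~ Poisson per physical copy for locus pairs
within one fragment span, so cis/trans structure is faithful. Bias is
either uniform (WGS-like) or a smooth strongly non-uniform positive field
(capture-like, ~10–100× dynamic range) shared between sample and
technology-matched reference. Copies are composed exactly from database
configuration vectors, so fusion and partial-deletion genotypes produce
stepped region profiles with known integer decompositions; two whole
pseudogene copies are always present in the background. Trios transmit one
uniformly-chosen allele copy per parent. A SAM writer tiles single-end
reads to the depth profile exactly (alt alleles planted to match counts)
for exercising the alignment-ingestion path.

What the simulator does **not** emulate: read mis-mapping between the
homologous units (the pipeline masks the affected segments regardless, so
their exclusion is exercised but the *cause* is not), alignment artefacts
around indels, GC-dependent bias drift between sample and reference, and
contamination. Passing recovery suites therefore demonstrate the
combinatorial machinery and its noise tolerance, not robustness to every
real-data failure mode.

## Numerical and degenerate-input choices

Solver tolerance 10⁻⁶ everywhere; enumeration cap 100 (far beyond
biologically plausible ambiguity). HiGHS presolve occasionally errors on
deeply-cut enumeration models (a known quirk of the vendored solver); the
implementation retries without presolve and, failing that, falls back to
the exhaustive sweep. Zero-depth mutation loci get mutcn = 0 with a warning
record; masked loci likewise. An all-masked region set, an empty
configuration catalogue, or a coverage-free copy-number-neutral span are
hard errors. Indels are counted at exact CIGAR positions only — no
realignment; alignment inputs are expected to be indel-realigned upstream.

## Problem sizes in the test suite

The bundled suites run the full pipeline ~900 times: 500 noisy + 40
noiseless recovery samples over four structural classes at per-copy depth
30, 100 noiseless trios, 100 + 100 random optimizer-versus-enumeration
instances (≤ 6 configurations / ≤ 5 candidate alleles, copies ≤ 4), and
500 region-level copy-number recovery draws at noise σ = 0.1. These sizes
keep the whole suite around a minute on one CPU while leaving the
statistical margins of the recovery thresholds intact.

## Known limitations

Breakpoints only at database resolution; no statistical likelihood model
(the objectives are the combinatorial ones, so co-optimal genotypes are
genuinely indistinguishable to the method); symmetric multiplication/
deletion ambiguities (e.g. fusion+gene vs fusion/gene arrangements with
identical coverage and mutation content) collapse to a single report under
the derived deletion-count rule; mutations outside the database catalogue
are invisible; diploid assumptions (ploidy 2) are hard-wired into the
deletion-allele derivation.
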