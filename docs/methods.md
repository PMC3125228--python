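# Methods

## Coordinate system and reference

All positions are 1-based rCRS coordinates on a circular 16,569-bp
molecule. The control region (D-loop) wraps the origin and is stored as
two arcs, 16,024–16,569 and 1–576; "D-loop" and "control region" are used
as synonyms with these boundaries. Overlapping genes (ATP8/ATP6,
ND4L/ND4, boundary tRNAs) are all reported by position lookup; the single
region label used for tabulation resolves overlaps with the fixed priority
protein > rRNA > tRNA > control > non-coding. The ~85 intergenic spacer
positions of the standard annotation carry the fifth label, "non-coding",
so that the per-position label is total and the label counts partition all
16,569 positions.

The bundled reference (`data/rcrs_synthetic.fasta`) is **synthetic**: it
reproduces the rCRS length, the standard gene coordinate table, an ATG
initiator and stop-free open reading frames for all 13 protein genes
(including the light-strand ND6 frame and the overlapping-frame regions),
and the two canonical control-region poly-C tracts (303–315 with T at 310;
16,184–16,193 with T at 16,189). A small set of positions used throughout
the documentation is anchored so that their codon-level behaviour is
stable: 4532 and 9275 are third codon positions (transitions there are
synonymous under the mitochondrial code), 6718, 15447, 15276 and the
light-strand site 14288 are second positions (always nonsynonymous), and
15332 is a first position. Everything else is drawn from a seeded RNG
with an mtDNA-like base composition
(`scripts/make_reference_fixture.py` regenerates it bit-identically). The
synthetic reference supports every structural property the pipeline
depends on — coordinates, frames, strand orientation, homopolymer context
— but not the literal human sequence; analyses of real genomes should load
the true rCRS FASTA via `load_reference`.

Protein genes whose length is not divisible by 3 (ND1, ND2, CO3, ND3,
ND4, CYB) end in a partial codon completed by polyadenylation in vivo;
the trailing positions are tracked, and substitutions there receive the
explicit effect label `incomplete-codon` rather than a codon-level
verdict.

## Variant scoring

Samples are rCRS-registered complete genomes (length within ±50 of
16,569). Alignment is optimal unit-cost global (Needleman–Wunsch)
alignment via edlib; at ≥ 95% identity — enforced as a guard against
mislabelled input — the per-position pairing is exact. Two-base IUPAC
codes expand to heteroplasmic allele pairs; three/four-base codes are
flagged unresolvable and excluded from downstream counts. Single-base
indels inside homopolymer runs are normalised to the 3'-most position
before the exclusion filter, which removes length variation (insertions
and deletions, not substitutions) inside the windows 303–315 and
16,180–16,195 — the conventional treatment of the two unstable C-tracts.

Nomenclature follows the compact field dialect: bare position for a
transition from the reference base (`16189`), position + base for other
substitutions (`16093A`; ref-prefixed `G4532A` accepted on input),
`pos X/Y` with alphabetical alleles for heteroplasmy, `d` for a deletion,
`315+C` (or `315insC`) for an insertion. `format` and `parse` are mutual
inverses on canonical strings.

Heteroplasmy detection emulates direct Sanger consensus reading: the
simulator writes an ambiguity code only when the minor allele fraction
reaches the detection threshold (default 0.20), and the caller treats any
two-base code as a binary heteroplasmic state. No allele-fraction
quantification is attempted — consensus sequences carry none.

## Haplogroup assignment and quality control

The haplogroup tree is a rooted motif phylogeny: each node lists the
variants its branch gains (trailing `!` marks a back mutation restoring
the reference base). A profile is scored against every node by the
Kulczynski mean, `(matched/|path| + matched/|profile|)/2`, chosen over raw
overlap because tissue profiles may carry few variants; ties go to the
deeper node, then the lexicographically smaller name. Private variants —
profile variants unexplained by the chosen path — are where all somatic
candidates live, mirroring the expectation that somatic mutations occur
only on terminal branches.

Two phylogeny-based QC checks gate the somatic caller. *Haplotype shift*:
tissues of one patient assigned to different haplogroups indicate sample
mix-up; somatic calling is refused for that patient (other patients are
unaffected). *Artificial recombination*: a profile whose private set
jointly reproduces ≥ k variants (default 3) covering ≥ 60% of a foreign
haplogroup's motif is flagged as chimeric/contaminated. Both thresholds
are configurable; the defaults are the package's own choice, since the QC
concept is conventionally described without parameters.

The bundled mini-phylotree (24 named East-Asian-style haplogroups) is a
test fixture with synthetic motifs in this package's coordinate space; it
makes no claim of fidelity to any published phylogeny version, and real
motif trees in the same tabular format can be substituted.

## Somatic calling and patterns

A somatic mutation is any position where the allele states of a patient's
available tissues (2 or 3; one patient may lack CP) are not all identical
— including a homoplasmic base in one tissue versus a heteroplasmic pair
in another, even when the homoplasmic base belongs to the pair. The
germline state at a discordant site is the modal *homoplasmic* state
(heteroplasmy is treated as derived; ties break toward CN, then CP, then
the reference base). This rule is forced by the observed data pattern in
which the cancerous tissue is homoplasmic-reference while both normal
tissues are heteroplasmic: the majority state there is heteroplasmic, yet
the deviating tissues are the normals. Tissues deviating from the
germline define the pattern (cancer-only, cancer+para — flagged as
possible invasion of the para-cancerous tissue by cancer cells —
normal-only, all-normal-tissues, para-only, other). Directionality of
homoplasmic↔heteroplasmic shifts is recorded but not interpreted.

Cohort tabulation counts a patient as carrying cancer-tissue somatic
mutation(s) when any mutation's pattern is cancer-only or cancer+para.
Effects are reported both as events and as distinct sites, since
recurrent sites make the two differ.

## Statistics

Carrier comparisons are 2×2 tables at the individual level. The default
test is the Pearson χ² without continuity correction (p from χ²₁); Yates
and two-sided Fisher variants are computed side by side because small
published cohorts are analysed under different conventions and the choice
is rarely stated. Degenerate tables (no carriers anywhere, or carriers
everywhere) return p = 1 by convention. The test-suite oracle is an
independent conditional permutation null (fixed margins ⇒ hypergeometric)
with the mid-p convention for the observed table's point mass; agreement
with the asymptotic Pearson p is asserted within 3 Monte-Carlo standard
errors plus a 0.02 allowance for the χ² approximation itself plus the
null's own discreteness resolution at the observed table — a discrete and
a continuous p cannot agree below that granularity, which dominates for
near-null tables.

The three-group heteroplasmy comparison (general population / patient
normal tissues / patient cancerous tissues) takes a carriers/total count
table as input; the bundled table is synthetic, with totals chosen to
produce carrier frequencies of 3.2%, 38.6% and 52.9%.

## The simulator

`SimulationConfig` defaults encode the emulated study design: 20
patients; each patient affected (≥ 1 somatic mutation in the cancerous
tissue) with probability 0.30; affected patients draw 1–3 events; an
unaffected patient carries a single normal-tissue event with probability
0.15 (normal tissues of cancer patients do mutate); pattern weights
cancer-only 0.5, cancer+para 0.2, normal-only 0.15, all-normal-tissues
0.15, with the first event of an affected patient forced to a cancer
pattern; somatic sites drawn with control : coding region weights 7 : 11,
uniformly within the region class, avoiding motif sites, germline sites
and the excluded C-tract windows; every event heteroplasmic with minor
fraction uniform on 0.25–0.50 (a stand-in — per-event fractions are not
observable from consensus Sanger data) against a detection threshold of
0.20; germlines are uniform tree leaves plus 1–3 private homoplasmic
transitions; exactly `round(n_patients/20)` patients lack the CP sample,
so a default cohort emits 59 genomes. Randomness flows from one seed
through per-patient substreams (stable under changes of `n_patients`);
identical configs give byte-identical FASTA and truth files.

Artifacts are opt-in: a sample swap exchanges one tissue between two
patients of different haplogroups (and must subsequently trip the
haplotype-shift QC), and a phantom mutation adds a spurious homoplasmic
variant to a single tissue, where it surfaces as a homoplasmic
cancer-only-style call distinguishable from the all-heteroplasmic truth.

`study_profile_cohort()` is a deterministic reconstruction of the study
design's outcome: 18 fixed heteroplasmic events (7 control-region, 11
coding; 2 synonymous at 4532/9275; 9 nonsynonymous events over 5 sites
with 14288 in three patients of three haplogroups; normal-tissue
mutations confined to patients 1, 3, 8, 14 and 20; patient 19 lacking
CP). The event table is hard-wired, but the emitted objects are raw
genome sequences — the pipeline must re-derive the profile from them.

What the simulator does *not* model: read- or chromatogram-level noise,
quality scores, allele-fraction dynamics across cell divisions, selection,
real mutational spectra (events are transitions at uniform positions),
and rotated/partial input genomes. Passing recovery tests therefore
demonstrates the correctness of the comparison and QC logic under the
design's statistical structure, not robustness to raw-data pathologies.

## Problem sizes and numerical choices

The test suite profiles one 59-genome cohort for the headline tabulation,
20 simulated cohorts for end-to-end recovery, 100 six-patient cohorts for
swap detection, and 200 cohorts for calibration of the affected fraction
(asserted within the binomial 99% half-width of 0.30); the acceptance
script uses 20 / 50 / 100 cohorts for the same three measurements. The
effect-annotation oracle translates whole mutated genes and diffs protein
strings at 500 random coding positions × 3 alternate bases, with ND6
coverage forced. Alignment identity uses IUPAC-aware matching; the
alignment band is implicit in edlib's optimal algorithm. All RNG use is
numpy `default_rng` seeded explicitly; hypothesis tests run derandomised.
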