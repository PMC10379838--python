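# Methods

## Coordinate model

Marker positions are 1-based coordinates in a named gene frame (e.g.
position 1035 of the COI frame), not segment-relative indices: field usage
names SNPs by gene position, and amplicon boundaries move with primer
choice. A `ReferenceSegment` carries its sequence plus the gene-frame
offset of its first base, so position p maps to string index `p − offset`.
Re-anchoring (shifting offset and sequence window together) leaves every
gene-frame lookup unchanged, and the test suite holds that invariant.

Specimen reads are treated as co-linear with their reference except inside
a declared indel window. Mapping is an exhaustive scan over integer shifts
in ±30 (IUPAC-compatible base pairs count as matches), choosing fewest
mismatches with ties broken toward the smaller absolute shift; full gapped
alignment is deliberately avoided because Sanger amplicons from fixed
primers have no structural variation other than the known intron indel,
and a shift scan is auditable in a way an affine-gap aligner is not. A
read is unmappable when no shift fits at ≤ 30% mismatches; if an indel
window is declared, the read is then split at the window and a downstream
region fitting at a nearby different shift marks `indel_suspected`, with
the downstream shift reported (a deletion of k bases in the read appears
as `downstream_shift = shift − k`).

## SNP discovery and haplotype calls

A position becomes a candidate SNP when at least two distinct unambiguous
bases are observed across specimens. Frequencies are per specimen
*carrying* an allele, pooled across all collections: a heterozygous male
(two phased alleles, or one direct read with a two-base IUPAC code)
contributes one specimen to both alleles' tallies. Positions observed in
only one specimen are flagged singletons and are never selectable as
marker sites regardless of threshold — rare private variants are treated
as noise, not markers. Selection keeps sites with minor frequency
*strictly greater than* the threshold (default 0.10), so a site at exactly
10% is excluded; the boundary behavior is documented and tested rather
than left to floating-point accident.

A COI haplotype call reads the base at each selected site through the
position map. Any IUPAC ambiguity at a marker site invalidates the whole
segment call (`unresolved_ambiguity`) rather than producing a partial
haplotype: the mitochondrion is haploid, so a mixed peak is an unreadable
trace, not a genotype (heteroplasmy is not modeled). Reads dropping a
site or failing to map give `missing`. Labels are canonicalized as
`<base><position>` joined by `/` in position order. Mitochondrial reads
with ambiguity at more than 20% of positions are rejected as unreadable at
ingestion, with a QC flag on the record.

## i65del genotyping

The intron deletion is scored from three read classes. A clean single read
(≥ 95% exact identity, ambiguity counting as mismatch) matching the
deleted reference is `del`; matching the full-length reference, `plus`. A
single read matching neither is tested for the heterozygous-indel
signature: clean exact identity upstream of the deletion window against
the full-length reference, then a run of ≥ 20 bases from the window start
in which ≥ 50% of positions are ambiguous or mismatched while ≥ 80%
remain IUPAC-compatible with the superposition of the full-length frame
and the frame shifted by the deletion length. That is precisely the
chromatogram a het male produces under direct sequencing. Reads failing
all three classes are `unknown` and excluded from frequency denominators.
The 50%/20-base run thresholds are this package's own operating points —
the artifact is qualitative in origin — and were chosen so that a random
intron sequence (¾ expected frame disagreement) clears the run criterion
with large margin while a clean allele cannot.

Per-specimen i65del frequency weights hets 0.5 by default (`half_weight`),
which under Hardy–Weinberg with two Z draws for males and one for females
is an unbiased estimator of the chromosome-level allele frequency; the
`carrier` mode (het weight 1) is available because per-specimen scoring of
het males is genuinely ambiguous when sex is unknown for many trapped
specimens. Both modes agree whenever no hets are present, in which case
per-specimen equals per-chromosome frequency exactly.

## Statistics

`M = (A − B)/(A + B)` over the two predominant haplotype counts of a
group; undefined (an error, never an imputed value) when both counts are
zero, and groups with A + B = 0 are dropped from M-based tests with a
warning. The unit of regional analysis is the collection-level M grouped
by state × year, with Puerto Rico excluded from the regional schemes by
default; the two schemes map states to East/West of the Appalachians and
to Gulf-bordering South vs migratory North. Regional comparisons use the
unpaired two-tailed t-test, defaulting to the classic pooled-variance
variant (integer df = n₁ + n₂ − 2, the convention of the Prism-style
workflows this field uses); Welch is a flag away. Chi-square tests counts
against a uniform expectation with df = k − 1. One-way ANOVA reports F,
(k−1, N−k) df, p and r² = SS_between/SS_total, and raises on zero
within-group variance rather than returning an infinite F. Tukey HSD uses
the studentized-range distribution (Tukey–Kramer for unequal n) and
renders a compact letter display by the insert-and-absorb algorithm,
letters assigned in order of decreasing group mean. p-values are reported
to 4 decimals; no multiple-testing correction is applied beyond Tukey.

Every closed-form test is verified in the suite against an independent
textbook-formula oracle (and the t-test additionally against a permutation
test) to 1e-8 on randomized instances.

## Founder-effect simulator

A founder event is a single multinomial draw of `n_founders` individuals
from the source haplotype frequencies, followed by frequency-exact
expansion: the founder draw is the only drift stage, which isolates the
bottleneck argument and gives the closed-form check

    Var(p̂) ≈ p(1 − p)(1/n_founders + 1/n_sampled)

(the exact two-stage variance is smaller by p(1−p)/(n_founders·n_sampled),
negligible at the sizes used). Optional Wright–Fisher expansion adds
per-generation binomial resampling at population size N and converges to
the exact-frequency mode as N → ∞. Both stages are unbiased, so expected
destination frequencies equal source frequencies at every founder size.

Destinations can each take an independent founder event (the default) or
share `n_waves` migrant waves, each wave one founder event inherited by
its destinations. The distinction matters statistically: independent
events inflate the between-collection variance of M without moving the
regional mean, so a mean-comparing t-test retains only its nominal
rejection rate, whereas a shared wave shifts a whole region's proportions
as a block — the situation a seasonal migration composed of a few small
groups actually produces, and the one in which a regional comparison has
power. The power analysis therefore models the north side as `n_waves = 1`
by default and reports, per founder size, the rejection rate at alpha and
the sd of destination M.

The Z-linked i65del allele passes through the same bottleneck as a
binomial draw over `round(1.5 × n_founders)` chromosomes (an even sex
ratio gives 1.5 Z per individual on average); this is the package's own
minimal extension of the haplotype-vector bottleneck to a sex-linked
locus.

## Synthetic cohorts

The generator writes per-specimen FASTA (headers `specimen|segment|
allele`) plus a per-specimen metadata CSV and a ground-truth CSV. Marker
bases are implanted on bundled ~140–570 bp synthetic reference segments
that carry the published marker coordinates; the defaults are calibrated
to the observed study conditions: COI haplotype frequencies
(0.68, 0.27, 0.04, 0.01) for (C1035/T1272, T1035/C1272, T1035/T1272,
C1035/C1272) — consistent with a ~67%/68% major-allele split at the two
sites and a rare-class ratio of about 3 — an i65del allele frequency of
0.16 (0.10 southern, 0.32 northern in the regional scenarios), Tpi exon
minor frequencies of 0.03–0.10, and a singleton noise rate of 5e-5 per
site per specimen (the observed rare-variant load is a handful of carriers
per ~180 kb scored). Males draw two Z alleles and are emitted as a single
direct-read IUPAC merge (phased output is an option); females draw one.
Singleton noise is placed only at non-marker positions so that marker
recovery stays exact while the singleton-handling logic is exercised.

What the generator does **not** emulate: chromatogram quality gradients
and basecalling error (noise is uniform substitution), primer failure and
partial reads, heteroplasmy, NUMT co-amplification, selection, sex-ratio
bias in traps, and any geographic structure beyond the two-region design.
Passing tests therefore demonstrate the pipeline's correctness on the
modeled data-generating process, not robustness to every field artifact.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
500-specimen cohorts for recovery checks, 2,000 replicates for type-I
calibration, 40,000 replicates for the variance law, and 100 batches of
60,000 replicates for the founder-size monotonicity of sd(M) — the last
size chosen so the 500-vs-5000 founder contrast (a ~1% sd difference) is
resolved with comfortable margin. All randomness flows from
`numpy.random.default_rng` seeded explicitly; identical config and seed
reproduce every artifact byte for byte (no timestamps are written), and
the CLI stamps each CSV with the tool version, a config hash and the seed.

## Known limitations

Reference-free discovery is out of scope: SNPs are called against a
reference segment, so variants inside primer sites or outside the
reference span are invisible. The het-indel caller assumes a single known
indel window per segment; nested or multiple intron indels would need a
more general model. M carries no per-collection confidence interval —
comparisons are made at the collection level, matching the field workflow,
rather than by count-aware modeling. The simulator's founder stage is a
single bottleneck; real migrations may compound several.
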