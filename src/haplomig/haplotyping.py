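"""SNP discovery, haplotype classification, and Tpi genotyping.

The mitochondrial COI marker is haploid and maternally inherited, so each
specimen carries a single haplotype: the combination of bases at the
selected marker SNPs (e.g. C1035/T1272). Marker SNPs are the polymorphic
positions whose minor-variant frequency, pooled across all collections,
exceeds a threshold (default 10%); singletons — variants seen in exactly
one specimen — are treated as noise and are never selectable.

Tpi is Z-linked: ZZ males carry two copies and can be heterozygous, ZW
females one. Direct sequencing of a heterozygous male superimposes both
alleles, producing IUPAC ambiguity codes at mismatched positions. A
heterozygous *indel* is worse: it shifts the reading frames of the two
alleles against each other, so everything downstream of the indel reads as
a sustained run of mixed calls. The i65del caller exploits exactly that
artifact to genotype a 7-bp intron deletion from single direct reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._iupac import MASK_TO_CODE, POPCOUNT_LUT, to_mask_array
from .errors import DataQualityError, UnmappableSequenceError, ValidationError
from .io import (I65_DEL_LENGTH, I65_WINDOW, PositionMap, ReferenceSegment,
                 SpecimenRecord, map_to_reference)

_BASE_BITS = [("A", 1), ("C", 2), ("G", 4), ("T", 8)]


@dataclass(frozen=True)
class SNPSite:
    """A polymorphic position in gene-frame coordinates.

    ``minor_frequency`` is the fraction of scored specimens *carrying* the
    minor allele: a heterozygous male carries both alleles and contributes
    one specimen to the minor tally (per-specimen, not per-chromosome).
    """

    position: int
    major: str
    minor: str
    minor_frequency: float
    n_scored: int
    singleton: bool

    @property
    def alleles(self) -> tuple[str, str]:
        return self.major, self.minor


@dataclass(frozen=True)
class HaplotypeCall:
    specimen_id: str
    segment: str
    site_calls: tuple[str, ...]
    status: str  # resolved | unresolved_ambiguity | missing
    label: str | None = None

    def __post_init__(self):
        if (self.label is not None) != (self.status == "resolved"):
            raise ValidationError("label defined iff status is resolved")


def haplotype_label(calls: dict[int, str]) -> str:
    """Canonical label: '<base><position>/...' sorted by position."""
    return "/".join(f"{b}{p}" for p, b in sorted(calls.items()))


@dataclass
class TpiGenotype:
    """Per-specimen Z-linked genotype: exon site calls plus i65 indel status.

    Exon calls are a base (hemizygous/homozygous) or a frozenset pair
    (heterozygous male); ``i65_status`` is del / plus / het / unknown.
    """

    specimen_id: str
    exon_calls: dict[int, object] = field(default_factory=dict)
    i65_status: str = "unknown"
    sex: str = "unknown"

    def __post_init__(self):
        if self.i65_status not in {"del", "plus", "het", "unknown"}:
            raise ValidationError(f"bad i65 status {self.i65_status!r}")
        if self.sex == "Z_hemizygous_female":
            if self.i65_status == "het" or any(
                    isinstance(c, frozenset) for c in self.exon_calls.values()):
                raise ValidationError(
                    f"{self.specimen_id}: heterozygous call for a hemizygous "
                    "female")


# ---------------------------------------------------------------------------
# SNP discovery

def _aligned_mask_row(seq: str, ref: ReferenceSegment, pmap: PositionMap,
                      ) -> np.ndarray:
    """Read masks placed onto reference indices; 0 where uncovered.

    For indel-suspected reads only the upstream (pre-window) frame is
    trusted; the mixed downstream region is left unscored.
    """
    row = np.zeros(len(ref.sequence), dtype=np.uint8)
    read_m = to_mask_array(seq)
    lo = max(0, -pmap.shift)
    hi = min(len(ref.sequence), len(read_m) - pmap.shift)
    if pmap.indel_suspected:
        hi = min(hi, lo)  # conservatively unscored; callers handle indels
    if hi > lo:
        row[lo:hi] = read_m[lo + pmap.shift:hi + pmap.shift]
    return row


def discover_snps(specimens: list[SpecimenRecord], segment: str,
                  ref: ReferenceSegment, max_shift: int = 30,
                  ) -> list[SNPSite]:
    """Tally every position with >=2 distinct unambiguous bases observed.

    Each specimen contributes one row; a phased two-allele male contributes
    the union of its alleles (so a het counts once, as a carrier of both).
    Unmappable reads are skipped with a warning; zero mappable reads is an
    error. Order of specimens never affects the result.
    """
    rows = []
    skipped = 0
    for rec in sorted(specimens, key=lambda r: r.specimen_id):
        alleles = rec.sequence(segment)
        if not alleles:
            continue
        union = np.zeros(len(ref.sequence), dtype=np.uint8)
        ok = False
        for seq in alleles:
            try:
                pmap = map_to_reference(seq, ref, max_shift=max_shift)
            except (UnmappableSequenceError, ValidationError):
                continue
            union |= _aligned_mask_row(seq, ref, pmap)
            ok = True
        if ok:
            rows.append(union)
        else:
            skipped += 1
    if not rows:
        raise DataQualityError(
            f"no mappable specimens for segment {segment!r}")
    if skipped:
        warnings.warn(f"{segment}: skipped {skipped} unmappable specimens")
    mat = np.vstack(rows)

    pop = POPCOUNT_LUT[mat]
    scored = (pop == 1) | (pop == 2)
    sites: list[SNPSite] = []
    for col in range(mat.shape[1]):
        masks = mat[:, col]
        sc = scored[:, col]
        n_scored = int(sc.sum())
        if n_scored == 0:
            continue
        # site definition uses unambiguous observations only
        distinct = [b for b, bit in _BASE_BITS
                    if np.any((masks == bit))]
        if len(distinct) < 2:
            continue
        carriers = {b: int(np.count_nonzero(((masks & bit) > 0) & sc))
                    for b, bit in _BASE_BITS}
        top = sorted(carriers, key=lambda b: (-carriers[b], b))
        major, minor = top[0], top[1]
        if carriers[minor] == 0:
            continue
        sites.append(SNPSite(
            position=ref.offset + col, major=major, minor=minor,
            minor_frequency=carriers[minor] / n_scored,
            n_scored=n_scored, singleton=carriers[minor] == 1))
    return sites


def select_marker_sites(sites: list[SNPSite],
                        threshold: float = 0.10) -> list[SNPSite]:
    """Keep sites with minor frequency strictly above ``threshold``.

    Singletons are never selectable regardless of threshold; position order
    is preserved.
    """
    if not 0 < threshold <= 0.5:
        raise ValidationError(f"threshold must be in (0, 0.5], got {threshold}")
    return [s for s in sites
            if not s.singleton and s.minor_frequency > threshold]


# ---------------------------------------------------------------------------
# haplotype calling

def call_haplotype(specimen: SpecimenRecord, segment: str,
                   sites: list[SNPSite], ref: ReferenceSegment,
                   ) -> HaplotypeCall:
    """Read the base at each marker site and label the haplotype.

    Any IUPAC ambiguity at a marker site invalidates the whole segment call
    (mitochondrial templates are haploid; a mixed peak means an unreadable
    trace, not a genotype). Sites outside the read's span give ``missing``.
    """
    if not sites:
        raise ValidationError("no marker sites supplied")
    alleles = specimen.sequence(segment)
    if len(alleles) != 1:
        return HaplotypeCall(specimen.specimen_id, segment, (), "missing")
    seq = alleles[0]
    try:
        pmap = map_to_reference(seq, ref)
    except (UnmappableSequenceError, ValidationError):
        return HaplotypeCall(specimen.specimen_id, segment, (), "missing")

    calls: dict[int, str] = {}
    bases: list[str] = []
    for site in sites:
        ref_i = ref.index(site.position)
        read_i = pmap.read_index(ref_i)
        if not 0 <= read_i < len(seq):
            return HaplotypeCall(specimen.specimen_id, segment, (), "missing")
        base = seq[read_i]
        bases.append(base)
        if base not in "ACGT":
            return HaplotypeCall(specimen.specimen_id, segment,
                                 tuple(bases), "unresolved_ambiguity")
        calls[site.position] = base
    return HaplotypeCall(specimen.specimen_id, segment, tuple(bases),
                         "resolved", haplotype_label(calls))


# ---------------------------------------------------------------------------
# Tpi genotyping

def _exact_identity(seq: str, ref: ReferenceSegment,
                    ref_lo: int = 0, ref_hi: int | None = None,
                    shift: int = 0) -> tuple[int, int]:
    """(exact mismatches, overlap) — ambiguity codes count as mismatches."""
    ref_hi = len(ref.sequence) if ref_hi is None else ref_hi
    lo = max(0, ref_lo + shift)
    hi = min(len(seq), ref_hi + shift)
    if hi <= lo:
        return 0, 0
    mism = sum(seq[i] != ref.sequence[i - shift] for i in range(lo, hi))
    return mism, hi - lo


def _classify_i65_allele(seq: str, ref_plus: ReferenceSegment,
                         ref_del: ReferenceSegment,
                         clean_tol: float = 0.05) -> str | None:
    """del / plus for a clean single-allele read, None if neither fits."""
    fracs = {}
    for status, ref in (("plus", ref_plus), ("del", ref_del)):
        try:
            pmap = map_to_reference(seq, ref)
        except (UnmappableSequenceError, ValidationError):
            fracs[status] = 1.0
            continue
        mism, ov = _exact_identity(seq, ref, shift=pmap.shift)
        fracs[status] = mism / ov if ov else 1.0
    best = min(fracs, key=lambda k: (fracs[k], k))
    return best if fracs[best] <= clean_tol else None


def _het_indel_signature(seq: str, ref_plus: ReferenceSegment,
                         window: tuple[int, int], del_length: int,
                         clean_tol: float, run_length: int,
                         run_fraction: float) -> bool:
    """Detect the direct-read artifact of a heterozygous deletion.

    Upstream of the indel window the read must match the full-length
    reference cleanly; from the window start a sustained run of ambiguous or
    mismatched positions must follow, while remaining IUPAC-compatible with
    the superposition of the full-length frame and the frame shifted by the
    deletion length. That is the chromatogram signature of two alleles whose
    frames diverge at the deletion.
    """
    try:
        pmap = map_to_reference(seq, ref_plus, indel_window=window)
    except (UnmappableSequenceError, ValidationError):
        return False
    w_start = ref_plus.index(window[0])
    up_mism, up_ov = _exact_identity(seq, ref_plus, ref_hi=w_start,
                                     shift=pmap.shift)
    if up_ov < 10 or up_mism / up_ov > clean_tol:
        return False

    read_start = pmap.read_index(w_start)
    run = seq[read_start:read_start + run_length]
    if len(run) < min(run_length, 10):
        return False
    masks = to_mask_array(run)
    ref_m = to_mask_array(ref_plus.sequence)
    n = len(run)
    plus_frame = ref_m[w_start:w_start + n]
    shifted = ref_m[w_start + del_length:w_start + del_length + n]
    if len(plus_frame) < n or len(shifted) < n:
        n = min(len(plus_frame), len(shifted))
        masks, plus_frame, shifted = masks[:n], plus_frame[:n], shifted[:n]
        if n < 10:
            return False
    ambiguous = POPCOUNT_LUT[masks] >= 2
    mismatch = (masks & plus_frame) == 0
    disrupted = float(np.mean(ambiguous | mismatch))
    superpos = (masks & (plus_frame | shifted)) != 0
    return disrupted >= run_fraction and float(np.mean(superpos)) >= 0.8


def call_tpi(specimen: SpecimenRecord, exon_sites: list[SNPSite],
             refs: dict[str, ReferenceSegment],
             i65_window: tuple[int, int] = I65_WINDOW,
             del_length: int = I65_DEL_LENGTH,
             exon_segment: str = "sTpiE", intron_segment: str = "sTpi140",
             clean_tol: float = 0.05, het_run_length: int = 20,
             het_run_fraction: float = 0.5) -> TpiGenotype:
    """Genotype the Tpi exon SNPs and the i65 intron indel for one specimen.

    Phased two-allele input (ZZ male) is genotyped per allele and combined;
    a single direct-read string is decoded via IUPAC codes (exon
    heterozygotes) and the het-indel frame-shift signature (i65 het).
    """
    exon_calls: dict[int, object] = {}
    exon_alleles = specimen.sequence(exon_segment)
    if len(exon_alleles) > 2:
        raise ValidationError(f"{specimen.specimen_id}: >2 Tpi sequences")
    if exon_alleles and exon_sites:
        ref = refs[exon_segment]
        per_allele: list[dict[int, str]] = []
        for seq in exon_alleles:
            try:
                pmap = map_to_reference(seq, ref)
            except (UnmappableSequenceError, ValidationError):
                continue
            calls = {}
            for site in exon_sites:
                read_i = pmap.read_index(ref.index(site.position))
                if 0 <= read_i < len(seq):
                    calls[site.position] = seq[read_i]
            per_allele.append(calls)
        if len(per_allele) == 2:  # phased male
            for site in exon_sites:
                a = per_allele[0].get(site.position)
                b = per_allele[1].get(site.position)
                if a in set("ACGT") and b in set("ACGT"):
                    exon_calls[site.position] = (a if a == b
                                                 else frozenset({a, b}))
        elif len(per_allele) == 1:  # direct read or hemizygous female
            for pos, base in per_allele[0].items():
                m = to_mask_array(base)[0]
                if POPCOUNT_LUT[m] == 1:
                    exon_calls[pos] = base
                elif POPCOUNT_LUT[m] == 2:
                    exon_calls[pos] = frozenset(
                        b for b, bit in _BASE_BITS if m & bit)

    i65 = "unknown"
    intron_alleles = specimen.sequence(intron_segment)
    if len(intron_alleles) > 2:
        raise ValidationError(f"{specimen.specimen_id}: >2 Tpi sequences")
    if intron_alleles and intron_segment in refs:
        ref_plus = refs[intron_segment]
        ref_del = ref_plus.with_deletion(i65_window)
        if len(intron_alleles) == 2:
            states = [_classify_i65_allele(s, ref_plus, ref_del, clean_tol)
                      for s in intron_alleles]
            if None not in states:
                i65 = states[0] if states[0] == states[1] else "het"
        else:
            state = _classify_i65_allele(intron_alleles[0], ref_plus,
                                         ref_del, clean_tol)
            if state is not None:
                i65 = state
            elif _het_indel_signature(intron_alleles[0], ref_plus, i65_window,
                                      del_length, clean_tol, het_run_length,
                                      het_run_fraction):
                i65 = "het"

    return TpiGenotype(specimen_id=specimen.specimen_id,
                       exon_calls=exon_calls, i65_status=i65,
                       sex=specimen.sex)


_I65_WEIGHTS = {
    "half_weight": {"del": 1.0, "het": 0.5, "plus": 0.0},
    "carrier": {"del": 1.0, "het": 1.0, "plus": 0.0},
}


def tpi_allele_frequency(genotypes: list[TpiGenotype],
                         mode: str = "half_weight") -> float:
    """Per-specimen i65del frequency.

    The marker is scored per specimen rather than per chromosome (sex, and
    hence chromosome count, is unknown for many field specimens). In
    ``half_weight`` a heterozygous male counts 0.5, matching the expected
    per-chromosome frequency under Hardy-Weinberg; in ``carrier`` mode he
    counts 1. Unknown statuses are excluded from the denominator.
    """
    if mode not in _I65_WEIGHTS:
        raise ValidationError(f"unknown mode {mode!r}")
    w = _I65_WEIGHTS[mode]
    known = [g for g in genotypes if g.i65_status != "unknown"]
    if not known:
        raise DataQualityError("no genotypes with known i65 status")
    return sum(w[g.i65_status] for g in known) / len(known)
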