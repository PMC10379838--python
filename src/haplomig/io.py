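"""Reading, writing and coordinate mapping for marker amplicon data.

Sequences live in FASTA files with ``specimen|segment|allele`` headers;
specimen metadata lives in a per-specimen CSV whose collection-level columns
mirror a field-collection source table (collection id, state, year, source
type, collector). Reference segments carry a 1-based offset anchoring them
in a named gene coordinate frame, so marker sites can be addressed by gene
position (e.g. sCOIB position 1035) rather than by segment-relative index.

Amplicons from fixed primers are treated as co-linear with their reference:
mapping is an exhaustive scan over small shifts, not a gapped alignment.
A declared indel window lets the mapper recognise the one structural variant
this assay cares about (a short intron deletion) from the characteristic
jump in best-fitting shift downstream of the window.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._iupac import MASK_LUT, POPCOUNT_LUT, to_mask_array
from .errors import DataQualityError, UnmappableSequenceError, ValidationError

MITO_SEGMENTS = {"sCOIA", "sCOIB"}
TPI_SEGMENTS = {"sTpiE", "sTpi140"}

SOURCE_TYPES = {"field_larva", "colony_F1_F2", "pheromone_trap"}
SEXES = {"ZZ_male", "Z_hemizygous_female", "unknown"}
_SEX_ALIASES = {
    "male": "ZZ_male", "m": "ZZ_male", "zz_male": "ZZ_male",
    "female": "Z_hemizygous_female", "f": "Z_hemizygous_female",
    "z_hemizygous_female": "Z_hemizygous_female",
    "unknown": "unknown", "": "unknown",
}

#: metadata CSV column order (one row per specimen)
META_COLUMNS = ["specimen_id", "collection_id", "state", "year",
                "source_type", "sex", "collector"]


def is_mito_segment(name: str) -> bool:
    """Mitochondrial segments are haploid: one sequence per specimen."""
    return name in MITO_SEGMENTS or name.lower().startswith(("scoi", "coi", "mt"))


@dataclass(frozen=True)
class ReferenceSegment:
    """A marker reference sequence anchored in a gene coordinate frame.

    ``offset`` is the 1-based gene-frame position of ``sequence[0]``;
    gene position ``p`` maps to string index ``p - offset``.
    """

    name: str
    sequence: str
    offset: int
    frame: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"reference {self.name!r}: empty sequence")
        if self.offset < 1:
            raise ValidationError(
                f"reference {self.name!r}: offset must be >= 1, got {self.offset}")
        for i, ch in enumerate(self.sequence):
            if ch not in "ACGT":
                raise ValidationError(
                    f"reference {self.name!r}: non-ACGT character {ch!r} "
                    f"at position {i + 1}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive (first, last) gene-frame positions covered."""
        return self.offset, self.offset + len(self.sequence) - 1

    def index(self, position: int) -> int:
        """String index for a 1-based gene-frame position."""
        i = position - self.offset
        if not 0 <= i < len(self.sequence):
            raise ValidationError(
                f"position {position} outside {self.name} span {self.span}")
        return i

    def base_at(self, position: int) -> str:
        return self.sequence[self.index(position)]

    def with_deletion(self, window: tuple[int, int]) -> "ReferenceSegment":
        """Reference allele with the inclusive gene-frame window removed."""
        a, b = self.index(window[0]), self.index(window[1])
        if b < a:
            raise ValidationError(f"bad deletion window {window}")
        return ReferenceSegment(
            name=f"{self.name}.del{window[0]}-{window[1]}",
            sequence=self.sequence[:a] + self.sequence[b + 1:],
            offset=self.offset, frame=self.frame)


@dataclass
class SpecimenRecord:
    """One insect: per-segment sequences plus collection metadata.

    ``sequences`` maps segment name to one or two nucleotide strings. Two
    strings are phased alleles and are legal only for Tpi segments of a
    ZZ male (Tpi is Z-linked; ZW females are hemizygous, mitochondria are
    maternally inherited and haploid). Single strings may carry IUPAC
    ambiguity codes, as produced by direct sequencing of mixed templates.
    """

    specimen_id: str
    collection_id: str
    state: str
    year: int
    source_type: str = "field_larva"
    sex: str = "unknown"
    sequences: dict[str, list[str]] = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in SEXES:
            self.sex = _SEX_ALIASES.get(str(self.sex).lower())
            if self.sex is None:
                raise ValidationError(
                    f"{self.specimen_id}: unrecognized sex value")
        self.validate_sequences()

    def validate_sequences(self):
        for seg, alleles in self.sequences.items():
            if not 1 <= len(alleles) <= 2:
                raise ValidationError(
                    f"{self.specimen_id}/{seg}: {len(alleles)} sequences "
                    "(1 or 2 allowed)")
            if len(alleles) == 2:
                if is_mito_segment(seg):
                    raise ValidationError(
                        f"{self.specimen_id}/{seg}: two alleles on a "
                        "mitochondrial segment")
                if self.sex == "Z_hemizygous_female":
                    raise ValidationError(
                        f"{self.specimen_id}/{seg}: two Tpi alleles for a "
                        "hemizygous female")

    def sequence(self, segment: str) -> list[str]:
        return self.sequences.get(segment, [])


@dataclass
class CollectionTable:
    """Collection-level source table: one row per collection."""

    frame: pd.DataFrame  # columns: collection_id, state, year, source_type, collector

    def __post_init__(self):
        if self.frame["collection_id"].duplicated().any():
            dup = self.frame.loc[self.frame["collection_id"].duplicated(),
                                 "collection_id"].iloc[0]
            raise ValidationError(f"duplicate collection_id {dup!r}")

    def resolve(self, collection_id: str) -> pd.Series:
        rows = self.frame[self.frame["collection_id"] == collection_id]
        if rows.empty:
            raise ValidationError(f"unknown collection_id {collection_id!r}")
        return rows.iloc[0]


@dataclass
class PositionMap:
    """Result of placing a read on its reference.

    ``shift`` follows the convention ``read[i]`` aligns ``ref[i - shift]``;
    a deletion in the read relative to the reference therefore shows up as
    ``downstream_shift == shift - deletion_length``.
    """

    segment: str
    shift: int
    mismatches: int
    overlap: int
    indel_suspected: bool = False
    downstream_shift: int | None = None

    @property
    def mismatch_fraction(self) -> float:
        return self.mismatches / self.overlap if self.overlap else 1.0

    def read_index(self, ref_index: int) -> int:
        """Read index aligned to a reference string index (upstream frame)."""
        return ref_index + self.shift


def _clean_sequence(raw: str, context: str) -> str:
    """Upcase, map U->T, and reject characters outside the IUPAC alphabet."""
    seq = raw.upper().replace("U", "T")
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = np.nonzero(MASK_LUT[arr] == 0)[0]
    if bad.size:
        raise ValidationError(
            f"{context}: non-IUPAC character {seq[bad[0]]!r} at position "
            f"{int(bad[0]) + 1}")
    return seq


def load_reference(path, offset: int, frame: str,
                   name: str | None = None) -> ReferenceSegment:
    """Load a single-record FASTA as a reference segment.

    ``offset`` anchors the first base at that 1-based gene-frame position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"{path}: expected a single FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValidationError(
                f"{path}: non-ACGT character {ch!r} at position {i + 1}")
    return ReferenceSegment(name=name or rec.id, sequence=seq,
                            offset=offset, frame=frame)


def builtin_references() -> dict[str, ReferenceSegment]:
    """Bundled synthetic reference segments (sCOIA, sCOIB, sTpiE, sTpi140).

    These are synthetic stand-ins carrying the published marker coordinates
    (sCOIB 1035/1272, sCOIA 474/528, sTpiE 48/51/153/177, the sTpi140 intron
    with its 7-bp deletion window at 65-71); the real mitochondrial genome
    and Tpi locus are not redistributed here.
    """
    refs: dict[str, ReferenceSegment] = {}
    data = resources.files("haplomig").joinpath("data/synthetic_refs.fasta")
    with data.open("r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fields = dict(kv.split("=") for kv in rec.description.split()
                          if "=" in kv)
            refs[rec.id] = ReferenceSegment(
                name=rec.id, sequence=str(rec.seq).upper(),
                offset=int(fields["offset"]), frame=fields["frame"])
    return refs


#: gene-frame window of the 7-bp intron deletion in the bundled sTpi140 frame
I65_WINDOW = (65, 71)
I65_DEL_LENGTH = 7


# ---------------------------------------------------------------------------
# specimen FASTA + metadata CSV

def _parse_header(header: str, delimiter: str) -> tuple[str, str, int]:
    parts = header.split(delimiter)
    if len(parts) != 3:
        raise ValidationError(
            f"FASTA header {header!r}: expected "
            f"'specimen{delimiter}segment{delimiter}allele'")
    sid, seg, allele = parts
    try:
        allele_i = int(allele)
    except ValueError:
        raise ValidationError(f"FASTA header {header!r}: allele index not an "
                              "integer") from None
    if allele_i not in (1, 2):
        raise ValidationError(f"FASTA header {header!r}: allele must be 1 or 2")
    return sid, seg, allele_i


def _ambiguity_fraction(seq: str) -> float:
    masks = to_mask_array(seq)
    return float(np.mean(POPCOUNT_LUT[masks] != 1))


def read_specimens(seq_path, meta_path, delimiter: str = "|",
                   max_mito_ambiguity: float = 0.20,
                   ) -> tuple[list[SpecimenRecord], CollectionTable]:
    """Read a specimen FASTA and its per-specimen metadata CSV.

    Headers encode ``specimen|segment|allele``. Every specimen in the FASTA
    must appear in the CSV. Mitochondrial reads with ambiguity at more than
    ``max_mito_ambiguity`` of positions are dropped as unreadable (QC flag
    on the record), since a clean haploid template should not produce mixed
    chromatogram peaks.
    """
    meta = pd.read_csv(meta_path, dtype=str, comment="#").fillna("")
    missing_cols = {"specimen_id", "collection_id", "state", "year"} - set(meta.columns)
    if missing_cols:
        raise ValidationError(
            f"{meta_path}: missing metadata columns {sorted(missing_cols)}")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValidationError(f"{meta_path}: duplicate specimen_id {dup!r}")
    meta_by_id = {r.specimen_id: r for r in meta.itertuples()}

    per_specimen: dict[str, dict[str, dict[int, str]]] = {}
    for rec in SeqIO.parse(str(seq_path), "fasta"):
        sid, seg, allele = _parse_header(rec.id, delimiter)
        seq = _clean_sequence(str(rec.seq), f"{sid}{delimiter}{seg}")
        segs = per_specimen.setdefault(sid, {})
        alleles = segs.setdefault(seg, {})
        if allele in alleles:
            raise ValidationError(
                f"duplicate record for ({sid}, {seg}, allele {allele})")
        alleles[allele] = seq

    records: list[SpecimenRecord] = []
    for sid in per_specimen:
        if sid not in meta_by_id:
            raise ValidationError(
                f"specimen {sid!r} present in FASTA but absent from metadata")
    for sid, segs in per_specimen.items():
        m = meta_by_id[sid]
        sequences: dict[str, list[str]] = {}
        qc: list[str] = []
        for seg, alleles in segs.items():
            ordered = [alleles[k] for k in sorted(alleles)]
            if is_mito_segment(seg):
                if len(ordered) > 1:
                    raise ValidationError(
                        f"{sid}/{seg}: two alleles on a mitochondrial segment")
                if _ambiguity_fraction(ordered[0]) > max_mito_ambiguity:
                    qc.append(f"{seg}:unreadable_mito_ambiguity")
                    continue
            sequences[seg] = ordered
        records.append(SpecimenRecord(
            specimen_id=sid, collection_id=m.collection_id, state=m.state,
            year=int(m.year),
            source_type=getattr(m, "source_type", "") or "field_larva",
            sex=getattr(m, "sex", "") or "unknown",
            sequences=sequences, qc_flags=qc))

    coll = (meta.assign(source_type=meta.get("source_type", "field_larva"),
                        collector=meta.get("collector", ""))
            [["collection_id", "state", "year", "source_type", "collector"]]
            .drop_duplicates(subset="collection_id")
            .reset_index(drop=True))
    return records, CollectionTable(coll)


def write_specimens(records: list[SpecimenRecord], seq_path, meta_path,
                    delimiter: str = "|") -> None:
    """Write specimens as FASTA + metadata CSV in canonical (sorted) order.

    Output is deterministic: re-writing what ``read_specimens`` returns
    reproduces the file byte for byte.
    """
    records = sorted(records, key=lambda r: r.specimen_id)
    with open(seq_path, "w") as fh:
        for rec in records:
            for seg in sorted(rec.sequences):
                for i, seq in enumerate(rec.sequences[seg], start=1):
                    fh.write(f">{rec.specimen_id}{delimiter}{seg}"
                             f"{delimiter}{i}\n{seq}\n")
    with open(meta_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(META_COLUMNS)
        for rec in records:
            w.writerow([rec.specimen_id, rec.collection_id, rec.state,
                        rec.year, rec.source_type, rec.sex, ""])


# ---------------------------------------------------------------------------
# co-linear mapping

def _mismatches_at_shift(read_m: np.ndarray, ref_m: np.ndarray, shift: int,
                         ref_lo: int = 0, ref_hi: int | None = None,
                         ) -> tuple[int, int]:
    """(mismatches, overlap) for read[i] ~ ref[i - shift], IUPAC-compatible
    pairs counting as matches, restricted to ref indices [ref_lo, ref_hi)."""
    if ref_hi is None:
        ref_hi = len(ref_m)
    lo = max(0, ref_lo + shift)
    hi = min(len(read_m), ref_hi + shift)
    if hi <= lo:
        return 0, 0
    r = read_m[lo:hi]
    f = ref_m[lo - shift:hi - shift]
    return int(np.count_nonzero((r & f) == 0)), hi - lo


def _best_shift(read_m, ref_m, shifts, min_overlap=10, ref_lo=0, ref_hi=None):
    best = None
    for s in shifts:
        mm, ov = _mismatches_at_shift(read_m, ref_m, s, ref_lo, ref_hi)
        if ov < min_overlap:
            continue
        frac = mm / ov
        key = (frac, abs(s), s)
        if best is None or key < best[0]:
            best = (key, s, mm, ov)
    return best  # (key, shift, mismatches, overlap) or None


def map_to_reference(seq: str, ref: ReferenceSegment,
                     indel_window: tuple[int, int] | None = None,
                     max_shift: int = 30,
                     max_mismatch_frac: float = 0.30) -> PositionMap:
    """Place a read on its reference by exhaustive shift scan.

    Tries every shift in ``[-max_shift, max_shift]`` and keeps the one with
    the fewest IUPAC-incompatible positions (ties go to the smaller absolute
    shift). If no single shift fits at ``max_mismatch_frac`` and an indel
    window is declared, the read is split at the window: a downstream region
    fitting at a nearby but different shift marks ``indel_suspected`` — the
    signature of a deletion/insertion relative to the reference, which shifts
    the reading frame of everything downstream.
    """
    if len(seq) < 40:
        raise ValidationError(f"read too short to map ({len(seq)} < 40 bases)")
    seq = seq.upper().replace("U", "T")
    read_m = to_mask_array(seq)
    ref_m = to_mask_array(ref.sequence)
    shifts = range(-max_shift, max_shift + 1)

    best = _best_shift(read_m, ref_m, shifts, min_overlap=40)
    if best is not None and best[0][0] <= max_mismatch_frac:
        _, s, mm, ov = best
        return PositionMap(segment=ref.name, shift=s, mismatches=mm, overlap=ov)

    if indel_window is not None:
        wi_start = ref.index(indel_window[0])
        wi_end = ref.index(indel_window[1])
        up = _best_shift(read_m, ref_m, shifts, ref_hi=wi_start)
        if (up is not None and up[0][0] <= max_mismatch_frac
                and len(ref_m) - (wi_end + 1) >= 10):
            s_up = up[1]
            down = _best_shift(read_m, ref_m, shifts, ref_lo=wi_end + 1)
            if (down is not None and down[0][0] <= max_mismatch_frac
                    and down[1] != s_up and abs(down[1] - s_up) <= 10):
                return PositionMap(
                    segment=ref.name, shift=s_up,
                    mismatches=up[2] + down[2], overlap=up[3] + down[3],
                    indel_suspected=True, downstream_shift=down[1])

    frac = best[0][0] if best is not None else 1.0
    raise UnmappableSequenceError(
        f"read unmappable to {ref.name}: best mismatch fraction "
        f"{frac:.2f} > {max_mismatch_frac:.2f}")
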