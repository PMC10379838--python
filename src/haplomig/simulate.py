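"""Founder-effect migration simulator and synthetic cohort generator.

The explanatory model: a migratory moth population whose long-distance
flights involve large numbers preserves the haplotype proportions of its
source (the per-stage sampling variance ~ p(1-p)/n is negligible), whereas
migration in small groups passes the source frequencies through a narrow
multinomial bottleneck, so destination proportions drift — collections far
from the overwintering source become more variable and can differ
significantly from it. A founder event is modeled as a single multinomial
draw of ``n_founders`` individuals from the source frequency vector,
followed by frequency-exact expansion (the founder draw is the only drift)
or, optionally, by Wright-Fisher binomial resampling for a few generations.
For the focal haplotype frequency p this gives, in exact-frequency mode,

    Var(p_hat) ~= p (1 - p) (1/n_founders + 1/n_sampled),

the sum of the founder bottleneck and the genotyping-sample stages.

The same machinery synthesizes full per-specimen FASTA + metadata fixtures:
marker bases implanted on the bundled references, uniform singleton noise at
non-marker positions, Z-linked i65del alleles drawn per chromosome (two for
ZZ males, one for ZW females), and — for heterozygous-indel males — the
direct-read IUPAC merge artifact the genotyper must decode. Ground truth is
written alongside so recovery is checkable end to end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._iupac import merge_strings
from .errors import ValidationError
from .io import (I65_DEL_LENGTH, I65_WINDOW, ReferenceSegment, SpecimenRecord,
                 write_specimens)
from .popstats import (CONTRAST_HAPLOTYPE, FOCAL_HAPLOTYPE, MResult,
                       RegionScheme, regional_compare)

#: default source haplotype frequencies for the COI marker, ordered
#: (focal, contrast, minor, rare); calibration defaults consistent with a
#: ~2:1 C/T split at site 1035 and T/C at 1272 with the two recombinant
#: classes rare and ~3-fold apart.
DEFAULT_COIB_FREQS = {
    "C1035/T1272": 0.68,
    "T1035/C1272": 0.27,
    "T1035/T1272": 0.04,
    "C1035/C1272": 0.01,
}

#: Tpi exon sites as (position, major, minor, minor frequency)
DEFAULT_STPIE_SITES = (
    (48, "A", "G", 0.03),
    (51, "G", "A", 0.10),
    (153, "C", "T", 0.03),
    (177, "C", "T", 0.03),
)

#: observed rare-variant load is a handful of carriers per ~180 kb scored,
#: so the default per-site per-specimen private-variant rate is 5e-5
DEFAULT_SINGLETON_RATE = 5e-5

_SOUTH_STATES = ("TX", "LA", "MS", "GA", "FL", "AL")
_NORTH_STATES = ("KS", "TN", "VA", "NC", "SC")


@dataclass(frozen=True)
class SourcePopulation:
    """Genetic composition of an overwintering source population."""

    name: str = "source"
    coib_freqs: dict = field(default_factory=lambda: dict(DEFAULT_COIB_FREQS))
    i65del_freq: float = 0.16
    stpie_sites: tuple = DEFAULT_STPIE_SITES
    singleton_rate: float = DEFAULT_SINGLETON_RATE

    def __post_init__(self):
        freqs = np.array(list(self.coib_freqs.values()), dtype=float)
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "haplotype frequencies must be non-negative and sum to 1")
        if not 0.0 <= self.i65del_freq <= 1.0:
            raise ValidationError("i65del frequency outside [0, 1]")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.coib_freqs)

    @property
    def freq_vector(self) -> np.ndarray:
        return np.array(list(self.coib_freqs.values()), dtype=float)


@dataclass(frozen=True)
class WrightFisher:
    """Optional post-founding drift: ``gens`` generations at size ``N``."""

    gens: int
    N: int


@dataclass(frozen=True)
class MigrationScenario:
    """One simulated migration-and-collection design.

    ``n_founders=None`` means direct sampling from the source (the model of
    a collection made inside the overwintering range, or of migration in
    effectively unlimited numbers). ``expansion=None`` is frequency-exact
    expansion; pass a :class:`WrightFisher` for generational drift.
    ``n_waves=None`` gives every destination its own independent founder
    event; an integer pools destinations onto that many shared migrant
    waves (round-robin), so a whole region inherits each wave's drift.
    """

    source: SourcePopulation = field(default_factory=SourcePopulation)
    n_founders: int | None = None
    n_waves: int | None = None
    n_destinations: int = 1
    expansion: WrightFisher | None = None
    n_sampled: int = 30
    sex_ratio: float = 0.5
    seed: int = 0
    states: tuple[str, ...] | None = None  # None -> role default at synthesis
    year: int = 2019
    source_type: str = "pheromone_trap"
    collection_prefix: str = ""

    def __post_init__(self):
        if self.n_founders is not None and self.n_founders < 1:
            raise ValidationError("n_founders must be >= 1")
        if self.n_waves is not None and self.n_waves < 1:
            raise ValidationError("n_waves must be >= 1")
        if self.n_sampled < 1 or self.n_destinations < 1:
            raise ValidationError("n_sampled and n_destinations must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValidationError("sex_ratio outside [0, 1]")


# ---------------------------------------------------------------------------
# count-level simulation

def sample_founders(source: SourcePopulation, n_founders: int,
                    rng: np.random.Generator) -> np.ndarray:
    """One multinomial founder draw from the source frequencies."""
    if n_founders < 1:
        raise ValidationError("n_founders must be >= 1")
    return rng.multinomial(n_founders, source.freq_vector)


def expand_and_sample(founder_counts: np.ndarray,
                      scenario: MigrationScenario,
                      rng: np.random.Generator) -> np.ndarray:
    """Haplotype counts among genotyped specimens at one destination."""
    founder_counts = np.asarray(founder_counts)
    total = founder_counts.sum()
    if total < 1:
        raise ValidationError("founder counts must sum to >= 1")
    p = founder_counts / total
    wf = scenario.expansion
    if wf is not None:
        if scenario.n_sampled > wf.N:
            raise ValidationError("cannot sample more specimens than the "
                                  "expanded population size")
        for _ in range(wf.gens):
            p = rng.multinomial(wf.N, p) / wf.N
    return rng.multinomial(scenario.n_sampled, p)


def destination_counts(scenario: MigrationScenario,
                       rng: np.random.Generator) -> np.ndarray:
    """Counts for one destination under the scenario's migration model."""
    if scenario.n_founders is None:
        return rng.multinomial(scenario.n_sampled,
                               scenario.source.freq_vector)
    founders = sample_founders(scenario.source, scenario.n_founders, rng)
    if founders.sum() == 0:  # unreachable; multinomial conserves total
        raise ValidationError("empty founder group")
    return expand_and_sample(founders, scenario, rng)


def founder_variance(p: float, n_founders: int, n_sampled: int) -> float:
    """Closed-form two-stage sampling variance of a destination frequency."""
    return p * (1 - p) * (1 / n_founders + 1 / n_sampled)


def simulate_destination_frequencies(scenario: MigrationScenario,
                                     replicates: int,
                                     rng: np.random.Generator,
                                     label_index: int = 0) -> np.ndarray:
    """Vectorized replicate draws of one haplotype's destination frequency."""
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    p = scenario.source.freq_vector
    if scenario.n_founders is None:
        counts = rng.multinomial(scenario.n_sampled, p, size=replicates)
    else:
        founders = rng.multinomial(scenario.n_founders, p, size=replicates)
        props = founders / scenario.n_founders
        counts = rng.multinomial(scenario.n_sampled, props)
    return counts[:, label_index] / scenario.n_sampled


def simulate_destination_m(scenario: MigrationScenario, replicates: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Vectorized replicate draws of the destination M statistic.

    Destinations where neither the focal nor the contrast haplotype was
    sampled (possible at tiny founder sizes) are dropped, mirroring the
    analysis rule for empty collections.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    labels = list(scenario.source.labels)
    fi = labels.index(FOCAL_HAPLOTYPE)
    ci = labels.index(CONTRAST_HAPLOTYPE)
    p = scenario.source.freq_vector
    if scenario.n_founders is None:
        counts = rng.multinomial(scenario.n_sampled, p, size=replicates)
    else:
        founders = rng.multinomial(scenario.n_founders, p, size=replicates)
        counts = rng.multinomial(scenario.n_sampled,
                                 founders / scenario.n_founders)
    a = counts[:, fi].astype(float)
    b = counts[:, ci].astype(float)
    ok = (a + b) > 0
    return (a[ok] - b[ok]) / (a[ok] + b[ok])


# ---------------------------------------------------------------------------
# sequence-level synthesis

def default_variant_map(labels=tuple(DEFAULT_COIB_FREQS)) -> dict:
    """Parse canonical labels like 'C1035/T1272' into {position: base}."""
    vmap = {}
    for label in labels:
        assignments = {}
        for token in label.split("/"):
            assignments[int(token[1:])] = token[0]
        vmap[label] = assignments
    return vmap


def _implant(sequence: str, offset: int, assignments: dict) -> str:
    s = list(sequence)
    for pos, base in assignments.items():
        s[pos - offset] = base
    return "".join(s)


def _add_noise(sequence: str, rng: np.random.Generator, rate: float,
               protected: set[int]) -> tuple[str, list[int]]:
    """Substitute random bases at non-protected 0-based positions."""
    if rate <= 0:
        return sequence, []
    hits = np.nonzero(rng.random(len(sequence)) < rate)[0]
    if hits.size == 0:
        return sequence, []
    s = list(sequence)
    placed = []
    for i in hits:
        if int(i) in protected:
            continue
        alternatives = [b for b in "ACGT" if b != s[i]]
        s[i] = alternatives[rng.integers(len(alternatives))]
        placed.append(int(i))
    return "".join(s), placed


@dataclass
class CohortTruth:
    """Ground truth written alongside a synthesized cohort."""

    specimens: pd.DataFrame           # per-specimen truth
    collection_counts: dict           # collection_id -> {label: count}
    collection_meta: pd.DataFrame     # collection_id, state, year, region tag


def _destination_i65_freq(scenario: MigrationScenario,
                          rng: np.random.Generator) -> float:
    """i65del frequency at a destination, after the founder bottleneck.

    The founder group carries ~1.5 Z chromosomes per individual at an even
    sex ratio, so the bottleneck on this Z-linked allele is a binomial draw
    over round(1.5 * n_founders) chromosomes.
    """
    f = scenario.source.i65del_freq
    if scenario.n_founders is None or f in (0.0, 1.0):
        return f
    n_chrom = max(1, round(1.5 * scenario.n_founders))
    return rng.binomial(n_chrom, f) / n_chrom


def generate_records(scenario: MigrationScenario,
                     refs: dict[str, ReferenceSegment],
                     rng: np.random.Generator | None = None,
                     variant_map: dict | None = None,
                     phased_males: bool = False,
                     segments: tuple[str, ...] = ("sCOIB", "sTpiE", "sTpi140"),
                     id_prefix: str = "SP",
                     ) -> tuple[list[SpecimenRecord], CohortTruth]:
    """Synthesize specimen records (in memory) for one scenario.

    Each destination becomes one collection (state taken round-robin from
    ``scenario.states``). Marker haplotypes, Tpi exon alleles and i65del
    alleles are drawn per the scenario; sequences are the bundled references
    with marker bases implanted plus singleton noise at non-marker sites.
    ZZ males get two Tpi allele draws; unless ``phased_males``, their Tpi
    output is the single direct-read IUPAC merge of the two alleles.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    if variant_map is None:
        variant_map = default_variant_map(scenario.source.labels)
    missing = set(scenario.source.labels) - set(variant_map)
    if missing:
        raise ValidationError(f"variant map lacks haplotypes {sorted(missing)}")
    for seg in segments:
        if seg not in refs:
            raise ValidationError(f"missing reference for segment {seg!r}")

    coib = refs.get("sCOIB")
    stpie = refs.get("sTpiE")
    stpi140 = refs.get("sTpi140")
    del_allele = (stpi140.with_deletion(I65_WINDOW).sequence
                  if stpi140 is not None else None)
    protected: dict[str, set[int]] = {}
    if "sCOIB" in segments:
        marker_pos = {p for a in variant_map.values() for p in a}
        protected["sCOIB"] = {coib.index(p) for p in marker_pos}
    if "sTpiE" in segments:
        protected["sTpiE"] = {stpie.index(p)
                              for p, *_ in scenario.source.stpie_sites}
    if "sTpi140" in segments:
        protected["sTpi140"] = set(
            range(stpi140.index(I65_WINDOW[0]) - 1,
                  stpi140.index(I65_WINDOW[1]) + 2))

    records: list[SpecimenRecord] = []
    truth_rows = []
    collection_counts: dict[str, dict[str, int]] = {}
    coll_meta_rows = []
    labels = scenario.source.labels
    counter = 0
    states = scenario.states or _SOUTH_STATES

    # shared migrant waves: one founder event (and one Z-allele bottleneck)
    # per wave, inherited by all destinations assigned to it
    wave_founders = wave_i65 = None
    if scenario.n_founders is not None and scenario.n_waves is not None:
        wave_founders = [sample_founders(scenario.source,
                                         scenario.n_founders, rng)
                         for _ in range(scenario.n_waves)]
        wave_i65 = [_destination_i65_freq(scenario, rng)
                    for _ in range(scenario.n_waves)]

    for d in range(scenario.n_destinations):
        state = states[d % len(states)]
        collection_id = (f"{scenario.collection_prefix}{state}"
                         f"{scenario.year}_{d:02d}")
        if wave_founders is not None:
            w = d % scenario.n_waves
            counts = expand_and_sample(wave_founders[w], scenario, rng)
            i65_f = wave_i65[w]
        else:
            counts = destination_counts(scenario, rng)
            i65_f = _destination_i65_freq(scenario, rng)
        collection_counts[collection_id] = dict(zip(labels, counts.tolist()))
        coll_meta_rows.append({"collection_id": collection_id, "state": state,
                               "year": scenario.year})

        hap_assignments = np.repeat(np.arange(len(labels)), counts)
        rng.shuffle(hap_assignments)
        for hap_i in hap_assignments:
            counter += 1
            sid = f"{id_prefix}{scenario.collection_prefix}{counter:05d}"
            label = labels[hap_i]
            male = rng.random() < scenario.sex_ratio
            sex = "ZZ_male" if male else "Z_hemizygous_female"
            sequences: dict[str, list[str]] = {}
            noise_truth: dict[str, list[int]] = {}

            if "sCOIB" in segments:
                seq = _implant(coib.sequence, coib.offset, variant_map[label])
                seq, placed = _add_noise(seq, rng, scenario.source.singleton_rate,
                                         protected["sCOIB"])
                sequences["sCOIB"] = [seq]
                noise_truth["sCOIB"] = [coib.offset + i for i in placed]

            n_z = 2 if male else 1
            exon_truth = {}
            if "sTpiE" in segments:
                alleles = []
                for _ in range(n_z):
                    s = list(stpie.sequence)
                    for pos, major, minor, mf in scenario.source.stpie_sites:
                        if rng.random() < mf:
                            s[stpie.index(pos)] = minor
                    alleles.append("".join(s))
                alleles = [_add_noise(a, rng, scenario.source.singleton_rate,
                                      protected["sTpiE"])[0] for a in alleles]
                exon_truth = {
                    pos: "".join(sorted({a[stpie.index(pos)] for a in alleles}))
                    for pos, *_ in scenario.source.stpie_sites}
                if male and not phased_males:
                    sequences["sTpiE"] = [merge_strings(*alleles)]
                else:
                    sequences["sTpiE"] = alleles

            i65_genotype = ""
            if "sTpi140" in segments:
                is_del = rng.random(n_z) < i65_f
                i65_genotype = ("het" if n_z == 2 and is_del[0] != is_del[1]
                                else ("del" if is_del[0] else "plus"))
                alleles = [del_allele if flag else stpi140.sequence
                           for flag in is_del]
                alleles = [_add_noise(a, rng, scenario.source.singleton_rate,
                                      protected["sTpi140"])[0] for a in alleles]
                if male and not phased_males:
                    sequences["sTpi140"] = [merge_strings(*alleles)]
                else:
                    sequences["sTpi140"] = alleles

            records.append(SpecimenRecord(
                specimen_id=sid, collection_id=collection_id, state=state,
                year=scenario.year, source_type=scenario.source_type,
                sex=sex, sequences=sequences))
            truth_rows.append({
                "specimen_id": sid, "collection_id": collection_id,
                "state": state, "year": scenario.year, "sex": sex,
                "coib_label": label, "i65_genotype": i65_genotype,
                "exon_calls": ";".join(f"{p}={b}" for p, b
                                       in sorted(exon_truth.items())),
                "noise_positions": ";".join(
                    f"{seg}:{p}" for seg in sorted(noise_truth)
                    for p in noise_truth[seg]),
            })

    truth = CohortTruth(
        specimens=pd.DataFrame(truth_rows),
        collection_counts=collection_counts,
        collection_meta=pd.DataFrame(coll_meta_rows))
    return records, truth


def synthesize_cohort(scenario: MigrationScenario,
                      refs: dict[str, ReferenceSegment], out_dir,
                      variant_map: dict | None = None,
                      phased_males: bool = False,
                      segments: tuple[str, ...] = ("sCOIB", "sTpiE", "sTpi140"),
                      ) -> CohortTruth:
    """Synthesize one scenario and write FASTA, metadata and truth files."""
    records, truth = generate_records(scenario, refs,
                                      variant_map=variant_map,
                                      phased_males=phased_males,
                                      segments=segments)
    _write_fixture(records, truth, out_dir)
    return truth


def synthesize_study(south: MigrationScenario, north: MigrationScenario,
                     refs: dict[str, ReferenceSegment], out_dir,
                     phased_males: bool = False,
                     segments: tuple[str, ...] = ("sCOIB", "sTpiE", "sTpi140"),
                     ) -> CohortTruth:
    """Two-region study fixture: direct south sampling + founder-event north.

    Each scenario keeps its own seed stream; collection prefixes keep ids
    distinct. This is the end-to-end input for the regional comparisons.
    """
    south = replace(south, collection_prefix=south.collection_prefix or "S",
                    states=south.states or _SOUTH_STATES)
    north = replace(north, collection_prefix=north.collection_prefix or "N",
                    states=north.states or _NORTH_STATES)
    rec_s, truth_s = generate_records(south, refs, phased_males=phased_males,
                                      segments=segments)
    rec_n, truth_n = generate_records(north, refs, phased_males=phased_males,
                                      segments=segments)
    truth = CohortTruth(
        specimens=pd.concat([truth_s.specimens, truth_n.specimens],
                            ignore_index=True),
        collection_counts={**truth_s.collection_counts,
                           **truth_n.collection_counts},
        collection_meta=pd.concat([truth_s.collection_meta,
                                   truth_n.collection_meta],
                                  ignore_index=True))
    _write_fixture(rec_s + rec_n, truth, out_dir)
    return truth


def _write_fixture(records, truth: CohortTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_specimens(records, out / "specimens.fasta", out / "metadata.csv")
    truth.specimens.sort_values("specimen_id").to_csv(
        out / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# power analysis

@dataclass
class PowerGrid:
    """Rejection rates of the regional comparison across founder sizes."""

    table: pd.DataFrame  # founder_size, replicates, rejection_rate, m_sd, ...
    alpha: float


def _collection_m(counts: np.ndarray, focal_i: int, contrast_i: int,
                  ) -> float | None:
    a, b = int(counts[focal_i]), int(counts[contrast_i])
    if a + b == 0:
        return None
    return (a - b) / (a + b)


def run_power_analysis(founder_sizes, replicates: int,
                       source: SourcePopulation | None = None,
                       n_collections_per_side: int = 10,
                       n_sampled: int = 30, alpha: float = 0.05,
                       seed: int = 0, variant: str = "pooled",
                       north_source: SourcePopulation | None = None,
                       n_waves: int = 1) -> PowerGrid:
    """Rejection rate of the North/South comparison per founder size.

    Each replicate simulates one study: southern collections sampled
    directly from the source; northern collections sampled from the
    drifted frequencies of ``n_waves`` migrant waves, each wave one founder
    event of the given size (collections assigned round-robin). A season's
    long-distance migration is a small number of waves, so the whole
    northern region shares each wave's drift — that regional shift, not
    per-collection scatter, is what the mean-comparing t-test can detect.
    Collection-level M is computed for both sides and the regional t-test
    run. With identical sources and a very large founder size this is a
    type-I-error calibration; with small founder sizes the rejection rate
    is the power to detect founder-driven divergence, and the sd of
    northern M quantifies the drift itself.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if n_waves < 1:
        raise ValidationError("n_waves must be >= 1")
    source = source or SourcePopulation()
    north_source = north_source or source
    labels = list(source.labels)
    focal_i = labels.index(FOCAL_HAPLOTYPE)
    contrast_i = labels.index(CONTRAST_HAPLOTYPE)
    scheme = RegionScheme.north_south()
    rng = np.random.default_rng(seed)

    rows = []
    for nf in founder_sizes:
        if nf is not None and nf < 1:
            raise ValidationError("founder sizes must be >= 1")
        rejections = 0
        tested = 0
        north_ms_all: list[float] = []
        for _ in range(replicates):
            m_values: list[MResult] = []
            for c in range(n_collections_per_side):
                state = _SOUTH_STATES[c % len(_SOUTH_STATES)]
                counts = rng.multinomial(n_sampled, source.freq_vector)
                m = _collection_m(counts, focal_i, contrast_i)
                if m is not None:
                    m_values.append(MResult((state, c), state,
                                            int(counts[focal_i]),
                                            int(counts[contrast_i]), m))
            if nf is None:
                wave_props = [north_source.freq_vector] * n_waves
            else:
                wave_props = [rng.multinomial(nf, north_source.freq_vector) / nf
                              for _ in range(n_waves)]
            for c in range(n_collections_per_side):
                state = _NORTH_STATES[c % len(_NORTH_STATES)]
                counts = rng.multinomial(n_sampled, wave_props[c % n_waves])
                m = _collection_m(counts, focal_i, contrast_i)
                if m is not None:
                    m_values.append(MResult((state, c), state,
                                            int(counts[focal_i]),
                                            int(counts[contrast_i]), m))
                    north_ms_all.append(m)
            try:
                with warnings.catch_warnings():
                    # degenerate replicates (near-constant M on a side) warn
                    # inside scipy and yield undefined p; they are skipped
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = regional_compare(m_values, scheme, variant=variant)
            except Exception:
                continue
            tested += 1
            if res.p_value < alpha:
                rejections += 1
        rows.append({
            "founder_size": nf, "replicates": tested,
            "rejection_rate": rejections / tested if tested else math.nan,
            "m_sd_destination": float(np.std(north_ms_all, ddof=1))
            if len(north_ms_all) > 1 else math.nan,
            "n_sampled": n_sampled, "alpha": alpha})
    return PowerGrid(table=pd.DataFrame(rows), alpha=alpha)
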