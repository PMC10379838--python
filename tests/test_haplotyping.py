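"""SNP discovery, haplotype calling, and Tpi/i65del genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplomig as hm
from haplomig._iupac import merge_strings
from conftest import make_coib_specimens


class TestDiscoverSnps:
    def test_biallelic_frequency(self, refs):
        # 67 C / 33 T at site 1035: the predominant COI marker-site profile
        specimens = make_coib_specimens(refs["sCOIB"], ["C"] * 67 + ["T"] * 33)
        sites = hm.discover_snps(specimens, "sCOIB", refs["sCOIB"])
        assert len(sites) == 1
        s = sites[0]
        assert (s.position, s.major, s.minor) == (1035, "C", "T")
        assert s.minor_frequency == pytest.approx(0.33)
        assert s.n_scored == 100 and not s.singleton

    def test_identical_specimens_give_no_sites(self, refs):
        specimens = make_coib_specimens(refs["sCOIB"], ["C"] * 10)
        assert hm.discover_snps(specimens, "sCOIB", refs["sCOIB"]) == []

    def test_singleton_flagged(self, refs):
        specimens = make_coib_specimens(refs["sCOIB"], ["C"] * 49 + ["G"])
        sites = hm.discover_snps(specimens, "sCOIB", refs["sCOIB"])
        assert len(sites) == 1
        assert sites[0].singleton
        assert sites[0].minor_frequency == pytest.approx(0.02)

    def test_het_male_counts_once_carrying_both(self, refs):
        ref = refs["sTpiE"]
        alt = list(ref.sequence)
        alt[ref.index(51)] = "A"
        alt = "".join(alt)
        specimens = [
            hm.SpecimenRecord("S1", "C1", "TX", 2019, sex="male",
                              sequences={"sTpiE": [ref.sequence, alt]}),
            hm.SpecimenRecord("S2", "C1", "TX", 2019, sex="female",
                              sequences={"sTpiE": [ref.sequence]}),
            hm.SpecimenRecord("S3", "C1", "TX", 2019, sex="female",
                              sequences={"sTpiE": [alt]}),
        ]
        sites = hm.discover_snps(specimens, "sTpiE", ref)
        (site,) = sites
        # 3 scored specimens; minor A carried by the het male and S3
        assert site.n_scored == 3
        assert site.minor_frequency == pytest.approx(2 / 3)
        # an IUPAC direct read carries both alleles too
        merged = merge_strings(ref.sequence, alt)
        specimens[0].sequences["sTpiE"] = [merged]
        sites2 = hm.discover_snps(specimens, "sTpiE", ref)
        assert sites2[0].minor_frequency == pytest.approx(2 / 3)

    def test_order_invariance(self, refs):
        rng = np.random.default_rng(5)
        bases = list(rng.choice(["C", "T"], size=40, p=[0.7, 0.3]))
        specimens = make_coib_specimens(refs["sCOIB"], bases)
        a = hm.discover_snps(specimens, "sCOIB", refs["sCOIB"])
        b = hm.discover_snps(specimens[::-1], "sCOIB", refs["sCOIB"])
        assert a == b

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 30))
    def test_matches_per_position_tally_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        ref_seq = "".join(rng.choice(list("ACGT"), size=60))
        ref = hm.ReferenceSegment("mini", ref_seq, 1001, "f")
        # specimens: reference copies with sparse random substitutions
        seqs = []
        for _ in range(n):
            s = list(ref_seq)
            for i in np.nonzero(rng.random(60) < 0.05)[0]:
                s[i] = "ACGT"[rng.integers(4)]
            seqs.append("".join(s))
        specimens = [hm.SpecimenRecord(f"S{i}", "C1", "LA", 2016,
                                       sequences={"sCOIB": [q]})
                     for i, q in enumerate(seqs)]
        sites = hm.discover_snps(specimens, "sCOIB", ref)
        # independent oracle: direct per-position tally
        expected = {}
        for col in range(60):
            column = [q[col] for q in seqs]
            distinct = sorted(set(column))
            if len(distinct) < 2:
                continue
            counts = {b: column.count(b) for b in distinct}
            major, minor = sorted(counts, key=lambda b: (-counts[b], b))[:2]
            expected[1001 + col] = (major, minor, counts[minor] / n,
                                    counts[minor] == 1)
        got = {s.position: (s.major, s.minor, s.minor_frequency, s.singleton)
               for s in sites}
        assert got == expected


class TestSelectMarkerSites:
    def _site(self, pos, freq, singleton=False, n=100):
        return hm.SNPSite(pos, "C", "T", freq, n, singleton)

    def test_threshold_filter(self):
        sites = [self._site(1035, 0.33), self._site(1272, 0.32),
                 self._site(1100, 0.02), self._site(1200, 0.01)]
        kept = hm.select_marker_sites(sites, 0.10)
        assert [s.position for s in kept] == [1035, 1272]

    def test_exactly_at_threshold_excluded(self):
        assert hm.select_marker_sites([self._site(1035, 0.10)], 0.10) == []
        assert len(hm.select_marker_sites([self._site(1035, 0.101)], 0.10)) == 1

    def test_empty_input(self):
        assert hm.select_marker_sites([], 0.10) == []

    def test_singletons_never_selectable(self):
        # a singleton in a 2-specimen set has frequency 0.5 > any threshold
        s = hm.SNPSite(1035, "C", "T", 0.5, 2, True)
        assert hm.select_marker_sites([s], 0.10) == []


class TestCallHaplotype:
    def _sites(self):
        return [hm.SNPSite(1035, "C", "T", 0.3, 100, False),
                hm.SNPSite(1272, "T", "C", 0.3, 100, False)]

    def test_canonical_label(self, refs):
        ref = refs["sCOIB"]
        seq = list(ref.sequence)
        seq[ref.index(1035)] = "C"
        seq[ref.index(1272)] = "T"
        rec = hm.SpecimenRecord("S1", "C1", "TX", 2019,
                                sequences={"sCOIB": ["".join(seq)]})
        call = hm.call_haplotype(rec, "sCOIB", self._sites(), ref)
        assert call.status == "resolved"
        assert call.label == "C1035/T1272"

    def test_ambiguity_invalidates_call(self, refs):
        ref = refs["sCOIB"]
        seq = list(ref.sequence)
        seq[ref.index(1035)] = "Y"
        rec = hm.SpecimenRecord("S1", "C1", "TX", 2019,
                                sequences={"sCOIB": ["".join(seq)]})
        call = hm.call_haplotype(rec, "sCOIB", self._sites(), ref)
        assert call.status == "unresolved_ambiguity"
        assert call.label is None

    def test_cohort_recovery_exact(self, refs, clean_cohort):
        records, truth = clean_cohort
        sites = hm.select_marker_sites(
            hm.discover_snps(records, "sCOIB", refs["sCOIB"]))
        assert sorted(s.position for s in sites) == [1035, 1272]
        expected = dict(zip(truth.specimens.specimen_id,
                            truth.specimens.coib_label))
        for rec in records:
            call = hm.call_haplotype(rec, "sCOIB", sites, refs["sCOIB"])
            assert call.label == expected[rec.specimen_id]


class TestCallTpi:
    def test_deleted_allele(self, refs):
        ref = refs["sTpi140"]
        rec = hm.SpecimenRecord(
            "S1", "C1", "TX", 2019, sex="female",
            sequences={"sTpi140": [ref.with_deletion(hm.I65_WINDOW).sequence]})
        assert hm.call_tpi(rec, [], refs).i65_status == "del"

    def test_reference_allele(self, refs):
        rec = hm.SpecimenRecord(
            "S1", "C1", "TX", 2019, sex="female",
            sequences={"sTpi140": [refs["sTpi140"].sequence]})
        assert hm.call_tpi(rec, [], refs).i65_status == "plus"

    def test_direct_read_het_merge(self, refs):
        # the direct-sequencing artifact: both alleles superimposed, IUPAC
        # soup downstream of the deletion start
        ref = refs["sTpi140"]
        merged = merge_strings(ref.sequence,
                               ref.with_deletion(hm.I65_WINDOW).sequence)
        rec = hm.SpecimenRecord("S1", "C1", "TX", 2019, sex="male",
                                sequences={"sTpi140": [merged]})
        assert hm.call_tpi(rec, [], refs).i65_status == "het"

    def test_phased_male_combinations(self, refs):
        ref = refs["sTpi140"]
        plus, dele = ref.sequence, ref.with_deletion(hm.I65_WINDOW).sequence
        for alleles, status in [([plus, plus], "plus"), ([dele, dele], "del"),
                                ([plus, dele], "het")]:
            rec = hm.SpecimenRecord("S1", "C1", "TX", 2019, sex="male",
                                    sequences={"sTpi140": list(alleles)})
            assert hm.call_tpi(rec, [], refs).i65_status == status

    def test_exon_het_from_iupac(self, refs):
        ref = refs["sTpiE"]
        seq = list(ref.sequence)
        seq[ref.index(51)] = "R"  # A/G
        rec = hm.SpecimenRecord("S1", "C1", "TX", 2019, sex="male",
                                sequences={"sTpiE": ["".join(seq)]})
        site = hm.SNPSite(51, "G", "A", 0.1, 100, False)
        g = hm.call_tpi(rec, [site], refs)
        assert g.exon_calls[51] == frozenset({"A", "G"})

    def test_more_than_two_sequences_rejected(self):
        with pytest.raises(hm.ValidationError):
            hm.SpecimenRecord("S1", "C1", "TX", 2019, sex="male",
                              sequences={"sTpi140": ["ACGT" * 35] * 3})

    def test_unrelated_sequence_is_unknown(self, refs):
        rng = np.random.default_rng(9)
        junk = "".join(rng.choice(list("ACGT"), size=140))
        rec = hm.SpecimenRecord("S1", "C1", "TX", 2019,
                                sequences={"sTpi140": [junk]})
        assert hm.call_tpi(rec, [], refs).i65_status == "unknown"


class TestTpiAlleleFrequency:
    def _gts(self, n_del, n_het, n_plus):
        out = []
        for i, status in enumerate(["del"] * n_del + ["het"] * n_het
                                   + ["plus"] * n_plus):
            out.append(hm.TpiGenotype(f"S{i}", {}, status))
        return out

    def test_no_hets_both_modes_agree(self):
        gts = self._gts(10, 0, 90)
        assert hm.tpi_allele_frequency(gts, "half_weight") == pytest.approx(0.10)
        assert hm.tpi_allele_frequency(gts, "carrier") == pytest.approx(0.10)

    def test_het_weighting(self):
        gts = self._gts(0, 4, 4)
        assert hm.tpi_allele_frequency(gts, "half_weight") == pytest.approx(0.25)
        assert hm.tpi_allele_frequency(gts, "carrier") == pytest.approx(0.5)

    def test_all_unknown_raises(self):
        gts = [hm.TpiGenotype("S1", {}, "unknown")]
        with pytest.raises(hm.DataQualityError):
            hm.tpi_allele_frequency(gts)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           mode=st.sampled_from(["half_weight", "carrier"]))
    def test_matches_weighted_tally_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        statuses = rng.choice(["del", "het", "plus", "unknown"], size=30)
        gts = [hm.TpiGenotype(f"S{i}", {}, s)
               for i, s in enumerate(statuses)]
        known = [s for s in statuses if s != "unknown"]
        if not known:
            with pytest.raises(hm.DataQualityError):
                hm.tpi_allele_frequency(gts, mode)
            return
        half = 0.5 if mode == "half_weight" else 1.0
        expected = sum(1.0 if s == "del" else half if s == "het" else 0.0
                       for s in known) / len(known)
        assert hm.tpi_allele_frequency(gts, mode) == pytest.approx(expected)

    def test_hemizygous_per_specimen_equals_per_chromosome(self):
        # with no heterozygotes each specimen carries one scored chromosome
        gts = self._gts(7, 0, 13)
        per_chrom = 7 / 20
        assert hm.tpi_allele_frequency(gts, "half_weight") == pytest.approx(per_chrom)


def test_i65_recovery_exact_on_clean_cohort(refs, clean_cohort):
    records, truth = clean_cohort
    expected = dict(zip(truth.specimens.specimen_id,
                        truth.specimens.i65_genotype))
    for rec in records:
        g = hm.call_tpi(rec, [], refs)
        assert g.i65_status == expected[rec.specimen_id]
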