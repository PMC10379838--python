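import pytest

import haplomig as hm


@pytest.fixture(scope="session")
def refs():
    return hm.builtin_references()


@pytest.fixture(scope="session")
def clean_cohort(refs):
    """Zero-noise synthetic cohort (200 specimens) with ground truth."""
    scenario = hm.MigrationScenario(
        source=hm.SourcePopulation(singleton_rate=0.0),
        n_destinations=4, n_sampled=50, seed=101)
    records, truth = hm.generate_records(scenario, refs)
    return records, truth


def make_coib_specimens(ref, base_by_specimen, position=1035):
    """Specimens that are reference copies except for one base at `position`."""
    out = []
    for i, base in enumerate(base_by_specimen):
        seq = list(ref.sequence)
        seq[ref.index(position)] = base
        out.append(hm.SpecimenRecord(
            specimen_id=f"SP{i:04d}", collection_id="C1", state="LA",
            year=2016, sequences={"sCOIB": ["".join(seq)]}))
    return out
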