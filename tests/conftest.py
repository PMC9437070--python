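import pytest

from slco1b1.io_formats import GenotypeTable, SampleRecord, default_variant_specs
from slco1b1.simulate import generate_cohort, qatari_preset, write_cohort


def make_table(dosage_pairs, groups=None):
    """Build a GenotypeTable from (dosage_388, dosage_521[, group]) tuples."""
    samples = []
    seen = []
    for i, entry in enumerate(dosage_pairs):
        d388, d521 = entry[0], entry[1]
        group = entry[2] if len(entry) > 2 else "all"
        if group not in seen:
            seen.append(group)
        samples.append(SampleRecord(f"S{i:04d}", group, d388, d521))
    return GenotypeTable(
        variants=default_variant_specs(), samples=samples, groups=groups or seen
    )


@pytest.fixture(scope="session")
def specs():
    return default_variant_specs()


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """A written maf-consistent cohort at the three published group sizes."""
    cfg = qatari_preset("maf-consistent", seed=11)
    table, truth = generate_cohort(cfg)
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(table, truth, out)
    return {"cfg": cfg, "table": table, "truth": truth, "paths": paths}
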