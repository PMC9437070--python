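"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from slco1b1.io_formats import apply_sample_groups, read_sample_groups, read_vcf_genotypes
from slco1b1.reference import GROUPS
from slco1b1.simulate import generate_cohort, qatari_preset, write_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORTS = RESULTS / "cohorts"
TABLES = RESULTS / "tables"

SEED = 11  # root seed for every analysis cohort


def ensure_cohort(preset: str) -> Path:
    """Simulate the preset cohort under results/cohorts/<preset> if absent."""
    out = COHORTS / preset
    if not (out / "cohort.vcf").exists():
        table, truth = generate_cohort(qatari_preset(preset, seed=SEED))
        write_cohort(table, truth, out)
    return out


def load_cohort(preset: str):
    """Read the preset cohort back through the VCF + metadata ingestion path."""
    d = ensure_cohort(preset)
    raw = read_vcf_genotypes(d / "cohort.vcf")
    mapping = read_sample_groups(d / "samples.tsv")
    table, _ = apply_sample_groups(raw, mapping, group_order=list(GROUPS))
    return table
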