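import json

import numpy as np
import pytest

from slco1b1.haplotypes import HAPLOTYPE_NAMES, two_locus_counts
from slco1b1.popgen import GenotypeCounts, hwe_exact_test
from slco1b1.reference import GROUPS, N_SAMPLES, PRINTED_HF_PCT
from slco1b1.simulate import (
    CohortConfig,
    GroupConfig,
    generate_cohort,
    qatari_preset,
    write_cohort,
)


def single_group(n, f, **kw):
    return CohortConfig(groups=(GroupConfig("g", n, f, **kw),), seed=0)


class TestGenerate:
    def test_monomorphic_wildtype(self):
        table, truth = generate_cohort(single_group(30, (1.0, 0.0, 0.0, 0.0)))
        assert all((s.dosage_388, s.dosage_521) == (0, 0) for s in table.samples)
        assert truth["haplotype_tallies"]["g"]["*1a"] == 60

    def test_full_inbreeding_no_heterozygotes(self):
        cfg = CohortConfig(
            groups=(GroupConfig("g", 400, (0.25, 0.25, 0.25, 0.25), inbreeding_f=1.0),), seed=2
        )
        table, _ = generate_cohort(cfg)
        assert all(s.dosage_388 != 1 and s.dosage_521 != 1 for s in table.samples)

    def test_truth_tallies_are_bookkeeping_identity(self):
        cfg = qatari_preset("hf-table", seed=5)
        table, truth = generate_cohort(cfg)
        for g in cfg.groups:
            tally = truth["haplotype_tallies"][g.label]
            assert sum(tally.values()) == 2 * g.n_samples
        # tallies agree with the per-sample pairs
        recount = {g.label: {h: 0 for h in HAPLOTYPE_NAMES} for g in cfg.groups}
        for s in table.samples:
            for h in truth["haplotype_pairs"][s.sample_id]:
                recount[s.group][h] += 1
        assert recount == truth["haplotype_tallies"]

    def test_missingness_rate(self):
        table, _ = generate_cohort(
            single_group(4000, (0.25, 0.25, 0.25, 0.25), missing_rate=0.1)
        )
        miss = sum(s.dosage_388 is None for s in table.samples) / len(table.samples)
        assert abs(miss - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 4000)

    def test_group_streams_independent_of_later_groups(self):
        g1 = GroupConfig("g1", 50, (0.25, 0.25, 0.25, 0.25))
        one, _ = generate_cohort(CohortConfig(groups=(g1,), seed=7))
        two, _ = generate_cohort(
            CohortConfig(groups=(g1, GroupConfig("g2", 50, (0.7, 0.1, 0.1, 0.1))), seed=7)
        )
        first = [(s.dosage_388, s.dosage_521) for s in one.samples]
        again = [(s.dosage_388, s.dosage_521) for s in two.samples if s.group == "g1"]
        assert first == again

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            GroupConfig("g", 10, (0.5, 0.5, 0.5, 0.5))


class TestWrite:
    def test_same_seed_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            cfg = qatari_preset("hf-table", seed=3)
            table, truth = generate_cohort(cfg)
            write_cohort(table, truth, tmp_path / d)
        assert (tmp_path / "a/cohort.vcf").read_bytes() == (tmp_path / "b/cohort.vcf").read_bytes()
        assert (tmp_path / "a/truth.json").read_bytes() == (tmp_path / "b/truth.json").read_bytes()

    def test_truth_json_roundtrips(self, sim_cohort):
        loaded = json.loads(sim_cohort["paths"]["truth"].read_text())
        assert loaded["haplotype_tallies"] == sim_cohort["truth"]["haplotype_tallies"]

    def test_vcf_records_sorted_by_position(self, sim_cohort):
        lines = [
            l for l in sim_cohort["paths"]["vcf"].read_text().splitlines() if not l.startswith("#")
        ]
        positions = [int(l.split("\t")[1]) for l in lines]
        assert positions == sorted(positions) and len(positions) == 2


class TestPresets:
    def test_group_sizes_match_study(self):
        for preset in ("hf-table", "maf-consistent"):
            cfg = qatari_preset(preset)
            assert [g.n_samples for g in cfg.groups] == [587, 387, 76]
            assert [g.label for g in cfg.groups] == list(GROUPS)

    def test_hf_table_bedouin_frequencies(self):
        cfg = qatari_preset("hf-table")
        bed = cfg.groups[0]
        assert np.allclose(bed.hap_freqs, (0.2368, 0.2930, 0.0358, 0.4344), atol=1e-9)

    def test_presets_on_simplex(self):
        for preset in ("hf-table", "maf-consistent"):
            for g in qatari_preset(preset).groups:
                f = np.asarray(g.hap_freqs)
                assert (f >= 0).all() and abs(f.sum() - 1) < 1e-9

    def test_maf_consistent_marginals(self):
        from slco1b1.reference import PRINTED_MAF, implied_521_frequency

        for g in qatari_preset("maf-consistent").groups:
            f1a, f1b, f5, f15 = g.hap_freqs
            assert f1b + f15 == pytest.approx(PRINTED_MAF["c.388A>G"][g.label], abs=1e-12)
            assert f5 + f15 == pytest.approx(implied_521_frequency(g.label), abs=1e-12)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="maf-consistent"):
            qatari_preset("bogus")


class TestHweCalibration:
    """Under random mating the exact test should reject at <= alpha; with
    inbreeding the heterozygote deficit should be detected at large n."""

    def test_null_rejection_rate_at_most_alpha(self):
        rejections = 0
        for seed in range(40):
            table, _ = generate_cohort(
                CohortConfig(groups=(GroupConfig("g", 500, (0.25, 0.25, 0.25, 0.25)),), seed=seed)
            )
            g = np.zeros(3, dtype=int)
            for s in table.samples:
                g[s.dosage_521] += 1
            rejections += hwe_exact_test(GenotypeCounts(*g)).p_value < 0.05
        # exact test is conservative: empirical size should not exceed alpha by
        # more than binomial noise on 40 replicates
        assert rejections / 40 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_inbreeding_power(self):
        rejections = 0
        for seed in range(10):
            table, _ = generate_cohort(
                CohortConfig(
                    groups=(GroupConfig("g", 1000, (0.25, 0.25, 0.25, 0.25), inbreeding_f=0.2),),
                    seed=seed,
                )
            )
            g = np.zeros(3, dtype=int)
            for s in table.samples:
                g[s.dosage_521] += 1
            rejections += hwe_exact_test(GenotypeCounts(*g)).p_value < 0.05
        assert rejections >= 9  # F=0.2 at n=1000 is essentially always detected
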