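import numpy as np
import pytest

from srnaome.annotate import annotate_collapsed
from srnaome.io import collapse, merge_collapsed, to_dna
from srnaome.preprocess import clean_reads, profile_library
from srnaome.simulate import (
    DEFAULT_HAIRPINS,
    DEFAULT_SPIKES,
    SimConfig,
    Spike,
    paired_embryo_config,
    simulate_pair,
)

LIBS = ("dormant", "germinated")


def _tiny_config(seed=3, n=3000):
    return paired_embryo_config(seed=seed, n_reads=n)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = simulate_pair(_tiny_config())
        b = simulate_pair(_tiny_config())
        for lib in LIBS:
            assert [(r.identifier, r.sequence) for r in a.reads[lib]] == [
                (r.identifier, r.sequence) for r in b.reads[lib]
            ]
        assert [(e.id, e.sequence) for e in a.catalog] == [
            (e.id, e.sequence) for e in b.catalog
        ]
        assert a.scaffolds == b.scaffolds

    def test_seed_changes_reads_not_structure(self):
        a = simulate_pair(_tiny_config(seed=3))
        b = simulate_pair(_tiny_config(seed=4))
        assert [r.sequence for r in a.reads["dormant"]] != [
            r.sequence for r in b.reads["dormant"]
        ]
        # expected (truth) shares are config properties, identical across seeds
        assert a.truth.expected_length_share == b.truth.expected_length_share
        assert a.truth.expected_category_share == b.truth.expected_category_share

    def test_recovered_shares_stable_across_seeds(self):
        sa = simulate_pair(paired_embryo_config(seed=5, n_reads=30_000))
        sb = simulate_pair(paired_embryo_config(seed=6, n_reads=30_000))
        for sim_a, sim_b in ((sa, sb),):
            for lib in LIBS:
                pa = profile_library(collapse([r.sequence for r in sim_a.reads[lib]], lib), lib)
                pb = profile_library(collapse([r.sequence for r in sim_b.reads[lib]], lib), lib)
                for length in pa.per_length.index:
                    diff = abs(
                        float(pa.share("redundant").get(length, 0))
                        - float(pb.share("redundant").get(length, 0))
                    )
                    assert diff < 0.015


class TestValidation:
    def test_invalid_probability_vector(self):
        cfg = paired_embryo_config()
        bad = dict(cfg.length_distribution)
        bad["dormant"] = {21: 0.5, 24: 0.4}  # sums to 0.9
        with pytest.raises(ValueError, match="probability"):
            SimConfig(
                seed=0,
                n_reads=cfg.n_reads,
                length_distribution=bad,
                category_mix=cfg.category_mix,
            )

    def test_unknown_category_rejected(self):
        cfg = paired_embryo_config()
        bad = {lib: {"lncRNA": 1.0} for lib in LIBS}
        with pytest.raises(ValueError, match="unknown"):
            SimConfig(
                seed=0,
                n_reads=cfg.n_reads,
                length_distribution=cfg.length_distribution,
                category_mix=bad,
            )

    def test_overfull_spike_mass_rejected(self):
        cfg = paired_embryo_config()
        spikes = (Spike("miRX", "UGACAGAAGAGAGUGAGCAC", 1_200_000.0, 0.0),)
        with pytest.raises(ValueError, match="background"):
            simulate_pair(
                SimConfig(
                    seed=0,
                    n_reads=cfg.n_reads,
                    length_distribution=cfg.length_distribution,
                    category_mix=cfg.category_mix,
                    mirna_spikes=spikes,
                    hairpin_loci=(),
                )
            )


class TestClosedLoop:
    def test_truth_manifest_covers_every_read(self, small_sim):
        for lib in LIBS:
            labels = small_sim.truth.read_labels[lib]
            assert len(labels) == len(small_sim.reads[lib])
            for read in small_sim.reads[lib]:
                assert read.sequence in small_sim.truth.sequence_category

    def test_annotation_recovers_truth_labels_exactly(self, small_sim):
        collapsed = merge_collapsed(
            *(
                collapse([r.sequence for r in small_sim.reads[lib]], lib)
                for lib in LIBS
            )
        )
        assignments = annotate_collapsed(collapsed, small_sim.catalog)
        mismatches = {
            seq: (assignments[seq].category, small_sim.truth.sequence_category[seq])
            for seq in collapsed
            if assignments[seq].category != small_sim.truth.sequence_category[seq]
        }
        assert mismatches == {}

    def test_all_reads_pass_default_cleaning(self, small_sim):
        for lib in LIBS:
            _, report = clean_reads(small_sim.reads[lib])
            assert report.clean_reads == len(small_sim.reads[lib])

    def test_star_reads_sit_on_scaffolds(self, small_sim):
        scaffolds = dict(small_sim.scaffolds)
        for _, row in small_sim.truth.loci.iterrows():
            scaffold = scaffolds[row["scaffold"]]
            assert row["mature"] in scaffold
            if row["with_star"]:
                assert row["star"] in scaffold


class TestFixedInputs:
    def test_hairpin_matures_far_from_spikes(self):
        def ham(a, b):
            return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else 99

        for h in DEFAULT_HAIRPINS:
            for s in DEFAULT_SPIKES:
                assert ham(to_dna(h.mature), to_dna(s.sequence)) > 2

    def test_spike_fold_changes_realized_in_expectation(self):
        sim = simulate_pair(_tiny_config())
        for _, row in sim.truth.spikes.iterrows():
            assert np.log2(row["tpm_dormant"] / row["tpm_germinated"]) == pytest.approx(
                row["log2fc"], abs=1e-9
            )

    def test_noise_perturbs_reads(self):
        cfg = _tiny_config()
        noisy = SimConfig(
            seed=cfg.seed,
            n_reads=cfg.n_reads,
            length_distribution=cfg.length_distribution,
            category_mix=cfg.category_mix,
            noise=0.2,
            redundancy_by_length=cfg.redundancy_by_length,
        )
        sim = simulate_pair(noisy)
        changed = sum(
            r.sequence not in sim.truth.sequence_category
            for r in sim.reads["dormant"]
        )
        assert changed > 0
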