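"""The generator: determinism, target-GC recovery, structure of outputs."""

import numpy as np
import pandas as pd
import pytest

from metagc.gc_metrics import build_gc_matrix, read_gc
from metagc.sequence_io import screen_reads
from metagc.synthetic_community import (
    ConfigurationError,
    EnvironmentProfile,
    PhylumProfile,
    SyntheticConfig,
    default_phylum_profiles,
    generate_collection,
    sample_read_gc,
    simulate_gc_matrix,
)


class TestValidation:
    def test_degenerate_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            PhylumProfile("P", 0.0, 5.0)
        with pytest.raises(ConfigurationError):
            EnvironmentProfile("e", n_samples=0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(phyla=[], environments=[EnvironmentProfile("e", 1)],
                            reads_per_sample=10, seed=1)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                phyla=[PhylumProfile("P", 50, 5), PhylumProfile("P", 60, 5)],
                environments=[EnvironmentProfile("e", 1)],
                reads_per_sample=10, seed=1,
            )

    def test_default_profiles_carry_survey_means(self):
        profiles = {p.name: p for p in default_phylum_profiles()}
        assert profiles["Actinobacteria"].mean_gc == 62.1
        assert profiles["Deinococcus-Thermus"].mean_gc == 64.4
        assert profiles["Tenericutes"].mean_gc == 32.2
        assert profiles["Spirochaetes"].sd_gc == 11.8
        assert profiles["Chlamydiae"].sd_gc == 5.5
        assert len(profiles) == 10


class TestSampleReadGC:
    def test_degenerate_sd_returns_mean(self, rng):
        assert sample_read_gc(PhylumProfile("P", 50, 0), 0.0, rng) == 0.50

    def test_deterministic_shift_with_offset(self, rng):
        g = sample_read_gc(PhylumProfile("P", 62.1, 0), 5.0, rng)
        assert g == pytest.approx(0.671)

    def test_clipped_into_unit_band(self, rng):
        assert sample_read_gc(PhylumProfile("P", 95, 0), 50.0, rng) == 0.99
        assert sample_read_gc(PhylumProfile("P", 5, 0), -50.0, rng) == 0.01

    def test_mean_recovery_over_many_draws(self, rng):
        profile = PhylumProfile("P", 50, 10)
        draws = [sample_read_gc(profile, 0.0, rng) * 100 for _ in range(10_000)]
        # 4 standard errors of the mean: 4 * 10/sqrt(10000) = 0.4
        assert np.mean(draws) == pytest.approx(50.0, abs=0.4)


def _tiny_config(seed=7, **kw):
    defaults = dict(
        phyla=[PhylumProfile("P", 50.0, 5.0, coding_fraction=0.3)],
        environments=[EnvironmentProfile("e", n_samples=1)],
        reads_per_sample=10,
        read_length=100,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerateCollection:
    def test_fixed_seed_is_byte_identical_on_disk(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_collection(_tiny_config()).write(d1)
        generate_collection(_tiny_config()).write(d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_different_seeds_differ(self):
        r1 = generate_collection(_tiny_config(seed=1)).reads
        r2 = generate_collection(_tiny_config(seed=2)).reads
        assert [x.sequence for x in r1] != [x.sequence for x in r2]

    def test_pooled_gc_matches_target(self):
        cfg = SyntheticConfig(
            phyla=[PhylumProfile("F", 43.1, 0.0)],
            environments=[EnvironmentProfile("e", n_samples=5)],
            reads_per_sample=10_000,
            read_length=100,
            confidence_noise=0.0,
            seed=13,
        )
        col = generate_collection(cfg)
        bases = gc = 0
        for r in col.reads:
            gc += r.sequence.count("G") + r.sequence.count("C")
            bases += len(r.sequence)
        assert gc / bases == pytest.approx(0.431, abs=0.005)

    def test_every_read_appears_exactly_once_in_truth(self, small_collection):
        _, col = small_collection
        truth_ids = col.truth.reads["read_id"]
        assert not truth_ids.duplicated().any()
        assert set(truth_ids) == {r.read_id for r in col.reads}

    def test_annotations_reference_emitted_reads_within_bounds(self, small_collection):
        _, col = small_collection
        by_id = {r.read_id: r for r in col.reads}
        assert len(col.annotations) > 0
        for ann in col.annotations.itertuples():
            read = by_id[ann.read_id]
            assert 0 <= ann.start < ann.end <= len(read.sequence)
            assert ann.strand in "+-"

    def test_confidence_noise_fraction_reaches_screening(self):
        cfg = _tiny_config(reads_per_sample=4000, confidence_noise=0.25)
        col = generate_collection(cfg)
        kept, removals = screen_reads(col.reads)
        frac = removals["confidence"] / len(col.reads)
        assert frac == pytest.approx(0.25, abs=0.03)
        assert all(r.confidence >= 0.8 for r in kept)

    def test_per_phylum_mean_recovery_without_offset(self):
        cfg = SyntheticConfig(
            phyla=[PhylumProfile("A", 62.1, 8.0), PhylumProfile("B", 43.1, 8.0)],
            environments=[EnvironmentProfile("e", n_samples=2)],
            reads_per_sample=3000,
            read_length=150,
            confidence_noise=0.0,
            seed=21,
        )
        col = generate_collection(cfg)
        m = build_gc_matrix(col.reads, min_reads=10)
        for sample in m.samples:
            for phylum, target in (("A", 62.1), ("B", 43.1)):
                n = m.n.loc[sample, phylum]
                se = 8.0 / np.sqrt(n)
                assert m.mean.loc[sample, phylum] == pytest.approx(target, abs=3 * se)

    def test_offset_identifiability_between_environments(self):
        cfg = SyntheticConfig(
            phyla=[PhylumProfile("A", 50.0, 6.0), PhylumProfile("B", 60.0, 6.0)],
            environments=[
                EnvironmentProfile("lo", n_samples=10, gc_offset=-5.0),
                EnvironmentProfile("hi", n_samples=10, gc_offset=5.0),
            ],
            reads_per_sample=1000,
            read_length=120,
            confidence_noise=0.0,
            seed=33,
        )
        col = generate_collection(cfg)
        m = build_gc_matrix(col.reads)
        env = {s.sample_id: s.environment for s in col.samples}
        hi = [s for s in m.samples if env[s] == "hi"]
        lo = [s for s in m.samples if env[s] == "lo"]
        for phylum in m.phyla:
            diff = m.mean.loc[hi, phylum].mean() - m.mean.loc[lo, phylum].mean()
            n_cell = m.n.loc[:, phylum].min()
            se_diff = 6.0 / np.sqrt(n_cell) * np.sqrt(2 / 10)
            assert diff == pytest.approx(10.0, abs=3 * se_diff)


class TestSimulateGcMatrix:
    def test_matches_generator_distribution_moments(self):
        """The shortcut's cell means must share the read-level generator's
        mean and spread (checked on 30 replicate cells each way)."""
        read_level, matrix_level = [], []
        for seed in range(30):
            cfg = SyntheticConfig(
                phyla=[PhylumProfile("P", 50.0, 8.0)],
                environments=[EnvironmentProfile("e", n_samples=1)],
                reads_per_sample=100,
                read_length=150,
                confidence_noise=0.0,
                seed=seed,
            )
            col = generate_collection(cfg)
            m = build_gc_matrix(col.reads)
            read_level.append(m.mean.iloc[0, 0])
            m2, _, _ = simulate_gc_matrix(cfg)
            matrix_level.append(m2.mean.iloc[0, 0])
        # identical model: same mean (SE ~ 0.8/sqrt(30)) and similar SD
        assert np.mean(read_level) == pytest.approx(np.mean(matrix_level), abs=0.6)
        assert np.std(matrix_level) == pytest.approx(0.8, abs=0.4)

    def test_abundance_rows_sum_to_one(self, gut_like_matrix):
        _, abundance, _ = gut_like_matrix
        assert np.allclose(abundance.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism(self):
        cfg = _tiny_config(reads_per_sample=200)
        m1, a1, o1 = simulate_gc_matrix(cfg)
        m2, a2, o2 = simulate_gc_matrix(cfg)
        pd.testing.assert_frame_equal(m1.mean, m2.mean)
        pd.testing.assert_frame_equal(a1, a2)
        assert o1 == o2
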