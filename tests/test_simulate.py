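"""The synthetic cohort generator: CDR3 draws, Zipf counts, cohort structure."""

import json

import numpy as np
import pytest

import tcrep
from tcrep import (
    AMINO_ACIDS,
    SimulationConfig,
    generate_cohort,
    random_cdr3,
    write_cohort,
    zipf_counts,
)
from tcrep.simulate import read_cohort_manifest
from tcrep.pipeline import load_repertoires, summarize_samples
from tcrep.io import read_repertoire


class TestRandomCdr3:
    def test_fixed_length_and_anchors(self, rng):
        for _ in range(50):
            s = random_cdr3(rng, (9, 9))
            assert len(s) == 9 and s[0] == "C" and s[-1] == "F"

    def test_deterministic_under_seed(self):
        a = [random_cdr3(np.random.default_rng(3)) for _ in range(1)]
        b = [random_cdr3(np.random.default_rng(3)) for _ in range(1)]
        assert a == b

    def test_alphabet_closure(self, rng):
        alphabet = set(AMINO_ACIDS)
        for _ in range(10_000):
            assert set(random_cdr3(rng, (9, 18))) <= alphabet

    def test_short_range_rejected(self, rng):
        with pytest.raises(ValueError):
            random_cdr3(rng, (2, 5))


class TestZipfCounts:
    def test_forced_minimum_when_t_equals_u(self, rng):
        assert (zipf_counts(4, 4, 2.0, rng) == 1).all()

    def test_counts_sum_exactly_and_positive(self, rng):
        for alpha in (0.0, 0.7, 2.5):
            counts = zipf_counts(137, 5000, alpha, rng)
            assert counts.sum() == 5000
            assert (counts >= 1).all()

    def test_alpha_zero_concentrates_around_uniform(self):
        # multinomial sd of each count is ~sqrt(t/u) = 10; ±4·sqrt(100) band
        for seed in range(20):
            counts = zipf_counts(10, 1000, 0.0, np.random.default_rng(seed))
            assert (np.abs(counts - 100) <= 40).all()

    def test_large_alpha_ranks_leading_clone_first(self):
        wins = sum(
            zipf_counts(1000, 100_000, 2.0, np.random.default_rng(s))[0]
            > zipf_counts(1000, 100_000, 2.0, np.random.default_rng(s))[99]
            for s in range(100)
        )
        assert wins >= 99

    def test_t_below_u_rejected(self, rng):
        with pytest.raises(ValueError):
            zipf_counts(10, 9, 1.0, rng)


class TestGenerateCohort:
    def test_structure_and_invariants(self, small_sim_config):
        cohort = generate_cohort(small_sim_config)
        assert len(cohort.repertoires) == small_sim_config.n_subjects * 2
        for rep in cohort.repertoires:
            assert rep.n_unique == small_sim_config.unique_clonotypes_per_sample
            assert rep.total_templates == small_sim_config.total_templates_per_sample
            assert rep.tissue in ("tumor", "ntl")
        assert len(cohort.pairing()) == small_sim_config.n_subjects

    def test_reproducible_from_seed(self, small_sim_config):
        a = generate_cohort(small_sim_config)
        b = generate_cohort(small_sim_config)
        for ra, rb in zip(a.repertoires, b.repertoires):
            assert ra.counts.equals(rb.counts)

    def test_full_sharing_uniform_counts_gives_moi_one(self):
        config = SimulationConfig(
            n_subjects=3, unique_clonotypes_per_sample=50,
            total_templates_per_sample=50, public_pool_size=50,
            powerlaw_exponent_tumor=0.0, public_fraction_tumor=1.0,
            public_fraction_ntl=0.0, within_subject_fraction=0.0, seed=5,
        )
        cohort = generate_cohort(config)
        tumors = cohort.by_tissue("tumor")
        for i in range(len(tumors)):
            for j in range(i + 1, len(tumors)):
                assert tcrep.morisita_overlap(tumors[i], tumors[j]) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_no_sharing_gives_cross_individual_moi_zero(self):
        config = SimulationConfig(
            n_subjects=3, unique_clonotypes_per_sample=100,
            total_templates_per_sample=500, public_pool_size=100,
            public_fraction_tumor=0.0, public_fraction_ntl=0.0,
            within_subject_fraction=0.0, seed=2,
        )
        cohort = generate_cohort(config)
        reps = cohort.repertoires
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                if reps[i].subject_id != reps[j].subject_id:
                    assert tcrep.morisita_overlap(reps[i], reps[j]) == 0.0

    def test_within_subject_pool_links_paired_samples(self, small_sim_config):
        cohort = generate_cohort(small_sim_config)
        for subject, (tid, nid) in cohort.pairing().items():
            tumor = next(r for r in cohort.repertoires if r.sample_id == tid)
            ntl = next(r for r in cohort.repertoires if r.sample_id == nid)
            assert tcrep.shared_clonotypes(tumor, ntl).n_shared > 0

    def test_provenance_labels_cover_every_clonotype(self, small_sim_config):
        cohort = generate_cohort(small_sim_config)
        for rep in cohort.repertoires:
            origins = cohort.provenance[rep.sample_id]
            assert set(origins) == set(rep.counts.index)
            assert all(
                o == "subject" or o == "private" or o.startswith("public:")
                for o in origins.values()
            )

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(public_fraction_tumor=0.99,
                             within_subject_fraction=0.05).validate()

    def test_pool_smaller_than_request_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(public_pool_size=10).validate()


class TestWriteCohort:
    def test_file_count_and_manifest(self, tmp_path):
        config = SimulationConfig(
            n_subjects=2, unique_clonotypes_per_sample=30,
            total_templates_per_sample=120, public_pool_size=50, seed=3,
        )
        manifest_path = write_cohort(generate_cohort(config), tmp_path)
        tsvs = sorted(p.name for p in tmp_path.glob("*.tsv"))
        assert len(tsvs) == 4
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["samples"]) == 4
        assert manifest["config"]["seed"] == 3

    def test_round_trip_reproduces_diversity_summaries(self, tmp_path,
                                                       small_sim_config):
        cohort = generate_cohort(small_sim_config)
        manifest_path = write_cohort(cohort, tmp_path)
        _, samples = read_cohort_manifest(manifest_path)
        for rep in cohort.repertoires:
            row = samples[samples.sample_id == rep.sample_id].iloc[0]
            back = read_repertoire(row.file, sample_id=rep.sample_id,
                                   subject_id=row.subject_id, tissue=row.tissue)
            assert back.counts.sort_index().equals(rep.counts.sort_index())
            assert tcrep.summarize(back).clonality == pytest.approx(
                tcrep.summarize(rep).clonality, abs=1e-12
            )

    def test_same_seed_rewrites_byte_identical_tsvs(self, tmp_path):
        config = SimulationConfig(
            n_subjects=2, unique_clonotypes_per_sample=40,
            total_templates_per_sample=200, public_pool_size=60, seed=9,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(config), d1)
        write_cohort(generate_cohort(config), d2)
        for p1 in sorted(d1.glob("*.tsv")):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()


class TestParameterRecovery:
    def test_clonality_monotone_in_alpha(self):
        """Mean clonality over seeds increases with the Zipf exponent, and is
        tiny at alpha=0 for a 1,000-clone repertoire."""
        alphas = (0.0, 0.5, 1.0, 2.0)
        means = []
        for alpha in alphas:
            vals = []
            for seed in range(20):
                counts = zipf_counts(1000, 10_000, alpha,
                                     np.random.default_rng(seed))
                rep = tcrep.Repertoire.from_counts(
                    {f"K{i}": int(c) for i, c in enumerate(counts)}
                )
                vals.append(tcrep.clonality(rep))
            means.append(np.mean(vals))
        assert means[0] < 0.01
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_moi_monotone_in_public_fraction(self):
        """Mean within-cohort MOI increases with the public-pool fraction f."""
        means = []
        for f in (0.0, 0.1, 0.3, 0.6, 1.0):
            vals = []
            for seed in range(20):
                config = SimulationConfig(
                    n_subjects=3, unique_clonotypes_per_sample=200,
                    total_templates_per_sample=2000, public_pool_size=300,
                    public_fraction_tumor=f, public_fraction_ntl=0.0,
                    within_subject_fraction=0.0,
                    powerlaw_exponent_tumor=1.0, seed=seed,
                )
                tumors = generate_cohort(config).by_tissue("tumor")
                vals.append(
                    tcrep.pairwise_overlap_matrix(tumors).offdiagonal().mean()
                )
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))
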