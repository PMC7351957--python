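"""Synthetic-data generators: determinism, invariants, ground-truth hooks."""

import numpy as np
import pandas as pd
import pytest

from phylostage import (
    ConfigurationError,
    ProteomeParams,
    ReadParams,
    SimulationConfig,
    anchored_one_to_one,
    best_hits,
    expdist,
    flat_profile,
    hourglass_profile,
    reciprocal_best_pairs,
    simulate_expression_dataset,
    simulate_proteome_set,
    simulate_reads,
    write_fasta,
)

TWO_SPECIES = dict(
    tree_newick="(Sp:1,Lv:1);",
    stages_per_species={sp: [f"s{i}" for i in range(6)] for sp in ["Sp", "Lv"]},
)


def mean_matched_stage_expdist(tables):
    """Average expdist between species at matched stages (replicate means)."""
    species = list(tables)
    stages = tables[species[0]].stages
    vals = []
    for si, stage_a in enumerate(stages):
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                ta, tb = tables[species[i]], tables[species[j]]
                vals.append(
                    (si, expdist(ta.stage_mean(ta.stages[si]), tb.stage_mean(tb.stages[si])))
                )
    return vals


class TestExpressionSimulation:
    def test_seeded_determinism(self, small_config):
        t1, g1 = simulate_expression_dataset(small_config)
        t2, g2 = simulate_expression_dataset(small_config)
        for sp in t1:
            pd.testing.assert_frame_equal(t1[sp].data, t2[sp].data)
        assert g1 == g2

    def test_zero_perturbation_identical_profiles(self):
        cfg = SimulationConfig(
            seed=2, n_groups=50, n_replicates=2, noise_sd=0.0, dropout_rate=0.0,
            divergence_profile=flat_profile(0.0), **TWO_SPECIES,
        )
        tables, _ = simulate_expression_dataset(cfg)
        a, b = tables["Sp"], tables["Lv"]
        for si, stage in enumerate(a.stages):
            np.testing.assert_allclose(
                a.stage_mean(stage), b.stage_mean(b.stages[si]), rtol=1e-9
            )

    def test_hourglass_minimizes_mid_stage_expdist(self, four_species_stages):
        # oracle: expdist computed directly on the generated tables must dip
        # at mid stages when the divergence profile has its minimum there
        cfg = SimulationConfig(
            seed=7, n_groups=600, n_replicates=2, dropout_rate=0.0,
            stages_per_species=four_species_stages,
        )
        tables, truth = simulate_expression_dataset(cfg)
        vals = mean_matched_stage_expdist(tables)
        stages = four_species_stages["Lv"]
        by_stage = [np.mean([d for si, d in vals if si == k]) for k in range(len(stages))]
        argmin = stages[int(np.argmin(by_stage))]
        assert argmin in truth.true_conserved_stages["Lv"]

    def test_tpm_columns_rescaled(self, small_config):
        tables, _ = simulate_expression_dataset(small_config)
        for t in tables.values():
            totals = t.data.sum(axis=0).to_numpy()
            np.testing.assert_allclose(totals, 1.0e6, rtol=1e-6)
            assert (t.data.to_numpy() >= 0).all()

    def test_divergence_scaling_monotonicity(self):
        # scaling the profile by c > 1 must not decrease the expected
        # stage-matched cross-species expdist (averaged over seeds)
        def mean_dist(scale, seed):
            cfg = SimulationConfig(
                seed=seed, n_groups=120, n_replicates=1, dropout_rate=0.0,
                divergence_profile=flat_profile(0.3 * scale), **TWO_SPECIES,
            )
            tables, _ = simulate_expression_dataset(cfg)
            return np.mean([d for _, d in mean_matched_stage_expdist(tables)])

        seeds = range(20)
        base = np.mean([mean_dist(1.0, s) for s in seeds])
        scaled = np.mean([mean_dist(2.0, s) for s in seeds])
        assert scaled >= base

    def test_dropout_removes_groups_from_truth_and_table(self):
        cfg = SimulationConfig(
            seed=9, n_groups=200, dropout_rate=0.3, **TWO_SPECIES,
        )
        tables, truth = simulate_expression_dataset(cfg)
        for sp, table in tables.items():
            present = {g for g, m in truth.true_ortholog_map.items() if sp in m}
            assert set(table.groups) == present
            assert len(present) < 200

    def test_unknown_species_rejected(self):
        cfg = SimulationConfig(
            tree_newick="(Sp:1,Lv:1);",
            stages_per_species={"Sp": ["s0"], "Xx": ["s0"]},
        )
        with pytest.raises(ConfigurationError):
            simulate_expression_dataset(cfg)


class TestProteomeSimulation:
    def _rbbh_sets(self, prot, reference="Anj"):
        others = [sp for sp in prot.sequences if sp != reference]
        pair_maps = {
            sp: reciprocal_best_pairs(
                best_hits(prot.hit_tables[(reference, sp)]),
                best_hits(prot.hit_tables[(sp, reference)]),
            )
            for sp in others
        }
        return anchored_one_to_one(reference, pair_maps)

    def test_zero_mutation_recovers_truth(self):
        cfg = SimulationConfig(
            seed=3, n_groups=40,
            proteome=ProteomeParams(mutation_rate=0.0, decoy_fraction=0.0),
        )
        prot = simulate_proteome_set(cfg)
        sets = self._rbbh_sets(prot)
        assert len(sets) == 40
        for s in sets:
            gid = s.reference_gene.split("_", 1)[1]
            assert s.genes == {sp: f"{sp}_{gid}" for sp in prot.sequences}

    def test_decoy_paralogs_do_not_break_recovery(self):
        cfg = SimulationConfig(
            seed=4, n_groups=40,
            proteome=ProteomeParams(mutation_rate=0.03, decoy_fraction=0.25),
        )
        prot = simulate_proteome_set(cfg)
        sets = self._rbbh_sets(prot)
        assert len(sets) == 40
        for s in sets:
            gid = s.reference_gene.split("_", 1)[1]
            assert all(g == f"{sp}_{gid}" for sp, g in s.genes.items())

    def test_fasta_bytes_deterministic(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_groups=10)
        p1, p2 = simulate_proteome_set(cfg), simulate_proteome_set(cfg)
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(p1.sequences["Lv"], f1)
        write_fasta(p2.sequences["Lv"], f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestReadSimulation:
    def test_read_count_arithmetic(self):
        cfg = SimulationConfig(
            seed=1, read_params=ReadParams(genome_length=10_000, coverage=30, read_length=100),
        )
        rs = simulate_reads(cfg)
        assert len(rs.reads) == 3000
        assert rs.true_genome_size == 10_000

    def test_error_free_reads_are_substrings(self):
        cfg = SimulationConfig(
            seed=2,
            read_params=ReadParams(genome_length=5_000, coverage=5, read_length=80,
                                   error_rate=0.0),
        )
        rs = simulate_reads(cfg)
        for _, seq, _ in rs.reads[:200]:
            assert seq in rs.genome

    def test_read_longer_than_genome_rejected(self):
        cfg = SimulationConfig(
            read_params=ReadParams(genome_length=50, read_length=100),
        )
        with pytest.raises(ConfigurationError):
            simulate_reads(cfg)
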