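import numpy as np
import pytest

from pirank.data_io import read_associations, read_fasta, read_ontology
from pirank.disease_similarity import disease_similarity_matrix
from pirank.sequence_similarity import normalized_similarity, similarity_matrix
from pirank.synthetic_data import (SyntheticConfig, disease_terms, family_of,
                                   generate_associations, generate_benchmark,
                                   generate_dataset, generate_ontology,
                                   generate_sequences)


class TestSequences:
    def test_zero_mutation_rate_gives_identical_family_members(self):
        config = SyntheticConfig(n_families=4, members_per_family=3,
                                 mutation_rate=0.0, seed=1)
        seqs = generate_sequences(config)
        for f in range(4):
            family = [s for i, s in zip(seqs.ids, seqs.sequences)
                      if family_of(i) == f]
            assert len(set(family)) == 1
            assert normalized_similarity(family[0], family[1]) == 1.0

    def test_lengths_within_configured_range(self):
        seqs = generate_sequences(SyntheticConfig(seed=2))
        assert all(24 <= len(s) <= 31 for s in seqs.sequences)

    def test_fixed_seed_reproduces_identical_fasta_bytes(self, tmp_path):
        config = SyntheticConfig(n_families=5, members_per_family=4, seed=3)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        generate_sequences(config).write_fasta(p1)
        generate_sequences(config).write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestOntology:
    def test_depth_one_tree_is_root_plus_leaves(self):
        dag = generate_ontology(SyntheticConfig(dag_depth=1, dag_branching=3))
        assert len(dag.roots) == 1
        assert len(dag.leaves) == 3
        assert len(dag.nodes) == 4

    @pytest.mark.parametrize("depth,branching", [(1, 2), (2, 3), (3, 2)])
    def test_uniform_node_count(self, depth, branching):
        dag = generate_ontology(SyntheticConfig(dag_depth=depth,
                                                dag_branching=branching))
        assert len(dag.nodes) == sum(branching ** d for d in range(depth + 1))

    def test_default_shape_has_20_leaf_diseases_in_5_subtrees(self):
        config = SyntheticConfig()
        dag = generate_ontology(config)
        assert len(dag.leaves) == 20
        assert sum(1 for n in dag.children(dag.roots[0])) == 5

    def test_same_subtree_leaves_are_semantically_closer(self):
        config = SyntheticConfig()
        dag = generate_ontology(config)
        diseases = disease_terms(dag)
        sd = disease_similarity_matrix(dag, diseases).values
        # first 4 leaves share a parent; leaf 5 sits in another subtree
        within = sd[0, 1]
        across = sd[0, 5]
        assert within > across


class TestAssociations:
    def test_deterministic_block_structure_at_extreme_probabilities(self):
        config = SyntheticConfig(n_families=4, members_per_family=3,
                                 dag_depth=2, dag_branching=(4, 2),
                                 n_disease_clusters=4, p_in=1.0, p_out=0.0,
                                 seed=5)
        seqs, dag, assoc = generate_dataset(config)
        for i, sid in enumerate(seqs.ids):
            cluster = family_of(sid) % 4
            for j in range(8):
                expected = 1 if j // 2 == cluster else 0
                assert assoc.labels[i, j] == expected

    def test_negative_control_rate_is_uniform(self):
        config = SyntheticConfig(n_families=6, members_per_family=5,
                                 p_in=0.4, p_out=0.4, seed=6)
        _, _, assoc = generate_dataset(config)
        rate = assoc.labels.mean()
        assert rate == pytest.approx(0.4, abs=0.06)

    def test_positive_count_matches_binomial_expectation(self):
        config = SyntheticConfig(n_families=10, members_per_family=5,
                                 dag_depth=2, dag_branching=(5, 4),
                                 n_disease_clusters=5)
        counts = []
        n_in = n_out = 0
        for seed in range(20):
            cfg = SyntheticConfig(**{**config.__dict__, "seed": seed})
            _, _, assoc = generate_dataset(cfg)
            counts.append(assoc.n_positives)
        n_pairs = 50 * 20
        n_in = 50 * 4          # 4 in-cluster diseases per piRNA
        n_out = n_pairs - n_in
        mean = n_in * cfg.p_in + n_out * cfg.p_out
        sigma = np.sqrt(n_in * cfg.p_in * (1 - cfg.p_in)
                        + n_out * cfg.p_out * (1 - cfg.p_out))
        assert abs(np.mean(counts) - mean) < 3 * sigma


def test_planted_families_recoverable_from_sequence_similarity():
    """Same-family similarity exceeds cross-family similarity for >= 95% of
    sampled pairs under the default mutation rate."""
    seqs, _, _ = generate_dataset(SyntheticConfig(seed=0))
    sp = similarity_matrix(seqs).values
    fams = np.array([family_of(i) for i in seqs.ids])
    rng = np.random.default_rng(0)
    wins = 0
    n_samples = 400
    for _ in range(n_samples):
        f = rng.integers(fams.max() + 1)
        members = np.nonzero(fams == f)[0]
        others = np.nonzero(fams != f)[0]
        a, b = rng.choice(members, size=2, replace=False)
        c = rng.choice(others)
        wins += sp[a, b] > sp[a, c]
    assert wins / n_samples >= 0.95


class TestBenchmarkFiles:
    def test_written_files_reload_consistently(self, tmp_path):
        config = SyntheticConfig(n_families=6, members_per_family=4, seed=9)
        paths = generate_benchmark(config, tmp_path / "bench")
        seqs = read_fasta(paths["sequences"])
        dag = read_ontology(paths["ontology"], dialect="edge-tsv")
        assoc = read_associations(paths["associations"], seqs, dag)
        ref_seqs, ref_dag, ref_assoc = generate_dataset(config)
        assert seqs.ids == ref_seqs.ids
        assert seqs.sequences == ref_seqs.sequences
        assert set(dag.edges) == set(ref_dag.edges)
        assert assoc.n_positives == ref_assoc.n_positives
        manifest = paths["manifest"].read_text()
        assert "seed=9" in manifest

    def test_default_config_writes_and_loads_quickly(self, tmp_path):
        import time

        start = time.time()
        paths = generate_benchmark(SyntheticConfig(), tmp_path / "full")
        read_fasta(paths["sequences"])
        assert time.time() - start < 5.0

    def test_generation_is_byte_reproducible(self, tmp_path):
        config = SyntheticConfig(n_families=4, members_per_family=3, seed=11)
        p1 = generate_benchmark(config, tmp_path / "one")
        p2 = generate_benchmark(config, tmp_path / "two")
        for key in ("sequences", "ontology", "associations"):
            assert p1[key].read_bytes() == p2[key].read_bytes()


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(p_in=0.1, p_out=0.5)
    with pytest.raises(ValueError):
        SyntheticConfig(mutation_rate=1.0)
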