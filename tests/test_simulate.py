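"""The synthetic pan-genome generator: family structure, divergence model,
determinism, and truth-table consistency."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from panstrep import (
    SimulationParams,
    expected_pairwise_identity,
    mutate_sequence,
    simulate_pangenome,
)
from panstrep.simulate import random_sequence, simulate_genome_fasta


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMutateSequence:
    def test_zero_rate_is_identity(self):
        assert mutate_sequence("ACGT", 0.0, seed=1) == "ACGT"

    def test_empty_sequence_passes_through(self):
        assert mutate_sequence("", 0.5, seed=1) == ""

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.5])
    def test_invalid_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", rate, seed=1)

    def test_substitution_count_matches_binomial(self):
        # Hamming distance ~ Binomial(n, rate): check within 3 s.d.
        n, rate = 10_000, 0.1
        seq = "A" * n
        mutated = mutate_sequence(seq, rate, seed=7)
        dist = sum(a != b for a, b in zip(seq, mutated))
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(dist - n * rate) <= 3 * sd

    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=200),
        rate=st.floats(min_value=0.0, max_value=0.9),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_length_alphabet_and_determinism(self, seq, rate, seed):
        out = mutate_sequence(seq, rate, seed)
        assert len(out) == len(seq)
        assert set(out) <= set("ACGT")
        assert out == mutate_sequence(seq, rate, seed)


class TestSimulateParams:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_strains=0), "n_strains"),
            (dict(n_core=-1), "n_core"),
            (dict(n_specific_per_strain=-2), "n_specific_per_strain"),
            (dict(divergence=1.0), "divergence"),
            (dict(n_strains=3, dispensable_spec=((1, 3),)), "strains_present"),
            (dict(n_strains=3, dispensable_spec=((1, 1),)), "strains_present"),
            (dict(gene_length_range=(0, 10)), "gene_length_range"),
            (dict(alphabet="rna"), "alphabet"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SimulationParams(**kwargs)


class TestSimulatePangenome:
    def test_zero_divergence_core_members_identical(self):
        params = SimulationParams(
            n_strains=3, n_core=5, dispensable_spec=(), n_specific_per_strain=2,
            gene_length_range=(150, 300), divergence=0.0, seed=1,
        )
        strains, truth = simulate_pangenome(params)
        assert all(len(s) == 7 for s in strains)  # 5 core + 2 specific
        by_family = {}
        for strain in strains:
            for gene_id, seq in strain.genes:
                family, _ = truth.gene_to_family[gene_id]
                by_family.setdefault(family, set()).add(seq)
        core_families = [f for f, p in truth.family_presence.items() if len(p) == 3]
        assert len(core_families) == 5
        for family in core_families:
            assert len(by_family[family]) == 1  # byte-identical members

    def test_seed_determinism(self):
        params = SimulationParams(
            n_strains=3, n_core=4, n_specific_per_strain=1, divergence=0.2,
            gene_length_range=(150, 500), paralog_rate=0.3, seed=9,
        )
        a, truth_a = simulate_pangenome(params)
        b, truth_b = simulate_pangenome(params)
        assert [s.genes for s in a] == [s.genes for s in b]
        assert truth_a.gene_to_family == truth_b.gene_to_family

    def test_core_pair_identity_matches_substitution_model(self):
        # mean pairwise identity of core pairs within 3 s.d. of the closed form
        d, length, n_core = 0.05, 300, 10
        params = SimulationParams(
            n_strains=2, n_core=n_core, n_specific_per_strain=0,
            gene_length_range=(length, length), divergence=d, seed=21,
        )
        strains, truth = simulate_pangenome(params)
        expected = expected_pairwise_identity(d, "nucleotide")
        identities = []
        genes_a = dict((truth.gene_to_family[g][0], s) for g, s in strains[0].genes)
        genes_b = dict((truth.gene_to_family[g][0], s) for g, s in strains[1].genes)
        for family in genes_a:
            identities.append(_identity(genes_a[family], genes_b[family]))
        mean_identity = np.mean(identities)
        se = (expected * (1 - expected) / (length * n_core)) ** 0.5
        assert abs(mean_identity - expected) <= 3 * se

    def test_truth_table_presence_consistency(self):
        params = SimulationParams(
            n_strains=4, n_core=3, dispensable_spec=((2, 2), (1, 3)),
            n_specific_per_strain=2, gene_length_range=(150, 300),
            divergence=0.1, paralog_rate=0.25, seed=5,
        )
        strains, truth = simulate_pangenome(params)
        # every emitted gene appears exactly once in the truth table
        emitted = [g for s in strains for g, _ in s.genes]
        assert sorted(emitted) == sorted(truth.gene_to_family)
        # presence vectors match the genes actually emitted
        observed = {}
        for strain in strains:
            for gene_id, _ in strain.genes:
                family, strain_id = truth.gene_to_family[gene_id]
                assert strain_id == strain.strain_id
                observed.setdefault(family, set()).add(strain_id)
        assert {f: frozenset(p) for f, p in observed.items()} == truth.family_presence
        # core families are present in all strains
        core = [f for f, p in truth.family_presence.items() if len(p) == 4]
        assert len(core) == 3
        assert truth.expected_partition() == (3, 3, 8)

    def test_paralogs_share_family_id(self):
        params = SimulationParams(
            n_strains=2, n_core=10, n_specific_per_strain=0,
            gene_length_range=(150, 200), divergence=0.0, paralog_rate=1.0, seed=2,
        )
        strains, truth = simulate_pangenome(params)
        for strain in strains:
            assert len(strain) == 20  # every family duplicated
        families = {truth.gene_to_family[g][0] for s in strains for g, _ in s.genes}
        assert len(families) == 10


class TestGenomeFasta:
    def test_gene_coordinates_recover_gene_sequences(self):
        params = SimulationParams(
            n_strains=1, n_core=0, n_specific_per_strain=5,
            gene_length_range=(150, 300), seed=3,
        )
        strains, _ = simulate_pangenome(params)
        genome, coords = simulate_genome_fasta(strains[0], seed=77)
        genes = dict(strains[0].genes)
        for gene_id, start, end in coords:
            assert genome[start - 1 : end] == genes[gene_id]

    def test_deterministic_for_seed(self):
        params = SimulationParams(n_strains=1, n_core=2, n_specific_per_strain=0, seed=4)
        strains, _ = simulate_pangenome(params)
        assert simulate_genome_fasta(strains[0], seed=5) == simulate_genome_fasta(strains[0], seed=5)
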