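"""Gene-pool accretion, the core/dispensable/specific partition, and
agreement with ground truth and a brute-force clustering oracle."""

import itertools

import pytest

from panstrep import (
    HomologyThresholds,
    OrthologueCluster,
    PanGenomeResult,
    ScoringScheme,
    SimulationParams,
    StrainGeneSet,
    align_pair,
    build_pan_pool,
    core_fraction,
    is_homologous,
    partition_counts,
    simulate_pangenome,
)


def brute_force_single_linkage(strains, thresholds, scoring):
    """Independent oracle: single-linkage clustering over the full pairwise
    homology graph (no accretion order, no prefilter)."""
    genes = [(s.strain_id, gid, seq) for s in strains for gid, seq in s.genes]
    parent = list(range(len(genes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            hit = align_pair(genes[i][2], genes[j][2], scoring)
            if is_homologous(hit, thresholds):
                parent[find(i)] = find(j)
    clusters = {}
    for idx, (strain, gid, _) in enumerate(genes):
        clusters.setdefault(find(idx), set()).add(strain)
    sizes = sorted(len(c) for c in clusters.values())
    return clusters, sizes


class TestBuildPanPool:
    def test_single_strain_all_specific(self, zero_div_sim):
        genes = [(f"g{i}", seq) for i, (_, seq) in enumerate(zero_div_sim[0][0].genes[:5])]
        result = build_pan_pool([StrainGeneSet("only", genes)])
        counts = partition_counts(result)
        assert counts == (0, 0, 5, 5)

    def test_two_identical_strains_all_core(self):
        params = SimulationParams(n_strains=1, n_core=0, n_specific_per_strain=5,
                                  gene_length_range=(150, 300), seed=8)
        strains, _ = simulate_pangenome(params)
        twin = StrainGeneSet("twin", [(g.replace("strain1", "twin"), s) for g, s in strains[0].genes])
        result = build_pan_pool([strains[0], twin])
        assert partition_counts(result) == (5, 0, 0, 5)

    def test_zero_divergence_recovers_truth_partition(self, zero_div_sim, zero_div_result):
        _, truth = zero_div_sim
        assert partition_counts(zero_div_result)[:3] == truth.expected_partition() == (3, 1, 6)

    def test_partition_identical_for_every_strain_ordering(self, zero_div_sim):
        strains, truth = zero_div_sim
        expected = truth.expected_partition()
        for perm in itertools.permutations(strains):
            result = build_pan_pool(list(perm))
            assert partition_counts(result)[:3] == expected

    def test_gene_conservation_and_reference_completeness(self, zero_div_sim, zero_div_result):
        strains, _ = zero_div_sim
        assert zero_div_result.gene_count() == sum(len(s) for s in strains)
        clustered = {g for c in zero_div_result.clusters for _, g in c.members}
        for strain in strains:
            for gene_id, _ in strain.genes:
                assert gene_id in clustered

    def test_agrees_with_single_linkage_oracle_at_moderate_divergence(self):
        params = SimulationParams(
            n_strains=3, n_core=4, dispensable_spec=((1, 2),), n_specific_per_strain=1,
            gene_length_range=(150, 400), divergence=0.08, seed=17,
        )
        strains, truth = simulate_pangenome(params)
        scoring = ScoringScheme.nucleotide()
        th = HomologyThresholds.for_alphabet("nucleotide")
        result = build_pan_pool(strains, th, scoring)
        _, oracle_sizes = brute_force_single_linkage(strains, th, scoring)
        assert sorted(len(c.presence) for c in result.clusters) == oracle_sizes
        assert partition_counts(result)[:3] == truth.expected_partition()

    def test_prefilter_does_not_change_partition(self):
        params = SimulationParams(
            n_strains=3, n_core=5, n_specific_per_strain=2,
            gene_length_range=(150, 500), divergence=0.1, seed=23,
        )
        strains, _ = simulate_pangenome(params)
        with_pf = build_pan_pool(strains, prefilter=True)
        without_pf = build_pan_pool(strains, prefilter=False)
        assert partition_counts(with_pf) == partition_counts(without_pf)

    def test_query_paralogs_join_clusters_without_inflating_cluster_count(self):
        params = SimulationParams(
            n_strains=2, n_core=6, n_specific_per_strain=0,
            gene_length_range=(150, 300), divergence=0.0, paralog_rate=0.0, seed=31,
        )
        strains, _ = simulate_pangenome(params)
        # duplicate every query-strain gene: intra-strain paralogs must join
        # the existing cluster, inflating member counts but not cluster counts
        query = strains[1]
        doubled = StrainGeneSet(
            query.strain_id,
            query.genes + [(g + "|copy2", s) for g, s in query.genes],
        )
        result = build_pan_pool([strains[0], doubled])
        counts = partition_counts(result)
        assert counts.total == 6  # clusters, not genes
        assert counts.core == 6
        assert result.gene_count() == 18

    def test_empty_strain_list_rejected(self):
        with pytest.raises(ValueError):
            build_pan_pool([])

    def test_duplicate_strain_id_rejected(self):
        s = StrainGeneSet("x", [("g1", "ACGTACGTACGTACGTACGTACGTACGTACGT")])
        with pytest.raises(ValueError):
            build_pan_pool([s, s])

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError):
            StrainGeneSet("x", [("g1", "ACGT"), ("g1", "ACGT")])


def _result_with_presence(sizes, n_strains=3):
    clusters = []
    for i, size in enumerate(sizes):
        members = [(f"strain{k + 1}", f"g{i}_{k}") for k in range(size)]
        clusters.append(OrthologueCluster(f"C{i}", members))
    return PanGenomeResult(clusters, n_strains, [f"strain{k + 1}" for k in range(n_strains)])


class TestPartitionCounts:
    def test_counting_by_presence_size(self):
        result = _result_with_presence([3, 3, 2, 1, 1])
        assert partition_counts(result) == (2, 1, 2, 5)

    def test_empty_cluster_list(self):
        result = PanGenomeResult([], 3, ["a", "b", "c"])
        assert partition_counts(result) == (0, 0, 0, 0)

    def test_single_strain_counts_as_specific(self):
        result = _result_with_presence([1, 1], n_strains=1)
        counts = partition_counts(result)
        assert counts.core == 0 and counts.specific == 2

    def test_flower_counts(self, zero_div_sim, zero_div_result):
        flower = zero_div_result.flower_counts()
        assert flower["core"] == 3
        assert all(v == 2 for v in flower["specific"].values())


class TestCoreFraction:
    @pytest.mark.parametrize(
        "core,total,expected", [(5047, 15404, 32.8), (0, 100, 0.0), (7, 9, 77.8)]
    )
    def test_examples(self, core, total, expected):
        assert core_fraction(core, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            core_fraction(5, 0)


def test_clusters_tsv_roundtrip(tmp_path, zero_div_result):
    path = tmp_path / "clusters.tsv"
    zero_div_result.write_clusters_tsv(path)
    loaded = PanGenomeResult.from_clusters_tsv(path)
    assert partition_counts(loaded) == partition_counts(zero_div_result)
    assert loaded.gene_count() == zero_div_result.gene_count()
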