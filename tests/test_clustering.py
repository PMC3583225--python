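"""Normalization, correlation distance, tree cutting, zones, annotation subsets."""

from itertools import permutations

import numpy as np
import pytest

from qisp import (
    ARCHETYPES,
    ZoneMap,
    archetype_profile,
    assign_zone,
    cluster_qisps,
    cut_clusters,
    group_summary,
    hierarchical_cluster,
    normalize_qisp,
    pearson_distance,
    subset_by_annotation,
)
from qisp.clustering import is_degenerate


class TestNormalize:
    def test_output_standardized(self, rng):
        p = rng.uniform(0, 1, 20)
        z = normalize_qisp(p)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_magnitude_invariance(self, rng):
        p = rng.uniform(0, 1, 20)
        np.testing.assert_allclose(normalize_qisp(p), normalize_qisp(5.0 * p))

    def test_constant_profile_degenerate(self):
        z = normalize_qisp(np.full(20, 0.8))
        np.testing.assert_array_equal(z, 0.0)
        assert is_degenerate(np.full(20, 0.8))


class TestPearsonDistance:
    def test_self_distance_zero(self, rng):
        p = rng.uniform(0, 1, 20)
        assert pearson_distance(p, p) == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self, rng):
        p = rng.uniform(0, 1, 20)
        assert pearson_distance(p, -p) == pytest.approx(2.0)

    def test_affine_invariance(self, rng):
        p = rng.uniform(0, 1, 20)
        assert pearson_distance(p, 3.0 * p + 7.0) == pytest.approx(0.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_distance(np.full(20, 1.0), np.arange(20.0))

    def test_distance_matrix_properties(self, rng):
        profs = [rng.uniform(0, 1, 20) for _ in range(8)]
        D = np.array([[pearson_distance(a, b) for b in profs] for a in profs])
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        assert D.min() >= -1e-12 and D.max() <= 2.0 + 1e-12


class TestTreeAndCut:
    def test_identical_pair_merges_first(self, rng):
        p = rng.uniform(0, 1, 20)
        profiles = {"a": p, "b": 2.0 * p, "c": -p}
        tree = hierarchical_cluster(profiles)
        first = tree.linkage_matrix[0]
        merged = {tree.leaf_ids[int(first[0])], tree.leaf_ids[int(first[1])]}
        assert merged == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_leaf_count_equals_gene_count(self, three_archetype_truth):
        tb = three_archetype_truth
        profiles = {g: tb.true_profiles[g] for g in tb.gene_ids}
        tree = hierarchical_cluster(profiles)
        assert tree.n_leaves == len(tb.gene_ids)
        assert tree.linkage_matrix.shape[0] == len(tb.gene_ids) - 1
        # merge heights non-decreasing
        heights = tree.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_archetype_clades_are_monophyletic(self, three_archetype_truth, rng):
        tb = three_archetype_truth
        profiles = {
            g: np.maximum(tb.true_profiles[g] + rng.normal(0, 0.03, 20), 0)
            for g in tb.gene_ids
        }
        tree = hierarchical_cluster(profiles)
        labels = cut_clusters(tree, 3)
        by_arch = {}
        for g in tb.gene_ids:
            by_arch.setdefault(tb.archetype_of[g], set()).add(labels[g])
        # each archetype falls in exactly one flat cluster
        assert all(len(s) == 1 for s in by_arch.values())
        # and the clusters are distinct
        assert len({next(iter(s)) for s in by_arch.values()}) == 3

    def test_trivial_cuts(self, rng):
        profiles = {f"g{i}": rng.uniform(0, 1, 20) for i in range(6)}
        tree = hierarchical_cluster(profiles)
        all_singletons = cut_clusters(tree, 6)
        assert len(set(all_singletons.values())) == 6
        one = cut_clusters(tree, 1)
        assert set(one.values()) == {1}
        with pytest.raises(ValueError):
            cut_clusters(tree, 7)

    def test_labels_numbered_by_first_appearance(self, rng):
        p1, p2 = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        profiles = {"z_first": p1, "a_second": -p1, "m_third": p1 + rng.normal(0, .01, 20)}
        tree = hierarchical_cluster(profiles)
        labels = cut_clusters(tree, 2)
        assert labels["z_first"] == 1  # first gene in input order defines cluster 1

    def test_newick_export_parses(self, rng):
        profiles = {f"g{i}": rng.uniform(0, 1, 20) for i in range(5)}
        tree = hierarchical_cluster(profiles)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for g in profiles:
            assert g in nwk
        # readable by an independent tree parser
        from io import StringIO
        from Bio import Phylo

        t = Phylo.read(StringIO(nwk), "newick")
        assert t.count_terminals() == 5

    def test_cluster_recovery_planted_archetypes(self):
        """3 single-peak archetypes, 20 genes each, 10% amplitude noise:
        permutation-matched accuracy >= 95% over 20 seeds."""
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profiles, truth = {}, {}
            for ai, name in enumerate(["vz_peak", "iz_peak", "cp_peak"]):
                base = archetype_profile(ARCHETYPES[name])
                for j in range(20):
                    g = f"{name}_{j:02d}"
                    profiles[g] = np.maximum(
                        base + rng.normal(0, 0.1 * base.max(), 20), 0
                    )
                    truth[g] = ai
            result = cluster_qisps(profiles, k=3)
            best = max(
                sum(perm[result.labels[g] - 1] == truth[g] for g in profiles)
                for perm in permutations(range(3))
            )
            hits += best
            total += len(profiles)
        assert hits / total >= 0.95


class TestZones:
    def test_default_zone_map_lookup(self):
        zones = ZoneMap()
        c = np.zeros(20)
        for peak, expected in [(5, "deep"), (12, "middle"), (18, "upper")]:
            c[:] = 0.0
            c[peak - 1] = 1.0
            assert assign_zone(c, zones) == expected

    def test_tie_breaks_toward_superficial(self):
        c = np.zeros(20)
        c[9] = c[10] = 1.0  # bins 10 (deep) and 11 (middle) tie
        assert assign_zone(c) == "middle"

    def test_degenerate_centroid_unassigned(self):
        assert assign_zone(np.full(20, 0.5)) == "unassigned"

    def test_zone_map_must_partition(self):
        with pytest.raises(ValueError):
            ZoneMap(deep_bins=(1, 2), middle_bins=(3, 4), upper_bins=(5, 20))

    def test_zone_agrees_with_brute_force_argmax(self, three_archetype_truth):
        tb = three_archetype_truth
        profiles = {g: tb.true_profiles[g] for g in tb.gene_ids}
        result = cluster_qisps(profiles, k=3)
        zones = ZoneMap()
        for cid, centroid in result.centroids.items():
            peak = int(np.flatnonzero(centroid == centroid.max())[-1]) + 1
            assert result.zone_of_cluster[cid] == zones.zone_of_bin(peak)


class TestEndToEndInvariance:
    def test_positive_affine_transform_keeps_label_and_zone(
        self, three_archetype_truth
    ):
        tb = three_archetype_truth
        profiles = {g: tb.true_profiles[g] for g in tb.gene_ids}
        base = cluster_qisps(profiles, k=3)
        victim = tb.gene_ids[7]
        transformed = dict(profiles)
        transformed[victim] = 4.2 * profiles[victim] + 0.9
        result = cluster_qisps(transformed, k=3)
        # same partition of genes into clusters
        def partition(res):
            groups = {}
            for g, c in res.labels.items():
                groups.setdefault(c, set()).add(g)
            return {frozenset(s) for s in groups.values()}

        assert partition(result) == partition(base)
        assert result.zone_of_gene[victim] == base.zone_of_gene[victim]


class TestGroupSummary:
    def test_published_zone_composition_arithmetic(self):
        """Counts 44/49/224 of 317 give deep 14%, middle 15% (15.5 at one
        decimal), upper 71% under half-up integer rounding."""
        zone_of_gene = {}
        for i in range(44):
            zone_of_gene[f"d{i}"] = "deep"
        for i in range(49):
            zone_of_gene[f"m{i}"] = "middle"
        for i in range(224):
            zone_of_gene[f"u{i}"] = "upper"
        df = group_summary(zone_of_gene).set_index("zone")
        assert df.loc["deep", "count"] == 44
        assert df.loc["deep", "percent"] == 14
        assert df.loc["upper", "percent"] == 71
        assert df.loc["middle", "percent_1dp"] == pytest.approx(15.5)
        assert 99 <= df["percent"].sum() <= 101

    def test_percent_sum_near_100(self, rng):
        zones = ["deep", "middle", "upper"]
        zone_of_gene = {f"g{i}": zones[rng.integers(3)] for i in range(137)}
        df = group_summary(zone_of_gene)
        assert 99 <= df["percent"].sum() <= 101

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary({})


def test_heatmap_figure_written(three_archetype_truth, tmp_path):
    from qisp.clustering import plot_cluster_heatmap

    tb = three_archetype_truth
    profiles = {g: tb.true_profiles[g] for g in tb.gene_ids[:12]}
    result = cluster_qisps(profiles, k=3)
    out = tmp_path / "heatmap.png"
    plot_cluster_heatmap(result, profiles, str(out))
    assert out.stat().st_size > 0


class TestAnnotationSubset:
    ANN = {
        "g1": {"receptor activity", "membrane"},
        "g2": {"synapse"},
        "g3": {"synaptic vesicle"},
        "g4": {"transcription, nuclear"},
        "g5": {"receptor binding"},
    }

    def test_no_match_is_empty(self):
        assert subset_by_annotation(list(self.ANN), self.ANN, "flux capacitor") == []

    def test_substring_match_preserves_order(self):
        got = subset_by_annotation(["g5", "g1", "g2"], self.ANN, "receptor")
        assert got == ["g5", "g1"]

    def test_query_matches_both_synapse_and_synaptic(self):
        got = subset_by_annotation(list(self.ANN), self.ANN, "synap")
        assert got == ["g2", "g3"]

    def test_case_insensitive(self):
        got = subset_by_annotation(list(self.ANN), self.ANN, "TRANSCRIPTION")
        assert got == ["g4"]

    def test_missing_genes_silently_absent(self):
        got = subset_by_annotation(["gX", "g2"], self.ANN, "synapse")
        assert got == ["g2"]
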