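"""Occurrence matrices, redundancy, filtering, clustering, and consensus."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oceanmags.config import PipelineConfig
from oceanmags.functional import (FunctionalLandscape, build_occurrence_matrix,
                                  cluster_genomes, consensus_annotation,
                                  differential_functions, filter_functions,
                                  functional_redundancy, linkage_to_newick,
                                  prevalence_filter, redundancy_table)
from oceanmags.simulate import SimulationSpec, simulate_annotations, simulate_genomes

from conftest import genome_frame


def annotation_frame(rows):
    return pd.DataFrame([
        {"gene_id": gid, "genome_id": g, "og_id": og,
         "og_known": bool(og) and not og.startswith("U"),
         "agnostos_cluster": cl, "retro_flag": False}
        for gid, g, og, cl in rows])


@pytest.fixture(scope="module")
def planted():
    """100 genomes x 500 functions with 4 planted groups at effect size 5.

    The runaway retrotransposon-like columns are removed with the pipeline's
    own cap-and-flag filter before any clustering, as in the analysis chain.
    """
    spec = SimulationSpec(n_genomes=100, n_redundant_pairs=0, n_functions=500,
                          group_effect_size=5.0, lambda_base=1.0, rng_seed=20)
    genomes, _, truth = simulate_genomes(spec)
    annotations = simulate_annotations(spec, genomes, truth)
    raw, _ = build_occurrence_matrix(annotations, genomes)
    largest = genomes.loc[genomes["length"].idxmax(), "genome_id"]
    flags = (annotations.loc[annotations["og_id"] != ""]
             .groupby("og_id")["retro_flag"].any().to_dict())
    matrix, _, dropped = filter_functions(raw, PipelineConfig(), exclusions=(),
                                          cap_reference_genome=largest,
                                          retro_flags=flags)
    assert dropped == sorted(truth.retro_functions)
    return spec, genomes, truth, annotations, matrix


class TestOccurrenceMatrix:
    def test_counts_per_genome_and_function(self):
        genomes = genome_frame([("g1", 10), ("g2", 10)])
        ann = annotation_frame([
            ("a", "g1", "f1", ""), ("b", "g1", "f1", ""), ("c", "g1", "f2", ""),
            ("d", "g2", "f2", ""), ("e", "g2", "", "")])
        matrix, empty = build_occurrence_matrix(ann, genomes)
        assert matrix.loc["g1", "f1"] == 2
        assert matrix.loc["g1", "f2"] == 1
        assert matrix.loc["g2", "f1"] == 0
        assert matrix.loc["g2", "f2"] == 1
        assert empty == []

    def test_genome_without_annotated_genes_flagged(self):
        genomes = genome_frame([("g1", 10), ("g2", 10)])
        ann = annotation_frame([("a", "g1", "f1", ""), ("b", "g2", "", "")])
        matrix, empty = build_occurrence_matrix(ann, genomes)
        assert empty == ["g2"]
        assert matrix.loc["g2"].sum() == 0

    def test_unknown_genome_rejected(self):
        genomes = genome_frame([("g1", 10)])
        ann = annotation_frame([("a", "ghost", "f1", "")])
        with pytest.raises(ValueError):
            build_occurrence_matrix(ann, genomes)

    def test_row_sums_equal_annotated_gene_counts(self, planted):
        _, genomes, _, annotations, _ = planted
        raw, _ = build_occurrence_matrix(annotations, genomes)
        tally = (annotations[annotations["og_id"] != ""]
                 .groupby("genome_id").size())
        for gid in raw.index:
            assert raw.loc[gid].sum() == tally.get(gid, 0)


class TestFunctionalRedundancy:
    def test_enumerated_example(self):
        matrix = pd.DataFrame({"f1": [3], "f2": [1]}, index=["g"])
        assert functional_redundancy(matrix, "g") == pytest.approx(0.75)

    def test_all_singletons_is_zero(self):
        matrix = pd.DataFrame({"f1": [1], "f2": [1], "f3": [1]}, index=["g"])
        assert functional_redundancy(matrix, "g") == 0.0

    def test_single_function_is_one(self):
        matrix = pd.DataFrame({"f1": [9]}, index=["g"])
        assert functional_redundancy(matrix, "g") == 1.0

    def test_duplicating_every_gene_sends_redundancy_to_one(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, size=20)
        matrix = pd.DataFrame([row, row * 2],
                              index=["orig", "doubled"],
                              columns=[f"f{i}" for i in range(20)])
        assert functional_redundancy(matrix, "doubled") == 1.0

    def test_zero_annotated_genes_rejected(self):
        matrix = pd.DataFrame({"f1": [0]}, index=["g"])
        with pytest.raises(ValueError):
            functional_redundancy(matrix, "g")

    def test_table_skips_empty_genomes(self):
        matrix = pd.DataFrame({"f1": [2, 0]}, index=["g1", "g2"])
        table = redundancy_table(matrix)
        assert list(table["genome_id"]) == ["g1"]


class TestFilterFunctions:
    def _matrix(self):
        return pd.DataFrame(
            {"f_cap_flag": [600, 1], "f_cap_noflag": [600, 1],
             "f_atcap_flag": [500, 1], "f_ok": [3, 3]},
            index=["big", "small"])

    def test_cap_and_flag_conjunction(self, config):
        flags = {"f_cap_flag": True, "f_atcap_flag": True, "f_cap_noflag": False}
        out, _, dropped = filter_functions(
            self._matrix(), config, cap_reference_genome="big", retro_flags=flags)
        assert dropped == ["f_cap_flag"]          # >500 AND flagged
        assert "f_cap_noflag" in out.columns      # >500 but unflagged
        assert "f_atcap_flag" in out.columns      # exactly 500: strict "more than"

    def test_excluded_genomes_dropped(self, config):
        out, dropped_g, _ = filter_functions(self._matrix(), config,
                                             exclusions=["small"])
        assert dropped_g == ["small"]
        assert list(out.index) == ["big"]

    def test_unknown_reference_rejected(self, config):
        with pytest.raises(ValueError):
            filter_functions(self._matrix(), config, cap_reference_genome="ghost")


class TestClustering:
    def test_identical_rows_merge_at_zero_height(self, config):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 5, size=(6, 10)).astype(float)
        rows[1] = rows[0]
        matrix = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)])
        res = cluster_genomes(matrix, config)
        assert res.linkage[:, 2].min() == pytest.approx(0.0)

    def test_planted_groups_recovered(self, planted, config):
        _, _, truth, _, matrix = planted
        res = cluster_genomes(matrix, config)
        truth_labels = [truth.group_of[g] for g in res.groups.index]
        assert adjusted_rand_score(truth_labels, list(res.groups)) == 1.0

    def test_partition_invariant_to_row_order(self, planted, config):
        _, _, _, _, matrix = planted
        res1 = cluster_genomes(matrix, config)
        shuffled = matrix.sample(frac=1.0, random_state=9)
        res2 = cluster_genomes(shuffled, config)
        pd.testing.assert_series_equal(res1.groups, res2.groups)

    def test_outgroup_excluded_from_groups(self, planted, config):
        _, _, _, _, matrix = planted
        outgroup = list(matrix.index[:3])
        res = cluster_genomes(matrix, config, outgroup=outgroup)
        assert not set(outgroup) & set(res.groups.index)
        assert set(res.full_leaf_order) == set(matrix.index)

    def test_too_few_genomes_rejected(self, config):
        matrix = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValueError):
            cluster_genomes(matrix, config)

    def test_newick_contains_all_leaves(self, planted, config):
        _, _, _, _, matrix = planted
        sub = matrix.iloc[:8]
        res = cluster_genomes(sub, config)
        nwk = linkage_to_newick(res.linkage, sorted(sub.index))
        assert nwk.endswith(";")
        for gid in sub.index:
            assert gid in nwk


class TestDifferentialFunctions:
    def test_planted_markers_significant(self, planted, config):
        _, _, truth, _, matrix = planted
        groups = pd.Series({g: "ABCD"[truth.group_of[g]] for g in matrix.index})
        results, top, skipped = differential_functions(matrix, groups, config)
        planted_markers = {f for fs in truth.marker_functions.values() for f in fs}
        res = results.set_index("function_id")
        testable = planted_markers & set(res.index)
        assert len(testable) >= 0.95 * len(planted_markers)
        assert res.loc[sorted(testable), "significant"].all()
        # null functions essentially never flagged at p < 1e-5
        null = res.drop(index=sorted(testable))
        assert null["significant"].mean() <= 0.01
        assert len(top) == min(100, len(results))
        assert (results["p_value"].diff().dropna() >= 0).all()

    def test_constant_function_skipped(self, config):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.poisson(2.0, size=(40, 3)).astype(float),
                              index=[f"g{i}" for i in range(40)],
                              columns=["f0", "f_const", "f2"])
        matrix["f_const"] = 5.0
        groups = pd.Series(["ABCD"[i % 4] for i in range(40)], index=matrix.index)
        results, _, skipped = differential_functions(matrix, groups, config)
        assert "f_const" in skipped
        assert "f_const" not in set(results["function_id"])

    def test_games_howell_only_for_significant(self, planted, config):
        _, _, truth, _, matrix = planted
        groups = pd.Series({g: "ABCD"[truth.group_of[g]] for g in matrix.index})
        results, _, _ = differential_functions(matrix, groups, config)
        gh_cols = [c for c in results.columns if c.startswith("gh_p_")]
        sig = results[results["significant"]]
        insig = results[~results["significant"]]
        assert sig[gh_cols].notna().all().all()
        assert insig[gh_cols].isna().all().all()


class TestModelFacade:
    def test_fit_returns_summary_and_newick(self, planted):
        _, _, truth, _, matrix = planted
        config = PipelineConfig()
        res = FunctionalLandscape(matrix, config).fit()
        text = res.summary()
        assert "significant functions" in text
        assert res.n_significant > 0
        truth_labels = [truth.group_of[g] for g in res.groups.index]
        assert adjusted_rand_score(truth_labels, list(res.groups)) == 1.0
        assert res.newick().endswith(";")


class TestConsensusAnnotation:
    def test_majority_resolves(self):
        ann = annotation_frame([
            ("a", "g1", "K1", "c1"), ("b", "g1", "K1", "c1"),
            ("c", "g2", "K2", "c1")])
        groups = consensus_annotation(ann)
        assert len(groups) == 1
        assert groups[0].consensus_og == "K1"

    def test_tie_is_unresolved_unknown(self):
        ann = annotation_frame([("a", "g1", "K1", "c1"), ("b", "g2", "K2", "c1")])
        groups = consensus_annotation(ann)
        assert groups[0].consensus_og == "unknown"

    def test_clusters_sharing_consensus_merged(self):
        ann = annotation_frame([
            ("a", "g1", "K7", "c1"), ("b", "g1", "K7", "c1"),
            ("c", "g2", "K7", "c2"), ("d", "g2", "K7", "c2")])
        groups = consensus_annotation(ann)
        assert len(groups) == 1
        assert groups[0].member_genes == frozenset("abcd")

    def test_unknown_clusters_pass_through_unmerged(self):
        ann = annotation_frame([
            ("a", "g1", "U1", "c1"), ("b", "g2", "U2", "c2")])
        groups = consensus_annotation(ann)
        assert len(groups) == 2
        assert all(g.consensus_og == "unknown" for g in groups)

    def test_unclustered_genes_ignored(self):
        ann = annotation_frame([("a", "g1", "K1", ""), ("b", "g1", "K1", "c1")])
        groups = consensus_annotation(ann)
        assert groups[0].member_genes == frozenset({"b"})


class TestPrevalenceFilter:
    def _setup(self, n_genomes, hit_genomes):
        genomes = genome_frame([(f"g{i}", 10) for i in range(n_genomes)])
        ann = annotation_frame(
            [(f"gene{i}", g, "K1", "c1") for i, g in enumerate(hit_genomes)])
        groups = consensus_annotation(ann)
        return groups, ann, genomes

    def test_below_two_percent_excluded(self, config):
        groups, ann, genomes = self._setup(100, ["g0"])
        assert prevalence_filter(groups, ann, genomes, config) == []

    def test_exactly_two_percent_retained(self, config):
        groups, ann, genomes = self._setup(100, ["g0", "g1"])
        kept = prevalence_filter(groups, ann, genomes, config)
        assert len(kept) == 1
        assert kept[0].prevalence == pytest.approx(0.02)

    def test_ubiquitous_group_retained(self, config):
        groups, ann, genomes = self._setup(10, [f"g{i}" for i in range(10)])
        kept = prevalence_filter(groups, ann, genomes, config)
        assert kept[0].prevalence == pytest.approx(1.0)


def test_unknown_only_matrix_recovers_groups(planted, config):
    """Clustering restricted to unknown-function columns still recovers the
    planted partition, mirroring the known/unknown concordance claim."""
    _, _, truth, _, matrix = planted
    unknown = matrix[[c for c in matrix.columns if c.startswith("UOG")]]
    res = cluster_genomes(unknown, config)
    truth_labels = [truth.group_of[g] for g in res.groups.index]
    assert adjusted_rand_score(truth_labels, list(res.groups)) == 1.0
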