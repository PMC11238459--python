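"""Splicing orthology, ortholog groups and conservation ratios."""
from itertools import combinations

import pytest

from splicesim import (are_orthologs, cluster_by_exon_composition,
                      cluster_by_phylogeny, conservation_ratio,
                      ortholog_groups, simulate)
from props_util import property_config


LEAVES = ("Gene2", "Gene3")


class TestPairwiseOrthology:
    def test_conserved_leaf_copies_are_orthologs(self, ancestral_forest):
        assert are_orthologs("Gene2#1", "Gene3#1", ancestral_forest)
        assert are_orthologs("Gene3#1", "Gene2#1", ancestral_forest)

    def test_as_derived_isoforms_are_not(self, ancestral_forest):
        assert not are_orthologs("Gene2#2", "Gene3#1", ancestral_forest)
        assert not are_orthologs("Gene2#2", "Gene3#2", ancestral_forest)

    def test_same_gene_never_orthologs(self, ancestral_forest):
        assert not are_orthologs("Gene2#1", "Gene2#2", ancestral_forest)
        assert not are_orthologs("Gene2#1", "Gene2#1", ancestral_forest)

    def test_separate_trees_not_orthologs(self, ancestral_forest):
        ancestral_forest.add_transcript("Gene2#9", "Gene2")
        ancestral_forest.add_transcript("Gene3#9", "Gene3")
        assert not are_orthologs("Gene2#9", "Gene3#9", ancestral_forest)

    def test_unknown_id_raises(self, ancestral_forest):
        with pytest.raises(KeyError):
            are_orthologs("Gene2#1", "nope#1", ancestral_forest)

    def test_ancestor_descendant_pair_is_orthologous(self, ancestral_forest):
        # pairwise definition only needs distinct genes + conserved path
        assert are_orthologs("Gene1#1", "Gene2#1", ancestral_forest)


class TestOrthologGroups:
    def test_single_group_of_extant_copies(self, ancestral_forest):
        groups = ortholog_groups(ancestral_forest, LEAVES)
        assert groups == [frozenset({"Gene2#1", "Gene3#1"})]

    def test_all_as_edges_no_groups(self, ancestral_forest):
        # relabel the only conserved edges as AS events -> nothing orthologous
        for u, v, d in ancestral_forest.graph.edges(data=True):
            if d["event"] == "conserved":
                d["event"] = "es"
        assert ortholog_groups(ancestral_forest, LEAVES) == []

    def test_groups_match_subset_enumeration_oracle(self, small_config):
        """Brute force: maximal pairwise-ortholog subsets of leaf isoforms."""
        result = simulate("((A:0.15,B:0.2):0.1,C:0.2);",
                          property_config(2).replace(tc_rs=0.2, k_tc=1.0))
        leaves = [l.label for l in result.tree.leaves]
        tids = [t.tid for t in result.leaf_transcripts()]
        # groups hold at most one transcript per gene, so subsets of size
        # 2..n_leaves suffice for the enumeration
        assert len(tids) <= 40, "simulation too large for enumeration"

        # independent pairwise oracle: BFS over conserved edges only
        adj = {}
        for a, b, d in result.forest.graph.edges(data=True):
            if d["event"] == "conserved":
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)

        def conserved_connected(a, b):
            seen, todo = {a}, [a]
            while todo:
                x = todo.pop()
                if x == b:
                    return True
                for y in adj.get(x, ()):
                    if y not in seen:
                        seen.add(y)
                        todo.append(y)
            return False

        def pairwise_ok(subset):
            return all(result.forest.gene_of(x) != result.forest.gene_of(y)
                       and conserved_connected(x, y)
                       for x, y in combinations(subset, 2))

        candidates = [frozenset(c) for size in range(2, len(leaves) + 1)
                      for c in combinations(tids, size) if pairwise_ok(c)]
        maximal = {c for c in candidates
                   if not any(c < other for other in candidates)}
        assert set(ortholog_groups(result.forest, leaves)) == maximal


class TestConservationRatio:
    def test_singletons_give_ratio_one(self):
        tids = [f"t{i}" for i in range(5)]
        assert conservation_ratio([{t} for t in tids], tids) == 1.0

    def test_single_cluster(self):
        tids = ["a", "b", "c", "d"]
        assert conservation_ratio([set(tids)], tids) == 0.25

    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            conservation_ratio([{"a"}, {"a", "b"}], ["a", "b"])
        with pytest.raises(ValueError):
            conservation_ratio([], [])

    def test_clusterings_partition_leaf_transcripts(self, small_config):
        result = simulate("((A:0.2,B:0.25):0.1,C:0.3);", small_config)
        leaves = [l.label for l in result.tree.leaves]
        tids = {t.tid for t in result.leaf_transcripts()}
        phylo = cluster_by_phylogeny(result.forest, leaves)
        comp = cluster_by_exon_composition(result.leaf_transcripts())
        for clusters in (phylo, comp):
            assert set().union(*clusters) == tids
            assert sum(len(c) for c in clusters) == len(tids)

    def test_ratio_recomputed_from_raw_outputs(self, small_config):
        """The report's ratio equals an independent recount."""
        from splicesim import conservation_report
        result = simulate("((A:0.2,B:0.25):0.1,C:0.3);", small_config)
        rep = conservation_report(result, "phylogeny")
        leaves = [l.label for l in result.tree.leaves]
        clusters = cluster_by_phylogeny(result.forest, leaves)
        assert rep.n_clusters == len(clusters)
        assert rep.n_transcripts == len(result.leaf_transcripts())
        assert rep.ratio == pytest.approx(len(clusters)
                                          / rep.n_transcripts)
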