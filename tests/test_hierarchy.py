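import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirhic import (
    build_dendrogram,
    correlation_cutoff,
    extract_signatures,
    pairwise_correlation,
)

from conftest import two_group_study
from oracles import naive_average_linkage


def _sim(mat, names=None):
    names = names or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=names, columns=names)


class TestPairwiseCorrelation:
    def test_identical_and_negated_vectors(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        values = np.vstack([base, base, -base])
        study = two_group_study(values, 2, 2)
        corr = pairwise_correlation(study)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # x=(1,2,3,4), y=(1,3,2,4): sum of deviation products = 4,
        # sqrt(5)*sqrt(5) = 5 -> r = 0.8
        values = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]])
        study = two_group_study(values, 2, 2)
        corr = pairwise_correlation(study)
        assert corr.iloc[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_gene_gets_zero(self, caplog):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        study = two_group_study(values, 2, 2)
        with caplog.at_level(logging.WARNING):
            corr = pairwise_correlation(study)
        assert corr.iloc[0, 1] == 0.0
        assert corr.iloc[1, 1] == 1.0

    def test_spearman_is_rank_based(self):
        values = np.array([[1.0, 2.0, 3.0, 40.0], [2.0, 4.0, 6.0, 7.0]])
        study = two_group_study(values, 2, 2)
        assert pairwise_correlation(study, method="spearman").iloc[
            0, 1
        ] == pytest.approx(1.0)


class TestCorrelationCutoff:
    def test_zero_z_gives_zero_r(self):
        assert correlation_cutoff(0.0, 60) == 0.0

    def test_closed_form_at_n120(self):
        assert correlation_cutoff(0.52, 120) == pytest.approx(
            np.tanh(0.52 / np.sqrt(117)), abs=1e-12
        )
        assert correlation_cutoff(0.52, 120) == pytest.approx(0.04806, abs=1e-4)

    def test_tail_probability_rounds_to_0_3(self):
        assert round(float(stats.norm.sf(0.52)), 1) == 0.3

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            correlation_cutoff(0.52, 3)


class TestBuildDendrogram:
    def test_two_perfect_blocks_make_a_forest(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 1.0
        np.fill_diagonal(m, 1.0)
        dendro = build_dendrogram(_sim(m), cutoff_r=0.5)
        assert dendro.n_kept == 2
        roots = sorted(map(sorted, dendro.roots()))
        assert roots == [[0, 1], [2, 3]]

    def test_vacuous_cutoff_builds_full_tree(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-0.5, 0.5, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        dendro = build_dendrogram(_sim(m), cutoff_r=-1.0)
        assert dendro.n_kept == 5
        assert len(dendro.roots()) == 1

    def test_merge_correlations_nonincreasing(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        dendro = build_dendrogram(_sim(m), cutoff_r=-1.0)
        assert (np.diff(dendro.merge_correlations) <= 1e-12).all()

    @pytest.mark.parametrize("n", [6, 12, 20])
    def test_matches_naive_agglomeration_oracle(self, n):
        rng = np.random.default_rng(n)
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        dendro = build_dendrogram(_sim(m), cutoff_r=-1.0)
        expected = naive_average_linkage(m)
        members = dendro.node_members()
        for idx, (left, right, corr) in enumerate(dendro.merges):
            # compare unordered pair of child leaf-sets and the merge value
            exp_left, exp_right, exp_corr = expected[idx]
            assert {
                _node_set(dendro, left, members),
                _node_set(dendro, right, members),
            } == {exp_left, exp_right}
            assert corr == pytest.approx(exp_corr, abs=1e-9)


def _node_set(dendro, node, members):
    n = len(dendro.leaves)
    return frozenset([node]) if node < n else frozenset(members[node - n])


class TestExtractSignatures:
    def _block_sim(self, sizes, within=0.9, between=0.0):
        n = sum(sizes)
        m = np.full((n, n), between)
        at = 0
        for s in sizes:
            m[at : at + s, at : at + s] = within
            at += s
        np.fill_diagonal(m, 1.0)
        return _sim(m)

    def test_two_disjoint_blocks(self):
        dendro = build_dendrogram(self._block_sim([50, 50]), cutoff_r=0.5)
        sigs = extract_signatures(dendro, min_size=30, dedup_jaccard=1.0)
        assert len(sigs) == 2
        assert sorted(s.size for s in sigs) == [50, 50]
        assert sigs[0].genes.isdisjoint(sigs[1].genes)

    def test_min_size_filters_everything(self, caplog):
        dendro = build_dendrogram(self._block_sim([5, 5]), cutoff_r=0.5)
        with caplog.at_level(logging.WARNING):
            sigs = extract_signatures(dendro, min_size=20)
        assert sigs == []
        assert "no signature" in caplog.text

    def test_nested_near_duplicates_deduplicated(self):
        # A (40 genes) inside B (44): Jaccard 40/44 ~ 0.909 >= 0.9 -> keep A only
        n = 44
        m = np.full((n, n), 0.5)
        m[:40, :40] = 0.9
        np.fill_diagonal(m, 1.0)
        dendro = build_dendrogram(_sim(m), cutoff_r=0.1)
        sigs = extract_signatures(
            dendro, min_size=30, max_size_fraction=1.0, dedup_jaccard=0.9
        )
        assert [s.size for s in sigs] == [40]

    def test_signatures_nested_or_disjoint_and_scales_ordered(self, small_dataset):
        from mirhic import RunConfig, differential_expression
        from mirhic.enrichment import hierarchy_signatures

        study, _, _ = small_dataset
        _, de = differential_expression(study, alpha=1e-4)
        sigs, dendro = hierarchy_signatures(
            study, de, RunConfig(min_size=10)
        )
        assert len(sigs) >= 2
        for a in sigs:
            for b in sigs:
                inter = a.genes & b.genes
                assert (
                    not inter or inter == a.genes or inter == b.genes
                ), "signatures must be nested or disjoint"
        # larger signatures form at weaker correlation
        for a in sigs:
            for b in sigs:
                if a.genes < b.genes:
                    assert a.level_correlation >= b.level_correlation - 1e-12


def test_newick_export_is_parseable(small_dataset):
    import io

    from Bio import Phylo

    from mirhic import RunConfig, differential_expression
    from mirhic.enrichment import hierarchy_signatures

    study, _, _ = small_dataset
    _, de = differential_expression(study, alpha=1e-4)
    _, dendro = hierarchy_signatures(study, de, RunConfig(min_size=10))
    text = dendro.to_newick()
    trees = list(Phylo.parse(io.StringIO(text), "newick"))
    leaves = [t for tree in trees for t in tree.get_terminals()]
    assert len(leaves) == len(dendro.leaves)
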