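import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirhic import (
    Signature,
    TargetNetwork,
    discretize_scores,
    empirical_pvalue,
    enrichment_score,
    generate_controls,
    p_score,
    q_values,
    run_mirhic,
    signature_pvalues,
)


def _sig(genes, sid="S"):
    return Signature(id=sid, genes=frozenset(genes), level_correlation=0.5)


@pytest.fixture
def scored_net():
    # discretized scores chosen via context ranks: gC strongest, gD weakest
    df = pd.DataFrame(
        {
            "family": ["m1", "m1", "m1", "m2", "m2", "m2"],
            "gene": ["gB", "gC", "gD", "gA", "gB", "gC"],
            "context_score": [-0.45, -0.9, -0.1, -0.3, -0.5, -0.85],
        }
    )
    return discretize_scores(TargetNetwork(df), K=3, b=3)


class TestEnrichmentScore:
    def test_direct_sum(self, scored_net):
        scores = scored_net.discretized_map()
        sig = _sig({"gA", "gB", "gC"})
        overlap, es = enrichment_score(sig, "m1", scored_net)
        assert overlap == {"gB", "gC"}
        assert es == scores[("m1", "gB")] + scores[("m1", "gC")]

    def test_disjoint_sets_give_zero(self, scored_net):
        overlap, es = enrichment_score(_sig({"gX", "gY"}), "m1", scored_net)
        assert overlap == frozenset() and es == 0.0

    def test_unknown_family_errors(self, scored_net):
        with pytest.raises(KeyError, match="m9"):
            enrichment_score(_sig({"gA"}), "m9", scored_net)

    def test_universe_restriction(self, scored_net):
        overlap, es = enrichment_score(
            _sig({"gB", "gC"}), "m1", scored_net, universe={"gB"}
        )
        assert overlap == {"gB"}

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        rows = []
        for f in range(4):
            for g in rng.choice(20, size=8, replace=False):
                rows.append((f"m{f}", genes[g], float(-rng.uniform(0.01, 1))))
        net = discretize_scores(
            TargetNetwork(pd.DataFrame(rows, columns=["family", "gene", "context_score"])),
            K=5,
            b=3,
        )
        sigs = [_sig(set(rng.choice(genes, size=6, replace=False)), f"S{j}")
                for j in range(3)]
        scores = net.discretized_map()
        for f in net.families:
            targets = net.target_sets()[f]
            for sig in sigs:
                expected = sum(
                    scores[(f, g)] for g in genes if g in targets and g in sig.genes
                )
                _, es = enrichment_score(sig, f, net)
                assert es == expected


class TestSignaturePvalues:
    def test_extremes(self, scored_net):
        controls = generate_controls(scored_net, R=50, seed=0)
        # a signature containing every gene: ES is invariant under rewiring
        p_all, _ = signature_pvalues(scored_net, controls, [_sig(set(scored_net.genes))])
        assert (p_all.to_numpy() == 1.0).all(), "constant statistic ties everywhere"

    def test_null_object_consistency(self, scored_net):
        controls = generate_controls(scored_net, R=100, seed=1)
        sigs = [_sig({"gB", "gC"}, "S1"), _sig({"gA", "gD"}, "S2")]
        p, null = signature_pvalues(scored_net, controls, sigs)
        es = null.observed_es()
        manual = (null.tensor >= es[None].astype(np.float32)).mean(axis=0)
        assert np.array_equal(p.to_numpy(), manual)


class TestPScore:
    def test_minimum(self):
        assert p_score([0.4, 0.02, 0.6]) == 0.02

    def test_single_signature_identity(self):
        assert p_score([0.37]) == 0.37

    def test_all_ones(self):
        assert p_score([1.0, 1.0]) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            p_score([])


class TestEmpiricalPvalue:
    def test_single_signature_is_monotone_in_p1(self):
        rng = np.random.default_rng(0)
        tensor = rng.normal(size=(500, 30, 1)).astype(np.float32)
        es_obs = rng.normal(size=(30, 1)).astype(np.float32)
        p1 = (tensor >= es_obs[None]).mean(axis=0)[:, 0]
        P = p1.copy()
        p_i = empirical_pvalue(P, tensor)
        rho = stats.spearmanr(p1, p_i).statistic
        assert rho == pytest.approx(1.0)

    def test_controls_selfranked_are_uniform(self):
        # scoring the controls by their own self-rank gives p-values uniform
        # on {1/R, ..., 1} up to ties
        rng = np.random.default_rng(1)
        R = 400
        tensor = rng.normal(size=(R, 10, 4)).astype(np.float32)
        from mirhic.enrichment import _control_pscores

        P_ctrl = _control_pscores(tensor)
        p_self = (P_ctrl[:, None, :] <= P_ctrl[None, :, :]).mean(axis=0)
        # for each family, the R self-scored values cover {1/R..1} uniformly
        for i in range(10):
            ks = stats.kstest(p_self[:, i], "uniform")
            assert ks.pvalue > 0.01

    def test_dominance_P_le_pij(self, scored_net):
        controls = generate_controls(scored_net, R=200, seed=3)
        sigs = [_sig({"gB"}, "S1"), _sig({"gC", "gD"}, "S2"), _sig({"gA"}, "S3")]
        p, null = signature_pvalues(scored_net, controls, sigs)
        P = p.to_numpy().min(axis=1)
        assert (P[:, None] <= p.to_numpy() + 1e-15).all()


class TestQValues:
    def test_all_zero(self):
        assert (q_values([0.0, 0.0, 0.0]) == 0).all()

    def test_single_value_identity(self):
        assert q_values([0.05])[0] == pytest.approx(0.05)

    def test_hand_example(self):
        assert np.allclose(q_values([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            q_values([0.5], method="storey")


class TestRunMirhic:
    def test_deterministic_given_seed(self, small_dataset, small_config):
        study, net, _ = small_dataset
        a = run_mirhic(study, net, small_config)
        b = run_mirhic(study, net, small_config)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.p_matrix, b.p_matrix)
        pd.testing.assert_frame_equal(a.subnetwork, b.subnetwork)

    def test_zero_p_reported_as_less_than_1_over_R(
        self, small_dataset, small_config, tmp_path
    ):
        study, net, truth = small_dataset
        run = run_mirhic(study, net, small_config)
        run.write(tmp_path)
        table = pd.read_csv(tmp_path / "results.tsv", sep="\t", index_col=0)
        planted = table.loc[truth.planted_family]
        if planted["empirical_p"] == 0:
            assert planted["empirical_p_label"] == f"<{1 / small_config.R:g}"

    def test_planted_family_recovered(self, small_dataset, small_config):
        study, net, truth = small_dataset
        run = run_mirhic(study, net, small_config)
        assert run.table.loc[truth.planted_family, "q"] < 0.1
        assert truth.planted_family in set(run.subnetwork["family"])

    def test_empty_de_set_raises_with_guidance(self, small_config):
        rng = np.random.default_rng(0)
        from conftest import two_group_study

        study = two_group_study(rng.normal(size=(120, 16)), 8, 8)
        df = pd.DataFrame(
            {
                "family": ["m1"] * 5 + ["m2"] * 5,
                "gene": [f"g{i}" for i in range(10)],
                "context_score": -rng.uniform(0.1, 1, 10),
            }
        )
        with pytest.raises(ValueError, match="de_alpha"):
            run_mirhic(study, TargetNetwork(df), small_config)

    def test_graphml_export(self, small_dataset, small_config, tmp_path):
        import networkx as nx

        study, net, _ = small_dataset
        run = run_mirhic(study, net, small_config)
        run.to_graphml(tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == len(run.subnetwork)
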