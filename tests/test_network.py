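import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mercnet import (
    CooccurrenceNetwork,
    CorrelationResult,
    build_network,
    detect_modules,
    filter_dominant_taxa,
    module_relative_abundance,
    recover_planted_modules,
    spearman_all_pairs,
)
from mercnet.errors import InsufficientDataError, MercnetError


def _corr_result(rho: np.ndarray, p: np.ndarray) -> CorrelationResult:
    taxa = [f"t{i}" for i in range(rho.shape[0])]
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n=100,
    )


class TestFilterDominantTaxa:
    def test_prefix_sum_rule(self):
        # mean abundances (0.5, 0.3, 0.15, 0.05): 0.5 + 0.3 reaches 0.8
        rel = pd.DataFrame(
            [[0.5, 0.3, 0.15, 0.05]] * 2,
            index=["s1", "s2"],
            columns=["a", "b", "c", "d"],
        )
        kept = filter_dominant_taxa(rel, coverage=0.8)
        assert list(kept.columns) == ["a", "b"]

    def test_full_coverage_keeps_all_nonzero(self):
        rel = pd.DataFrame(
            [[0.6, 0.4, 0.0]], index=["s"], columns=["a", "b", "z"]
        )
        kept = filter_dominant_taxa(rel, coverage=1.0)
        assert sorted(kept.columns) == ["a", "b"]

    def test_single_taxon_always_kept(self):
        rel = pd.DataFrame([[1.0]], index=["s"], columns=["only"])
        for cov in (0.01, 0.5, 1.0):
            assert list(filter_dominant_taxa(rel, cov).columns) == ["only"]

    def test_ties_broken_by_taxon_id(self):
        rel = pd.DataFrame(
            [[0.25, 0.25, 0.25, 0.25]], index=["s"], columns=["d", "b", "c", "a"]
        )
        kept = filter_dominant_taxa(rel, coverage=0.5)
        assert list(kept.columns) == ["a", "b"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_dominant_taxa(pd.DataFrame(index=["s"]), coverage=0.8)


class TestSpearman:
    def test_hand_example(self):
        rel = pd.DataFrame(
            {"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]},
            index=[f"s{i}" for i in range(5)],
        )
        res = spearman_all_pairs(rel)
        assert res.rho.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)
        assert res.n == 5

    def test_monotone_pair_is_one(self):
        rel = pd.DataFrame(
            {"x": [1.0, 2.0, 5.0, 9.0], "y": [0.1, 0.4, 0.5, 3.0]},
            index=list("abcd"),
        )
        res = spearman_all_pairs(rel)
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_constant_taxon_zeroed(self):
        rel = pd.DataFrame(
            {"x": [1, 2, 3, 4], "c": [5, 5, 5, 5]}, index=list("abcd")
        )
        res = spearman_all_pairs(rel)
        assert res.rho.loc["x", "c"] == 0.0
        assert res.p.loc["x", "c"] == 1.0
        assert res.rho.loc["c", "c"] == 1.0

    def test_too_few_samples_rejected(self):
        rel = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3]}, index=list("abc"))
        with pytest.raises(InsufficientDataError):
            spearman_all_pairs(rel)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.random((10, 6)), columns=[f"t{i}" for i in range(6)])
        res = spearman_all_pairs(rel)
        assert np.allclose(res.rho, res.rho.T)
        assert np.allclose(res.p, res.p.T)
        assert np.allclose(np.diag(res.rho), 1.0)


class TestBuildNetwork:
    def test_edge_inclusion_rules(self):
        rho = np.array([[1.0, 0.3], [0.3, 1.0]])
        p = np.array([[0.0, 0.005], [0.005, 0.0]])
        net = build_network(_corr_result(rho, p))
        assert net.graph.has_edge("t0", "t1")

    def test_negative_rho_never_included(self):
        rho = np.array([[1.0, -0.9], [-0.9, 1.0]])
        p = np.array([[0.0, 1e-8], [1e-8, 0.0]])
        net = build_network(_corr_result(rho, p))
        assert net.graph.number_of_edges() == 0

    def test_boundary_rho_excluded(self):
        rho = np.array([[1.0, 0.25], [0.25, 1.0]])
        p = np.array([[0.0, 1e-8], [1e-8, 0.0]])
        net = build_network(_corr_result(rho, p))
        assert net.graph.number_of_edges() == 0

    def test_boundary_alpha_excluded(self):
        rho = np.array([[1.0, 0.9], [0.9, 1.0]])
        p = np.array([[0.0, 0.01], [0.01, 0.0]])
        net = build_network(_corr_result(rho, p))
        assert net.graph.number_of_edges() == 0

    def test_isolated_nodes_dropped(self):
        rho = np.array(
            [[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        p = np.where(rho > 0, 1e-6, 1.0)
        net = build_network(_corr_result(rho, p))
        assert sorted(net.nodes) == ["t0", "t1"]
        assert net.n_tested_pairs == 3

    def test_threshold_validation(self):
        rho = np.eye(2)
        p = np.zeros((2, 2))
        with pytest.raises(ValueError):
            build_network(_corr_result(rho, p), rho_min=1.5)
        with pytest.raises(ValueError):
            build_network(_corr_result(rho, p), alpha=0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_edges_invariant_under_monotone_transform(self, seed):
        # Spearman is a rank statistic: exp() of abundances changes nothing
        rng = np.random.default_rng(seed)
        rel = pd.DataFrame(
            rng.random((12, 5)), columns=[f"t{i}" for i in range(5)]
        )
        net_a = build_network(spearman_all_pairs(rel), rho_min=0.2, alpha=0.3)
        net_b = build_network(
            spearman_all_pairs(np.exp(3 * rel)), rho_min=0.2, alpha=0.3
        )
        assert set(net_a.graph.edges) == set(net_b.graph.edges)


class TestDetectModules:
    def _net(self, graph: nx.Graph) -> CooccurrenceNetwork:
        return CooccurrenceNetwork(graph=graph)

    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        net = detect_modules(self._net(g), seed=0)
        assert net.n_modules == 2
        groups = {}
        for node, m in net.module_of.items():
            groups.setdefault(m, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            [f"t{i}" for i in range(5)],
            [f"t{i}" for i in range(5, 10)],
        ]

    def test_single_clique_single_module(self):
        g = nx.relabel_nodes(nx.complete_graph(6), {i: f"t{i}" for i in range(6)})
        net = detect_modules(self._net(g), seed=0)
        assert net.n_modules == 1
        assert net.modularity == pytest.approx(0.0, abs=1e-12)

    def test_modules_ordered_by_descending_size(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(7))
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        net = detect_modules(self._net(g), seed=0)
        sizes = net.module_sizes()
        assert sizes[0] == 7 and sizes[1] == 3
        assert net.major_modules(min_size=5) == [0]

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(30, 0.2, seed=42)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        g.remove_nodes_from(list(nx.isolates(g)))
        a = detect_modules(self._net(g.copy()), seed=7)
        b = detect_modules(self._net(g.copy()), seed=7)
        assert a.module_of == b.module_of

    def test_empty_network_rejected(self):
        with pytest.raises(MercnetError):
            detect_modules(self._net(nx.Graph()), seed=0)


class TestModuleProfile:
    def _net_with_modules(self, module_of: dict) -> CooccurrenceNetwork:
        g = nx.Graph()
        g.add_nodes_from(module_of)
        return CooccurrenceNetwork(graph=g, module_of=module_of)

    def test_single_taxon_module_equals_z_scores(self):
        rel = pd.DataFrame(
            {"a": [0.2, 0.4, 0.6], "b": [0.8, 0.6, 0.4]}, index=["s1", "s2", "s3"]
        )
        net = self._net_with_modules({"a": 0})
        prof = module_relative_abundance(rel, net)
        z = (rel["a"] - rel["a"].mean()) / rel["a"].std(ddof=0)
        assert np.allclose(prof.values["module_0"], z)

    def test_columns_centred(self):
        rng = np.random.default_rng(3)
        rel = pd.DataFrame(
            rng.random((8, 6)), columns=[f"t{i}" for i in range(6)]
        )
        net = self._net_with_modules({f"t{i}": i % 2 for i in range(6)})
        prof = module_relative_abundance(rel, net)
        assert np.allclose(prof.values.mean(axis=0), 0.0, atol=1e-9)

    def test_mean_of_member_z_scores_oracle(self):
        rng = np.random.default_rng(11)
        rel = pd.DataFrame(
            rng.random((6, 5)), columns=[f"t{i}" for i in range(5)]
        )
        module_of = {"t0": 0, "t1": 0, "t2": 1, "t3": 1, "t4": 1}
        prof = module_relative_abundance(rel, self._net_with_modules(module_of))
        z = (rel - rel.mean()) / rel.std(ddof=0)
        assert np.allclose(prof.values["module_0"], z[["t0", "t1"]].mean(axis=1))
        assert np.allclose(
            prof.values["module_1"], z[["t2", "t3", "t4"]].mean(axis=1)
        )

    def test_zero_variance_member_contributes_zero(self):
        rel = pd.DataFrame(
            {"a": [0.5, 0.5, 0.5], "b": [0.1, 0.2, 0.3]}, index=["s1", "s2", "s3"]
        )
        net = self._net_with_modules({"a": 0, "b": 0})
        prof = module_relative_abundance(rel, net)
        zb = (rel["b"] - rel["b"].mean()) / rel["b"].std(ddof=0)
        assert np.allclose(prof.values["module_0"], zb / 2)

    def test_module_absent_from_table_raises(self):
        rel = pd.DataFrame({"a": [0.1, 0.2]}, index=["s1", "s2"])
        net = self._net_with_modules({"a": 0, "missing": 1})
        with pytest.raises(MercnetError, match="module"):
            module_relative_abundance(rel, net)


class TestPlantedRecovery:
    def _net(self, module_of: dict) -> CooccurrenceNetwork:
        g = nx.Graph()
        g.add_nodes_from(module_of)
        return CooccurrenceNetwork(graph=g, module_of=module_of)

    def test_identical_partitions(self):
        truth = {f"t{i}": i % 3 for i in range(12)}
        assert recover_planted_modules(self._net(truth), truth) == pytest.approx(1.0)

    def test_singletons_vs_balanced_truth_near_zero(self):
        truth = {f"t{i}": i % 2 for i in range(10)}
        singletons = {f"t{i}": i for i in range(10)}
        ari = recover_planted_modules(self._net(singletons), truth)
        assert abs(ari) < 1e-9

    def test_no_overlap_raises(self):
        net = self._net({"a": 0})
        with pytest.raises(MercnetError):
            recover_planted_modules(net, {"other": 1})
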