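import math

import numpy as np
import pandas as pd
import pytest

from secretomenet.network import (
    ClassNetwork,
    ProteinNetwork,
    average_class_networks,
    collapse_classes,
    discretize_weights,
    edge_pvalue,
    export_network,
    filter_network,
    import_graphml,
    impute_missing,
    mlf_edge_pvalues,
    node_strength,
    protein_adjacency,
)


def brute_force_collapse(net: ProteinNetwork, class_sets):
    """Independent oracle: literal double sums with the intra-class
    adjustment, no vectorization shared with the implementation."""
    labels = list(class_sets)
    C = {}
    for a in labels:
        for b in labels:
            Si, Sj = class_sets[a], class_sets[b]
            if not Si or not Sj:
                C[(a, b)] = math.nan
                continue
            total = 0.0
            for v in Si:
                for u in Sj:
                    total += net.edge(v, u)
            if a == b:
                denom = len(Si) ** 2 - len(Si)
                C[(a, b)] = (total - len(Si)) / denom if denom > 0 else math.nan
            else:
                C[(a, b)] = total / (len(Si) * len(Sj))
    return C


def random_protein_network(rng, n):
    w = rng.uniform(0, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return ProteinNetwork(node_ids=[f"P{i}" for i in range(n)], weights=w)


class TestImputeMissing:
    def test_all_missing_row_becomes_floor(self):
        df = pd.DataFrame([[np.nan, np.nan], [1.0, np.nan]], index=["a", "b"])
        out = impute_missing(df)
        assert out.loc["a"].tolist() == [-10.0, -10.0]
        assert out.loc["b"].tolist() == [1.0, -10.0]

    def test_identity_without_missing(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["a"])
        assert impute_missing(df).equals(df)


class TestProteinAdjacency:
    def test_duplicate_profiles_fully_connected(self):
        df = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4]], index=["u", "v"])
        net = protein_adjacency(df)
        assert net.edge("u", "v") == pytest.approx(1.0)

    def test_anticorrelated_profiles_fully_connected(self):
        # unsigned adjacency: |r| = 1 for a profile mirrored about its mean
        df = pd.DataFrame([[1.0, 2, 3, 4], [4.0, 3, 2, 1]], index=["u", "v"])
        net = protein_adjacency(df, beta=1.0)
        assert net.edge("u", "v") == pytest.approx(1.0)

    def test_soft_threshold_matches_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 15))
        df = pd.DataFrame(x, index=[f"P{i}" for i in range(6)])
        net = protein_adjacency(df, beta=6.0)
        expected = np.abs(np.corrcoef(x)) ** 6
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(net.weights, expected, atol=1e-12)

    def test_constant_profile_carries_no_signal(self):
        df = pd.DataFrame([[5.0, 5, 5, 5], [1.0, 2, 3, 4]], index=["flat", "x"])
        net = protein_adjacency(df)
        assert net.edge("flat", "x") == 0.0
        assert net.edge("flat", "flat") == 1.0

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1.0, 2], [2.0, 1]], index=["a", "b"])
        with pytest.raises(ValueError, match="at least 3 samples"):
            protein_adjacency(df)

    def test_unimputed_matrix_rejected(self):
        df = pd.DataFrame([[1.0, np.nan, 3]], index=["a"])
        with pytest.raises(ValueError, match="impute"):
            protein_adjacency(df)


class TestProteinNetworkInvariants:
    def test_asymmetry_rejected(self):
        w = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ProteinNetwork(["a", "b"], w)

    def test_out_of_bounds_rejected(self):
        w = np.array([[1.0, 1.4], [1.4, 1.0]])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            ProteinNetwork(["a", "b"], w)


class TestCollapseClasses:
    def _toy(self, edges):
        ids = sorted({x for e in edges for x in e[:2]})
        n = len(ids)
        w = np.eye(n)
        for a, b, val in edges:
            i, j = ids.index(a), ids.index(b)
            w[i, j] = w[j, i] = val
        return ProteinNetwork(ids, w)

    def test_inter_class_hand_value(self):
        net = self._toy([("a", "b", 0.0), ("a", "c", 0.5), ("b", "c", 0.7)])
        out = collapse_classes(net, {"i": {"a", "b"}, "j": {"c"}})
        assert out.coefficient("i", "j") == pytest.approx(0.6)

    def test_intra_class_removes_self_correlation(self):
        net = self._toy([("a", "b", 0.8)])
        out = collapse_classes(net, {"i": {"a", "b"}})
        # (1 + .8 + .8 + 1 - 2) / (4 - 2)
        assert out.coefficient("i", "i") == pytest.approx(0.8)

    def test_singleton_classes_reduce_to_edge_weight(self):
        net = self._toy([("a", "b", 0.37)])
        out = collapse_classes(net, {"i": {"a"}, "j": {"b"}})
        assert out.coefficient("i", "j") == pytest.approx(0.37)
        assert np.isnan(out.coefficient("i", "i"))  # singleton intra undefined

    def test_empty_class_undefined(self):
        net = self._toy([("a", "b", 0.5)])
        out = collapse_classes(net, {"i": {"a", "b"}, "empty": set()})
        assert np.isnan(out.coefficient("i", "empty"))
        assert out.size("empty") == 0

    def test_overlapping_membership_allowed(self):
        net = self._toy([("a", "b", 0.4), ("a", "c", 0.2), ("b", "c", 0.9)])
        out = collapse_classes(net, {"i": {"a", "b"}, "j": {"b", "c"}})
        oracle = brute_force_collapse(net, {"i": {"a", "b"}, "j": {"b", "c"}})
        assert out.coefficient("i", "j") == pytest.approx(oracle[("i", "j")], abs=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 11))
        net = random_protein_network(rng, n)
        n_classes = int(rng.integers(1, 5))
        class_sets = {
            f"c{k}": {f"P{i}" for i in range(n) if rng.uniform() < 0.5}
            for k in range(n_classes)
        }
        out = collapse_classes(net, class_sets)
        oracle = brute_force_collapse(net, class_sets)
        for a in class_sets:
            for b in class_sets:
                got = out.coefficient(a, b)
                want = oracle[(a, b)]
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_unknown_member_rejected(self):
        net = self._toy([("a", "b", 0.5)])
        with pytest.raises(KeyError):
            collapse_classes(net, {"i": {"zzz"}})


class TestAverageClassNetworks:
    def _net(self, C, classes=("x", "y"), sizes=(2, 2)):
        return ClassNetwork(classes=list(classes), sizes=np.array(sizes, float),
                            C=np.array(C, float))

    def test_single_network_is_identity(self):
        net = self._net([[np.nan, 0.3], [0.3, np.nan]])
        out = average_class_networks([net])
        assert out.coefficient("x", "y") == pytest.approx(0.3)

    def test_undefined_entries_omitted_from_mean(self):
        a = self._net([[np.nan, 0.2], [0.2, np.nan]])
        b = self._net([[np.nan, np.nan], [np.nan, np.nan]])
        out = average_class_networks([a, b])
        assert out.coefficient("x", "y") == pytest.approx(0.2)

    def test_plain_mean_of_defined_entries(self):
        a = self._net([[np.nan, 0.2], [0.2, np.nan]])
        b = self._net([[np.nan, 0.6], [0.6, np.nan]])
        out = average_class_networks([a, b])
        assert out.coefficient("x", "y") == pytest.approx(0.4)

    def test_idempotent_over_copies(self):
        rng = np.random.default_rng(8)
        C = rng.uniform(0, 1, size=(3, 3))
        C = (C + C.T) / 2
        net = ClassNetwork(classes=["a", "b", "c"], sizes=np.ones(3) * 2, C=C)
        out = average_class_networks([net] * 5)
        assert np.allclose(out.C, C)

    def test_union_of_class_vocabularies(self):
        a = self._net([[np.nan, 0.5], [0.5, np.nan]], classes=("x", "y"))
        b = self._net([[np.nan, 0.1], [0.1, np.nan]], classes=("y", "z"))
        out = average_class_networks([a, b])
        assert set(out.classes) == {"x", "y", "z"}
        assert out.coefficient("x", "y") == pytest.approx(0.5)
        assert out.coefficient("y", "z") == pytest.approx(0.1)
        assert np.isnan(out.coefficient("x", "z"))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_class_networks([])


class TestNodeStrength:
    def test_isolated_class_has_zero_strength(self):
        net = ClassNetwork(classes=["a", "b"], sizes=np.array([2.0, 2.0]),
                           C=np.full((2, 2), np.nan))
        s = node_strength(net)
        assert s == {"a": 0.0, "b": 0.0}

    def test_triangle_without_self_loops(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, np.nan)
        net = ClassNetwork(classes=["a", "b", "c"], sizes=np.ones(3) * 2, C=C)
        s = node_strength(net)
        assert all(v == pytest.approx(1.0) for v in s.values())

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(10)
        C = rng.uniform(0, 1, size=(6, 6))
        C = (C + C.T) / 2
        C[2, 4] = C[4, 2] = np.nan
        net = ClassNetwork(classes=[f"c{i}" for i in range(6)], sizes=np.ones(6) * 3, C=C)
        s = node_strength(net)
        for i, label in enumerate(net.classes):
            assert s[label] == pytest.approx(np.nansum(C[i]))


class TestDiscretizeWeights:
    def _one_edge(self, c):
        C = np.array([[np.nan, c], [c, np.nan]])
        return ClassNetwork(classes=["a", "b"], sizes=np.array([2.0, 2.0]), C=C)

    @pytest.mark.parametrize("c,expected", [(0.006, 1), (0.0049, 0), (1.0, 100), (0.505, 51), (0.005, 1)])
    def test_half_up_rounding(self, c, expected):
        out = discretize_weights(self._one_edge(c))
        assert out.int_weights[0, 1] == expected

    def test_out_of_range_rejected(self):
        net = ClassNetwork(classes=["a", "b"], sizes=np.array([2.0, 2.0]),
                           C=np.array([[np.nan, 0.5], [0.5, np.nan]]))
        net.C[0, 1] = net.C[1, 0] = 1.5  # bypass constructor check
        with pytest.raises(ValueError):
            discretize_weights(net)


class TestMarginalLikelihoodFilter:
    def _triangle(self, ab, ac, bc):
        C = np.array(
            [[np.nan, ab, ac], [ab, np.nan, bc], [ac, bc, np.nan]]
        ) / 100.0
        net = ClassNetwork(classes=["A", "B", "C"], sizes=np.ones(3) * 2, C=C)
        return discretize_weights(net)

    def test_triangle_case_exact_binomial_tail(self):
        # AB=5, AC=3, BC=2: T=10, k_A=8, k_B=7 -> p_AB=0.28,
        # pval = P(Bin(10, .28) >= 5)
        net = self._triangle(5, 3, 2)
        edges = {frozenset((e.i, e.j)): e for e in mlf_edge_pvalues(net)}
        ab = edges[frozenset(("A", "B"))]
        assert (ab.w, ab.k_i, ab.k_j, ab.T) == (5, 8, 7, 10)
        assert ab.p_ij == pytest.approx(0.28)
        assert ab.pvalue == pytest.approx(0.1181170641, abs=1e-9)

    @pytest.mark.parametrize("w", [1, 3, 7])
    def test_single_edge_degenerate_case(self, w):
        C = np.array([[np.nan, w / 100], [w / 100, np.nan]])
        net = discretize_weights(
            ClassNetwork(classes=["A", "B"], sizes=np.array([1.0, 1.0]), C=C)
        )
        edges = mlf_edge_pvalues(net)
        assert len(edges) == 1
        assert edges[0].p_ij == pytest.approx(0.5)  # w^2 / (2 w^2)
        assert edges[0].pvalue == pytest.approx(0.5**w)

    def test_zero_total_weight_empty_result(self):
        net = discretize_weights(
            ClassNetwork(classes=["A", "B"], sizes=np.array([1.0, 1.0]),
                         C=np.array([[np.nan, 0.001], [0.001, np.nan]]))
        )
        assert mlf_edge_pvalues(net) == []

    def test_pvalue_nonincreasing_in_weight(self):
        pvals = [edge_pvalue(w, k_i=8, k_j=7, T=10) for w in range(0, 11)]
        assert pvals[0] == pytest.approx(1.0)  # upper tail at zero
        assert all(a >= b - 1e-15 for a, b in zip(pvals, pvals[1:]))

    def test_requires_discretization(self):
        net = ClassNetwork(classes=["A", "B"], sizes=np.array([1.0, 1.0]),
                           C=np.array([[np.nan, 0.5], [0.5, np.nan]]))
        with pytest.raises(ValueError, match="discretize"):
            mlf_edge_pvalues(net)


class TestFilterNetwork:
    def _with_pvalues(self):
        net = ClassNetwork(
            classes=["A", "B", "C"], sizes=np.ones(3) * 2,
            C=np.array([[np.nan, 0.05, 0.03], [0.05, np.nan, 0.02], [0.03, 0.02, np.nan]]),
        )
        net = discretize_weights(net)
        mlf_edge_pvalues(net)
        return net

    def test_alpha_one_keeps_everything(self):
        net = self._with_pvalues()
        out = filter_network(net, alpha=1.0)
        assert (out.int_weights > 0).sum() == (net.int_weights > 0).sum()

    def test_alpha_zero_drops_everything(self):
        net = self._with_pvalues()
        out = filter_network(net, alpha=0.0)
        assert (out.int_weights > 0).sum() == 0
        assert out.classes == net.classes  # isolated nodes retained

    def test_strengths_reported_from_prefilter_network(self):
        net = self._with_pvalues()
        strengths = node_strength(net)
        out = filter_network(net, alpha=0.0)
        # filtering removed the edges, but the hub ranking input is unchanged
        assert node_strength(net) == strengths
        assert all(np.isnan(out.C[i, j]) for i in range(3) for j in range(3) if i != j)


class TestExportImport:
    def _network(self):
        C = np.array([[0.7, 0.5, np.nan], [0.5, np.nan, 0.2], [np.nan, 0.2, np.nan]])
        net = ClassNetwork(classes=["lpmo", "cdh", "laccase"],
                           sizes=np.array([4.0, 2.0, 3.0]), C=C)
        net = discretize_weights(net)
        mlf_edge_pvalues(net)
        return net

    def test_graphml_round_trip(self, tmp_path):
        net = self._network()
        paths = export_network(net, tmp_path / "net", formats=("graphml",))
        back = import_graphml(paths["graphml"])
        for a in net.classes:
            for b in net.classes:
                i, j = net.index(a), net.index(b)
                bi, bj = back.index(a), back.index(b)
                if i != j and not np.isnan(net.C[i, j]) and net.int_weights[i, j] > 0:
                    assert back.C[bi, bj] == pytest.approx(net.C[i, j])
                    assert back.int_weights[bi, bj] == net.int_weights[i, j]
        assert back.size("lpmo") == 4

    def test_empty_network_yields_valid_files(self, tmp_path):
        net = ClassNetwork(classes=["a", "b"], sizes=np.array([1.0, 1.0]),
                           C=np.full((2, 2), np.nan))
        net = discretize_weights(net)
        mlf_edge_pvalues(net)
        paths = export_network(net, tmp_path / "empty")
        back = import_graphml(paths["graphml"])
        assert set(back.classes) == {"a", "b"}
        assert paths["edges"].read_text().splitlines()[0] == "source\ttarget\tC\tw_int\tpvalue"

    def test_sif_snapshot(self, tmp_path):
        net = self._network()
        paths = export_network(net, tmp_path / "net", formats=("sif",))
        assert paths["sif"].read_text() == "cdh\tco\tlaccase\nlpmo\tco\tcdh\n"
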