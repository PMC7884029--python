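"""Co-expression network: correlations, TOM, modules, eigengenes, graph."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from centproteo import (ModuleSet, build_module_graph, correlation_matrix,
                        detect_modules, module_eigengene,
                        module_group_difference, soft_threshold_select,
                        topological_overlap)
from conftest import block_expression, make_study


def detect(expr, min_size=20):
    corr = correlation_matrix(expr, expr.index)
    sel = soft_threshold_select(corr)
    tom = topological_overlap(sel["adjacency"])
    return detect_modules(tom, min_module_size=min_size, corr=corr)


class TestCorrelation:
    def test_duplicated_columns_fully_correlated(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(7, 0.3, 50)
        expr = pd.DataFrame({"a": x, "b": x, "c": rng.lognormal(7, 0.3, 50)},
                            index=[f"S{i}" for i in range(50)])
        corr = correlation_matrix(expr, expr.index)
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_weakly_correlated(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(np.exp(rng.normal(7, 0.3, (500, 40))),
                            index=[f"S{i}" for i in range(500)],
                            columns=[f"A{j}" for j in range(40)])
        corr = correlation_matrix(expr, expr.index).to_numpy()
        off = corr[np.triu_indices(40, 1)]
        assert (np.abs(off) < 0.2).mean() >= 0.99

    def test_hand_computed_pearson(self):
        logx = np.array([[1.0, 2.0, 0.5, 3.0],
                         [2.0, 1.0, 1.5, 2.5],
                         [3.0, 4.0, 2.5, 1.0]]).T  # 4 samples x 3 aptamers
        expr = pd.DataFrame(np.exp(logx), index=list("wxyz"),
                            columns=list("abc"))
        # oracle by explicit sums (10 samples min relaxed via direct call)
        with pytest.raises(ValueError):
            correlation_matrix(expr, expr.index)  # < 10 samples rejected
        expr10 = pd.concat([expr] * 3)[:10]
        expr10.index = [f"S{i}" for i in range(10)]
        corr = correlation_matrix(expr10, expr10.index)
        logx10 = np.log(expr10.to_numpy())
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            xi, xj = logx10[:, i], logx10[:, j]
            oracle = (np.sum((xi - xi.mean()) * (xj - xj.mean()))
                      / np.sqrt(np.sum((xi - xi.mean()) ** 2)
                                * np.sum((xj - xj.mean()) ** 2)))
            assert corr.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_column_zeroed(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(np.exp(rng.normal(7, 0.3, (20, 3))),
                            index=[f"S{i}" for i in range(20)],
                            columns=list("abc"))
        expr["b"] = 5.0
        corr = correlation_matrix(expr, expr.index)
        assert corr.loc["a", "b"] == 0.0 and corr.loc["b", "b"] == 1.0


class TestSoftThreshold:
    def test_block_fixture_amplifies_contrast(self):
        expr = block_expression(seed=0, latent_share=0.5)
        corr = correlation_matrix(expr, expr.index)
        sel = soft_threshold_select(corr)
        adj = sel["adjacency"].to_numpy()
        within = adj[:30, :30][np.triu_indices(30, 1)]
        between = adj[:30, 60:]
        assert np.median(within) >= 10 * max(np.median(between), 1e-12)

    def test_power_one_is_absolute_correlation(self):
        expr = block_expression(seed=1)
        corr = correlation_matrix(expr, expr.index)
        sel = soft_threshold_select(corr, powers=[1])
        np.testing.assert_allclose(sel["adjacency"].to_numpy(),
                                   np.abs(corr.to_numpy()), atol=1e-12)

    def test_mean_adjacency_monotone_in_power(self):
        expr = block_expression(seed=2)
        corr = np.abs(correlation_matrix(expr, expr.index).to_numpy())
        means = [(corr**b).mean() for b in range(1, 13)]
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestTOM:
    def test_isolated_strong_pair_has_unit_overlap(self):
        adj = pd.DataFrame(np.array([[0.0, 1.0], [1.0, 0.0]]),
                           index=list("ab"), columns=list("ab"))
        tom = topological_overlap(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_four_node_hand_example(self):
        A = np.array([[0.0, 0.5, 0.2, 0.0],
                      [0.5, 0.0, 0.4, 0.1],
                      [0.2, 0.4, 0.0, 0.3],
                      [0.0, 0.1, 0.3, 0.0]])
        adj = pd.DataFrame(A, index=list("abcd"), columns=list("abcd"))
        tom = topological_overlap(adj)
        k = A.sum(axis=0)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(4))
                oracle = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_values_bounded_on_random_adjacency(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0, 1, (30, 30))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = topological_overlap(pd.DataFrame(A)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(pd.DataFrame(A))


class TestModuleDetection:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(5):
            expr = block_expression(seed=seed)
            mods = detect(expr)
            truth = np.array([0] * 30 + [1] * 30 + [2] * 140)
            pred = np.full(200, 99)
            for mi, members in enumerate(mods.memberships.values()):
                for a in members:
                    pred[int(a[1:])] = mi
            aris.append(adjusted_rand_score(truth, pred))
        assert np.mean(aris) >= 0.9

    def test_pure_noise_all_null(self):
        null_runs = 0
        for seed in range(10):
            expr = block_expression(seed=seed, n_blocks=0)
            mods = detect(expr)
            if len(mods.memberships) == 0:
                null_runs += 1
        assert null_runs >= 9

    def test_module_sizes_respect_floor(self):
        for seed in range(3):
            mods = detect(block_expression(seed=seed))
            assert all(s >= 20 for s in mods.sizes.values())

    def test_partition_invariant(self):
        expr = block_expression(seed=7)
        mods = detect(expr)
        assigned = set().union(*mods.memberships.values()) \
            if mods.memberships else set()
        assert assigned | mods.null_module == set(expr.columns)
        assert sum(mods.sizes.values()) + len(mods.null_module) == 200


class TestEigengene:
    def test_rank_one_module_perfectly_represented(self):
        rng = np.random.default_rng(11)
        latent = rng.normal(0, 1, 60)
        logx = np.outer(latent, np.full(5, 0.5)) + 7.0
        expr = pd.DataFrame(np.exp(logx), index=[f"S{i}" for i in range(60)],
                            columns=list("abcde"))
        eig = module_eigengene(expr, set("abcde"), expr.index)
        z = (np.log(expr) - np.log(expr).mean()) / np.log(expr).std(ddof=1)
        for c in "abcde":
            assert abs(np.corrcoef(eig, z[c])[0, 1]) == pytest.approx(1.0,
                                                                      abs=1e-9)

    def test_sign_convention_positive_vs_mean_profile(self):
        for seed in range(5):
            expr = block_expression(seed=seed)
            eig = module_eigengene(expr, set(expr.columns[:30]), expr.index)
            logx = np.log(expr[expr.columns[:30]])
            z = (logx - logx.mean()) / logx.std(ddof=1)
            assert np.corrcoef(eig, z.mean(axis=1))[0, 1] >= 0

    def test_explained_variance_matches_eigendecomposition(self):
        expr = block_expression(seed=13)
        members = set(expr.columns[:30])
        logx = np.log(expr[sorted(members)])
        z = ((logx - logx.mean()) / logx.std(ddof=1)).to_numpy()
        eig = module_eigengene(expr, members, expr.index)
        # independent oracle: eigendecomposition of the covariance
        evals = np.linalg.eigvalsh(z.T @ z)
        share_oracle = evals[-1] / evals.sum()
        proj = z.T @ (eig / np.linalg.norm(eig))
        share = (proj @ proj) / (z**2).sum()
        assert share == pytest.approx(share_oracle, abs=1e-10)

    def test_unit_variance(self):
        expr = block_expression(seed=17)
        eig = module_eigengene(expr, set(expr.columns[:30]), expr.index)
        assert eig.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestGroupDifference:
    @staticmethod
    def _with_groups(expr, n_cent):
        samples = pd.DataFrame(
            {"group": ["centenarian"] * n_cent
             + ["control"] * (len(expr) - n_cent)}, index=expr.index)
        return samples

    def test_identical_groups_near_zero(self):
        vals = []
        for seed in range(5):
            expr = block_expression(seed=seed, n=120)
            samples = self._with_groups(expr, 60)
            vals.append(module_group_difference(
                expr, set(expr.columns[:30]), samples, "centenarian"))
        assert np.all(np.abs(vals) < 0.1 * 3)  # no planted shift

    def test_planted_shift_gives_positive_difference(self):
        expr = block_expression(seed=19, n=120)
        shifted = expr.copy()
        cols = expr.columns[:30]
        shifted.loc[shifted.index[:60], cols] *= np.exp(0.5 * 0.25)
        samples = self._with_groups(shifted, 60)
        val = module_group_difference(shifted, set(cols), samples,
                                      "centenarian")
        assert val > 0

    def test_antisymmetry(self):
        expr = block_expression(seed=23, n=100)
        samples = self._with_groups(expr, 40)
        a = module_group_difference(expr, set(expr.columns[:30]), samples,
                                    "centenarian", "control")
        b = module_group_difference(expr, set(expr.columns[:30]), samples,
                                    "control", "centenarian")
        assert a == pytest.approx(-b, abs=1e-12)


class TestModuleGraph:
    @staticmethod
    def _module_set(group, memberships, universe):
        assigned = set().union(*memberships.values()) if memberships else set()
        return ModuleSet(group, memberships, set(universe) - assigned)

    def test_identical_modules_fully_connected_across_groups(self):
        universe = {f"A{i}" for i in range(100)}
        mem = {"M1": {f"A{i}" for i in range(30)},
               "M2": {f"A{i}" for i in range(30, 60)}}
        g = build_module_graph(self._module_set("a", mem, universe),
                               self._module_set("b", dict(mem), universe))
        cross = [(u, v) for u, v, d in g.edges(data=True)
                 if d["kind"] == "jaccard_overlap"]
        assert len(cross) == 2
        assert all(d["weight"] == 1.0 for _u, _v, d in g.edges(data=True))

    def test_disjoint_modules_unconnected(self):
        universe = {f"A{i}" for i in range(100)}
        a = self._module_set("a", {"M1": {f"A{i}" for i in range(30)}},
                             universe)
        b = self._module_set("b", {"M1": {f"A{i}" for i in range(30, 60)}},
                             universe)
        assert build_module_graph(a, b).number_of_edges() == 0

    def test_edges_equal_brute_force_jaccard(self):
        rng = np.random.default_rng(29)
        universe = [f"A{i}" for i in range(120)]
        mem_a = {f"M{k}": set(rng.choice(universe, 25, replace=False))
                 for k in range(1, 4)}
        used = set().union(*mem_a.values())
        mem_a = {k: v - set().union(*(mem_a[j] for j in mem_a if j < k))
                 for k, v in mem_a.items()}
        mem_a = {k: v for k, v in mem_a.items() if len(v) >= 5}
        mem_b = {f"M{k}": set(rng.choice(universe, 30, replace=False))
                 for k in range(1, 3)}
        mem_b = {"M1": mem_b["M1"], "M2": mem_b["M2"] - mem_b["M1"]}
        g = build_module_graph(self._module_set("a", mem_a, universe),
                               self._module_set("b", mem_b, universe),
                               jaccard_threshold=0.05)
        expected = set()
        for ka, va in mem_a.items():
            for kb, vb in mem_b.items():
                if len(va & vb) / len(va | vb) > 0.05:
                    expected.add((("a", ka), ("b", kb)))
        got = {(u, v) if u[0] == "a" else (v, u)
               for u, v, d in g.edges(data=True)
               if d["kind"] == "jaccard_overlap"}
        assert got == expected

    def test_mismatched_universes_rejected(self):
        a = self._module_set("a", {}, {"A1"})
        b = self._module_set("b", {}, {"A2"})
        with pytest.raises(ValueError):
            build_module_graph(a, b)

    def test_conserved_planted_modules_connected(self):
        # same modules planted in both groups: the graph should link
        # nearly all planted pairs across layers
        connected, total = 0, 0
        for seed in range(3):
            study, truth = make_study(n_aptamers=250, n_modules=2,
                                      module_size_range=(25, 35),
                                      module_latent_sd=0.3,
                                      seed=600 + seed)
            layers = {}
            for label, groups in (("cent", ["centenarian"]),
                                  ("young", ["offspring", "control"])):
                samp = study.samples.index[study.samples["group"].isin(groups)]
                corr = correlation_matrix(study.expression, samp)
                sel = soft_threshold_select(corr)
                tom = topological_overlap(sel["adjacency"])
                layers[label] = detect_modules(tom, 20, corr=corr, group=label)
            g = build_module_graph(layers["cent"], layers["young"])
            for mod in set(truth.module_assignment) - {"unassigned"}:
                total += 1
                planted = set(
                    truth.module_assignment.index[truth.module_assignment == mod])
                # find best-matching detected module in each layer
                pair = []
                for label in ("cent", "young"):
                    best = None, 0.0
                    for mid, members in layers[label].memberships.items():
                        j = len(members & planted) / len(members | planted)
                        if j > best[1]:
                            best = (label, mid), j
                    pair.append(best[0])
                if pair[0] and pair[1] and g.has_edge(pair[0], pair[1]):
                    connected += 1
        assert total > 0 and connected / total >= 0.9
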