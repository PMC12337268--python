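import dataclasses

import numpy as np
import pandas as pd
import pytest

from pavcoex import network
from pavcoex.config import AnalysisConfig
from pavcoex.io import CountsMatrix


def block_expression(rng, blocks, n_strains=20, noise=0.5, loading=1.0):
    """Planted-block expression: genes in a block share a strain factor."""
    rows, names = [], []
    for b, size in enumerate(blocks):
        factor = rng.normal(size=n_strains)
        for i in range(size):
            rows.append(loading * factor + noise * rng.normal(size=n_strains))
            names.append(f"b{b}_g{i}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"S{i}" for i in range(n_strains)])


class TestPrefilter:
    def test_median_boundary(self):
        counts = np.array([[9] * 5, [10] * 5, [0, 0, 10, 10, 10]])
        cm = CountsMatrix(pd.Index(["lo", "hi", "mid"]),
                          pd.Index([f"s{i}" for i in range(5)]), counts)
        kept = network.prefilter_for_network(cm, floor=10)
        assert set(kept) == {"hi", "mid"}

    def test_all_above_floor_is_identity(self):
        cm = CountsMatrix(pd.Index(["a", "b"]), pd.Index(["s1", "s2"]),
                          np.full((2, 2), 50))
        assert list(network.prefilter_for_network(cm, 10)) == ["a", "b"]


class TestTOM:
    def test_two_gene_perfect_adjacency(self):
        tom = network.compute_tom(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 0] == 1.0

    def test_zero_adjacency_zero_overlap(self):
        tom = network.compute_tom(np.zeros((4, 4)))
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 10))
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = network.compute_tom(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                    expected = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            network.compute_tom(np.array([[0.0, 0.5], [0.1, 0.0]]))


class TestSoftPower:
    def test_beta_one_adjacency_is_absolute_correlation(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(3, 10)))
        adj = network.adjacency_matrix(expr, beta=1)
        cor = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(cor, 0.0)
        assert np.allclose(adj, cor, atol=1e-12)

    def test_deterministic_choice(self):
        rng = np.random.default_rng(2)
        expr = block_expression(rng, [30, 30])
        cfg = AnalysisConfig()
        b1, f1 = network.pick_soft_power(expr, cfg)
        b2, f2 = network.pick_soft_power(expr, cfg)
        assert b1 == b2
        pd.testing.assert_frame_equal(f1, f2)
        assert b1 in cfg.soft_power_grid

    def test_independent_genes_use_fallback_argmax(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(120, 20)))
        cfg = AnalysisConfig()
        beta, fit = network.pick_soft_power(expr, cfg)
        eligible = fit[fit["mean_connectivity"] <= cfg.max_mean_connectivity]
        if (eligible["r2"] < cfg.scale_free_r2).all():
            assert beta == int(eligible.loc[eligible["r2"].idxmax(), "beta"])
        else:
            assert beta == int(
                eligible.loc[eligible["r2"] >= cfg.scale_free_r2, "beta"].iloc[0])

    def test_constant_matrix_rejected(self):
        expr = pd.DataFrame(np.ones((5, 6)))
        with pytest.raises(ValueError):
            network.pick_soft_power(expr, AnalysisConfig())


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(4)
        expr = block_expression(rng, [30, 30], noise=0.33)  # within-block cor ~0.9
        net = network.build_network(expr, AnalysisConfig())
        assert len(net.module_sizes) == 2
        labels = net.assignment
        for b in (0, 1):
            members = labels[labels.index.str.startswith(f"b{b}_")]
            assert members.nunique() == 1
            assert (members != network.UNASSIGNED).all()

    def test_min_module_size_above_n_genes_unassigns_all(self):
        rng = np.random.default_rng(5)
        expr = block_expression(rng, [8])
        cfg = dataclasses.replace(AnalysisConfig(), min_module_size=50)
        adj = network.adjacency_matrix(expr, 6)
        with pytest.warns(UserWarning, match="unassigned"):
            assignment = network.cut_modules(network.compute_tom(adj),
                                             expr.index, cfg)
        assert (assignment == network.UNASSIGNED).all()

    def test_gene_relabeling_gives_identical_partition(self):
        from pavcoex.pipeline import adjusted_rand_index

        rng = np.random.default_rng(6)
        expr = block_expression(rng, [25, 20], noise=0.4)
        net_a = network.build_network(expr, AnalysisConfig())
        shuffled = expr.sample(frac=1, random_state=1)
        net_b = network.build_network(shuffled, AnalysisConfig())
        joined = pd.concat([net_a.assignment.rename("a"),
                            net_b.assignment.rename("b")], axis=1)
        assert adjusted_rand_index(joined["a"], joined["b"]) == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_gene_module_fully_explained(self):
        profile = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        expr = pd.DataFrame([profile] * 12,
                            index=[f"g{i}" for i in range(12)],
                            columns=[f"S{i}" for i in range(5)])
        assignment = pd.Series("M1", index=expr.index)
        eig, var = network.module_eigengenes(expr, assignment)
        r = np.corrcoef(eig.loc["M1"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert var["M1"] == pytest.approx(1.0, abs=1e-10)

    def test_orientation_positive_with_module_mean(self):
        rng = np.random.default_rng(7)
        factor = rng.normal(size=10)
        expr = pd.DataFrame([factor + 0.2 * rng.normal(size=10) for _ in range(15)],
                            index=[f"g{i}" for i in range(15)],
                            columns=[f"S{i}" for i in range(10)])
        assignment = pd.Series("M1", index=expr.index)
        eig, _ = network.module_eigengenes(expr, assignment)
        mean_profile = expr.mean(axis=0)
        assert np.corrcoef(eig.loc["M1"], mean_profile)[0, 1] > 0

    def test_unit_norm_over_strains(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(6, 7)),
                            index=[f"g{i}" for i in range(6)])
        eig, _ = network.module_eigengenes(expr, pd.Series("M1", index=expr.index))
        assert np.linalg.norm(eig.loc["M1"]) == pytest.approx(1.0, abs=1e-12)

    def test_variance_explained_matches_eigen_oracle(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(4, 8)),
                            index=list("abcd"))
        eig, var = network.module_eigengenes(expr, pd.Series("M1", index=expr.index))
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        lam = np.sort(np.linalg.eigvalsh(z @ z.T))[::-1]
        assert var["M1"] == pytest.approx(lam[0] / lam.sum(), abs=1e-8)


class TestMerge:
    def test_nearly_identical_modules_merged(self):
        rng = np.random.default_rng(10)
        factor = rng.normal(size=12)
        rows = [factor + 0.05 * rng.normal(size=12) for _ in range(24)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(24)])
        assignment = pd.Series(["A"] * 12 + ["B"] * 12, index=expr.index)
        merged, eig, _ = network.merge_similar_modules(expr, assignment, 0.75)
        assert merged.nunique() == 1

    def test_uncorrelated_modules_untouched(self):
        rng = np.random.default_rng(11)
        expr = block_expression(rng, [12, 12], noise=0.1)
        assignment = pd.Series(
            ["A"] * 12 + ["B"] * 12, index=expr.index)
        merged, _, _ = network.merge_similar_modules(expr, assignment, 0.75)
        assert merged.nunique() == 2

    def test_three_mutually_similar_modules_collapse_to_one(self):
        rng = np.random.default_rng(12)
        factor = rng.normal(size=15)
        rows = [factor + 0.1 * rng.normal(size=15) for _ in range(30)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(30)])
        assignment = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                               index=expr.index)
        merged, _, _ = network.merge_similar_modules(expr, assignment, 0.75)
        assert merged.nunique() == 1


def test_kme_rescue_attaches_left_out_members():
    rng = np.random.default_rng(13)
    expr = block_expression(rng, [20], noise=0.4)
    assignment = pd.Series(network.UNASSIGNED, index=expr.index, dtype=object)
    assignment.iloc[:12] = "M1"  # core misses 8 members
    rescued = network.assign_by_kme(expr, assignment, kme_min=0.6)
    assert (rescued == "M1").sum() > 12


def test_network_size_guard():
    rng = np.random.default_rng(14)
    expr = pd.DataFrame(rng.normal(size=(30, 6)))
    cfg = dataclasses.replace(AnalysisConfig(), max_network_genes=10)
    with pytest.raises(ValueError, match="max_network_genes"):
        network.build_network(expr, cfg)
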