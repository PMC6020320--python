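"""Network construction, module detection, eigengenes, and trait correlation."""

import numpy as np
import pandas as pd
import pytest

from eqtlnet.network import (
    CoexpressionNetwork,
    ModuleTraitCor,
    NetworkParams,
    adjacency,
    detect_modules,
    gene_significance,
    merge_modules,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    scale_free_fit,
    scale_tom,
    select_hub_genes,
    select_trait_modules,
    split_by_genotype,
    tom,
)
from tests.conftest import make_blocks


def frame(X, prefix="g"):
    return pd.DataFrame(
        X,
        index=[f"{prefix}{i}" for i in range(X.shape[0])],
        columns=[f"s{i}" for i in range(X.shape[1])],
    )


class TestSplit:
    def test_partition_and_exclusion(self):
        d = pd.Series([0, 0, 1, 1, 2], index=[f"s{i}" for i in range(5)], dtype=float)
        groups = split_by_genotype(d)
        assert groups["AA"] == ["s0", "s1"]
        assert groups["AB"] == ["s2", "s3"]
        assert groups["n_excluded"] == 1

    def test_monomorphic_error(self):
        d = pd.Series([0.0] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="monomorphic"):
            split_by_genotype(d)


class TestAdjacency:
    def test_identical_genes_unit_edge(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = frame(np.vstack([x, x]))
        a = adjacency(X)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 0] == 0.0

    def test_soft_power_closed_form(self):
        # cor = 0.5 at power 6 gives 0.5^6 = 0.015625
        assert 0.5**6 == pytest.approx(0.015625)
        rng = np.random.default_rng(1)
        X = frame(rng.standard_normal((5, 100)))
        a1 = adjacency(X, soft_power=1)
        np.testing.assert_allclose(
            a1 + np.eye(5), np.abs(np.corrcoef(X.to_numpy())), atol=1e-12
        )


class TestScaleFree:
    def test_planted_power_law(self):
        # exact power-law degree sequence: n(k) ~ k^-2 over k = 1..50
        ks = np.arange(1, 51, dtype=float)
        counts = np.maximum(1, np.round(400 * ks**-2.0)).astype(int)
        k = np.repeat(ks, counts)
        w = k / np.sqrt(k.sum())
        a = np.clip(np.outer(w, w), 0, 1)
        np.fill_diagonal(a, 0.0)
        r2, slope = scale_free_fit(a)
        assert r2 >= 0.9
        assert slope < 0

    def test_degenerate_errors(self):
        a = np.ones((25, 25)) * 0.5
        np.fill_diagonal(a, 0.0)
        with pytest.raises(ValueError, match="connectivities equal|occupied"):
            scale_free_fit(a)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = frame(rng.standard_normal((40, 60)))
        a = adjacency(X)
        perm = rng.permutation(40)
        r2a, _ = scale_free_fit(a)
        r2b, _ = scale_free_fit(a[np.ix_(perm, perm)])
        assert r2a == pytest.approx(r2b)


class TestTom:
    def test_clique_of_three(self):
        a = np.ones((3, 3)) - np.eye(3)
        t = tom(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_isolated_pair(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.5
        t = tom(a)
        # (l + a) / (min(k) + 1 - a) = (0 + 0.5) / (0.5 + 1 - 0.5)
        assert t[0, 1] == pytest.approx(0.5)

    def test_matches_brute_force_triple_sum(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(0, 1, size=(20, 20))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        t = tom(a)
        n = 20
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(5)
        X = frame(rng.standard_normal((30, 50)))
        t = tom(adjacency(X))
        assert ((t >= 0) & (t <= 1)).all()
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(t), 1.0)


class TestModules:
    def test_two_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        X, truth = make_blocks(seed=42)
        res = CoexpressionNetwork(X, NetworkParams()).fit()
        codes = pd.factorize(res.labels)[0]
        ari = adjusted_rand_score(truth[truth > 0], codes[truth > 0])
        assert ari >= 0.9
        assert len(res.modules) == 2

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal(100)
        X = frame(
            np.vstack(
                [0.9 * f + 0.3 * rng.standard_normal(100) for _ in range(10)]
                + [rng.standard_normal(100) for _ in range(40)]
            )
        )
        d = 1.0 - tom(adjacency(X))
        labels, _ = detect_modules(d, min_module_size=30)
        assert (labels == 0).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        rng = np.random.default_rng(7)
        X = frame(rng.standard_normal((10, 30)))
        labels, _ = detect_modules(1.0 - tom(adjacency(X)), min_module_size=30)
        assert (labels == 0).all()

    def test_noise_mostly_grey(self):
        rng = np.random.default_rng(8)
        X = frame(rng.standard_normal((120, 150)))
        res = CoexpressionNetwork(X).fit()
        assert (res.labels == "grey").mean() >= 0.8


class TestEigengene:
    def test_identical_genes(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(40)
        X = frame(np.vstack([x, x, x]))
        eig, var_exp = module_eigengene(X, np.array([1, 1, 1]))
        assert var_exp[1] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        r = np.corrcoef(eig.loc[1], z)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(10)
        X = frame(rng.standard_normal((15, 60)))
        labels = np.ones(15, dtype=int)
        eig, var_exp = module_eigengene(X, labels)
        Z = X.to_numpy()
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        v = vt[0] * np.sign(np.corrcoef(vt[0], Z.mean(axis=0))[0, 1])
        got = eig.loc[1].to_numpy()
        assert np.allclose(got, v, atol=1e-10) or np.allclose(got, -v, atol=1e-10)
        assert var_exp[1] == pytest.approx(float(s[0] ** 2 / (s**2).sum()))

    def test_sign_orientation(self):
        rng = np.random.default_rng(11)
        X = frame(rng.standard_normal((20, 50)))
        labels = np.ones(20, dtype=int)
        eig, _ = module_eigengene(X, labels)
        cors = [np.corrcoef(X.iloc[i], eig.loc[1])[0, 1] for i in range(20)]
        assert np.mean(cors) >= 0


class TestMerge:
    def _correlated_modules(self, rho, seed=12):
        rng = np.random.default_rng(seed)
        n = 150
        f1 = rng.standard_normal(n)
        f2 = rho * f1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        genes = [f1 + 0.1 * rng.standard_normal(n) for _ in range(35)]
        genes += [f2 + 0.1 * rng.standard_normal(n) for _ in range(35)]
        X = frame(np.asarray(genes))
        labels = np.array([1] * 35 + [2] * 35)
        return X, labels

    def test_high_correlation_merges(self):
        X, labels = self._correlated_modules(0.95)
        merged, history = merge_modules(X, labels, merge_height=0.25)
        assert len(set(merged)) == 1
        assert history

    def test_low_correlation_kept(self):
        X, labels = self._correlated_modules(0.5)
        merged, history = merge_modules(X, labels, merge_height=0.25)
        assert set(merged) == {1, 2}
        assert history == []

    def test_idempotent_at_fixed_point(self):
        X, labels = self._correlated_modules(0.95)
        merged, _ = merge_modules(X, labels, merge_height=0.25)
        again, history = merge_modules(X, merged, merge_height=0.25)
        np.testing.assert_array_equal(merged, again)
        assert history == []


class TestScaling:
    def test_closed_form_exponent(self):
        assert np.log(0.5) / np.log(0.25) == pytest.approx(0.5)
        t_small = np.full((4, 4), 0.25)
        np.fill_diagonal(t_small, 1.0)
        t_ref = np.full((4, 4), 0.5)
        np.fill_diagonal(t_ref, 1.0)
        scaled = scale_tom(t_small, t_ref, scale_quantile=0.95)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(scaled[off], 0.5, atol=1e-12)

    def test_identity_when_quantiles_match(self):
        rng = np.random.default_rng(13)
        t = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(0.1, 0.9, (10, 10))), 0, 1)
        np.fill_diagonal(t, 1.0)
        np.testing.assert_allclose(scale_tom(t, t), t, atol=1e-12)

    def test_order_preserved_and_quantile_matched(self):
        rng = np.random.default_rng(14)
        sym = lambda m: (m + m.T) / 2
        t1 = sym(rng.uniform(0.05, 0.6, (30, 30)))
        t2 = sym(rng.uniform(0.2, 0.9, (30, 30)))
        np.fill_diagonal(t1, 1.0)
        np.fill_diagonal(t2, 1.0)
        scaled = scale_tom(t1, t2, scale_quantile=0.95)
        off = ~np.eye(30, dtype=bool)
        assert np.quantile(scaled[off], 0.95) == pytest.approx(
            np.quantile(t2[off], 0.95), abs=1e-6
        )
        order1 = np.argsort(t1[off])
        order2 = np.argsort(scaled[off])
        np.testing.assert_array_equal(order1, order2)


class TestModuleTrait:
    def test_perfect_and_null_correlation(self):
        rng = np.random.default_rng(15)
        n = 30
        eig = pd.DataFrame([rng.standard_normal(n)], index=["blue"],
                           columns=[f"s{i}" for i in range(n)])
        traits = pd.DataFrame(
            {"t1": eig.loc["blue"].to_numpy()}, index=eig.columns
        )
        out = module_trait_correlation(eig, traits)
        assert out.r.loc["blue", "t1"] == pytest.approx(1.0)
        assert out.p.loc["blue", "t1"] < 1e-20

    def test_closed_form_p_at_r_0444_n20(self):
        # t = 0.444*sqrt(18)/sqrt(1-0.444^2) ~ 2.10 -> p ~ 0.05
        from eqtlnet._stats import pearson_pvalue

        p = pearson_pvalue(np.array([0.444]), 20)[0]
        assert p == pytest.approx(0.05, abs=0.005)

    def test_gs_mm_symmetries(self):
        rng = np.random.default_rng(16)
        g = rng.standard_normal(50)
        t = rng.standard_normal(50)
        assert gene_significance(g, g) == pytest.approx(1.0)
        assert module_membership(g, g) == pytest.approx(1.0)
        assert gene_significance(g, -t) == pytest.approx(gene_significance(g, t))
        assert module_membership(g, -t) == pytest.approx(-module_membership(g, t))


class TestSelection:
    def test_hub_cap_and_determinism(self):
        mm = pd.Series({"g3": 0.5, "g1": -0.9, "g2": 0.9, "g4": 0.1})
        assert select_hub_genes(mm, k=20) == ["g1", "g2", "g3", "g4"]
        assert select_hub_genes(mm, k=2) == ["g1", "g2"]

    def test_planted_hub_first(self):
        rng = np.random.default_rng(17)
        X, _ = make_blocks(seed=18, per_block=40, n_noise=20)
        res = CoexpressionNetwork(X).fit()
        mod = res.modules[0]
        eig = res.eigengenes.loc[mod]
        hub_profile = eig.to_numpy() * 5 + 0.01 * rng.standard_normal(len(eig))
        X2 = X.copy()
        X2.loc[res.module_genes(mod)[0]] = hub_profile
        res2 = CoexpressionNetwork(X2).fit()
        # the near-eigengene gene has the largest |MM| in its module
        mod2 = res2.labels[X.index[0]] if False else res2.labels[res.module_genes(mod)[0]]
        hubs = res2.hub_genes(mod2, k=1)
        assert hubs[0] == res.module_genes(mod)[0]

    def test_trait_module_selection(self):
        r = pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.0], [0.5, 0.5, 0.0, 0.0]],
            index=["blue", "grey"],
            columns=["t1", "t2", "t3", "t4"],
        )
        p = pd.DataFrame(
            [[0.05, 0.05, 0.05, 0.9], [0.05, 0.05, 0.9, 0.9]],
            index=["blue", "grey"],
            columns=r.columns,
        )
        sel = select_trait_modules(ModuleTraitCor(r=r, p=p, n=100))
        assert sel == ["blue"]
        p2 = p.copy()
        p2.loc["blue"] = [0.05, 0.05, 0.9, 0.9]
        assert select_trait_modules(ModuleTraitCor(r=r, p=p2, n=100)) == []
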