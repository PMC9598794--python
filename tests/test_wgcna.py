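"""Scale-free fit, soft threshold, TOM (with brute-force oracle), module
detection on planted partitions, eigengenes, trait association, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import gammaln

from cernet.errors import ValidationError
from cernet.wgcna import (
    FALLBACK_BETA,
    ModuleAssignment,
    adjacency,
    assign_modules,
    cluster_modules,
    compute_kme,
    connectivity,
    correlation_pvalue,
    hub_genes,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)
from conftest import make_block_expr


class TestScaleFreeFit:
    def test_power_law_scores_high(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(1.0, size=5000) + 1  # p(k) ~ k^-2
        assert scale_free_fit(k) >= 0.9

    def test_uniform_scores_low(self):
        rng = np.random.default_rng(1)
        assert scale_free_fit(rng.uniform(1, 10, size=5000)) < 0.5

    def test_increasing_frequency_is_negative(self):
        # frequency grows with k -> positive slope -> negative signed R^2
        k = np.concatenate([np.full(20, 1.0) + np.arange(20) * 1e-3,
                            np.full(100, 5.0) + np.arange(100) * 1e-3,
                            np.full(500, 10.0) + np.arange(500) * 1e-3])
        assert scale_free_fit(k) < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            scale_free_fit(np.ones(100))
        with pytest.raises(ValidationError):
            scale_free_fit(np.arange(10))  # too few genes


class TestAdjacency:
    def _expr(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 12)),
                            index=[f"G{i}" for i in range(n)])

    def test_beta_one_is_absolute_correlation(self):
        expr = self._expr()
        a = adjacency(expr, 1).to_numpy()
        r = np.abs(np.corrcoef(expr.to_numpy()))
        assert np.allclose(a, r)
        assert np.allclose(np.diag(a), 1.0)

    def test_power_is_elementwise(self):
        expr = self._expr(1)
        a1 = adjacency(expr, 1).to_numpy()
        a2 = adjacency(expr, 2).to_numpy()
        assert np.allclose(a2, a1**2)

    def test_raising_beta_shrinks_offdiagonal(self):
        expr = self._expr(2)
        a3 = adjacency(expr, 3).to_numpy()
        a6 = adjacency(expr, 6).to_numpy()
        off = ~np.eye(len(a3), dtype=bool)
        assert (a6[off] <= a3[off] + 1e-15).all()

    def test_zero_variance_gene_rejected(self):
        expr = self._expr(3)
        expr.iloc[0] = 5.0
        with pytest.raises(ValidationError, match="G0"):
            adjacency(expr, 6)


def naive_tom(a):
    """Triple-loop oracle for the topological overlap matrix."""
    n = len(a)
    out = np.eye(n)
    k = a.sum(axis=1) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_two_gene_limits(self):
        ids = ["a", "b"]
        full = pd.DataFrame(np.ones((2, 2)), index=ids, columns=ids)
        assert tom_similarity(full).to_numpy() == pytest.approx(np.ones((2, 2)))
        empty = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        assert tom_similarity(empty).to_numpy() == pytest.approx(np.eye(2))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        r = rng.uniform(0, 1, size=(n, n))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"G{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        got = tom_similarity(adj).to_numpy()
        assert np.abs(got - naive_tom(a)).max() < 1e-12

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(9)
        n = 40
        r = rng.uniform(0, 1, size=(n, n))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"G{i}" for i in range(n)]
        t = tom_similarity(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
        assert t.min() >= 0 and t.max() <= 1
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)


class TestSoftThreshold:
    def test_trivial_target_returns_smallest_beta(self):
        # a target every power satisfies -> the smallest-beta rule gives 1
        expr, _ = make_block_expr(0)
        beta, _diag = pick_soft_threshold(expr, r2_target=-1.0)
        assert beta == 1

    def test_unreachable_target_falls_back(self, caplog):
        expr, _ = make_block_expr(0)  # homogeneous blocks: no power qualifies
        with caplog.at_level("WARNING"):
            beta, diag = pick_soft_threshold(expr)
        assert beta == FALLBACK_BETA == 21
        assert (diag["signed_r2"].dropna() < 0.85).all()
        assert any("falling back" in r.message for r in caplog.records)

    def test_modular_data_reaches_target(self):
        """Blocks of uneven tightness give a heavy-tailed connectivity
        distribution; the chosen power's recomputed fit meets the target."""
        expr, _ = make_block_expr(0, n_per=100, kme_range=(0.5, 0.95))
        beta, diag = pick_soft_threshold(expr)
        assert diag.loc[beta, "signed_r2"] >= 0.85
        # independent recomputation at the returned beta
        r2 = scale_free_fit(connectivity(adjacency(expr, beta)))
        assert r2 == pytest.approx(diag.loc[beta, "signed_r2"])


class TestClusterModules:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import rand_score

        expr, labels = make_block_expr(3)
        modules = cluster_modules(tom_similarity(adjacency(expr, 21)),
                                  cut_height=0.995, min_size=30)
        assert rand_score(labels, modules.to_numpy()) >= 0.95
        assert (modules != "grey").sum() >= 120

    def test_independent_genes_go_grey(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(80, 12)),
                            index=[f"G{i}" for i in range(80)])
        modules = cluster_modules(tom_similarity(adjacency(expr, 21)),
                                  cut_height=0.92, min_size=30)
        assert (modules == "grey").all()

    def test_min_size_above_gene_count_all_grey(self):
        expr, _ = make_block_expr(0, n_per=10)
        modules = cluster_modules(tom_similarity(adjacency(expr, 6)),
                                  min_size=1000)
        assert (modules == "grey").all()

    def test_labels_ordered_by_size(self):
        expr, _ = make_block_expr(1, n_per=40)
        extra, _ = make_block_expr(2, n_blocks=1, n_per=60)
        extra.index = [f"X{i}" for i in range(len(extra))]
        both = pd.concat([expr, extra])
        modules = cluster_modules(tom_similarity(adjacency(both, 21)),
                                  min_size=30)
        sizes = modules[modules != "grey"].value_counts()
        assert sizes.index[0] == "turquoise"
        assert sizes.is_monotonic_decreasing


class TestEigengenes:
    def test_identical_profiles_rank_one(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=12)
        expr = pd.DataFrame([profile] * 5, index=[f"G{i}" for i in range(5)])
        modules = pd.Series("turquoise", index=expr.index)
        eig = module_eigengenes(expr, modules).loc["turquoise"].to_numpy()
        z = (profile - profile.mean()) / profile.std(ddof=1)
        expected = z / np.linalg.norm(z)
        assert np.allclose(eig, expected)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_pca_optimality_over_random_directions(self):
        expr, _ = make_block_expr(4, n_blocks=1, n_per=40)
        modules = pd.Series("blue", index=expr.index)
        eig = module_eigengenes(expr, modules).loc["blue"].to_numpy()
        x = expr.to_numpy()
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                        keepdims=True)
        explained = ((x @ eig) ** 2).sum()
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = rng.normal(size=x.shape[1])
            v /= np.linalg.norm(v)
            assert ((x @ v) ** 2).sum() <= explained + 1e-9

    def test_sign_alignment_under_global_flip(self):
        expr, _ = make_block_expr(5, n_blocks=1, n_per=30)
        modules = pd.Series("red", index=expr.index)
        eig = module_eigengenes(expr, modules).loc["red"]
        eig_flipped = module_eigengenes(-expr, modules).loc["red"]
        assert np.allclose(eig.to_numpy(), -eig_flipped.to_numpy())
        # alignment rule: correlation with the module mean profile >= 0
        mean_profile = expr.mean(axis=0)
        assert np.corrcoef(eig, mean_profile)[0, 1] >= 0

    def test_singleton_module_is_standardized_profile(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame([rng.normal(size=12)], index=["G0"])
        eig = module_eigengenes(expr, pd.Series({"G0": "tan"})).loc["tan"]
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        assert abs(np.corrcoef(eig, expr.iloc[0])[0, 1]) == pytest.approx(1.0)


def t_cdf_by_quadrature(t, df):
    """Independent Student-t CDF via numerical integration of the density."""
    def pdf(x):
        c = np.exp(gammaln((df + 1) / 2) - gammaln(df / 2)) / np.sqrt(df * np.pi)
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    val, _err = integrate.quad(pdf, -np.inf, t)
    return val


class TestModuleTrait:
    def _eigs(self, vectors):
        samples = [f"S{i}" for i in range(len(next(iter(vectors.values()))))]
        return pd.DataFrame(vectors, index=samples).T

    def test_proportional_trait(self):
        trait = np.arange(12, dtype=float)
        e = trait - trait.mean()
        eigs = self._eigs({"purple": e / np.linalg.norm(e)})
        assoc = module_trait_correlation(eigs, trait)
        assert assoc.table.loc["purple", "r"] == pytest.approx(1.0)
        assert assoc.table.loc["purple", "p"] == pytest.approx(0.0, abs=1e-12)
        assert assoc.significant_modules() == ["purple"]

    def test_orthogonal_trait_p_one(self):
        e = np.array([1.0, -1.0] * 6)
        trait = np.array([1.0, 1.0, -1.0, -1.0] * 3)
        assert abs(np.dot(e - e.mean(), trait - trait.mean())) < 1e-12
        eigs = self._eigs({"salmon": e / np.linalg.norm(e)})
        assoc = module_trait_correlation(eigs, trait)
        assert assoc.table.loc["salmon", "p"] == pytest.approx(1.0)

    def test_p_matches_independent_cdf(self):
        """r = 0.7, n = 12: p from t = r sqrt(n-2)/sqrt(1-r^2) agrees with a
        quadrature evaluation of the t CDF to 1e-8."""
        r, n = 0.7, 12
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert t == pytest.approx(3.0995, abs=2e-4)
        expected = 2 * (1 - t_cdf_by_quadrature(t, n - 2))
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=1e-8)

    def test_constant_trait_rejected(self):
        eigs = self._eigs({"m": np.ones(12) / np.sqrt(12)})
        with pytest.raises(ValidationError, match="constant trait"):
            module_trait_correlation(eigs, np.ones(12))


class TestHubGenes:
    def test_full_pass_finds_trait_module_hubs(self):
        """A module driven by a trait-like latent profile: its eigengene
        correlates with the trait and its tight genes are hubs."""
        rng = np.random.default_rng(12)
        trait = rng.normal(size=12)
        rows, idx = [], []
        for i in range(40):  # tight trait-driven block
            rows.append(trait + 0.3 * rng.normal(size=12))
            idx.append(f"T{i:02d}")
        for i in range(40):  # unrelated block
            z = rng.normal(size=12)
            rows.append(z + 0.3 * rng.normal(size=12))
            idx.append(f"U{i:02d}")
        expr = pd.DataFrame(rows, index=idx)
        assignment = assign_modules(expr, beta=12, min_size=20)
        assoc = module_trait_correlation(assignment.eigengenes, trait)
        sig = assoc.significant_modules()
        trait_modules = {assignment.modules[f"T{i:02d}"] for i in range(40)}
        assert trait_modules <= set(sig)
        hubs = hub_genes(assignment, kme_cutoff=0.8)
        hub_union = set().union(*hubs.values())
        assert any(g.startswith("T") for g in hub_union)

    def test_gene_equal_to_eigengene_is_hub(self):
        expr, _ = make_block_expr(8, n_blocks=1, n_per=30, within_r=0.95)
        assignment = assign_modules(expr, beta=6, min_size=10)
        mod = assignment.modules.iloc[0]
        hubs = hub_genes(assignment, kme_cutoff=0.8)
        assert len(hubs[mod]) > 0
        # an independent gene has low |kME| against this eigengene
        rng = np.random.default_rng(0)
        indep = pd.Series(rng.normal(size=expr.shape[1]), index=expr.columns)
        kme = np.corrcoef(indep, assignment.eigengenes.loc[mod])[0, 1]
        assert abs(kme) < 0.8

    def test_raising_cutoff_shrinks_hub_sets(self):
        expr, _ = make_block_expr(9, n_per=40)
        assignment = assign_modules(expr, beta=12, min_size=20)
        loose = hub_genes(assignment, kme_cutoff=0.6)
        tight = hub_genes(assignment, kme_cutoff=0.9)
        for mod in loose:
            assert tight.get(mod, set()) <= loose[mod]
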