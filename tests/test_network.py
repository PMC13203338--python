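import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from rfi_coexnet.expression import ExpressionMatrix
from rfi_coexnet.network import (
    GREY,
    NetworkParams,
    adjacency,
    cluster_genes,
    cut_modules,
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    pairwise_correlation,
    soft_threshold_scan,
    tom_similarity,
)
from rfi_coexnet.network import _scale_free_fit

from conftest import planted_dataset


def expr_from(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit="TPM")


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop TOM oracle, straight from the definition."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestPairwiseCorrelation:
    def test_duplicate_and_negated_genes(self, rng):
        base = rng.normal(10, 2, 8) + 20
        vals = np.vstack([base, base, 40 - base])
        cor = pairwise_correlation(expr_from(vals))
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_two_pass_formula(self, rng):
        vals = rng.lognormal(2, 0.5, (4, 6))
        cor = pairwise_correlation(expr_from(vals)).to_numpy()
        for i in range(4):
            for j in range(4):
                x, y = vals[i], vals[j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert cor[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_gene_named(self):
        vals = np.array([[1, 2, 3, 4], [5, 5, 5, 5.0]])
        with pytest.raises(ValueError, match="g1"):
            pairwise_correlation(expr_from(vals))

    def test_sample_order_invariance(self, rng):
        vals = rng.lognormal(2, 0.5, (5, 7))
        e1 = expr_from(vals)
        perm = rng.permutation(7)
        e2 = ExpressionMatrix(e1.values.iloc[:, perm], unit="TPM")
        assert np.allclose(
            pairwise_correlation(e1).to_numpy(), pairwise_correlation(e2).to_numpy()
        )


class TestAdjacency:
    def test_hand_arithmetic(self):
        cor = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"), columns=list("ab"))
        a6 = adjacency(cor, 6, "unsigned")
        assert a6.loc["a", "b"] == pytest.approx(0.015625)
        assert a6.loc["a", "a"] == 1.0

    def test_power_one_is_absolute_value(self, rng):
        vals = rng.lognormal(2, 0.5, (6, 9))
        cor = pairwise_correlation(expr_from(vals))
        a = adjacency(cor, 1, "unsigned")
        assert np.allclose(a.to_numpy(), np.abs(cor.to_numpy()))

    def test_signed_transform(self):
        cor = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=list("ab"), columns=list("ab"))
        a = adjacency(cor, 2, "signed")
        assert a.loc["a", "b"] == pytest.approx(0.0)
        cor1 = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        assert adjacency(cor1, 5, "signed").loc["a", "b"] == pytest.approx(1.0)


class TestTom:
    def test_two_gene_network_from_definition(self):
        # l=0 and k_1=k_2=0.5, so tom = (0 + 0.5)/(0.5 + 1 - 0.5) = 0.5
        a = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        tom = tom_similarity(a)
        assert tom.loc["a", "b"] == pytest.approx(0.5)

    def test_identity_adjacency_gives_identity(self):
        a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        assert np.allclose(tom_similarity(a).to_numpy(), np.eye(4))

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        assert np.max(np.abs(tom_similarity(adj).to_numpy() - tom_bruteforce(a))) < 1e-12

    def test_values_bounded_and_symmetric(self, rng):
        a = rng.uniform(0, 1, (15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)

    def test_block_diagonal_preserved(self):
        block = np.full((3, 3), 0.6)
        np.fill_diagonal(block, 1.0)
        a = np.zeros((6, 6))
        a[:3, :3] = block
        a[3:, 3:] = block
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom[:3, 3:], 0.0)
        assert tom[0, 1] > 0


class TestClustering:
    def test_two_separated_blocks_split_at_top(self):
        t = np.full((6, 6), 0.05)
        t[:3, :3] = 0.9
        t[3:, 3:] = 0.9
        np.fill_diagonal(t, 1.0)
        tom = pd.DataFrame(t, index=list("abcdef"), columns=list("abcdef"))
        link = cluster_genes(tom)
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_average_linkage_merge_heights_hand_trace(self):
        # dissimilarity: d(a,b)=0.1; d(a,c)=0.4, d(b,c)=0.6 -> avg 0.5;
        # singleton d to the (a,b,c) cluster from d: avg(0.9,0.8,0.7)=0.8
        d = np.array([
            [0.0, 0.1, 0.4, 0.9],
            [0.1, 0.0, 0.6, 0.8],
            [0.4, 0.6, 0.0, 0.7],
            [0.9, 0.8, 0.7, 0.0],
        ])
        tom = pd.DataFrame(1 - d, index=list("abcd"), columns=list("abcd"))
        link = cluster_genes(tom)
        assert np.allclose(sorted(link[:, 2]), [0.1, 0.5, 0.8])

    def test_gene_permutation_gives_same_tree(self, rng):
        expr, _, _ = planted_dataset(seed=0, module_sizes=(30,), cors=(0.5,),
                                     n_genes=60, n_samples=20)
        tom = tom_similarity(adjacency(pairwise_correlation(expr), 6))
        link1 = cluster_genes(tom)
        perm = rng.permutation(60)
        tom_p = tom.iloc[perm, perm]
        link2 = cluster_genes(tom_p)
        # same multiset of merge heights = same tree shape
        assert np.allclose(np.sort(link1[:, 2]), np.sort(link2[:, 2]))


class TestCutModules:
    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth, _ = planted_dataset(seed=1, module_sizes=(80, 60), cors=(0.3, -0.3),
                                         n_genes=240, n_samples=50)
        net = detect_modules(expr, NetworkParams(min_module_size=50))
        tm = truth.module_of_gene
        mask = (tm != "background").to_numpy()
        ari = adjusted_rand_score(tm[mask], net["modules"][mask])
        assert ari >= 0.9

    def test_small_module_goes_grey(self):
        expr, truth, _ = planted_dataset(seed=2, module_sizes=(30,), cors=(0.2,),
                                         n_genes=120, n_samples=40)
        net = detect_modules(expr, NetworkParams(min_module_size=50))
        members = truth.module_of_gene == "M1"
        assert (net["modules"][members.to_numpy()] == GREY).all()

    def test_largest_module_named_turquoise(self):
        expr, truth, _ = planted_dataset(seed=3, module_sizes=(90, 55), cors=(0.3, -0.2),
                                         n_genes=220, n_samples=50)
        net = detect_modules(expr, NetworkParams(min_module_size=50))
        sizes = net["modules"][net["modules"] != GREY].value_counts()
        assert sizes.index[0] == "turquoise"
        assert sizes.iloc[0] == sizes.max()


class TestSoftThreshold:
    def test_fit_index_high_on_power_law_degrees(self, rng):
        # connectivity vector drawn from an exact discrete power law
        k = (rng.pareto(2.0, 4000) + 1) * 3
        r2, slope = _scale_free_fit(k)
        assert r2 >= 0.9 and slope < 0

    def test_mean_connectivity_strictly_decreasing(self):
        expr, _, _ = planted_dataset(seed=4, module_sizes=(40,), cors=(0.3,),
                                     n_genes=120, n_samples=30)
        scan = soft_threshold_scan(expr, powers=tuple(range(1, 13)))
        mc = scan.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mc) < 0)

    def test_independent_noise_connectivity_drops_with_power(self, rng):
        vals = rng.lognormal(3, 0.5, (80, 25))
        expr = expr_from(vals)
        scan = soft_threshold_scan(expr, powers=(1, 10))
        t = scan.table.set_index("power")["mean_connectivity"]
        assert t[10] < t[1]

    def test_recommended_power_bracket_on_planted_defaults(self):
        expr, _, _ = planted_dataset(seed=5)
        scan = soft_threshold_scan(expr)
        assert 3 <= scan.recommended_power <= 9


class TestEigengenes:
    def test_identical_genes_reproduce_profile(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        vals = np.vstack([prof, prof, prof]) * np.array([[1.0], [2.0], [3.0]])
        expr = expr_from(vals)
        modules = pd.Series(["blue"] * 3, index=expr.gene_ids)
        eig, varexp = module_eigengenes(expr, modules)
        z = (prof - prof.mean()) / prof.std(ddof=1)
        assert np.allclose(eig["blue"].to_numpy(), z, atol=1e-10)
        assert varexp["blue"] == pytest.approx(1.0)

    def test_gene_and_its_negation(self):
        g = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0]) + 10
        vals = np.vstack([g, 22 - g])
        expr = expr_from(vals)
        modules = pd.Series(["m"] * 2, index=expr.gene_ids)
        eig, varexp = module_eigengenes(expr, modules)
        assert varexp["m"] == pytest.approx(1.0)
        # orientation deterministic: rerun gives identical sign
        eig2, _ = module_eigengenes(expr, modules)
        assert np.allclose(eig["m"], eig2["m"])

    def test_matches_svd_oracle_up_to_sign(self, rng):
        vals = rng.lognormal(2, 0.6, (5, 12))
        expr = expr_from(vals)
        modules = pd.Series(["m"] * 5, index=expr.gene_ids)
        eig, _ = module_eigengenes(expr, modules)
        z = (vals.T - vals.T.mean(0)) / vals.T.std(0, ddof=1)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = u[:, 0] / u[:, 0].std(ddof=1)
        got = eig["m"].to_numpy()
        assert np.allclose(got, oracle, atol=1e-10) or np.allclose(got, -oracle, atol=1e-10)

    def test_singleton_module_is_standardised_gene(self):
        g = np.array([4.0, 8.0, 6.0, 10.0])
        expr = expr_from(g[None, :])
        modules = pd.Series(["m"], index=expr.gene_ids)
        eig, varexp = module_eigengenes(expr, modules)
        assert np.allclose(eig["m"], (g - g.mean()) / g.std(ddof=1))
        assert varexp["m"] == pytest.approx(1.0)

    def test_unit_variance_and_orientation(self):
        expr, _, _ = planted_dataset(seed=6, module_sizes=(40,), cors=(0.3,),
                                     n_genes=80, n_samples=30)
        net = detect_modules(expr, NetworkParams(min_module_size=30))
        for col in net["eigengenes"]:
            e = net["eigengenes"][col]
            assert e.std(ddof=1) == pytest.approx(1.0)


class TestMergeModules:
    def _two_module_expr(self, rho, seed=0, size=20, n=40):
        """Two planted modules whose eigengenes correlate at ~rho."""
        rng = np.random.default_rng(seed)
        me1 = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        noise -= noise @ me1 / (me1 @ me1) * me1
        me2 = rho * (me1 - me1.mean()) / me1.std() + np.sqrt(1 - rho**2) * (
            (noise - noise.mean()) / noise.std()
        )
        rows = []
        for me in (me1, me2):
            for _ in range(size):
                lam = rng.uniform(0.85, 0.95)
                rows.append(lam * (me - me.mean()) / me.std()
                            + np.sqrt(1 - lam**2) * rng.standard_normal(n))
        vals = 50 * np.exp(0.4 * np.asarray(rows))
        expr = expr_from(vals)
        modules = pd.Series(["turquoise"] * size + ["blue"] * size, index=expr.gene_ids)
        return expr, modules

    def test_near_identical_eigengenes_merged(self):
        expr, modules = self._two_module_expr(rho=0.995)
        merged, eig, _ = merge_close_modules(expr, modules, merge_cut_height=0.15)
        assert merged[merged != GREY].nunique() == 1

    def test_distant_eigengenes_unmerged(self):
        expr, modules = self._two_module_expr(rho=0.5)
        merged, eig, _ = merge_close_modules(expr, modules, merge_cut_height=0.15)
        assert merged[merged != GREY].nunique() == 2

    def test_chain_merges_to_one_and_order_invariant(self):
        rng = np.random.default_rng(7)
        n = 40
        me = rng.standard_normal(n)
        rows, labels = [], []
        for m, shift in enumerate([0.0, 0.08, 0.16]):
            mm = me + shift * rng.standard_normal(n)
            for _ in range(15):
                lam = rng.uniform(0.85, 0.95)
                zm = (mm - mm.mean()) / mm.std()
                rows.append(lam * zm + np.sqrt(1 - lam**2) * rng.standard_normal(n))
                labels.append(f"mod{m}")
        vals = 50 * np.exp(0.4 * np.asarray(rows))
        expr = expr_from(vals)
        modules = pd.Series(labels, index=expr.gene_ids)
        merged, _, _ = merge_close_modules(expr, modules, merge_cut_height=0.15)
        assert merged.nunique() == 1
        # permute module input order (relabel) -> same partition
        remap = {"mod0": "zeta", "mod1": "alpha", "mod2": "mid"}
        merged2, _, _ = merge_close_modules(
            expr, modules.map(remap), merge_cut_height=0.15
        )
        assert (merged == merged2).all()
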