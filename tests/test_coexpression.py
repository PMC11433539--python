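"""Similarity, soft thresholding, TOM, module detection, eigengenes,
module-trait selection and DCEG derivation."""

import numpy as np
import pandas as pd
import pytest

from coexpath import coexpression as cx
from coexpath.io_formats import ExpressionMatrix, SampleAnnotations
from conftest import random_expression


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Independent double-loop TOM oracle."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def _sim(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return cx.SimilarityMatrix(pd.DataFrame(values, index=genes, columns=genes))


class TestSimilarity:
    def test_duplicate_and_negated_profiles(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        df = pd.DataFrame(
            [base, base, -base],
            index=["a", "b", "c"],
            columns=[f"S{i}" for i in range(20)],
        )
        s = cx.similarity(ExpressionMatrix(df, "t"))
        assert s.data.loc["a", "b"] == pytest.approx(1.0)
        assert s.data.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(s.data), 1.0)
        assert np.allclose(s.data, s.data.T)

    def test_independent_genes_mostly_uncorrelated(self):
        expr = random_expression(60, 100, seed=1)
        s = cx.similarity(expr).data.to_numpy()
        off = np.abs(s[np.triu_indices(60, 1)])
        assert np.mean(off < 0.3) >= 0.99

    def test_constant_gene_named(self):
        df = pd.DataFrame(
            [[1, 1, 1, 1], [1, 2, 3, 4]], index=["FLAT", "OK"],
            columns=list("wxyz"),
        )
        with pytest.raises(ValueError, match="FLAT"):
            cx.similarity(ExpressionMatrix(df, "t"))


class TestPickSoftThreshold:
    def test_zero_target_picks_power_one(self):
        expr = random_expression(120, 30, seed=2)
        s = cx.similarity(expr)
        beta, table = cx.pick_soft_threshold(s, fit_target=0.0)
        assert beta == 1
        assert list(table["power"]) == list(range(1, 21))

    def test_mean_connectivity_decreases_with_power(self):
        expr = random_expression(150, 30, seed=3)
        _, table = cx.pick_soft_threshold(cx.similarity(expr))
        k = table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) <= 0)

    def test_scale_free_network_fits_well(self):
        """A similarity built from a hub-dominated (power-law-ish) weight
        pattern reaches signed R^2 > 0.85 at some power <= 20."""
        rng = np.random.default_rng(4)
        n = 300
        # hub weights ~ power law; S_ij proportional to w_i * w_j
        w = (rng.pareto(2.0, size=n) + 1.0)
        w = np.sqrt(w / w.max())
        s = np.clip(np.outer(w, w), 0, 0.999)
        np.fill_diagonal(s, 1.0)
        _, table = cx.pick_soft_threshold(_sim(s))
        assert table["signed_r2"].max() > 0.85


class TestAdjacency:
    @pytest.mark.parametrize(
        "sij,beta,expected", [(0.5, 2, 0.25), (-0.5, 5, 0.03125), (0.7, 1, 0.7)]
    )
    def test_unsigned_power(self, sij, beta, expected):
        s = _sim([[1.0, sij], [sij, 1.0]])
        a = cx.adjacency(s, beta)
        assert a.data.iloc[0, 1] == pytest.approx(expected)

    def test_beta_range_enforced(self):
        s = _sim([[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError):
            cx.adjacency(s, 0)
        with pytest.raises(ValueError):
            cx.adjacency(s, 21)


class TestTom:
    def test_three_gene_identity(self):
        for a_val in (0.2, 0.5, 0.9):
            a = np.full((3, 3), a_val)
            np.fill_diagonal(a, 1.0)
            t = cx.tom(cx.AdjacencyMatrix(pd.DataFrame(
                a, index=list("abc"), columns=list("abc")), 1))
            off = t.data.to_numpy()[np.triu_indices(3, 1)]
            assert np.allclose(off, a_val)

    def test_empty_network(self):
        a = np.eye(4)
        t = cx.tom(cx.AdjacencyMatrix(pd.DataFrame(
            a, index=list("abcd"), columns=list("abcd")), 1))
        off = t.data.to_numpy()[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(t.data), 1.0)
        assert np.allclose(t.dissimilarity.to_numpy()[np.triu_indices(4, 1)], 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            a = rng.uniform(0, 1, size=(30, 30))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            t = cx.tom(cx.AdjacencyMatrix(pd.DataFrame(
                a, index=[f"G{i}" for i in range(30)],
                columns=[f"G{i}" for i in range(30)]), 1))
            assert np.allclose(t.data.to_numpy(), tom_brute_force(a), atol=1e-10)


def _block_expression(seed=6, n_modules=3, size=60, n_bg=120, n_samples=60, rho=0.6):
    """Correlated blocks + independent background, directly on the
    normalized scale."""
    rng = np.random.default_rng(seed)
    rows, names, truth = [], [], []
    lam = np.sqrt(rho / (1 - rho))
    for m in range(n_modules):
        z = rng.normal(size=n_samples)
        for g in range(size):
            rows.append(lam * z + rng.normal(size=n_samples))
            names.append(f"M{m}_G{g}")
            truth.append(m + 1)
    for g in range(n_bg):
        rows.append(rng.normal(size=n_samples))
        names.append(f"BG_G{g}")
        truth.append(0)
    df = pd.DataFrame(rows, index=names, columns=[f"S{j}" for j in range(n_samples)])
    return ExpressionMatrix(df, "t"), np.array(truth)


class TestDetectModules:
    def test_recovers_planted_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = _block_expression()
        s = cx.similarity(expr)
        t = cx.tom(cx.adjacency(s, 6))
        mods = cx.detect_modules(t.dissimilarity, min_size=50, expr=expr)
        assert len(mods.module_names) == 3
        pred = [0 if l == cx.UNASSIGNED else int(l[1:]) for l in mods.labels]
        assert adjusted_rand_score(truth, pred) >= 0.8

    def test_min_size_above_gene_count(self):
        expr, _ = _block_expression(size=20, n_bg=20, n_modules=1)
        s = cx.similarity(expr)
        t = cx.tom(cx.adjacency(s, 6))
        mods = cx.detect_modules(t.dissimilarity, min_size=1000, expr=expr)
        assert mods.module_names == []
        assert (mods.labels == cx.UNASSIGNED).all()

    def test_gene_permutation_invariance(self):
        expr, truth = _block_expression(seed=7, n_modules=2, size=55, n_bg=60)
        s = cx.similarity(expr)
        t = cx.tom(cx.adjacency(s, 6))
        mods = cx.detect_modules(t.dissimilarity, min_size=50, expr=expr)

        rng = np.random.default_rng(8)
        perm = rng.permutation(len(expr.data))
        expr_p = ExpressionMatrix(expr.data.iloc[perm], "t")
        s_p = cx.similarity(expr_p)
        t_p = cx.tom(cx.adjacency(s_p, 6))
        mods_p = cx.detect_modules(t_p.dissimilarity, min_size=50, expr=expr_p)
        # partitions identical up to module-label permutation
        for m in mods.module_names:
            members = set(mods.members(m))
            matches = [
                set(mods_p.members(mp)) for mp in mods_p.module_names
            ]
            assert members in matches

    def test_identity_similarity_yields_no_modules(self):
        n = 30
        genes = [f"G{i}" for i in range(n)]
        dissim = pd.DataFrame(1.0 - np.eye(n), index=genes, columns=genes)
        mods = cx.detect_modules(dissim, min_size=5)
        assert mods.module_names == []

    def test_quantile_mode_available(self):
        expr, _ = _block_expression(seed=9, n_modules=1, size=60, n_bg=30)
        s = cx.similarity(expr)
        t = cx.tom(cx.adjacency(s, 6))
        mods = cx.detect_modules(t.dissimilarity, min_size=5, cut_quantile=0.5)
        assert set(mods.labels.index) == set(expr.data.index)


class TestModuleEigengene:
    def test_identical_members_rank_one(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=30)
        df = pd.DataFrame([base, base, base], index=["a", "b", "c"],
                          columns=[f"S{i}" for i in range(30)])
        expr = ExpressionMatrix(df, "t")
        me = cx.module_eigengene(expr, ["a", "b", "c"])
        r = np.corrcoef(me, base)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign aligned with the member mean profile

    def test_negating_members_negates_me(self):
        expr, _ = _block_expression(seed=11, n_modules=1, size=10, n_bg=0,
                                    n_samples=25)
        members = list(expr.data.index)
        me = cx.module_eigengene(expr, members)
        neg = ExpressionMatrix(-expr.data, "t")
        me_neg = cx.module_eigengene(neg, members)
        assert np.allclose(me.to_numpy(), -me_neg.to_numpy(), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.normal(size=(12, 20))
            genes = [f"G{i}" for i in range(12)]
            expr = ExpressionMatrix(
                pd.DataFrame(x, index=genes,
                             columns=[f"S{j}" for j in range(20)]), "t")
            me = cx.module_eigengene(expr, genes).to_numpy()
            z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            evals, evecs = np.linalg.eigh(z.T @ z)
            pc1 = evecs[:, -1]
            agreement = min(np.abs(me - pc1).max(), np.abs(me + pc1).max())
            assert agreement < 1e-8

    def test_missing_member_named(self):
        expr = random_expression(5, 10, seed=13)
        with pytest.raises(KeyError, match="NOPE"):
            cx.module_eigengene(expr, ["G0", "NOPE"])


class TestModuleTrait:
    def _ann(self, groups, samples):
        return SampleAnnotations(pd.DataFrame({"group": groups}, index=samples))

    def test_perfect_ordering_small_n_exact_p(self):
        samples = [f"S{i}" for i in range(12)]
        ann = self._ann(["healthy"] * 6 + ["lesional"] * 6, samples)
        mes = pd.DataFrame({"M1": np.arange(12, dtype=float)}, index=samples)
        table = cx.module_trait(mes, ann, ("healthy", "lesional"))
        assert table.loc["M1", "spearman_r"] > 0.5
        assert table.loc["M1", "p_value"] < 0.05
        assert bool(table.loc["M1", "selected"])

    def test_reversed_coding_flips_sign(self):
        rng = np.random.default_rng(14)
        samples = [f"S{i}" for i in range(30)]
        ann = self._ann(["healthy"] * 15 + ["lesional"] * 15, samples)
        mes = pd.DataFrame({"M1": rng.normal(size=30)}, index=samples)
        fwd = cx.module_trait(mes, ann, ("healthy", "lesional"))
        rev = cx.module_trait(mes, ann, ("lesional", "healthy"))
        assert fwd.loc["M1", "spearman_r"] == pytest.approx(
            -rev.loc["M1", "spearman_r"])
        assert fwd.loc["M1", "p_value"] == pytest.approx(rev.loc["M1", "p_value"])

    def test_null_me_rarely_selected(self):
        samples = [f"S{i}" for i in range(54)]
        ann = self._ann(["healthy"] * 27 + ["lesional"] * 27, samples)
        rng = np.random.default_rng(15)
        n_selected = 0
        for _ in range(40):
            mes = pd.DataFrame({"M1": rng.normal(size=54)}, index=samples)
            table = cx.module_trait(mes, ann, ("healthy", "lesional"))
            n_selected += int(table["selected"].iloc[0])
        assert n_selected <= 2  # |R| > 0.5 at n = 54 is far outside the null


class TestDeriveDcegs:
    def _inputs(self):
        genes = [f"G{i}" for i in range(10)]
        de = pd.DataFrame(
            {"significant": [True] * 4 + [False] * 6}, index=genes
        )
        labels = pd.Series(
            ["M1"] * 3 + ["M2"] * 3 + [cx.UNASSIGNED] * 4, index=genes
        )
        modules = cx.ModuleAssignment(labels, min_size=3)
        return de, modules, genes

    def test_intersection_and_union(self):
        de, modules, genes = self._inputs()
        trait = pd.DataFrame(
            {"spearman_r": [0.8, 0.1], "p_value": [0.001, 0.9],
             "selected": [True, False]},
            index=["M1", "M2"],
        )
        per_module, union = cx.derive_dcegs(de, modules, trait)
        assert per_module == {"M1": {"G0", "G1", "G2"}}
        assert union == {"G0", "G1", "G2"}
        sig = set(de.index[de["significant"]])
        assert union <= sig

    def test_no_selected_modules_gives_empty_union(self):
        de, modules, _ = self._inputs()
        trait = pd.DataFrame(
            {"spearman_r": [0.2, 0.1], "p_value": [0.5, 0.9],
             "selected": [False, False]},
            index=["M1", "M2"],
        )
        per_module, union = cx.derive_dcegs(de, modules, trait)
        assert per_module == {} and union == set()


def test_color_aliases_follow_size_order():
    labels = pd.Series(["M1"] * 5 + ["M2"] * 3, index=[f"G{i}" for i in range(8)])
    mods = cx.ModuleAssignment(labels, min_size=3)
    assert mods.color_alias("M1") == "turquoise"
    assert mods.color_alias("M2") == "blue"
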