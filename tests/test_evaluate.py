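"""Group t-tests, severity correlation, ROC/AUC and replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexpath import evaluate
from coexpath.io_formats import ExpressionMatrix, SampleAnnotations
from coexpath.pathway import PathwayExpressionMatrix


def auc_all_pairs(feature, labels):
    """Exhaustive Mann–Whitney oracle: count case/control pairs with the
    half-point tie credit."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    pos = feature[labels == 1]
    neg = feature[labels == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def _pmatrix(values, pathways, samples):
    df = pd.DataFrame(values, index=pathways, columns=samples)
    return PathwayExpressionMatrix(df, {p: ("X",) for p in pathways})


def _ann(groups, samples, easi=None):
    df = pd.DataFrame({"group": groups}, index=samples)
    if easi is not None:
        df["easi"] = easi
    return SampleAnnotations(df)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***"),
         (0.00009, "****"), (0.05, ""), (0.0001, "***")],
    )
    def test_bands(self, p, expected):
        assert evaluate.stars(p) == expected


class TestGroupTtests:
    def _setup(self, delta, seed=0, n=27):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(3 * n)]
        groups = ["lesional"] * n + ["non_lesional"] * n + ["healthy"] * n
        base = rng.normal(0, 1, 3 * n)
        base[:n] += delta
        p = _pmatrix([base], ["P1"], samples)
        return p, _ann(groups, samples)

    def test_separated_groups_reach_four_stars(self):
        p, ann = self._setup(delta=3.0)
        table = evaluate.group_ttests(p, ann)
        row = table[(table["pathway"] == "P1")
                    & (table["comparison"] == "lesional_vs_healthy")].iloc[0]
        assert row["stars"] == "****"
        assert row["mean_b"] > row["mean_a"]

    def test_swapping_groups_negates_t(self):
        p, ann = self._setup(delta=1.0, seed=1)
        fwd = evaluate.group_ttests(
            p, ann, {"c": ("healthy", "lesional")}).iloc[0]
        rev = evaluate.group_ttests(
            p, ann, {"c": ("lesional", "healthy")}).iloc[0]
        assert fwd["t_stat"] == pytest.approx(-rev["t_stat"])
        assert fwd["p_value"] == pytest.approx(rev["p_value"])

    def test_null_pathways_rarely_starred(self):
        rng = np.random.default_rng(2)
        n = 27
        samples = [f"S{i}" for i in range(2 * n)]
        groups = ["lesional"] * n + ["healthy"] * n
        values = rng.normal(size=(60, 2 * n))
        p = _pmatrix(values, [f"P{i}" for i in range(60)], samples)
        table = evaluate.group_ttests(p, _ann(groups, samples),
                                      {"c": ("healthy", "lesional")})
        assert (table["stars"] != "").mean() < 0.15

    def test_constant_identical_groups_p_one(self):
        samples = [f"S{i}" for i in range(8)]
        groups = ["lesional"] * 4 + ["healthy"] * 4
        p = _pmatrix([[2.0] * 8], ["P1"], samples)
        table = evaluate.group_ttests(p, _ann(groups, samples),
                                      {"c": ("healthy", "lesional")})
        assert table.iloc[0]["p_value"] == 1.0


class TestSeverityCorrelation:
    def test_noiseless_linear_severity(self):
        samples = [f"S{i}" for i in range(10)]
        activity = np.arange(10, dtype=float)
        p = _pmatrix([activity], ["P1"], samples)
        ann = _ann(["lesional"] * 10, samples, easi=3 * activity + 7)
        table = evaluate.severity_correlation(p, ann, "easi")
        assert table.loc["P1", "pearson_r"] == pytest.approx(1.0)
        assert table.loc["P1", "n"] == 10

    def test_missing_severity_excluded(self):
        samples = [f"S{i}" for i in range(8)]
        activity = np.arange(8, dtype=float)
        easi = 2 * activity
        easi[5:] = np.nan
        p = _pmatrix([activity], ["P1"], samples)
        ann = _ann(["lesional"] * 8, samples, easi=easi)
        table = evaluate.severity_correlation(p, ann, "easi")
        assert table.loc["P1", "n"] == 5

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(20)]
        activity = rng.normal(size=20)
        easi = np.abs(activity * 2 + rng.normal(0, 0.5, 20)) * 10
        p = _pmatrix([activity], ["P1"], samples)
        r1 = evaluate.severity_correlation(
            p, _ann(["lesional"] * 20, samples, easi=easi), "easi"
        ).loc["P1", "pearson_r"]
        r2 = evaluate.severity_correlation(
            p, _ann(["lesional"] * 20, samples, easi=easi * 4.5), "easi"
        ).loc["P1", "pearson_r"]
        assert r1 == pytest.approx(r2)

    def test_too_few_usable_samples(self):
        samples = [f"S{i}" for i in range(6)]
        p = _pmatrix([np.arange(6.0)], ["P1"], samples)
        ann = _ann(["lesional"] * 6, samples,
                   easi=[1.0, 2.0, np.nan, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="EASI"):
            evaluate.severity_correlation(p, ann, "easi")


class TestRocAuc:
    def test_worked_examples(self):
        auc, direction = evaluate.roc_auc([1.0, 2.0, 3.0], [0, 0, 1])
        assert auc == pytest.approx(1.0) and direction == "positive"
        # single case sitting between the two controls: one win, one loss
        assert auc_all_pairs([1.0, 2.0, 3.0], [0, 1, 0]) == pytest.approx(0.5)
        auc, _ = evaluate.roc_auc([1.0, 2.0, 3.0], [0, 1, 0])
        assert auc == pytest.approx(0.5)
        auc, _ = evaluate.roc_auc([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_complete_separation_flagged_but_defined(self):
        auc, direction = evaluate.roc_auc(
            [0.0, 0.1, 0.9, 1.0], [0, 0, 1, 1]
        )
        assert auc == pytest.approx(1.0) and direction == "positive"

    def test_orientation(self):
        auc, direction = evaluate.roc_auc([5.0, 4.0, 1.0, 0.0], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0) and direction == "negative"

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=4, max_size=30),
        st.data(),
    )
    def test_rank_formula_matches_all_pairs_oracle(self, feature, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(feature),
                     max_size=len(feature))
        )
        if sum(labels) in (0, len(labels)):
            return
        ours = evaluate.rank_auc(np.array(feature, dtype=float),
                                 np.array(labels))
        oracle = auc_all_pairs(feature, labels)
        assert ours == pytest.approx(oracle, abs=1e-12)


class TestReplicate:
    def _discovery(self):
        samples = [f"S{i}" for i in range(30)]
        groups = ["lesional"] * 10 + ["non_lesional"] * 10 + ["healthy"] * 10
        rng = np.random.default_rng(5)
        signal = np.array([3.0] * 10 + [1.0] * 10 + [0.0] * 10)
        genes = pd.DataFrame(
            {s: signal[i] + rng.normal(0, 0.5, 4)
             for i, s in enumerate(samples)},
            index=["Ga", "Gb", "Gc", "Gd"],
        )
        expr = ExpressionMatrix(genes, "t")
        p = PathwayExpressionMatrix(
            genes.iloc[:2].mean().to_frame("P1").T, {"P1": ("Ga", "Gb")}
        )
        ann = _ann(groups, samples)
        tests = evaluate.group_ttests(p, ann)
        return expr, ann, tests

    def test_same_signal_replicates(self):
        expr, ann, tests = self._discovery()
        # validation cohort: same construction, new noise
        rng = np.random.default_rng(6)
        samples = [f"V{i}" for i in range(30)]
        groups = ["lesional"] * 10 + ["non_lesional"] * 10 + ["healthy"] * 10
        signal = np.array([3.0] * 10 + [1.0] * 10 + [0.0] * 10)
        vdf = pd.DataFrame(
            {s: signal[i] + rng.normal(0, 0.5, 4)
             for i, s in enumerate(samples)},
            index=["Ga", "Gb", "Gc", "Gd"],
        )
        res = evaluate.replicate(
            ["P1"], {"P1": ("Ga", "Gb")},
            ExpressionMatrix(vdf, "t"), _ann(groups, samples), tests,
        )
        assert res["replication"]["replicated"].all()

    def test_missing_genes_restrict_never_extend(self):
        expr, ann, tests = self._discovery()
        vdf = expr.data.drop(index=["Gb"])
        res = evaluate.replicate(
            ["P1"], {"P1": ("Ga", "Gb")},
            ExpressionMatrix(vdf, "t"), ann, tests, min_fraction=0.5,
        )
        assert res["pathway_expression"].gene_lists["P1"] == ("Ga",)

    def test_no_surviving_lists_is_an_error(self):
        expr, ann, tests = self._discovery()
        vdf = expr.data.drop(index=["Ga", "Gb"])
        with pytest.raises(ValueError):
            evaluate.replicate(
                ["P1"], {"P1": ("Ga", "Gb")},
                ExpressionMatrix(vdf, "t"), ann, tests,
            )
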