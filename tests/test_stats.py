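"""Statistical machinery vs. independent reference implementations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sst

from emgkit.stats_report import (
    ConfusionMatrix,
    average_confusions,
    confusion,
    games_howell,
    levene,
    run_method_comparison,
    variance_ftests,
    welch_anova,
)


def _random_groups(seed, k=4, n=25, scale_spread=True):
    rng = np.random.default_rng(seed)
    return [
        rng.normal(loc=rng.normal(), scale=1 + 2 * rng.random() if scale_spread else 1,
                   size=n + (rng.integers(0, 10) if scale_spread else 0))
        for _ in range(k)
    ]


def _long_format(groups):
    return pd.DataFrame(
        {
            "y": np.concatenate(groups),
            "g": np.concatenate([[f"g{i}"] * len(g) for i, g in enumerate(groups)]),
        }
    )


class TestLevene:
    def test_identical_groups(self):
        g = np.arange(10.0)
        w, p = levene([g, g.copy(), g.copy()])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_detects_unequal_variances(self):
        rng = np.random.default_rng(0)
        a = rng.normal(scale=1.0, size=30)
        b = rng.normal(scale=10.0, size=30)
        _, p = levene([a, b])
        assert p < 0.01

    def test_matches_hand_coded_formula(self):
        # classical mean-centered Levene, coded directly from its definition
        for seed in range(5):
            groups = _random_groups(seed)
            z = [np.abs(g - g.mean()) for g in groups]
            k = len(z)
            n = sum(len(g) for g in z)
            zbar = np.concatenate(z).mean()
            num = sum(len(g) * (g.mean() - zbar) ** 2 for g in z) / (k - 1)
            den = sum(((g - g.mean()) ** 2).sum() for g in z) / (n - k)
            w_expected = num / den
            w, p = levene(groups)
            assert w == pytest.approx(w_expected, rel=1e-8)
            assert p == pytest.approx(sst.f.sf(w_expected, k - 1, n - k), rel=1e-8)


class TestWelchAnova:
    def test_equal_groups_give_zero_f(self):
        g = np.arange(12.0)
        f, df1, df2, p = welch_anova([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df1 == 2

    def test_two_groups_equal_squared_welch_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 3, 35)
        f, _, df2, p = welch_anova([a, b])
        t = sst.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-8)
        assert df2 == pytest.approx(t.df, rel=1e-10)

    def test_matches_reference_implementation(self):
        for seed in range(5):
            groups = _random_groups(seed)
            f, df1, df2, p = welch_anova(groups)
            ref = pg.welch_anova(data=_long_format(groups), dv="y", between="g")
            assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
            assert df1 == pytest.approx(float(ref["ddof1"].iloc[0]))
            assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-8)
            assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-8, abs=1e-12)

    def test_converges_to_classical_anova_under_homoscedasticity(self):
        # identical within-group variances: shifted copies of one sample
        rng = np.random.default_rng(2)
        errors = []
        for n in (100, 1000, 10_000):
            base = rng.normal(size=n)
            groups = [base + shift for shift in (0.0, 0.1, 0.25, 0.4)]
            f_w, *_ = welch_anova(groups)
            f_c = sst.f_oneway(*groups).statistic
            errors.append(abs(f_w - f_c) / f_c)
        assert errors[-1] <= 1e-3
        assert errors[0] > errors[-1]  # shrinks with sample size


class TestGamesHowell:
    def test_identical_pair_p_near_one(self):
        g = np.arange(10.0)
        out = games_howell([g, g.copy()])
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_separated_pair_significant(self):
        rng = np.random.default_rng(3)
        out = games_howell([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        assert out["p"].iloc[0] < 0.001

    def test_pair_count_is_k_choose_2(self):
        groups = _random_groups(4, k=5)
        assert len(games_howell(groups)) == 10

    def test_matches_reference_implementation(self):
        for seed in range(5):
            groups = _random_groups(seed)
            names = [f"g{i}" for i in range(len(groups))]
            mine = games_howell(groups, names)
            ref = pg.pairwise_gameshowell(data=_long_format(groups), dv="y",
                                          between="g")
            merged = mine.merge(ref, left_on=["group_a", "group_b"],
                                right_on=["A", "B"])
            assert len(merged) == len(mine)
            assert np.allclose(merged["mean_diff"], merged["diff"], rtol=1e-8)
            assert np.allclose(merged["df_x"], merged["df_y"], rtol=1e-8)
            assert np.allclose(merged["p"], merged["pval"], atol=1e-3)


class TestVarianceFTests:
    def test_identical_samples_ratio_one(self):
        g = np.arange(10.0)
        out = variance_ftests([g, g.copy()])
        assert out["f"].iloc[0] == pytest.approx(1.0)
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["p_fdr"].iloc[0] == pytest.approx(1.0)  # single pair: raw

    def test_matches_hand_coded_two_sided_f(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1.0, 12)
        b = rng.normal(0, 2.5, 17)
        out = variance_ftests([a, b])
        f = a.var(ddof=1) / b.var(ddof=1)
        p = 2 * min(sst.f.cdf(f, 11, 16), sst.f.sf(f, 11, 16))
        assert out["f"].iloc[0] == pytest.approx(f, rel=1e-12)
        assert out["p_raw"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_bh_adjustment_matches_hand_rolled(self):
        groups = _random_groups(6, k=4)
        out = variance_ftests(groups)
        p = out["p_raw"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):  # step-up from the largest p
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        assert np.allclose(out["p_fdr"], adj, rtol=1e-12)

    def test_bh_monotone_and_never_below_raw(self):
        groups = _random_groups(7, k=5)
        out = variance_ftests(groups)
        assert np.all(out["p_fdr"] >= out["p_raw"] - 1e-15)
        order = out.sort_values("p_raw")
        assert order["p_fdr"].is_monotonic_increasing


class TestConfusion:
    LABELS = ("a", "b", "c")

    def test_perfect_predictions_identity(self):
        truth = np.array(["a", "b", "c"] * 4)
        cm = confusion(truth, truth, self.LABELS)
        assert np.array_equal(cm.row_normalized(), np.eye(3))
        assert cm.accuracy == 1.0

    def test_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(8)
        truth = rng.choice(self.LABELS, 200)
        pred = rng.choice(self.LABELS, 200)
        cm = confusion(pred, truth, self.LABELS)
        assert cm.accuracy == pytest.approx(np.mean(pred == truth))
        assert cm.counts.sum() == 200

    def test_averaging_identical_matrices_is_identity_op(self):
        truth = np.array(["a", "a", "b", "c"])
        pred = np.array(["a", "b", "b", "c"])
        cm = confusion(pred, truth, self.LABELS)
        avg = average_confusions([cm, cm, cm])
        assert np.allclose(avg, cm.row_normalized())

    def test_averaging_mixes_row_sensitivities(self):
        # subject 1: class-a sensitivity 1.0; subject 2: 0.5
        cm1 = confusion(["a", "a"], ["a", "a"], self.LABELS)
        cm2 = confusion(["a", "b"], ["a", "a"], self.LABELS)
        avg = average_confusions([cm1, cm2])
        assert avg[0, 0] == pytest.approx(0.75)

    def test_zero_support_rows_flagged(self):
        cm = confusion(["a"], ["a"], self.LABELS)
        assert set(cm.zero_support_rows) == {"b", "c"}
        assert np.all(cm.row_normalized()[1:] == 0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["z"], ["a"], self.LABELS)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.zeros((2, 2)), self.LABELS)


class TestMethodComparison:
    def test_separated_methods_detected(self):
        rng = np.random.default_rng(9)
        acc = {
            "ann": rng.normal(0.94, 0.005, 10),
            "svm": rng.normal(0.87, 0.02, 10),
            "rf": rng.normal(0.83, 0.03, 10),
            "lr": rng.normal(0.54, 0.08, 10),
        }
        report = run_method_comparison(acc)
        assert report.welch["p"] < 0.05
        gh = report.games_howell
        ann_pairs = gh[(gh.group_a == "ann") | (gh.group_b == "ann")]
        assert len(ann_pairs) == 3
        assert (ann_pairs["p"] < 0.05).all()
        assert len(gh) == 6  # k(k-1)/2
        assert len(report.variance_ftests) == 6

    def test_single_method_descriptive_only(self):
        report = run_method_comparison({"ann": [0.9, 0.91, 0.92]})
        assert report.levene is None
        assert report.welch is None
        assert report.descriptives.loc["ann", "mean"] == pytest.approx(0.91)

    def test_json_round_trip(self, tmp_path):
        import json

        rng = np.random.default_rng(10)
        report = run_method_comparison(
            {"a": rng.normal(0.9, 0.01, 6), "b": rng.normal(0.8, 0.05, 6)}
        )
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert set(loaded) >= {"accuracy_table", "levene", "welch_anova",
                               "games_howell", "variance_ftests"}
        assert 0 <= loaded["welch_anova"]["p"] <= 1
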