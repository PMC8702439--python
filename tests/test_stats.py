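import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from delaydisc import stats as gs
from delaydisc.errors import ValidationError


def anova_oracle(y1, y2):
    """Textbook split-plot sum-of-squares decomposition, coded with explicit loops."""
    all_rows = [(0, s, y1[s]) for s in range(len(y1))] + [
        (1, s, y2[s]) for s in range(len(y2))
    ]
    values = [v for _, _, row in all_rows for v in row]
    grand = sum(values) / len(values)
    groups = {0: y1, 1: y2}

    ss_total = sum((v - grand) ** 2 for v in values)
    subj_means = [sum(row) / 2 for _, _, row in all_rows]
    ss_between_subj = sum(2 * (m - grand) ** 2 for m in subj_means)
    ss_group = 0.0
    for g, rows in groups.items():
        gm = sum(v for row in rows for v in row) / (2 * len(rows))
        ss_group += 2 * len(rows) * (gm - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group
    n_subj = len(all_rows)
    ss_cond = 0.0
    for c in (0, 1):
        cm = sum(row[c] for _, _, row in all_rows) / n_subj
        ss_cond += n_subj * (cm - grand) ** 2
    ss_cells = 0.0
    for g, rows in groups.items():
        for c in (0, 1):
            cell = sum(row[c] for row in rows) / len(rows)
            ss_cells += len(rows) * (cell - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within = ss_total - ss_between_subj
    ss_cond_err = ss_within - ss_cond - ss_inter
    df_err = n_subj - 2
    out = {}
    for name, ss_eff, ss_err in (
        ("group", ss_group, ss_subj_within),
        ("condition", ss_cond, ss_cond_err),
        ("interaction", ss_inter, ss_cond_err),
    ):
        f = (ss_eff / 1) / (ss_err / df_err)
        out[name] = {
            "F": f,
            "p": float(sps.f.sf(f, 1, df_err)),
            "pes": ss_eff / (ss_eff + ss_err),
        }
    return out


def _long(y1, y2):
    rows = []
    for g, arr in (("g1", y1), ("g2", y2)):
        for i, (a, b) in enumerate(arr):
            pid = f"{g}_{i}"
            rows.append({"participant_id": pid, "group": g, "condition": "immediate", "value": a})
            rows.append({"participant_id": pid, "group": g, "condition": "non_immediate", "value": b})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_symmetric_groups_have_zero_group_effect(self):
        res = gs.mixed_anova_2x2(_long([(1, 2), (3, 4)], [(2, 1), (4, 3)]))
        assert res.between.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            y1 = rng.normal(size=(n, 2))
            y2 = rng.normal(size=(n, 2))
            res = gs.mixed_anova_2x2(_long(y1, y2))
            ref = anova_oracle(y1.tolist(), y2.tolist())
            for eff, mine in (
                ("group", res.between),
                ("condition", res.within),
                ("interaction", res.interaction),
            ):
                assert mine.F == pytest.approx(ref[eff]["F"], abs=1e-9)
                assert mine.p == pytest.approx(ref[eff]["p"], abs=1e-9)
                assert mine.partial_eta_sq == pytest.approx(ref[eff]["pes"], abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        df = _long(rng.normal(size=(9, 2)), rng.normal(size=(9, 2)))
        res = gs.mixed_anova_2x2(df)
        aov = pg.mixed_anova(
            data=df, dv="value", within="condition", subject="participant_id", between="group"
        ).set_index("Source")
        assert res.between.F == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert res.within.F == pytest.approx(aov.loc["condition", "F"], rel=1e-9)
        assert res.interaction.F == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)

    def test_unbalanced_between_groups_supported(self):
        rng = np.random.default_rng(3)
        res = gs.mixed_anova_2x2(_long(rng.normal(size=(57, 2)), rng.normal(size=(58, 2))))
        assert res.between.df2 == 113  # N - 2, as reported for a 57/58 design

    def test_posthoc_bonferroni_adjustment(self):
        rng = np.random.default_rng(4)
        res = gs.mixed_anova_2x2(_long(rng.normal(1, 1, (8, 2)), rng.normal(0, 1, (8, 2))))
        assert len(res.posthoc) == 2
        for _, row in res.posthoc.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, 2 * row["p_raw"]))
            assert row["ci_low"] <= row["mean_diff"] <= row["ci_high"]

    def test_missing_cell_rejected(self):
        df = _long([(1, 2), (3, 4)], [(2, 1), (4, 3)]).iloc[:-1]
        with pytest.raises(ValidationError):
            gs.mixed_anova_2x2(df)


class TestTTest:
    def test_hand_computed_example(self):
        res = gs.t_test_with_d([0, 1, 2], [2, 3, 4])
        assert res.t == pytest.approx(-2.4495, abs=1e-4)
        assert res.df == 4
        assert res.cohen_d == pytest.approx(-2.0)

    def test_identical_samples(self):
        res = gs.t_test_with_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0 and res.cohen_d == 0

    def test_d_equals_t_times_sqrt_inverse_ns(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(5, 40)))
            y = rng.normal(0.5, 1, size=int(rng.integers(5, 40)))
            res = gs.t_test_with_d(x, y, variant="student")
            assert res.cohen_d == pytest.approx(
                gs.cohen_d_from_t(res.t, x.size, y.size), abs=1e-9
            )

    def test_welch_degrees_of_freedom_fractional(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.2, 20)
        y = rng.normal(0, 3.0, 35)
        res = gs.t_test_with_d(x, y, variant="welch")
        assert res.df != x.size + y.size - 2
        assert res.variant == "welch"

    def test_zero_variance_d_undefined(self):
        with pytest.raises(ValidationError):
            gs.t_test_with_d([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            gs.t_test_with_d([1.0], [2.0, 3.0])


class TestChiSquare:
    def test_hand_computed_table(self):
        res = gs.chi_square_2x2([[10, 20], [20, 10]])
        assert res.chi2 == pytest.approx(6.6667, abs=1e-4)
        assert res.effect_r == pytest.approx(0.3333, abs=1e-4)
        assert res.df == 1

    def test_independence_gives_zero(self):
        res = gs.chi_square_2x2([[15, 15], [15, 15]])
        assert res.chi2 == 0 and res.effect_r == 0

    def test_transpose_invariance(self):
        t = np.array([[12, 30], [25, 8]])
        assert gs.chi_square_2x2(t).chi2 == pytest.approx(gs.chi_square_2x2(t.T).chi2)
        assert gs.chi_square_2x2(t[::-1]).effect_r == pytest.approx(
            gs.chi_square_2x2(t).effect_r
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            gs.chi_square_2x2([[0, 0], [5, 10]])


class TestProportionSS:
    def _trials(self, choices_by_pid):
        rows = []
        for pid, choices in choices_by_pid.items():
            for i, ch in enumerate(choices):
                rows.append(
                    {
                        "participant_id": pid,
                        "group": "g1",
                        "condition": "immediate",
                        "choice": ch,
                    }
                )
        return pd.DataFrame(rows)

    def test_counting(self):
        df = self._trials({"a": ["SS"] * 10, "b": ["SS"] * 7 + ["LL"] * 3})
        out = gs.proportion_ss(df).set_index("participant_id")["proportion_ss"]
        assert out["a"] == 1.0
        assert out["b"] == pytest.approx(0.7)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            gs.proportion_ss(pd.DataFrame(columns=["participant_id", "condition", "choice"]))
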