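"""Repeated-measures ANOVA battery: SS partition, sphericity, follow-ups."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awtsim.stats import (
    mauchly_gg,
    pairwise_bonferroni,
    percent_reduction,
    rm_anova_2way,
    rm_anova_2way_array,
)


def naive_rm_anova(y):
    """Independent oracle: explicit-loop cell-means SS partition.

    Deliberately naive (pure Python loops over subjects and cells) so that
    it shares no code path with the vectorised implementation.
    """
    n, a, b = y.shape
    grand = sum(y[s, i, j] for s in range(n) for i in range(a) for j in range(b)) / (n * a * b)
    ms = [sum(y[s, i, j] for i in range(a) for j in range(b)) / (a * b) for s in range(n)]
    ma = [sum(y[s, i, j] for s in range(n) for j in range(b)) / (n * b) for i in range(a)]
    mb = [sum(y[s, i, j] for s in range(n) for i in range(a)) / (n * a) for j in range(b)]
    mab = [[sum(y[s, i, j] for s in range(n)) / n for j in range(b)] for i in range(a)]
    msa = [[sum(y[s, i, j] for j in range(b)) / b for i in range(a)] for s in range(n)]
    msb = [[sum(y[s, i, j] for i in range(a)) / a for j in range(b)] for s in range(n)]
    ss_a = n * b * sum((m - grand) ** 2 for m in ma)
    ss_b = n * a * sum((m - grand) ** 2 for m in mb)
    ss_ab = n * sum(
        (mab[i][j] - ma[i] - mb[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (msa[s][i] - ms[s] - ma[i] + grand) ** 2 for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (msb[s][j] - ms[s] - mb[j] + grand) ** 2 for s in range(n) for j in range(b)
    )
    ss_abs = sum(
        (
            y[s, i, j] - mab[i][j] - msa[s][i] - msb[s][j]
            + ma[i] + mb[j] + ms[s] - grand
        ) ** 2
        for s in range(n) for i in range(a) for j in range(b)
    )
    def f(ss_eff, df_eff, ss_err, df_err):
        return (ss_eff / df_eff) / (ss_err / df_err)
    return {
        "A": f(ss_a, a - 1, ss_as, (n - 1) * (a - 1)),
        "B": f(ss_b, b - 1, ss_bs, (n - 1) * (b - 1)),
        "A x B": f(ss_ab, (a - 1) * (b - 1), ss_abs, (n - 1) * (a - 1) * (b - 1)),
    }


def long_frame(y, dv="threshold_deg"):
    n, a, b = y.shape
    rows = [
        {"subject": f"s{s}", "condition": f"a{i}", "meridian_class": f"b{j}", dv: y[s, i, j]}
        for s in range(n) for i in range(a) for j in range(b)
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_df_structure_20_subjects_2x3(self):
        y = np.random.default_rng(0).normal(size=(20, 2, 3))
        res = rm_anova_2way(long_frame(y), within=("condition", "meridian_class"))
        eff = res.effects
        assert (eff.loc["condition", "df_num"], eff.loc["condition", "df_den"]) == (1, 19)
        # uncorrected df; GG may rescale the reported ones for >=2 df effects
        assert res.sphericity.index.tolist() == [
            "meridian_class", "condition x meridian_class"
        ]
        core = rm_anova_2way_array(y)
        assert core["df"]["B"] == (2, 38)
        assert core["df"]["A x B"] == (2, 38)

    def test_null_effect_gives_zero_f(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(8, 1, 3))
        y = np.concatenate([half, half], axis=1)  # identical across A within subject
        core = rm_anova_2way_array(y)
        assert core["ss"]["A"] == pytest.approx(0.0, abs=1e-12)
        assert core["F"]["A"] == pytest.approx(0.0, abs=1e-12)

    def test_f_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.normal(20, 5, size=(5, 2, 3))
            core = rm_anova_2way_array(y)
            oracle = naive_rm_anova(y)
            for eff in ("A", "B", "A x B"):
                assert core["F"][eff] == pytest.approx(oracle[eff], abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ss_partition_conserves_total(self, seed):
        rng = np.random.default_rng(seed)
        n, a, b = rng.integers(3, 8), rng.integers(2, 4), rng.integers(2, 5)
        y = rng.normal(size=(n, a, b))
        ss = rm_anova_2way_array(y)["ss"]
        parts = (ss["subject"] + ss["A"] + ss["B"] + ss["A x B"]
                 + ss["A error"] + ss["B error"] + ss["A x B error"])
        assert parts == pytest.approx(ss["total"], abs=1e-9)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_2way_array(np.zeros((1, 2, 3)))

    def test_missing_cell_rejected(self):
        y = np.random.default_rng(0).normal(size=(4, 2, 3))
        df = long_frame(y)
        df = df[~((df.subject == "s0") & (df.condition == "a1") & (df.meridian_class == "b2"))]
        with pytest.raises(ValueError, match="incomplete|missing"):
            rm_anova_2way(df, within=("condition", "meridian_class"))

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(25, 5, (12, 2, 3)) + rng.normal(0, 3, (12, 1, 1))
        df = long_frame(y)
        res = rm_anova_2way(df, within=("condition", "meridian_class"))
        ref = pg.rm_anova(dv="threshold_deg", within=["condition", "meridian_class"],
                          subject="subject", data=df, detailed=True)
        for eff, src in (("condition", "condition"),
                         ("meridian_class", "meridian_class"),
                         ("condition x meridian_class", "condition * meridian_class")):
            row = ref[ref["Source"] == src].iloc[0]
            assert res.effects.loc[eff, "F"] == pytest.approx(row["F"], rel=1e-9)
            if np.isfinite(res.effects.loc[eff, "eps_gg"]):
                assert res.effects.loc[eff, "eps_gg"] == pytest.approx(row["eps"], rel=1e-9)

    def test_partial_eta_sq_in_unit_interval(self):
        y = np.random.default_rng(7).normal(size=(6, 3, 3))
        res = rm_anova_2way(y)
        assert ((res.effects["partial_eta_sq"] >= 0) & (res.effects["partial_eta_sq"] <= 1)).all()


class TestMauchlyGG:
    def test_spherical_covariance_is_trivial(self):
        w, chi2, p, eps = mauchly_gg(np.eye(2) * 3.0, n=20)
        assert (w, chi2, p, eps) == (1.0, pytest.approx(0.0), pytest.approx(1.0), 1.0)

    def test_two_level_factor_trivially_spherical(self):
        w, chi2, p, eps = mauchly_gg(np.array([[2.5]]), n=20)
        assert (w, eps) == (1.0, 1.0)

    def test_epsilon_from_eigenvalues_4_and_1(self):
        # eps = (4+1)^2 / (2*(16+1)) = 25/34
        w, chi2, p, eps = mauchly_gg(np.diag([4.0, 1.0]), n=20)
        assert eps == pytest.approx(25 / 34)
        assert w < 1.0

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=(15, 3))
            s = np.cov((x @ np.array([[1, -1, 0], [0, 1, -1]]).T), rowvar=False)
            eps = mauchly_gg(s, n=15)[3]
            assert 1 / 2 - 1e-12 <= eps <= 1 + 1e-12

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            mauchly_gg(np.zeros((2, 2)), n=10)

    def test_matches_pingouin_sphericity(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(size=(14, 3)) * np.array([1.0, 2.0, 4.0])
        df = pd.DataFrame(
            [{"subject": s, "level": j, "y": x[s, j]} for s in range(14) for j in range(3)]
        )
        spher = pg.sphericity(df, dv="y", subject="subject", within="level")
        eps_ref = pg.epsilon(df, dv="y", subject="subject", within="level", correction="gg")
        c = np.array([[1, -1, 0], [0, 1, -1]], dtype=float)
        # orthonormalise the contrast rows
        q, _ = np.linalg.qr(c.T)
        s = np.cov(x @ q, rowvar=False)
        w, chi2, p, eps = mauchly_gg(s, n=14)
        assert w == pytest.approx(spher.W, rel=1e-9)
        assert chi2 == pytest.approx(spher.chi2, rel=1e-9)
        assert p == pytest.approx(spher.pval, rel=1e-9)
        assert eps == pytest.approx(eps_ref, rel=1e-9)


class TestPairwiseBonferroni:
    def test_three_levels_alpha_017(self):
        y = np.random.default_rng(2).normal(size=(10, 2, 3))
        table = pairwise_bonferroni(long_frame(y), factor="meridian_class")
        assert len(table) == 3
        assert table["adjusted_alpha"].unique() == pytest.approx([0.05 / 3])
        assert table["adjusted_alpha"].iloc[0] == pytest.approx(0.017, abs=5e-4)

    def test_identical_levels_not_significant(self):
        y = np.tile(np.random.default_rng(3).normal(size=(8, 2, 1)), (1, 1, 3))
        table = pairwise_bonferroni(long_frame(y), factor="meridian_class")
        assert (table["mean_diff"] == 0).all()
        assert not table["significant"].any()

    def test_two_levels_no_correction(self):
        y = np.random.default_rng(4).normal(size=(10, 2, 3))
        table = pairwise_bonferroni(long_frame(y), factor="condition")
        assert len(table) == 1
        assert table["adjusted_alpha"].iloc[0] == 0.05

    def test_strong_difference_detected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(12, 2, 3))
        y[:, :, 0] += 10.0
        table = pairwise_bonferroni(long_frame(y), factor="meridian_class")
        involving_b0 = table[(table.level_1 == "b0") | (table.level_2 == "b0")]
        assert involving_b0["significant"].all()


class TestPercentReduction:
    def test_worked_example_14_percent(self):
        red = percent_reduction(28.83, 24.75)
        assert red == pytest.approx(14.1519, abs=1e-3)
        assert round(red) == 14

    @pytest.mark.parametrize("ref,cmp,expected", [(30.0, 30.0, 0.0), (40.0, 20.0, 50.0)])
    def test_simple_cases(self, ref, cmp, expected):
        assert percent_reduction(ref, cmp) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 10.0)
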