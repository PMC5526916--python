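"""Seed indices, G-tests, ANOVA/Tukey, PCA and stepwise discriminant."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from beandiv.morphology import (ContingencyTable, anova_tukey, lr_chisq,
                                quantitative_summary, seed_indices,
                                seed_size_class, stepwise_discriminant)

# seed-coat colors of plain-coat accessions in the three true-type groups
# of the Portuguese collection (white, yellow, pink, light brown, brown,
# red, purplish red, black)
TRUETYPE_COLOR_COUNTS = np.array([
    [7, 0, 1, 2, 3, 0, 0, 1],
    [4, 1, 2, 0, 0, 5, 1, 0],
    [1, 0, 10, 3, 6, 6, 1, 0],
])


class TestSeedIndices:
    def test_cube_symmetry(self):
        assert seed_indices(5, 5, 5) == (1, 1, 1)

    def test_hand_arithmetic(self):
        flat, fidx, elong = seed_indices(10, 5, 6)
        assert (flat, fidx) == (1.2, 1.6)
        assert elong == pytest.approx(1.6667, abs=5e-5)

    def test_zero_dimension_errors(self):
        with pytest.raises(ValueError):
            seed_indices(10, 0, 6)


class TestSeedSizeClass:
    @pytest.mark.parametrize("w,cls", [
        (20, "small"), (24.9, "small"),
        (25, "medium"), (32, "medium"), (40, "medium"),
        (40.1, "large"), (45, "large"),
    ])
    def test_thresholds(self, w, cls):
        assert seed_size_class(w) == cls


class TestLrChisq:
    def test_seed_color_counts_reproduce_published_p(self):
        """G-test on the 3×8 true-type color table gives P = 0.0007."""
        t = ContingencyTable(["AP1", "B1P3", "B2P2"], list(range(8)),
                             TRUETYPE_COLOR_COUNTS)
        G, df, p = lr_chisq(t)
        assert df == 14
        assert p == pytest.approx(0.0007, abs=5e-5)

    def test_proportional_table_g_zero(self):
        t = ContingencyTable(["r1", "r2"], ["c1", "c2"],
                             np.array([[10, 20], [30, 60]]))
        G, df, p = lr_chisq(t)
        assert G == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        t = ContingencyTable(["a", "b"], ["x", "y"],
                             np.array([[10, 0], [0, 10]]))
        G, df, p = lr_chisq(t)
        assert G == pytest.approx(40 * np.log(2), abs=1e-9)  # 27.726
        assert df == 1

    def test_matches_scipy_log_likelihood(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(1, 30, size=(3, 4))
            t = ContingencyTable(list("abc"), list("wxyz"), counts)
            G, df, p = lr_chisq(t)
            g2, p2, df2, _ = chi2_contingency(
                counts, lambda_="log-likelihood", correction=False)
            assert G == pytest.approx(g2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-12)

    def test_permutation_invariance(self):
        t = ContingencyTable(["a", "b", "c"], ["x", "y"],
                             np.array([[3, 9], [5, 1], [7, 7]]))
        perm = ContingencyTable(["c", "a", "b"], ["y", "x"],
                                np.array([[7, 7], [9, 3], [1, 5]]))
        assert lr_chisq(t)[0] == pytest.approx(lr_chisq(perm)[0], abs=1e-12)

    def test_structural_zero_column_dropped_with_warning(self):
        t = ContingencyTable(["a", "b"], ["x", "y", "z"],
                             np.array([[3, 0, 9], [5, 0, 1]]))
        with pytest.warns(UserWarning, match="all-zero"):
            G, df, p = lr_chisq(t)
        assert df == 1

    def test_zero_total_errors(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            lr_chisq(t)


class TestAnovaTukey:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        F, p, letters = anova_tukey({"a": base, "b": base + 1e-9,
                                     "c": base - 1e-9})
        assert p > 0.9
        assert len(set(letters.values())) == 1

    def test_widely_shifted_groups_distinct_letters(self):
        rng = np.random.default_rng(2)
        F, p, letters = anova_tukey({
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(10, 1, 20),
            "c": rng.normal(20, 1, 20)})
        assert p < 1e-10
        assert len({letters[g] for g in "abc"}) == 3

    def test_f_matches_hand_ss_decomposition(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 4, 6]),
                  "c": np.array([5.0, 5, 8])}
        allv = np.concatenate(list(groups.values()))
        gm = allv.mean()
        ssb = sum(len(v) * (v.mean() - gm) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        F_hand = (ssb / 2) / (ssw / 6)
        F, p, _ = anova_tukey(groups)
        assert F == pytest.approx(F_hand, abs=1e-10)

    def test_degenerate_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            F, p, letters = anova_tukey({"a": np.array([1.0, 1]),
                                         "b": np.array([2.0, 2])})
        assert np.isnan(F)


class TestQuantitativeSummary:
    def test_duplicated_trait_r_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        df = pd.DataFrame({"t1": x, "t2": x, "t3": rng.normal(size=25)})
        corr, *_ = quantitative_summary(df)
        assert corr.loc["t1", "t2"] == pytest.approx(1.0)

    def test_collinear_data_pc1_all_variance(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"t1": x, "t2": 3 * x + 1})
        _, _, _, pct = quantitative_summary(df)
        assert pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(20, 5)),
                          columns=[f"t{i}" for i in range(5)])
        _, scores, loadings, _ = quantitative_summary(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-10)


class TestStepwiseDiscriminant:
    def _fixture(self, effect=8.0, seed=5):
        rng = np.random.default_rng(seed)
        n = 30
        groups = pd.Series(["g1"] * n + ["g2"] * n)
        signal = np.concatenate([rng.normal(0, 1, n),
                                 rng.normal(effect, 1, n)])
        df = pd.DataFrame({
            "signal": signal,
            "noise1": rng.normal(size=2 * n),
            "noise2": rng.normal(size=2 * n)})
        return df, groups

    def test_perfect_separator_selected_first(self):
        df, groups = self._fixture(effect=10)
        model = stepwise_discriminant(df, groups)
        assert model.selected[0] == "signal"
        assert model.cv_error == 0.0

    def test_identical_traits_give_empty_model(self):
        df = pd.DataFrame({"t1": np.ones(20), "t2": np.ones(20)})
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        with pytest.warns(UserWarning, match="empty model"):
            model = stepwise_discriminant(df, groups)
        assert model.selected == []

    def test_partial_r2_equals_point_biserial_squared(self):
        """Two groups, one trait: partial r² is the squared point-biserial
        correlation between trait and group indicator."""
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15)])
        df = pd.DataFrame({"t": x})
        groups = pd.Series(["a"] * 15 + ["b"] * 15)
        model = stepwise_discriminant(df, groups)
        ind = np.array([0] * 15 + [1] * 15)
        r = np.corrcoef(x, ind)[0, 1]
        assert model.partial_r2[0] == pytest.approx(r ** 2, abs=1e-10)

    def test_cv_error_decreases_with_effect_size(self):
        errors = []
        for effect in (0.5, 1.5, 4.0):
            df, groups = self._fixture(effect=effect, seed=7)
            model = stepwise_discriminant(df, groups)
            errors.append(model.cv_error if model.selected else 0.5)
        assert errors[0] > errors[2]
        assert errors[1] >= errors[2]

    def test_wilks_lambda_decreasing(self):
        rng = np.random.default_rng(8)
        n = 40
        groups = pd.Series(["a"] * n + ["b"] * n)
        df = pd.DataFrame({
            "t1": np.concatenate([rng.normal(0, 1, n),
                                  rng.normal(3, 1, n)]),
            "t2": np.concatenate([rng.normal(0, 1, n),
                                  rng.normal(1.5, 1, n)])})
        model = stepwise_discriminant(df, groups)
        lam = model.wilks_lambda
        assert all(b <= a + 1e-12 for a, b in zip(lam, lam[1:]))
        assert all(0 < l <= 1 for l in lam)
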