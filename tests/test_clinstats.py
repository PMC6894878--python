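import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from clotquant import clinstats
from clotquant.quantify import ClotCategory
from oracles import chi2_2x2_closed_form, spearman_oracle


class TestHasFlag:
    @pytest.mark.parametrize("hu,expected", [(54.0, True), (49.4, False), (50.0, True)])
    def test_threshold(self, hu, expected):
        assert clinstats.has_flag(hu) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            clinstats.has_flag(float("nan"))


class TestBlandAltman:
    def test_identity(self):
        res = clinstats.bland_altman([1, 2, 3], [1, 2, 3])
        assert res.bias == 0 and res.sd == 0 and res.loa_low == res.loa_high == 0

    def test_hand_arithmetic(self):
        # differences [-2, 0, 2]: bias 0, sample SD 2, limits +/- 3.92
        res = clinstats.bland_altman([1, 2, 3], [3, 2, 1])
        assert res.bias == pytest.approx(0)
        assert res.sd == pytest.approx(2)
        assert res.loa_low == pytest.approx(-3.92)
        assert res.loa_high == pytest.approx(3.92)
        assert res.points == ((2.0, -2.0), (2.0, 0.0), (2.0, 2.0))

    def test_limits_reconstruct_from_bias_and_sd(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        res = clinstats.bland_altman(a, b)
        assert res.loa_low == res.bias - 1.96 * res.sd
        assert res.loa_high == res.bias + 1.96 * res.sd

    def test_input_validation(self):
        with pytest.raises(ValueError):
            clinstats.bland_altman([1], [2])
        with pytest.raises(ValueError):
            clinstats.bland_altman([1, 2], [1, 2, 3])


class TestSpearman:
    def test_perfect_monotone(self):
        assert clinstats.spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1)
        assert clinstats.spearman([1, 2, 3, 4], [10, 20, 30, 40]).p == 0.0

    def test_perfect_inverse(self):
        assert clinstats.spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == pytest.approx(-1)

    def test_rank_arithmetic_example(self):
        # d^2 = (0,1,1,1,1): rho = 1 - 6*4/(5*24) = 0.8
        res = clinstats.spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.rho == pytest.approx(0.8)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_rank_then_pearson_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 40))
        # integer draws force ties
        x = r.integers(0, 8, size=n).astype(float)
        y = x + r.integers(0, 8, size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        res = clinstats.spearman(x, y)
        assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-9)

    def test_p_matches_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = clinstats.spearman(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref_rho, abs=1e-12)
        assert res.p == pytest.approx(ref_p, abs=1e-12)

    def test_exact_permutation_small_n(self):
        res = clinstats.spearman([1, 2, 3, 4], [1, 2, 4, 3], exact=True)
        assert 0 < res.p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            clinstats.spearman([1, 1, 1], [1, 2, 3])


class TestChiSquared:
    def test_independent_table(self):
        res = clinstats.pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p == pytest.approx(1)

    def test_closed_form_example(self):
        res = clinstats.pearson_chi2([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_permutation_invariance(self):
        t = [[5, 9], [12, 3]]
        a = clinstats.pearson_chi2(t)
        b = clinstats.pearson_chi2([r[::-1] for r in t[::-1]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_exhaustive_small_2x2_closed_form(self):
        # every 2x2 table with margins <= 8 and no zero margin
        for a, b, c, d in itertools.product(range(9), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = clinstats.pearson_chi2([[a, b], [c, d]])
            assert res.statistic == pytest.approx(chi2_2x2_closed_form(a, b, c, d), abs=1e-9)

    def test_matches_scipy_contingency(self, rng):
        obs = rng.integers(1, 30, size=(3, 2))
        res = clinstats.pearson_chi2(obs)
        ref = sps.chi2_contingency(obs, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        np.testing.assert_allclose(res.expected, ref.expected_freq)

    def test_expected_margins_match_observed(self):
        res = clinstats.pearson_chi2([[20, 10], [10, 20]])
        exp = np.asarray(res.expected)
        obs = np.asarray(res.observed)
        np.testing.assert_allclose(exp.sum(axis=0), obs.sum(axis=0), atol=1e-9)
        np.testing.assert_allclose(exp.sum(axis=1), obs.sum(axis=1), atol=1e-9)

    def test_yates_correction_flag(self):
        plain = clinstats.pearson_chi2([[20, 10], [10, 20]])
        corr = clinstats.pearson_chi2([[20, 10], [10, 20]], correction=True)
        assert corr.statistic < plain.statistic

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            clinstats.pearson_chi2([[0, 0], [5, 5]])


class TestHasTable:
    def test_direct_tally(self):
        cats = [ClotCategory.RBC_RICH, ClotCategory.MIXED, ClotCategory.FIBRIN_RICH]
        t3, t2 = clinstats.composition_has_table(cats, [True, True, True])
        np.testing.assert_array_equal(t3, [[1, 0], [1, 0], [1, 0]])
        np.testing.assert_array_equal(t2, [[1, 0], [2, 0]])

    def test_collapsed_sums_consistent(self):
        cats = [ClotCategory.RBC_RICH] * 4 + [ClotCategory.MIXED] * 3 + [ClotCategory.FIBRIN_RICH] * 5
        flags = [True, False] * 6
        t3, t2 = clinstats.composition_has_table(cats, flags)
        np.testing.assert_array_equal(t2[0], t3[0])
        np.testing.assert_array_equal(t2[1], t3[1] + t3[2])

    def test_empty_category_gives_zero_row(self):
        t3, _ = clinstats.composition_has_table([ClotCategory.RBC_RICH], [True])
        assert (t3[1] == 0).all()
        with pytest.raises(ValueError, match="margin"):
            clinstats.pearson_chi2(t3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clinstats.composition_has_table([ClotCategory.MIXED], [True, False])


def synthetic_cohort(n=30, seed=5):
    """A synthetic per-clot cohort standing in for a real study table."""
    r = np.random.default_rng(seed)
    rbc = np.clip(r.uniform(5, 95, n), 0, 100)
    wbc = np.clip(r.uniform(1, 8, n), 0, 100 - rbc)
    fib = 100 - rbc - wbc
    a = pd.DataFrame({"clot_id": [f"c{i}" for i in range(n)], "pct_rbc": rbc, "pct_wbc": wbc, "pct_fibrin": fib})
    # method B: method A plus noise, renormalized to 100
    nb = np.clip(np.stack([rbc, wbc, fib], axis=1) + r.normal(0, 4, (n, 3)), 0.5, None)
    nb = 100 * nb / nb.sum(axis=1, keepdims=True)
    b = a.copy()
    b[["pct_rbc", "pct_wbc", "pct_fibrin"]] = nb
    clin = pd.DataFrame(
        {"clot_id": a.clot_id, "mean_hu": np.round(35 + 0.3 * rbc + r.normal(0, 6, n), 1)}
    )
    from clotquant.quantify import categorize_percentages

    for df in (a, b):
        df["category"] = [
            categorize_percentages(x, y).value for x, y in zip(df.pct_rbc, df.pct_fibrin)
        ]
    return a, b, clin


class TestAgreementReport:
    def test_self_agreement(self):
        a, _, clin = synthetic_cohort()
        rep = clinstats.agreement_report(a, a.copy(), clin)
        assert rep.pooled_spearman.rho == pytest.approx(1)
        assert rep.bland_altman.bias == 0 and rep.bland_altman.sd == 0
        assert rep.pooled_spearman.n == 3 * len(a)

    def test_statistics_match_componentwise_oracles(self):
        a, b, clin = synthetic_cohort()
        rep = clinstats.agreement_report(a, b, clin, names=("ml", "ref"))
        pooled_a = np.concatenate([a[c] for c in ("pct_rbc", "pct_wbc", "pct_fibrin")])
        pooled_b = np.concatenate([b[c] for c in ("pct_rbc", "pct_wbc", "pct_fibrin")])
        assert rep.pooled_spearman.rho == pytest.approx(spearman_oracle(pooled_a, pooled_b))
        diff = pooled_a - pooled_b
        assert rep.bland_altman.bias == pytest.approx(diff.mean())
        assert rep.bland_altman.sd == pytest.approx(diff.std(ddof=1))
        assert rep.rbc_vs_hu["ml"].rho == pytest.approx(
            spearman_oracle(a.pct_rbc.to_numpy(), clin.mean_hu.to_numpy())
        )
        assert set(rep.has_3x2) <= {"ml", "ref"}

    def test_invariant_to_row_order(self):
        a, b, clin = synthetic_cohort()
        rep1 = clinstats.agreement_report(a, b, clin)
        rep2 = clinstats.agreement_report(
            a.sample(frac=1, random_state=1), b.sample(frac=1, random_state=2), clin
        )
        assert rep1.to_json() == rep2.to_json()

    def test_determinism(self):
        a, b, clin = synthetic_cohort()
        assert clinstats.agreement_report(a, b, clin).to_json() == clinstats.agreement_report(a, b, clin).to_json()

    def test_no_overlap_errors(self):
        a, b, clin = synthetic_cohort()
        b = b.assign(clot_id=["x" + i for i in b.clot_id])
        with pytest.raises(ValueError, match="common"):
            clinstats.agreement_report(a, b, clin)


class TestTableImport:
    def test_csv_and_xlsx_with_column_map(self, tmp_path):
        a, _, clin = synthetic_cohort(n=8)
        renamed = a.rename(
            columns={"clot_id": "Clot ID", "pct_rbc": "RBC %", "pct_wbc": "WBC %", "pct_fibrin": "Fibrin %"}
        ).drop(columns=["category"])
        cmap = {"Clot ID": "clot_id", "RBC %": "pct_rbc", "WBC %": "pct_wbc", "Fibrin %": "pct_fibrin"}
        csv_path = str(tmp_path / "a.csv")
        renamed.to_csv(csv_path, index=False)
        xlsx_path = str(tmp_path / "a.xlsx")
        renamed.to_excel(xlsx_path, index=False)
        for path in (csv_path, xlsx_path):
            df = clinstats.load_composition_table(path, cmap)
            np.testing.assert_allclose(df.pct_rbc, a.pct_rbc)
            assert list(df.category) == list(a.category)  # derived by >=60% rule

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"clot_id": ["a"], "pct_rbc": [50]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="pct_fibrin"):
            clinstats.load_composition_table(str(path))

    def test_clinical_table_has_flags(self, tmp_path):
        path = tmp_path / "clin.csv"
        pd.DataFrame({"clot_id": ["a", "b"], "mean_hu": [54.0, 49.4]}).to_csv(path, index=False)
        df = clinstats.load_clinical_table(str(path))
        assert list(df.has_positive) == [True, False]
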