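"""Agreement/discrimination/calibration metrics against independent oracles."""

import numpy as np
import pytest

from lobescore.metrics import (
    BootstrapInterval,
    auroc_ovr,
    bland_altman,
    bootstrap_ci,
    confusion_matrix,
    cwce,
    gwet_ac2,
    icc_2_1,
    macro_auroc,
    macro_cwce,
    ovr_rates,
    pearson_r,
    quadratic_weighted_kappa,
)

# ---------------------------------------------------------------- oracles


def _auroc_pairs(y, p, k):
    """Brute-force AUROC: count concordant positive/negative pairs."""
    pos = p[np.asarray(y) == k]
    neg = p[np.asarray(y) != k]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def _kappa_qw_direct(y_true, y_pred, K=3):
    """Textbook quadratic weighted kappa via explicit loops."""
    n = len(y_true)
    O = np.zeros((K, K))
    for t, p in zip(y_true, y_pred):
        O[t, p] += 1 / n
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    num = den = 0.0
    for i in range(K):
        for j in range(K):
            w = (i - j) ** 2 / (K - 1) ** 2
            num += w * O[i, j]
            den += w * row[i] * col[j]
    return 1 - num / den


def _ac2_direct(y_true, y_pred, K=3):
    """Gwet's AC2 with quadratic ordinal weights, written out explicitly."""
    n = len(y_true)
    P = np.zeros((K, K))
    for t, p in zip(y_true, y_pred):
        P[t, p] += 1 / n
    w = np.array([[1 - (i - j) ** 2 / (K - 1) ** 2 for j in range(K)] for i in range(K)])
    p_a = sum(w[i, j] * P[i, j] for i in range(K) for j in range(K))
    pi = [(P[k].sum() + P[:, k].sum()) / 2 for k in range(K)]
    p_e = w.sum() / (K * (K - 1)) * sum(x * (1 - x) for x in pi)
    return (p_a - p_e) / (1 - p_e)


def _cwce_direct(y, p, k, B=10):
    y = (np.asarray(y) == k).astype(float)
    p = np.asarray(p, float)
    total = 0.0
    for b in range(B):
        lo, hi = b / B, (b + 1) / B
        sel = (p >= lo) & ((p < hi) if b < B - 1 else (p <= hi))
        if sel.sum():
            total += sel.mean() * abs(y[sel].mean() - p[sel].mean())
    return total


# --------------------------------------------------------- confusion & rates


class TestConfusionAndRates:
    def test_identity(self):
        cm = confusion_matrix([0, 1, 2], [0, 1, 2])
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_total_is_n(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        assert confusion_matrix(y, p).sum() == 40

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])

    def test_out_of_range_label_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1])

    def test_row_normalised_display(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], normalize=True)
        assert np.allclose(cm[0], [0.5, 0.5, 0])
        assert np.allclose(cm[2], 0)

    def test_hand_example_rates(self):
        # 2x2 one-vs-rest collapse: TP=2, FN=1, FP=0, TN=3
        cm = np.array([[3, 0], [1, 2]])
        sens, spec, acc = ovr_rates(cm, 1)
        assert (sens, spec, acc) == pytest.approx((2 / 3, 1.0, 5 / 6))

    def test_perfect_diagonal_rates(self):
        cm = np.diag([5, 3, 2])
        for k in range(3):
            assert ovr_rates(cm, k) == pytest.approx((1.0, 1.0, 1.0))

    def test_absent_class_sensitivity_nan(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1])
        sens, spec, acc = ovr_rates(cm, 2)
        assert np.isnan(sens) and spec == 1.0


# ------------------------------------------------------------------- AUROC


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc_ovr([1, 1, 0, 0], np.array([0.9, 0.8, 0.2, 0.1]), 1) == 1.0

    def test_all_ties_give_half(self):
        assert auroc_ovr([1, 0, 1, 0], np.full(4, 0.3), 1) == 0.5

    def test_single_class_nan(self):
        assert np.isnan(auroc_ovr([1, 1], np.array([0.2, 0.4]), 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        y = rng.integers(0, 3, n)
        p = np.round(rng.random(n), 1)  # coarse grid to force ties
        for k in range(3):
            ours = auroc_ovr(y, p, k)
            ref = _auroc_pairs(y, p, k)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_macro_is_mean_of_defined(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 30)  # class 2 never appears
        probs = rng.dirichlet(np.ones(3), 30)
        per = [auroc_ovr(y, probs[:, k], k) for k in range(3)]
        assert np.isnan(per[2])
        assert macro_auroc(y, probs) == pytest.approx(np.mean(per[:2]), abs=1e-12)


# -------------------------------------------------------------------- CWCE


class TestCwce:
    def test_perfect_onehot_zero(self):
        y = [0, 1, 2, 1]
        probs = np.eye(3)[y]
        for k in range(3):
            assert cwce(y, probs[:, k], k) == 0.0

    def test_calibrated_constant_half(self):
        y = [1, 0, 1, 0]
        assert cwce(y, np.full(4, 0.5), 1) == pytest.approx(0.0)

    def test_two_bin_hand_example(self):
        # bin [0,0.5): p=[0.2,0.4], freq=0.5 -> |0.5-0.3|=0.2, weight 0.5
        # bin [0.5,1]: p=[0.6,0.8], freq=1.0 -> |1.0-0.7|=0.3, weight 0.5
        y = [1, 0, 1, 1]
        p = np.array([0.2, 0.4, 0.6, 0.8])
        assert cwce(y, p, 1, bins=2) == pytest.approx(0.5 * 0.2 + 0.5 * 0.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_binning(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(5, 50)
        y = rng.integers(0, 3, n)
        p = rng.random(n)
        for k in range(3):
            assert cwce(y, p, k) == pytest.approx(_cwce_direct(y, p, k), abs=1e-10)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            cwce([0, 1], [0.5, 0.5], 0, bins=0)

    def test_macro_is_mean(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, 40)
        probs = rng.dirichlet(np.ones(3), 40)
        per = [cwce(y, probs[:, k], k) for k in range(3)]
        assert macro_cwce(y, probs) == pytest.approx(np.mean(per), abs=1e-12)


# ----------------------------------------------------- kappa / AC2 agreement


class TestOrdinalAgreement:
    def test_perfect_agreement_is_one(self):
        y = [0, 1, 2, 1, 0]
        assert quadratic_weighted_kappa(y, y) == pytest.approx(1.0)
        assert gwet_ac2(y, y) == pytest.approx(1.0)

    def test_reversed_ordinal_negative(self):
        y = [0, 0, 1, 1, 2, 2]
        rev = [2 - v for v in y]
        assert quadratic_weighted_kappa(y, rev) < 0

    @pytest.mark.parametrize("seed", range(20))
    def test_kappa_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert quadratic_weighted_kappa(a, b) == pytest.approx(
            _kappa_qw_direct(a, b), abs=1e-10
        )

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 3, 30)
            assert quadratic_weighted_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b, weights="quadratic"), abs=1e-10
            )

    def test_ac2_hand_computed_table(self):
        # 8-item worked example, K=3, quadratic ordinal weights:
        # p_a = 6.5/8, pi = (.375, .375, .25), p_e = .65625, AC2 = 5/11
        y_true = [0, 0, 1, 1, 2, 2, 0, 1]
        y_pred = [0, 1, 1, 1, 2, 0, 0, 2]
        assert gwet_ac2(y_true, y_pred) == pytest.approx(5 / 11, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_ac2_matches_direct_formula(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = rng.integers(4, 50)
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert gwet_ac2(a, b) == pytest.approx(_ac2_direct(a, b), abs=1e-10)

    def test_ac2_resists_prevalence_paradox(self):
        # nearly constant data: kappa collapses, AC2 stays high
        y_true = [0] * 18 + [1, 0]
        y_pred = [0] * 18 + [0, 1]
        assert gwet_ac2(y_true, y_pred) > quadratic_weighted_kappa(y_true, y_pred)

    def test_degenerate_constant_agreement(self):
        with pytest.warns(UserWarning):
            assert quadratic_weighted_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            quadratic_weighted_kappa([0, 1], [0])


# ------------------------------------------------------------------ ICC(2,1)


class TestIcc:
    def test_identical_columns(self):
        x = np.column_stack([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert icc_2_1(x) == pytest.approx(1.0)

    def test_constant_offset_penalised(self):
        a = np.array([1.0, 2, 3, 4, 5])
        x = np.column_stack([a, a + 2])
        r, _, _ = pearson_r(a, a + 2)
        assert r == pytest.approx(1.0)
        assert icc_2_1(x) < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        n = 12
        x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 2
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single rater: labelled ICC2
        # or ICC(A,1) depending on the pingouin version
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert icc_2_1(x) == pytest.approx(icc2, abs=1e-8)

    def test_zero_subject_variance_nan(self):
        x = np.column_stack([[1.0, 1, 1], [2.0, 2, 2]])
        with pytest.warns(UserWarning):
            assert np.isnan(icc_2_1(x))


# ------------------------------------------------- Pearson & Bland-Altman


class TestReliability:
    def test_linear_map_r_one(self):
        x = np.arange(10.0)
        r, (lo, hi), p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_anticorrelation(self):
        x = np.arange(5.0)
        r, _, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        direct = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        r, _, _ = pearson_r(x, y)
        assert r == pytest.approx(direct, abs=1e-12)

    def test_bland_altman_identical(self):
        a = np.array([3.0, 5, 7])
        assert bland_altman(a, a) == (0.0, 0.0, 0.0)

    def test_bland_altman_constant_difference(self):
        a = np.array([2.0, 3, 4, 5])
        assert bland_altman(a + 1, a) == (1.0, 1.0, 1.0)

    def test_bland_altman_hand_case(self):
        m, lo, hi = bland_altman(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        sd = np.sqrt(2)
        assert (m, lo, hi) == pytest.approx((1.0, 1 - 1.96 * sd, 1 + 1.96 * sd))

    def test_bland_altman_needs_two(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    def test_loa_coverage_on_simulated_normals(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.5, 1.3, 10_000)
        m, lo, hi = bland_altman(d, np.zeros_like(d))
        cover = np.mean((d >= lo) & (d <= hi))
        assert 0.93 <= cover <= 0.97


# ------------------------------------------------------------------ bootstrap


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        ci = bootstrap_ci(lambda cs: 3.5, [1, 2, 3, 4], B=200, seed=0)
        assert ci.low == ci.high == 3.5

    def test_same_seed_same_interval(self):
        clusters = [np.array([i, i + 1]) for i in range(10)]
        stat = lambda cs: float(np.mean(np.concatenate(cs)))
        a = bootstrap_ci(stat, clusters, B=300, seed=5)
        b = bootstrap_ci(stat, clusters, B=300, seed=5)
        assert (a.low, a.high) == (b.low, b.high)

    def test_interval_contains_point_estimate_for_mean(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            clusters = [rng.normal(size=3) for _ in range(40)]
            stat = lambda cs: float(np.mean(np.concatenate(cs)))
            point = stat(clusters)
            ci = bootstrap_ci(stat, clusters, B=500, seed=seed)
            assert ci.low <= point <= ci.high

    def test_mostly_undefined_statistic_flagged(self):
        def stat(cs):
            return np.nan if len(set(map(id, cs))) < 4 else 1.0

        ci = bootstrap_ci(lambda cs: np.nan, [1, 2, 3], B=200, seed=0)
        assert ci.flagged and np.isnan(ci.low)

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda cs: 0.0, [1, 2], B=10, seed=0)
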