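"""Ordinal agreement, discrimination, calibration and reliability metrics.

Lobe-level predictions (scores 0/1/2) are evaluated one-vs-rest
(sensitivity/specificity/accuracy, AUROC, class-wise calibration error) and
with chance-corrected ordinal agreement (quadratic weighted Cohen's kappa,
Gwet's AC2).  Exam-level overall scores (0-12) are evaluated with ICC(2,1),
Pearson's r and Bland-Altman limits of agreement.  Confidence intervals use
a nonparametric cluster bootstrap resampling whole examinations, since the
six lobes of one exam are not independent.

Undefined quantities (a class absent from the reference, zero variance) are
reported as NaN and flagged, never silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "confusion_matrix",
    "ovr_rates",
    "auroc_ovr",
    "macro_auroc",
    "cwce",
    "macro_cwce",
    "quadratic_weighted_kappa",
    "gwet_ac2",
    "icc_2_1",
    "pearson_r",
    "bland_altman",
    "bootstrap_ci",
    "EvalReport",
    "evaluate_predictions",
]


def _check_labels(y, K: int, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(y, np.arange(K)).all():
        raise ValueError(f"{name} contains labels outside 0..{K - 1}")
    return y.astype(int)


def confusion_matrix(y_true, y_pred, K: int = 3, normalize: bool = False) -> np.ndarray:
    """K x K counts, rows = reference, columns = predicted.

    ``normalize=True`` returns row-stochastic proportions for display
    (rows with no reference cases stay zero).
    """
    y_true = _check_labels(y_true, K, "y_true")
    y_pred = _check_labels(y_pred, K, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((K, K), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    if normalize:
        row = cm.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, cm / row, 0.0)
    return cm


def ovr_rates(cm: np.ndarray, k: int) -> tuple[float, float, float]:
    """One-vs-rest (sensitivity, specificity, accuracy) for class ``k``.

    Undefined ratios (0/0) are returned as NaN.
    """
    cm = np.asarray(cm)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = cm[k, k]
    fn = cm[k].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = n - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    return float(sens), float(spec), float((tp + tn) / n)


def auroc_ovr(y_true, prob_k, k: int) -> float:
    """One-vs-rest AUROC for class ``k`` from its predicted probability.

    Rank-based (Mann-Whitney) with the midrank tie convention; NaN when the
    one-vs-rest labels are single-class.
    """
    y = np.asarray(y_true) == k
    p = np.asarray(prob_k, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(p)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def macro_auroc(y_true, probs: np.ndarray, K: int = 3) -> float:
    """Unweighted mean of the defined per-class one-vs-rest AUROCs."""
    vals = [auroc_ovr(y_true, probs[:, k], k) for k in range(K)]
    defined = [v for v in vals if not np.isnan(v)]
    return float(np.mean(defined)) if defined else np.nan


def cwce(y_true, prob_k, k: int, bins: int = 10) -> float:
    """Class-wise calibration error: binned one-vs-rest calibration gap.

    Partitions the class-k probabilities into ``bins`` equal-width bins over
    [0, 1] and sums, weighted by bin occupancy, the absolute difference
    between the empirical class-k frequency and the mean predicted
    probability in each bin.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    y = (np.asarray(y_true) == k).astype(float)
    p = np.asarray(prob_k, dtype=float)
    idx = np.minimum((p * bins).astype(int), bins - 1)
    n = p.size
    err = 0.0
    for b in range(bins):
        in_bin = idx == b
        nb = in_bin.sum()
        if nb:
            err += (nb / n) * abs(y[in_bin].mean() - p[in_bin].mean())
    return float(err)


def macro_cwce(y_true, probs: np.ndarray, K: int = 3, bins: int = 10) -> float:
    return float(np.mean([cwce(y_true, probs[:, k], k, bins) for k in range(K)]))


def quadratic_weighted_kappa(y_true, y_pred, K: int = 3) -> float:
    """Cohen's kappa with quadratic disagreement weights (i-j)^2/(K-1)^2.

    kappa_w = 1 - sum(w * O) / sum(w * E) with O the observed joint
    proportions and E the outer product of the marginals.  When both raters
    are constant and identical the statistic is degenerate (0/0); it is
    defined as 1 here, with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 ratings")
    O = confusion_matrix(y_true, y_pred, K).astype(float)
    O /= O.sum()
    i, j = np.indices((K, K))
    w = (i - j) ** 2 / (K - 1) ** 2
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    denom = (w * E).sum()
    if denom == 0:
        warnings.warn("degenerate agreement (both raters constant); kappa := 1")
        return 1.0
    return float(1.0 - (w * O).sum() / denom)


def gwet_ac2(y_true, y_pred, K: int = 3) -> float:
    """Gwet's AC2 with quadratic ordinal (agreement) weights.

    Agreement weights w_ij = 1 - (i-j)^2/(K-1)^2.  Observed weighted
    agreement p_a = sum_ij w_ij p_ij; chance agreement uses the mean
    category prevalences pi_k = (p_k. + p_.k)/2:

        p_e = T_w / (K (K - 1)) * sum_k pi_k (1 - pi_k),   T_w = sum_ij w_ij

    AC2 = (p_a - p_e) / (1 - p_e).  Robust to the prevalence paradoxes that
    depress kappa on near-constant data.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 ratings")
    P = confusion_matrix(y_true, y_pred, K).astype(float)
    P /= P.sum()
    i, j = np.indices((K, K))
    w = 1.0 - (i - j) ** 2 / (K - 1) ** 2
    p_a = (w * P).sum()
    pi = (P.sum(axis=1) + P.sum(axis=0)) / 2
    p_e = w.sum() / (K * (K - 1)) * (pi * (1 - pi)).sum()
    if abs(1 - p_e) < 1e-12:
        warnings.warn("degenerate chance agreement; AC2 := 1")
        return 1.0
    return float((p_a - p_e) / (1 - p_e))


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n subjects x k raters), no missing cells.  Computed from
    the two-way ANOVA decomposition:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

    NaN (with a warning) when between-subject variance is zero.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be (n>=3 subjects, k>=2 raters)")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_r = k * ((row_means - grand) ** 2).sum()
    ss_c = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_e = ss_tot - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if ss_r == 0 or abs(denom) < 1e-15:
        warnings.warn("zero between-subject variance; ICC undefined")
        return np.nan
    return float((ms_r - ms_e) / denom)


def pearson_r(x, y, level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation with Fisher-z confidence interval and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        return np.nan, (np.nan, np.nan), np.nan
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1 / np.sqrt(x.size - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    return float(r), (float(lo), float(hi)), float(p)


def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement between two raters.

    d = a - b; LoA = mean(d) +/- 1.96 * sd(d) with sample SD (ddof=1; 0 for
    n=1 differences is impossible since n >= 2 is required).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    d = a - b
    m = d.mean()
    sd = d.std(ddof=1)
    return float(m), float(m - 1.96 * sd), float(m + 1.96 * sd)


def bland_altman_pairs(a, b) -> np.ndarray:
    """(mean(a,b), a-b) pairs for the standard agreement plot."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.column_stack([(a + b) / 2, a - b])


@dataclass
class BootstrapInterval:
    low: float
    high: float
    flagged: bool = False  # statistic undefined on > 20% of resamples


def bootstrap_ci(
    statistic,
    clusters: list,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapInterval:
    """Nonparametric percentile bootstrap over exam-level clusters.

    ``clusters`` is a list of per-examination data units; ``statistic``
    maps a list of clusters to a scalar.  Whole exams are resampled with
    replacement, respecting the within-exam dependence of the six lobes.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(clusters)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals[b] = statistic([clusters[i] for i in idx])
    bad = np.isnan(vals)
    flagged = bad.mean() > 0.2
    good = vals[~bad]
    if good.size == 0:
        return BootstrapInterval(np.nan, np.nan, True)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(good, [alpha, 1 - alpha])
    return BootstrapInterval(float(lo), float(hi), flagged)


@dataclass
class EvalReport:
    """Complete evaluation battery over one set of predictions."""

    n_lobes: int
    n_exams: int
    per_class: dict[int, dict[str, float]]  # accuracy/sensitivity/specificity/auroc/cwce
    macro_auroc: float
    macro_cwce: float
    kappa_qw: float
    gwet_ac2: float
    icc_2_1: float
    pearson_r: float
    pearson_p: float
    bland_altman: tuple[float, float, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_lobes": self.n_lobes,
            "n_exams": self.n_exams,
            "per_class": {
                str(k): {m: _jsonify(v) for m, v in d.items()}
                for k, d in self.per_class.items()
            },
            "macro_auroc": _jsonify(self.macro_auroc),
            "macro_cwce": _jsonify(self.macro_cwce),
            "kappa_qw": _jsonify(self.kappa_qw),
            "gwet_ac2": _jsonify(self.gwet_ac2),
            "icc_2_1": _jsonify(self.icc_2_1),
            "pearson_r": _jsonify(self.pearson_r),
            "pearson_p": _jsonify(self.pearson_p),
            "bland_altman": {
                "mean_diff": _jsonify(self.bland_altman[0]),
                "loa_low": _jsonify(self.bland_altman[1]),
                "loa_high": _jsonify(self.bland_altman[2]),
            },
            "ci": {k: [_jsonify(v[0]), _jsonify(v[1])] for k, v in self.ci.items()},
            "flags": list(self.flags),
        }


def _jsonify(v):
    v = float(v)
    return None if np.isnan(v) else v


def evaluate_predictions(
    y_true,
    y_pred,
    probs: np.ndarray,
    exam_ids,
    overall_true=None,
    overall_pred=None,
    bootstrap: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Full lobe- and exam-level evaluation of one prediction set.

    Lobe-level: per-class one-vs-rest rates, AUROC and CWCE, macro
    summaries, quadratic weighted kappa and Gwet's AC2.  Exam-level (when
    the overall 0-12 scores are given): ICC(2,1), Pearson's r and
    Bland-Altman limits of agreement.  ``bootstrap > 0`` adds cluster-
    bootstrap 95% CIs for kappa, AC2 and macro AUROC.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    probs = np.asarray(probs, float)
    exam_ids = np.asarray(exam_ids)
    cm = confusion_matrix(y_true, y_pred)
    flags = []
    per_class = {}
    for k in range(3):
        sens, spec, acc = ovr_rates(cm, k)
        auc = auroc_ovr(y_true, probs[:, k], k)
        if np.isnan(auc):
            flags.append(f"auroc_class_{k}_undefined")
        per_class[k] = {
            "accuracy": acc, "sensitivity": sens, "specificity": spec,
            "auroc": auc, "cwce": cwce(y_true, probs[:, k], k),
        }

    icc = r = p = np.nan
    ba = (np.nan, np.nan, np.nan)
    if overall_true is not None and overall_pred is not None:
        overall_true = np.asarray(overall_true, float)
        overall_pred = np.asarray(overall_pred, float)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            icc = icc_2_1(np.column_stack([overall_true, overall_pred]))
        if caught:
            flags.extend(str(c.message) for c in caught)
        r, _, p = pearson_r(overall_true, overall_pred)
        ba = bland_altman(overall_pred, overall_true)

    report = EvalReport(
        n_lobes=len(y_true),
        n_exams=len(np.unique(exam_ids)),
        per_class=per_class,
        macro_auroc=macro_auroc(y_true, probs),
        macro_cwce=macro_cwce(y_true, probs),
        kappa_qw=quadratic_weighted_kappa(y_true, y_pred),
        gwet_ac2=gwet_ac2(y_true, y_pred),
        icc_2_1=icc,
        pearson_r=r,
        pearson_p=p,
        bland_altman=ba,
        flags=flags,
    )
    if bootstrap > 0:
        uniq = np.unique(exam_ids)
        clusters = [
            (y_true[exam_ids == e], y_pred[exam_ids == e], probs[exam_ids == e])
            for e in uniq
        ]

        def _stat(fn):
            def inner(cs):
                yt = np.concatenate([c[0] for c in cs])
                yp = np.concatenate([c[1] for c in cs])
                return fn(yt, yp)
            return inner

        report.ci["kappa_qw"] = _interval(
            bootstrap_ci(_stat(quadratic_weighted_kappa), clusters, bootstrap, seed)
        )
        report.ci["gwet_ac2"] = _interval(
            bootstrap_ci(_stat(gwet_ac2), clusters, bootstrap, seed)
        )

        def _macro_auc(cs):
            yt = np.concatenate([c[0] for c in cs])
            pr = np.concatenate([c[2] for c in cs])
            return macro_auroc(yt, pr)

        report.ci["macro_auroc"] = _interval(
            bootstrap_ci(_macro_auc, clusters, bootstrap, seed)
        )
    return report


def _interval(bi: BootstrapInterval) -> tuple[float, float]:
    return (bi.low, bi.high)
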