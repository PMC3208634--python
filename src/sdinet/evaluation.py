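"""Evaluation statistics: group comparisons, ROC/AUC, 5x2 cross-validation.

Metric conventions follow the study design this pipeline replicates:

* *Overall accuracy* is the mean of sensitivity and specificity (balanced
  accuracy) -- the convention is forced by the published fold arithmetic
  (e.g. SN 72.5, SP 78.5 -> accuracy 75.5).  The raw proportion correct is
  kept as a secondary field.
* ROC curves are empirical (non-parametric), the AUC is the trapezoid area,
  which equals the Mann-Whitney probability that a random case outscores a
  random control with ties counting one half.
* Correlated AUCs are compared with the Hanley-McNeil z-test; for paired
  scores the correlation term is the average of the within-case and
  within-control Pearson correlations of the two score vectors.
* Group comparisons gate on a Kolmogorov-Smirnov normality check per group:
  t-test if both groups look normal, Mann-Whitney otherwise; 2x2 factors
  use the continuity-corrected (Yates) chi-square.
* The 5x2 cross-validation protocol: five seeded stratified halvings, each
  half used once for training and once for testing with frozen weights,
  giving ten fold evaluations whose arithmetic averages are the headline
  numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away, substream


class UndefinedMetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass
class FoldMetrics:
    fold_id: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent, (SN + SP) / 2
    raw_accuracy: float  # percent, proportion correct

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(y_true, y_pred, fold_id: str = "") -> FoldMetrics:
    """Sensitivity, specificity and overall (balanced) accuracy in percent."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("both classes must be present in y_true")
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    return FoldMetrics(
        fold_id=fold_id,
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sn,
        specificity=sp,
        accuracy=(sn + sp) / 2.0,
        raw_accuracy=100.0 * (tp + tn) / y_true.size,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels) -> RocCurve:
    """Empirical ROC over all score thresholds; trapezoid AUC (ties -> 1/2)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("both classes must be present")
    if np.ptp(scores) == 0.0:
        warnings.warn("constant scores: ROC is the diagonal, AUC 0.5", stacklevel=2)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n1, 1.0]
    fpr = np.r_[0.0, fps / n0, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=fpr, tpr=tpr, auc=auc, n_cases=n1, n_controls=n0,
        scores=scores, labels=labels,
    )


def hanley_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Standard error of an empirical AUC (Hanley-McNeil approximation)."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a)
        + (n_cases - 1) * (q1 - a * a)
        + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def compare_auc(roc1: RocCurve, roc2: RocCurve, paired: bool = True) -> tuple[float, float]:
    """z-test for a difference between two (possibly correlated) AUCs.

    In paired mode the two score vectors must be over the same sample; the
    correlation term is estimated as the mean of the Pearson correlations
    between the score vectors within cases and within controls.
    """
    se1 = hanley_se(roc1.auc, roc1.n_cases, roc1.n_controls)
    se2 = hanley_se(roc2.auc, roc2.n_cases, roc2.n_controls)
    r = 0.0
    if paired:
        if (
            roc1.scores is None or roc2.scores is None
            or roc1.labels is None or roc2.labels is None
            or roc1.labels.shape != roc2.labels.shape
            or not np.array_equal(roc1.labels, roc2.labels)
        ):
            raise ValueError("paired comparison requires scores over the same sample")
        y = roc1.labels
        rs = []
        for cls in (1, 0):
            a, b = roc1.scores[y == cls], roc2.scores[y == cls]
            if np.ptp(a) > 0 and np.ptp(b) > 0:
                rs.append(float(stats.pearsonr(a, b)[0]))
        r = float(np.mean(rs)) if rs else 0.0
    var = se1 * se1 + se2 * se2 - 2.0 * r * se1 * se2
    if var <= 0.0:
        return 0.0, 1.0
    z = (roc1.auc - roc2.auc) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# 5x2 cross-validation


@dataclass
class CrossValReport:
    folds: list[FoldMetrics]
    avg_sensitivity: float
    avg_specificity: float
    avg_accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    n_variables: int
    scores: np.ndarray  # pooled out-of-sample scores, shape (n_repeats, n)
    labels: np.ndarray  # (n,)
    partitions: np.ndarray  # (n_repeats, n) bool, True = half 'a'
    seed: int = 0

    def fold_table(self) -> pd.DataFrame:
        rows = [
            {
                "Testing on subset": f.fold_id,
                "Sensitivity (%)": round_half_away(f.sensitivity, 1),
                "Specificity (%)": round_half_away(f.specificity, 1),
                "Overall accuracy (%)": round_half_away(f.accuracy, 1),
            }
            for f in self.folds
        ]
        rows.append(
            {
                "Testing on subset": "Average",
                "Sensitivity (%)": round_half_away(self.avg_sensitivity, 1),
                "Specificity (%)": round_half_away(self.avg_specificity, 1),
                "Overall accuracy (%)": round_half_away(self.avg_accuracy, 1),
            }
        )
        return pd.DataFrame(rows)


def stratified_half_split(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random halving preserving the case/control ratio; True = half 'a'."""
    labels = np.asarray(labels, dtype=int).ravel()
    mask = np.zeros(labels.size, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise UndefinedMetricError(
                f"class {cls} has fewer than 2 records; cannot halve with stratification"
            )
        rng.shuffle(idx)
        mask[idx[: idx.size // 2 + (idx.size % 2) * int(rng.random() < 0.5)]] = True
    return mask


def five_by_two_cv(
    X: pd.DataFrame,
    y,
    trainer,
    seed: int = 0,
    n_repeats: int = 5,
    partitions: np.ndarray | None = None,
) -> CrossValReport:
    """The 5x2 cross-validation protocol.

    ``trainer(X_train, y_train, seed)`` must return a scoring callable
    ``score(X_test) -> array of scores in [0, 1]`` (the frozen model).  Each
    repeat halves the sample with stratification, trains on half a / tests
    on half b, then reverses the roles; ten folds in total.  A fixed
    ``partitions`` array may be supplied so a second arm is evaluated on
    identical splits.
    """
    y = np.asarray(y, dtype=int).ravel()
    n = y.size
    if n < 20:
        raise ValueError("5x2 cross-validation needs at least 20 records")
    if partitions is None:
        rng = substream(seed, "five_by_two")
        partitions = np.stack(
            [stratified_half_split(y, rng) for _ in range(n_repeats)]
        )
    folds: list[FoldMetrics] = []
    all_scores = np.empty((n_repeats, n), dtype=float)
    for rep in range(n_repeats):
        half_a = partitions[rep]
        for tag, train_mask in (("a", half_a), ("b", ~half_a)):
            test_mask = ~train_mask
            fold_seed = (seed * 1000 + rep * 10 + (0 if tag == "a" else 1)) & 0x7FFFFFFF
            score = trainer(X.loc[train_mask], y[train_mask], fold_seed)
            s = np.asarray(score(X.loc[test_mask]), dtype=float)
            all_scores[rep, test_mask] = s
            from .mlp import classify

            folds.append(
                confusion_metrics(
                    y[test_mask], classify(s), fold_id=f"{rep + 1}{tag}"
                )
            )
    aucs = [roc_auc(all_scores[rep], y).auc for rep in range(n_repeats)]
    auc = float(np.mean(aucs))
    se = hanley_se(auc, int(y.sum()), int((1 - y).sum()))
    report = CrossValReport(
        folds=folds,
        avg_sensitivity=float(np.mean([f.sensitivity for f in folds])),
        avg_specificity=float(np.mean([f.specificity for f in folds])),
        avg_accuracy=float(np.mean([f.accuracy for f in folds])),
        auc=auc,
        auc_ci=(auc - 1.959963984540054 * se, auc + 1.959963984540054 * se),
        n_variables=X.shape[1],
        scores=all_scores,
        labels=y,
        partitions=np.asarray(partitions, dtype=bool),
        seed=seed,
    )
    return report


def fold_homogeneity_chi2(folds: list[FoldMetrics]) -> tuple[float, float]:
    """Goodness-of-fit chi-square of per-fold correct counts vs pooled rate.

    Observed correct/incorrect per fold against expectations from the pooled
    correct rate; df = folds - 1.  A non-significant value indicates the ten
    cross-validation experiments behave homogeneously.
    """
    if len(folds) < 2:
        raise ValueError("need at least two folds")
    n_i = np.array([f.tp + f.fn + f.tn + f.fp for f in folds], dtype=float)
    o_i = np.array([f.tp + f.tn for f in folds], dtype=float)
    pooled = o_i.sum() / n_i.sum()
    e_correct = n_i * pooled
    e_wrong = n_i * (1.0 - pooled)
    if np.any(e_correct < 1e-9) or np.any(e_wrong < 1e-9):
        raise ValueError("zero expected count; pool folds before testing")
    chi2 = float(
        np.sum((o_i - e_correct) ** 2 / e_correct)
        + np.sum(((n_i - o_i) - e_wrong) ** 2 / e_wrong)
    )
    p = float(stats.chi2.sf(chi2, df=len(folds) - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# group comparisons and correlation


def ks_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov normality check (standardised, estimated moments)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or x.size < 3:
        return False
    return stats.kstest((x - x.mean()) / sd, "norm").pvalue >= alpha


def yates_chi2(table, correction: bool | str = True) -> tuple[float, float]:
    """Chi-square test on a 2x2 (or RxC) table.

    ``correction=True`` applies the Yates continuity correction (default for
    2x2); ``'fisher'`` switches to Fisher's exact test on 2x2 tables.
    """
    table = np.asarray(table, dtype=float)
    if correction == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test needs a 2x2 table")
        odds, p = stats.fisher_exact(table)
        return float("nan"), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=bool(correction))
    return float(chi2), float(p)


def two_group_pvalue(x0: np.ndarray, x1: np.ndarray) -> float:
    """Bivariate case/control p-value for a single variable.

    Dichotomous variables (<= 2 distinct values) get the continuity-corrected
    chi-square; continuous ones the KS-gated t-test / Mann-Whitney.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    values = np.unique(np.r_[x0, x1])
    if values.size == 1:
        return 1.0
    if values.size <= 2:
        table = np.array(
            [[np.sum(x0 == values[1]), np.sum(x0 == values[0])],
             [np.sum(x1 == values[1]), np.sum(x1 == values[0])]]
        )
        return yates_chi2(table)[1]
    if ks_normal(x0) and ks_normal(x1):
        return float(stats.ttest_ind(x0, x1, equal_var=True).pvalue)
    return float(stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)


def group_compare(
    table: pd.DataFrame,
    groups,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group clinical-characteristics comparison (cohort-table style).

    Continuous variables are summarised mean+/-SD when both groups pass the
    KS normality check (then compared by t-test) and median (range) with
    Mann-Whitney otherwise; dichotomous variables as n (%) with the
    continuity-corrected chi-square.
    """
    groups = np.asarray(groups).ravel()
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("group_compare needs exactly two groups")
    g0, g1 = (groups == uniq[0]), (groups == uniq[1])
    if g0.sum() == 0 or g1.sum() == 0:
        raise ValueError("both groups must be non-empty")
    continuous = list(continuous) if continuous is not None else [
        c for c in table.columns if table[c].nunique() > 2
    ]
    rows = []
    for col in table.columns:
        x0 = table.loc[g0, col].to_numpy(dtype=float)
        x1 = table.loc[g1, col].to_numpy(dtype=float)
        if np.ptp(np.r_[x0, x1]) == 0:
            rows.append({"variable": col, "group0": "constant", "group1": "constant",
                         "test": "skipped", "p": np.nan})
            continue
        if col in continuous:
            normal = ks_normal(x0) and ks_normal(x1)
            if normal:
                summ = [f"{v.mean():.1f}±{v.std(ddof=1):.1f}" for v in (x0, x1)]
                p = float(stats.ttest_ind(x0, x1, equal_var=True).pvalue)
                test = "t-test"
            else:
                summ = [
                    f"{np.median(v):.1f} ({v.min():.0f}–{v.max():.0f})" for v in (x0, x1)
                ]
                p = float(stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)
                test = "Mann-Whitney"
        else:
            n_yes = [int(v.sum()) for v in (x0, x1)]
            summ = [
                f"{k} ({100.0 * k / v.size:.1f})" for k, v in zip(n_yes, (x0, x1))
            ]
            tab = np.array(
                [[n_yes[0], x0.size - n_yes[0]], [n_yes[1], x1.size - n_yes[1]]]
            )
            p = yates_chi2(tab)[1]
            test = "chi-square (Yates)"
        rows.append(
            {"variable": col, "group0": summ[0], "group1": summ[1],
             "test": test, "p": round_half_away(p, 3)}
        )
    return pd.DataFrame(rows)


def correlate(x, y, method: str = "auto") -> tuple[float, float]:
    """Pearson or Spearman correlation, gated on KS normality of both vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    if method == "auto":
        method = "pearson" if (ks_normal(x) and ks_normal(y)) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'auto', 'pearson' or 'spearman'")
    return float(r), float(p)
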