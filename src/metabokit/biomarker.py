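"""ROC-based biomarker analysis.

Covers classical single-feature ROC curves (empirical curve, tie-corrected
AUC, stratified-bootstrap confidence intervals, partial AUC, optimal
cutoffs), the multivariate ROC explorer driven by Monte-Carlo
cross-validation (repeated stratified 2/3 : 1/3 splits with feature ranking
on the training split only), manual model evaluation with an optional
holdout set, and permutation significance testing.

The AUC is computed by tie-corrected pair counting (ties count 1/2), which
coincides with the trapezoidal area under the empirical curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .core_data import DataTable, DataTableError

CLASSIFIERS = ("plsda", "linear_svm", "random_forest")
DEFAULT_FEATURE_COUNTS = (2, 3, 5, 10, 20, 35, 60, 100)
TEST_FRACTION = 1.0 / 3.0
RF_TREES = 100


@dataclass
class RocCurve:
    thresholds: np.ndarray            # descending cutoffs (+inf first)
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    direction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.one_minus_specificity = np.asarray(self.one_minus_specificity,
                                                dtype=float)


@dataclass
class RocModelResult:
    classifier: str
    n_features_used: int
    mean_curve: RocCurve
    auc: float                        # mean of per-iteration AUCs
    auc_ci: tuple
    per_iteration_auc: list
    selection_frequency: dict
    accuracy: float
    permutation_p: float | None = None
    holdout_curve: RocCurve | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Classical ROC
# ---------------------------------------------------------------------------

def _binary_labels(labels, positive) -> np.ndarray:
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise DataTableError("both classes must be present")
    return y


def pair_count_auc(scores, y) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels, positive, flip: bool = True) -> RocCurve:
    """Empirical ROC over all distinct score thresholds.

    A sample is called positive when its score is >= the threshold.  If the
    raw AUC is below 0.5 and ``flip`` is enabled, the reversed score is used
    and the flip is recorded in ``direction`` (never silent).
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels, positive)
    auc = pair_count_auc(scores, y)
    flipped = False
    if flip and auc < 0.5:
        scores = -scores
        auc = pair_count_auc(scores, y)
        flipped = True
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    distinct = np.r_[True, np.diff(ss) != 0]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    idx = np.where(np.r_[distinct[1:], True])[0]   # last index of each tie block
    n1, n0 = tps[-1], fps[-1]
    sens = np.r_[0.0, tps[idx] / n1]
    fpr = np.r_[0.0, fps[idx] / n0]
    thresholds = np.r_[np.inf, ss[idx]]
    return RocCurve(thresholds=thresholds, sensitivity=sens,
                    one_minus_specificity=fpr, auc=auc,
                    direction={"positive": positive,
                               "higher_scores_positive": not flipped,
                               "flipped": flipped})


def _stratified_boot_auc(pos, neg, n_boot, rng) -> np.ndarray:
    """AUCs of class-stratified bootstrap resamples, vectorized."""
    n1, n0 = len(pos), len(neg)
    bpos = pos[rng.integers(0, n1, size=(n_boot, n1))]
    bneg = neg[rng.integers(0, n0, size=(n_boot, n0))]
    both = np.concatenate([bpos, bneg], axis=1)
    ranks = rankdata(both, axis=1)
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


def auc_ci(scores, labels, positive, level: float = 0.95,
           n_boot: int = 2000, seed: int = 0) -> tuple:
    """Percentile bootstrap confidence interval for the AUC.

    Resampling is stratified within each class so every resample retains
    both classes.
    """
    if not 0 < level < 1:
        raise DataTableError("level must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels, positive)
    if y.sum() < 3 or (len(y) - y.sum()) < 3:
        raise DataTableError("both classes need at least 3 samples")
    rng = np.random.default_rng(seed)
    aucs = _stratified_boot_auc(scores[y == 1], scores[y == 0], n_boot, rng)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


def partial_auc(curve: RocCurve, fpr_lo: float = 0.0, fpr_hi: float = 1.0,
                standardized: bool = False) -> float:
    """Trapezoidal ROC area restricted to a false-positive-rate window,
    with linear interpolation at the window bounds."""
    if not 0 <= fpr_lo < fpr_hi <= 1:
        raise DataTableError("need 0 <= fpr_lo < fpr_hi <= 1")
    x = curve.one_minus_specificity
    y = curve.sensitivity
    area = 0.0
    for i in range(len(x) - 1):
        x0, x1 = x[i], x[i + 1]
        if x1 <= fpr_lo or x0 >= fpr_hi or x1 == x0:
            continue
        lo = max(x0, fpr_lo)
        hi = min(x1, fpr_hi)
        y_lo = y[i] + (y[i + 1] - y[i]) * (lo - x0) / (x1 - x0)
        y_hi = y[i] + (y[i + 1] - y[i]) * (hi - x0) / (x1 - x0)
        area += 0.5 * (y_lo + y_hi) * (hi - lo)
    if standardized:
        area /= (fpr_hi - fpr_lo)
    return float(area)


def optimal_cutoff(curve: RocCurve, criterion: str = "youden") -> dict:
    """Best operating point: Youden's J or closest-to-top-left.

    Ties are broken toward higher specificity.  A curve whose J is 0
    everywhere (e.g. all-tied scores) is flagged degenerate.
    """
    sens = curve.sensitivity
    spec = 1 - curve.one_minus_specificity
    if criterion == "youden":
        objective = sens + spec - 1
        best = max(range(len(sens)), key=lambda i: (objective[i], spec[i]))
        degenerate = bool(np.max(objective) <= 0)
    elif criterion == "closest_topleft":
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        best = min(range(len(sens)), key=lambda i: (d2[i], -spec[i]))
        degenerate = False
    else:
        raise DataTableError(f"unknown criterion {criterion!r}")
    return {"threshold": float(curve.thresholds[best]),
            "sensitivity": float(sens[best]), "specificity": float(spec[best]),
            "degenerate": degenerate}


# ---------------------------------------------------------------------------
# Classifiers for the multivariate explorer
# ---------------------------------------------------------------------------

def _fit_score(classifier: str, x_train, y_train, x_test, seed: int):
    """Fit one classifier and return continuous test scores plus hard
    predictions.  Scores: PLS-DA regression output for the positive class,
    SVM signed margin, random-forest positive-class vote fraction."""
    if classifier == "plsda":
        n_comp = min(2, x_train.shape[1], np.linalg.matrix_rank(
            x_train - x_train.mean(axis=0)))
        n_comp = max(n_comp, 1)
        model = PLSRegression(n_components=n_comp, scale=False)
        model.fit(x_train, y_train.astype(float))
        score = model.predict(x_test).ravel()
        pred = (score >= 0.5).astype(int)
    elif classifier == "linear_svm":
        model = SVC(kernel="linear", random_state=seed)
        model.fit(x_train, y_train)
        score = model.decision_function(x_test)
        pred = (score >= 0).astype(int)
    elif classifier == "random_forest":
        model = RandomForestClassifier(n_estimators=RF_TREES, random_state=seed)
        model.fit(x_train, y_train)
        score = model.predict_proba(x_test)[:, list(model.classes_).index(1)]
        pred = (score >= 0.5).astype(int)
    else:
        raise DataTableError(f"unknown classifier {classifier!r}")
    return np.asarray(score, dtype=float), pred


def _welch_t_abs(x, y01) -> np.ndarray:
    """|Welch t| per feature; the training-split feature-ranking statistic."""
    a = x[y01 == 0]
    b = x[y01 == 1]
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b.mean(axis=0) - a.mean(axis=0)) / denom
    return np.abs(np.where(np.isfinite(t), t, 0.0))


def _stratified_split(y01: np.ndarray, rng) -> tuple:
    """2/3 train : 1/3 test split preserving class proportions."""
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.where(y01 == cls)[0]
        if len(idx) < 6:
            raise DataTableError(
                "each class needs at least 6 samples for a 2/3:1/3 split")
        perm = rng.permutation(idx)
        n_test = max(1, int(round(len(idx) * TEST_FRACTION)))
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _percentile_ci(values, level: float = 0.95) -> tuple:
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return float(lo), float(hi)


def _binary_table(dt: DataTable, positive):
    levels = dt.group_levels()
    if len(levels) != 2:
        raise DataTableError("biomarker analysis requires exactly 2 groups")
    if positive not in levels:
        raise DataTableError(f"positive label {positive!r} not found")
    x = dt.values.to_numpy(dtype=float)
    y01 = (dt.group == positive).to_numpy().astype(int)
    return x, y01


def mccv_explore(dt: DataTable, positive, classifier: str = "plsda",
                 feature_counts=None, n_iter: int = 50,
                 seed: int = 0) -> list[RocModelResult]:
    """Automatic biomarker-model explorer.

    Repeats ``n_iter`` stratified Monte-Carlo splits (2/3 train, 1/3 test);
    on each split, features are ranked by the training-split |Welch t| only,
    and for every candidate panel size k the classifier is fit on the top-k
    training features and scored on the held-out third.  Per panel size the
    held-out scores are pooled into a mean ROC curve; the confidence band is
    the empirical 2.5/97.5 percentile range of the per-iteration AUCs, and
    ``selection_frequency`` is the fraction of iterations in which each
    feature entered the panel.  Deterministic given ``seed``.
    """
    x, y01 = _binary_table(dt, positive)
    feature_ids = np.asarray(dt.feature_ids, dtype=object)
    m = x.shape[1]
    if feature_counts is None:
        feature_counts = [k for k in DEFAULT_FEATURE_COUNTS if k <= m] or [m]
    else:
        kept = [k for k in feature_counts if k <= m]
        if len(kept) < len(feature_counts):
            kept = kept or [m]
        feature_counts = kept
    pooled = {k: ([], []) for k in feature_counts}       # scores, labels
    per_iter_auc = {k: [] for k in feature_counts}
    sel_counts = {k: np.zeros(m) for k in feature_counts}
    correct = {k: 0 for k in feature_counts}
    total = {k: 0 for k in feature_counts}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        clf_seed = int(rng.integers(0, 2 ** 31 - 1))
        train, test = _stratified_split(y01, rng)
        ranking = np.lexsort((feature_ids.astype(str),
                              -_welch_t_abs(x[train], y01[train])))
        for k in feature_counts:
            cols = ranking[:k]
            score, pred = _fit_score(classifier, x[np.ix_(train, cols)],
                                     y01[train], x[np.ix_(test, cols)],
                                     clf_seed)
            pooled[k][0].extend(score)
            pooled[k][1].extend(y01[test])
            per_iter_auc[k].append(pair_count_auc(score, y01[test]))
            sel_counts[k][cols] += 1
            correct[k] += int((pred == y01[test]).sum())
            total[k] += len(test)
    results = []
    for k in feature_counts:
        scores, labels = map(np.asarray, pooled[k])
        curve = roc_curve(scores, labels, positive=1, flip=False)
        freq = {feature_ids[j]: sel_counts[k][j] / n_iter
                for j in np.where(sel_counts[k] > 0)[0]}
        aucs = per_iter_auc[k]
        results.append(RocModelResult(
            classifier=classifier, n_features_used=k, mean_curve=curve,
            auc=float(np.mean(aucs)), auc_ci=_percentile_ci(aucs),
            per_iteration_auc=list(map(float, aucs)),
            selection_frequency=freq,
            accuracy=correct[k] / total[k], seed=seed))
    return results


def evaluate_model(dt: DataTable, positive, features, classifier: str = "plsda",
                   holdout_ids=(), n_iter: int = 50, seed: int = 0) -> RocModelResult:
    """Evaluate a manually chosen biomarker panel.

    Runs MCCV on the non-holdout samples restricted to ``features``.  If a
    holdout set is given, the model refit on all non-holdout samples is
    applied to the holdout samples and their ROC is reported separately.
    """
    missing = [f for f in features if f not in set(dt.feature_ids)]
    if missing:
        raise DataTableError(f"unknown features: {missing}")
    holdout_ids = list(holdout_ids)
    unknown = [s for s in holdout_ids if s not in set(dt.sample_ids)]
    if unknown:
        raise DataTableError(f"unknown holdout samples: {unknown}")
    work_samples = [s for s in dt.sample_ids if s not in set(holdout_ids)]
    sub = DataTable(values=dt.values.loc[work_samples, list(features)],
                    group=dt.group.loc[work_samples], log=list(dt.log))
    if len(sub.group_levels()) != 2:
        raise DataTableError("holdout removes an entire class")
    x, y01 = _binary_table(sub, positive)
    m = x.shape[1]
    [result] = mccv_explore(sub, positive, classifier=classifier,
                            feature_counts=[m], n_iter=n_iter, seed=seed)
    result = RocModelResult(**{**vars(result)})
    if holdout_ids:
        hx = dt.values.loc[holdout_ids, list(features)].to_numpy(dtype=float)
        hy = (dt.group.loc[holdout_ids] == positive).to_numpy().astype(int)
        if hy.sum() == 0 or hy.sum() == len(hy):
            raise DataTableError("holdout must contain both classes")
        clf_seed = int(np.random.default_rng(
            np.random.SeedSequence(seed)).integers(0, 2 ** 31 - 1))
        score, _ = _fit_score(classifier, x, y01, hx, clf_seed)
        result.holdout_curve = roc_curve(score, hy, positive=1, flip=False)
    return result


def permutation_test(dt: DataTable, positive, features, classifier: str = "plsda",
                     n_perm: int = 99, n_iter: int = 20, seed: int = 0) -> float:
    """Permutation significance of a biomarker panel.

    The statistic is the mean MCCV AUC; group labels are permuted ``n_perm``
    times and the whole cross-validation pipeline re-run each time.
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise DataTableError("n_perm must be at least 19")

    def _mean_auc(table, sub_seed):
        [res] = mccv_explore(table, positive, classifier=classifier,
                             feature_counts=[len(features)], n_iter=n_iter,
                             seed=sub_seed)
        return res.auc

    sub = DataTable(values=dt.values[list(features)], group=dt.group,
                    log=list(dt.log))
    observed = _mean_auc(sub, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB10)))
    exceed = 0
    for b in range(n_perm):
        perm = sub.copy()
        shuffled = perm.group.to_numpy().copy()
        rng.shuffle(shuffled)
        perm.group = type(sub.group)(shuffled, index=sub.group.index)
        if _mean_auc(perm, seed) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
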