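"""Per-feature univariate statistics: fold change, t-tests, one-way ANOVA,
FDR adjustment, volcano selection, and sortable result tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import DataTable, DataTableError, MIN_GROUP_SIZE

COLUMNS = ["feature", "effect", "statistic", "p_value", "fdr", "rank"]


@dataclass
class TestResultTable:
    """Per-feature effect estimates and test results.

    ``rank`` is the 1-based order by ascending p-value with ties broken by
    feature id; when p-values are absent (pure fold-change tables) the rank
    orders by descending absolute effect instead.
    """

    feature_ids: list
    effect: np.ndarray
    statistic: np.ndarray | None = None
    p_value: np.ndarray | None = None
    fdr: np.ndarray | None = None
    rank: np.ndarray = field(default=None)
    posthoc: dict | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rank is None:
            if self.p_value is not None:
                key = list(zip(self.p_value, map(str, self.feature_ids)))
            else:
                key = list(zip(-np.abs(self.effect), map(str, self.feature_ids)))
            order = sorted(range(len(key)), key=lambda i: key[i])
            rank = np.empty(len(key), dtype=int)
            rank[order] = np.arange(1, len(key) + 1)
            self.rank = rank

    def to_frame(self) -> pd.DataFrame:
        n = len(self.feature_ids)
        absent = np.full(n, np.nan)
        return pd.DataFrame({
            "feature": self.feature_ids,
            "effect": self.effect,
            "statistic": absent if self.statistic is None else self.statistic,
            "p_value": absent if self.p_value is None else self.p_value,
            "fdr": absent if self.fdr is None else self.fdr,
            "rank": self.rank,
        }, columns=COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _group_matrix(dt: DataTable, label) -> np.ndarray:
    mask = (dt.group == label).to_numpy()
    if not mask.any():
        raise DataTableError(f"group {label!r} not found")
    return dt.values.to_numpy(dtype=float)[mask]


def fold_change(dt: DataTable, group_a, group_b, log_base2: bool = True) -> TestResultTable:
    """Between-group mean ratio per feature, optionally on the log2 scale.

    Meant for pre-scaling positive data; scaling destroys the ratio
    interpretation.
    """
    a = _group_matrix(dt, group_a)
    b = _group_matrix(dt, group_b)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    if log_base2:
        if (mean_a <= 0).any() or (mean_b <= 0).any():
            raise DataTableError("log2 fold change requires positive group means")
        effect = np.log2(mean_b / mean_a)
    else:
        effect = mean_b / mean_a
    return TestResultTable(feature_ids=dt.feature_ids, effect=effect)


def t_test(dt: DataTable, group_a, group_b, equal_var: bool = False,
           paired: bool = False) -> TestResultTable:
    """Two-sample t-test per feature (Welch by default), with BH-adjusted FDR.

    Features with zero variance in both groups get statistic 0 and p = 1
    with a warning rather than a failure.
    """
    a = _group_matrix(dt, group_a)
    b = _group_matrix(dt, group_b)
    if a.shape[0] < MIN_GROUP_SIZE or b.shape[0] < MIN_GROUP_SIZE:
        raise DataTableError("both groups need at least 3 samples")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise DataTableError("paired test requires equal group sizes")
        res = stats.ttest_rel(b, a, axis=0)
    else:
        res = stats.ttest_ind(b, a, axis=0, equal_var=equal_var)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    warnings = []
    degenerate = np.isnan(stat)
    if degenerate.any():
        for fid in np.asarray(dt.feature_ids)[degenerate]:
            warnings.append(f"feature {fid!r}: zero variance in both groups; p set to 1")
        stat = np.where(degenerate, 0.0, stat)
        p = np.where(degenerate, 1.0, p)
    effect = b.mean(axis=0) - a.mean(axis=0)
    return TestResultTable(feature_ids=dt.feature_ids, effect=effect,
                           statistic=stat, p_value=p, fdr=adjust_bh(p),
                           warnings=warnings)


def anova(dt: DataTable, posthoc: bool = False, alpha: float = 0.05) -> TestResultTable:
    """One-way ANOVA per feature across all group levels.

    With exactly two levels this defers to the pooled-variance t-test (whose
    squared statistic equals F).  Optional Tukey HSD post-hoc comparisons are
    reported for features significant at ``alpha`` (FDR-adjusted).
    """
    levels = dt.group_levels()
    if len(levels) < 2:
        raise DataTableError("ANOVA needs at least 2 groups")
    groups = [_group_matrix(dt, g) for g in levels]
    if any(g.shape[0] < MIN_GROUP_SIZE for g in groups):
        raise DataTableError("every group needs at least 3 samples")
    if len(levels) == 2:
        tt = t_test(dt, levels[0], levels[1], equal_var=True)
        return TestResultTable(feature_ids=tt.feature_ids, effect=tt.effect,
                               statistic=tt.statistic ** 2, p_value=tt.p_value,
                               fdr=tt.fdr, warnings=tt.warnings)
    res = stats.f_oneway(*groups, axis=0)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(stat)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, p)
    grand = np.vstack(groups).mean(axis=0)
    effect = np.max([g.mean(axis=0) - grand for g in groups], axis=0)
    fdr = adjust_bh(p)
    ph = None
    if posthoc:
        ph = {}
        for idx in np.where(fdr <= alpha)[0]:
            hsd = stats.tukey_hsd(*[g[:, idx] for g in groups])
            pairs = {}
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    pairs[f"{levels[i]}-{levels[j]}"] = float(hsd.pvalue[i, j])
            ph[dt.feature_ids[idx]] = pairs
    return TestResultTable(feature_ids=dt.feature_ids, effect=effect,
                           statistic=stat, p_value=p, fdr=fdr, posthoc=ph)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_select(fc: TestResultTable, tt: TestResultTable,
                   fc_threshold: float = 2.0, p_threshold: float = 0.05,
                   use_fdr: bool = False):
    """Select features by joint fold-change and significance thresholds.

    Returns ``(selected_ids, coords)`` where ``coords`` is the volcano-plot
    coordinate table (x = log2 fold change, y = -log10 p).
    """
    if list(fc.feature_ids) != list(tt.feature_ids):
        raise DataTableError("fold-change and test tables have mismatched features")
    log2fc = np.asarray(fc.effect, dtype=float)
    p = np.asarray(tt.fdr if use_fdr else tt.p_value, dtype=float)
    with np.errstate(divide="ignore"):
        y = -np.log10(p)
    coords = pd.DataFrame({"feature": fc.feature_ids, "log2_fc": log2fc,
                           "neg_log10_p": y})
    mask = (np.abs(log2fc) >= np.log2(fc_threshold)) & (p <= p_threshold)
    selected = [f for f, m in zip(fc.feature_ids, mask) if m]
    return selected, coords


def rank_table(tr: TestResultTable, sort_key: str = "p_value",
               search: str | None = None) -> pd.DataFrame:
    """Sorted, optionally substring-filtered view of a result table."""
    frame = tr.to_frame()
    if sort_key not in frame.columns:
        raise KeyError(f"unknown column {sort_key!r}")
    view = frame.sort_values(sort_key, kind="stable")
    if search:
        view = view[view["feature"].astype(str).str.contains(search, case=False,
                                                             regex=False)]
    return view.reset_index(drop=True)
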