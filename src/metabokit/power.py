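"""Pilot-data power analysis and sample-size estimation for two-group
high-dimensional studies.

The full vector of per-feature two-sample t statistics from a pilot study is
deconvolved into a mixture of a central t (the null fraction pi0) and
noncentral t components on a grid of standardized effect sizes.  Average
power — the expected fraction of true effects detected — is then predicted
for candidate per-group sample sizes under a false-discovery-rate criterion:
for each n the two-sided rejection threshold solves the marginal FDR
operating equation

    pi0 * P0(|T| > u) / (pi0 * P0(|T| > u) + sum_j w_j * Pj(|T| > u)) = alpha

with P0 central and Pj noncentral t at the rescaled noncentrality, and
average power is the weighted alternative tail mass at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import DataTable, DataTableError

#: Default candidate per-group sample sizes: log-spaced over 3..1000.
DEFAULT_SAMPLE_SIZES = (3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50, 63,
                        80, 100, 126, 159, 200, 252, 317, 400, 504, 635,
                        800, 1000)
#: Default noncentrality grid: symmetric, +-GRID_MAX in steps of GRID_STEP,
#: zero excluded (zero belongs to the null component).
GRID_MAX = 6.0
GRID_STEP = 0.5
N_BINS = 60
#: Noncentralities at or below this magnitude are nearly indistinguishable
#: from the central component; a small ridge penalty on their weights
#: resolves the degeneracy in favor of the null (see NEAR_NULL_RIDGE).
NEAR_NULL_CUT = 1.0
NEAR_NULL_RIDGE = 0.1


@dataclass
class PilotStatistics:
    statistics: np.ndarray
    p_values: np.ndarray
    n1: int
    n2: int

    @property
    def m(self) -> int:
        return len(self.statistics)

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


@dataclass
class EffectSizeDistribution:
    """Mixture estimate: null proportion pi0 plus weights on a grid of
    noncentrality values; ``effect_sizes`` are the corresponding
    standardized per-observation effects d."""

    pi0: float
    grid: np.ndarray          # noncentrality (pilot scale)
    weights: np.ndarray       # sums to 1 - pi0
    effect_sizes: np.ndarray  # d = ncp / sqrt(n1*n2/(n1+n2))
    n_pilot: tuple


@dataclass
class PowerCurve:
    sample_sizes: np.ndarray
    avg_power: np.ndarray
    fdr_level: float
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_per_group": self.sample_sizes,
                             "avg_power": self.avg_power,
                             "threshold": self.thresholds})


@dataclass
class DiagnosticReport:
    stat_normality: dict      # slope, intercept, max_central_deviation
    pvalue_hist: np.ndarray   # counts over 20 equal-width bins on [0,1]
    frac_small_p: float
    assumptions_ok: bool


# ---------------------------------------------------------------------------
# Pilot statistics
# ---------------------------------------------------------------------------

def pilot_statistics(dt: DataTable) -> PilotStatistics:
    """Equal-variance two-sample t statistics per feature.

    The pooled-variance test is used (rather than Welch) because the
    downstream power model is the noncentral t with n1+n2-2 degrees of
    freedom.
    """
    levels = dt.group_levels()
    if len(levels) != 2:
        raise DataTableError("power analysis requires exactly 2 groups")
    x = dt.values.to_numpy(dtype=float)
    mask_a = (dt.group == levels[0]).to_numpy()
    a, b = x[mask_a], x[~mask_a]
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise DataTableError("each group needs at least 3 samples")
    res = stats.ttest_ind(b, a, axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return PilotStatistics(statistics=t, p_values=p,
                           n1=int(a.shape[0]), n2=int(b.shape[0]))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def diagnose(ps: PilotStatistics, small_p: float = 0.05) -> DiagnosticReport:
    """Check the assumptions behind the mixture model.

    A QQ comparison of the statistics against the central t reference
    summarizes distributional shape (slope/intercept through the quartiles,
    maximum deviation over the central 80% of order statistics), and the
    fraction of small p-values indicates whether any signal is present.
    ``assumptions_ok`` requires both a well-behaved central region and a
    small-p fraction exceeding the null expectation by more than two
    binomial standard errors.
    """
    m = ps.m
    t_sorted = np.sort(ps.statistics)
    probs = (np.arange(1, m + 1) - 0.5) / m
    theo = stats.t.ppf(probs, df=ps.df)
    # fit the QQ line on the central half only: alternatives live in the
    # tails and would otherwise drag the line
    central = (probs >= 0.25) & (probs <= 0.75)
    slope, intercept = np.polyfit(theo[central], t_sorted[central], 1)
    max_dev = float(np.max(np.abs(t_sorted[central]
                                  - (intercept + slope * theo[central]))))
    hist, _ = np.histogram(ps.p_values, bins=20, range=(0.0, 1.0))
    frac = float(np.mean(ps.p_values < small_p))
    floor = small_p + 2 * np.sqrt(small_p * (1 - small_p) / m)
    ok = (max_dev < 0.5) and (frac > floor)
    return DiagnosticReport(
        stat_normality={"slope": float(slope), "intercept": float(intercept),
                        "max_central_deviation": max_dev},
        pvalue_hist=hist, frac_small_p=frac, assumptions_ok=bool(ok))


# ---------------------------------------------------------------------------
# Effect-size deconvolution
# ---------------------------------------------------------------------------

def _design_ncp(ps_n1: int, ps_n2: int) -> float:
    """Scale factor between standardized effect d and noncentrality."""
    return float(np.sqrt(ps_n1 * ps_n2 / (ps_n1 + ps_n2)))


def estimate_effect_sizes(ps: PilotStatistics, grid_max: float = GRID_MAX,
                          grid_step: float = GRID_STEP,
                          n_bins: int = N_BINS) -> EffectSizeDistribution:
    """Binned non-negative least-squares mixture deconvolution.

    The observed statistics are binned; bin probabilities are modeled as
    pi0 times the central t mass plus non-negative weights on noncentral t
    components over a symmetric noncentrality grid, with the total mass
    constrained to 1.  Solved by NNLS with the sum constraint imposed as a
    heavily weighted extra equation.

    Components with |noncentrality| <= 1 overlap the central t so strongly
    that the fit cannot tell them apart from null mass; a small ridge
    penalty on those weights breaks the tie toward the null, which keeps
    pi0 well calibrated and makes the power prediction conservative.
    """
    t = np.asarray(ps.statistics, dtype=float)
    m = len(t)
    grid = np.concatenate([np.arange(-grid_max, 0, grid_step),
                           np.arange(grid_step, grid_max + grid_step / 2,
                                     grid_step)])
    if n_bins <= len(grid) + 1:
        n_bins = 2 * (len(grid) + 1)   # coarse grids get more bins, not fewer
    lo, hi = t.min(), t.max()
    if hi <= lo:
        lo, hi = lo - 1.0, hi + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    observed, _ = np.histogram(t, bins=edges)
    obs_prob = observed / m
    cols = [np.diff(stats.t.cdf(edges, df=ps.df))]
    for ncp in grid:
        cols.append(np.diff(stats.nct.cdf(edges, df=ps.df, nc=ncp)))
    # nct.cdf underflows to nan far in the tails; those bins carry no mass
    a = np.clip(np.nan_to_num(np.column_stack(cols)), 0.0, 1.0)
    # sum-to-one as a penalty row (standard NNLS equality trick)
    lam = 1000.0
    a_aug = np.vstack([a, lam * np.ones(a.shape[1])])
    b_aug = np.concatenate([obs_prob, [lam]])
    near_null = np.abs(grid) <= NEAR_NULL_CUT + 1e-9
    if near_null.any():
        pen = np.zeros((int(near_null.sum()), a.shape[1]))
        pen[:, 1 + np.where(near_null)[0]] = (np.eye(int(near_null.sum()))
                                              * NEAR_NULL_RIDGE)
        a_aug = np.vstack([a_aug, pen])
        b_aug = np.concatenate([b_aug, np.zeros(pen.shape[0])])
    coef, _ = optimize.nnls(a_aug, b_aug)
    total = coef.sum()
    if total > 0:
        coef = coef / total
    pi0 = float(coef[0])
    weights = coef[1:]
    scale = _design_ncp(ps.n1, ps.n2)
    return EffectSizeDistribution(pi0=pi0, grid=grid, weights=weights,
                                  effect_sizes=grid / scale,
                                  n_pilot=(ps.n1, ps.n2))


# ---------------------------------------------------------------------------
# Power prediction
# ---------------------------------------------------------------------------

def _two_sided_tail_central(u: float, df: float) -> float:
    return 2.0 * stats.t.sf(u, df=df)


def _two_sided_tail_nct(u: float, df: float, ncp: np.ndarray) -> np.ndarray:
    tail = stats.nct.sf(u, df=df, nc=ncp) + stats.nct.cdf(-u, df=df, nc=ncp)
    # nct tail probabilities can underflow to nan deep in the tails; treat
    # nan as the saturated value implied by the sign of the noncentrality
    ncp = np.asarray(ncp, dtype=float)
    sat = (np.abs(ncp) > u).astype(float)
    return np.clip(np.where(np.isnan(tail), sat, tail), 0.0, 1.0)


def _fdr_threshold(pi0: float, weights: np.ndarray, ncp: np.ndarray,
                   df: float, alpha: float) -> float:
    """Two-sided threshold u solving the marginal FDR operating equation.

    When the equation has no root because the marginal FDR stays below
    alpha everywhere (pi0 near 0), the per-test alpha quantile is used.
    """
    w_alt = weights.sum()

    def fdr_minus_alpha(u):
        p0 = pi0 * _two_sided_tail_central(u, df)
        p1 = float(weights @ _two_sided_tail_nct(u, df, ncp))
        denom = p0 + p1
        if denom <= 0:
            return -alpha
        return p0 / denom - alpha

    fallback = float(stats.t.isf(alpha / 2, df=df))
    if w_alt <= 0:
        return fallback
    lo, hi = 1e-9, 60.0
    f_lo = fdr_minus_alpha(lo)
    if f_lo <= 0:
        return fallback
    f_hi = fdr_minus_alpha(hi)
    if f_hi > 0:
        # marginal FDR exceeds alpha at every attainable threshold: nothing
        # can be rejected under this criterion
        return np.inf
    return float(optimize.brentq(fdr_minus_alpha, lo, hi, xtol=1e-12,
                                 rtol=8.9e-16))


def power_curve(esd: EffectSizeDistribution, sample_sizes=DEFAULT_SAMPLE_SIZES,
                fdr_level: float = 0.05) -> PowerCurve:
    """Predicted average power over candidate per-group sample sizes.

    Each grid effect's noncentrality is rescaled to the candidate size
    (equal groups: ncp_n = d * sqrt(n/2)); the rejection threshold solves
    the FDR operating equation, and average power is the weighted
    noncentral tail mass beyond it, normalized by the alternative mass.
    """
    if not 0 < fdr_level < 1:
        raise DataTableError("fdr_level must be in (0, 1)")
    sizes = np.asarray(sorted(sample_sizes), dtype=int)
    powers = np.empty(len(sizes))
    thresholds = np.empty(len(sizes))
    w_alt = esd.weights.sum()
    for i, n in enumerate(sizes):
        df = 2 * n - 2
        ncp_n = esd.effect_sizes * np.sqrt(n / 2.0)
        u = _fdr_threshold(esd.pi0, esd.weights, ncp_n, df, fdr_level)
        thresholds[i] = u
        if w_alt <= 0:
            powers[i] = 0.0
        else:
            powers[i] = float(esd.weights
                              @ _two_sided_tail_nct(u, df, ncp_n)) / w_alt
    return PowerCurve(sample_sizes=sizes, avg_power=np.clip(powers, 0, 1),
                      fdr_level=fdr_level, thresholds=thresholds)


def min_sample_size(pc: PowerCurve, target_power: float = 0.8):
    """Smallest grid sample size reaching the target average power.

    Returns ``(n, achieved_power)``; ``n`` is None when the grid tops out
    below the target, with the maximum achieved power reported.
    """
    if not 0 < target_power < 1:
        raise DataTableError("target_power must be in (0, 1)")
    ok = np.where(pc.avg_power >= target_power)[0]
    if len(ok) == 0:
        return None, float(pc.avg_power.max())
    i = int(ok[0])
    return int(pc.sample_sizes[i]), float(pc.avg_power[i])


def noncentral_t_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided two-sample equal-variance t-test
    at standardized effect d with n per group."""
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    crit = stats.t.isf(alpha / 2, df=df)
    return float(_two_sided_tail_nct(crit, df, np.array([ncp]))[0])


def solve_effect_for_power(target_power: float, n_per_group: int,
                           alpha: float = 0.05) -> float:
    """Standardized effect d whose two-sample t-test power equals the target."""
    return float(optimize.brentq(
        lambda d: noncentral_t_power(d, n_per_group, alpha) - target_power,
        1e-6, 10.0, xtol=1e-12))
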